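"""Synthetic annotation screens with planted ground truth.

The generator emulates the statistical shape of a whole-mount in-situ screen
over a four-stage window: structures fall into germ-layer-like groups that
share tissue types; restricted genes belong to one group's cohort and are
expressed — with a single contiguous true SWEP drawn from a per-group onset x
persistence distribution — in most structures of their home group and
occasionally elsewhere; a small fraction of genes is ubiquitous, a large
fraction silent; and each detected stage is independently lost with a small
false-negative probability, producing the occasional non-contiguous observed
pattern (1101, 1001) that the fill-in correction exists to repair. False
positives are off by default: in this assay spurious staining is far rarer
than missed detection.

Default composition mirrors the screen summary (~25% tissue-restricted,
~2% ubiquitous, the rest undetected); the default layout is the three planted
groups used throughout the tests: an ectoderm-like trio, a mesoderm-like pair
and an endoderm-like pair (7 structures).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from skbio import TreeNode

from .annotation_core import (
    SWEP,
    AnnotationMatrix,
    AnnotationRecord,
    GeneMeta,
    StageAxis,
    fill_in,
)
from .coexpression_pathways import PathwayMap
from .trends import TrendProfile, classify_trend

DEFAULT_GROUPS = {
    "ectoderm": ("NS", "OV", "eye"),
    "mesoderm": ("somites", "limb"),
    "endoderm": ("liver", "gut"),
}

# onset probabilities over stages / duration probabilities (truncated at the
# stage window's end and renormalised), one archetype per group
DEFAULT_ONSET = {
    "ectoderm": (0.70, 0.20, 0.07, 0.03),
    "mesoderm": (0.15, 0.35, 0.40, 0.10),
    "endoderm": (0.10, 0.20, 0.30, 0.40),
}
DEFAULT_DURATION = {
    "ectoderm": (0.45, 0.35, 0.15, 0.05),
    "mesoderm": (0.30, 0.40, 0.25, 0.05),
    "endoderm": (0.15, 0.15, 0.20, 0.50),
}
DEFAULT_TREND_ARCHETYPE = {
    "ectoderm": "early_peak_decline",
    "mesoderm": "mid_peak",
    "endoderm": "accumulating",
}

# gene-class proportions shaped like a metabolism screen's target list
DEFAULT_CLASS_WEIGHTS = {
    "Kinases": 215,
    "SUMO associated": 5,
    "Ubiquitin associated": 42,
    "Carriers/Transporters": 127,
    "GTPase and associated": 41,
    "Others": 1190,
}

DEFAULT_PATHWAY_CATEGORIES = (
    "carbohydrate",
    "amino_acid",
    "lipid",
    "glycan",
    "nucleotide",
    "energy",
    "cofactor_vitamin",
    "xenobiotic_degradation",
    "terpenoid_polyketide",
    "secondary_metabolite",
    "other_metabolism",
)


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; the defaults define the standard test conditions."""

    seed: int = 0
    stage_axis: StageAxis = field(default_factory=StageAxis)
    groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    n_genes_total: int = 400
    frac_ubiquitous: float = 0.02
    frac_silent: float = 0.727
    p_within: float = 0.6  # P(cohort gene expressed in each home-group structure)
    p_cross: float = 0.1  # P(cohort gene expressed in each foreign structure)
    p_dropout: float = 0.05  # per-(gene, structure, stage) false-negative rate
    onset_probs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ONSET)
    )
    duration_probs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_DURATION)
    )
    n_domains_per_structure: int = 2
    p_second_domain: float = 0.1
    frac_pathway_annotated: float = 0.6

    def __post_init__(self) -> None:
        for name, p in (
            ("frac_ubiquitous", self.frac_ubiquitous),
            ("frac_silent", self.frac_silent),
            ("p_within", self.p_within),
            ("p_cross", self.p_cross),
            ("p_dropout", self.p_dropout),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.frac_ubiquitous + self.frac_silent > 1.0:
            raise ValueError("ubiquitous + silent fractions exceed 1 (cohort oversubscription)")
        if self.n_genes_total < 1:
            raise ValueError("n_genes_total must be >= 1")
        missing = set(self.groups) - set(self.onset_probs)
        if missing:
            raise ValueError(f"groups without onset distribution: {sorted(missing)}")

    @property
    def structures(self) -> tuple[str, ...]:
        return tuple(s for g in self.groups.values() for s in g)


@dataclass
class SimTruth:
    """Planted ground truth: roles, cohorts, and noise-free SWEPs."""

    groups: dict[str, tuple[str, ...]]
    gene_role: dict[str, str]  # gene -> restricted | ubiquitous | silent
    gene_group: dict[str, Optional[str]]
    true_sweps: dict[tuple[str, str, Optional[str]], str]  # (gene, structure, domain) -> SWEP
    expected_trend: dict[str, str]  # structure -> planted trend archetype
    config: SimConfig

    def to_json(self) -> str:
        return json.dumps(
            {
                "groups": {g: list(s) for g, s in self.groups.items()},
                "gene_role": self.gene_role,
                "gene_group": self.gene_group,
                "true_sweps": {
                    f"{g}\t{s}\t{d or ''}": sw for (g, s, d), sw in self.true_sweps.items()
                },
                "expected_trend": self.expected_trend,
                "config": {
                    k: (list(v.labels) if isinstance(v, StageAxis) else v)
                    for k, v in asdict(self.config).items()
                },
            },
            indent=1,
            sort_keys=True,
        )


def _draw_swep(rng: np.random.Generator, onset_p, duration_p, K: int) -> SWEP:
    onset = int(rng.choice(K, p=np.asarray(onset_p) / np.sum(onset_p)))
    max_d = K - onset
    dp = np.asarray(duration_p[:max_d], dtype=float)
    duration = 1 + int(rng.choice(max_d, p=dp / dp.sum()))
    return SWEP(tuple(1 if onset <= i < onset + duration else 0 for i in range(K)))


def generate(config: SimConfig) -> tuple[AnnotationMatrix, SimTruth]:
    """Draw one synthetic screen; fully reproducible from ``config.seed``.

    Observed records differ from the planted truth only through stage-level
    dropout; records whose every detected stage is dropped are omitted, like
    a gene never scored in that structure.
    """
    rng = np.random.default_rng(config.seed)
    K = config.stage_axis.K
    structures = config.structures
    group_of_structure = {s: g for g, ss in config.groups.items() for s in ss}

    n = config.n_genes_total
    n_ubi = int(round(config.frac_ubiquitous * n))
    n_silent = int(round(config.frac_silent * n))
    n_restricted = n - n_ubi - n_silent
    if n_restricted < 0:
        raise ValueError("cohort oversubscription: ubiquitous + silent exceed total genes")

    width = len(str(n))
    genes = [f"g{i:0{width}d}" for i in range(1, n + 1)]
    roles = ["restricted"] * n_restricted + ["ubiquitous"] * n_ubi + ["silent"] * n_silent
    rng.shuffle(roles)  # roles are not correlated with gene id order

    class_names = list(DEFAULT_CLASS_WEIGHTS)
    class_p = np.array(list(DEFAULT_CLASS_WEIGHTS.values()), dtype=float)
    class_p /= class_p.sum()
    gene_classes = rng.choice(class_names, size=n, p=class_p)

    group_names = sorted(config.groups)
    gene_role: dict[str, str] = {}
    gene_group: dict[str, Optional[str]] = {}
    true_sweps: dict[tuple[str, str, Optional[str]], str] = {}
    records: list[AnnotationRecord] = []
    gene_meta: dict[str, GeneMeta] = {}

    full_span = SWEP(tuple([1] * K))

    def observe(gene: str, structure: str, domain: Optional[str], true_swep: SWEP) -> None:
        true_sweps[(gene, structure, domain)] = str(true_swep)
        bits = tuple(
            b if b == 0 or rng.random() >= config.p_dropout else 0 for b in true_swep.bits
        )
        if any(bits):
            records.append(AnnotationRecord(gene, structure, domain, SWEP(bits)))

    def domains_for(structure: str) -> list[str]:
        d1 = int(rng.integers(config.n_domains_per_structure)) + 1
        doms = [f"{structure}.d{d1}"]
        if config.n_domains_per_structure > 1 and rng.random() < config.p_second_domain:
            d2 = 1 + (d1 % config.n_domains_per_structure)
            doms.append(f"{structure}.d{d2}")
        return doms

    for idx, (gene, role) in enumerate(zip(genes, roles)):
        gene_role[gene] = role
        if role == "silent":
            gene_group[gene] = None
            gene_meta[gene] = GeneMeta(gene_classes[idx], "not-detected")
            continue
        if role == "ubiquitous":
            gene_group[gene] = None
            gene_meta[gene] = GeneMeta(gene_classes[idx], "ubiquitous")
            for s in structures:
                observe(gene, s, None, full_span)
            continue
        home = group_names[int(rng.integers(len(group_names)))]
        gene_group[gene] = home
        gene_meta[gene] = GeneMeta(gene_classes[idx], "tissue-restricted")
        swep = _draw_swep(
            rng, config.onset_probs[home], config.duration_probs[home], K
        )
        expressed = [
            s
            for s in structures
            if rng.random() < (config.p_within if group_of_structure[s] == home else config.p_cross)
        ]
        if not expressed:
            home_structs = config.groups[home]
            expressed = [home_structs[int(rng.integers(len(home_structs)))]]
        for s in expressed:
            for dom in domains_for(s):
                observe(gene, s, dom, swep)

    expected_trend = {
        s: DEFAULT_TREND_ARCHETYPE.get(group_of_structure[s], "unclassified")
        for s in structures
    }
    truth = SimTruth(dict(config.groups), gene_role, gene_group, true_sweps, expected_trend, config)
    return AnnotationMatrix(config.stage_axis, records, gene_meta), truth


def planted_pathway_map(config: SimConfig) -> PathwayMap:
    """Random pathway annotations over the simulated gene universe (a planted
    map for exercising the distribution/enrichment machinery; categories are
    not correlated with cohorts)."""
    rng = np.random.default_rng(config.seed + 104729)  # decorrelated stream
    width = len(str(config.n_genes_total))
    pm = PathwayMap()
    cats = list(DEFAULT_PATHWAY_CATEGORIES)
    for i in range(1, config.n_genes_total + 1):
        if rng.random() >= config.frac_pathway_annotated:
            continue
        g = f"g{i:0{width}d}"
        k = 1 + int(rng.random() < 0.25)  # a quarter of annotated genes span 2 categories
        for c in rng.choice(len(cats), size=k, replace=False):
            pm.major.setdefault(g, set()).add(cats[int(c)])
            pm.specific.setdefault(g, set()).add(f"{cats[int(c)]}:map{int(c) + 1:03d}")
    return pm


def _splits(tree: TreeNode) -> set[frozenset]:
    leaves = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        out.add(side)
        out.add(leaves - side)
    for t in tree.tips():
        out.add(frozenset([t.name]))
        out.add(leaves - frozenset([t.name]))
    return out


def planted_grouping_recovered(tree: TreeNode, groups: dict[str, tuple[str, ...]]) -> bool:
    """True when every planted structure group forms a clade of the unrooted
    tree (its leaf set is one side of some split)."""
    splits = _splits(tree)
    return all(frozenset(ss) in splits for ss in groups.values())


def truth_recovery_report(
    filled_matrix: AnnotationMatrix,
    tree: Optional[TreeNode],
    trend_labels: Optional[dict[str, str]],
    truth: SimTruth,
) -> dict:
    """Compare pipeline outputs against the planted truth.

    Reports (a) the fraction of true (gene, structure, domain) SWEPs exactly
    recovered after fill-in — endpoint-stage dropout shortens the observed
    run and is uncorrectable, so recovery < 1 exactly measures those cases;
    (b) whether the neighbor-joining tree makes every planted structure group
    monophyletic; (c) the planted-vs-observed trend label per structure.
    """
    unknown = set(g for g in filled_matrix.genes) - set(truth.gene_role)
    if unknown:
        raise ValueError(f"genes absent from truth: {sorted(unknown)[:5]}")
    observed = {r.key: str(r.swep) for r in filled_matrix.records}
    n_true = len(truth.true_sweps)
    n_recovered = sum(1 for k, sw in truth.true_sweps.items() if observed.get(k) == sw)
    report: dict = {
        "swep_recovery": n_recovered / n_true if n_true else 1.0,
        "n_true_records": n_true,
        "n_observed_records": len(filled_matrix.records),
    }
    if tree is not None:
        report["grouping_recovered"] = planted_grouping_recovered(tree, truth.groups)
    if trend_labels is not None:
        report["trend_confusion"] = {
            s: {"expected": truth.expected_trend.get(s), "observed": lab}
            for s, lab in sorted(trend_labels.items())
        }
    return report


def correctable_masks(true_swep: SWEP) -> tuple[int, int]:
    """Enumerate dropout outcomes for one contiguous SWEP: (#masks whose
    filled-in observation equals the truth, #total non-missing masks).

    A dropout mask is correctable by fill-in exactly when both endpoint
    detections survive; only internal losses are repaired. Used as an
    independent check of recovery-rate arithmetic.
    """
    ones = [i for i, b in enumerate(true_swep.bits) if b]
    total = correct = 0
    for mask in range(2 ** len(ones)):
        kept = [ones[i] for i in range(len(ones)) if not (mask >> i) & 1]
        if not kept:
            continue  # record omitted entirely, not scored
        total += 1
        bits = tuple(1 if i in kept else 0 for i in range(len(true_swep.bits)))
        if fill_in(SWEP(bits)) == true_swep:
            correct += 1
    return correct, total
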