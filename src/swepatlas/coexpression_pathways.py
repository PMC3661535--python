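"""Co-expression clusters, expression breadth, shared tissue signatures and
pathway-category distributions of co-expressed gene sets."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation_core import AnnotationMatrix, ParseError


@dataclass
class PathwayMap:
    """gene_id -> major metabolic-pathway categories and specific pathways.

    A gene may belong to several categories; genes absent from the map are
    "unannotated". Categories are data-driven from the supplied map (e.g. the
    major KEGG-style metabolism categories), never hard-coded.
    """

    major: dict[str, set[str]] = field(default_factory=dict)
    specific: dict[str, set[str]] = field(default_factory=dict)

    @property
    def categories(self) -> list[str]:
        return sorted(set().union(*self.major.values())) if self.major else []

    def categories_of(self, gene_id: str) -> set[str]:
        return self.major.get(gene_id, set())

    @classmethod
    def from_tsv(cls, tsv: IO[str] | str) -> "PathwayMap":
        """Columns: gene_id, major_category, specific_pathway (one row per
        mapping; specific_pathway may be empty)."""
        df = pd.read_csv(tsv, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in ("gene_id", "major_category") if c not in df.columns]
        if missing:
            raise ParseError(f"pathway map TSV missing columns: {missing}")
        pm = cls()
        for row in df.itertuples(index=False):
            pm.major.setdefault(row.gene_id, set()).add(row.major_category)
            sp = getattr(row, "specific_pathway", "")
            if sp:
                pm.specific.setdefault(row.gene_id, set()).add(sp)
        return pm


def breadth_table(matrix: AnnotationMatrix) -> pd.DataFrame:
    """Expression breadth per expressed gene.

    Returns one row per gene with ``n_structures`` (distinct structures with
    expression) and ``n_patterns`` (distinct (structure, domain) expression
    patterns; a structure scored without a named domain counts as one
    pattern). Threshold queries are plain DataFrame filters, e.g.
    ``table[table.n_structures >= 5]``.
    """
    rows = {}
    for r in matrix.records:
        st, pat = rows.setdefault(r.gene_id, (set(), set()))
        st.add(r.structure)
        pat.add((r.structure, r.domain))
    df = pd.DataFrame(
        [(g, len(st), len(pat)) for g, (st, pat) in sorted(rows.items())],
        columns=["gene_id", "n_structures", "n_patterns"],
    )
    return df


@dataclass(frozen=True)
class CoexpressionCluster:
    """Genes sharing one expression domain, partitioned by SWEP."""

    structure: str
    domain: Optional[str]
    genes: frozenset[str]
    partition: dict[str, frozenset[str]]


def coexpression_cluster(
    matrix: AnnotationMatrix,
    structure: str,
    domain_label: Optional[str],
    require_identical_swep: bool = True,
) -> CoexpressionCluster:
    """Genes annotated to one well-defined (structure, domain) pattern.

    With ``require_identical_swep`` the domain's genes are partitioned by
    SWEP and the largest class is returned as the cluster (ties broken by
    lexicographically smallest SWEP string); the full partition is kept on
    the result. Without it the cluster is every gene in the domain.
    """
    in_structure = matrix.records_in(structure)
    if not in_structure:
        raise KeyError(f"unknown structure {structure!r}")
    recs = [r for r in in_structure if r.domain == domain_label]
    if not recs and domain_label not in {r.domain for r in in_structure}:
        raise KeyError(f"unknown domain {domain_label!r} in structure {structure!r}")
    partition: dict[str, set[str]] = {}
    for r in recs:
        partition.setdefault(str(r.swep), set()).add(r.gene_id)
    frozen = {k: frozenset(v) for k, v in partition.items()}
    if not recs:
        genes: frozenset[str] = frozenset()
    elif require_identical_swep:
        best = max(frozen, key=lambda k: (len(frozen[k]), [-ord(c) for c in k]))
        genes = frozen[best]
    else:
        genes = frozenset(r.gene_id for r in recs)
    return CoexpressionCluster(structure, domain_label, genes, frozen)


def shared_signature(
    matrix: AnnotationMatrix,
    structures: Sequence[str],
    min_structures: Optional[int] = None,
) -> set[str]:
    """Genes expressed in at least ``min_structures`` of the listed structures
    (default: in all of them) — the shared signature of a tissue type that
    occurs in several embryonic structures."""
    if len(structures) < 2:
        raise ValueError("shared_signature needs at least 2 structures")
    need = len(structures) if min_structures is None else min_structures
    structs = set(structures)
    per_gene: dict[str, set[str]] = {}
    for r in matrix.records:
        if r.structure in structs:
            per_gene.setdefault(r.gene_id, set()).add(r.structure)
    return {g for g, ss in per_gene.items() if len(ss) >= need}


@dataclass(frozen=True)
class PathwayDistribution:
    counts: dict[str, int]
    fractions: dict[str, float]
    n_annotated: int
    n_unannotated: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c, self.counts[c], self.fractions[c]) for c in sorted(self.counts)],
            columns=["category", "count", "fraction"],
        )


def pathway_distribution(
    gene_set: Iterable[str], pathway_map: PathwayMap
) -> PathwayDistribution:
    """Distribution of a gene set over the major pathway categories.

    A gene belonging to several categories is counted once in each, so the
    category fractions may sum to more than 1. Fractions are over the
    annotated genes only; the unannotated count is reported separately
    (the "69 out of 127 annotated"-style bookkeeping).
    """
    genes = set(gene_set)
    counts = {c: 0 for c in pathway_map.categories}
    annotated = 0
    for g in sorted(genes):
        cats = pathway_map.categories_of(g)
        if cats:
            annotated += 1
            for c in cats:
                counts[c] = counts.get(c, 0) + 1
    fractions = {c: (n / annotated if annotated else 0.0) for c, n in counts.items()}
    return PathwayDistribution(counts, fractions, annotated, len(genes) - annotated)


def enrichment_test(
    gene_set: Iterable[str],
    category: str,
    pathway_map: PathwayMap,
    background: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation test for over-representation of one pathway category.

    Draws ``n_perm`` uniform samples of size ``|gene_set|`` (without
    replacement) from the background and reports the one-sided p-value
    ``(1 + #{permuted count >= observed}) / (1 + n_perm)``; never exactly
    zero, reproducible from ``seed``. This test is a convenience extra
    layered on top of the descriptive distribution analysis.
    """
    genes = sorted(set(gene_set))
    bg = sorted(set(background))
    if not set(genes) <= set(bg):
        raise ValueError("gene_set must be a subset of background")
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1 (>= 100 recommended), got {n_perm}")
    if category not in pathway_map.categories:
        raise KeyError(f"category {category!r} absent from pathway map")
    member = np.array([category in pathway_map.categories_of(g) for g in bg])
    observed = sum(category in pathway_map.categories_of(g) for g in genes)
    rng = np.random.default_rng(seed)
    k = len(genes)
    hits = 0
    for _ in range(n_perm):
        idx = rng.choice(len(bg), size=k, replace=False)
        if int(member[idx].sum()) >= observed:
            hits += 1
    return {"observed_count": observed, "p_value": (1 + hits) / (1 + n_perm), "n_perm": n_perm}
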