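"""Stage-wise acquisition-of-expression trends per embryonic structure.

For one structure the genes expressed there are decomposed, stage by stage,
into the *newly added* cohort (first detection at that stage) and the
*pre-existing* cohort (also detected at the previous stage). After fill-in
every SWEP is contiguous, so these two cohorts partition the stage total at
every stage after the first. A coarse rule-based classifier labels the
resulting profile with one of four acquisition trends observed in early
organogenesis (steadily accumulating gut-like profiles, early-peaking
ectoderm-like profiles, late surges of new genes as in the heart, and
mid-window peaks as in somites or liver).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .annotation_core import SWEP, AnnotationMatrix, enumerate_valid_sweps

TREND_LABELS = (
    "accumulating",
    "early_peak_decline",
    "mid_peak",
    "late_surge",
    "unclassified",
)


@dataclass(frozen=True)
class TrendProfile:
    """Per-structure stagewise accounting of expression acquisition.

    ``pre_existing[0]`` is ``None``: "also expressed at the previous stage"
    is undefined at the first stage, and is reported as absent rather than 0.
    """

    structure: str
    stage_labels: tuple[str, ...]
    totals: tuple[int, ...]
    newly_added: tuple[int, ...]
    pre_existing: tuple[Optional[int], ...]
    swep_partition: dict[str, int] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return sum(self.swep_partition.values())

    def to_dict(self) -> dict:
        return {
            "structure": self.structure,
            "stages": list(self.stage_labels),
            "totals": list(self.totals),
            "newly_added": list(self.newly_added),
            "pre_existing": list(self.pre_existing),
            "swep_partition": dict(self.swep_partition),
        }


def _profile_from_sweps(
    structure: str, stage_labels: tuple[str, ...], sweps: list[SWEP]
) -> TrendProfile:
    K = len(stage_labels)
    totals = [0] * K
    new = [0] * K
    pre: list[Optional[int]] = [None] + [0] * (K - 1)
    partition = {str(s): 0 for s in sorted(enumerate_valid_sweps(K))}
    for s in sweps:
        for i, b in enumerate(s.bits):
            totals[i] += b
        new[s.onset] += 1
        for i in range(1, K):
            if s.bits[i - 1] == 1 and s.bits[i] == 1:
                pre[i] += 1
        key = str(s)
        partition[key] = partition.get(key, 0) + 1
    return TrendProfile(structure, stage_labels, tuple(totals), tuple(new), tuple(pre), partition)


def trend_profile(
    matrix: AnnotationMatrix, structure: str, count_patterns: bool = False
) -> TrendProfile:
    """Stagewise totals / newly-added / pre-existing counts for a structure.

    By default genes are counted once per structure (domain SWEPs unioned);
    with ``count_patterns=True`` each distinct (gene, domain) expression
    pattern is counted separately, matching per-pattern tallies such as the
    2, 8, 20, 31 hind-limb pattern series. Fill-in must have been applied,
    which guarantees totals = newly_added + pre_existing at every stage >= 2.
    """
    if structure not in matrix.structures:
        raise KeyError(f"unknown structure {structure!r}; known: {matrix.structures}")
    if count_patterns:
        sweps = [r.swep for r in matrix.records_in(structure)]
    else:
        genes = {r.gene_id for r in matrix.records_in(structure)}
        sweps = [matrix.structure_swep(g, structure) for g in sorted(genes)]
    return _profile_from_sweps(structure, matrix.stage_axis.labels, sweps)


def embryo_trend_profile(matrix: AnnotationMatrix) -> TrendProfile:
    """Whole-embryo profile: each gene's SWEP is the union over all structures."""
    sweps = []
    for g in matrix.genes:
        u = None
        for s in matrix.structures:
            sw = matrix.structure_swep(g, s)
            if sw is not None:
                u = sw if u is None else u.union(sw)
        sweps.append(u)
    return _profile_from_sweps("embryo", matrix.stage_axis.labels, sweps)


def swep_partition(matrix: AnnotationMatrix, structure: str) -> dict[str, int]:
    """Partition of a structure's genes over the K(K+1)/2 valid SWEPs
    (zero-count classes included); sums to the structure's gene count."""
    return trend_profile(matrix, structure).swep_partition


def classify_trend(profile: TrendProfile, theta: float = 0.75) -> str:
    """Label an acquisition profile with one of four heuristic trends.

    The rules are an explicit operationalisation of verbally described
    trends, applied in fixed order (first match wins) and defined only for
    the four-stage design; other stage counts return "unclassified":

    1. accumulating — totals non-decreasing and newly-added non-decreasing
       from the second stage on (at the first stage newly-added equals the
       total by construction, so it is excluded from the monotonicity check).
    2. early_peak_decline — totals peak at stage 1 or 2 and the final total
       has dropped below ``theta`` times the peak.
    3. late_surge — more new genes arrive at the last stage than at the one
       before (checked only after the first two rules).
    4. mid_peak — totals peak at the third stage.
    """
    K = len(profile.totals)
    if K != 4:
        return "unclassified"
    totals = np.asarray(profile.totals)
    new = np.asarray(profile.newly_added)
    peak = int(np.argmax(totals))
    if np.all(np.diff(totals) >= 0) and np.all(np.diff(new[1:]) >= 0):
        return "accumulating"
    if peak in (0, 1) and totals[-1] < theta * totals[peak]:
        return "early_peak_decline"
    if new[-1] > new[-2]:
        return "late_surge"
    if peak == 2:
        return "mid_peak"
    return "unclassified"
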