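"""Tissue-tissue distances from identically co-expressed genes, and
neighbor-joining clustering of embryonic structures.

Two structures are compared through three counts: N_A and N_B, the numbers of
genes expressed in each structure, and C_AB, the number of genes expressed in
both with an *identical* stage-wise expression pattern (same onset stage, same
detected duration). Since C_AB <= min(N_A, N_B), any of the shipped formulas

    dice:  D = 1 - 2*C_AB / (N_A + N_B)
    max:   D = 1 - C_AB / max(N_A, N_B)
    geom:  D = 1 - C_AB^2 / (N_A * N_B)

maps the counts into [0, 1] with D = 0 exactly when N_A = N_B = C_AB (the two
structures express exactly the same genes, identically staged) and D = 1
exactly when C_AB = 0. The Dice form is the default; the algebra of the
original measure satisfies the same three constraints, so all compliant
variants are provided behind one flag.

The resulting structure x structure matrix is clustered with the Saitou-Nei
neighbor-joining algorithm into an unrooted tree in which the most similar
structures are nearest neighbours.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .annotation_core import AnnotationMatrix

logger = logging.getLogger(__name__)

FORMULAS: dict[str, Callable[[int, int, int], float]] = {
    "dice": lambda na, nb, c: 1.0 - 2.0 * c / (na + nb),
    "max": lambda na, nb, c: 1.0 - c / max(na, nb),
    "geom": lambda na, nb, c: 1.0 - (c * c) / (na * nb),
}


def genes_expressed(matrix: AnnotationMatrix, structure: str) -> set[str]:
    """Genes with at least one record in the structure (domains collapsed:
    a gene counts once per structure however many domains show it)."""
    if structure not in matrix.structures:
        raise KeyError(f"unknown structure {structure!r}; known: {matrix.structures}")
    return {r.gene_id for r in matrix.records if r.structure == structure}


def count_identical_sweps(matrix: AnnotationMatrix, a: str, b: str) -> int:
    """C_AB: genes expressed in both structures with equal per-structure SWEPs.

    The per-structure SWEP of a multi-domain gene is the positionwise union of
    its domain SWEPs. Fill-in is assumed to have been applied already.
    For a == b this equals ``len(genes_expressed(matrix, a))``.
    """
    shared = genes_expressed(matrix, a) & genes_expressed(matrix, b)
    return sum(
        1 for g in shared if matrix.structure_swep(g, a) == matrix.structure_swep(g, b)
    )


def pairwise_distance(n_a: int, n_b: int, c_ab: int, formula: str = "dice") -> float:
    """Distance D(A, B) from the co-expression counts, in [0, 1]."""
    if formula not in FORMULAS:
        raise KeyError(f"unknown formula {formula!r}; available: {sorted(FORMULAS)}")
    if n_a < 0 or n_b < 0 or c_ab < 0:
        raise ValueError("counts must be non-negative")
    if n_a == 0 or n_b == 0:
        raise ValueError(
            "distance undefined for a structure with no expressed genes "
            f"(N_A={n_a}, N_B={n_b})"
        )
    if c_ab > min(n_a, n_b):
        raise ValueError(f"C_AB={c_ab} exceeds min(N_A, N_B)={min(n_a, n_b)}")
    return FORMULAS[formula](n_a, n_b, c_ab)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric structure x structure distance matrix with zero diagonal."""

    structures: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "structures", tuple(self.structures))
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.structures)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.structures.index(pair[0]), self.structures.index(pair[1])
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.structures, columns=self.structures)

    def to_tsv(self) -> str:
        """Square TSV with a leading header row/column of structure names."""
        return self.to_frame().to_csv(sep="\t", index_label="structure")

    def to_phylip(self) -> str:
        """PHYLIP square format: count line, then name + row per structure."""
        lines = [f"{len(self.structures)}"]
        for name, row in zip(self.structures, self.values):
            lines.append(name + "\t" + "\t".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, tsv: str) -> "DistanceMatrix":
        df = pd.read_csv(io.StringIO(tsv), sep="\t", index_col=0)
        return cls(tuple(df.columns), df.to_numpy(dtype=float))


def build_distance_matrix(
    matrix: AnnotationMatrix,
    structures: Optional[Sequence[str]] = None,
    formula: str = "dice",
) -> DistanceMatrix:
    """All pairwise D(A, B) over the listed structures (default: all scored).

    Every structure must have at least one expressed gene; the distance is
    undefined (not 1) for empty structures, so offenders raise.
    """
    structs = tuple(structures) if structures is not None else tuple(matrix.structures)
    gene_sets = {s: genes_expressed(matrix, s) for s in structs}
    empty = [s for s in structs if not gene_sets[s]]
    if empty:
        raise ValueError(f"structures with zero expressed genes: {empty}")
    n = len(structs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = structs[i], structs[j]
            c = count_identical_sweps(matrix, a, b)
            d[i, j] = d[j, i] = pairwise_distance(len(gene_sets[a]), len(gene_sets[b]), c, formula)
    return DistanceMatrix(structs, d)


def _new_node(name_key: str, children: list[tuple[TreeNode, float]]) -> TreeNode:
    node = TreeNode()
    node._sort_key = name_key  # deterministic tie-break identity
    for child, length in children:
        child.length = length
        node.append(child)
    return node


def neighbor_joining(
    dm: DistanceMatrix, clamp_negative: bool = True
) -> TreeNode:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Returns an unrooted tree (represented with a trifurcating root) whose
    leaves are the structures. Pair selection minimises the Q criterion
    Q(i,j) = (n-2) d(i,j) - r_i - r_j; ties are broken by the lexicographic
    order of the sorted pair of node labels, with internal nodes labelled by
    the sorted concatenation of their leaf labels, so the output is fully
    deterministic. Negative branch lengths are clamped to zero with a warning
    unless ``clamp_negative=False``.

    Exact on additive matrices: the generating topology and branch lengths
    are recovered. ``n == 2`` is handled as a documented special case (a
    single edge with the distance split evenly); ``n < 2`` raises.
    """
    labels = list(dm.structures)
    n = len(labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 structures")

    def _len(x: float) -> float:
        if x < 0 and clamp_negative:
            logger.warning("clamping negative branch length %.6g to 0", x)
            return 0.0
        return x

    nodes: dict[str, TreeNode] = {}
    for lab in labels:
        leaf = TreeNode(name=lab)
        leaf._sort_key = lab
        nodes[lab] = leaf

    if n == 2:
        d = dm.values[0, 1]
        return _new_node("", [(nodes[labels[0]], _len(d / 2)), (nodes[labels[1]], _len(d / 2))])

    # work on a label-keyed copy of the matrix
    dist: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((labels[i], labels[j]))] = float(dm.values[i, j])
    active = sorted(labels)

    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist[frozenset((a, b))] for b in active if b != a) for a in active}
        best, best_pair = None, None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * dist[frozenset((a, b))] - r[a] - r[b]
                pair = tuple(sorted((a, b)))
                if best is None or q < best - 1e-12 or (abs(q - best) <= 1e-12 and pair < best_pair):
                    best, best_pair = q, pair
        a, b = best_pair
        d_ab = dist[frozenset((a, b))]
        la = d_ab / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lb = d_ab - la
        key = "".join(sorted(a + b))
        parent = _new_node(key, [(nodes[a], _len(la)), (nodes[b], _len(lb))])
        u = f"({key})"
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((u, c))] = (
                dist[frozenset((a, c))] + dist[frozenset((b, c))] - d_ab
            ) / 2
        nodes[u] = parent
        active = sorted([c for c in active if c not in (a, b)] + [u])

    # closed form for the final three nodes around the central vertex
    a, b, c = active
    dab, dac, dbc = (
        dist[frozenset((a, b))],
        dist[frozenset((a, c))],
        dist[frozenset((b, c))],
    )
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    return _new_node("", [(nodes[a], _len(la)), (nodes[b], _len(lb)), (nodes[c], _len(lc))])


def write_newick(tree: TreeNode, precision: int = 6) -> str:
    """Serialise to Newick with branch lengths at the given significant digits.

    Reparsing (e.g. via ``skbio.TreeNode.read``) yields an isomorphic tree.
    """

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            body = node.name or ""
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                body += node.name
        if node.length is not None:
            body += f":{node.length:.{precision}g}"
        return body

    return fmt(tree) + ";"


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text))
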