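"""Data model for stage-wise expression-pattern (SWEP) annotation screens.

An in-situ screen scores each gene in each embryonic structure (optionally in
a named sub-structure expression domain) at an ordered series of developmental
stages, yielding a binary presence vector per (gene, structure, domain): the
SWEP. Absence of expression at every stage is encoded by the *absence* of a
record, never by an all-zero SWEP. A biologically coherent SWEP is a single
contiguous run of detections; isolated internal misses (e.g. ``1101``) are
treated as experimental/annotation error and repaired by the fill-in
correction, which sets every stage between the first and last detection to 1.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations_with_replacement
from typing import IO, Iterable, Iterator, Optional

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("HH18", "HH22", "HH26", "HH28")

GENE_CLASSES = (
    "Kinases",
    "SUMO associated",
    "Ubiquitin associated",
    "Carriers/Transporters",
    "GTPase and associated",
    "Others",
)

CATEGORIES = ("tissue-restricted", "ubiquitous", "not-detected")


class AnnotationError(ValueError):
    """Base class for annotation-data contract violations."""


class ParseError(AnnotationError):
    """Malformed annotation input (bad header, unknown stage, bad value)."""


class ConflictError(AnnotationError):
    """The same (gene, structure, domain, stage) scored with both 0 and 1."""


class ConsistencyError(AnnotationError):
    """Metadata contradicts the records (e.g. 'not-detected' gene with records)."""


@dataclass(frozen=True)
class StageAxis:
    """Ordered, fixed stage list shared by every SWEP in a dataset."""

    labels: tuple[str, ...] = DEFAULT_STAGES

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) < 1:
            raise ValueError("stage axis needs at least one stage")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"stage labels must be unique, got {self.labels}")

    @property
    def K(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown stage label {label!r}; known: {self.labels}") from None


@dataclass(frozen=True, order=True)
class SWEP:
    """Binary detection vector over the ordered stages of a :class:`StageAxis`.

    ``bits[i] == 1`` means expression was detected at stage ``i``. A SWEP is
    *valid* when its 1s form one contiguous run with at least one detection.
    """

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", tuple(int(b) for b in self.bits))
        if not all(b in (0, 1) for b in self.bits):
            raise ValueError(f"SWEP bits must be 0/1, got {self.bits}")
        if len(self.bits) < 1:
            raise ValueError("SWEP must cover at least one stage")

    @classmethod
    def from_string(cls, s: str) -> "SWEP":
        return cls(tuple(int(c) for c in s))

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def any_detected(self) -> bool:
        return any(self.bits)

    @property
    def onset(self) -> Optional[int]:
        """0-based index of the first detected stage, or None if all-zero."""
        return self.bits.index(1) if self.any_detected else None

    @property
    def last(self) -> Optional[int]:
        return len(self.bits) - 1 - self.bits[::-1].index(1) if self.any_detected else None

    def is_valid(self) -> bool:
        """True when the 1s form a single contiguous run of length >= 1."""
        if not self.any_detected:
            return False
        return all(self.bits[i] == 1 for i in range(self.onset, self.last + 1))

    def union(self, other: "SWEP") -> "SWEP":
        if len(other) != len(self):
            raise ValueError("SWEP length mismatch")
        return SWEP(tuple(a | b for a, b in zip(self.bits, other.bits)))


def fill_in(swep: SWEP) -> SWEP:
    """Repair internal missed detections: set to 1 every stage strictly
    between the first and last detected stage.

    ``1101 -> 1111``, ``1001 -> 1111``; contiguous patterns (and the all-zero
    pattern) pass through unchanged, so the operation is idempotent and never
    clears a detection.
    """
    if not swep.any_detected:
        return swep
    lo, hi = swep.onset, swep.last
    bits = tuple(1 if lo <= i <= hi else b for i, b in enumerate(swep.bits))
    return SWEP(bits) if bits != swep.bits else swep


def enumerate_valid_sweps(K: int) -> set[SWEP]:
    """All SWEPs of length ``K`` whose detections form one contiguous run.

    There are K(K+1)/2 of them — each is determined by the (onset, offset)
    stage pair. For K = 4 this reduces the 2^4 = 16 conceivable patterns to 10
    once non-contiguous patterns are filled in and the all-absent pattern is
    excluded by design.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    out = set()
    for lo, hi in combinations_with_replacement(range(K), 2):
        out.add(SWEP(tuple(1 if lo <= i <= hi else 0 for i in range(K))))
    return out


@dataclass(frozen=True)
class AnnotationRecord:
    """One scored (gene, structure[, domain]) observation across all stages."""

    gene_id: str
    structure: str
    domain: Optional[str]
    swep: SWEP

    def __post_init__(self) -> None:
        if not self.swep.any_detected:
            raise ValueError(
                f"all-zero SWEP for ({self.gene_id}, {self.structure}, {self.domain}); "
                "absence of expression is encoded by absence of the record"
            )

    @property
    def key(self) -> tuple[str, str, Optional[str]]:
        return (self.gene_id, self.structure, self.domain)


@dataclass(frozen=True)
class GeneMeta:
    gene_class: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}; expected one of {CATEGORIES}")


@dataclass
class AnnotationMatrix:
    """The screen dataset: SWEP records plus optional per-gene metadata.

    At most one record per (gene, structure, domain) triple. ``gene_meta``
    maps gene_id -> :class:`GeneMeta` (gene class and expression category) and
    may cover genes with no records (the not-detected fraction of the screen).
    """

    stage_axis: StageAxis
    records: list[AnnotationRecord] = field(default_factory=list)
    gene_meta: Optional[dict[str, GeneMeta]] = None

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            dup = next(k for k, c in Counter(keys).items() if c > 1)
            raise ValueError(f"duplicate record for (gene, structure, domain) = {dup}")
        bad = [r for r in self.records if len(r.swep) != self.stage_axis.K]
        if bad:
            raise ValueError(f"SWEP length != {self.stage_axis.K} for record {bad[0].key}")
        if self.gene_meta is not None:
            missing = {r.gene_id for r in self.records} - set(self.gene_meta)
            if missing:
                raise ValueError(f"records for genes absent from gene_meta: {sorted(missing)[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AnnotationRecord]:
        return iter(self.records)

    @property
    def structures(self) -> list[str]:
        return sorted({r.structure for r in self.records})

    @property
    def genes(self) -> list[str]:
        return sorted({r.gene_id for r in self.records})

    def records_in(self, structure: str) -> list[AnnotationRecord]:
        return [r for r in self.records if r.structure == structure]

    def structure_swep(self, gene_id: str, structure: str) -> Optional[SWEP]:
        """Per-structure SWEP of a gene: positionwise union of its domain
        SWEPs (a gene counts as expressed at a stage if any domain shows it)."""
        sweps = [r.swep for r in self.records if r.gene_id == gene_id and r.structure == structure]
        if not sweps:
            return None
        out = sweps[0]
        for s in sweps[1:]:
            out = out.union(s)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format stage-level view (one row per detected or scored stage)."""
        rows = []
        for r in self.records:
            for stage, bit in zip(self.stage_axis.labels, r.swep.bits):
                rows.append((r.gene_id, r.structure, r.domain or "", stage, bit))
        return pd.DataFrame(rows, columns=["gene_id", "structure", "domain", "stage", "detected"])


REQUIRED_COLUMNS = ["gene_id", "structure", "domain", "stage", "detected"]


def parse_annotations(
    tsv: IO[str] | str,
    stage_axis: StageAxis | None = None,
    gene_meta: Optional[dict[str, GeneMeta]] = None,
) -> AnnotationMatrix:
    """Assemble an :class:`AnnotationMatrix` from a long-format annotation TSV.

    The TSV must carry the header ``gene_id structure domain stage detected``
    (domain may be empty). Rows for the same (gene, structure, domain) at
    different stages are merged into one SWEP; stages never mentioned are
    scored 0. Records that assemble to all-zero are dropped with a warning.

    Raises
    ------
    ParseError
        Missing columns, unknown stage label, or non-binary ``detected``.
    ConflictError
        Duplicate (gene, structure, domain, stage) rows that disagree.
    """
    axis = stage_axis or StageAxis()
    df = pd.read_csv(tsv, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"annotation TSV missing columns: {missing}")

    bits: dict[tuple[str, str, Optional[str]], list[int]] = {}
    seen: dict[tuple[str, str, Optional[str], str], int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        if row.stage not in axis.labels:
            raise ParseError(f"row {i}: unknown stage label {row.stage!r} (axis: {axis.labels})")
        if row.detected not in ("0", "1"):
            raise ParseError(f"row {i}: detected must be 0 or 1, got {row.detected!r}")
        det = int(row.detected)
        domain = row.domain or None
        key = (row.gene_id, row.structure, domain)
        skey = (*key, row.stage)
        if skey in seen:
            if seen[skey] != det:
                raise ConflictError(
                    f"row {i}: conflicting 'detected' for gene={row.gene_id} "
                    f"structure={row.structure} domain={domain} stage={row.stage}"
                )
            continue
        seen[skey] = det
        vec = bits.setdefault(key, [0] * axis.K)
        vec[axis.index(row.stage)] = det

    records = []
    for key, vec in bits.items():
        swep = SWEP(tuple(vec))
        if not swep.any_detected:
            logger.warning("dropping all-zero assembled SWEP for %s", key)
            continue
        records.append(AnnotationRecord(key[0], key[1], key[2], swep))
    return AnnotationMatrix(axis, records, gene_meta)


def parse_gene_meta(tsv: IO[str] | str) -> dict[str, GeneMeta]:
    """Read the gene metadata TSV: columns gene_id, gene_class, category."""
    df = pd.read_csv(tsv, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("gene_id", "gene_class", "category") if c not in df.columns]
    if missing:
        raise ParseError(f"gene metadata TSV missing columns: {missing}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ParseError(f"duplicate gene_id in metadata: {dup.iloc[0]!r}")
    return {
        row.gene_id: GeneMeta(row.gene_class, row.category) for row in df.itertuples(index=False)
    }


def annotation_tsv(matrix: AnnotationMatrix, detected_only: bool = True) -> str:
    """Render the matrix back to long-format TSV (round-trips through
    :func:`parse_annotations`). With ``detected_only`` only detected stages
    are written; missing stages are implicitly 0 on re-parse."""
    df = matrix.to_frame()
    if detected_only:
        df = df[df["detected"] == 1]
    df = df.sort_values(["gene_id", "structure", "domain", "stage"], kind="stable")
    return df.to_csv(sep="\t", index=False)


def gene_meta_tsv(gene_meta: dict[str, GeneMeta]) -> str:
    rows = [(g, m.gene_class, m.category) for g, m in sorted(gene_meta.items())]
    return pd.DataFrame(rows, columns=["gene_id", "gene_class", "category"]).to_csv(
        sep="\t", index=False
    )


def apply_fill_in(matrix: AnnotationMatrix) -> tuple[AnnotationMatrix, int]:
    """Apply the fill-in correction to every record; the input is unmodified.

    Returns the corrected matrix and the number of records whose SWEP changed,
    so the correction burden is reportable as a pipeline statistic.
    """
    corrected, n = [], 0
    for r in matrix.records:
        filled = fill_in(r.swep)
        if filled != r.swep:
            n += 1
            r = AnnotationRecord(r.gene_id, r.structure, r.domain, filled)
        corrected.append(r)
    return AnnotationMatrix(matrix.stage_axis, corrected, matrix.gene_meta), n


def _pct_half_up(numer: int, denom: int) -> float:
    """100*numer/denom rounded half-up to 1 decimal (printed-table convention)."""
    q = (Decimal(100) * Decimal(numer) / Decimal(denom)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass(frozen=True)
class ClassRow:
    n_investigated: int
    n_tissue_restricted: int
    pct_tissue_restricted: float
    n_ubiquitous: int


@dataclass(frozen=True)
class ClassSummary:
    """Per-gene-class screen summary plus the TOTAL row."""

    rows: dict[str, ClassRow]
    total: ClassRow

    def to_frame(self) -> pd.DataFrame:
        data = {**self.rows, "TOTAL": self.total}
        return pd.DataFrame(
            [
                (
                    name,
                    r.n_investigated,
                    r.n_tissue_restricted,
                    r.pct_tissue_restricted,
                    r.n_ubiquitous,
                )
                for name, r in data.items()
            ],
            columns=[
                "gene_class",
                "n_investigated",
                "n_tissue_restricted",
                "pct_tissue_restricted",
                "n_ubiquitous",
            ],
        )

    def to_dict(self) -> dict:
        f = self.to_frame()
        return {row["gene_class"]: {k: row[k] for k in f.columns if k != "gene_class"}
                for _, row in f.iterrows()}


def summarize_classes(
    matrix: AnnotationMatrix, class_order: Iterable[str] = GENE_CLASSES
) -> ClassSummary:
    """Tabulate, per gene class, how many genes were investigated and how many
    showed tissue-restricted vs ubiquitous expression.

    Counts come from the metadata table (category is an annotator's call, not
    recomputed); percentages are 100 * restricted / investigated, rounded
    half-up to one decimal. Genes with records must not be categorised
    'not-detected'.
    """
    if matrix.gene_meta is None:
        raise ConsistencyError("summarize_classes requires a gene metadata table")
    expressed = {r.gene_id for r in matrix.records}
    for g in sorted(expressed):
        if matrix.gene_meta[g].category == "not-detected":
            raise ConsistencyError(f"gene {g} has records but category 'not-detected'")

    by_class: dict[str, list[GeneMeta]] = {}
    for meta in matrix.gene_meta.values():
        by_class.setdefault(meta.gene_class, []).append(meta)

    order = [c for c in class_order if c in by_class]
    order += sorted(set(by_class) - set(order))
    rows: dict[str, ClassRow] = {}
    for cls in order:
        metas = by_class[cls]
        n_inv = len(metas)
        if n_inv == 0:  # pragma: no cover - unreachable via dict construction
            logger.warning("gene class %r has no investigated genes; omitted", cls)
            continue
        n_res = sum(m.category == "tissue-restricted" for m in metas)
        n_ubi = sum(m.category == "ubiquitous" for m in metas)
        rows[cls] = ClassRow(n_inv, n_res, _pct_half_up(n_res, n_inv), n_ubi)

    n_inv = sum(r.n_investigated for r in rows.values())
    n_res = sum(r.n_tissue_restricted for r in rows.values())
    n_ubi = sum(r.n_ubiquitous for r in rows.values())
    if n_inv == 0:
        raise ConsistencyError("no investigated genes in metadata")
    total = ClassRow(n_inv, n_res, _pct_half_up(n_res, n_inv), n_ubi)
    return ClassSummary(rows, total)
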