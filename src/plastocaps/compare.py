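"""Pairwise and multiple-alignment comparison of near-identical plastomes.

Implements the comparison statistics used for whole-plastome similarity
(gap-excluded identity, gap and SNP column counts) and specimen-specific
variant extraction from a multiple alignment: a variant is attributed to a
specimen when that row alone disagrees with the unanimous consensus of all
other rows.

The pairwise aligner is a global end-to-end alignment under unit costs
(match 0, mismatch 1, gap 1 per column), computed with Myers' bit-parallel
algorithm (edlib), which is optimal under that cost model for sequences of
any length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

from .seqio import GenomeRecord

__all__ = [
    "PairwiseAlignment",
    "PairwiseStats",
    "VariantEvent",
    "VariantScan",
    "align_pair",
    "pairwise_stats",
    "pairwise_variants",
    "msa_specimen_variants",
]


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences as gapped rows of equal length."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: int  # unit-cost edit distance

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")

    @property
    def columns(self) -> int:
        return len(self.aligned_a)


@dataclass(frozen=True)
class PairwiseStats:
    aligned_columns: int
    match_columns: int
    mismatch_columns: int
    gap_columns: int
    gap_events: int  # contiguous gap runs (openings), secondary to the bp count
    identity_pct: float  # gap-excluded, rounded half-up to 2 decimals

    def __post_init__(self) -> None:
        if self.match_columns + self.mismatch_columns + self.gap_columns != self.aligned_columns:
            raise ValueError("column accounting does not sum to aligned_columns")


@dataclass(frozen=True)
class VariantEvent:
    """A specimen-attributed substitution, insertion, or deletion."""

    specimen: str
    kind: str  # {"substitution", "insertion", "deletion"}
    alignment_column_start: int  # 0-based column of the first event column
    length: int
    allele: str  # the specimen's bases ('' for a deletion)
    background_allele: str  # the consensus bases ('' for an insertion)

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"bad kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.kind == "substitution" and len(self.allele) != len(self.background_allele):
            raise ValueError("substitution alleles must have equal length")


@dataclass
class VariantScan:
    """Specimen-specific events plus the count of ambiguous (multi-way) columns."""

    events: list[VariantEvent]
    ambiguous_columns: int = 0
    ambiguous_positions: list[int] = field(default_factory=list)


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def align_pair(a: GenomeRecord | str, b: GenomeRecord | str, k: int = -1) -> PairwiseAlignment:
    """Globally align two sequences end-to-end under unit costs.

    Circular genome records should be canonically rotated first (see
    :mod:`plastocaps.quadripartite`) so that origin placement cannot create
    spurious terminal gaps.
    """
    id_a, seq_a = (a.id, a.sequence) if isinstance(a, GenomeRecord) else ("a", a.upper())
    id_b, seq_b = (b.id, b.sequence) if isinstance(b, GenomeRecord) else ("b", b.upper())
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    res = edlib.align(seq_a, seq_b, mode="NW", task="path", k=k)
    rows_a: list[str] = []
    rows_b: list[str] = []
    ia = ib = 0
    for count, op in _CIGAR_RE.findall(res["cigar"]):
        c = int(count)
        if op in "=XM":
            rows_a.append(seq_a[ia : ia + c])
            rows_b.append(seq_b[ib : ib + c])
            ia += c
            ib += c
        elif op == "I":  # bases of query (a) absent from target (b)
            rows_a.append(seq_a[ia : ia + c])
            rows_b.append("-" * c)
            ia += c
        elif op == "D":
            rows_a.append("-" * c)
            rows_b.append(seq_b[ib : ib + c])
            ib += c
    return PairwiseAlignment(
        id_a=id_a,
        id_b=id_b,
        aligned_a="".join(rows_a),
        aligned_b="".join(rows_b),
        score=res["editDistance"],
    )


def pairwise_stats(alignment: PairwiseAlignment) -> PairwiseStats:
    """Column accounting and gap-excluded percent identity.

    ``identity_pct = 100 * match / (match + mismatch)`` — gap columns are
    excluded from the identity denominator, so a pair differing only by
    indels still reports 100.00.
    """
    aa, bb = alignment.aligned_a, alignment.aligned_b
    match = mismatch = gaps = gap_events = 0
    in_gap = False
    for x, y in zip(aa, bb):
        if x == "-" or y == "-":
            gaps += 1
            if not in_gap:
                gap_events += 1
                in_gap = True
        else:
            in_gap = False
            if x == y:
                match += 1
            else:
                mismatch += 1
    denom = match + mismatch
    pct = 100.0 if denom == 0 else 100.0 * match / denom
    # round half-up to 2 decimals
    pct = int(pct * 100 + 0.5) / 100
    return PairwiseStats(
        aligned_columns=len(aa),
        match_columns=match,
        mismatch_columns=mismatch,
        gap_columns=gaps,
        gap_events=gap_events,
        identity_pct=pct,
    )


def pairwise_variants(alignment: PairwiseAlignment) -> list[VariantEvent]:
    """Events in which sequence A differs from sequence B, A as the specimen."""
    scan = msa_specimen_variants(
        [
            (alignment.id_a, alignment.aligned_a),
            (alignment.id_b, alignment.aligned_b),
            (alignment.id_b + "#bg1", alignment.aligned_b),
            (alignment.id_b + "#bg2", alignment.aligned_b),
        ]
    )
    return [e for e in scan.events if e.specimen == alignment.id_a]


def msa_specimen_variants(rows: list[tuple[str, str]]) -> VariantScan:
    """Extract specimen-specific variants from a multiple alignment.

    ``rows`` is a list of ``(id, aligned_sequence)`` with equal column
    counts, N >= 3. A column contributes to an event when exactly one row
    disagrees with the unanimous consensus of all other rows; maximal
    adjacent runs of the same (specimen, kind) merge into one event.
    Columns where two or more rows disagree with each other and the rest
    are counted as ambiguous, never silently dropped.
    """
    if len(rows) < 3:
        raise ValueError("msa_specimen_variants requires N >= 3 rows")
    ids = [r[0] for r in rows]
    seqs = [r[1].upper() for r in rows]
    ncol = len(seqs[0])
    if any(len(s) != ncol for s in seqs):
        raise ValueError("alignment rows differ in column count")

    # per-column classification: (specimen_index, kind) or None or "ambiguous"
    events: list[VariantEvent] = []
    ambiguous: list[int] = []
    run_key: tuple[int, str] | None = None
    run_start = 0
    run_allele: list[str] = []
    run_background: list[str] = []

    def flush() -> None:
        nonlocal run_key
        if run_key is None:
            return
        idx, kind = run_key
        events.append(
            VariantEvent(
                specimen=ids[idx],
                kind=kind,
                alignment_column_start=run_start,
                length=len(run_allele) if kind != "deletion" else len(run_background),
                allele="".join(run_allele),
                background_allele="".join(run_background),
            )
        )
        run_key = None

    for col in range(ncol):
        column = [s[col] for s in seqs]
        distinct = set(column)
        if len(distinct) == 1:
            flush()
            continue
        if len(distinct) > 2:
            flush()
            ambiguous.append(col)
            continue
        x, y = distinct
        carriers_x = [i for i, c in enumerate(column) if c == x]
        carriers_y = [i for i, c in enumerate(column) if c == y]
        if len(carriers_x) == 1:
            idx, minor, major = carriers_x[0], x, y
        elif len(carriers_y) == 1:
            idx, minor, major = carriers_y[0], y, x
        else:
            flush()
            ambiguous.append(col)
            continue
        if minor == "-":
            kind = "deletion"
            allele_piece, bg_piece = "", major
        elif major == "-":
            kind = "insertion"
            allele_piece, bg_piece = minor, ""
        else:
            kind = "substitution"
            allele_piece, bg_piece = minor, major
        if run_key == (idx, kind):
            run_allele.append(allele_piece)
            run_background.append(bg_piece)
        else:
            flush()
            run_key = (idx, kind)
            run_start = col
            run_allele = [allele_piece]
            run_background = [bg_piece]
    flush()
    return VariantScan(events=events, ambiguous_columns=len(ambiguous), ambiguous_positions=ambiguous)
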