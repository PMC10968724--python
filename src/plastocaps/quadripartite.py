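"""Quadripartite plastome structure: IR detection, partitioning, junctions.

A typical plastome is a circle tiled by four regions — large single copy
(LSC), inverted repeat b (IRb), small single copy (SSC), inverted repeat a
(IRa) — where IRb and IRa are exact reverse complements of each other.
This module finds the IR pair, labels the four regions, rotates records
into a canonical origin, and reports signed gene-to-junction distances.

Intervals are ``(start, end)`` in 0-based coordinates; on circular records
``end`` may exceed the genome length to denote wrap-around.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .seqio import Feature, GenomeRecord, revcomp

__all__ = [
    "QuadripartitePartition",
    "JunctionGene",
    "JunctionReport",
    "InvalidPartitionError",
    "find_inverted_repeat",
    "partition_genome",
    "canonical_rotation",
    "junction_report",
    "rotate_record",
    "flip_record",
]

JUNCTION_NAMES = ("LSC/IRb", "IRb/SSC", "SSC/IRa", "IRa/LSC")

_COMP = str.maketrans("ACGTN", "TGCAN")


class InvalidPartitionError(ValueError):
    pass


def _slice_circ(seq: str, start: int, end: int) -> str:
    """Slice [start, end) allowing end > len(seq) (wrap) on a circle."""
    n = len(seq)
    start %= n
    length = end - start if end >= start else end + n - start
    if start + length <= n:
        return seq[start : start + length]
    return seq[start:] + seq[: start + length - n]


@dataclass(frozen=True)
class QuadripartitePartition:
    """The LSC/IRb/SSC/IRa intervals of one plastome."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int

    @property
    def lengths(self) -> tuple[int, int, int, int]:
        return tuple(e - s for s, e in (self.lsc, self.irb, self.ssc, self.ira))

    @property
    def junctions(self) -> dict[str, int]:
        """Junction positions (0-based, mod genome length), in canonical order."""
        n = self.genome_length
        return {
            "LSC/IRb": self.lsc[1] % n,
            "IRb/SSC": self.irb[1] % n,
            "SSC/IRa": self.ssc[1] % n,
            "IRa/LSC": self.ira[1] % n,
        }

    def validate(self, record: GenomeRecord) -> None:
        n = self.genome_length
        if n != len(record):
            raise InvalidPartitionError("partition built for a different genome length")
        l_lsc, l_irb, l_ssc, l_ira = self.lengths
        if l_lsc + l_irb + l_ssc + l_ira != n:
            raise InvalidPartitionError(
                f"regions do not tile the genome: {self.lengths} vs length {n}"
            )
        if l_irb != l_ira:
            raise InvalidPartitionError(f"IR copies differ in length: {l_irb} vs {l_ira}")
        if l_ssc > l_lsc:
            raise InvalidPartitionError("SSC longer than LSC")
        irb_seq = _slice_circ(record.sequence, *self.irb)
        ira_seq = _slice_circ(record.sequence, *self.ira)
        if irb_seq != revcomp(ira_seq):
            raise InvalidPartitionError("IRb is not the exact reverse complement of IRa")


@dataclass(frozen=True)
class JunctionGene:
    junction: str
    junction_position: int  # 0-based position of the boundary
    gene: str
    distance: int | None  # signed bp; negative = straddles; None = gene absent


@dataclass
class JunctionReport:
    entries: list[JunctionGene]

    def for_gene(self, junction: str, gene: str) -> int | None:
        for e in self.entries:
            if e.junction == junction and e.gene == gene:
                return e.distance
        raise KeyError(f"{gene} not reported at {junction}")


# ---------------------------------------------------------------------------
# IR detection
# ---------------------------------------------------------------------------


def _extend_pair(seq: str, a: int, b: int, length: int, circular: bool) -> tuple[int, int, int]:
    """Maximally extend an inverted-repeat arm pair.

    Arms are ``[a, a+length)`` and ``[b, b+length)`` with
    ``seq[a+t] == complement(seq[b+length-1-t])``. Returns the maximal
    ``(a, b, length)``; on circles indices are mod ``n``.
    """
    n = len(seq)
    comp = seq.translate(_COMP)

    def at(i: int) -> str:
        return seq[i % n] if circular else (seq[i] if 0 <= i < n else "\0")

    def cat(i: int) -> str:
        return comp[i % n] if circular else (comp[i] if 0 <= i < n else "\1")

    # grow left end of A together with right end of B
    while length < n // 2 and at(a - 1) == cat(b + length):
        # stop if the two arms would collide on the circle
        if (a - 1) % n == (b + length) % n or (b + length) % n == a % n:
            break
        a -= 1
        length += 1
    # grow right end of A together with left end of B
    while length < n // 2 and at(a + length) == cat(b - 1):
        if (a + length) % n == (b - 1) % n or (a + length) % n == b % n:
            break
        b -= 1
        length += 1
    return a % n if circular else a, b % n if circular else b, length


def _arms_disjoint(a: int, b: int, length: int, n: int) -> bool:
    """True when circle intervals [a, a+length) and [b, b+length) do not overlap."""
    pa = {(a + t) % n for t in range(length)}
    pb = {(b + t) % n for t in range(length)}
    return not (pa & pb)


def _gap_lengths(a: int, b: int, length: int, n: int) -> tuple[int, int]:
    """Lengths of the two single-copy gaps between arm A and arm B on the circle."""
    end_a = (a + length) % n
    end_b = (b + length) % n
    gap_ab = (b - end_a) % n
    gap_ba = (a - end_b) % n
    return gap_ab, gap_ba


def find_inverted_repeat(
    record: GenomeRecord, min_len: int = 1000, seed_k: int = 25
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Locate the longest pair of exact, non-overlapping inverted repeats.

    Seeds exact ``seed_k``-mers against the reverse complement and extends
    each hit maximally; among maximal pairs of the greatest length, prefers
    the pair maximizing the shorter single-copy gap, then the lowest start.
    Returns ``((a_start, a_end), (b_start, b_end))`` ordered by start, or
    ``None`` when no pair reaches ``min_len``.
    """
    if min_len < 50:
        raise ValueError("min_len must be >= 50")
    n = len(record)
    if n < 2 * min_len:
        raise ValueError(f"record length {n} < 2*min_len ({2 * min_len})")
    seq = record.sequence
    k = min(seed_k, min_len)
    circular = record.circular
    dseq = seq + seq[: k - 1] if circular else seq

    index: dict[str, list[int]] = {}
    for j in range(n if circular else n - k + 1):
        index.setdefault(dseq[j : j + k], []).append(j)

    found: dict[int, list[tuple[int, int, int]]] = {}
    candidates: list[tuple[int, int, int]] = []

    def seed_covered(i: int, j: int, g: int) -> bool:
        for a, b, length in found.get(g, []):
            off_i = (i - a) % n if circular else i - a
            off_j = (j - b) % n if circular else j - b
            if 0 <= off_i <= length - k and 0 <= off_j <= length - k:
                return True
        return False

    for i in range(n if circular else n - k + 1):
        kmer = dseq[i : i + k]
        rc = revcomp(kmer)
        for j in index.get(rc, ()):
            if j == i and not circular:
                continue
            g = (i + j + k) % n if circular else i + j + k
            if seed_covered(i, j, g):
                continue
            a, b, length = _extend_pair(seq, i, j, k, circular)
            found.setdefault(g, []).append((a, b, length))
            if length >= min_len and _arms_disjoint(a, b, length, n):
                candidates.append((a, b, length))

    if not candidates:
        return None

    def canonical(c: tuple[int, int, int]) -> tuple[int, int, int]:
        a, b, length = c
        return (min(a, b), max(a, b), length) if a != b else c

    best: tuple[int, int, int] | None = None
    best_key: tuple | None = None
    for c in {canonical(c) for c in candidates}:
        a, b, length = c
        gaps = _gap_lengths(a, b, length, n)
        key = (length, min(gaps), -a)
        if best_key is None or key > best_key:
            best, best_key = c, key
    a, b, length = best
    return (a, a + length), (b, b + length)


# ---------------------------------------------------------------------------
# Partitioning and rotation
# ---------------------------------------------------------------------------


def partition_genome(
    record: GenomeRecord, ir_pair: tuple[tuple[int, int], tuple[int, int]]
) -> QuadripartitePartition:
    """Label LSC/IRb/SSC/IRa from a detected IR pair.

    The longer single-copy gap is the LSC (tie: the gap following the
    first-encountered arm, with a warning); IRb is the IR copy immediately
    downstream of the LSC.
    """
    n = len(record)
    (a0, a1), (b0, b1) = ir_pair
    length = a1 - a0
    if b1 - b0 != length:
        raise InvalidPartitionError("IR arms differ in length")
    if not _arms_disjoint(a0, b0, length, n):
        raise InvalidPartitionError("IR arms overlap")

    gap_ab, gap_ba = _gap_lengths(a0, b0, length, n)
    # gap_ab runs from end of arm A to start of arm B
    if gap_ab == gap_ba:
        warnings.warn(
            "single-copy regions have equal length; labeling first-encountered as LSC",
            stacklevel=2,
        )
        lsc_start, lsc_len = (a0 + length) % n, gap_ab
        irb, ira = (b0, b1), (a0, a1)
        ssc_start, ssc_len = (b0 + length) % n, gap_ba
    elif gap_ab > gap_ba:
        lsc_start, lsc_len = (a0 + length) % n, gap_ab
        irb, ira = (b0, b1), (a0, a1)
        ssc_start, ssc_len = (b0 + length) % n, gap_ba
    else:
        lsc_start, lsc_len = (b0 + length) % n, gap_ba
        irb, ira = (a0, a1), (b0, b1)
        ssc_start, ssc_len = (a0 + length) % n, gap_ab

    part = QuadripartitePartition(
        lsc=(lsc_start, lsc_start + lsc_len),
        irb=(irb[0] % n, irb[0] % n + length),
        ssc=(ssc_start, ssc_start + ssc_len),
        ira=(ira[0] % n, ira[0] % n + length),
        genome_length=n,
    )
    part.validate(record)
    return part


def _remap_part(part: tuple[int, int], shift: int, n: int) -> list[tuple[int, int]]:
    s, e = part
    ns, ne = (s - shift) % n, (e - shift) % n or n
    if ns < ne:
        return [(ns, ne)]
    return [(ns, n), (0, ne)]  # wrapped: split


def rotate_record(record: GenomeRecord, shift: int) -> GenomeRecord:
    """Rotate a circular record so old position ``shift`` becomes position 0."""
    n = len(record)
    shift %= n
    seq = record.sequence[shift:] + record.sequence[:shift]
    feats = []
    for f in record.features:
        parts: list[tuple[int, int]] = []
        for p in f.parts:
            parts.extend(_remap_part(p, shift, n))
        feats.append(Feature(name=f.name, kind=f.kind, strand=f.strand, parts=tuple(parts)))
    return GenomeRecord(id=record.id, sequence=seq, circular=record.circular, features=feats)


def flip_record(record: GenomeRecord) -> GenomeRecord:
    """Reverse-complement a record, remapping features."""
    n = len(record)
    seq = revcomp(record.sequence)
    feats = []
    for f in record.features:
        parts = tuple(sorted((n - e, n - s) for s, e in f.parts))
        strand = "-" if f.strand == "+" else "+"
        feats.append(Feature(name=f.name, kind=f.kind, strand=strand, parts=parts))
    return GenomeRecord(id=record.id, sequence=seq, circular=record.circular, features=feats)


def _nearest_end_dist(record: GenomeRecord, gene: Feature, pos: int) -> int:
    n = len(record)
    best = n
    for s, e in gene.parts:
        for x in (s, e):
            d = min((x - pos) % n, (pos - x) % n)
            best = min(best, d)
    return best


def canonical_rotation(
    record: GenomeRecord, partition: QuadripartitePartition | None = None
) -> GenomeRecord:
    """Rotate (and possibly flip) so position 0 is the LSC start.

    Orientation is chosen so that *rps19*, when annotated, lies near the
    LSC/IRb junction; unannotated records take the lexicographically
    smaller of the two candidate sequences. Idempotent.
    """
    if partition is None:
        pair = find_inverted_repeat(record, min_len=max(50, min(1000, len(record) // 8)))
        if pair is None:
            raise InvalidPartitionError("no inverted repeat found; cannot canonicalize")
        partition = partition_genome(record, pair)

    fwd = rotate_record(record, partition.lsc[0] % len(record))
    flipped = flip_record(record)
    pair_f = find_inverted_repeat(flipped, min_len=max(50, partition.lengths[1] // 2))
    rev = rotate_record(flipped, partition_genome(flipped, pair_f).lsc[0] % len(record))

    lsc_len = partition.lengths[0]
    rps19_fwd = fwd.feature_by_name("rps19")
    rps19_rev = rev.feature_by_name("rps19")
    if rps19_fwd is not None and rps19_rev is not None:
        d_fwd = _nearest_end_dist(fwd, rps19_fwd, lsc_len)
        d_rev = _nearest_end_dist(rev, rps19_rev, lsc_len)
        return fwd if d_fwd <= d_rev else rev
    return fwd if fwd.sequence <= rev.sequence else rev


# ---------------------------------------------------------------------------
# Junction reporting
# ---------------------------------------------------------------------------


def _gene_distance(record: GenomeRecord, gene: Feature, pos: int) -> int:
    """Signed distance from a gene to a junction at ``pos``.

    Negative: the gene straddles the junction, extending ``|d|`` bp beyond
    it (the shorter of the two split pieces). Positive: nearest gene end is
    ``d`` bp from the junction. Zero: an end coincides with the junction.
    """
    n = len(record)
    for s, e in gene.parts:
        # circle-aware containment with pos strictly inside (s, e)
        off = (pos - s) % n
        if 0 < off < (e - s) % n or (s < pos < e):
            left = off
            right = ((e - s) % n or (e - s)) - off
            return -min(left, right)
    return _nearest_end_dist(record, gene, pos)


def junction_report(
    record: GenomeRecord,
    partition: QuadripartitePartition,
    genes_of_interest: list[str] | None = None,
) -> JunctionReport:
    """Signed gene-to-junction distances for the four region boundaries.

    With no ``genes_of_interest``, reports the nearest gene on each side of
    every junction plus any gene straddling it. A requested gene absent
    from the annotation is reported with distance ``None``.
    """
    partition.validate(record)
    n = len(record)
    genes = [f for f in record.features if f.kind in ("gene", "tRNA", "rRNA")]
    entries: list[JunctionGene] = []

    for jname, pos in partition.junctions.items():
        if genes_of_interest is not None:
            for gname in genes_of_interest:
                g = record.feature_by_name(gname)
                d = None if g is None else _gene_distance(record, g, pos)
                entries.append(JunctionGene(jname, pos, gname, d))
            continue
        # default: nearest gene upstream, nearest downstream, any straddler
        chosen: dict[str, int] = {}
        straddlers = [g for g in genes if _gene_distance(record, g, pos) < 0]
        for g in straddlers:
            chosen[g.name] = _gene_distance(record, g, pos)
        for side in (+1, -1):
            best: tuple[int, Feature] | None = None
            for g in genes:
                if g.name in chosen:
                    continue
                ends = [x for s, e in g.parts for x in (s, e)]
                d = min(((x - pos) % n if side > 0 else (pos - x) % n) for x in ends)
                if best is None or d < best[0]:
                    best = (d, g)
            if best is not None:
                chosen.setdefault(best[1].name, _gene_distance(record, best[1], pos))
        for gname, d in sorted(chosen.items(), key=lambda kv: abs(kv[1])):
            entries.append(JunctionGene(jname, pos, gname, d))
    return JunctionReport(entries)
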