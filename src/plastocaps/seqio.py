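"""Sequence and feature I/O: FASTA, GenBank flat files, allele tables.

All coordinates are 0-based half-open internally; user-facing reports are
1-based inclusive (GenBank convention). Sequences are uppercase DNA over
``{A, C, G, T, N}``; ``U`` is mapped to ``T`` on input so tRNA-annotated
records and primers share one alphabet.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeRecord",
    "Feature",
    "AlleleRecord",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "read_allele_table",
    "revcomp",
]

SEQ_ALPHABET = set("ACGTN")

_IUPAC_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)
_IUPAC = set("ACGTUNRYSWKMBDHV")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class Feature:
    """An annotated element of a genome.

    ``parts`` is an ordered list of ``[start, end)`` intervals; a feature
    wrapping the circular origin is split into two parts.
    """

    name: str
    kind: str  # one of {"gene", "tRNA", "rRNA", "other"}
    strand: str  # "+" or "-"
    parts: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.parts:
            raise ValueError(f"feature {self.name!r} has no parts")
        for s, e in self.parts:
            if not s < e:
                raise ValueError(f"feature {self.name!r}: empty interval [{s},{e})")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name!r}: bad strand {self.strand!r}")

    @property
    def start(self) -> int:
        return self.parts[0][0]

    @property
    def end(self) -> int:
        return self.parts[-1][1]

    def length(self) -> int:
        return sum(e - s for s, e in self.parts)


@dataclass
class GenomeRecord:
    """A (possibly circular) annotated nucleotide sequence."""

    id: str
    sequence: str
    circular: bool = False
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - SEQ_ALPHABET
        if bad:
            raise ValueError(f"record {self.id!r}: non-ACGTN characters {sorted(bad)}")
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.parts:
                if not (0 <= s < e <= n):
                    raise ValueError(
                        f"feature {f.name!r} interval [{s},{e}) outside [0,{n})"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_by_name(self, name: str) -> Feature | None:
        for f in self.features:
            if f.name == name:
                return f
        return None

    def gc_percent(self) -> float:
        gc = sum(self.sequence.count(b) for b in "GC")
        return 100.0 * gc / len(self.sequence)


@dataclass
class AlleleRecord:
    """One genotyping-panel entry: a cultivar and its printed sequence window."""

    index: int
    name: str
    sequence_window: str
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence_window:
            raise ValueError(f"panel entry {self.name!r}: empty sequence window")

    def ungapped(self) -> str:
        return self.sequence_window.replace("-", "")


def revcomp(seq: str) -> str:
    """Reverse complement with full IUPAC degenerate support."""
    bad = set(seq.upper()) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq.translate(_IUPAC_COMPLEMENT)[::-1]


def _normalize_seq(raw: str, where: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - SEQ_ALPHABET
    if bad:
        raise ParseError(f"{where}: non-IUPAC characters {sorted(bad)}")
    return seq


def read_fasta(path: str | Path, circular_token: str = "circular") -> list[GenomeRecord]:
    """Read a multi-entry FASTA file into :class:`GenomeRecord` objects.

    The ``circular`` flag is set when the header line contains
    ``circular_token`` (case-insensitive).
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    with open(path) as fh:
        header: str | None = None
        chunks: list[str] = []
        lineno_of_header = 0

        def flush() -> None:
            if header is None:
                return
            seq = "".join(chunks)
            if not seq:
                raise ParseError(f"{path}:{lineno_of_header}: entry {header!r} has no sequence")
            rid = header.split()[0]
            circ = circular_token.lower() in header.lower()
            records.append(GenomeRecord(id=rid, sequence=seq, circular=circ))

        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                lineno_of_header = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"{path}:{lineno}: sequence before first '>' header")
                chunks.append(_normalize_seq(line, f"{path}:{lineno}"))
        flush()
    if not records:
        raise ParseError(f"{path}: no FASTA entries found")
    return records


def write_fasta(records: list[GenomeRecord] | GenomeRecord, path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA; circular records get a 'circular' header token."""
    if isinstance(records, GenomeRecord):
        records = [records]
    with open(path, "w") as fh:
        for rec in records:
            tag = " circular" if rec.circular else ""
            fh.write(f">{rec.id}{tag}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_KIND_MAP = {"gene": "gene", "tRNA": "tRNA", "rRNA": "rRNA"}


def _feature_name(bf) -> str:
    for key in ("gene", "standard_name", "locus_tag", "product"):
        if key in bf.qualifiers:
            return bf.qualifiers[key][0]
    return bf.type


def read_genbank(path: str | Path) -> GenomeRecord:
    """Read one GenBank flat-file record.

    GenBank 1-based inclusive locations (including ``join``/``complement``)
    are converted to 0-based half-open :class:`Feature` parts. CDS features
    are folded into their parent gene; gene/tRNA/rRNA types are kept, other
    feature types map to kind ``other`` (``source`` is dropped).
    """
    path = Path(path)
    try:
        bio = _BioSeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: not a parseable GenBank record ({exc})") from exc
    if len(bio.seq) == 0:
        raise ParseError(f"{path}: GenBank record has no ORIGIN sequence")
    seq = _normalize_seq(str(bio.seq), str(path))
    circular = bio.annotations.get("topology", "") == "circular"

    features: list[Feature] = []
    seen: set[tuple] = set()
    for bf in bio.features:
        if bf.type in ("source", "CDS", "exon", "intron", "misc_feature"):
            continue
        kind = _KIND_MAP.get(bf.type, "other")
        loc = bf.location
        if isinstance(loc, CompoundLocation):
            parts = tuple(sorted((int(p.start), int(p.end)) for p in loc.parts))
        else:
            parts = ((int(loc.start), int(loc.end)),)
        strand = "-" if loc.strand == -1 else "+"
        name = _feature_name(bf)
        key = (name, kind, strand, parts)
        if key in seen:
            continue
        seen.add(key)
        features.append(Feature(name=name, kind=kind, strand=strand, parts=parts))

    return GenomeRecord(id=bio.id or path.stem, sequence=seq, circular=circular, features=features)


def feature_to_genbank_location(feature: Feature) -> str:
    """Render a feature back to a GenBank location string (1-based inclusive)."""
    spans = [f"{s + 1}..{e}" for s, e in feature.parts]
    body = spans[0] if len(spans) == 1 else "join(" + ",".join(spans) + ")"
    return f"complement({body})" if feature.strand == "-" else body


def _clean_window(raw: str) -> str:
    # printed tables may embed bold markers and stray whitespace
    return raw.replace("*", "").replace(" ", "").strip().upper()


def read_allele_table(path: str | Path, sequence_column: str | None = None) -> list[AlleleRecord]:
    """Read a TSV genotyping panel into :class:`AlleleRecord` objects.

    One row per cultivar; the sequence column may contain ``-`` gap
    characters marking the deletion allele. Duplicate cultivar names raise
    a warning, not an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
    if sequence_column is None:
        cands = [c for c in df.columns if "seq" in c.lower()]
        if not cands:
            raise ParseError(f"{path}: no sequence column found (columns: {list(df.columns)})")
        sequence_column = cands[0]
    elif sequence_column not in df.columns:
        raise ParseError(f"{path}: missing sequence column {sequence_column!r}")

    name_col = next((c for c in df.columns if c.lower() in ("name", "cultivar")), df.columns[0])
    names = list(df[name_col])
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        warnings.warn(f"{path}: duplicate cultivar names {sorted(dupes)}", stacklevel=2)

    records: list[AlleleRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = dict(zip(df.columns, row))
        window = _clean_window(d[sequence_column])
        if set(window) - (SEQ_ALPHABET | {"-"}):
            raise ParseError(f"{path}: row {i}: bad characters in sequence window {window!r}")
        meta = {k: v for k, v in d.items() if k not in (sequence_column, name_col)}
        idx = int(d.get("index", i)) if str(d.get("index", i)).isdigit() else i
        records.append(
            AlleleRecord(index=idx, name=str(d[name_col]), sequence_window=window, metadata=meta)
        )
    return records


def to_biopython(record: GenomeRecord) -> SeqRecord:
    """Convert to a Biopython SeqRecord (sequence + id only)."""
    return SeqRecord(Seq(record.sequence), id=record.id, description="")


def write_genbank(record: GenomeRecord, path: str | Path) -> None:
    """Write a minimal GenBank flat file (sequence + gene-level features)."""
    from Bio.SeqFeature import FeatureLocation, SeqFeature

    bio = to_biopython(record)
    bio.annotations["molecule_type"] = "DNA"
    bio.annotations["topology"] = "circular" if record.circular else "linear"
    for f in record.features:
        locs = [FeatureLocation(s, e, strand=-1 if f.strand == "-" else 1) for s, e in f.parts]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        ftype = f.kind if f.kind in ("gene", "tRNA", "rRNA") else "misc_feature"
        if ftype == "misc_feature":
            ftype = "gene"
        bio.features.append(SeqFeature(loc, type=ftype, qualifiers={"gene": [f.name]}))
    with open(path, "w") as fh:
        _BioSeqIO.write(bio, fh, "genbank")
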