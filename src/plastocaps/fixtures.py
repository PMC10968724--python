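"""Deterministic synthetic data: toy plastomes, allele loci, packaged panels.

Everything here is a pure function of its parameters and seed, so tests
and examples run fully offline and bit-identically. The packaged panel and
primer tables reproduce the published 43-cultivar genotyping panel and the
marker primer pair; the marker locus is a synthetic reconstruction of the
amplified region (no deposited accession sequence is shipped), built so
that the printed primers and alleles interact exactly as a dCAPS assay
requires.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources

from .compare import VariantEvent
from .dcaps import (
    DcapsMarker,
    PrimerDesign,
    builtin_enzyme,
    digest,
    insilico_pcr,
)
from .seqio import AlleleRecord, Feature, GenomeRecord, read_allele_table, revcomp

__all__ = [
    "PlastomeSpec",
    "make_toy_plastome",
    "make_allele_locus",
    "mutate",
    "random_dna",
    "load_cultivar_panel",
    "load_marker_primers",
    "marker_locus",
    "packaged_marker",
    "INSERTION_WINDOW",
    "REFERENCE_WINDOW",
]

#: The two printed allele windows of the trnL-UAA P8 intron InDel.
INSERTION_WINDOW = "CACTCCATAATAGTCTGATA"
REFERENCE_WINDOW = "CACTCCATAGTCTGATA"

_REGIONS = ("LSC", "IRb", "SSC", "IRa")


def random_dna(rng: random.Random, length: int, gc: float = 0.37) -> str:
    """Random DNA with the given GC fraction (plastome-like default)."""
    at = (1 - gc) / 2
    g = gc / 2
    return "".join(rng.choices("ACGT", weights=[at, g, g, at], k=length))


@dataclass(frozen=True)
class PlastomeSpec:
    """Blueprint for a synthetic circular quadripartite genome."""

    lsc_len: int
    ir_len: int
    ssc_len: int
    gc: float = 0.37
    seed: int = 0
    planted_genes: tuple[tuple[str, str, int, int, str], ...] = ()
    # (name, region in {LSC, IRb, SSC, IRa}, offset within region, length, strand)
    planted_variants: tuple[VariantEvent, ...] = ()

    def __post_init__(self) -> None:
        if min(self.lsc_len, self.ir_len, self.ssc_len) < 1:
            raise ValueError("all region lengths must be >= 1")
        if self.ssc_len > self.lsc_len:
            raise ValueError("SSC must not exceed LSC")


def make_toy_plastome(spec: PlastomeSpec) -> GenomeRecord:
    """Build a circular LSC + IRb + SSC + IRa(=revcomp IRb) genome.

    Planted genes become annotated features (offsets are region-relative
    and may place a gene across a junction). Reproducible from the seed.
    """
    rng = random.Random(spec.seed)
    lsc = random_dna(rng, spec.lsc_len, spec.gc)
    ir = random_dna(rng, spec.ir_len, spec.gc)
    ssc = random_dna(rng, spec.ssc_len, spec.gc)
    # keep the planted IR maximal: a chance complement at a junction would
    # otherwise let exact extension grow the repeat into the single-copy DNA
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    if spec.ssc_len >= 1 and ssc[0] == comp[ssc[-1]]:
        ssc = ssc[:-1] + ("A" if ssc[0] != "T" else "C")
    if spec.lsc_len >= 1 and lsc[-1] == comp[lsc[0]]:
        lsc = lsc[:-1] + ("A" if lsc[0] != "T" else "C")
    seq = lsc + ir + ssc + revcomp(ir)
    n = len(seq)
    region_start = {
        "LSC": 0,
        "IRb": spec.lsc_len,
        "SSC": spec.lsc_len + spec.ir_len,
        "IRa": spec.lsc_len + spec.ir_len + spec.ssc_len,
    }
    features = []
    for name, region, offset, length, strand in spec.planted_genes:
        if region not in _REGIONS:
            raise ValueError(f"unknown region {region!r}")
        start = region_start[region] + offset
        end = start + length
        if not (0 <= start < end):
            raise ValueError(f"gene {name!r} placed at negative coordinates")
        if end > n:
            if end - n >= start:
                raise ValueError(f"gene {name!r} wraps onto itself")
            parts = ((start, n), (0, end - n))
        else:
            parts = ((start, end),)
        features.append(Feature(name=name, kind="gene", strand=strand, parts=parts))
    record = GenomeRecord(id=f"toy-plastome-{spec.seed}", sequence=seq, circular=True, features=features)
    if spec.planted_variants:
        record = mutate(record, list(spec.planted_variants), seed=spec.seed)
    return record


def make_allele_locus(
    flank5: int,
    flank3: int,
    ref_window: str = REFERENCE_WINDOW,
    alt_window: str = INSERTION_WINDOW,
    seed: int = 0,
    gc: float = 0.37,
) -> tuple[str, str]:
    """Two sequences identical except at the embedded allele windows.

    Windows are the gap-stripped allele strings; flanks are random from
    the seed and shared between the two sequences.
    """
    rng = random.Random(seed)
    left = random_dna(rng, flank5, gc)
    right = random_dna(rng, flank3, gc)
    ref_window = ref_window.replace("-", "").upper()
    alt_window = alt_window.replace("-", "").upper()
    return left + ref_window + right, left + alt_window + right


def mutate(record: GenomeRecord, events: list[VariantEvent], seed: int = 0) -> GenomeRecord:
    """Apply substitution/insertion/deletion events to a record.

    ``alignment_column_start`` is interpreted as the 0-based position on
    the record. Events are applied right-to-left so earlier coordinates
    remain valid; overlapping events are an error. An insertion with an
    empty allele string receives random bases of the stated length.
    """
    rng = random.Random(seed)
    spans: list[tuple[int, int]] = []
    for ev in events:
        start = ev.alignment_column_start
        span = (start, start + (0 if ev.kind == "insertion" else ev.length))
        if not 0 <= span[0] <= span[1] <= len(record):
            raise ValueError(f"event at {start} outside record bounds")
        spans.append(span)
    order = sorted(range(len(events)), key=lambda i: spans[i][0])
    for i, j in zip(order, order[1:]):
        if spans[i][1] > spans[j][0]:
            raise ValueError("overlapping variant events")

    seq = record.sequence
    for i in sorted(order, key=lambda i: spans[i][0], reverse=True):
        ev = events[i]
        start = ev.alignment_column_start
        if ev.kind == "substitution":
            allele = ev.allele or "".join(
                rng.choice([b for b in "ACGT" if b != seq[start + k]]) for k in range(ev.length)
            )
            seq = seq[:start] + allele + seq[start + ev.length :]
        elif ev.kind == "insertion":
            allele = ev.allele or random_dna(rng, ev.length)
            seq = seq[:start] + allele + seq[start:]
        elif ev.kind == "deletion":
            seq = seq[:start] + seq[start + ev.length :]
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    return GenomeRecord(id=record.id, sequence=seq, circular=record.circular, features=[])


# ---------------------------------------------------------------------------
# Packaged panel, primers and marker
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("plastocaps.data").joinpath(name)


def load_cultivar_panel() -> list[AlleleRecord]:
    """The packaged 43-cultivar genotyping panel (printed allele windows)."""
    with resources.as_file(_data_path("hs_trnl_panel.tsv")) as p:
        return read_allele_table(p, sequence_column="sequence")


def load_marker_primers() -> dict[str, str]:
    """The packaged marker primer pair, keyed ``forward``/``reverse``."""
    with resources.as_file(_data_path("hs_dcaps_primers.tsv")) as p:
        rows = [line.split("\t") for line in p.read_text().strip().splitlines()[1:]]
    by_name = {name: seq for name, seq in rows}
    fwd = next(v for k, v in by_name.items() if k.endswith("_F"))
    rev = next(v for k, v in by_name.items() if k.endswith("_R"))
    return {"forward": fwd, "reverse": rev}


def marker_locus(flank5: int = 100, flank3: int = 100, seed: int = 2024) -> tuple[str, str]:
    """Synthetic reconstruction of the marker's amplified locus.

    Returns ``(ref, alt)`` top-strand templates for the non-insertion and
    insertion alleles. The amplicon interior is fixed by the printed
    primers and allele windows: the forward-primer binding region ends in
    ``...AGA`` on the template (the primer's engineered terminal C destroys
    the constitutive AATT it would otherwise complete), and the reverse
    primer's 3'-terminal base writes a T into the amplicon top strand that
    completes AATT only when the insertion supplies the upstream A bases.
    Flanks and the inter-primer filler are deterministic from the seed and
    chosen so the reference amplicon carries no MluCI site.
    """
    primers = load_marker_primers()
    fwd, rev = primers["forward"], primers["reverse"]
    enzyme = builtin_enzyme("MluCI")
    # template under the forward primer: terminal base A (primer carries C)
    fwd_region = fwd[:-1] + "A"
    rev_footprint = revcomp(rev)  # TGTCTGATA...; template carries A at its first base
    rev_region = "A" + rev_footprint[1:]
    # amplicon interior: 134 bp reference product with the printed primer pair;
    # the reverse-primer region overlaps the window's trailing A+GTCTGATA
    interior_len = 134 - len(fwd) - len(rev) - 3 - (len(REFERENCE_WINDOW) - 9)

    for attempt in range(100):
        rng = random.Random(seed * 1000 + attempt)
        filler = random_dna(rng, interior_len)
        left = random_dna(rng, flank5)
        right = random_dna(rng, flank3)
        core_ref = fwd_region + "ATT" + filler + REFERENCE_WINDOW[:-9] + rev_region
        core_alt = fwd_region + "ATT" + filler + INSERTION_WINDOW[:-9] + rev_region
        ref = left + core_ref + right
        alt = left + core_alt + right
        try:
            amp_ref = insilico_pcr(ref, fwd, rev)
            amp_alt = insilico_pcr(alt, fwd, rev)
        except Exception:
            continue
        if len(amp_ref) != 134 or len(amp_alt) != 137:
            continue
        if digest(amp_ref.sequence, enzyme) != [134]:
            continue
        if len(digest(amp_alt.sequence, enzyme)) < 2:
            continue
        return ref, alt
    raise RuntimeError("could not realize a clean marker locus from this seed")


def packaged_marker() -> DcapsMarker:
    """The packaged InDel dCAPS marker: printed primers + MluCI, validated.

    Fragment predictions come from re-simulating PCR and digestion of both
    alleles on the synthetic locus; the insertion allele is the cut allele.
    """
    primers = load_marker_primers()
    fwd, rev = primers["forward"], primers["reverse"]
    enzyme = builtin_enzyme("MluCI")
    ref, alt = marker_locus()
    amp_ref = insilico_pcr(ref, fwd, rev)
    amp_alt = insilico_pcr(alt, fwd, rev)
    frags = {
        "ref": digest(amp_ref.sequence, enzyme),
        "alt": digest(amp_alt.sequence, enzyme),
    }
    variant = VariantEvent(
        specimen="HSVM",
        kind="insertion",
        alignment_column_start=amp_alt.template_start,
        length=3,
        allele="ATA",
        background_allele="",
    )
    forward = PrimerDesign(
        sequence=fwd,
        strand="+",
        template_window=(amp_ref.template_start, amp_ref.template_start + len(fwd)),
        introduced_mismatches=((len(fwd) - 1, "A", "C"),),
    )
    reverse = PrimerDesign(
        sequence=rev,
        strand="-",
        template_window=(amp_ref.template_end - len(rev), amp_ref.template_end),
        introduced_mismatches=((len(rev) - 1, "T", "A"),),
    )
    return DcapsMarker(
        forward=forward,
        reverse=reverse,
        enzyme=enzyme,
        variant=variant,
        predicted_fragments=frags,
        cut_allele="alt",
        allele_patterns={"ref": REFERENCE_WINDOW, "alt": INSERTION_WINDOW},
    )
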