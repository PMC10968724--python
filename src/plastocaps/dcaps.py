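"""dCAPS/CAPS marker design, in-silico PCR + restriction digestion, genotyping.

A CAPS marker discriminates two alleles because a variant creates or
destroys a restriction site in the PCR product. When no natural site
difference exists, a dCAPS marker introduces one or more deliberate
mismatches in a primer so that, combined with the variant, a recognition
site is completed in exactly one allele's amplicon. Because the amplicon
carries primer-encoded bases rather than pure template, those engineered
mismatches propagate into the product — the essential dCAPS mechanism.

Fragment lengths are defined by top-strand cut coordinates: gel mobility
reflects duplex length, so overhang geometry is stored but does not affect
reported sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path

import edlib
from Bio.SeqUtils import MeltingTemp as _mt

from .compare import VariantEvent
from .seqio import AlleleRecord, GenomeRecord, revcomp

__all__ = [
    "RestrictionEnzyme",
    "PrimerDesign",
    "DcapsMarker",
    "PrimerQC",
    "GenotypeCall",
    "PcrError",
    "PcrParams",
    "Amplicon",
    "DesignConstraints",
    "DesignResult",
    "BUILTIN_ENZYMES",
    "builtin_enzyme",
    "load_enzyme_table",
    "scan_sites",
    "digest",
    "insilico_pcr",
    "design_dcaps",
    "primer_qc",
    "predict_gel",
    "genotype_panel",
]

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease with an IUPAC recognition site.

    ``cut_offset_top`` is the top-strand cut position in bp from the site
    start; ``cut_offset_bottom`` is measured from the site start on the
    bottom strand read 5'->3' (so a palindromic blunt cutter has both
    offsets equal to half the site length).
    """

    name: str
    site: str
    cut_offset_top: int
    cut_offset_bottom: int

    def __post_init__(self) -> None:
        if not 4 <= len(self.site) <= 8:
            raise ValueError(f"{self.name}: site length must be 4-8")
        bad = set(self.site) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC site characters {sorted(bad)}")
        for off in (self.cut_offset_top, self.cut_offset_bottom):
            if not 0 <= off <= len(self.site):
                raise ValueError(f"{self.name}: cut offset {off} outside site")

    @property
    def is_palindromic(self) -> bool:
        return revcomp(self.site) == self.site

    @classmethod
    def from_caret(cls, name: str, caret_site: str) -> "RestrictionEnzyme":
        """Build from ``'^AATT'``-style notation (caret = top-strand cut)."""
        if caret_site.count("^") != 1:
            raise ValueError(f"{name}: expected exactly one '^' in {caret_site!r}")
        top = caret_site.index("^")
        site = caret_site.replace("^", "")
        return cls(name=name, site=site, cut_offset_top=top, cut_offset_bottom=len(site) - top)


_BUILTIN_CARET = {
    "MluCI": "^AATT",
    "Tsp509I": "^AATT",
    "EcoRI": "G^AATTC",
    "DpnII": "^GATC",
    "MboI": "^GATC",
    "TaqI": "T^CGA",
    "HinfI": "G^ANTC",
    "RsaI": "GT^AC",
    "AluI": "AG^CT",
    "HaeIII": "GG^CC",
    "MseI": "T^TAA",
    "DdeI": "C^TNAG",
    "HpaII": "C^CGG",
    "NlaIII": "CATG^",
}
BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {
    name: RestrictionEnzyme.from_caret(name, caret) for name, caret in _BUILTIN_CARET.items()
}


def builtin_enzyme(name: str) -> RestrictionEnzyme:
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        raise KeyError(f"unknown enzyme {name!r}; known: {sorted(BUILTIN_ENZYMES)}") from None


def load_enzyme_table(path: str | Path) -> dict[str, RestrictionEnzyme]:
    """Load enzymes from a two-column TSV: name <TAB> site-with-caret."""
    out: dict[str, RestrictionEnzyme] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, caret = line.split("\t")[:2]
        out[name] = RestrictionEnzyme.from_caret(name, caret)
    return out


def _iupac_match(seq: str, site: str, pos: int) -> bool:
    for k, s in enumerate(site):
        if seq[pos + k] not in IUPAC_SETS[s]:
            return False
    return True


def scan_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Top-strand cut coordinates of all recognition sites on both strands.

    Plus-strand hits cut at ``site_start + cut_offset_top``; minus-strand
    hits (the site read on the bottom strand) cut the top strand at
    ``site_start + site_length - cut_offset_bottom``. Positions are
    deduplicated and sorted, so palindromic sites contribute once.
    """
    seq = seq.upper()
    L = len(enzyme.site)
    rc_site = revcomp(enzyme.site)
    cuts: set[int] = set()
    for i in range(len(seq) - L + 1):
        if _iupac_match(seq, enzyme.site, i):
            cuts.add(i + enzyme.cut_offset_top)
        if _iupac_match(seq, rc_site, i):
            cuts.add(i + L - enzyme.cut_offset_bottom)
    return sorted(cuts)


def digest(amplicon: str, enzyme: RestrictionEnzyme | list[RestrictionEnzyme]) -> list[int]:
    """Fragment lengths after complete digestion, in descending order."""
    enzymes = [enzyme] if isinstance(enzyme, RestrictionEnzyme) else list(enzyme)
    cuts: set[int] = set()
    for e in enzymes:
        cuts.update(scan_sites(amplicon, e))
    cuts -= {0, len(amplicon)}  # terminal 'cuts' do not create new fragments
    bounds = [0, *sorted(cuts), len(amplicon)]
    frags = [b - a for a, b in zip(bounds, bounds[1:])]
    return sorted(frags, reverse=True)


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------


class PcrError(RuntimeError):
    """In-silico PCR failure with a machine-parsable ``code``."""

    def __init__(self, code: str, message: str):
        super().__init__(f"{code}: {message}")
        self.code = code


@dataclass(frozen=True)
class PcrParams:
    seed_len: int = 12
    seed_mismatch: int = 1  # mismatches tolerated in the 3'-terminal seed
    max_mismatch: int = 3  # over the full primer
    uniqueness_margin: int = 2  # best site must beat runner-up by this many mismatches
    min_product: int = 40
    max_product: int = 20_000


@dataclass(frozen=True)
class Amplicon:
    """A simulated PCR product; the primer footprints carry primer bases."""

    sequence: str
    template_start: int  # top-strand interval [start, end) spanned on the template
    template_end: int
    fwd_mismatches: int
    rev_mismatches: int

    def __len__(self) -> int:
        return len(self.sequence)


def _mismatches(a: str, b: str, limit: int) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > limit:
                return m
    return m


def _scan_primer(template: str, footprint: str, seed_at_start: bool, params: PcrParams) -> list[tuple[int, int]]:
    """All (start, mismatches) where ``footprint`` can bind the top strand.

    ``seed_at_start`` marks whether the primer's 3'-terminal seed lies at
    the left (reverse primer footprint) or right (forward primer) end of
    the footprint on the top strand.
    """
    plen = len(footprint)
    slen = min(params.seed_len, plen)
    seed = footprint[:slen] if seed_at_start else footprint[-slen:]
    hits: list[tuple[int, int]] = []
    for s in range(len(template) - plen + 1):
        spos = s if seed_at_start else s + plen - slen
        if _mismatches(template[spos : spos + slen], seed, params.seed_mismatch) > params.seed_mismatch:
            continue
        mm = _mismatches(template[s : s + plen], footprint, params.max_mismatch)
        if mm <= params.max_mismatch:
            hits.append((s, mm))
    return hits


def _best_unique(hits: list[tuple[int, int]], margin: int, what: str) -> tuple[int, int]:
    if not hits:
        raise PcrError("E_NO_SITE", f"no binding site for the {what} primer")
    hits = sorted(hits, key=lambda h: (h[1], h[0]))
    if len(hits) > 1 and hits[1][1] - hits[0][1] < margin:
        raise PcrError(
            "E_MULTI_SITE",
            f"{what} primer binds multiple near-equivalent sites "
            f"(best {hits[0][1]} vs runner-up {hits[1][1]} mismatches)",
        )
    return hits[0]


def insilico_pcr(
    template: GenomeRecord | str,
    fwd: str,
    rev: str,
    params: PcrParams = PcrParams(),
) -> Amplicon:
    """Simulate PCR of a linear top-strand template.

    The forward primer binds the top strand (3' end rightmost); the reverse
    primer binds the bottom strand, i.e. its reverse complement appears on
    the top strand with the primer's 3' end leftmost. The product spans the
    two primer 5' ends and its footprints carry the primer sequences, so
    primer-introduced mismatches propagate into the amplicon.
    """
    seq = (template.sequence if isinstance(template, GenomeRecord) else template).upper()
    fwd = fwd.upper()
    rev = rev.upper()
    for p, what in ((fwd, "forward"), (rev, "reverse")):
        if not 15 <= len(p) <= 40:
            raise PcrError("E_PRIMER_LEN", f"{what} primer length {len(p)} outside 15-40 nt")

    fwd_s, fwd_mm = _best_unique(_scan_primer(seq, fwd, False, params), params.uniqueness_margin, "forward")
    rev_fp = revcomp(rev)
    rev_s, rev_mm = _best_unique(_scan_primer(seq, rev_fp, True, params), params.uniqueness_margin, "reverse")

    rev_e = rev_s + len(rev_fp)
    if fwd_s >= rev_e or fwd_s + len(fwd) > rev_e or fwd_s >= rev_s:
        raise PcrError("E_ORIENTATION", "forward site is not upstream of the reverse site")
    if rev_s < fwd_s + len(fwd):
        raise PcrError("E_ORIENTATION", "primer footprints overlap")
    product_len = rev_e - fwd_s
    if not params.min_product <= product_len <= params.max_product:
        raise PcrError("E_PRODUCT_BOUNDS", f"product length {product_len} outside configured bounds")
    amplicon = fwd + seq[fwd_s + len(fwd) : rev_s] + rev_fp
    return Amplicon(
        sequence=amplicon,
        template_start=fwd_s,
        template_end=rev_e,
        fwd_mismatches=fwd_mm,
        rev_mismatches=rev_mm,
    )


# ---------------------------------------------------------------------------
# Primer QC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrimerQC:
    length: int
    gc_pct: float
    tm: float  # nearest-neighbor, 50 mM monovalent salt, 250 nM primer
    hairpin_stem: int
    dimer_run: int


_PAIRS = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _hairpin_stem(seq: str) -> int:
    """Longest antiparallel self-complementary run between non-overlapping segments."""
    n = len(seq)
    best = 0
    # run[i][j]: length of complementary run with seq[i] pairing seq[j], growing i up / j down
    prev = [0] * n
    for i in range(n):
        cur = [0] * n
        for j in range(n - 1, i, -1):
            if _PAIRS.get(seq[i]) == seq[j]:
                cur[j] = (prev[j + 1] if j + 1 < n else 0) + 1
                # segments [i-L+1, i] and [j, j+L-1] must not overlap: i < j suffices
                if i - cur[j] + 1 >= 0 and i < j:
                    best = max(best, cur[j])
        prev = cur
    return best


def _anchored_run(p: str, q: str) -> int:
    """Longest complementary run anchored at p's 3' terminus against q (antiparallel)."""
    best = 0
    for j in range(len(q)):
        k = 0
        # antiparallel: stepping 3'->5' along p walks 5'->3' along q
        while j + k < len(q) and k < len(p) and _PAIRS.get(p[len(p) - 1 - k]) == q[j + k]:
            k += 1
        best = max(best, k)
    return best


def primer_qc(seq: str, partner: str | None = None) -> PrimerQC:
    """Composition, nearest-neighbor Tm, hairpin and 3'-dimer checks.

    Tm uses SantaLucia (2004) nearest-neighbor parameters at 50 mM
    monovalent salt and 250 nM primer concentration.
    """
    seq = seq.upper()
    if not 10 <= len(seq) <= 50:
        raise ValueError(f"primer length {len(seq)} outside 10-50 nt")
    gc = 100.0 * sum(seq.count(b) for b in "GC") / len(seq)
    tm = _mt.Tm_NN(seq, nn_table=_mt.DNA_NN4, Na=50, dnac1=250, dnac2=0)
    other = (partner or seq).upper()
    dimer = max(_anchored_run(seq, other), _anchored_run(other, seq))
    return PrimerQC(
        length=len(seq),
        gc_pct=round(gc, 2),
        tm=round(tm, 2),
        hairpin_stem=_hairpin_stem(seq),
        dimer_run=dimer,
    )


# ---------------------------------------------------------------------------
# Gel prediction and band matching
# ---------------------------------------------------------------------------


def predict_gel(fragments: list[int], min_visible: int = 20) -> list[int]:
    """Bands expected to be visible on a 2% agarose gel (>= ``min_visible`` bp)."""
    return sorted((f for f in fragments if f >= min_visible), reverse=True)


def _bands_match(observed: list[int], predicted: list[int], tolerance: float, floor: int) -> bool:
    """Pair bands one-to-one within max(tolerance*size, floor) bp."""
    if len(observed) != len(predicted):
        return False
    for o, p in zip(sorted(observed), sorted(predicted)):
        if abs(o - p) > max(tolerance * p, floor):
            return False
    return True


def fragments_distinguishable(
    frags_a: list[int],
    frags_b: list[int],
    tolerance: float = 0.10,
    floor: int = 5,
    min_visible: int = 20,
) -> bool:
    """Whether two digests produce gel patterns a reader could tell apart."""
    return not _bands_match(
        predict_gel(frags_a, min_visible), predict_gel(frags_b, min_visible), tolerance, floor
    )


# ---------------------------------------------------------------------------
# Marker design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrimerDesign:
    sequence: str
    strand: str  # "+" forward, "-" reverse
    template_window: tuple[int, int]  # [start, end) on the design locus (ref allele, + strand)
    introduced_mismatches: tuple[tuple[int, str, str], ...] = ()
    # (0-based position within the primer, template base, primer base)


@dataclass
class DcapsMarker:
    """A validated primer pair + enzyme with per-allele fragment predictions."""

    forward: PrimerDesign
    reverse: PrimerDesign
    enzyme: RestrictionEnzyme
    variant: VariantEvent | None
    predicted_fragments: dict[str, list[int]]  # allele name -> descending fragment sizes
    cut_allele: str
    allele_patterns: dict[str, str] = field(default_factory=dict)
    # short diagnostic windows per allele, for classifying panel sequence windows

    def __post_init__(self) -> None:
        vals = list(self.predicted_fragments.values())
        if len(vals) >= 2 and sorted(vals[0]) == sorted(vals[1]):
            raise ValueError("alleles have identical fragment multisets; marker is uninformative")

    @property
    def n_introduced(self) -> int:
        return len(self.forward.introduced_mismatches) + len(self.reverse.introduced_mismatches)

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "forward": {
                "sequence": self.forward.sequence,
                "strand": self.forward.strand,
                "template_window": list(self.forward.template_window),
                "introduced_mismatches": [list(m) for m in self.forward.introduced_mismatches],
            },
            "reverse": {
                "sequence": self.reverse.sequence,
                "strand": self.reverse.strand,
                "template_window": list(self.reverse.template_window),
                "introduced_mismatches": [list(m) for m in self.reverse.introduced_mismatches],
            },
            "enzyme": {
                "name": self.enzyme.name,
                "site": self.enzyme.site,
                "cut_offset_top": self.enzyme.cut_offset_top,
                "cut_offset_bottom": self.enzyme.cut_offset_bottom,
            },
            "variant": None
            if self.variant is None
            else {
                "specimen": self.variant.specimen,
                "kind": self.variant.kind,
                "alignment_column_start": self.variant.alignment_column_start,
                "length": self.variant.length,
                "allele": self.variant.allele,
                "background_allele": self.variant.background_allele,
            },
            "predicted_fragments": self.predicted_fragments,
            "cut_allele": self.cut_allele,
            "allele_patterns": self.allele_patterns,
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DcapsMarker":
        src = str(source)
        text = Path(src).read_text() if "\n" not in src and Path(src).exists() else src
        d = json.loads(text)
        mkprimer = lambda p: PrimerDesign(  # noqa: E731
            sequence=p["sequence"],
            strand=p["strand"],
            template_window=tuple(p["template_window"]),
            introduced_mismatches=tuple(tuple(m) for m in p["introduced_mismatches"]),
        )
        var = d["variant"]
        return cls(
            forward=mkprimer(d["forward"]),
            reverse=mkprimer(d["reverse"]),
            enzyme=RestrictionEnzyme(**d["enzyme"]),
            variant=None if var is None else VariantEvent(**var),
            predicted_fragments={k: list(v) for k, v in d["predicted_fragments"].items()},
            cut_allele=d["cut_allele"],
            allele_patterns=dict(d.get("allele_patterns", {})),
        )


@dataclass(frozen=True)
class DesignConstraints:
    primer_len_min: int = 18
    primer_len_max: int = 35
    max_mismatches: int = 1  # introduced mismatches per mismatch primer
    max_dist_3prime: int = 10  # bp from mismatch-primer 3' end to the variant
    mod_window: int = 12  # 3'-most primer positions eligible for modification
    tm_target: float = 57.0
    product_min: int = 60
    product_max: int = 400
    band_tolerance: float = 0.10
    gel_floor: int = 5
    min_visible: int = 20


class DesignResult(list):
    """Ranked markers; ``rejections`` maps enzyme name -> reasons."""

    def __init__(self, markers=(), rejections: dict[str, list[str]] | None = None):
        super().__init__(markers)
        self.rejections: dict[str, list[str]] = rejections or {}


def _split_variant(ref: str, alt: str) -> tuple[int, str, str]:
    """Locate the single difference between two allele contexts.

    Returns ``(start, ref_allele, alt_allele)`` where the alleles may be
    empty (pure insertion/deletion).
    """
    if ref == alt:
        raise ValueError("allele contexts are identical; no variant to target")
    pre = 0
    while pre < min(len(ref), len(alt)) and ref[pre] == alt[pre]:
        pre += 1
    suf = 0
    while (
        suf < min(len(ref), len(alt)) - pre
        and ref[len(ref) - 1 - suf] == alt[len(alt) - 1 - suf]
    ):
        suf += 1
    return pre, ref[pre : len(ref) - suf], alt[pre : len(alt) - suf]


def _variant_event_from_contexts(ref: str, alt: str, specimen: str = "alt") -> VariantEvent:
    pos, ra, aa = _split_variant(ref, alt)
    if ra and aa:
        if len(ra) == len(aa):
            kind = "substitution"
        else:  # complex; classify by the net length change
            kind = "insertion" if len(aa) > len(ra) else "deletion"
    elif aa:
        kind = "insertion"
    else:
        kind = "deletion"
    return VariantEvent(
        specimen=specimen,
        kind=kind,
        alignment_column_start=pos,
        length=max(len(ra), len(aa)),
        allele=aa,
        background_allele=ra,
    )


def _pick_length(context: str, end: int, constraints: DesignConstraints) -> int:
    """Primer length in range whose Tm is closest to the target."""
    best_len, best_gap = None, None
    for plen in range(constraints.primer_len_min, constraints.primer_len_max + 1):
        if plen > end:
            continue
        tm = _mt.Tm_NN(context[end - plen : end], nn_table=_mt.DNA_NN4, Na=50, dnac1=250, dnac2=0)
        gap = abs(tm - constraints.tm_target)
        if best_gap is None or gap < best_gap:
            best_len, best_gap = plen, gap
    if best_len is None:
        raise ValueError("context too short for any primer length in range")
    return best_len


def design_dcaps(
    ref_context: str,
    alt_context: str,
    variant: VariantEvent | None = None,
    enzymes: list[RestrictionEnzyme] | None = None,
    constraints: DesignConstraints = DesignConstraints(),
) -> DesignResult:
    """Enumerate dCAPS/CAPS designs discriminating two allele contexts.

    The contexts are the two allele sequences of one locus (identical
    except at the variant, with generous flanks). For each enzyme and each
    strand, the mismatch primer's 3' end is slid up to
    ``max_dist_3prime`` bp from the variant and up to ``max_mismatches``
    base edits in the primer's 3'-most ``mod_window`` positions are tried;
    the zero-edit case covers plain CAPS where the variant itself creates a
    native site difference. Every candidate is validated by full
    re-simulation (in-silico PCR of both alleles + digestion); designs
    whose visible band patterns coincide within the gel-resolution floor
    are rejected. Constitutive sites elsewhere in the amplicon are allowed
    and appear in the predicted fragments.

    Returns markers ranked by (fewest introduced mismatches, non-terminal
    mismatch preferred, largest discriminating fragment-size difference,
    Tm closeness to target).
    """
    ref_context = ref_context.upper()
    alt_context = alt_context.upper()
    enzymes = enzymes if enzymes is not None else list(BUILTIN_ENZYMES.values())
    rejections: dict[str, list[str]] = {e.name: [] for e in enzymes}
    candidates: list[tuple[tuple, DcapsMarker]] = []
    seen: set[tuple] = set()
    pcr_params = PcrParams(min_product=constraints.product_min, max_product=constraints.product_max)

    for strand in "+-":
        if strand == "+":
            ref_s, alt_s = ref_context, alt_context
        else:
            ref_s, alt_s = revcomp(ref_context), revcomp(alt_context)
        vpos, ref_allele, alt_allele = _split_variant(ref_s, alt_s)

        # opposite (mismatch-free) primer: anchored at the far end of the locus
        opp_len = _pick_length(revcomp(ref_s), len(ref_s), constraints)
        opposite = revcomp(ref_s[-opp_len:])

        ends = range(max(constraints.primer_len_min, vpos - constraints.max_dist_3prime), vpos + 1)
        for end in ends:
            try:
                plen = _pick_length(ref_s, end, constraints)
            except ValueError:
                continue
            base_primer = ref_s[end - plen : end]
            mod_positions = range(max(0, plen - constraints.mod_window), plen)
            edit_sets: list[tuple[tuple[int, str], ...]] = [()]
            for m in range(1, constraints.max_mismatches + 1):
                for pos_combo in combinations(mod_positions, m):
                    for bases in product("ACGT", repeat=m):
                        if any(base_primer[p] == b for p, b in zip(pos_combo, bases)):
                            continue
                        edit_sets.append(tuple(zip(pos_combo, bases)))

            for edits in edit_sets:
                primer = list(base_primer)
                for p, b in edits:
                    primer[p] = b
                primer_seq = "".join(primer)
                for enzyme in enzymes:
                    key = (strand, primer_seq, opposite, enzyme.name)
                    if key in seen:
                        continue
                    seen.add(key)
                    try:
                        amp_ref = insilico_pcr(ref_s, primer_seq, opposite, pcr_params)
                        amp_alt = insilico_pcr(alt_s, primer_seq, opposite, pcr_params)
                    except PcrError as exc:
                        if not edits:
                            rejections[enzyme.name].append(f"{strand}{end}: {exc.code}")
                        continue
                    frags_ref = digest(amp_ref.sequence, enzyme)
                    frags_alt = digest(amp_alt.sequence, enzyme)
                    if sorted(frags_ref) == sorted(frags_alt):
                        continue
                    if not fragments_distinguishable(
                        frags_ref,
                        frags_alt,
                        constraints.band_tolerance,
                        constraints.gel_floor,
                        constraints.min_visible,
                    ):
                        rejections[enzyme.name].append(
                            f"{strand}{end}{'+' + str(len(edits)) + 'mod' if edits else ''}: "
                            "patterns indistinguishable at gel resolution"
                        )
                        continue
                    cut_allele = "alt" if len(frags_alt) > len(frags_ref) else "ref"
                    disc = _discriminating_difference(frags_ref, frags_alt)
                    terminal = any(p == plen - 1 for p, _ in edits)
                    tm_gap = abs(
                        _mt.Tm_NN(primer_seq, nn_table=_mt.DNA_NN4, Na=50, dnac1=250, dnac2=0)
                        - constraints.tm_target
                    )
                    mism = tuple((p, base_primer[p], b) for p, b in edits)
                    fwd_design = PrimerDesign(
                        sequence=primer_seq,
                        strand=strand,
                        template_window=(end - plen, end),
                        introduced_mismatches=mism,
                    )
                    rev_design = PrimerDesign(
                        sequence=opposite,
                        strand="-" if strand == "+" else "+",
                        template_window=(len(ref_s) - opp_len, len(ref_s)),
                    )
                    marker = DcapsMarker(
                        forward=fwd_design,
                        reverse=rev_design,
                        enzyme=enzyme,
                        variant=_variant_event_from_contexts(ref_context, alt_context),
                        predicted_fragments={"ref": frags_ref, "alt": frags_alt},
                        cut_allele=cut_allele,
                        allele_patterns=_default_patterns(ref_s, alt_s, vpos, ref_allele, alt_allele, strand),
                    )
                    rank = (len(edits), int(terminal), -disc, tm_gap)
                    candidates.append((rank, marker))

    candidates.sort(key=lambda c: c[0])
    result = DesignResult([m for _, m in candidates], rejections)
    return result


def _discriminating_difference(frags_a: list[int], frags_b: list[int]) -> int:
    """Largest size gap between any unmatched fragments of the two patterns."""
    a, b = sorted(frags_a, reverse=True), sorted(frags_b, reverse=True)
    diffs = [abs(x - y) for x, y in zip(a, b)]
    tail = a[len(b):] + b[len(a):]
    return max(diffs + [t for t in tail] + [0])


def _default_patterns(
    ref_s: str, alt_s: str, vpos: int, ref_allele: str, alt_allele: str, strand: str
) -> dict[str, str]:
    flank = 8
    ref_pat = ref_s[max(0, vpos - flank) : vpos + len(ref_allele) + flank]
    alt_pat = alt_s[max(0, vpos - flank) : vpos + len(alt_allele) + flank]
    if strand == "-":
        ref_pat, alt_pat = revcomp(ref_pat), revcomp(alt_pat)
    return {"ref": ref_pat, "alt": alt_pat}


# ---------------------------------------------------------------------------
# Genotyping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeCall:
    sample: str
    observed_fragments: tuple[int, ...]
    call: str  # {"cut_allele", "uncut_allele", "uninformative"}
    reason: str = ""


def _classify_window(marker: DcapsMarker, window: str) -> tuple[str, str]:
    """Classify a short allele window against the marker's allele patterns.

    Windows containing ``-`` are gap-stripped first (the deletion allele as
    printed). Classification is by ungapped exact containment of either
    allele pattern, falling back to edit-distance nearest allele.
    """
    seq = window.replace("-", "").upper()
    if not seq or set(seq) == {"N"}:
        return "uninformative", "window empty or all N"
    patterns = marker.allele_patterns
    if not patterns:
        return "uninformative", "marker carries no allele patterns"
    hits = []
    for allele in sorted(patterns, key=lambda a: -len(patterns[a])):
        pat = patterns[allele]
        if pat in seq or seq in pat:
            hits.append(allele)
    if len(hits) == 1:
        return hits[0], "pattern containment"
    if len(hits) > 1:
        return "uninformative", "window matches both allele patterns"
    dists = {}
    for allele, pat in patterns.items():
        a, b = (seq, pat) if len(seq) >= len(pat) else (pat, seq)
        dists[allele] = edlib.align(b, a, mode="HW", task="distance")["editDistance"]
    best = sorted(dists.items(), key=lambda kv: kv[1])
    if len(best) > 1 and best[0][1] == best[1][1]:
        return "uninformative", "equidistant from both allele patterns"
    if best[0][1] > max(3, len(seq) // 4):
        return "uninformative", "window not alignable to either allele pattern"
    return best[0][0], f"edit-distance nearest ({best[0][1]})"


def genotype_panel(
    marker: DcapsMarker,
    panel: list[AlleleRecord | GenomeRecord | str | tuple[str, str]],
    tolerance: float = 0.10,
    floor: int = 5,
    min_visible: int = 20,
    pcr_params: PcrParams = PcrParams(),
) -> list[GenotypeCall]:
    """Call each panel entry against a marker's per-allele fragment predictions.

    Short windows (anything shorter than the smallest predicted amplicon,
    or containing gap characters) are classified by sequence against the
    marker's two allele patterns; full-length sequences are run through
    in-silico PCR + digestion and their fragment multiset matched to the
    predictions within a size tolerance. ``uninformative`` is returned when
    neither allele matches.
    """
    min_amplicon = min(sum(f) for f in marker.predicted_fragments.values())
    visible_pred = {
        allele: predict_gel(frags, min_visible) for allele, frags in marker.predicted_fragments.items()
    }
    calls: list[GenotypeCall] = []
    for entry in panel:
        if isinstance(entry, AlleleRecord):
            name, seq = entry.name, entry.sequence_window
        elif isinstance(entry, GenomeRecord):
            name, seq = entry.id, entry.sequence
        elif isinstance(entry, tuple):
            name, seq = entry
        else:
            name, seq = "sample", str(entry)
        seq = seq.upper()

        if "-" in seq or len(seq) < min_amplicon:
            allele, reason = _classify_window(marker, seq)
            if allele == "uninformative":
                calls.append(GenotypeCall(name, (), "uninformative", reason))
            else:
                call = "cut_allele" if allele == marker.cut_allele else "uncut_allele"
                calls.append(GenotypeCall(name, tuple(marker.predicted_fragments[allele]), call, reason))
            continue

        try:
            amp = insilico_pcr(seq, marker.forward.sequence, marker.reverse.sequence, pcr_params)
        except PcrError as exc:
            calls.append(GenotypeCall(name, (), "uninformative", exc.code))
            continue
        observed = digest(amp.sequence, marker.enzyme)
        matched = [
            allele
            for allele, pred in visible_pred.items()
            if _bands_match(predict_gel(observed, min_visible), pred, tolerance, floor)
        ]
        if len(matched) == 1:
            call = "cut_allele" if matched[0] == marker.cut_allele else "uncut_allele"
            calls.append(GenotypeCall(name, tuple(observed), call, "fragment match"))
        else:
            why = "matches no allele pattern" if not matched else "matches both allele patterns"
            calls.append(GenotypeCall(name, tuple(observed), "uninformative", why))
    return calls
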