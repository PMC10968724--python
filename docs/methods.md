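# Methods

This note documents the models and procedures implemented in
`plastocaps`, the defaults that matter, what the synthetic data emulate,
and the design decisions taken where the design was genuinely open.

## Coordinate and sequence model

All internal coordinates are 0-based half-open; every user-facing report
(junction tables, variant TSVs, GenBank locations) is 1-based inclusive.
Sequences are uppercase DNA over `{A,C,G,T,N}`; `U` is normalized to `T`
on input so tRNA-derived sequences and primers share one alphabet.
Circular records are stored linearized at their deposited origin;
rotation is always an explicit operation, never implicit.

## Quadripartite structure

A plastome is modeled as a circle tiled by LSC + IRb + SSC + IRa with
`IRb = revcomp(IRa)` exactly. Detection is exact-match seed-and-extend:
25-mers of the sequence are matched against its reverse complement, each
hit is extended maximally on the circle, and the longest non-overlapping
pair wins (ties: maximize the shorter single-copy gap, then lowest start
coordinate — deterministic output). Exact matching is appropriate because
within-genome IR copies of the target genomes are identical; diverged-IR
support is out of scope. The default `min_len` is 1,000 bp for real
plastomes; toy fixtures use 50 bp. The partition invariants (regions tile
the genome; IR equality; SSC ≤ LSC) are asserted on every call.

Junction distances are signed: negative means the gene straddles the
junction and extends `|d|` bp beyond it (the shorter of the two split
pieces), positive means the gene's nearest end is `d` bp away, zero means
an end coincides with the boundary. Where prose conventions are ambiguous
(distance from gene start vs nearest end), the nearest-end reading is
used and both ends are recoverable from the feature table.

Canonical rotation places the LSC start at position 0 and chooses the
orientation that puts *rps19* (when annotated) nearest the LSC/IRb
junction — its conserved position in Malvaceae plastomes — falling back
to the lexicographically smaller candidate sequence for unannotated
records. The operation is idempotent and rotation/flip-invariant.

## Pairwise comparison

`align_pair` produces a global end-to-end alignment under unit costs
(match 0, mismatch 1, gap 1 per column) using Myers' bit-parallel
edit-distance algorithm (edlib), which is optimal under this cost model
at any sequence length; the test suite cross-checks it against an
independent full Needleman–Wunsch DP. Circular inputs should be
canonically rotated first so origin placement cannot fabricate terminal
gaps.

Percent identity is **gap-excluded**:
`identity = 100 · match / (match + mismatch)`, rounded half-up to two
decimals. Rationale: for plastome pairs differing by a handful of SNPs
plus short indels, the gap-excluded figure reflects substitutional
divergence and is the convention that makes a 12-SNP pair read as 99.99%
rather than depending on how many columns its indels occupy. Gap content
is reported separately, primarily as gap columns in bp, secondarily as
gap openings (runs).

Specimen-specific variants are extracted from an N ≥ 3 multiple
alignment at the assembly level: a column run is an event when exactly
one row disagrees with the unanimous consensus of all other rows; maximal
adjacent runs of the same (specimen, kind) merge; one row with bases
against all-gap background is an insertion, one row gapped is a deletion.
Columns where two or more rows disagree with the rest are counted and
positioned as ambiguous, never silently dropped. This deliberately
replaces read-level evidence thresholds (read depth, base quality) with
assembly-level consensus logic — a semantic difference worth remembering
when comparing against read-based callers.

## Restriction digestion

Recognition sites are scanned on both strands under IUPAC matching.
Fragment lengths are defined by top-strand cut coordinates; overhang
geometry (`cut_offset_bottom`) is stored but does not affect lengths,
since gel mobility reflects duplex length. This also sidesteps the common
mislabeling of *Mlu*CI as a blunt cutter — it leaves 5′ AATT overhangs,
which is irrelevant to band sizes. Complete digestion is assumed. The
built-in table ships a small curated enzyme set (MluCI, Tsp509I, EcoRI,
DpnII/MboI, TaqI, HinfI, RsaI, AluI, HaeIII, MseI, DdeI, HpaII, NlaIII)
in `'^'`-caret notation; additional enzymes load from a two-column TSV.
There is no live REBASE dependency.

## In-silico PCR

Primer binding is seeded by the 3'-terminal 12-mer (≤ 1 mismatch), with
≤ 3 mismatches over the full primer; the best site per primer must beat
the runner-up by ≥ 2 mismatches, otherwise a multiple-binding error is
raised — deterministic, explainable failures (`E_NO_SITE`,
`E_MULTI_SITE`, `E_PRODUCT_BOUNDS`). The product spans the two primer 5'
ends and its primer footprints carry the **primer** sequences, so
engineered mismatches propagate into the amplicon — the mechanism dCAPS
depends on. Thermodynamic simulation (amplification efficiency,
dimer-driven dropout) is out of scope.

## dCAPS design

`design_dcaps` takes the two allele contexts of one locus (identical
except at the variant, ≥ 60 bp flanks). The search space is: both
strands × mismatch-primer 3'-end placements within 10 bp of the variant ×
up to `max_mismatches` (default 1) base edits within the primer's
3'-most 12 positions, plus the zero-edit case (plain CAPS, when the
variant itself creates a native site difference). The space is enumerated
exhaustively and every candidate is validated by full re-simulation —
in-silico PCR of both alleles followed by digestion — so design
soundness (every emitted marker reproduces its own fragment predictions)
holds by construction, and completeness against brute-force enumeration
is a tested property rather than a hope. Designs whose visible band
patterns coincide within the gel floor are rejected with per-enzyme
reasons. Constitutive sites elsewhere in the amplicon are allowed and
included in predictions. Ranking: fewest introduced mismatches, then
non-terminal mismatch preferred over 3'-terminal (terminal mismatches
work — the packaged marker uses one — but destabilize extension more),
then largest discriminating fragment-size difference, then Tm closeness
to target (57 °C default). The recognition site may span the inserted
bases themselves, as in the ATA case.

Primer QC reports exact GC%, nearest-neighbor Tm (SantaLucia 2004
parameters, 50 mM monovalent salt, 250 nM primer — standard endpoint-PCR
conditions), the longest self-complementary hairpin stem between
non-overlapping segments, and the longest complementary run anchored at
either 3' terminus against the partner (or self).

Gel model: fragments ≥ 20 bp are visible on 2% agarose; band matching
uses ±10% of fragment size with a 5-bp floor. All thresholds are
configurable; the defaults are declared once and logged with every run.

## The packaged marker and its synthetic locus

The packaged assay consists of the printed primer pair
(`ATGCAAAATCTATTTATATGAAAAATAAAAAGC` / `AATCAGTTTTTCAAAAGATTTATCAGACA`),
*Mlu*CI, and the two printed allele windows
(`CACTCCATAATAGTCTGATA` vs `CACTCCATA---GTCTGATA`). Because no deposited
genome sequence is shipped, the amplified locus is a **synthetic
reconstruction** (`fixtures.marker_locus`): the primer binding regions
and the allele windows fix most of the amplicon, and the remaining 61 bp
of interior filler plus the outer flanks are deterministic pseudo-random
sequence constrained so the reference amplicon contains no *Mlu*CI site
and both primers bind uniquely.

The reconstruction makes the assay mechanics explicit. On the insertion
allele the reverse primer's 3'-terminal base writes a T into the amplicon
top strand immediately after the `..CCATA-AT` supplied by the insertion,
completing `AATT` at amplicon position 105; the reference allele lacks
the two upstream A's, so no site forms. The forward primer's terminal
A→C edit destroys a constitutive template `AATT` spanning its 3' end that
would otherwise cleave both products. The simulated digest is therefore
**137 → [105, 32]** for the insertion allele and an uncut **[134]** for
the reference. The wet assay is reported to resolve the small fragment
further into 28 + 4 bp (same 32-bp total, identical 105-bp diagnostic
band and identical calls); producing that extra cut would require a
second `AATT` four bases from the amplicon end, which the printed reverse
primer sequence (ending `...AGACA`, amplicon top strand `...GATT`)
cannot form — the discrepancy sits in sequence not printed in full, so
the reconstruction keeps the printed primers authoritative and the
single-cut geometry. Genotype calls are unaffected: panel windows are
classified by sequence, and full-length samples match on the shared
105-bp band and total product size.

Panel genotyping: entries containing `-` or shorter than the smallest
predicted amplicon are classified by ungapped exact containment of either
allele pattern, falling back to nearest edit distance (ties or
unalignable windows → `uninformative`); full sequences are genotyped by
re-simulating PCR + digestion and matching visible bands within the
tolerance above.

## Synthetic data: what it does and does not emulate

`make_toy_plastome` produces circular LSC+IRb+SSC+IRa genomes with
plastome-like GC (0.37 default), planted genes, and planted variants;
junction bases are adjusted so the planted IR is exactly maximal. It does
not emulate gene content, codon structure, repeat families, or IR
boundary shifts, so passing tests demonstrate the correctness of the
detection/partition/junction machinery, not performance on diverged or
misassembled genomes. `make_allele_locus` embeds the printed allele
windows in random shared flanks; no sequencing error or heteroplasmy is
simulated. Test problem sizes (toy genomes ≤ ~1.2 kb for the quadratic
oracle comparisons, 2 kb for alignment-optimality checks, 161-kb
synthetic genomes for scale checks) keep the full suite under two
minutes on a single CPU.

## Known limitations

- IR detection is exact-match only; genomes with diverged IR copies need
  a different detector.
- In-silico PCR scans the linearized top strand; an amplicon spanning the
  deposited origin of a circular genome requires prior rotation
  (`canonical_rotation` places the origin in the LSC, far from typical
  marker loci).
- Identity/gap statistics follow this package's stated conventions;
  numbers from aligners with unpublished counting rules can differ
  slightly on gap-rich pairs.
- `design_dcaps` enumerates exhaustively within its constraint box, which
  is tractable for marker-scale loci (hundreds of bp), not whole genomes:
  pass variant contexts, not assemblies.
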