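# plastocaps

**dCAPS/CAPS marker design and in-silico validation for near-identical
plastomes.**

Chloroplast genomes of closely related cultivars are often > 99.9%
identical, so distinguishing a maternal lineage needs a marker built
around a single short variant. `plastocaps` is a toolkit for exactly that
workflow, developed around an InDel assay for *Hibiscus syriacus* var.
*micranthus* (HSVM), a rare natural dwarf rose-of-Sharon: a 3-bp **ATA**
insertion in the P8 stem-loop of the *trnL-UAA* Group I intron is private
to HSVM and its maternal descendants, and a mismatch-primer (dCAPS) assay
with the 4-cutter *Mlu*CI turns that insertion into an allele-specific
band pattern on an agarose gel.

The toolkit covers the full path from genomes to genotype calls:

- **seqio** — FASTA / GenBank flat-file / allele-table I/O with a shared
  0-based internal coordinate model (1-based in all reports).
- **quadripartite** — exact inverted-repeat detection, LSC/IRb/SSC/IRa
  partitioning, canonical rotation, and signed gene-to-junction distances
  (negative = the gene straddles the junction).
- **compare** — global pairwise alignment under unit costs (optimal, via
  Myers' bit-parallel algorithm), gap-excluded identity statistics, and
  specimen-specific variant extraction from a multiple alignment.
- **dcaps** — the core: IUPAC restriction-site scanning, complete-digest
  fragment prediction, in-silico PCR in which primer-introduced mismatches
  propagate into the amplicon, exhaustive dCAPS/CAPS design with full
  re-simulation of every candidate, nearest-neighbor primer QC, gel-band
  visibility filtering, and panel genotyping.
- **fixtures** — deterministic synthetic plastomes and allele loci, plus
  the packaged 43-cultivar genotyping panel and marker primer pair.
- **cli** — a `plastocaps` console script exposing each step.

## The marker in one paragraph

dCAPS (derived Cleaved Amplified Polymorphic Sequence): when a variant
does not itself create a restriction-site difference, a primer carrying a
deliberate mismatch completes a recognition site in exactly one allele's
PCR product. Here the reverse primer's 3'-terminal base writes a T into
the amplicon top strand; together with the `..CCATA-AT` bases supplied by
the ATA insertion this completes an `AATT` *Mlu*CI site, so the insertion
allele's 137-bp product is cleaved (105 bp + the remainder) while the
non-insertion 134-bp product stays uncut. The forward primer's terminal
A→C edit removes a constitutive template `AATT` that would otherwise cut
both alleles.

## Worked example

Genotype the packaged 43-cultivar panel with the packaged marker:

```console
$ plastocaps --no-timestamp genotype
# plastocaps 0.1.0
# params: {"marker": "packaged", "panel": "packaged"}
sample	call	observed_fragments	reason
HSVM	cut_allele	105,32	pattern containment
HS 'Andong'	cut_allele	105,32	pattern containment
HS 'Lil Kim'	cut_allele	105,32	pattern containment
...
# samples	43	cut_allele	11
```

Exactly 11 of the 43 cultivars carry the insertion allele (HSVM, its
graft mutants and the cultivars bred with them as maternal parent); the
other 32 are called `uncut_allele`. Simulating the assay itself on the
reconstructed locus:

```console
$ plastocaps --no-timestamp pcr-digest --template alt.fa \
    --fwd ATGCAAAATCTATTTATATGAAAAATAAAAAGC \
    --rev AATCAGTTTTTCAAAAGATTTATCAGACA --enzyme MluCI
metric	value
product_bp	137
fragments	105,32
visible_bands	105,32
```

The non-insertion template gives `product_bp 134` and a single uncut
`134` band. Fragments shorter than 20 bp are dropped by the gel-visibility
filter (`predict_gel`), mirroring what a 2% agarose gel resolves.

Partition a plastome and report junction genes:

```bash
plastocaps partition genome.gb --min-ir 1000 --tsv regions.tsv --bed regions.bed
plastocaps junctions genome.gb --genes rps19,rpl2,ycf1,rps15
plastocaps compare a.gb b.gb            # gap-excluded identity, gaps, SNPs
plastocaps dcaps-design --ref ref.fa --alt alt.fa --json marker.json
plastocaps genotype --marker marker.json --panel panel.tsv --tsv calls.tsv
```

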