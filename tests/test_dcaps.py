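import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import iupac_expansions

from plastocaps.dcaps import (
    DcapsMarker,
    DesignConstraints,
    PcrError,
    RestrictionEnzyme,
    builtin_enzyme,
    design_dcaps,
    digest,
    fragments_distinguishable,
    genotype_panel,
    insilico_pcr,
    load_enzyme_table,
    predict_gel,
    primer_qc,
    scan_sites,
)
from plastocaps.fixtures import (
    load_marker_primers,
    marker_locus,
    packaged_marker,
    random_dna,
)
from plastocaps.seqio import revcomp

MLUCI = builtin_enzyme("MluCI")
ENZYME_NAMES = ["MluCI", "EcoRI", "DpnII", "TaqI", "HinfI", "RsaI", "MseI"]


class TestEnzymes:
    def test_caret_parsing(self):
        e = RestrictionEnzyme.from_caret("EcoRI", "G^AATTC")
        assert (e.site, e.cut_offset_top, e.cut_offset_bottom) == ("GAATTC", 1, 5)
        assert e.is_palindromic

    def test_palindrome_offset_invariant(self):
        for name in ENZYME_NAMES:
            e = builtin_enzyme(name)
            if e.is_palindromic:
                assert e.cut_offset_bottom == len(e.site) - e.cut_offset_top

    def test_site_length_bounds(self):
        with pytest.raises(ValueError):
            RestrictionEnzyme(name="bad", site="ACT", cut_offset_top=0, cut_offset_bottom=3)

    def test_tsv_loading(self, tmp_path):
        p = tmp_path / "enz.tsv"
        p.write_text("# custom\nFakeI\tAC^GT\n")
        table = load_enzyme_table(p)
        assert table["FakeI"].cut_offset_top == 2


class TestScanSites:
    def test_absence(self):
        assert scan_sites("GGGGGG", MLUCI) == []

    def test_manual_scan(self):
        # AATT occurrences at 0-based 2 and 10; MluCI cuts at the site start
        assert scan_sites("AAAATTCCCCAATTGG", MLUCI) == [2, 10]

    @pytest.mark.parametrize("name", ENZYME_NAMES)
    def test_palindromic_strand_symmetry(self, name):
        """A palindromic site yields mirror-image cut sets on the two strands."""
        enzyme = builtin_enzyme(name)
        assert enzyme.is_palindromic
        rng = random.Random(hash(name) % 2**31)
        seq = random_dna(rng, 600, gc=0.5)
        cuts = scan_sites(seq, enzyme)
        # plus-strand matches alone already give the full cut set
        plus_only = set()
        for word in iupac_expansions(enzyme.site):
            start = 0
            while (i := seq.find(word, start)) != -1:
                plus_only.add(i + enzyme.cut_offset_top)
                start = i + 1
        assert cuts == sorted(plus_only)
        # and the cut set mirrors correctly onto the reverse complement
        L, cot = len(enzyme.site), enzyme.cut_offset_top
        mirrored = sorted(len(seq) - L + 2 * cot - c for c in scan_sites(revcomp(seq), enzyme))
        assert cuts == mirrored

    def test_iupac_expansion_matches_literal_enumeration(self):
        enzyme = builtin_enzyme("HinfI")  # G^ANTC
        rng = random.Random(7)
        seq = random_dna(rng, 800, gc=0.5)
        expected = set()
        for word in iupac_expansions(enzyme.site):
            start = 0
            while (i := seq.find(word, start)) != -1:
                expected.add(i + enzyme.cut_offset_top)
                start = i + 1
        for word in iupac_expansions(revcomp(enzyme.site)):
            start = 0
            while (i := seq.find(word, start)) != -1:
                expected.add(i + len(enzyme.site) - enzyme.cut_offset_bottom)
                start = i + 1
        assert scan_sites(seq, enzyme) == sorted(expected)


class TestDigest:
    def test_no_site(self):
        assert digest("GGGGGGGGGG", MLUCI) == [10]

    def test_two_cut_fragments(self):
        assert digest("AAAATTCCCCAATTGG", MLUCI) == [8, 6, 2]

    @given(st.integers(0, 2**31 - 1), st.sampled_from(ENZYME_NAMES))
    @settings(max_examples=150, derandomize=True)
    def test_mass_conservation(self, seed, name):
        """Fragment lengths always sum to the amplicon length."""
        rng = random.Random(seed)
        amplicon = random_dna(rng, rng.randint(20, 400), gc=0.5)
        frags = digest(amplicon, builtin_enzyme(name))
        assert sum(frags) == len(amplicon)
        assert frags == sorted(frags, reverse=True)


class TestInsilicoPcr:
    def test_exact_end_primers_reproduce_template(self):
        rng = random.Random(11)
        tmpl = random_dna(rng, 200)
        amp = insilico_pcr(tmpl, tmpl[:20], revcomp(tmpl[-20:]))
        assert amp.sequence == tmpl
        assert (amp.template_start, amp.template_end) == (0, 200)

    def test_primer_mismatch_propagates(self):
        rng = random.Random(12)
        tmpl = random_dna(rng, 200)
        fwd = list(tmpl[:20])
        fwd[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[fwd[10]]
        amp = insilico_pcr(tmpl, "".join(fwd), revcomp(tmpl[-20:]))
        diffs = [i for i, (x, y) in enumerate(zip(amp.sequence, tmpl)) if x != y]
        assert diffs == [10]

    def test_no_site_error(self):
        rng = random.Random(13)
        tmpl = random_dna(rng, 200)
        with pytest.raises(PcrError) as exc:
            insilico_pcr(tmpl, "GCGCGCGCATATATGCGCGC", revcomp(tmpl[-20:]))
        assert exc.value.code == "E_NO_SITE"

    def test_multiple_binding_sites_error(self):
        rng = random.Random(14)
        block = random_dna(rng, 40)
        tmpl = block + random_dna(rng, 60) + block + random_dna(rng, 60)
        with pytest.raises(PcrError) as exc:
            insilico_pcr(tmpl, block[:20], revcomp(tmpl[-20:]))
        assert exc.value.code == "E_MULTI_SITE"

    def test_product_bounds_error(self):
        from plastocaps.dcaps import PcrParams

        rng = random.Random(15)
        tmpl = random_dna(rng, 500)
        with pytest.raises(PcrError) as exc:
            insilico_pcr(tmpl, tmpl[:20], revcomp(tmpl[-20:]), PcrParams(max_product=100))
        assert exc.value.code == "E_PRODUCT_BOUNDS"

    def test_printed_primers_on_reconstructed_locus(self):
        primers = load_marker_primers()
        ref, alt = marker_locus()
        assert len(insilico_pcr(ref, primers["forward"], primers["reverse"])) == 134
        assert len(insilico_pcr(alt, primers["forward"], primers["reverse"])) == 137


class TestPrimerQc:
    def test_printed_primer_lengths(self):
        primers = load_marker_primers()
        assert primer_qc(primers["forward"]).length == 33
        assert primer_qc(primers["reverse"]).length == 29

    def test_gc_exact(self):
        assert primer_qc("ATGCATGCATGC").gc_pct == 50.0
        assert primer_qc("AAAAAAAAAA").gc_pct == 0.0

    def test_planted_hairpin_stem(self):
        # GCGCG pairs with CGCGC antiparallel: stem of 5
        assert primer_qc("GCGCGAAAAAAACGCGC").hairpin_stem == 5

    def test_dimer_run_anchored_at_three_prime(self):
        # 3' end ...ACGT pairs with ACGT in the partner
        qc = primer_qc("TTTTTTTTTTTTACGT", "TTTTACGTTTTTTTTT")
        assert qc.dimer_run >= 4

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            primer_qc("ACGT")


class TestPredictGel:
    @pytest.mark.parametrize(
        "frags,expected",
        [([105, 28, 4], [105, 28]), ([134], [134]), ([], []), ([19, 20], [20])],
    )
    def test_visibility_floor(self, frags, expected):
        assert predict_gel(frags) == expected


def _plant_snp(rng, n=200):
    """A random locus and its single-SNP mutant."""
    seq = random_dna(rng, n)
    pos = rng.randint(80, n - 80)
    alt_base = rng.choice([b for b in "ACGT" if b != seq[pos]])
    return seq, seq[:pos] + alt_base + seq[pos + 1 :]


class TestDesignDcaps:
    def test_native_site_gives_plain_caps(self):
        # SNP completes GAATTC in the alt allele: no primer edits needed
        rng = random.Random(21)
        left = random_dna(rng, 90).replace("AATT", "ACTT")
        right = random_dna(rng, 90).replace("AATT", "ACTT")
        ref = left + "GAcTTC".upper() + right
        alt = left + "GAATTC" + right
        res = design_dcaps(ref, alt, enzymes=[builtin_enzyme("EcoRI")])
        assert res, res.rejections
        best = res[0]
        assert best.n_introduced == 0
        assert best.cut_allele == "alt"

    def test_insertion_allele_cut_reference_uncut(self, allele_locus_pair):
        """The printed allele pair + MluCI yields an insertion-specific cut."""
        ref, alt = allele_locus_pair
        res = design_dcaps(ref, alt, enzymes=[MLUCI])
        assert res, res.rejections
        good = [
            m
            for m in res
            if m.cut_allele == "alt"
            and m.predicted_fragments["ref"] == [sum(m.predicted_fragments["ref"])]
            and len(m.predicted_fragments["alt"]) > 1
        ]
        assert good

    @pytest.mark.parametrize("seed", range(10))
    def test_soundness_resimulation(self, seed):
        """Every emitted marker reproduces its own fragment predictions."""
        rng = random.Random(seed)
        ref, alt = _plant_snp(rng)
        res = design_dcaps(ref, alt)
        for marker in res[:10]:
            ref_s = ref if marker.forward.strand == "+" else revcomp(ref)
            alt_s = alt if marker.forward.strand == "+" else revcomp(alt)
            amp_ref = insilico_pcr(ref_s, marker.forward.sequence, marker.reverse.sequence)
            amp_alt = insilico_pcr(alt_s, marker.forward.sequence, marker.reverse.sequence)
            assert digest(amp_ref.sequence, marker.enzyme) == marker.predicted_fragments["ref"]
            assert digest(amp_alt.sequence, marker.enzyme) == marker.predicted_fragments["alt"]

    @pytest.mark.parametrize("seed", range(6))
    def test_completeness_vs_brute_force(self, seed):
        """A design exists whenever exhaustive single-edit enumeration finds one."""
        rng = random.Random(1000 + seed)
        ref, alt = _plant_snp(rng, n=220)
        enzyme = builtin_enzyme(rng.choice(ENZYME_NAMES))
        constraints = DesignConstraints()
        found_by_brute = False
        for strand in "+-":
            ref_s = ref if strand == "+" else revcomp(ref)
            alt_s = alt if strand == "+" else revcomp(alt)
            pre = next(i for i, (x, y) in enumerate(zip(ref_s, alt_s)) if x != y)
            opp = revcomp(ref_s[-22:])
            for end in range(max(20, pre - constraints.max_dist_3prime), pre + 1):
                base = ref_s[end - 22 : end]
                if len(base) < 22:
                    continue
                variants = [base] + [
                    base[:i] + b + base[i + 1 :]
                    for i in range(22 - constraints.mod_window, 22)
                    for b in "ACGT"
                    if b != base[i]
                ]
                for primer in variants:
                    try:
                        fr = digest(insilico_pcr(ref_s, primer, opp).sequence, enzyme)
                        fa = digest(insilico_pcr(alt_s, primer, opp).sequence, enzyme)
                    except PcrError:
                        continue
                    if sorted(fr) != sorted(fa) and fragments_distinguishable(fr, fa):
                        found_by_brute = True
                        break
                if found_by_brute:
                    break
            if found_by_brute:
                break
        res = design_dcaps(ref, alt, enzymes=[enzyme], constraints=constraints)
        if found_by_brute:
            assert res, f"brute force found a design but design_dcaps did not: {res.rejections}"

    def test_identical_contexts_rejected(self):
        rng = random.Random(30)
        seq = random_dna(rng, 200)
        with pytest.raises(ValueError):
            design_dcaps(seq, seq)


class TestGenotyping:
    def test_all_n_window_uninformative(self):
        marker = packaged_marker()
        (call,) = genotype_panel(marker, [("blank", "NNNNNNNNNN")])
        assert call.call == "uninformative"

    def test_full_sequences_called_by_simulation(self):
        marker = packaged_marker()
        ref, alt = marker_locus()
        calls = genotype_panel(marker, [("noins", ref), ("ins", alt)])
        assert [c.call for c in calls] == ["uncut_allele", "cut_allele"]
        assert list(calls[1].observed_fragments) == [105, 32]
        assert list(calls[0].observed_fragments) == [134]

    def test_window_classification_by_containment(self):
        marker = packaged_marker()
        calls = genotype_panel(
            marker,
            [("ins", "CACTCCATAATAGTCTGATA"), ("del", "CACTCCATA---GTCTGATA")],
        )
        assert [c.call for c in calls] == ["cut_allele", "uncut_allele"]

    def test_marker_json_round_trip(self, tmp_path):
        marker = packaged_marker()
        p = tmp_path / "marker.json"
        marker.to_json(p)
        back = DcapsMarker.from_json(p)
        assert back.predicted_fragments == marker.predicted_fragments
        assert back.enzyme == marker.enzyme
        assert back.forward == marker.forward
        assert back.allele_patterns == marker.allele_patterns

    def test_uninformative_fragments(self):
        marker = packaged_marker()
        rng = random.Random(40)
        stranger = random_dna(rng, 300)
        (call,) = genotype_panel(marker, [("other", stranger)])
        assert call.call == "uninformative"
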