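import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastocaps.seqio import (
    Feature,
    GenomeRecord,
    ParseError,
    feature_to_genbank_location,
    read_allele_table,
    read_fasta,
    read_genbank,
    revcomp,
    write_fasta,
)

IUPAC = "ACGTNRYSWKMBDHV"


class TestFasta:
    def test_single_entry(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">x\nacgt\n")
        (rec,) = read_fasta(p)
        assert rec.id == "x"
        assert rec.sequence == "ACGT"
        assert len(rec) == 4
        assert not rec.circular

    def test_two_entries_order_preserved(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">a\nAC\nGT\n>b circular\nTTTT\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["a", "b"]
        assert recs[0].sequence == "ACGT"
        assert recs[1].circular

    def test_u_mapped_to_t(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">t\nACGU\n")
        assert read_fasta(p)[0].sequence == "ACGT"

    def test_bad_character_names_line(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">x\nACGT\nAJGT\n")
        with pytest.raises(ParseError, match=r":3"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text("")
        with pytest.raises(ParseError):
            read_fasta(p)

    def test_round_trip_byte_exact(self, tmp_path):
        recs = [
            GenomeRecord(id="one", sequence="ACGT" * 40),
            GenomeRecord(id="two", sequence="GGGTTTAAAN", circular=True),
        ]
        p = tmp_path / "rt.fa"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [(r.id, r.sequence, r.circular) for r in back] == [
            (r.id, r.sequence, r.circular) for r in recs
        ]


TOY_GENBANK = """\
LOCUS       toy                       40 bp    DNA     circular PLN 01-JAN-2024
DEFINITION  toy record.
ACCESSION   toy
FEATURES             Location/Qualifiers
     source          1..40
                     /organism="synthetic"
     gene            10..20
                     /gene="alpha"
     tRNA            complement(5..8)
                     /gene="trnX"
     gene            join(30..34,36..40)
                     /gene="beta"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
"""


class TestGenBank:
    @pytest.fixture()
    def toy_gb(self, tmp_path):
        p = tmp_path / "toy.gb"
        p.write_text(TOY_GENBANK)
        return read_genbank(p)

    def test_coordinates_zero_based_half_open(self, toy_gb):
        alpha = toy_gb.feature_by_name("alpha")
        assert alpha.parts == ((9, 20),)
        assert alpha.strand == "+"

    def test_complement_location(self, toy_gb):
        trn = toy_gb.feature_by_name("trnX")
        assert trn.strand == "-"
        assert trn.parts == ((4, 8),)
        assert trn.kind == "tRNA"

    def test_join_location(self, toy_gb):
        beta = toy_gb.feature_by_name("beta")
        assert beta.parts == ((29, 34), (35, 40))

    def test_circular_topology_and_sequence(self, toy_gb):
        assert toy_gb.circular
        assert toy_gb.sequence == "ACGT" * 10

    def test_location_round_trip(self, toy_gb):
        assert feature_to_genbank_location(toy_gb.feature_by_name("alpha")) == "10..20"
        assert feature_to_genbank_location(toy_gb.feature_by_name("trnX")) == "complement(5..8)"
        assert feature_to_genbank_location(toy_gb.feature_by_name("beta")) == "join(30..34,36..40)"

    @pytest.mark.filterwarnings("ignore:Attempting to parse malformed locus line")
    def test_missing_origin_rejected(self, tmp_path):
        p = tmp_path / "bad.gb"
        p.write_text("LOCUS       bad  0 bp DNA linear PLN 01-JAN-2024\n//\n")
        with pytest.raises(ParseError):
            read_genbank(p)


class TestAlleleTable:
    def test_packaged_panel_shape(self):
        from plastocaps.fixtures import load_cultivar_panel

        panel = load_cultivar_panel()
        assert len(panel) == 43
        assert panel[0].name == "HSVM"
        assert panel[0].sequence_window == "CACTCCATAATAGTCTGATA"
        assert len(panel[0].sequence_window) == 20
        assert "-" not in panel[0].sequence_window
        assert panel[3].sequence_window.count("-") == 3

    def test_markup_stripped_and_metadata_kept(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text("name\tcountry\tsequence\nA\tKR\tCAC**TCC**ATA\n")
        (rec,) = read_allele_table(p)
        assert rec.sequence_window == "CACTCCATA"
        assert rec.metadata["country"] == "KR"

    def test_duplicate_names_warn_not_error(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text("name\tsequence\nA\tACGT\nA\tACGT\n")
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            recs = read_allele_table(p)
        assert len(recs) == 2
        assert any("duplicate" in str(x.message) for x in w)

    def test_missing_sequence_column(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text("name\tcolor\nA\tred\n")
        with pytest.raises(ParseError, match="sequence column"):
            read_allele_table(p)


class TestRevcomp:
    @pytest.mark.parametrize(
        "seq,expected",
        [("AATT", "AATT"), ("ACGTN", "NACGT"), ("RY", "RY"), ("GANTC", "GANTC")],
    )
    def test_examples(self, seq, expected):
        assert revcomp(seq) == expected

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError):
            revcomp("ACJT")

    @given(st.text(alphabet=IUPAC, min_size=1, max_size=200))
    @settings(max_examples=100, derandomize=True)
    def test_involution_and_length(self, seq):
        rc = revcomp(seq)
        assert len(rc) == len(seq)
        assert revcomp(rc) == seq


class TestDomainTypes:
    def test_record_rejects_bad_alphabet(self):
        with pytest.raises(ValueError):
            GenomeRecord(id="x", sequence="ACGJ")

    def test_record_rejects_out_of_bounds_feature(self):
        f = Feature(name="g", kind="gene", strand="+", parts=((2, 10),))
        with pytest.raises(ValueError):
            GenomeRecord(id="x", sequence="ACGT", features=[f])

    def test_feature_rejects_empty_interval(self):
        with pytest.raises(ValueError):
            Feature(name="g", kind="gene", strand="+", parts=((5, 5),))
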