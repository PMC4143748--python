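"""Reading, matching, allele-consistency, and harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gtconcord import (
    GenotypeMatrix, VariantRecord, check_allele_consistency, harmonize,
    match_variants, read_genotypes, write_genotypes_tsv,
)
from gtconcord.calls import CALL_LABELS
from gtconcord.genio import GenotypeParseError

from conftest import make_matrix


def var(rs, major, minor):
    return VariantRecord(rs, "1", 100, major, minor)


class TestVariantRecord:
    @pytest.mark.parametrize("kwargs", [
        dict(rs_id="", major="A", minor="G"),
        dict(rs_id="rs1", major="A", minor="A"),
        dict(rs_id="rs1", major="N", minor="G"),
        dict(rs_id="rs1", major="A", minor="G", pos=0),
    ])
    def test_invalid_records_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VariantRecord(kwargs.get("rs_id", "rs1"), "1",
                          kwargs.get("pos", 100),
                          kwargs["major"], kwargs["minor"])


class TestTsv:
    def test_read_simple(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("rs_id\tchrom\tpos\tallele_major\tallele_minor"
                     "\ts1\ts2\ts3\n"
                     "rs1\t1\t100\tA\tG\tAA\tAB\tXX\n")
        gm = read_genotypes(p, "tsv")
        assert gm.n_variants == 1 and gm.samples == ["s1", "s2", "s3"]
        assert list(gm.to_frame().loc["rs1"]) == ["AA", "AB", "XX"]

    def test_na_maps_to_missing(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("rs_id\tchrom\tpos\tallele_major\tallele_minor\ts1\n"
                     "rs1\t1\t100\tA\tG\tNA\n")
        assert read_genotypes(p, "tsv").to_frame().iloc[0, 0] == "XX"

    def test_bad_call_reports_position(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("rs_id\tchrom\tpos\tallele_major\tallele_minor\ts1\n"
                     "rs1\t1\t100\tA\tG\tZZ\n")
        with pytest.raises(GenotypeParseError, match="line 2.*s1"):
            read_genotypes(p, "tsv")

    def test_wrong_header_fatal(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("snp\tchrom\tpos\tmaj\tmin\ts1\nrs1\t1\t100\tA\tG\tAA\n")
        with pytest.raises(GenotypeParseError):
            read_genotypes(p, "tsv")

    def test_round_trip_exact(self, tmp_path, rng):
        gm = make_matrix(
            {f"rs{i}": list(np.array(CALL_LABELS)[rng.integers(0, 4, 7)])
             for i in range(11)},
            alleles={"rs3": ("C", "T")})
        p = tmp_path / "rt.tsv"
        write_genotypes_tsv(gm, p)
        assert read_genotypes(p, "tsv").equals(gm)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_property(self, tmp_path_factory, seed):
        r = np.random.default_rng(seed)
        n_var, n_smp = int(r.integers(1, 6)), int(r.integers(1, 6))
        gm = make_matrix(
            {f"rs{i}": list(np.array(CALL_LABELS)[r.integers(0, 4, n_smp)])
             for i in range(n_var)})
        p = tmp_path_factory.mktemp("rt") / "g.tsv"
        write_genotypes_tsv(gm, p)
        assert read_genotypes(p, "tsv").equals(gm)


VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
"""


class TestVcf:
    def test_read_calls_and_missing(self, tmp_path):
        p = tmp_path / "g.vcf"
        p.write_text(VCF_HEADER
                     + "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t./.\n"
                     + "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t1/1\t0/0\t0/1\n")
        gm = read_genotypes(p, "vcf")
        assert gm.rs_ids == ["rs1", "rs2"]
        assert list(gm.to_frame().loc["rs1"]) == ["AA", "AB", "XX"]
        assert list(gm.to_frame().loc["rs2"]) == ["BB", "AA", "AB"]
        # REF/ALT populate the major/minor allele metadata
        assert gm.variant_record("rs2").alleles == ("C", "T")

    def test_multiallelic_excluded(self, tmp_path):
        p = tmp_path / "g.vcf"
        p.write_text(VCF_HEADER
                     + "1\t100\trs1\tA\tG,T\t.\t.\t.\tGT\t0/0\t0/1\t2/2\n"
                     + "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0/0\t0/0\t0/0\n")
        gm = read_genotypes(p, "vcf")
        assert gm.rs_ids == ["rs2"]


class TestPlinkText:
    def _write(self, tmp_path, ped, vmap):
        (tmp_path / "d.ped").write_text(ped)
        (tmp_path / "d.map").write_text(vmap)
        return tmp_path / "d.ped"

    def test_major_allele_from_frequency(self, tmp_path):
        # G is the more frequent allele -> major; 'G G' encodes as AA
        ped = ("F1 I1 0 0 1 0 G G\n"
               "F2 I2 0 0 1 0 G A\n"
               "F3 I3 0 0 1 0 G G\n")
        p = self._write(tmp_path, ped, "1 rs1 0 100\n")
        gm = read_genotypes(p, "plink_text")
        assert gm.variant_record("rs1").alleles == ("G", "A")
        assert list(gm.to_frame().loc["rs1"]) == ["AA", "AB", "AA"]

    def test_frequency_tie_broken_alphabetically(self, tmp_path):
        ped = ("F1 I1 0 0 1 0 G A\n"
               "F2 I2 0 0 1 0 A G\n")
        p = self._write(tmp_path, ped, "1 rs1 0 100\n")
        assert read_genotypes(p, "plink_text").variant_record("rs1").alleles \
            == ("A", "G")

    def test_missing_code(self, tmp_path):
        ped = ("F1 I1 0 0 1 0 0 0 A A\n"
               "F2 I2 0 0 1 0 A C A C\n")
        p = self._write(tmp_path, ped, "1 rs1 0 100\n1 rs2 0 200\n")
        gm = read_genotypes(p, "plink_text")
        assert list(gm.to_frame().loc["rs1"]) == ["XX", "AB"]
        assert list(gm.to_frame().loc["rs2"]) == ["AA", "AB"]

    def test_field_count_mismatch_fatal(self, tmp_path):
        p = self._write(tmp_path, "F1 I1 0 0 1 0 A\n", "1 rs1 0 100\n")
        with pytest.raises(GenotypeParseError, match="expected 8 fields"):
            read_genotypes(p, "plink_text")


class TestMatchVariants:
    def test_intersection_in_a_order(self):
        a = make_matrix({"rs1": ["AA"], "rs2": ["AB"]})
        b = make_matrix({"rs2": ["AA"], "rs3": ["AB"]})
        assert match_variants(a, b) == ["rs2"]

    def test_identical_lists(self):
        a = make_matrix({"rs1": ["AA"], "rs2": ["AB"]})
        assert match_variants(a, a) == ["rs1", "rs2"]

    def test_disjoint_fatal(self):
        a = make_matrix({"rs1": ["AA"]})
        b = make_matrix({"rs9": ["AA"]})
        with pytest.raises(ValueError, match="no shared rs_ids"):
            match_variants(a, b)


class TestAlleleConsistency:
    @pytest.mark.parametrize("pa, pb, flips, expected", [
        (("A", "G"), ("A", "G"), False, "identical"),
        (("A", "G"), ("G", "A"), False, "swapped"),
        (("A", "G"), ("T", "C"), True, "strand_flip"),
        (("A", "G"), ("C", "T"), True, "strand_flip_swapped"),
        (("A", "G"), ("T", "C"), False, "mismatch"),
        (("A", "G"), ("A", "C"), False, "mismatch"),
        (("A", "G"), ("A", "C"), True, "mismatch"),
        (("A", "T"), ("A", "T"), True, "ambiguous_palindromic"),
        (("C", "G"), ("G", "C"), True, "ambiguous_palindromic"),
        (("A", "T"), ("A", "T"), False, "identical"),
        (("A", "T"), ("T", "A"), False, "swapped"),
    ])
    def test_classification(self, pa, pb, flips, expected):
        assert check_allele_consistency(
            var("rs1", *pa), var("rs1", *pb), allow_strand_flip=flips
        ) == expected

    def test_rsid_mismatch_raises(self):
        with pytest.raises(ValueError):
            check_allele_consistency(var("rs1", "A", "G"), var("rs2", "A", "G"))


class TestHarmonize:
    def test_mismatch_excluded_with_accounting(self):
        seq = make_matrix({"rs1": ["AA"], "rs2": ["AB"], "rs3": ["BB"]})
        micro = make_matrix({"rs1": ["AA"], "rs2": ["AB"], "rs3": ["BB"]},
                            alleles={"rs3": ("C", "T")})
        pair = harmonize(seq, micro)
        assert pair.rs_ids == ["rs1", "rs2"]
        assert len(pair.exclusions) == 1
        assert pair.exclusions.iloc[0].rs_id == "rs3"
        assert pair.exclusions.iloc[0].reason == "mismatch"
        assert pair.n_variants + len(pair.exclusions) == pair.n_matched == 3

    def test_swapped_orientation_relabels_calls(self):
        seq = make_matrix({"rs1": ["AA", "AB", "BB", "XX"]})
        micro = make_matrix({"rs1": ["BB", "AB", "AA", "XX"]},
                            alleles={"rs1": ("G", "A")})
        pair = harmonize(seq, micro)
        assert pair.orientation["rs1"] == "swapped"
        # after relabelling onto seq's frame the calls agree
        assert list(pair.micro.to_frame().loc["rs1"]) == ["AA", "AB", "BB", "XX"]
        assert pair.micro.variant_record("rs1").alleles == ("A", "G")

    def test_swap_twice_restores(self):
        from gtconcord.genio import _SWAP_RECODE
        calls = np.array([0, 1, 2, 3], dtype=np.int8)
        assert np.array_equal(_SWAP_RECODE[_SWAP_RECODE[calls]], calls)

    def test_strand_flip_rescued_only_when_allowed(self):
        seq = make_matrix({"rs1": ["AA", "AB"]})
        micro = make_matrix({"rs1": ["AA", "AB"]},
                            alleles={"rs1": ("T", "C")})
        strict = harmonize(seq, micro)
        assert strict.n_variants == 0 and len(strict.exclusions) == 1
        rescued = harmonize(seq, micro, allow_strand_flip=True)
        assert rescued.orientation["rs1"] == "strand_flip"
        # strand flip only reorients the allele metadata, not the calls
        assert list(rescued.micro.to_frame().loc["rs1"]) == ["AA", "AB"]
        assert rescued.micro.variant_record("rs1").alleles == ("A", "G")

    def test_palindromic_excluded_when_flips_allowed(self):
        seq = make_matrix({"rs1": ["AA"]}, alleles={"rs1": ("A", "T")})
        micro = make_matrix({"rs1": ["AA"]}, alleles={"rs1": ("A", "T")})
        pair = harmonize(seq, micro, allow_strand_flip=True)
        assert len(pair.exclusions) == 1
        assert pair.exclusions.iloc[0].reason == "ambiguous_palindromic"
        kept = harmonize(seq, micro, allow_strand_flip=True,
                         keep_palindromic=True)
        assert kept.n_variants == 1

    def test_sample_intersection_and_no_overlap_fatal(self):
        seq = make_matrix({"rs1": ["AA", "AB"]}, samples=["s1", "s2"])
        micro = make_matrix({"rs1": ["AA", "BB"]}, samples=["s2", "s3"])
        pair = harmonize(seq, micro)
        assert pair.samples == ["s2"]
        micro2 = make_matrix({"rs1": ["AA"]}, samples=["s9"])
        with pytest.raises(ValueError, match="no shared samples"):
            harmonize(seq, micro2)

    def test_idempotent(self, rng):
        labels = np.array(CALL_LABELS, dtype=object)
        seq = make_matrix(
            {f"rs{i}": list(labels[rng.integers(0, 4, 6)]) for i in range(8)},
            alleles={"rs2": ("C", "T")})
        micro = make_matrix(
            {f"rs{i}": list(labels[rng.integers(0, 4, 6)]) for i in range(8)},
            alleles={"rs2": ("T", "C"), "rs5": ("G", "A")})
        once = harmonize(seq, micro)
        twice = harmonize(once.seq, once.micro)
        assert twice.seq.equals(once.seq) and twice.micro.equals(once.micro)
        assert len(twice.exclusions) == 0
        assert (twice.orientation == "identical").all()


class TestGenotypeMatrixValidation:
    def test_duplicate_rsid_rejected(self):
        variants = pd.DataFrame({
            "rs_id": ["rs1", "rs1"], "chrom": "1", "pos": [1, 2],
            "allele_major": "A", "allele_minor": "G"})
        with pytest.raises(ValueError, match="duplicate rs_id"):
            GenotypeMatrix(variants, ["s1"], np.zeros((2, 1), dtype=np.int8))

    def test_duplicate_sample_rejected(self):
        variants = pd.DataFrame({
            "rs_id": ["rs1"], "chrom": "1", "pos": [1],
            "allele_major": "A", "allele_minor": "G"})
        with pytest.raises(ValueError, match="duplicate sample"):
            GenotypeMatrix(variants, ["s1", "s1"],
                           np.zeros((1, 2), dtype=np.int8))

    def test_shape_mismatch_rejected(self):
        variants = pd.DataFrame({
            "rs_id": ["rs1"], "chrom": "1", "pos": [1],
            "allele_major": "A", "allele_minor": "G"})
        with pytest.raises(ValueError, match="shape"):
            GenotypeMatrix(variants, ["s1"], np.zeros((2, 1), dtype=np.int8))
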