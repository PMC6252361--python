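"""Pedigree parsing, VCF normalization, decomposition and round-trips."""

from __future__ import annotations

import pytest

from triotriage.models import Genotype, PedigreeError, Sex
from triotriage.simulate import TOY_CONTIGS, TrioPlan, simulate_trio, toy_filter_config
from triotriage.variant_io import (
    AnnotationKeys,
    VcfFormatError,
    normalize_chrom,
    read_pedigree,
    read_trio_vcf,
    write_pedigree,
    write_trio_vcf,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##INFO=<ID=AF_1KG,Number=A,Type=Float,Description="x">
##INFO=<ID=AF_EXAC,Number=A,Type=Float,Description="x">
##INFO=<ID=AF_EVS,Number=A,Type=Float,Description="x">
##INFO=<ID=EXAC_HOM,Number=A,Type=Integer,Description="x">
##INFO=<ID=CSQ_CAT,Number=1,Type=String,Description="x">
##INFO=<ID=GENE,Number=1,Type=String,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tM1\tF1
"""


def write_vcf(tmp_path, records):
    path = tmp_path / "t.vcf"
    path.write_text(VCF_HEADER + "\n".join(records) + "\n")
    return path


class TestPedigree:
    def test_three_row_ped_maps_roles_and_sex(self, tmp_path):
        p = tmp_path / "fam.ped"
        p.write_text(
            "fam1\tF1\t0\t0\t1\t1\nfam1\tM1\t0\t0\t2\t1\nfam1\tP1\tF1\tM1\t1\t2\n"
        )
        ped = read_pedigree(p)
        assert (ped.proband_id, ped.mother_id, ped.father_id) == ("P1", "M1", "F1")
        assert ped.proband_sex is Sex.MALE

    def test_missing_father_is_incomplete_trio(self, tmp_path):
        p = tmp_path / "fam.ped"
        p.write_text(
            "fam1\tM1\t0\t0\t2\t1\nfam1\tP1\t0\tM1\t2\t2\n"
        )
        with pytest.raises(PedigreeError, match="incomplete trio"):
            read_pedigree(p)

    def test_fourth_family_member_rejected_by_name(self, tmp_path):
        p = tmp_path / "fam.ped"
        p.write_text(
            "fam1\tF1\t0\t0\t1\t1\nfam1\tM1\t0\t0\t2\t1\n"
            "fam1\tP1\tF1\tM1\t2\t2\nfam1\tSIB\tF1\tM1\t1\t1\n"
        )
        with pytest.raises(PedigreeError, match="SIB"):
            read_pedigree(p)

    def test_duplicate_sample_id_is_format_error(self, tmp_path):
        p = tmp_path / "fam.ped"
        p.write_text(
            "fam1\tF1\t0\t0\t1\t1\nfam1\tF1\t0\t0\t2\t1\nfam1\tP1\tF1\tF1\t2\t2\n"
        )
        with pytest.raises(PedigreeError, match="duplicate"):
            read_pedigree(p)

    def test_pedigree_roundtrip(self, tmp_path, male_ped):
        write_pedigree(tmp_path / "out.ped", male_ped)
        assert read_pedigree(tmp_path / "out.ped") == male_ped


@pytest.mark.parametrize(
    "raw, expected, canonical",
    [
        ("X", "chrX", True),
        ("chr7", "chr7", True),
        ("MT", "chrM", True),
        ("22", "chr22", True),
        ("GL000220.1", "GL000220.1", False),
    ],
)
def test_normalize_chrom(raw, expected, canonical):
    assert normalize_chrom(raw) == (expected, canonical)


class TestDecomposition:
    # hand-enumerated recodings of every GT over two alt alleles:
    # for record k, allele k counts as alt and the other alt as reference
    GT_RECODING = {
        "0/0": ("hom_ref", "hom_ref"),
        "0/1": ("het", "hom_ref"),
        "0/2": ("hom_ref", "het"),
        "1/1": ("hom_alt", "hom_ref"),
        "1/2": ("het", "het"),
        "2/2": ("hom_ref", "hom_alt"),
        "./.": ("missing", "missing"),
    }

    @pytest.mark.parametrize("gt", sorted(GT_RECODING))
    def test_two_alt_recoding_matches_enumeration(self, tmp_path, ped, gt):
        rec = (
            f"chr1\t100\t.\tA\tC,G\t.\tPASS\tCSQ_CAT=synonymous\t"
            f"GT:GQ:DP\t{gt}:60:30\t0/0:60:30\t0/0:60:30"
        )
        out = list(read_trio_vcf(write_vcf(tmp_path, [rec]), ped))
        assert len(out) == 2
        assert [v.alt for v in out] == ["C", "G"]
        states = tuple(v.genotypes.proband.value for v in out)
        assert states == self.GT_RECODING[gt]
        assert all("from_multiallelic" in v.flags for v in out)

    def test_single_alt_identity_unflagged(self, tmp_path, ped):
        rec = "chr1\t100\t.\tA\tC\t.\tPASS\tCSQ_CAT=frameshift;GENE=G1\tGT:GQ:DP\t0/1:60:30\t0/0:60:30\t0/1:60:30"
        (v,) = list(read_trio_vcf(write_vcf(tmp_path, [rec]), ped))
        assert "from_multiallelic" not in v.flags
        assert v.genotypes.father is Genotype.HET

    def test_symbolic_alt_flagged(self, tmp_path, ped):
        rec = "chr1\t100\t.\tA\t<DEL>\t.\tPASS\tCSQ_CAT=other\tGT:GQ:DP\t0/1:60:30\t0/0:60:30\t0/0:60:30"
        (v,) = list(read_trio_vcf(write_vcf(tmp_path, [rec]), ped))
        assert "symbolic" in v.flags

    def test_output_count_equals_alt_count(self, tmp_path, ped):
        rec = "chr1\t100\t.\tA\tC,G,T\t.\tPASS\tCSQ_CAT=other\tGT:GQ:DP\t1/2:60:30\t0/0:60:30\t0/3:60:30"
        out = list(read_trio_vcf(write_vcf(tmp_path, [rec]), ped))
        assert len(out) == 3

    def test_per_allele_af_split(self, tmp_path, ped):
        rec = (
            "chr1\t100\t.\tA\tC,G\t.\tPASS\tAF_EXAC=0.001,0.2;CSQ_CAT=other\t"
            "GT:GQ:DP\t0/1:60:30\t0/0:60:30\t0/0:60:30"
        )
        out = list(read_trio_vcf(write_vcf(tmp_path, [rec]), ped))
        assert [v.af_exac for v in out] == pytest.approx([0.001, 0.2])


class TestReadTrioVcf:
    def test_missing_sample_column_errors(self, tmp_path, ped):
        path = tmp_path / "bad.vcf"
        path.write_text(VCF_HEADER.replace("\tM1\t", "\tMX\t"))
        with pytest.raises(VcfFormatError, match="sample not found"):
            list(read_trio_vcf(path, ped))

    def test_absent_annotation_maps_to_none_not_zero(self, tmp_path, ped):
        rec = "chr1\t100\t.\tA\tC\t.\tPASS\tAF_1KG=0.001;CSQ_CAT=other\tGT:GQ:DP\t0/1:60:30\t0/0:60:30\t0/0:60:30"
        (v,) = list(read_trio_vcf(write_vcf(tmp_path, [rec]), ped))
        assert v.af_exac is None and v.af_evs is None
        assert v.exac_hom_count is None
        assert v.af_1000g == pytest.approx(0.001)

    def test_quality_gate_drops_low_gq_records(self, tmp_path, ped, cfg):
        recs = [
            "chr1\t100\t.\tA\tC\t.\tPASS\tCSQ_CAT=other\tGT:GQ:DP\t0/1:5:30\t0/0:60:30\t0/0:60:30",
            "chr1\t200\t.\tA\tC\t.\tPASS\tCSQ_CAT=other\tGT:GQ:DP\t0/1:60:30\t0/0:60:4\t0/0:60:30",
            "chr1\t300\t.\tA\tC\t.\tPASS\tCSQ_CAT=other\tGT:GQ:DP\t0/1:60:30\t0/0:60:30\t0/0:60:30",
        ]
        out = list(read_trio_vcf(write_vcf(tmp_path, recs), ped, cfg=cfg))
        assert [v.pos for v in out] == [300]

    def test_every_genotype_is_a_model_state(self, tmp_path):
        plan = TrioPlan(trio_id="rt_01", plant_model=None, n_background=150)
        variants, ped, _ = simulate_trio(plan, seed=3)
        path = tmp_path / "sim.vcf"
        write_trio_vcf(path, variants, ped, contigs=TOY_CONTIGS)
        for v in read_trio_vcf(path, ped):
            for g in v.genotypes.as_tuple():
                assert isinstance(g, Genotype)


class TestRoundTrip:
    def test_write_read_write_is_identity(self, tmp_path):
        """Serializing the decomposed stream and re-reading preserves
        every field; a second write/read cycle is exactly stable."""
        plan = TrioPlan(trio_id="rt_02", plant_model=None, n_background=200)
        variants, ped, _ = simulate_trio(plan, seed=11)
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_trio_vcf(p1, variants, ped, contigs=TOY_CONTIGS)
        first = list(read_trio_vcf(p1, ped))
        assert len(first) == len(variants)
        write_trio_vcf(p2, first, ped, contigs=TOY_CONTIGS)
        second = list(read_trio_vcf(p2, ped))
        assert first == second
        assert p1.read_bytes() == p2.read_bytes()

    def test_reread_matches_generated_values(self, tmp_path):
        plan = TrioPlan(trio_id="rt_03", plant_model=None, n_background=100)
        variants, ped, _ = simulate_trio(plan, seed=5)
        path = tmp_path / "sim.vcf"
        write_trio_vcf(path, variants, ped, contigs=TOY_CONTIGS)
        back = list(read_trio_vcf(path, ped))
        for orig, re_read in zip(variants, back):
            assert orig.key == re_read.key
            assert orig.genotypes == re_read.genotypes
            assert orig.consequence == re_read.consequence
            assert orig.gene == re_read.gene
            for field in ("af_1000g", "af_exac", "af_evs"):
                a, b = getattr(orig, field), getattr(re_read, field)
                assert (a is None) == (b is None)
                if a is not None:
                    assert b == pytest.approx(a, rel=1e-5)
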