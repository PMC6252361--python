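"""Inheritance-model calling against exhaustive genotype enumerations."""

from __future__ import annotations

from itertools import permutations, product

import pytest

from tests.conftest import make_variant
from tests.oracle import (
    oracle_ar_homozygous_autosomal,
    oracle_ar_homozygous_x_female,
    oracle_compound_het_pairs,
    oracle_de_novo,
    oracle_x_linked_male,
)
from triotriage.inheritance import (
    call_ar_homozygous,
    call_compound_het,
    call_de_novo,
    call_x_linked,
    mendelian_consistency,
    shortlist_single_hets,
)
from triotriage.models import (
    Consequence,
    InheritanceModel,
    MendelianStatus,
    ParentalOrigin,
)

STATES = ("hom_ref", "het", "hom_alt", "hemi_alt", "missing")
ALL_CONFIGS = list(product(STATES, repeat=3))  # 125 ordered trio configurations


class TestTruthTables:
    """The implementation must agree with the exhaustive 125-configuration
    oracle for every model."""

    @pytest.mark.parametrize("p,m,f", ALL_CONFIGS)
    def test_de_novo(self, p, m, f):
        v = make_variant(proband=p, mother=m, father=f)
        call = call_de_novo(v)
        assert (call is not None) is oracle_de_novo(p, m, f)
        if call:
            assert call.model is InheritanceModel.DE_NOVO

    @pytest.mark.parametrize("p,m,f", ALL_CONFIGS)
    def test_ar_homozygous_autosomal(self, p, m, f, ped, cfg):
        v = make_variant(proband=p, mother=m, father=f, chrom="chr2")
        call = call_ar_homozygous(v, ped, cfg)
        assert (call is not None) is oracle_ar_homozygous_autosomal(p, m, f)

    @pytest.mark.parametrize("p,m,f", ALL_CONFIGS)
    def test_ar_homozygous_x_female(self, p, m, f, ped, cfg):
        v = make_variant(proband=p, mother=m, father=f, chrom="chrX", pos=3_000_000)
        call = call_ar_homozygous(v, ped, cfg)
        assert (call is not None) is oracle_ar_homozygous_x_female(p, m, f)

    @pytest.mark.parametrize("p,m,f", ALL_CONFIGS)
    def test_x_linked_male(self, p, m, f, male_ped, cfg):
        v = make_variant(proband=p, mother=m, father=f, chrom="chrX", pos=3_000_000)
        call = call_x_linked(v, male_ped, cfg)
        assert (call is not None) is oracle_x_linked_male(p, m, f)

    @pytest.mark.parametrize("p,m,f", ALL_CONFIGS)
    def test_de_novo_and_ar_homozygous_are_exclusive(self, p, m, f, ped, cfg):
        v = make_variant(proband=p, mother=m, father=f, chrom="chr2")
        dn = call_de_novo(v)
        ar = call_ar_homozygous(v, ped, cfg)
        assert dn is None or ar is None


class TestDeNovoDetails:
    def test_double_de_novo_flagged_not_called(self):
        v = make_variant(proband="hom_alt")
        assert call_de_novo(v) is None
        assert "mendelian_inconsistent" in v.flags

    def test_missing_parent_logged_untestable(self):
        v = make_variant(proband="het", mother="missing")
        assert call_de_novo(v) is None
        assert any("untestable" in line for line in v.filter_trail)


class TestXLinkedDetails:
    def test_maternal_carrier_gives_maternal_origin(self, male_ped, cfg):
        v = make_variant(
            proband="hemi_alt", mother="het", father="hom_ref",
            chrom="chrX", pos=3_000_000,
        )
        call = call_x_linked(v, male_ped, cfg)
        assert call.parental_origin == (ParentalOrigin.MATERNAL,)
        assert not call.flags

    def test_reference_mother_flags_de_novo_on_x(self, male_ped, cfg):
        v = make_variant(
            proband="hemi_alt", mother="hom_ref", father="hom_ref",
            chrom="chrX", pos=3_000_000,
        )
        call = call_x_linked(v, male_ped, cfg)
        assert call is not None and "de_novo_on_x" in call.flags

    def test_unknown_sex_gives_no_call(self, cfg):
        from triotriage.models import Pedigree, Sex

        ped = Pedigree("f", "P1", "M1", "F1", Sex.UNKNOWN)
        v = make_variant(
            proband="hemi_alt", mother="het", father="hom_ref",
            chrom="chrX", pos=3_000_000,
        )
        assert call_x_linked(v, ped, cfg) is None
        assert any("sex required" in line for line in v.filter_trail)

    def test_female_het_on_x_not_called_here(self, ped, cfg):
        v = make_variant(
            proband="het", mother="het", father="hom_ref",
            chrom="chrX", pos=3_000_000,
        )
        assert call_x_linked(v, ped, cfg) is None


class TestCompoundHet:
    def _hets(self, origins, gene="G1"):
        out = []
        for i, origin in enumerate(origins):
            mother = "het" if origin in ("maternal", "both") else "hom_ref"
            father = "het" if origin in ("paternal", "both") else "hom_ref"
            out.append(
                make_variant(
                    proband="het", mother=mother, father=father,
                    pos=1000 + i, gene=gene,
                )
            )
        return out

    def test_trans_pair_reported(self, cfg):
        calls = call_compound_het(self._hets(["maternal", "paternal"]), cfg)
        assert len(calls) == 1
        assert set(calls[0].parental_origin) == {
            ParentalOrigin.MATERNAL,
            ParentalOrigin.PATERNAL,
        }

    def test_cis_pair_not_reported(self, cfg):
        assert call_compound_het(self._hets(["paternal", "paternal"]), cfg) == []

    def test_three_hets_give_exactly_two_pairs(self, cfg):
        """Brute force over C(3,2) origin-constrained pairs."""
        variants = self._hets(["maternal", "maternal", "paternal"])
        calls = call_compound_het(variants, cfg)
        expected = oracle_compound_het_pairs(
            [
                (v.key, v.genotypes.proband.value, v.genotypes.mother.value,
                 v.genotypes.father.value, False)
                for v in variants
            ]
        )
        assert len(calls) == 2
        assert {frozenset(c.variant_keys) for c in calls} == expected

    def test_unresolved_phase_excluded_by_default(self, cfg):
        variants = self._hets(["maternal", "both"])
        assert call_compound_het(variants, cfg) == []

    def test_unresolved_phase_pairs_under_config_flag(self):
        from triotriage.simulate import toy_filter_config

        cfg = toy_filter_config(allow_unresolved_phase=True)
        variants = self._hets(["maternal", "both"])
        assert len(call_compound_het(variants, cfg)) == 1

    @pytest.mark.parametrize("order", list(permutations(range(3))))
    def test_input_order_never_changes_reported_pairs(self, cfg, order):
        variants = self._hets(["maternal", "paternal", "paternal"])
        shuffled = [variants[i] for i in order]
        pairs = {frozenset(c.variant_keys) for c in call_compound_het(shuffled, cfg)}
        baseline = {
            frozenset(c.variant_keys) for c in call_compound_het(variants, cfg)
        }
        assert pairs == baseline

    def test_every_pair_has_one_maternal_one_paternal(self, cfg):
        variants = self._hets(["maternal", "paternal", "maternal", "paternal"])
        for call in call_compound_het(variants, cfg):
            assert sorted(o.value for o in call.parental_origin) == [
                "maternal",
                "paternal",
            ]


class TestHetShortlist:
    def test_lone_deleterious_het_shortlisted(self, cfg):
        v = make_variant(proband="het", mother="het", father="hom_ref")
        entries = shortlist_single_hets([v], "recessive", cfg)
        assert len(entries) == 1 and entries[0].gene == v.gene

    def test_trans_pair_handled_as_compound_het_not_shortlist(self, cfg):
        a = make_variant(proband="het", mother="het", father="hom_ref", pos=100)
        b = make_variant(proband="het", mother="hom_ref", father="het", pos=200)
        assert shortlist_single_hets([a, b], "recessive", cfg) == []

    def test_synonymous_het_not_shortlisted(self, cfg):
        v = make_variant(
            proband="het", mother="het", father="hom_ref",
            consequence=Consequence.SYNONYMOUS,
        )
        assert shortlist_single_hets([v], "recessive", cfg) == []

    def test_dominant_gene_not_shortlisted(self, cfg):
        v = make_variant(proband="het", mother="het", father="hom_ref")
        assert shortlist_single_hets([v], "dominant", cfg) == []


class TestMendelianConsistency:
    @pytest.mark.parametrize(
        "p,m,f,status",
        [
            ("hom_alt", "hom_ref", "het", MendelianStatus.INCONSISTENT),
            ("het", "het", "het", MendelianStatus.CONSISTENT),
            ("het", "missing", "hom_ref", MendelianStatus.UNTESTABLE),
            ("hom_ref", "hom_alt", "hom_ref", MendelianStatus.INCONSISTENT),
            ("hom_alt", "het", "het", MendelianStatus.CONSISTENT),
        ],
    )
    def test_status(self, p, m, f, status):
        assert mendelian_consistency(make_variant(proband=p, mother=m, father=f)).status is status

    def test_de_novo_het_labelled_separately(self):
        check = mendelian_consistency(make_variant())
        assert check.status is MendelianStatus.INCONSISTENT
        assert check.detail == "de_novo_single_allele"
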