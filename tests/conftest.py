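"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from triotriage.models import (
    AnnotatedVariant,
    Consequence,
    Genotype,
    Pedigree,
    SampleQuality,
    Sex,
    TrioGenotypes,
)
from triotriage.simulate import toy_filter_config

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


SAMPLES = ("P1", "M1", "F1")


@pytest.fixture
def cfg():
    """Filter thresholds with PAR masks matching the toy genome."""
    return toy_filter_config()


@pytest.fixture
def ped():
    return Pedigree(
        family_id="fam1",
        proband_id="P1",
        mother_id="M1",
        father_id="F1",
        proband_sex=Sex.FEMALE,
    )


@pytest.fixture
def male_ped():
    return Pedigree(
        family_id="fam1",
        proband_id="P1",
        mother_id="M1",
        father_id="F1",
        proband_sex=Sex.MALE,
    )


def make_variant(
    proband="het",
    mother="hom_ref",
    father="hom_ref",
    chrom="chr1",
    pos=1000,
    ref="A",
    alt="T",
    gene="GENE1",
    consequence=Consequence.SNV_DELETERIOUS_MISSENSE,
    **kwargs,
) -> AnnotatedVariant:
    """A rare deleterious variant with good genotype quality by default."""
    quality = kwargs.pop(
        "quality",
        {sid: SampleQuality(gq=60, depth=30) for sid in SAMPLES},
    )
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        genotypes=TrioGenotypes(
            proband=Genotype(proband),
            mother=Genotype(mother),
            father=Genotype(father),
        ),
        quality=quality,
        **kwargs,
    )
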