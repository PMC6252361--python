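"""Core data model for trio variant prioritization.

A *trio* is a proband sequenced together with both biological parents, so
that every variant's inheritance can be resolved directly from genotypes.
The types here carry exactly the information the downstream filters
consume: trio genotypes, population allele frequencies from three
reference databases, a coarse consequence category, and curated
pathogenicity / deleteriousness flags supplied by an upstream annotator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Genotype(str, enum.Enum):
    """Per-sample genotype state after biallelic decomposition.

    ``HEMI_ALT`` is only legal on chrX outside the pseudoautosomal
    regions (or on chrY) for a male sample.
    """

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI_ALT = "hemi_alt"
    MISSING = "missing"


class Consequence(str, enum.Enum):
    SNV_DELETERIOUS_MISSENSE = "snv_deleterious_missense"
    FRAMESHIFT = "frameshift"
    START_LOST = "start_lost"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    SPLICE_REGION = "splice_region"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    OTHER = "other"


class InheritanceModel(str, enum.Enum):
    DE_NOVO = "de_novo"
    AR_HOMOZYGOUS = "ar_homozygous"
    AR_COMPOUND_HET = "ar_compound_het"
    X_LINKED = "x_linked"


class ParentalOrigin(str, enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    UNRESOLVED = "unresolved"


class MendelianStatus(str, enum.Enum):
    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"
    UNTESTABLE = "untestable"


class PedigreeError(ValueError):
    """Raised for pedigrees that do not describe a single complete trio."""


@dataclass(frozen=True)
class Pedigree:
    """One family: proband plus both biological parents."""

    family_id: str
    proband_id: str
    mother_id: str
    father_id: str
    proband_sex: Sex = Sex.UNKNOWN

    def __post_init__(self) -> None:
        ids = {self.proband_id, self.mother_id, self.father_id}
        if len(ids) != 3 or "" in ids or "0" in ids:
            raise PedigreeError(
                f"incomplete trio in family {self.family_id!r}: "
                "proband, mother and father must be three distinct samples"
            )

    @property
    def sample_ids(self) -> tuple[str, str, str]:
        return (self.proband_id, self.mother_id, self.father_id)


@dataclass(frozen=True)
class TrioGenotypes:
    proband: Genotype
    mother: Genotype
    father: Genotype

    def as_tuple(self) -> tuple[Genotype, Genotype, Genotype]:
        return (self.proband, self.mother, self.father)


@dataclass(frozen=True)
class SampleQuality:
    """Genotype quality (phred GQ) and read depth for one sample."""

    gq: Optional[int] = None
    depth: Optional[int] = None


@dataclass
class AnnotatedVariant:
    """One biallelic variant with trio genotypes and filter annotations.

    Population allele fractions (``af_1000g``/``af_exac``/``af_evs``) and
    ExAC homozygote/hemizygote counts are ``None`` when the database did
    not report the variant; "absent" is a meaningful state (not observed,
    hence presumed rare) and is never silently coerced to 0.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: TrioGenotypes
    gene: str = ""
    consequence: Consequence = Consequence.OTHER
    splice_distance: Optional[int] = None
    af_1000g: Optional[float] = None
    af_exac: Optional[float] = None
    af_evs: Optional[float] = None
    exac_hom_count: Optional[int] = None
    exac_hemi_count: Optional[int] = None
    known_pathogenic: bool = False
    quality: dict[str, SampleQuality] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)
    filter_trail: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for name in ("af_1000g", "af_exac", "af_evs"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("exac_hom_count", "exac_hemi_count"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name}={v} negative")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def reported_afs(self) -> list[float]:
        """Allele fractions actually reported by a database (absent dropped)."""
        return [
            v
            for v in (self.af_1000g, self.af_exac, self.af_evs)
            if v is not None
        ]

    @property
    def max_reported_af(self) -> float:
        afs = self.reported_afs
        return max(afs) if afs else 0.0

    def log(self, message: str) -> None:
        self.filter_trail.append(message)


@dataclass
class ModelCall:
    """A variant (or trans pair) explained by one trio inheritance model."""

    model: InheritanceModel
    variants: tuple[AnnotatedVariant, ...]
    gene: str
    parental_origin: tuple[ParentalOrigin, ...]
    flags: set[str] = field(default_factory=set)
    phase: Optional[str] = None

    def __post_init__(self) -> None:
        expected = 2 if self.model is InheritanceModel.AR_COMPOUND_HET else 1
        if len(self.variants) != expected:
            raise ValueError(
                f"{self.model.value} call must carry {expected} variant(s), "
                f"got {len(self.variants)}"
            )
        if len(self.parental_origin) != len(self.variants):
            raise ValueError("one parental origin per variant required")

    @property
    def known_pathogenic(self) -> bool:
        return any(v.known_pathogenic for v in self.variants)

    @property
    def variant_keys(self) -> tuple[str, ...]:
        return tuple(v.key for v in self.variants)

    @property
    def max_reported_af(self) -> float:
        return max(v.max_reported_af for v in self.variants)


@dataclass
class HetShortlistEntry:
    """A lone deleterious het in a recessive-inheritance panel gene.

    These are flagged for manual inspection of the region (a structural
    variant may disable the second allele); the inspection itself is a
    human step outside this package.
    """

    variant: AnnotatedVariant
    gene: str
    reason: str = "single deleterious het in recessive-MOI panel gene"
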