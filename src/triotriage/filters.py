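"""Frequency and consequence filters for rare-disease trio triage.

Two frequency paths exist:

* the **standard** path keeps variants at ≤0.5% allele frequency in every
  population database that reports them (1000 Genomes, ExAC, EVS);
* the **permissive** path, used only when searching for recessive and
  X-linked candidates with a high carrier frequency, relaxes the cut-off
  to ≤10% but additionally requires that ExAC reports no homozygous
  (and, on chrX, no hemizygous) carriers — a common allele never seen in
  two copies is still a viable recessive candidate.

Both thresholds are inclusive. A database that does not report the
variant contributes nothing to either test: absence of evidence of
commonness is treated as rarity, so novel variants survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .models import AnnotatedVariant, Consequence

#: Consequence categories counted as predicted deleterious: deleterious
#: missense SNVs, frameshifts, start/stop codon changes. Splice-region
#: variants are handled separately via the distance window.
DEFAULT_DELETERIOUS_CONSEQUENCES = frozenset(
    {
        Consequence.SNV_DELETERIOUS_MISSENSE,
        Consequence.FRAMESHIFT,
        Consequence.START_LOST,
        Consequence.STOP_GAINED,
        Consequence.STOP_LOST,
    }
)

#: GRCh38 pseudoautosomal regions on chrX (1-based, inclusive).
GRCH38_PAR_X: tuple[tuple[str, int, int], ...] = (
    ("chrX", 10_001, 2_781_479),
    ("chrX", 155_701_383, 156_030_895),
)


@dataclass
class FilterConfig:
    """Thresholds and masks shared by every filtering stage.

    Parameters
    ----------
    af_standard_max
        Inclusive allele-frequency ceiling for the standard path (0.005).
    af_permissive_max
        Inclusive ceiling for the permissive recessive/X-linked path (0.10).
    splice_window_bp
        Splice-region variants within this many bp of an exon boundary
        count as deleterious (±7 bp).
    deleterious_consequences
        Consequence categories treated as deleterious outright.
    min_gq, min_depth
        Genotype-quality gate applied to all three samples at read time.
    allow_unresolved_phase
        Whether a variant het in both parents (phase unresolvable from the
        trio) may participate in compound-het pairs.
    par_regions
        1-based inclusive (chrom, start, end) pseudoautosomal intervals;
        positions inside them are treated as autosomal.
    """

    af_standard_max: float = 0.005
    af_permissive_max: float = 0.10
    splice_window_bp: int = 7
    deleterious_consequences: frozenset[Consequence] = (
        DEFAULT_DELETERIOUS_CONSEQUENCES
    )
    min_gq: int = 20
    min_depth: int = 8
    allow_unresolved_phase: bool = False
    par_regions: tuple[tuple[str, int, int], ...] = GRCH38_PAR_X

    def __post_init__(self) -> None:
        if not (0.0 <= self.af_standard_max <= self.af_permissive_max <= 1.0):
            raise ValueError(
                "need 0 <= af_standard_max <= af_permissive_max <= 1, got "
                f"{self.af_standard_max} / {self.af_permissive_max}"
            )
        if self.splice_window_bp < 0:
            raise ValueError("splice_window_bp must be >= 0")
        self.deleterious_consequences = frozenset(
            Consequence(c) for c in self.deleterious_consequences
        )

    @classmethod
    def from_mapping(cls, data: dict) -> "FilterConfig":
        """Build from a parsed YAML/JSON mapping; unknown keys rejected."""
        known = cls.__dataclass_fields__  # noqa: SLF001 - public dataclass API
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown filter config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "deleterious_consequences" in kwargs:
            kwargs["deleterious_consequences"] = frozenset(
                Consequence(c) for c in kwargs["deleterious_consequences"]
            )
        if "par_regions" in kwargs:
            kwargs["par_regions"] = tuple(
                (str(c), int(s), int(e)) for c, s, e in kwargs["par_regions"]
            )
        return cls(**kwargs)


def in_par(chrom: str, pos: int, par_regions: Sequence[tuple[str, int, int]]) -> bool:
    return any(c == chrom and s <= pos <= e for c, s, e in par_regions)


def is_x_nonpar(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """True for chrX positions outside the pseudoautosomal regions."""
    return v.chrom == "chrX" and not in_par(v.chrom, v.pos, cfg.par_regions)


def passes_standard_frequency(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Rare in every database that reports the variant (≤ ``af_standard_max``)."""
    return all(af <= cfg.af_standard_max for af in v.reported_afs)


def passes_permissive_recessive_frequency(
    v: AnnotatedVariant, cfg: FilterConfig
) -> bool:
    """High-carrier-frequency recessive rule: AF ≤ 10%, no ExAC hom/hemi.

    The hemizygote check only applies on chrX outside the pseudoautosomal
    regions; autosomal variants are judged on homozygote count alone.
    """
    if any(af > cfg.af_permissive_max for af in v.reported_afs):
        return False
    if v.exac_hom_count not in (None, 0):
        return False
    if is_x_nonpar(v, cfg) and v.exac_hemi_count not in (None, 0):
        return False
    return True


def is_predicted_deleterious(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Deleterious consequence, or splice-region within the ±window.

    A splice-region record lacking a distance annotation cannot be placed
    relative to the window and is conservatively not deleterious; the
    decision is recorded on the variant's filter trail.
    """
    if v.consequence in cfg.deleterious_consequences:
        return True
    if v.consequence is Consequence.SPLICE_REGION:
        if v.splice_distance is None:
            v.log("splice_region without splice_distance: not deleterious")
            return False
        return abs(v.splice_distance) <= cfg.splice_window_bp
    return False


def passes_quality_gate(
    v: AnnotatedVariant, cfg: FilterConfig, sample_ids: Sequence[str]
) -> bool:
    """All three samples meet the GQ/depth floor (missing metrics fail)."""
    for sid in sample_ids:
        q = v.quality.get(sid)
        if q is None or q.gq is None or q.depth is None:
            return False
        if q.gq < cfg.min_gq or q.depth < cfg.min_depth:
            return False
    return True
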