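"""Synthetic annotated trio cohorts with planted causal variants.

The generator emulates the statistical structure the trio filters
assume, at desk scale: a toy four-contig genome, a few thousand
Mendelian-consistent background variants per trio, and optional planted
causal variants satisfying exactly one inheritance model plus the
frequency and consequence filters. Background variants are constructed
to deterministically fail at least one filter — common alleles with
nonzero ExAC homozygote counts, benign consequences, or lone inherited
deleterious hets in genes outside every panel — so a background-only
trio yields zero calls in every phase, by construction.

Ground truth travels only through the JSON manifest; the VCF carries
nothing a real annotator would not supply (the curated-pathogenic flag
emulates a clinical-database match). Identical seeds give byte-identical
output. Allele frequencies are drawn independently per database within
a stratum, a declared simplification of their real joint distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .config import dump_config
from .filters import FilterConfig
from .models import (
    AnnotatedVariant,
    Consequence,
    Genotype,
    InheritanceModel,
    Pedigree,
    SampleQuality,
    Sex,
    TrioGenotypes,
)
from .variant_io import AnnotationKeys, write_pedigree, write_trio_vcf


class DesignError(ValueError):
    """Raised for cohort designs that cannot be generated."""


#: toy genome: four contigs, chrX carries a pseudoautosomal head segment
TOY_CONTIGS: tuple[tuple[str, int], ...] = (
    ("chr1", 10_000_000),
    ("chr2", 10_000_000),
    ("chr7", 10_000_000),
    ("chrX", 5_000_000),
)
TOY_PAR: tuple[tuple[str, int, int], ...] = (("chrX", 1, 100_000),)

_CONTIG_INDEX = {name: i for i, (name, _) in enumerate(TOY_CONTIGS)}
_CONTIG_LEN = dict(TOY_CONTIGS)

#: contig placement for named causal/secondary genes (X-linked gene on chrX)
GENE_CONTIG = {
    "WT1": "chr1", "GLDC": "chr1", "TBCE": "chr1",
    "COL3A1": "chr2", "NSD1": "chr2", "POLE1": "chr2", "CC2D2A": "chr2",
    "BCHE": "chr2",
    "CHD7": "chr7", "PIGT": "chr7", "RRM2B": "chr7",
    "IL2RG": "chrX",
}

DECOY_PANEL_GENES = tuple(f"PNLG{i:02d}" for i in range(1, 13))
BACKGROUND_GENE_POOL = tuple(f"BGG{i:03d}" for i in range(1, 61))

_DELETERIOUS_CHOICES = (
    Consequence.SNV_DELETERIOUS_MISSENSE,
    Consequence.FRAMESHIFT,
    Consequence.START_LOST,
    Consequence.STOP_GAINED,
    Consequence.STOP_LOST,
)
_BENIGN_CHOICES = (
    Consequence.SYNONYMOUS,
    Consequence.INTRONIC,
    Consequence.INTERGENIC,
    Consequence.OTHER,
)

_BASES = ("A", "C", "G", "T")


def toy_filter_config(**overrides) -> FilterConfig:
    """Default thresholds with PAR masks matching the toy genome."""
    kwargs = dict(par_regions=TOY_PAR)
    kwargs.update(overrides)
    return FilterConfig(**kwargs)


@dataclass(frozen=True)
class TrioPlan:
    """Design for one synthetic trio.

    ``panel_tier`` places the planted gene: ``"I"`` in the bespoke
    phase I panel, ``"II"`` only in the broad phase II lists, ``"none"``
    outside every panel (phase III scope only).
    """

    trio_id: str
    proband_sex: Sex = Sex.FEMALE
    plant_model: Optional[InheritanceModel] = None
    plant_gene: Optional[str] = None
    panel_tier: str = "I"
    known_pathogenic: bool = True
    permissive_stratum: bool = False
    secondary_plant: bool = False
    secondary_gene: str = "BCHE"
    n_background: int = 2000

    def __post_init__(self) -> None:
        if self.plant_model is not None and self.plant_gene is None:
            raise DesignError(f"{self.trio_id}: plant model without a gene")
        if (
            self.plant_model is InheritanceModel.X_LINKED
            and self.proband_sex is not Sex.MALE
        ):
            raise DesignError(
                f"{self.trio_id}: hemizygous X-linked plant requires a male proband"
            )
        if self.panel_tier not in {"I", "II", "none"}:
            raise DesignError(f"{self.trio_id}: panel_tier must be I, II or none")
        if self.n_background < 0:
            raise DesignError("n_background must be >= 0")


@dataclass(frozen=True)
class CohortDesign:
    trios: tuple[TrioPlan, ...]

    def __post_init__(self) -> None:
        ids = [t.trio_id for t in self.trios]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate trio ids in cohort design")


def fixture_design(n_background: int = 2000) -> CohortDesign:
    """The 24-trio benchmark cohort.

    Ten trios carry a curated-pathogenic primary plant in their phase I
    panel gene — four de novo, three compound-het pairs, three
    homozygous — one further trio carries a homozygous secondary-finding
    plant in an actionable-list gene, and the remaining trios are
    background only. One compound-het plant sits in the permissive
    5–10% frequency stratum so both frequency paths are exercised.
    """
    dn = InheritanceModel.DE_NOVO
    hom = InheritanceModel.AR_HOMOZYGOUS
    cpht = InheritanceModel.AR_COMPOUND_HET
    plants: dict[int, tuple[InheritanceModel, str, bool]] = {
        1: (cpht, "POLE1", False),
        2: (dn, "COL3A1", False),
        5: (dn, "CHD7", False),
        7: (hom, "PIGT", False),
        11: (dn, "WT1", False),
        12: (hom, "GLDC", False),
        15: (cpht, "RRM2B", False),
        16: (dn, "NSD1", False),
        21: (hom, "TBCE", False),
        24: (cpht, "CC2D2A", True),  # permissive-frequency stratum
    }
    trios = []
    for i in range(1, 25):
        sex = Sex.MALE if i % 2 == 1 else Sex.FEMALE
        model, gene, permissive = (None, None, False)
        if i in plants:
            model, gene, permissive = plants[i]
        trios.append(
            TrioPlan(
                trio_id=f"trio_{i:02d}",
                proband_sex=sex,
                plant_model=model,
                plant_gene=gene,
                permissive_stratum=permissive,
                secondary_plant=(i == 18),
                n_background=n_background,
            )
        )
    return CohortDesign(trios=tuple(trios))


# ---------------------------------------------------------------------------
# genotype and annotation sampling


def _parent_diploid(rng: np.random.Generator, p: float) -> tuple[int, int]:
    return (int(rng.random() < p), int(rng.random() < p))


def _gt_state(alleles: Sequence[int]) -> Genotype:
    if len(alleles) == 1:
        return Genotype.HEMI_ALT if alleles[0] == 1 else Genotype.HOM_REF
    n = sum(alleles)
    return (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[n]


def _consistent_trio(
    rng: np.random.Generator,
    carrier_p: float,
    x_nonpar: bool,
    proband_sex: Sex,
) -> TrioGenotypes:
    """Draw parental genotypes and transmit alleles to the proband.

    Transmission guarantees Mendelian consistency; on non-PAR chrX the
    father is haploid and a male proband receives only a maternal allele.
    """
    mother = _parent_diploid(rng, carrier_p)
    if x_nonpar:
        father: tuple[int, ...] = (int(rng.random() < carrier_p),)
        maternal = mother[int(rng.integers(2))]
        if proband_sex is Sex.MALE:
            child: tuple[int, ...] = (maternal,)
        else:
            child = (maternal, father[0])
    else:
        father = _parent_diploid(rng, carrier_p)
        child = (mother[int(rng.integers(2))], father[int(rng.integers(2))])
    return TrioGenotypes(
        proband=_gt_state(child), mother=_gt_state(mother), father=_gt_state(father)
    )


def _rare_afs(rng: np.random.Generator, cap: float = 0.005) -> dict[str, Optional[float]]:
    out: dict[str, Optional[float]] = {}
    for k in ("af_1000g", "af_exac", "af_evs"):
        out[k] = None if rng.random() < 0.35 else float(rng.uniform(0, cap))
    return out


def _permissive_afs(rng: np.random.Generator) -> dict[str, Optional[float]]:
    return {
        "af_1000g": float(rng.uniform(0.05, 0.10)),
        "af_exac": float(rng.uniform(0.05, 0.10)),
        "af_evs": None,
    }


def _alleles(rng: np.random.Generator, frameshift: bool = False) -> tuple[str, str]:
    ref = _BASES[int(rng.integers(4))]
    if frameshift:
        return ref, ref + _BASES[int(rng.integers(4))]
    alt = _BASES[int((rng.integers(3) + _BASES.index(ref) + 1) % 4)]
    return ref, alt


def _quality(rng: np.random.Generator, sample_ids: Sequence[str]) -> dict[str, SampleQuality]:
    return {
        sid: SampleQuality(
            gq=int(rng.integers(30, 100)), depth=int(rng.integers(12, 60))
        )
        for sid in sample_ids
    }


def _draw_position(
    rng: np.random.Generator, chrom: str, used: set[tuple[str, int]]
) -> int:
    while True:
        pos = int(rng.integers(1, _CONTIG_LEN[chrom] + 1))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return pos


# ---------------------------------------------------------------------------
# trio generation


def simulate_trio(
    plan: TrioPlan, seed: int
) -> tuple[list[AnnotatedVariant], Pedigree, dict]:
    """Generate one trio in memory: variants (sorted), pedigree, truth record."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _plan_index(plan)]))
    ped = Pedigree(
        family_id=plan.trio_id,
        proband_id=f"{plan.trio_id}_P",
        mother_id=f"{plan.trio_id}_M",
        father_id=f"{plan.trio_id}_F",
        proband_sex=plan.proband_sex,
    )
    sample_ids = ped.sample_ids
    used: set[tuple[str, int]] = set()
    variants: list[AnnotatedVariant] = []

    truth: dict = {
        "trio_id": plan.trio_id,
        "proband_sex": plan.proband_sex.value,
        "n_background": plan.n_background,
        "plant": None,
        "secondary": None,
    }

    # --- planted causal variant(s)
    if plan.plant_model is not None:
        planted = _plant_primary(rng, plan, ped, used)
        variants.extend(planted)
        truth["plant"] = {
            "model": plan.plant_model.value,
            "gene": plan.plant_gene,
            "variant_keys": [v.key for v in planted],
            "known_pathogenic": plan.known_pathogenic,
            "expected_phase": {"I": "I", "II": "II", "none": "III"}[plan.panel_tier],
            "permissive_stratum": plan.permissive_stratum,
        }
    if plan.secondary_plant:
        sv = _plant_secondary(rng, plan, ped, used)
        variants.append(sv)
        truth["secondary"] = {
            "gene": plan.secondary_gene,
            "variant_keys": [sv.key],
            "model": InheritanceModel.AR_HOMOZYGOUS.value,
        }

    # --- background
    contig_names = [c for c, _ in TOY_CONTIGS]
    contig_weights = np.array([ln for _, ln in TOY_CONTIGS], dtype=float)
    contig_weights /= contig_weights.sum()
    for i in range(plan.n_background):
        chrom = contig_names[int(rng.choice(len(contig_names), p=contig_weights))]
        pos = _draw_position(rng, chrom, used)
        x_nonpar = chrom == "chrX" and pos > TOY_PAR[0][2]
        stratum = rng.random()
        if stratum < 0.45:
            variants.append(
                _background_common(rng, chrom, pos, x_nonpar, ped, sample_ids)
            )
        elif stratum < 0.80 or x_nonpar:  # lone-het stratum is autosomal-only
            variants.append(
                _background_benign(rng, chrom, pos, x_nonpar, ped, sample_ids)
            )
        else:
            variants.append(
                _background_lone_het(
                    rng, chrom, pos, ped, sample_ids, f"{plan.trio_id.upper()}U{i:05d}"
                )
            )

    variants.sort(key=lambda v: (_CONTIG_INDEX[v.chrom], v.pos, v.alt))
    return variants, ped, truth


def _plan_index(plan: TrioPlan) -> int:
    # stable per-trio stream split derived from the id digits
    digits = "".join(ch for ch in plan.trio_id if ch.isdigit())
    return int(digits) if digits else abs(hash(plan.trio_id)) % 10_000


def _plant_primary(
    rng: np.random.Generator,
    plan: TrioPlan,
    ped: Pedigree,
    used: set[tuple[str, int]],
) -> list[AnnotatedVariant]:
    gene = plan.plant_gene
    assert gene is not None
    chrom = GENE_CONTIG.get(gene.upper(), "chr2")
    afs = _permissive_afs(rng) if plan.permissive_stratum else _rare_afs(rng)
    common = dict(
        gene=gene,
        exac_hom_count=0,
        exac_hemi_count=0 if chrom == "chrX" else None,
        known_pathogenic=plan.known_pathogenic,
        **afs,
    )
    model = plan.plant_model
    out: list[AnnotatedVariant] = []
    if model is InheritanceModel.DE_NOVO:
        # de novo candidates only use the standard frequency path
        if plan.permissive_stratum:
            raise DesignError("a de novo plant cannot use the permissive stratum")
        ref, alt = _alleles(rng)
        out.append(
            AnnotatedVariant(
                chrom=chrom,
                pos=_draw_position(rng, chrom, used),
                ref=ref,
                alt=alt,
                genotypes=TrioGenotypes(Genotype.HET, Genotype.HOM_REF, Genotype.HOM_REF),
                consequence=Consequence.STOP_GAINED,
                quality=_quality(rng, ped.sample_ids),
                **common,
            )
        )
    elif model is InheritanceModel.AR_HOMOZYGOUS:
        ref, alt = _alleles(rng)
        out.append(
            AnnotatedVariant(
                chrom=chrom,
                pos=_draw_position(rng, chrom, used),
                ref=ref,
                alt=alt,
                genotypes=TrioGenotypes(Genotype.HOM_ALT, Genotype.HET, Genotype.HET),
                consequence=Consequence.SNV_DELETERIOUS_MISSENSE,
                quality=_quality(rng, ped.sample_ids),
                **common,
            )
        )
    elif model is InheritanceModel.AR_COMPOUND_HET:
        pos1 = _draw_position(rng, chrom, used)
        pos2 = pos1 + int(rng.integers(1, 5000))
        while (chrom, pos2) in used:
            pos2 += 1
        used.add((chrom, pos2))
        ref1, alt1 = _alleles(rng, frameshift=True)
        ref2, alt2 = _alleles(rng)
        maternal = AnnotatedVariant(
            chrom=chrom,
            pos=min(pos1, pos2),
            ref=ref1,
            alt=alt1,
            genotypes=TrioGenotypes(Genotype.HET, Genotype.HET, Genotype.HOM_REF),
            consequence=Consequence.FRAMESHIFT,
            quality=_quality(rng, ped.sample_ids),
            **common,
        )
        second_afs = _permissive_afs(rng) if plan.permissive_stratum else _rare_afs(rng)
        paternal = AnnotatedVariant(
            chrom=chrom,
            pos=max(pos1, pos2),
            ref=ref2,
            alt=alt2,
            genotypes=TrioGenotypes(Genotype.HET, Genotype.HOM_REF, Genotype.HET),
            consequence=Consequence.SPLICE_REGION,
            splice_distance=int(rng.integers(1, 8)),  # inside the ±7 bp window
            gene=gene,
            exac_hom_count=0,
            exac_hemi_count=None,
            known_pathogenic=plan.known_pathogenic,
            quality=_quality(rng, ped.sample_ids),
            **second_afs,
        )
        out.extend([maternal, paternal])
    elif model is InheritanceModel.X_LINKED:
        chrom = "chrX"
        par_end = TOY_PAR[0][2]
        pos = par_end + 1 + int(rng.integers(1, _CONTIG_LEN[chrom] - par_end - 1))
        while (chrom, pos) in used:
            pos += 1
        used.add((chrom, pos))
        ref, alt = _alleles(rng)
        out.append(
            AnnotatedVariant(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                genotypes=TrioGenotypes(
                    Genotype.HEMI_ALT, Genotype.HET, Genotype.HOM_REF
                ),
                consequence=Consequence.SNV_DELETERIOUS_MISSENSE,
                quality=_quality(rng, ped.sample_ids),
                **dict(common, exac_hemi_count=0),
            )
        )
    else:  # pragma: no cover - enum is closed
        raise DesignError(f"unsupported plant model {model}")
    return out


def _plant_secondary(
    rng: np.random.Generator,
    plan: TrioPlan,
    ped: Pedigree,
    used: set[tuple[str, int]],
) -> AnnotatedVariant:
    gene = plan.secondary_gene
    chrom = GENE_CONTIG.get(gene.upper(), "chr2")
    ref, alt = _alleles(rng)
    return AnnotatedVariant(
        chrom=chrom,
        pos=_draw_position(rng, chrom, used),
        ref=ref,
        alt=alt,
        genotypes=TrioGenotypes(Genotype.HOM_ALT, Genotype.HET, Genotype.HET),
        gene=gene,
        consequence=Consequence.SNV_DELETERIOUS_MISSENSE,
        exac_hom_count=0,
        known_pathogenic=True,
        quality=_quality(rng, ped.sample_ids),
        **_rare_afs(rng),
    )


def _background_common(
    rng: np.random.Generator,
    chrom: str,
    pos: int,
    x_nonpar: bool,
    ped: Pedigree,
    sample_ids: Sequence[str],
) -> AnnotatedVariant:
    """Common allele: fails the standard AF filter; nonzero ExAC homozygote
    count closes the permissive path too."""
    ref, alt = _alleles(rng)
    csq = (
        _DELETERIOUS_CHOICES[int(rng.integers(len(_DELETERIOUS_CHOICES)))]
        if rng.random() < 0.4
        else _BENIGN_CHOICES[int(rng.integers(len(_BENIGN_CHOICES)))]
    )
    gene = _background_gene(rng)
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        genotypes=_consistent_trio(rng, 0.3, x_nonpar, ped.proband_sex),
        gene=gene,
        consequence=csq,
        af_1000g=float(rng.uniform(0.02, 0.45)),
        af_exac=float(rng.uniform(0.02, 0.45)),
        af_evs=float(rng.uniform(0.02, 0.45)),
        exac_hom_count=int(rng.integers(1, 200)),
        exac_hemi_count=int(rng.integers(1, 50)) if x_nonpar else None,
        quality=_quality(rng, sample_ids),
    )


def _background_benign(
    rng: np.random.Generator,
    chrom: str,
    pos: int,
    x_nonpar: bool,
    ped: Pedigree,
    sample_ids: Sequence[str],
) -> AnnotatedVariant:
    """Rare but non-deleterious: benign category, or splice region
    outside the ±7 bp window."""
    ref, alt = _alleles(rng)
    if rng.random() < 0.15:
        csq = Consequence.SPLICE_REGION
        splice = int(rng.integers(8, 41))
    else:
        csq = _BENIGN_CHOICES[int(rng.integers(len(_BENIGN_CHOICES)))]
        splice = None
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        genotypes=_consistent_trio(rng, 0.2, x_nonpar, ped.proband_sex),
        gene=_background_gene(rng),
        consequence=csq,
        splice_distance=splice,
        exac_hom_count=0 if rng.random() < 0.5 else None,
        quality=_quality(rng, sample_ids),
        **_rare_afs(rng),
    )


def _background_lone_het(
    rng: np.random.Generator,
    chrom: str,
    pos: int,
    ped: Pedigree,
    sample_ids: Sequence[str],
    unique_gene: str,
) -> AnnotatedVariant:
    """Rare deleterious het inherited from one carrier parent, in a gene
    outside every panel and unique to this variant (no trans partner)."""
    ref, alt = _alleles(rng)
    maternal = rng.random() < 0.5
    gts = TrioGenotypes(
        Genotype.HET,
        Genotype.HET if maternal else Genotype.HOM_REF,
        Genotype.HOM_REF if maternal else Genotype.HET,
    )
    if rng.random() < 0.2:
        csq = Consequence.SPLICE_REGION
        splice = int(rng.integers(1, 8))
    else:
        csq = _DELETERIOUS_CHOICES[int(rng.integers(len(_DELETERIOUS_CHOICES)))]
        splice = None
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        genotypes=gts,
        gene=unique_gene,
        consequence=csq,
        splice_distance=splice,
        exac_hom_count=0,
        quality=_quality(rng, sample_ids),
        **_rare_afs(rng),
    )


def _background_gene(rng: np.random.Generator) -> str:
    r = rng.random()
    if r < 0.2:
        return ""  # intergenic space
    if r < 0.4:
        return DECOY_PANEL_GENES[int(rng.integers(len(DECOY_PANEL_GENES)))]
    return BACKGROUND_GENE_POOL[int(rng.integers(len(BACKGROUND_GENE_POOL)))]


# ---------------------------------------------------------------------------
# cohort generation (files on disk)


def _moi_for_model(model: str) -> str:
    return {
        "de_novo": "dominant",
        "ar_homozygous": "recessive",
        "ar_compound_het": "recessive",
        "x_linked": "x_linked",
    }[model]


def generate_trio(
    plan: TrioPlan, seed: int, out_dir: str | Path, keys: AnnotationKeys = AnnotationKeys()
) -> dict:
    """Write one trio bundle (VCF + PED) and return its truth record."""
    variants, ped, truth = simulate_trio(plan, seed)
    trio_dir = Path(out_dir)
    trio_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = trio_dir / f"{plan.trio_id}.vcf"
    ped_path = trio_dir / f"{plan.trio_id}.ped"
    write_trio_vcf(vcf_path, variants, ped, keys, contigs=TOY_CONTIGS)
    write_pedigree(ped_path, ped)
    truth["files"] = {"vcf": vcf_path.name, "ped": ped_path.name}
    return truth


def generate_cohort(
    design: CohortDesign,
    seed: int,
    out_dir: str | Path,
    keys: AnnotationKeys = AnnotationKeys(),
) -> dict:
    """Write a full cohort: trio bundles, panels, maps, config, manifest.

    Layout::

        out_dir/
          manifest.json
          resources/  hpo_map.tsv ddg2p.tsv omim_morbid.tsv acmg_genes.tsv
                      gene_moi.tsv config.yaml
          trios/<trio_id>/  <trio_id>.{vcf,ped,hpo.txt,clinician_genes.txt}
    """
    out = Path(out_dir)
    res = out / "resources"
    trios_dir = out / "trios"
    res.mkdir(parents=True, exist_ok=True)
    trios_dir.mkdir(parents=True, exist_ok=True)

    hpo_map: dict[str, list[str]] = {}
    ddg2p: set[str] = set(DECOY_PANEL_GENES[:8])
    omim: set[str] = set(DECOY_PANEL_GENES[4:])
    gene_moi: dict[str, str] = {g: "dominant" for g in DECOY_PANEL_GENES}
    acmg: dict[str, str] = {"LDLR": "dominant", "MYH7": "dominant"}

    generic_term = "HP:0000001"
    hpo_map[generic_term] = list(DECOY_PANEL_GENES[:4])

    truths = []
    for n, plan in enumerate(design.trios, start=1):
        trio_dir = trios_dir / plan.trio_id
        truth = generate_trio(plan, seed, trio_dir, keys)
        term = f"HP:{n:07d}"
        mapped = [DECOY_PANEL_GENES[n % len(DECOY_PANEL_GENES)]]
        clinician: list[str] = [DECOY_PANEL_GENES[0]]
        if plan.plant_model is not None and plan.plant_gene:
            gene = plan.plant_gene.upper()
            gene_moi[gene] = _moi_for_model(plan.plant_model.value)
            if plan.panel_tier == "I":
                # the causal gene reaches phase I via HPO or the clinician list
                if n % 3 == 0:
                    clinician.append(plan.plant_gene)
                else:
                    mapped.append(plan.plant_gene)
                ddg2p.add(gene)
            elif plan.panel_tier == "II":
                ddg2p.add(gene)
        if plan.secondary_plant:
            acmg[plan.secondary_gene.upper()] = "recessive"
            gene_moi[plan.secondary_gene.upper()] = "recessive"
        hpo_map[term] = mapped
        (trio_dir / f"{plan.trio_id}.hpo.txt").write_text(
            "\n".join([term, generic_term]) + "\n"
        )
        (trio_dir / f"{plan.trio_id}.clinician_genes.txt").write_text(
            "\n".join(clinician) + "\n"
        )
        truth["hpo_terms"] = [term, generic_term]
        truths.append(truth)

    map_lines = [
        f"{term}\t{gene}"
        for term in sorted(hpo_map)
        for gene in sorted(set(hpo_map[term]))
    ]
    (res / "hpo_map.tsv").write_text("\n".join(map_lines) + "\n")
    (res / "ddg2p.tsv").write_text("\n".join(sorted(ddg2p)) + "\n")
    (res / "omim_morbid.tsv").write_text("\n".join(sorted(omim)) + "\n")
    (res / "acmg_genes.tsv").write_text(
        "\n".join(f"{g}\t{m}" for g, m in sorted(acmg.items())) + "\n"
    )
    (res / "gene_moi.tsv").write_text(
        "\n".join(f"{g}\t{m}" for g, m in sorted(gene_moi.items())) + "\n"
    )
    dump_config(toy_filter_config(), keys, res / "config.yaml")

    manifest = {
        "seed": int(seed),
        "n_trios": len(design.trios),
        "trios": truths,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def generate_fixture_cohort(
    seed: int, out_dir: str | Path, n_background: int = 2000
) -> dict:
    """Generate the 24-trio benchmark cohort on disk; returns the manifest."""
    return generate_cohort(fixture_design(n_background), seed, out_dir)
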