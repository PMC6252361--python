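"""Trio inheritance-model classification.

Four genetic models are investigated: de novo, autosomal recessive
homozygous, autosomal recessive compound heterozygous (two variants in
one gene in trans, one inherited from each parent), and X-linked. The
trio design phases variants implicitly: a proband het whose mother is
het and father is reference must sit on the maternal haplotype, so
compound-het pairs can be required to be in trans without read-backed
phasing.

Conservative conventions: a homozygous-alt proband with a reference
parent is Mendelian-inconsistent (likely genotyping error), not a call;
missing parental genotypes make a variant untestable for a model rather
than letting it pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

from .filters import FilterConfig, is_predicted_deleterious, is_x_nonpar
from .models import (
    AnnotatedVariant,
    Genotype,
    HetShortlistEntry,
    InheritanceModel,
    MendelianStatus,
    ModelCall,
    ParentalOrigin,
    Pedigree,
    Sex,
    TrioGenotypes,
)

_GT = Genotype


@dataclass(frozen=True)
class MendelianCheck:
    status: MendelianStatus
    detail: str = ""


def call_de_novo(v: AnnotatedVariant) -> Optional[ModelCall]:
    """Proband het, both parents homozygous reference.

    A hom-alt proband with reference parents would require two
    independent mutation events and is flagged Mendelian-inconsistent
    instead of called.
    """
    gt = v.genotypes
    if _GT.MISSING in (gt.mother, gt.father):
        v.log("de_novo: untestable (missing parental genotype)")
        return None
    if gt.proband is _GT.HET and gt.mother is _GT.HOM_REF and gt.father is _GT.HOM_REF:
        return ModelCall(
            model=InheritanceModel.DE_NOVO,
            variants=(v,),
            gene=v.gene,
            parental_origin=(ParentalOrigin.UNRESOLVED,),
        )
    if (
        gt.proband is _GT.HOM_ALT
        and gt.mother is _GT.HOM_REF
        and gt.father is _GT.HOM_REF
    ):
        v.flags.add("mendelian_inconsistent")
    return None


def call_ar_homozygous(
    v: AnnotatedVariant,
    ped: Optional[Pedigree] = None,
    cfg: Optional[FilterConfig] = None,
) -> Optional[ModelCall]:
    """Homozygous-alt proband with both parents carriers.

    On autosomes (and pseudoautosomal X) both parents must be het. For a
    female proband on X outside the PARs the transmitting configuration
    is a het mother and a hemizygous-alt father.
    """
    gt = v.genotypes
    if _GT.MISSING in (gt.mother, gt.father):
        v.log("ar_homozygous: untestable (missing parental genotype)")
        return None
    on_x = cfg is not None and is_x_nonpar(v, cfg)
    if on_x:
        if ped is None or ped.proband_sex is not Sex.FEMALE:
            return None
        required_father = _GT.HEMI_ALT
    else:
        required_father = _GT.HET
    if (
        gt.proband is _GT.HOM_ALT
        and gt.mother is _GT.HET
        and gt.father is required_father
    ):
        return ModelCall(
            model=InheritanceModel.AR_HOMOZYGOUS,
            variants=(v,),
            gene=v.gene,
            parental_origin=(ParentalOrigin.UNRESOLVED,),
        )
    if gt.proband is _GT.HOM_ALT and (
        gt.mother is _GT.HOM_REF or gt.father is _GT.HOM_REF
    ):
        v.flags.add("mendelian_inconsistent")
    return None


def classify_parental_origin(
    v: AnnotatedVariant, cfg: Optional[FilterConfig] = None
) -> Optional[ParentalOrigin]:
    """Phase a proband het through the trio.

    Returns ``None`` when the variant is not a phaseable proband het
    (e.g. missing parental genotypes). ``UNRESOLVED`` means both parents
    carry the allele, so the transmitting haplotype cannot be determined.
    """
    gt = v.genotypes
    if gt.proband is not _GT.HET:
        return None
    if _GT.MISSING in (gt.mother, gt.father):
        return None
    on_x = cfg is not None and is_x_nonpar(v, cfg)
    father_carrier_states = (
        (_GT.HEMI_ALT,) if on_x else (_GT.HET, _GT.HOM_ALT)
    )
    mother_carries = gt.mother in (_GT.HET, _GT.HOM_ALT)
    father_carries = gt.father in father_carrier_states
    if mother_carries and not father_carries:
        return ParentalOrigin.MATERNAL
    if father_carries and not mother_carries:
        return ParentalOrigin.PATERNAL
    if mother_carries and father_carries:
        return ParentalOrigin.UNRESOLVED
    return None  # neither parent carries: de novo, not phaseable


def call_compound_het(
    variants_in_gene: Sequence[AnnotatedVariant],
    cfg: Optional[FilterConfig] = None,
) -> list[ModelCall]:
    """Trans pairs of proband hets within one gene.

    One variant must be maternally and the other paternally inherited;
    pairs from the same parent (cis) are never reported. Variants het in
    both parents have unresolved phase and are excluded unless
    ``cfg.allow_unresolved_phase`` is set, in which case a pair is
    reported whenever cis cannot be demonstrated.
    """
    allow_unresolved = bool(cfg and cfg.allow_unresolved_phase)
    origins: list[tuple[AnnotatedVariant, ParentalOrigin]] = []
    for v in variants_in_gene:
        origin = classify_parental_origin(v, cfg)
        if origin is None:
            continue
        if origin is ParentalOrigin.UNRESOLVED and not allow_unresolved:
            v.log("compound_het: unresolved phase (het in both parents), excluded")
            continue
        origins.append((v, origin))

    calls: list[ModelCall] = []
    for (va, oa), (vb, ob) in combinations(origins, 2):
        resolved = {oa, ob} - {ParentalOrigin.UNRESOLVED}
        if ParentalOrigin.UNRESOLVED in (oa, ob):
            trans_possible = True  # cannot prove cis; gated by config above
        else:
            trans_possible = resolved == {
                ParentalOrigin.MATERNAL,
                ParentalOrigin.PATERNAL,
            }
        if not trans_possible:
            continue
        # deterministic variant order within the pair: genomic coordinate
        pair = sorted([(va, oa), (vb, ob)], key=lambda t: (t[0].pos, t[0].alt))
        calls.append(
            ModelCall(
                model=InheritanceModel.AR_COMPOUND_HET,
                variants=(pair[0][0], pair[1][0]),
                gene=pair[0][0].gene,
                parental_origin=(pair[0][1], pair[1][1]),
            )
        )
    return calls


def call_x_linked(
    v: AnnotatedVariant, ped: Pedigree, cfg: FilterConfig
) -> Optional[ModelCall]:
    """Hemizygous model for a male proband on chrX outside the PARs.

    The father must not carry the allele (he transmits Y to a son); a
    het mother gives a maternally inherited call, a reference mother a
    call flagged as de novo on X. Female probands on X are handled by
    the autosomal-recessive operations with the father hemizygous-alt as
    the transmitting state.
    """
    if not is_x_nonpar(v, cfg):
        return None
    if ped.proband_sex is Sex.UNKNOWN:
        v.log("x_linked: sex required")
        return None
    if ped.proband_sex is not Sex.MALE:
        return None
    gt = v.genotypes
    if _GT.MISSING in (gt.mother, gt.father):
        v.log("x_linked: untestable (missing parental genotype)")
        return None
    if gt.proband is not _GT.HEMI_ALT:
        return None
    if gt.father is not _GT.HOM_REF:  # haploid reference decodes as hom_ref
        return None
    if gt.mother is _GT.HET:
        return ModelCall(
            model=InheritanceModel.X_LINKED,
            variants=(v,),
            gene=v.gene,
            parental_origin=(ParentalOrigin.MATERNAL,),
        )
    if gt.mother is _GT.HOM_REF:
        return ModelCall(
            model=InheritanceModel.X_LINKED,
            variants=(v,),
            gene=v.gene,
            parental_origin=(ParentalOrigin.MATERNAL,),
            flags={"de_novo_on_x"},
        )
    return None


def shortlist_single_hets(
    variants_in_gene: Sequence[AnnotatedVariant],
    gene_moi: str,
    cfg: FilterConfig,
) -> list[HetShortlistEntry]:
    """Lone deleterious hets in a recessive-inheritance gene.

    A single deleterious het in a recessive gene cannot explain disease
    by itself, but a structural variant on the second allele could; such
    variants are shortlisted as input to manual region inspection.
    Hets with a trans partner are reported as compound-het calls
    instead, never shortlisted.
    """
    if gene_moi != "recessive":
        return []
    paired_keys: set[str] = set()
    for call in call_compound_het(variants_in_gene, cfg):
        paired_keys.update(call.variant_keys)
    entries = []
    for v in variants_in_gene:
        if v.genotypes.proband is not _GT.HET:
            continue
        if v.key in paired_keys:
            continue
        if not is_predicted_deleterious(v, cfg):
            continue
        entries.append(HetShortlistEntry(variant=v, gene=v.gene))
    return entries


def mendelian_consistency(v: AnnotatedVariant) -> MendelianCheck:
    """Can the proband genotype arise from the parents biparentally?

    A proband het with two reference parents is inconsistent by a single
    allele and labelled ``de_novo_single_allele`` so QC can separate
    plausible de novo events from outright genotype conflicts.
    """
    gt = v.genotypes
    if _GT.MISSING in gt.as_tuple():
        return MendelianCheck(MendelianStatus.UNTESTABLE)

    def alleles(g: Genotype) -> set[int]:
        return {
            _GT.HOM_REF: {0},
            _GT.HET: {0, 1},
            _GT.HOM_ALT: {1},
            _GT.HEMI_ALT: {1},
        }[g]

    proband = {
        _GT.HOM_REF: (0, 0),
        _GT.HET: (0, 1),
        _GT.HOM_ALT: (1, 1),
        _GT.HEMI_ALT: (1,),
    }[gt.proband]
    maternal = alleles(gt.mother)
    paternal = alleles(gt.father)
    if len(proband) == 1:
        # hemizygous proband: the single X allele is maternal
        if proband[0] in maternal:
            return MendelianCheck(MendelianStatus.CONSISTENT)
        return MendelianCheck(MendelianStatus.INCONSISTENT)
    a, b = proband
    ok = (a in maternal and b in paternal) or (b in maternal and a in paternal)
    if ok:
        return MendelianCheck(MendelianStatus.CONSISTENT)
    if (
        gt.proband is _GT.HET
        and gt.mother is _GT.HOM_REF
        and gt.father is _GT.HOM_REF
    ):
        return MendelianCheck(MendelianStatus.INCONSISTENT, "de_novo_single_allele")
    return MendelianCheck(MendelianStatus.INCONSISTENT)
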