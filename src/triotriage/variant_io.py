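"""Reading and writing annotated trio VCFs and pedigree files.

Raw VCF records are normalized into the pipeline's data model at the
door: multiallelic sites are decomposed into biallelic records, contig
labels are mapped to a single ``chr``-prefixed dialect, raw GT strings
are collapsed to five genotype states, and missing annotations become
``None`` (absent), never a silent 0. Annotation INFO keys are
config-mapped because upstream annotators name them differently.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from cyvcf2 import VCF

from .filters import FilterConfig, passes_quality_gate
from .models import (
    AnnotatedVariant,
    Consequence,
    Genotype,
    Pedigree,
    PedigreeError,
    SampleQuality,
    Sex,
    TrioGenotypes,
)

CANONICAL_CONTIGS = frozenset(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY", "chrM"]
)


class VcfFormatError(ValueError):
    """Raised for malformed records or missing sample columns."""


@dataclass(frozen=True)
class AnnotationKeys:
    """INFO/annotation field names in the input VCF (annotator-specific)."""

    af_1000g: str = "AF_1KG"
    af_exac: str = "AF_EXAC"
    af_evs: str = "AF_EVS"
    exac_hom_count: str = "EXAC_HOM"
    exac_hemi_count: str = "EXAC_HEMI"
    consequence: str = "CSQ_CAT"
    splice_distance: str = "SPLICE_DIST"
    gene: str = "GENE"
    known_pathogenic: str = "KNOWN_PATH"

    @classmethod
    def from_mapping(cls, data: dict) -> "AnnotationKeys":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown annotation keys: {sorted(unknown)}")
        return cls(**data)


def normalize_chrom(label: str) -> tuple[str, bool]:
    """Map a contig label to the ``chr``-prefixed dialect.

    Returns ``(label, canonical)``; unrecognised contigs (scaffolds,
    patches) are preserved verbatim with ``canonical=False``.
    """
    raw = label.strip()
    body = raw[3:] if raw.lower().startswith("chr") else raw
    if body.upper() == "MT":
        body = "M"
    candidate = f"chr{body}"
    if candidate in CANONICAL_CONTIGS:
        return candidate, True
    return raw, False


def read_pedigree(path: str | Path) -> Pedigree:
    """Parse a standard 6-column PED file describing exactly one trio.

    The proband is the unique sample whose father and mother columns
    both name other samples in the file; parents must be founders.
    """
    rows: list[tuple[str, str, str, str, str]] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise PedigreeError(f"PED line has {len(parts)} columns, need 6: {line!r}")
        fam, sid, father, mother, sex, _pheno = parts[:6]
        if sid in seen:
            raise PedigreeError(f"duplicate sample id {sid!r} in PED file")
        seen.add(sid)
        rows.append((fam, sid, father, mother, sex))

    if len(rows) > 3:
        extras = [sid for _, sid, *_ in rows[3:]]
        raise PedigreeError(
            f"pedigree must describe a single trio; extra sample(s): {extras}"
        )
    probands = [r for r in rows if r[2] != "0" and r[3] != "0"]
    if len(probands) != 1:
        raise PedigreeError(
            "incomplete trio: expected exactly one sample with both parents, "
            f"found {len(probands)}"
        )
    fam, sid, father, mother, sex_code = probands[0]
    if father not in seen or mother not in seen:
        raise PedigreeError(
            f"incomplete trio: parent(s) of {sid!r} missing from PED file"
        )
    sex = {"1": Sex.MALE, "2": Sex.FEMALE}.get(sex_code, Sex.UNKNOWN)
    return Pedigree(
        family_id=fam,
        proband_id=sid,
        mother_id=mother,
        father_id=father,
        proband_sex=sex,
    )


def _genotype_for_alt(alleles: Sequence[int], alt_index: int) -> Genotype:
    """Collapse a GT allele vector to one state for one alt allele.

    Other alt alleles are recoded as reference for this record, so a
    ``1/2`` proband becomes het in each decomposed record.
    """
    if any(a == -1 for a in alleles):
        return Genotype.MISSING
    n_alt = sum(1 for a in alleles if a == alt_index)
    if len(alleles) == 1:  # haploid call (male X/Y)
        return Genotype.HEMI_ALT if n_alt == 1 else Genotype.HOM_REF
    if n_alt == 2:
        return Genotype.HOM_ALT
    if n_alt == 1:
        return Genotype.HET
    return Genotype.HOM_REF


def _per_alt(value, alt_index: int, n_alts: int):
    """Pick the value for one alt from a Number=A INFO payload."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        if len(value) != n_alts:
            raise VcfFormatError(
                f"per-allele INFO field has {len(value)} values for {n_alts} alts"
            )
        return value[alt_index - 1]
    return value


def _as_float(value, what: str, where: str) -> Optional[float]:
    if value is None:
        return None
    try:
        f = float(value)
    except (TypeError, ValueError) as exc:
        raise VcfFormatError(f"malformed {what} value {value!r} at {where}") from exc
    if f != f:  # NaN encodes a '.' placeholder in some annotators
        return None
    return f


def decompose_multiallelic(
    record,
    sample_index: dict[str, int],
    keys: AnnotationKeys = AnnotationKeys(),
) -> list[AnnotatedVariant]:
    """Split one raw VCF record into biallelic :class:`AnnotatedVariant`s.

    Produces one record per alt allele; genotypes are recoded per alt
    (other alts count as reference) and multi-alt outputs are flagged
    ``from_multiallelic``. Symbolic alts (``<DEL>`` etc.) are passed
    through flagged ``symbolic`` so downstream filters can exclude them.
    """
    chrom, canonical = normalize_chrom(record.CHROM)
    where = f"{record.CHROM}:{record.POS}"
    alts = list(record.ALT)
    n_alts = len(alts)
    gt_rows = record.genotypes  # [[a0, a1, phased], ...] or haploid [[a0, phased]]
    gqs = record.format("GQ")
    depths = record.format("DP")
    info = record.INFO

    out: list[AnnotatedVariant] = []
    for alt_index, alt in enumerate(alts, start=1):
        flags: set[str] = set()
        if n_alts > 1:
            flags.add("from_multiallelic")
        if alt.startswith("<") or "[" in alt or "]" in alt:
            flags.add("symbolic")
        if not canonical:
            flags.add("non_canonical_contig")

        quality: dict[str, SampleQuality] = {}
        gts = {}
        for sid, idx in sample_index.items():
            alleles = [a for a in gt_rows[idx][:-1]]
            gts[sid] = _genotype_for_alt(alleles, alt_index)
            gq = (
                int(gqs[idx][0])
                if gqs is not None and 0 <= gqs[idx][0] < 2**30
                else None
            )
            dp = (
                int(depths[idx][0])
                if depths is not None and 0 <= depths[idx][0] < 2**30
                else None
            )
            quality[sid] = SampleQuality(gq=gq, depth=dp)

        csq_raw = info.get(keys.consequence)
        try:
            consequence = (
                Consequence(csq_raw) if csq_raw is not None else Consequence.OTHER
            )
        except ValueError:
            consequence = Consequence.OTHER
        splice_raw = info.get(keys.splice_distance)
        gene = info.get(keys.gene) or ""

        out.append(
            AnnotatedVariant(
                chrom=chrom,
                pos=record.POS,
                ref=record.REF,
                alt=alt,
                genotypes=TrioGenotypes(
                    proband=gts["proband"],
                    mother=gts["mother"],
                    father=gts["father"],
                ),
                gene=str(gene),
                consequence=consequence,
                splice_distance=int(splice_raw) if splice_raw is not None else None,
                af_1000g=_as_float(
                    _per_alt(info.get(keys.af_1000g), alt_index, n_alts),
                    keys.af_1000g,
                    where,
                ),
                af_exac=_as_float(
                    _per_alt(info.get(keys.af_exac), alt_index, n_alts),
                    keys.af_exac,
                    where,
                ),
                af_evs=_as_float(
                    _per_alt(info.get(keys.af_evs), alt_index, n_alts),
                    keys.af_evs,
                    where,
                ),
                exac_hom_count=(
                    int(h)
                    if (h := _per_alt(info.get(keys.exac_hom_count), alt_index, n_alts))
                    is not None
                    else None
                ),
                exac_hemi_count=(
                    int(h)
                    if (
                        h := _per_alt(info.get(keys.exac_hemi_count), alt_index, n_alts)
                    )
                    is not None
                    else None
                ),
                known_pathogenic=bool(info.get(keys.known_pathogenic)),
                quality=quality,
                flags=flags,
            )
        )
    return out


def read_trio_vcf(
    path: str | Path,
    ped: Pedigree,
    keys: AnnotationKeys = AnnotationKeys(),
    cfg: Optional[FilterConfig] = None,
) -> Iterator[AnnotatedVariant]:
    """Stream decomposed, quality-gated variants from a multi-sample VCF.

    When ``cfg`` is given, records failing the trio genotype-quality gate
    (GQ/depth floor in any of the three samples) are dropped at the door;
    de novo assessment on low-quality genotypes is not meaningful.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for sid in ped.sample_ids:
        if sid not in samples:
            raise VcfFormatError(f"sample not found in VCF: {sid!r}")
    sample_index = {
        "proband": samples.index(ped.proband_id),
        "mother": samples.index(ped.mother_id),
        "father": samples.index(ped.father_id),
    }
    role_by_sid = {
        "proband": ped.proband_id,
        "mother": ped.mother_id,
        "father": ped.father_id,
    }
    for record in vcf:
        for v in decompose_multiallelic(record, sample_index, keys):
            # re-key quality from role to sample id for the gate
            v.quality = {
                role_by_sid[role]: q for role, q in v.quality.items()
            }
            if cfg is not None and not passes_quality_gate(
                v, cfg, ped.sample_ids
            ):
                continue
            yield v
    vcf.close()


def _fmt_af(x: float) -> str:
    return f"{x:.6g}"


VCF_HEADER_INFO = """\
##INFO=<ID={af1},Number=A,Type=Float,Description="1000 Genomes allele frequency">
##INFO=<ID={afx},Number=A,Type=Float,Description="ExAC allele frequency">
##INFO=<ID={afe},Number=A,Type=Float,Description="EVS allele frequency">
##INFO=<ID={hom},Number=A,Type=Integer,Description="ExAC homozygote count">
##INFO=<ID={hemi},Number=A,Type=Integer,Description="ExAC hemizygote count">
##INFO=<ID={csq},Number=1,Type=String,Description="Consequence category">
##INFO=<ID={spl},Number=1,Type=Integer,Description="Distance to nearest exon boundary (bp)">
##INFO=<ID={gene},Number=1,Type=String,Description="Gene symbol">
##INFO=<ID={kp},Number=0,Type=Flag,Description="Matches a curated pathogenic assertion">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def _gt_string(gt: Genotype) -> str:
    return {
        Genotype.HOM_REF: "0/0",
        Genotype.HET: "0/1",
        Genotype.HOM_ALT: "1/1",
        Genotype.HEMI_ALT: "1",
        Genotype.MISSING: "./.",
    }[gt]


def write_trio_vcf(
    path: str | Path,
    variants: Iterable[AnnotatedVariant],
    ped: Pedigree,
    keys: AnnotationKeys = AnnotationKeys(),
    contigs: Optional[Sequence[tuple[str, int]]] = None,
) -> None:
    """Write biallelic variants as a deterministic plain-text VCF 4.2.

    Output bytes depend only on the input values (stable float
    formatting, fixed header), so identical runs produce identical files.
    """
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs or []:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(
        VCF_HEADER_INFO.format(
            af1=keys.af_1000g,
            afx=keys.af_exac,
            afe=keys.af_evs,
            hom=keys.exac_hom_count,
            hemi=keys.exac_hemi_count,
            csq=keys.consequence,
            spl=keys.splice_distance,
            gene=keys.gene,
            kp=keys.known_pathogenic,
        ).rstrip("\n")
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(ped.sample_ids)
    )
    for v in variants:
        info_parts: list[str] = []
        if v.af_1000g is not None:
            info_parts.append(f"{keys.af_1000g}={_fmt_af(v.af_1000g)}")
        if v.af_exac is not None:
            info_parts.append(f"{keys.af_exac}={_fmt_af(v.af_exac)}")
        if v.af_evs is not None:
            info_parts.append(f"{keys.af_evs}={_fmt_af(v.af_evs)}")
        if v.exac_hom_count is not None:
            info_parts.append(f"{keys.exac_hom_count}={v.exac_hom_count}")
        if v.exac_hemi_count is not None:
            info_parts.append(f"{keys.exac_hemi_count}={v.exac_hemi_count}")
        info_parts.append(f"{keys.consequence}={v.consequence.value}")
        if v.splice_distance is not None:
            info_parts.append(f"{keys.splice_distance}={v.splice_distance}")
        if v.gene:
            info_parts.append(f"{keys.gene}={v.gene}")
        if v.known_pathogenic:
            info_parts.append(keys.known_pathogenic)
        samples = []
        for sid, gt in zip(
            ped.sample_ids,
            (v.genotypes.proband, v.genotypes.mother, v.genotypes.father),
        ):
            q = v.quality.get(sid, SampleQuality())
            gq = q.gq if q.gq is not None else "."
            dp = q.depth if q.depth is not None else "."
            samples.append(f"{_gt_string(gt)}:{gq}:{dp}")
        lines.append(
            "\t".join(
                [
                    v.chrom,
                    str(v.pos),
                    ".",
                    v.ref,
                    v.alt,
                    ".",
                    "PASS",
                    ";".join(info_parts),
                    "GT:GQ:DP",
                ]
                + samples
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_pedigree(path: str | Path, ped: Pedigree) -> None:
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}[ped.proband_sex]
    lines = [
        f"{ped.family_id}\t{ped.father_id}\t0\t0\t1\t1",
        f"{ped.family_id}\t{ped.mother_id}\t0\t0\t2\t1",
        f"{ped.family_id}\t{ped.proband_id}\t{ped.father_id}\t{ped.mother_id}\t{sex_code}\t2",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
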