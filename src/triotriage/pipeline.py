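"""Phased trio triage: escalating scopes, secondary findings, reports.

The workflow analyses one trio in up to three phases of widening gene
scope: a bespoke patient panel (phase I), a broad disease-gene panel
(phase II), then genome-wide (phase III, research-only). A phase's
candidate calls go to multidisciplinary review; the pipeline escalates
automatically when a phase yields nothing and otherwise follows an
explicit review decision (a candidate that fully explains the phenotype
stops the analysis). A consented secondary-findings scan over a
medically actionable gene list runs at phase II breadth.

Pathogenicity classification is a human judgement: the pipeline carries
a ``classification`` field and drives its machine-readable
``reportable`` flag from the curated known-pathogenic annotation, so
reports are testable without automating clinical review.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .filters import (
    FilterConfig,
    is_predicted_deleterious,
    is_x_nonpar,
    passes_permissive_recessive_frequency,
    passes_standard_frequency,
)
from .inheritance import (
    call_ar_homozygous,
    call_compound_het,
    call_de_novo,
    call_x_linked,
    shortlist_single_hets,
)
from .models import (
    AnnotatedVariant,
    HetShortlistEntry,
    InheritanceModel,
    ModelCall,
    Pedigree,
)
from .panels import GenePanel

PHASES = ("I", "II", "III")

_MODEL_PRIORITY = {
    InheritanceModel.DE_NOVO: 0,
    InheritanceModel.AR_HOMOZYGOUS: 1,
    InheritanceModel.AR_COMPOUND_HET: 2,
    InheritanceModel.X_LINKED: 3,
}

_CHROM_ORDER = {f"chr{i}": i for i in range(1, 23)}
_CHROM_ORDER.update({"chrX": 23, "chrY": 24, "chrM": 25})

#: gene mode of inheritance → models that satisfy it (secondary scan)
MOI_MODELS = {
    "recessive": {
        InheritanceModel.AR_HOMOZYGOUS,
        InheritanceModel.AR_COMPOUND_HET,
    },
    "dominant": {InheritanceModel.DE_NOVO},
    "x_linked": {InheritanceModel.X_LINKED},
}


@dataclass
class CandidateSet:
    """Variants surviving one phase, tagged with inheritance models."""

    phase: str
    calls: list[ModelCall] = field(default_factory=list)
    het_shortlist: list[HetShortlistEntry] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class TriageReport:
    patient_id: str
    outcome: str  # provisional_finding | no_primary_findings
    diagnostic_calls: list[ModelCall] = field(default_factory=list)
    review_candidates: list[ModelCall] = field(default_factory=list)
    secondary_findings: list[ModelCall] = field(default_factory=list)
    research_candidates: list[ModelCall] = field(default_factory=list)
    het_shortlist: list[HetShortlistEntry] = field(default_factory=list)
    phases_run: list[str] = field(default_factory=list)
    opt_in_secondary: bool = False
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.outcome == "provisional_finding") != bool(self.diagnostic_calls):
            raise ValueError(
                "outcome must be provisional_finding iff diagnostic calls exist"
            )
        if self.secondary_findings and not self.opt_in_secondary:
            raise ValueError("secondary findings present without opt-in")


def _recessive_frequency_ok(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    return passes_standard_frequency(v, cfg) or passes_permissive_recessive_frequency(
        v, cfg
    )


def _model_calls_for_variant(
    v: AnnotatedVariant, ped: Pedigree, cfg: FilterConfig
) -> list[ModelCall]:
    """Single-variant models (compound het needs the per-gene view)."""
    calls: list[ModelCall] = []
    if passes_standard_frequency(v, cfg):
        dn = call_de_novo(v)
        if dn is not None:
            calls.append(dn)
    if _recessive_frequency_ok(v, cfg):
        if is_x_nonpar(v, cfg):
            xl = call_x_linked(v, ped, cfg)
            if xl is not None:
                calls.append(xl)
        ar = call_ar_homozygous(v, ped, cfg)
        if ar is not None:
            calls.append(ar)
    return calls


def run_phase(
    variants: Sequence[AnnotatedVariant],
    panel: GenePanel,
    phase: str,
    cfg: FilterConfig,
    ped: Pedigree,
) -> CandidateSet:
    """Apply scope, consequence, frequency and inheritance filters.

    De novo candidates must pass the standard ≤0.5% frequency rule;
    recessive and X-linked candidates may instead pass the permissive
    ≤10% zero-homozygote rule. In phase I, recessive-inheritance panel
    genes additionally contribute the lone-het shortlist.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    counts = {
        "total": 0,
        "in_scope": 0,
        "deleterious": 0,
        "frequency_ok": 0,
        "calls": 0,
    }
    eligible: list[AnnotatedVariant] = []
    for v in variants:
        counts["total"] += 1
        if "symbolic" in v.flags:
            v.log(f"phase {phase}: symbolic allele excluded")
            continue
        if v.gene not in panel and not panel.universal:
            v.log(f"phase {phase}: gene {v.gene or '(none)'} outside panel scope")
            continue
        counts["in_scope"] += 1
        if not is_predicted_deleterious(v, cfg):
            v.log(f"phase {phase}: consequence {v.consequence.value} not deleterious")
            continue
        counts["deleterious"] += 1
        std = passes_standard_frequency(v, cfg)
        perm = passes_permissive_recessive_frequency(v, cfg)
        v.log(
            f"phase {phase}: frequency standard={'pass' if std else 'fail'} "
            f"permissive={'pass' if perm else 'fail'}"
        )
        if not (std or perm):
            continue
        counts["frequency_ok"] += 1
        eligible.append(v)

    calls: list[ModelCall] = []
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in eligible:
        calls.extend(_model_calls_for_variant(v, ped, cfg))
        if v.gene:
            by_gene.setdefault(v.gene.upper(), []).append(v)

    for gene, gene_variants in sorted(by_gene.items()):
        pairable = [v for v in gene_variants if _recessive_frequency_ok(v, cfg)]
        calls.extend(call_compound_het(pairable, cfg))

    shortlist: list[HetShortlistEntry] = []
    if phase == "I":
        for gene, gene_variants in sorted(by_gene.items()):
            shortlist.extend(
                shortlist_single_hets(gene_variants, panel.moi(gene), cfg)
            )

    for call in calls:
        call.phase = phase
        for v in call.variants:
            v.log(f"phase {phase}: {call.model.value} call")
    counts["calls"] = len(calls)
    return CandidateSet(
        phase=phase, calls=rank_candidates(calls), het_shortlist=shortlist,
        counts=counts,
    )


def escalate(phase: str, mdt_decision: str) -> Optional[str]:
    """Next phase under the review decision, or ``None`` to stop.

    A candidate judged to fully explain the phenotype ends the analysis;
    a partial or absent explanation widens the scope to the next phase.
    """
    if mdt_decision not in {"fully_explained", "partial", "unexplained"}:
        raise ValueError(f"unknown review decision {mdt_decision!r}")
    if mdt_decision == "fully_explained":
        return None
    return {"I": "II", "II": "III", "III": None}[phase]


def scan_secondary_findings(
    variants: Sequence[AnnotatedVariant],
    acmg_panel: Optional[GenePanel],
    opt_in: bool,
    cfg: FilterConfig,
    ped: Pedigree,
    exclude_keys: Iterable[str] = (),
) -> list[ModelCall]:
    """Consented scan of a medically actionable gene list.

    Reports deleterious, frequency-passing variants whose inheritance
    call matches the listed gene's mode of inheritance; anything already
    reported as a primary candidate is excluded. Without opt-in the scan
    returns nothing, unconditionally.
    """
    if not opt_in or acmg_panel is None:
        return []
    excluded = set(exclude_keys)
    in_genes = [
        v
        for v in variants
        if "symbolic" not in v.flags
        and v.gene in acmg_panel
        and is_predicted_deleterious(v, cfg)
    ]
    calls: list[ModelCall] = []
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in in_genes:
        moi = acmg_panel.moi(v.gene)
        allowed = MOI_MODELS.get(moi, set())
        if InheritanceModel.DE_NOVO in allowed and passes_standard_frequency(v, cfg):
            dn = call_de_novo(v)
            if dn is not None:
                calls.append(dn)
        if allowed & {
            InheritanceModel.AR_HOMOZYGOUS,
            InheritanceModel.X_LINKED,
        } and _recessive_frequency_ok(v, cfg):
            if InheritanceModel.AR_HOMOZYGOUS in allowed:
                ar = call_ar_homozygous(v, ped, cfg)
                if ar is not None:
                    calls.append(ar)
            if InheritanceModel.X_LINKED in allowed and is_x_nonpar(v, cfg):
                xl = call_x_linked(v, ped, cfg)
                if xl is not None:
                    calls.append(xl)
        if InheritanceModel.AR_COMPOUND_HET in allowed and _recessive_frequency_ok(
            v, cfg
        ):
            by_gene.setdefault(v.gene.upper(), []).append(v)
    for gene in sorted(by_gene):
        calls.extend(call_compound_het(by_gene[gene], cfg))
    for call in calls:
        call.phase = "II"
        call.flags.add("secondary_finding")
    calls = [
        c for c in calls if not (set(c.variant_keys) & excluded)
    ]
    return rank_candidates(calls)


def rank_candidates(calls: Sequence[ModelCall]) -> list[ModelCall]:
    """Deterministic total order over candidate calls.

    Curated-pathogenic calls first, then earlier phase, then model
    priority (de novo, homozygous, compound het, X-linked), then
    ascending maximum reported allele frequency, with genomic
    coordinates as the final tie-break.
    """

    def chrom_rank(chrom: str) -> tuple[int, str]:
        return (_CHROM_ORDER.get(chrom, 99), chrom)

    def sort_key(call: ModelCall):
        v0 = call.variants[0]
        return (
            0 if call.known_pathogenic else 1,
            PHASES.index(call.phase) if call.phase in PHASES else 9,
            _MODEL_PRIORITY[call.model],
            call.max_reported_af,
            chrom_rank(v0.chrom),
            v0.pos,
            v0.alt,
        )

    return sorted(calls, key=sort_key)


def _resolve_decision(mdt_decision: str, candidate_set: CandidateSet) -> str:
    """Translate the configured decision mode into a concrete decision.

    With no calls the decision defaults to ``unexplained``; in ``auto``
    mode a curated-pathogenic call counts as a full explanation (the
    testable stand-in for clinical review).
    """
    if not candidate_set.calls:
        return "unexplained"
    if mdt_decision == "auto":
        if any(c.known_pathogenic for c in candidate_set.calls):
            return "fully_explained"
        return "unexplained"
    return mdt_decision


def triage(
    variants: Sequence[AnnotatedVariant],
    ped: Pedigree,
    phase1_panel: GenePanel,
    phase2_panel: GenePanel,
    phase3_panel: GenePanel,
    cfg: FilterConfig,
    acmg_panel: Optional[GenePanel] = None,
    opt_in_secondary: bool = False,
    mdt_decision: str = "auto",
) -> TriageReport:
    """Run the full phased workflow for one trio and assemble the report.

    ``mdt_decision`` is ``auto`` (escalate unless a curated-pathogenic
    call is found) or an explicit ``fully_explained`` / ``partial`` /
    ``unexplained`` applied after every phase with candidates.
    """
    variants = list(variants)
    panels = {"I": phase1_panel, "II": phase2_panel, "III": phase3_panel}
    phases_run: list[str] = []
    candidate_sets: dict[str, CandidateSet] = {}
    secondary: list[ModelCall] = []
    counts: dict[str, dict[str, int]] = {}

    phase: Optional[str] = "I"
    while phase is not None:
        cs = run_phase(variants, panels[phase], phase, cfg, ped)
        candidate_sets[phase] = cs
        phases_run.append(phase)
        counts[phase] = cs.counts
        if phase == "II":
            primary_keys = [
                k
                for p in ("I", "II")
                if p in candidate_sets
                for c in candidate_sets[p].calls
                for k in c.variant_keys
            ]
            secondary = scan_secondary_findings(
                variants, acmg_panel, opt_in_secondary, cfg, ped, primary_keys
            )
        decision = _resolve_decision(mdt_decision, cs)
        phase = escalate(phase, decision)

    primary_calls = [
        c
        for p in ("I", "II")
        if p in candidate_sets
        for c in candidate_sets[p].calls
    ]
    diagnostic = rank_candidates([c for c in primary_calls if c.known_pathogenic])
    review = rank_candidates([c for c in primary_calls if not c.known_pathogenic])
    research = (
        candidate_sets["III"].calls if "III" in candidate_sets else []
    )
    outcome = "provisional_finding" if diagnostic else "no_primary_findings"
    return TriageReport(
        patient_id=ped.proband_id,
        outcome=outcome,
        diagnostic_calls=diagnostic,
        review_candidates=review,
        secondary_findings=secondary,
        research_candidates=research,
        het_shortlist=(
            candidate_sets["I"].het_shortlist if "I" in candidate_sets else []
        ),
        phases_run=phases_run,
        opt_in_secondary=opt_in_secondary,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# file-based entry points


def triage_from_files(
    vcf_path: str | Path,
    ped_path: str | Path,
    hpo_path: str | Path,
    hpo_map_path: str | Path,
    ddg2p_path: str | Path,
    omim_morbid_path: str | Path,
    clinician_genes_path: Optional[str | Path] = None,
    acmg_genes_path: Optional[str | Path] = None,
    gene_moi_path: Optional[str | Path] = None,
    cfg: Optional[FilterConfig] = None,
    keys=None,
    opt_in_secondary: bool = False,
    mdt_decision: str = "auto",
) -> TriageReport:
    """Load one trio's inputs from disk and run the phased workflow."""
    from .panels import (
        PhenotypeProfile,
        build_phase1_panel,
        build_phase2_panel,
        phase3_scope,
        read_gene_list,
        read_gene_moi,
        read_hpo_gene_map,
        read_hpo_terms,
    )
    from .variant_io import AnnotationKeys, read_pedigree, read_trio_vcf

    cfg = cfg or FilterConfig()
    keys = keys or AnnotationKeys()
    ped = read_pedigree(ped_path)
    variants = list(read_trio_vcf(vcf_path, ped, keys, cfg))

    moi = read_gene_moi(gene_moi_path) if gene_moi_path else {}
    profile = PhenotypeProfile(
        patient_id=ped.proband_id, hpo_terms=read_hpo_terms(hpo_path)
    )
    clinician = (
        read_gene_list(clinician_genes_path) if clinician_genes_path else []
    )
    phase1 = build_phase1_panel(
        profile, read_hpo_gene_map(hpo_map_path), clinician, moi
    )
    phase2 = build_phase2_panel(
        read_gene_list(ddg2p_path), read_gene_list(omim_morbid_path), moi
    )
    acmg_panel = None
    if acmg_genes_path is not None:
        acmg_moi = read_gene_moi(acmg_genes_path)
        acmg_panel = GenePanel(
            name="actionable secondary-findings list",
            genes=set(acmg_moi),
            moi_by_gene=acmg_moi,
            provenance={g: ["ACMG-style list"] for g in acmg_moi},
        )
    return triage(
        variants,
        ped,
        phase1,
        phase2,
        phase3_scope(),
        cfg,
        acmg_panel=acmg_panel,
        opt_in_secondary=opt_in_secondary,
        mdt_decision=mdt_decision,
    )


def triage_cohort_dir(
    cohort_dir: str | Path,
    opt_in_secondary: bool = True,
    mdt_decision: str = "auto",
    cfg: Optional[FilterConfig] = None,
) -> dict[str, TriageReport]:
    """Triage every trio of a generated cohort directory (see simulate).

    Uses the cohort's own ``resources/config.yaml`` unless ``cfg`` is
    given; returns reports keyed by trio id.
    """
    from .config import load_config

    root = Path(cohort_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    file_cfg, keys = load_config(root / "resources" / "config.yaml")
    cfg = cfg or file_cfg
    res = root / "resources"
    reports: dict[str, TriageReport] = {}
    for entry in manifest["trios"]:
        tid = entry["trio_id"]
        tdir = root / "trios" / tid
        reports[tid] = triage_from_files(
            vcf_path=tdir / entry["files"]["vcf"],
            ped_path=tdir / entry["files"]["ped"],
            hpo_path=tdir / f"{tid}.hpo.txt",
            hpo_map_path=res / "hpo_map.tsv",
            ddg2p_path=res / "ddg2p.tsv",
            omim_morbid_path=res / "omim_morbid.tsv",
            clinician_genes_path=tdir / f"{tid}.clinician_genes.txt",
            acmg_genes_path=res / "acmg_genes.tsv",
            gene_moi_path=res / "gene_moi.tsv",
            cfg=cfg,
            keys=keys,
            opt_in_secondary=opt_in_secondary,
            mdt_decision=mdt_decision,
        )
    return reports


# ---------------------------------------------------------------------------
# serialization


def _call_record(call: ModelCall) -> dict:
    return {
        "model": call.model.value,
        "gene": call.gene,
        "phase": call.phase,
        "variants": [
            {
                "key": v.key,
                "consequence": v.consequence.value,
                "af_1000g": v.af_1000g,
                "af_exac": v.af_exac,
                "af_evs": v.af_evs,
                "known_pathogenic": v.known_pathogenic,
                "filter_trail": list(v.filter_trail),
            }
            for v in call.variants
        ],
        "parental_origin": [o.value for o in call.parental_origin],
        "flags": sorted(call.flags),
        "known_pathogenic": call.known_pathogenic,
        "reportable": call.known_pathogenic,
        "classification": "",  # completed at clinical review, not computed
    }


def report_to_dict(report: TriageReport) -> dict:
    return {
        "patient_id": report.patient_id,
        "outcome": report.outcome,
        "phases_run": report.phases_run,
        "opt_in_secondary": report.opt_in_secondary,
        "diagnostic_calls": [_call_record(c) for c in report.diagnostic_calls],
        "review_candidates": [_call_record(c) for c in report.review_candidates],
        "secondary_findings": [_call_record(c) for c in report.secondary_findings],
        "research_candidates": [
            dict(_call_record(c), research_only=True)
            for c in report.research_candidates
        ],
        "het_shortlist": [
            {"variant": e.variant.key, "gene": e.gene, "reason": e.reason}
            for e in report.het_shortlist
        ],
        "filter_counts": report.counts,
    }


def _tsv_rows(section: str, calls: Sequence[ModelCall]) -> list[str]:
    rows = []
    for c in calls:
        rows.append(
            "\t".join(
                [
                    section,
                    ";".join(c.variant_keys),
                    c.gene,
                    c.model.value,
                    ";".join(o.value for o in c.parental_origin),
                    c.phase or "",
                    "yes" if c.known_pathogenic else "no",
                    ";".join(sorted(c.flags)) or ".",
                ]
            )
        )
    return rows


def generate_report(report: TriageReport, out_dir: str | Path) -> dict[str, Path]:
    """Serialize one trio's report as JSON plus a human-readable TSV.

    Phase III candidates are research-only and additionally exported as
    a shareable TSV; they never contribute to the diagnostic outcome.
    Output is byte-deterministic for identical inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / f"{report.patient_id}.report.json"
    tsv_path = out / f"{report.patient_id}.report.tsv"
    json_path.write_text(
        json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n"
    )
    header = "section\tvariants\tgene\tmodel\torigin\tphase\treportable\tflags"
    lines = [f"# patient: {report.patient_id}", f"# outcome: {report.outcome}",
             f"# phases run: {','.join(report.phases_run)}", header]
    lines += _tsv_rows("diagnostic", report.diagnostic_calls)
    lines += _tsv_rows("review_candidate", report.review_candidates)
    lines += _tsv_rows("secondary_finding", report.secondary_findings)
    for e in report.het_shortlist:
        lines.append(
            "\t".join(
                ["het_shortlist", e.variant.key, e.gene, "single_het", ".", "I",
                 "no", e.reason]
            )
        )
    lines += _tsv_rows("research_only", report.research_candidates)
    tsv_path.write_text("\n".join(lines) + "\n")
    paths = {"json": json_path, "tsv": tsv_path}
    if report.research_candidates:
        share = out / f"{report.patient_id}.phase3_candidates.tsv"
        share.write_text(
            "\n".join([header] + _tsv_rows("research_only", report.research_candidates))
            + "\n"
        )
        paths["phase3"] = share
    return paths
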