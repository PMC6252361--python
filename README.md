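# triotriage

Phased trio whole-genome variant prioritization for rare-disease
diagnosis, with a synthetic trio-cohort simulator for end-to-end
testing.

`triotriage` is aimed at diagnostic and research groups running rapid
trio WGS for children with suspected monogenic disease. Given an
annotated multi-sample VCF (proband + both biological parents), a
pedigree, the patient's HPO phenotype terms and a set of gene lists, it
reproduces the variant-interpretation stage of a tiered rapid-WGS
workflow: population-frequency and consequence filtering, trio
inheritance-model classification, escalating gene-panel scopes, a
consented secondary-findings scan, and deterministic tiered reports.
Wet-lab steps, read mapping/variant calling, annotation computation and
clinical (ACMG) pathogenicity scoring are out of scope — annotations are
consumed, and the classification judgement stays with the reviewing
clinicians.

## The model

Candidate variants must be **rare**, **deleterious** and fit a **trio
inheritance model**:

- *Standard frequency rule* — allele frequency ≤ 0.5% in each of three
  population databases (1000 Genomes, ExAC, EVS) that report the
  variant; unreported means unobserved, which passes.
- *Permissive recessive rule* — for recessive and X-linked candidates
  with a high carrier frequency: AF ≤ 10% **and** no homozygotes (nor
  hemizygotes, on chrX) reported in ExAC. Both thresholds inclusive.
- *Deleterious consequence* — deleterious missense SNVs, frameshifts,
  start/stop codon changes, and splice-region variants within ±7 bp of
  an exon boundary.
- *Inheritance models* — de novo (proband het, both parents reference);
  autosomal recessive homozygous (proband hom-alt, both parents
  carriers); autosomal recessive compound heterozygous (two hets in one
  gene, one maternal and one paternal, phased through the trio);
  X-linked (hemizygous male proband, carrier or reference mother). Lone
  deleterious hets in recessive-inheritance panel genes are shortlisted
  for manual inspection of the second allele.

Scopes escalate in three phases: **I** a bespoke per-patient panel (HPO
term → gene map ∪ clinician gene lists); **II** a broad
disease-gene scope (DDG2P-like ∪ OMIM-morbid-like lists), during which
an opt-in scan of a medically actionable (ACMG-style) gene list runs;
**III** genome-wide, research-only. A phase's candidates go to review; a
candidate judged to fully explain the phenotype stops the analysis,
otherwise the scope widens.

## Worked example

Generate the 24-trio synthetic benchmark cohort and triage one trio:

```bash
triotriage simulate-fixture --seed 17 --out cohort/
triotriage triage \
    --vcf cohort/trios/trio_07/trio_07.vcf \
    --ped cohort/trios/trio_07/trio_07.ped \
    --hpo cohort/trios/trio_07/trio_07.hpo.txt \
    --hpo-map cohort/resources/hpo_map.tsv \
    --clinician-genes cohort/trios/trio_07/trio_07.clinician_genes.txt \
    --ddg2p cohort/resources/ddg2p.tsv \
    --omim-morbid cohort/resources/omim_morbid.tsv \
    --acmg-genes cohort/resources/acmg_genes.tsv \
    --gene-moi cohort/resources/gene_moi.tsv \
    --config cohort/resources/config.yaml \
    --opt-in-secondary --out report/
```

which prints:

```
phase I: total=2001, in_scope=84, deleterious=15, frequency_ok=1, calls=1
outcome: provisional_finding
report: report/trio_07_P.report.json
```

Of the 2,001 decomposed variants, 84 fall in the bespoke phase I panel,
15 of those have a deleterious consequence, and exactly one survives the
frequency rules — the planted *PIGT* homozygote, called under the
autosomal-recessive model. Because it matches a curated pathogenic
assertion it is reportable, the analysis stops after phase I, and the
trio's report carries a provisional finding:

```
diagnostic  chr7:9461033:A:G  PIGT  ar_homozygous  unresolved  I  yes  .
```

The same workflow is available as a library (`triotriage.triage`,
`triotriage.triage_cohort_dir`), which is how the test suite drives it.

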