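# Methods

## Scope and model

`triotriage` implements the variant-interpretation stage of a rapid
trio-WGS diagnostic workflow. Its inputs are downstream of sequencing:
a jointly called, annotator-decorated multi-sample VCF, a pedigree, a
patient phenotype profile (HPO terms), and gene lists. Its outputs are
tiered, deterministic triage reports. The package deliberately does not
map reads, call or annotate variants, detect structural variants, or
score pathogenicity — those are upstream tools and human review,
respectively. The lone-het shortlist exists precisely because the
second allele of a recessive gene may be a structural variant that only
manual inspection of the region will reveal.

A variant is a candidate when it is simultaneously (i) in the active
gene scope, (ii) predicted deleterious, (iii) sufficiently rare, and
(iv) consistent with one of four trio inheritance models. Each
predicate's outcome is appended to the variant's filter trail so every
exclusion is auditable in the report.

### Frequency rules

Two inclusive thresholds on the per-database allele frequencies
(1000 Genomes, ExAC, EVS):

- standard: every *reported* AF ≤ `af_standard_max` (default 0.005);
- permissive (recessive/X-linked searches only): every reported AF ≤
  `af_permissive_max` (default 0.10) **and** ExAC homozygote count 0 or
  unreported (**and** hemizygote count 0/unreported on non-PAR chrX).

The standard rule is conjunctive over databases: a variant common in
any one database is a poor Mendelian candidate, whereas thresholding
the minimum would pass common alleles simply because one database
lacks them. An unreported frequency is "absent", never 0 — but absent
passes both rules, since novel variants are exactly the ones a
rare-disease search must keep. De novo candidates always use the
standard rule; a 10%-frequency allele cannot plausibly be a recurrent
de novo event, and the permissive rule's justification (carrier
frequency) is specific to recessive inheritance. The permissive rule is
applied identically in all three phases; nothing about the rule is
panel-specific, and restricting it to phase I would make phase
escalation change the meaning of "rare".

### Consequence rule

Deleterious = {deleterious missense SNV, frameshift, start-lost,
stop-gained, stop-lost} ∪ {splice-region within ±`splice_window_bp`
(default 7) of an exon boundary}. "Deleterious missense" is a flag the
upstream annotator supplies; taking all SNVs would defeat the purpose
of a deleteriousness filter, so plain missense without the flag maps to
`other`. `splice_distance` is defined as distance to the nearest exon
boundary — a declared convention; annotators measuring from the splice
dinucleotide differ by ≤ 2 bp. A splice-region call without a distance
annotation is conservatively non-deleterious and logged.

### Inheritance models

With genotype states {hom_ref, het, hom_alt, hemi_alt, missing} per
sample:

- **de novo**: proband het, both parents hom_ref. A hom_alt proband
  with reference parents would need two independent mutations and is
  flagged `mendelian_inconsistent` instead — overwhelmingly a
  genotyping artefact.
- **AR homozygous**: proband hom_alt with both parents het. A hom_alt
  proband with a hom_ref parent is inconsistent, not a call;
  uniparental disomy is not modelled.
- **AR compound het**: within one gene, one proband het inherited from
  the mother (mother carries, father hom_ref) paired with one from the
  father. Trio genotypes phase the pair; variants het in both parents
  are unphaseable and excluded from pairs unless
  `allow_unresolved_phase` is set (then a pair is kept whenever cis
  cannot be demonstrated).
- **X-linked** (non-PAR chrX): male proband hemi_alt with a
  non-carrier father; a het mother gives a maternal call, a hom_ref
  mother a call flagged `de_novo_on_x`. Affected females on X are
  handled by the AR operations with a hemizygous-alt father as the
  transmitting state — a declared convention splitting one biological
  continuum across two code paths. PAR1/PAR2 intervals are
  configuration (GRCh38 defaults; the toy genome supplies its own) and
  are treated as autosomal.

Missing parental genotypes make a variant *untestable* for a model —
never a silent pass — because resolving inheritance is the entire point
of sequencing the trio. A genotype-quality gate (GQ ≥ 20 and depth ≥ 8
in all three samples, configurable) is applied at read time; upstream
pipelines vary here, and de novo calling on low-confidence genotypes is
noise.

### Phases, escalation, reporting

Phase I scope is the union of HPO-mapped genes and clinician-supplied
lists; phase II the union of a developmental-disorder list and an
OMIM-morbid-like list; phase III genome-wide (variants in no annotated
gene included). Panels are independent unions — phase I is *not* a
subset of phase II, and the pipeline never assumes nesting. The HPO→
gene map is a supplied table rather than a live resource query so runs
are reproducible offline, and a term contributes only its own mapped
genes (no ontology propagation) unless an expansion is provided in the
map itself. Gene identity is by case-insensitive symbol; alias
resolution is a known limitation.

Escalation stops when a candidate is judged to fully explain the
phenotype and otherwise widens the scope; with zero candidates the
decision defaults to "unexplained". That judgement is clinical, so the
pipeline takes it as an input (`--mdt-decision`); in `auto` mode a
curated-pathogenic candidate stands in for "fully explained", which is
what makes the workflow testable end-to-end. For the same reason the
report's `reportable` flag is driven by the curated `known_pathogenic`
annotation while `classification` stays empty for the reviewing team.
Phase III output is research-only and never changes the diagnostic
outcome. The secondary-findings scan runs at phase II breadth, only
under explicit opt-in, over a supplied actionable-gene list whose
per-gene mode of inheritance must match the model call (recessive →
homozygous/compound het, dominant → de novo, X-linked → hemizygous);
variants already reported as primary candidates are excluded.

Ranking is a deterministic total order: curated-pathogenic first, then
phase, then model priority (de novo, homozygous, compound het,
X-linked), then ascending maximum reported AF, then genomic
coordinates.

## Synthetic cohorts

The generator emulates what the filters consume, not how sequencing
produces it: no read-level error model, no coverage model, no
structural variants. The toy genome is four contigs (chr1, chr2, chr7,
chrX with a 100 kb pseudoautosomal head) and the default background is
2,000 variants per trio — enough to exercise every filter stratum while
keeping a full 24-trio run in seconds; genome-scale variant counts
(millions per trio) are deliberately not reproduced. Consequently,
passing tests demonstrate the correctness of the filtering logic, not
calibrated performance on real genomes, where annotation errors,
genotyping noise, segmental duplications and incomplete gene maps
dominate.

Background variants are built to fail at least one filter each, by
stratum: (a) common alleles — all three AFs in [0.02, 0.45] with ≥ 1
ExAC homozygote, closing both frequency paths; (b) rare benign —
synonymous/intronic/intergenic consequences or splice-region beyond the
±7 bp window; (c) rare deleterious lone hets — inherited from exactly
one carrier parent, each in a gene unique to that variant (so no trans
partner can arise) and outside every panel. Parental genotypes are
drawn per stratum and proband alleles are *transmitted* from them,
making every background variant Mendelian-consistent by construction;
stratum (c) is restricted to autosomes and the PAR so male X haploidy
is never violated. Planted variants get the designated model's genotype
configuration, a deleterious consequence, rare (or, in the designated
permissive stratum, 5–10% with zero ExAC homozygotes) frequencies, and
the curated-pathogenic flag when the design says so. AFs are sampled
independently per database within a stratum — the real joint
distribution across databases is not modelled.

The benchmark cohort mirrors a 24-trio study template: 10 trios with a
curated-pathogenic phase I plant (4 de novo, 3 compound het — one in
the permissive stratum — 3 homozygous), one trio whose only plant is a
homozygous variant in an actionable-list gene (a secondary finding, so
that trio still ends "no primary findings"), and 13 purely background
trios. All randomness flows from a single integer seed through
per-trio `numpy` `SeedSequence` streams, and the VCF/report writers use
fixed formatting, so identical seeds give byte-identical output. Truth
lives only in `manifest.json`; the VCFs carry nothing an annotator
would not supply.

## Numerical and I/O choices

- Coordinates are 1-based VCF convention throughout; no half-open
  conversion.
- Multiallelic records are decomposed one output per alt allele; other
  alts are recoded as reference for that record and the outputs flagged
  `from_multiallelic`. Symbolic alleles (`<DEL>`, breakends) pass
  through flagged `symbolic` and are excluded from filtering.
- Contig labels are normalized to the `chr`-prefixed dialect; unknown
  contigs are preserved verbatim and flagged.
- Haploid calls decode to hemi_alt/hom_ref; a hemizygous-reference male
  is represented as hom_ref, so genotype states round-trip even though
  ploidy notation does not.
- Annotation INFO keys are config-mapped (`annotation_keys` section),
  not hard-coded, since annotators name these fields differently.
- VCF parsing uses `cyvcf2`; writing is plain-text VCF 4.2 with `%.6g`
  float formatting, chosen so that byte-level determinism is a property
  of the values alone.
- Ties everywhere break on genomic coordinates (canonical contig order,
  then position, then alt allele).

## Test design

Filter predicates and inheritance calls are checked against
independent brute-force re-implementations (direct truth tables and
pair enumeration, in `tests/oracle.py`) — exhaustively for all 125 trio
genotype configurations, and variant-for-variant on randomized
synthetic trios. Generator cross-checks assert that exactly the planted
variants survive a genome-wide evaluation and that background-only
trios yield zero calls in every phase. Property tests cover threshold
monotonicity, the nesting of the standard rule inside the permissive
rule, compound-het order invariance and the consent gate. The
acceptance suite runs the full 24-trio benchmark (100 random trios for
the oracle-equivalence check, 50 small cohorts for the consent gate)
at the sizes above.
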