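# Methods

## Scope and data model

`acmgsf` analyses secondary findings in the 59-gene ACMG SF v2.0 panel
for a population cohort. Inputs are five surfaces: diploid genotypes
(VCF 4.2), a per-variant annotation table (TSV keyed by
chrom/pos/ref/alt carrying gene, consequence term, impact class, CADD,
GERP and eight database-membership booleans), a sample table with one of
six subpopulation labels (GAR, PAR, WEP, SAS, AFR, ADM), a pairwise
kinship table (φ ∈ [0, 0.5]; unlisted pairs are unrelated), and a
phenotype table (ECG class, chest pain, parental heart-disease history,
self-reported conditions). Annotation deliberately lives beside the VCF
rather than in INFO fields so the cascade is testable without an
annotation toolchain; CADD, GERP and consequence calls are consumed as
inputs, never computed.

Coordinates are half-open 0-based internally; BED is read as-is and
VCF/TSV positions are converted from 1-based at the boundary.
Multiallelic records are split so every internal record has exactly one
alt allele; a genotype with any missing allele is missing, and missing
genotypes are excluded from allele-number denominators (AN counts
non-missing alleles — the standard cohort convention).

## Panel

The shipped panel maps each of the 59 genes to exactly one of five
disease categories (cardiovascular, cancers, familial
hypercholesteremia, malignant hyperthermia, others), following the ACMG
SF v2.0 phenotype groupings; GLA, ATP7B and OTC sit in *others*, the
aortopathy and cardiomyopathy/arrhythmia genes in *cardiovascular*. The
mapping is data (YAML), not code, so an alternative assignment of
ambiguous genes is a config edit. The companion BED of coding intervals
is a synthetic stand-in (true chromosomes, constructed start/end) —
adequate for interval-membership logic and simulation, and replaceable
with a real exon BED without code changes.

## Filter cascade

Seven predicates, applied in the narrative order of the analysis they
implement: panel region → database novelty → deleteriousness → cohort
MAF → singleton removal → unrelated carriers → impact/effect.
Thresholds (all configurable through `CascadeParams`):

| parameter | default | meaning |
|---|---|---|
| `cadd_min` | 20.0 | phred-scaled CADD, inclusive |
| `gerp_min` | 3.0 | GERP rejected-substitution score, inclusive |
| `maf_max` | 0.001 | folded MAF min(AC, AN−AC)/AN, strict `<` |
| `min_ac` | 2 | cohort alt allele count floor |
| `phi_threshold` | 0.0884 | kinship above which a pair is "related" |

Numerical conventions follow a literal reading of the criteria:
inclusive `≥` on scores, strict `<` on MAF, folding on the minor allele.
"Unrelated" is never defined by the source analysis; the default φ ≤
0.0884 is the conventional third-degree cut-off of the KING threshold
family. The unrelated-carrier predicate asks whether the relatedness
graph restricted to carriers (edge iff φ > threshold) has an independent
set of size ≥ 2, which holds iff that graph is not complete; a
`max_unrelated_set` helper additionally reports a maximum unrelated set
(exact via complement-clique search for ≤ 20 carriers, deterministic
lowest-degree-first greedy above). Carriers absent from the kinship
table are treated as unrelated to everyone, with a logged warning. A
variant whose genotypes are all missing (AN = 0) is dropped at the
frequency stage with a warning rather than dividing by zero. Unknown
consequence terms are kept (impact permitting) with a warning, never
silently discarded.

Because every stage is a pure predicate, the final set equals the
intersection of the per-stage predicate sets; `run_cascade` asserts this
internally, and the funnel therefore depends on stage order only through
its intermediate counts. The funnel also reports *sole-failure*
attribution (variants failing exactly one predicate), which is the
honest notion of marginal stage importance.

## Frequency summaries

Genotype-positive frequencies are reported per subpopulation ×
disease category with an overall row. Two numerator conventions exist
because "participants frequency" and "allele frequency" name the same
table in the source material: `allele` mode (default) counts alternate
alleles of any surviving variant over twice the subpopulation size —
a participant carrying two different survivors counts twice; and
`participant` mode counts distinct carriers over the subpopulation size
— such a participant counts once. Exact inversion of the published
per-subpopulation cells is consistent with allele counts over 2n, hence
the default. Stored values are full precision; percent columns round
only for display.

## Association and selection

The cardiovascular rubric: CVD-positive iff ECG abnormal, or ECG
borderline together with chest pain or a self-reported condition from a
configurable term list (default: angina, heart attack, heart failure,
arrhythmia). Records with missing ECG are unclassifiable and excluded
from both rows of the 2×2 table. The comparator defaults to all
genotype-negative cohort members with usable phenotype; an explicit
reference set can be supplied.

The two-sided Fisher exact p sums hypergeometric point probabilities
(computed via log-gamma) of all tables with the observed margins whose
probability is ≤ the observed table's, with relative tolerance 1e-9 on
the comparison — the point-probability convention of mainstream
statistical software (the doubling convention could be added alongside).
Degenerate margins return p = 1 by convention, logged. Odds ratios are
the cross-product (a·d)/(b·c); the Haldane–Anscombe +0.5 correction is
auto-applied iff a cell is zero, and the result records whether it was.
An exhaustive test checks agreement with exact rational-arithmetic
enumeration for every 2×2 table with N ≤ 40, and `scipy.stats.
fisher_exact` serves as an independent cross-check on random tables.

Selection requires p_CVD < α (default 0.05, two-sided), ≥ 2 CVD-positive
carriers, and ≥ 2 carriers with parental heart-disease history. The
parental-history threshold is a design choice: the source criteria
require "positive parent history" without a count, and both published
evidence profiles (4/11 CVD-positive with 5 parental reports;
5/9 with 6) clear a floor of two. Significance is gated on the
CVD-rubric association only — one of the published variants was selected
despite a non-significant parental-history test (p = 0.3197), so
parental history acts as supporting evidence. Carriers of known
pathogenic variants in cardiovascular-category genes are removed from
the cohort before association; list entries with off-panel genes warn
and are ignored.

## Synthetic cohort generator

The generator targets the analysis' decision structure, not
population-genetic realism: no LD, no site-frequency spectrum, no
admixture model, planted carriers are heterozygous, and genotypes have
no missingness by default. Passing tests on synthetic bundles therefore
demonstrates correctness of the filtering/association logic under the
stated assumptions, not performance on real sequencing artefacts
(batch effects, genotyping error, population stratification).

Defaults and their provenance:

- `n_samples = 1200`, subpopulation weights proportional to the modelled
  cohort's published sizes (1180/92/2311/1052/1372/38 over 6045). The
  scaled size is the smallest round cohort at which an allele count of 2
  both clears the singleton floor and stays under MAF < 0.001
  (feasibility requires n > 1000); smaller cohorts raise
  `InfeasibleConfigError` rather than silently bending a threshold.
- `n_variants = 90`, ten per fate across the nine fates
  (`fails_panel` … `fails_impact_effect`, `survives_all`), apportioned
  by largest remainder when the mix is changed.
- 60 families of size 2–3 with within-family φ drawn from {0.25, 0.125};
  both values exceed the unrelated threshold, so a within-family carrier
  pair is related by construction. Carriers for all other fates are
  drawn one-per-independent-unit (family or singleton), guaranteeing
  pairwise kinship 0.
- Phenotype model: abnormal ECG 5%, borderline 15%, chest pain 10%,
  self-reported condition 3%, parental history 15% — free parameters of
  the emulation chosen to put the background rubric prevalence near 7%,
  a plausible adult figure. Carrier effects default to the published
  anchors (odds ratio 6.6 on the rubric, 4.8 on parental history).
  Carrier status is drawn first as Bernoulli with the odds-shifted
  probability, then a component configuration consistent with that
  status is drawn by rejection from the background distribution, so the
  configured odds ratio holds exactly in expectation. `math.inf` acts as
  a full-penetrance switch.

One fate is structurally entangled: an allele count of 1 implies a
single carrier, so `fails_singleton` plants necessarily also fail the
unrelated-carriers predicate. The truth table's fate names the first
failing stage in canonical order, and the fate-faithfulness test asserts
exactly this pattern.

Determinism: a single `SeedSequence` seed spawns one child generator per
surface, and all writers are deterministic, so bundles are
byte-identical across runs of the same config.

The *demo* configuration (`demo_config`) used by `run-all --demo` and
the acceptance script sets both carrier odds ratios to the
full-penetrance switch. This makes end-to-end survivor recovery a
deterministic property of the decision structure for any seed; the
stochastic behaviour at the 6.6 anchor is measured separately by the
calibration studies (type-I error at planted odds ratio 1; mean log-OR
recovery at planted 6.6 over repeated cohorts of n = 2000 with 40
carriers — the Haldane-corrected estimator carries a small-sample bias
measured at well under one Monte-Carlo standard error of the mean under
these conditions).

## Problem sizes used in verification

Checks run at desk scale: 100 random cohorts (≤ 500 variants, 20–50
samples) for cascade-vs-brute-force agreement; all 135 751 2×2 tables
with N ≤ 40 for the exact test; 1000 simulated cohorts of n = 1200 for
type-I error; 200 cohorts of n = 2000 for effect recovery. These sizes
make the whole suite run in well under a minute while keeping the
binomial/Monte-Carlo error bounds tight enough to be meaningful.

## Known limitations

- The cascade consumes annotation as given; disagreement between
  annotation sources (consequence terms, impact classes) is out of
  scope, as is any liftover or normalization beyond multiallelic
  splitting.
- Database membership is boolean — ClinVar assertion levels and allele
  matching subtleties are not modelled.
- No multiple-testing correction is applied across variants (matching
  the analysis modelled), and confidence intervals for odds ratios are
  not reported.
- The shipped interval BED is a labelled synthetic stand-in; positional
  filtering against real transcripts requires supplying a real coding
  BED.
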