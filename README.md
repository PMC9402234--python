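# acmgsf

Novel-variant prioritization and genotype–phenotype association for the
ACMG secondary-findings gene panel in population cohorts.

## The problem

Population sequencing programmes routinely discover variants in the 59
ACMG SF v2.0 genes — genes where pathogenic variants are highly
penetrant and medically actionable — that appear in no public database.
Deciding which of these previously unreported variants deserve clinical
attention and functional follow-up requires a reproducible chain of
filters and statistics rather than ad-hoc spreadsheet work. `acmgsf`
implements that chain for cohorts with diploid genotypes (VCF), side
annotation tables, subpopulation labels, pairwise kinship, and
cardiovascular phenotype records:

1. **Filter cascade.** Keep variants that fall in the panel's coding
   intervals; are absent from dbSNP, gnomAD, TOPMed, 1000 Genomes, ExAC,
   GME Variome, HGMD and ClinVar; have CADD ≥ 20 and GERP ≥ 3; have
   folded cohort minor-allele frequency min(AC, AN−AC)/AN < 0.001; have
   allele count ≥ 2; are carried by at least two participants with
   pairwise kinship φ ≤ 0.0884; and are MODERATE-impact,
   non-intronic, non-loss-of-function consequences. Each stage is a pure
   predicate, so the surviving set is the intersection of the predicates
   and is invariant to stage order; the funnel reports per-stage and
   sole-failure drop counts.
2. **Frequency summaries.** Genotype-positive allele/participant
   frequencies per subpopulation (GAR, PAR, WEP, SAS, AFR, ADM) crossed
   with the five disease categories, and the disease-category
   distribution of survivors.
3. **Phenotype association.** A participant is CVD-positive iff their
   ECG is abnormal, or borderline together with chest pain or a
   self-reported cardiovascular condition. Carrier status × phenotype
   forms a 2×2 table tested with a two-sided Fisher exact test
   (point-probability convention), with Haldane–Anscombe-corrected odds
   ratios when a cell is zero.
4. **Selection.** A variant is nominated for functional follow-up when
   its CVD association has p < α (default 0.05), at least two carriers
   are CVD-positive, and at least two carriers report parental
   heart-disease history; carriers of known pathogenic cardiovascular
   variants are excluded beforehand. Every criterion's value is recorded
   per variant so near-misses are auditable.

Because real programme data of this kind is access-restricted, the
package ships a seeded synthetic-cohort generator
(`acmgsf.simulate`) that emits the full input bundle — VCF plus
annotation/sample/kinship/phenotype TSVs — with a ground-truth table
stating which cascade stage each planted variant should fail and which
planted carriers receive a phenotype effect of configurable odds ratio.

## Worked example

```bash
acmgsf run-all --demo --seed 1 --out-dir demo_run
```

simulates a 1200-sample cohort (subpopulation weights proportional to
the 6045-participant cohort the analysis models) with ten variants
planted per cascade fate, then runs the full pipeline. It prints:

```json
{
  "samples": 1200,
  "variants_ingested": 90,
  "variants_surviving": 10,
  "genotype_positive_participants": 20,
  "genotype_positive_rate_pct_x1000": 1667,
  "samples_excluded_known_pathogenic": 0,
  "variants_selected": 10
}
```

Ninety annotated variants enter the cascade; each stage removes exactly
the ten variants planted to fail it (`demo_run/funnel.tsv`):

```text
stage	surviving	dropped	sole_failure
input	90	0	0
panel	80	10	10
novelty	70	10	10
deleterious	50	20	20
frequency	40	10	10
singleton	30	10	0
unrelated	20	10	10
impact_effect	10	10	10
```

(The deleterious stage drops 20 because low-CADD and low-GERP fates both
fail it; singleton failures have zero sole-failure attribution because a
single-allele-count variant necessarily also lacks two unrelated
carriers.) The ten survivors are carried by 20 distinct participants —
a genotype-positive rate of 1.7% — and all ten are selected
(`demo_run/selection.tsv`), e.g.:

```text
chrom  pos      ref alt gene  n_carriers p_cvd    odds_ratio_cvd n_cvd_positive_carriers
1      5400983  T   A   LMNA  2          0.00745  53.5           2
```

The demo plants survivors at full penetrance so this recovery is
deterministic; statistical behaviour at realistic effect sizes is
covered by the calibration checks below.

Library use mirrors the CLI: `simulate_cohort` → `read_cohort` /
`attach_annotations` → `run_cascade` → `genotype_positive_frequency` /
`associate_variant` → `select_candidates`, or `run_all(PipelineConfig(...))`
for the whole chain with a reproducibility manifest.

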