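"""Cohort and subpopulation frequency summaries.

Summaries over the cascade survivors: per-subpopulation genotype-positive
frequencies stratified by disease category, the disease-category
distribution of surviving variants, and the overall genotype-positive
participant rate. All stored values are full precision; rounding is
applied only for display columns.

Two numerator conventions are supported. In ``allele`` mode (default)
the numerator is the number of alternate alleles of any surviving
variant in a subpopulation and the denominator is twice the
subpopulation size; a participant carrying two different surviving
variants contributes twice. In ``participant`` mode the numerator is the
number of distinct carriers and the denominator the subpopulation size;
such a participant counts once.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort_io import SUBPOPULATIONS, GenotypeMatrix, SampleRecord, VariantRecord
from .panel import GenePanel

CATEGORY_ORDER = (
    "cardiovascular",
    "cancers",
    "familial_hypercholesteremia",
    "malignant_hyperthermia",
    "others",
)

OVERALL_ROW = "acmg_genotype_positive"


def allele_frequency(ac: int, an: int) -> float:
    """Plain allele frequency AC/AN at full precision."""
    if an <= 0:
        raise ValueError(f"allele number must be positive, got {an}")
    if not 0 <= ac <= an:
        raise ValueError(f"allele count {ac} outside [0, {an}]")
    return ac / an


def genotype_positive_rate(carriers: int, cohort_n: int) -> float:
    """Percent of the cohort carrying >= 1 candidate allele (full precision)."""
    if cohort_n <= 0:
        raise ValueError(f"cohort size must be positive, got {cohort_n}")
    if carriers > cohort_n:
        raise ValueError(f"carriers {carriers} exceed cohort size {cohort_n}")
    return 100.0 * carriers / cohort_n


@dataclass
class SubpopSummary:
    """Frequencies, numerators and denominators per category x subpopulation.

    Rows are the overall genotype-positive row followed by the five
    disease categories; columns are the six subpopulations plus a
    ``cohort`` column aggregating all samples.
    """

    mode: str
    frequencies: pd.DataFrame
    numerators: pd.DataFrame
    denominators: pd.DataFrame


def genotype_positive_frequency(
    surviving_variants: list[VariantRecord],
    genotypes: GenotypeMatrix,
    samples: list[SampleRecord],
    panel: GenePanel,
    mode: str = "allele",
) -> SubpopSummary:
    """Subpopulation x disease-category genotype-positive frequencies.

    An empty subpopulation, or one with no carriers, reports frequency 0
    with its denominator intact.
    """
    if mode not in ("allele", "participant"):
        raise ValueError(f"mode must be 'allele' or 'participant', got {mode!r}")

    subpop_of = {s.id: s.subpopulation for s in samples}
    n_subpop = {p: sum(1 for s in samples if s.subpopulation == p) for p in SUBPOPULATIONS}
    cols = [*SUBPOPULATIONS, "cohort"]
    rows = [OVERALL_ROW, *CATEGORY_ORDER]

    by_category: dict[str, list[VariantRecord]] = {c: [] for c in CATEGORY_ORDER}
    for v in surviving_variants:
        by_category[panel.category_of(v.gene)].append(v)
    groups = {OVERALL_ROW: list(surviving_variants), **by_category}

    num = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    den = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    factor = 2 if mode == "allele" else 1
    for row in rows:
        for p in SUBPOPULATIONS:
            den.loc[row, p] = factor * n_subpop[p]
        den.loc[row, "cohort"] = factor * len(samples)

    for row, variants in groups.items():
        if mode == "allele":
            for v in variants:
                for s, d in zip(genotypes.samples, genotypes.dosages(v.key)):
                    if d > 0:
                        num.loc[row, subpop_of[s]] += int(d)
        else:
            carriers: set[str] = set()
            for v in variants:
                carriers.update(genotypes.carriers(v.key))
            for s in carriers:
                num.loc[row, subpop_of[s]] += 1
        num.loc[row, "cohort"] = int(num.loc[row, list(SUBPOPULATIONS)].sum())

    freq = pd.DataFrame(0.0, index=rows, columns=cols)
    for row in rows:
        for col in cols:
            d = int(den.loc[row, col])
            freq.loc[row, col] = 0.0 if d == 0 else num.loc[row, col] / d
    return SubpopSummary(mode=mode, frequencies=freq, numerators=num, denominators=den)


def category_distribution(
    surviving_variants: list[VariantRecord], panel: GenePanel
) -> pd.DataFrame:
    """Variant and distinct-gene counts per disease category.

    ``percent`` is full precision; ``percent_display`` is rounded to the
    nearest integer for reporting. Percents are computed from counts, so
    the display column can sum to 100 +/- rounding.
    """
    total = len(surviving_variants)
    rows = []
    for category in CATEGORY_ORDER:
        vs = [v for v in surviving_variants if panel.category_of(v.gene) == category]
        pct = 100.0 * len(vs) / total if total else 0.0
        rows.append(
            {
                "category": category,
                "n_variants": len(vs),
                "n_genes": len({v.gene for v in vs}),
                "percent": pct,
                "percent_display": int(round(pct)),
            }
        )
    return pd.DataFrame(rows).set_index("category")
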