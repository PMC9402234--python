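"""Genotype-phenotype association with Fisher's exact test.

The cardiovascular phenotype rubric classifies a participant as
CVD-positive iff their ECG report is abnormal, or borderline together
with self-reported cardiovascular symptoms (chest pain or a condition
from a configurable term list). Carrier status (dosage >= 1) against the
rubric, or against parental heart-disease history, forms a 2x2 table
tested with a two-sided Fisher exact test; effect size is the odds
ratio, Haldane-Anscombe corrected when a cell is zero.

The two-sided p-value follows the point-probability convention of
mainstream statistical software: the sum of hypergeometric probabilities
of all tables with the observed margins whose point probability does not
exceed that of the observed table (a relative tolerance of 1e-9 guards
the <= comparison against floating-point noise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import exp, inf, lgamma

from .cohort_io import GenotypeMatrix, PhenotypeRecord, VariantKey
from .errors import ZeroCarrierError

log = logging.getLogger(__name__)

#: self-reported condition terms counting as cardiovascular symptoms
DEFAULT_CVD_TERMS = frozenset({"angina", "heart attack", "heart failure", "arrhythmia"})

COLUMN_DEFS = ("cvd_rubric", "parental_history")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows carrier/non-carrier, columns phenotype +/-."""

    a: int  # carrier, phenotype-positive
    b: int  # carrier, phenotype-negative
    c: int  # non-carrier, phenotype-positive
    d: int  # non-carrier, phenotype-negative

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_carriers(self) -> int:
        return self.a + self.b


@dataclass(frozen=True)
class AssociationResult:
    table: ContingencyTable
    p_two_sided: float
    odds_ratio: float
    haldane_applied: bool
    phenotype_definition: str


def classify_cvd_phenotype(
    record: PhenotypeRecord, cvd_terms: frozenset[str] = DEFAULT_CVD_TERMS
) -> bool | None:
    """Apply the cardiovascular rubric; ``None`` if ECG is missing.

    Positive iff ECG abnormal, or ECG borderline with chest pain or any
    self-reported condition from ``cvd_terms``.
    """
    if record.ecg == "missing":
        return None
    if record.ecg == "abnormal":
        return True
    if record.ecg == "borderline":
        return record.chest_pain or bool(record.self_reported_conditions & cvd_terms)
    return False


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Degenerate margins (an empty row or column) carry no information and
    return p = 1.0 by convention.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1, c2, n = a + b, c + d, a + c, b + d, table.n
    if min(r1, r2, c1, c2) == 0:
        log.info("degenerate margins in %s; p = 1.0 by convention", table)
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    log_denom = _log_comb(n, c1)
    pmf = [
        exp(_log_comb(r1, x) + _log_comb(r2, c1 - x) - log_denom) for x in range(lo, hi + 1)
    ]
    obs = pmf[a - lo]
    p = sum(px for px in pmf if px <= obs * (1.0 + 1e-9))
    return min(p, 1.0)


def odds_ratio(table: ContingencyTable, correction: str = "auto") -> float:
    """Cross-product odds ratio (a*d)/(b*c).

    ``correction``: ``"none"`` (raw; infinite/zero with empty cells),
    ``"haldane"`` (add 0.5 to every cell), or ``"auto"`` (Haldane iff any
    cell is zero).
    """
    if correction not in ("none", "haldane", "auto"):
        raise ValueError(f"unknown correction {correction!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    if correction == "haldane" or (correction == "auto" and 0 in (a, b, c, d)):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        return inf if a * d > 0 else 1.0
    return (a * d) / (b * c)


def build_contingency(
    variant: VariantKey,
    genotypes: GenotypeMatrix,
    phenotypes: list[PhenotypeRecord],
    column_def: str = "cvd_rubric",
    cvd_terms: frozenset[str] = DEFAULT_CVD_TERMS,
    comparator: set[str] | None = None,
) -> ContingencyTable:
    """Carrier-status x phenotype 2x2 table for one variant.

    Rows split on dosage >= 1. Columns follow ``column_def``: the CVD
    rubric or parental heart-disease history. Samples with an
    unclassifiable phenotype (missing ECG under the rubric) are excluded
    from both rows. The comparator row defaults to all genotype-negative
    cohort members with usable phenotype; pass ``comparator`` to restrict
    to an explicit reference set.
    """
    if column_def not in COLUMN_DEFS:
        raise ValueError(f"column_def must be one of {COLUMN_DEFS}, got {column_def!r}")
    pheno_of = {p.sample_id: p for p in phenotypes}
    carriers = set(genotypes.carriers(variant))
    if not carriers:
        raise ZeroCarrierError(f"variant {variant} has no carriers; association undefined")

    a = b = c = d = 0
    n_excluded = 0
    for s, dosage in zip(genotypes.samples, genotypes.dosages(variant)):
        is_carrier = dosage >= 1
        if not is_carrier and comparator is not None and s not in comparator:
            continue
        rec = pheno_of.get(s)
        if rec is None:
            n_excluded += 1
            continue
        if column_def == "cvd_rubric":
            status = classify_cvd_phenotype(rec, cvd_terms)
        else:
            status = rec.parental_heart_disease
        if status is None:
            n_excluded += 1
            continue
        if is_carrier:
            a, b = (a + 1, b) if status else (a, b + 1)
        else:
            c, d = (c + 1, d) if status else (c, d + 1)
    if n_excluded:
        log.info("%s/%s: %d samples excluded for missing phenotype", variant, column_def, n_excluded)
    return ContingencyTable(a, b, c, d)


def associate_variant(
    variant: VariantKey,
    genotypes: GenotypeMatrix,
    phenotypes: list[PhenotypeRecord],
    column_def: str = "cvd_rubric",
    cvd_terms: frozenset[str] = DEFAULT_CVD_TERMS,
    comparator: set[str] | None = None,
) -> AssociationResult:
    """Contingency table + exact test + odds ratio for one variant."""
    table = build_contingency(variant, genotypes, phenotypes, column_def, cvd_terms, comparator)
    haldane = 0 in (table.a, table.b, table.c, table.d)
    return AssociationResult(
        table=table,
        p_two_sided=fisher_exact_two_sided(table),
        odds_ratio=odds_ratio(table, "auto"),
        haldane_applied=haldane,
        phenotype_definition=column_def,
    )
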