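"""Segregation criteria nominating variants for functional follow-up.

A surviving variant is nominated when its carrier genotype segregates
with cardiovascular phenotype: the CVD-rubric association is significant
(two-sided exact p below alpha), at least two genotype-positive
participants are CVD-positive, and at least two carriers report parental
heart-disease history. Parental history is supporting evidence only --
its own association p-value is recorded but not gated, since a variant
can be convincing on the rubric while its parental-history test is not
significant. Carriers of known pathogenic variants in
cardiovascular-category genes are excluded from the cohort before any
association is computed.

Every criterion's observed value is recorded per variant so near-misses
are auditable; the selection flag is exactly the conjunction of the
per-criterion checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cohort_io import GenotypeMatrix, VariantKey
from .panel import GenePanel

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionCriteria:
    alpha: float = 0.05
    min_cvd_carriers: int = 2
    min_parental_history_carriers: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.min_cvd_carriers < 1 or self.min_parental_history_carriers < 1:
            raise ValueError("carrier minima must be >= 1")


@dataclass(frozen=True)
class VariantEvidence:
    """Association evidence for one candidate variant."""

    key: VariantKey
    gene: str
    p_cvd: float
    odds_ratio_cvd: float
    n_carriers: int
    n_cvd_positive_carriers: int
    n_parental_positive_carriers: int
    p_parental: float | None = None
    odds_ratio_parental: float | None = None


@dataclass
class SelectionRecord:
    evidence: VariantEvidence
    checks: dict[str, bool] = field(default_factory=dict)

    @property
    def selected(self) -> bool:
        return all(self.checks.values())


def select_candidates(
    evidence_list: list[VariantEvidence], criteria: SelectionCriteria = SelectionCriteria()
) -> list[SelectionRecord]:
    """Apply the segregation criteria; returns a per-criterion ledger.

    Output is ranked: selected variants first, then ascending CVD p.
    """
    records = []
    for ev in evidence_list:
        checks = {
            "significant_cvd_association": ev.p_cvd < criteria.alpha,
            "min_cvd_positive_carriers": ev.n_cvd_positive_carriers >= criteria.min_cvd_carriers,
            "min_parental_history_carriers": (
                ev.n_parental_positive_carriers >= criteria.min_parental_history_carriers
            ),
        }
        records.append(SelectionRecord(evidence=ev, checks=checks))
    records.sort(key=lambda r: (not r.selected, r.evidence.p_cvd, r.evidence.key))
    return records


def selection_table(records: list[SelectionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        ev = r.evidence
        chrom, pos, ref, alt = ev.key
        rows.append(
            {
                "chrom": chrom,
                "pos": pos + 1,
                "ref": ref,
                "alt": alt,
                "gene": ev.gene,
                "n_carriers": ev.n_carriers,
                "p_cvd": ev.p_cvd,
                "odds_ratio_cvd": ev.odds_ratio_cvd,
                "n_cvd_positive_carriers": ev.n_cvd_positive_carriers,
                "n_parental_positive_carriers": ev.n_parental_positive_carriers,
                "p_parental": ev.p_parental,
                "odds_ratio_parental": ev.odds_ratio_parental,
                **{f"pass_{name}": check for name, check in r.checks.items()},
                "selected": r.selected,
            }
        )
    return pd.DataFrame(rows)


def read_known_pathogenic(tsv: str | Path) -> pd.DataFrame:
    df = pd.read_csv(tsv, sep="\t", dtype={"chrom": str})
    needed = {"chrom", "pos", "ref", "alt", "gene"}
    if needed - set(df.columns):
        raise ValueError(f"{tsv}: missing columns {sorted(needed - set(df.columns))}")
    return df


def exclude_known_pathogenic_carriers(
    genotypes: GenotypeMatrix,
    known_pathogenic: pd.DataFrame,
    panel: GenePanel,
) -> set[str]:
    """Samples carrying a listed pathogenic variant in a cardiovascular gene.

    Entries whose gene is not on the panel draw a warning and are
    ignored; entries in non-cardiovascular genes do not trigger
    exclusion. Listed variants absent from the cohort exclude nobody.
    Returns the sample ids to drop from downstream association/selection.
    """
    excluded: set[str] = set()
    for row in known_pathogenic.itertuples():
        gene = str(row.gene)
        if gene not in panel.genes:
            log.warning("known-pathogenic list: unknown gene %r; entry ignored", gene)
            continue
        if panel.category_of(gene) != "cardiovascular":
            continue
        key = (str(row.chrom), int(row.pos) - 1, str(row.ref), str(row.alt))
        if key in genotypes._variant_idx:
            excluded.update(genotypes.carriers(key))
    return excluded
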