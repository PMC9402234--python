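"""End-to-end orchestration: ingest -> cascade -> summaries -> selection.

``run_all`` wires the modules together, writes every result table with a
stable layout, and records a run manifest (config snapshot, SHA-256
digests of inputs and outputs, per-stage record counts, tool version) so
a run can be replayed and verified byte for byte. A stage failure still
writes a manifest naming the failed stage before the error propagates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, cohort_io
from .association import associate_variant
from .cascade import CascadeParams, FilterFunnel, run_cascade
from .errors import ConfigError
from .frequency import category_distribution, genotype_positive_frequency, genotype_positive_rate
from .panel import default_panel, load_gene_panel
from .selector import (
    SelectionCriteria,
    VariantEvidence,
    exclude_known_pathogenic_carriers,
    read_known_pathogenic,
    select_candidates,
    selection_table,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and analysis parameters for one full run."""

    vcf: Path
    annotations: Path
    samples: Path
    kinship: Path
    phenotypes: Path
    out_dir: Path
    panel_config: Path | None = None
    known_pathogenic: Path | None = None
    cascade: CascadeParams = field(default_factory=CascadeParams)
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    frequency_mode: str = "allele"

    def __post_init__(self) -> None:
        for name in ("vcf", "annotations", "samples", "kinship", "phenotypes"):
            path = Path(getattr(self, name))
            setattr(self, name, path)
            if not path.exists():
                raise ConfigError(f"input {name!r} not found: {path}")
        self.out_dir = Path(self.out_dir)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str
    config: dict
    input_digests: dict[str, str]
    stage_counts: dict[str, int]
    output_digests: dict[str, str]
    failed_stage: str | None = None

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True, default=str) + "\n")


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis and write all result tables.

    Outputs under ``config.out_dir``: ``funnel.tsv``/``funnel.json``,
    ``survivors.tsv``, ``subpop_summary.tsv``, ``category_distribution.tsv``,
    ``associations.tsv``, ``selection.tsv``, ``manifest.json``.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    snapshot = {k: str(v) if isinstance(v, Path) else v for k, v in asdict(config).items()}
    input_digests = {
        name: _sha256(getattr(config, name))
        for name in ("vcf", "annotations", "samples", "kinship", "phenotypes")
    }
    if config.panel_config:
        input_digests["panel_config"] = _sha256(Path(config.panel_config))
    if config.known_pathogenic:
        input_digests["known_pathogenic"] = _sha256(Path(config.known_pathogenic))
    manifest = RunManifest(
        version=__version__,
        config=snapshot,
        input_digests=input_digests,
        stage_counts={},
        output_digests={},
    )

    stage = "ingest"
    try:
        panel = (
            load_gene_panel(config.panel_config) if config.panel_config else default_panel()
        )
        matrix, stubs, samples = cohort_io.read_cohort(config.vcf, config.samples)
        variants = cohort_io.attach_annotations(stubs, config.annotations)
        sample_ids = {s.id for s in samples}
        kinship = cohort_io.read_kinship(config.kinship, known_samples=sample_ids)
        phenotypes = cohort_io.read_phenotypes(config.phenotypes, known_samples=sample_ids)
        manifest.stage_counts["samples"] = len(samples)
        manifest.stage_counts["variants_ingested"] = len(variants)

        stage = "cascade"
        funnel: FilterFunnel = run_cascade(variants, matrix, kinship, panel, config.cascade)
        survivors = [v for v in variants if v.key in set(funnel.final_keys)]
        manifest.stage_counts["variants_surviving"] = len(survivors)
        funnel_df = pd.DataFrame(funnel.to_records())
        funnel_df.to_csv(out / "funnel.tsv", sep="\t", index=False)
        (out / "funnel.json").write_text(
            json.dumps(
                {
                    "initial": funnel.initial,
                    "stages": funnel.to_records(),
                    "final_keys": [list(k) for k in funnel.final_keys],
                },
                indent=2,
            )
            + "\n"
        )
        surv_rows = [
            {
                "chrom": v.chrom, "pos": v.pos + 1, "ref": v.ref, "alt": v.alt,
                "gene": v.gene, "category": panel.category_of(v.gene),
                "effect": v.effect, "impact": v.impact, "cadd": v.cadd, "gerp": v.gerp,
                "ac": matrix.allele_counts(v.key)[0], "an": matrix.allele_counts(v.key)[1],
                "n_carriers": len(matrix.carriers(v.key)),
            }
            for v in survivors
        ]
        pd.DataFrame(
            surv_rows,
            columns=["chrom", "pos", "ref", "alt", "gene", "category", "effect",
                     "impact", "cadd", "gerp", "ac", "an", "n_carriers"],
        ).to_csv(out / "survivors.tsv", sep="\t", index=False)

        stage = "frequency"
        summary = genotype_positive_frequency(
            survivors, matrix, samples, panel, mode=config.frequency_mode
        )
        summary.frequencies.to_csv(out / "subpop_summary.tsv", sep="\t")
        category_distribution(survivors, panel).to_csv(
            out / "category_distribution.tsv", sep="\t"
        )
        all_carriers: set[str] = set()
        for v in survivors:
            all_carriers.update(matrix.carriers(v.key))
        manifest.stage_counts["genotype_positive_participants"] = len(all_carriers)
        manifest.stage_counts["genotype_positive_rate_pct_x1000"] = int(
            round(1000 * genotype_positive_rate(len(all_carriers), len(samples)))
        )

        stage = "exclusion"
        excluded: set[str] = set()
        if config.known_pathogenic:
            known = read_known_pathogenic(config.known_pathogenic)
            excluded = exclude_known_pathogenic_carriers(matrix, known, panel)
        manifest.stage_counts["samples_excluded_known_pathogenic"] = len(excluded)
        if excluded:
            keep = [s for s in matrix.samples if s not in excluded]
            assoc_matrix = matrix.subset_samples(keep)
            assoc_phenotypes = [p for p in phenotypes if p.sample_id not in excluded]
        else:
            assoc_matrix, assoc_phenotypes = matrix, phenotypes

        stage = "association"
        evidence: list[VariantEvidence] = []
        assoc_rows = []
        for v in survivors:
            carriers = assoc_matrix.carriers(v.key)
            if not carriers:
                log.warning("%s: no carriers left after exclusion; skipped", v.label)
                continue
            res_cvd = associate_variant(v.key, assoc_matrix, assoc_phenotypes, "cvd_rubric")
            res_par = associate_variant(v.key, assoc_matrix, assoc_phenotypes, "parental_history")
            n_cvd_pos = res_cvd.table.a
            n_par_pos = res_par.table.a
            evidence.append(
                VariantEvidence(
                    key=v.key,
                    gene=v.gene,
                    p_cvd=res_cvd.p_two_sided,
                    odds_ratio_cvd=res_cvd.odds_ratio,
                    n_carriers=len(carriers),
                    n_cvd_positive_carriers=n_cvd_pos,
                    n_parental_positive_carriers=n_par_pos,
                    p_parental=res_par.p_two_sided,
                    odds_ratio_parental=res_par.odds_ratio,
                )
            )
            for res in (res_cvd, res_par):
                t = res.table
                assoc_rows.append(
                    {
                        "chrom": v.chrom, "pos": v.pos + 1, "ref": v.ref, "alt": v.alt,
                        "gene": v.gene, "phenotype_definition": res.phenotype_definition,
                        "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                        "p_two_sided": res.p_two_sided, "odds_ratio": res.odds_ratio,
                        "haldane_applied": res.haldane_applied,
                    }
                )
        pd.DataFrame(
            assoc_rows,
            columns=["chrom", "pos", "ref", "alt", "gene", "phenotype_definition",
                     "a", "b", "c", "d", "p_two_sided", "odds_ratio", "haldane_applied"],
        ).to_csv(out / "associations.tsv", sep="\t", index=False)

        stage = "selection"
        records = select_candidates(evidence, config.criteria)
        selection_table(records).to_csv(out / "selection.tsv", sep="\t", index=False)
        manifest.stage_counts["variants_selected"] = sum(r.selected for r in records)
    except Exception:
        manifest.failed_stage = stage
        manifest.write(out / "manifest.json")
        raise

    for name in ("funnel.tsv", "funnel.json", "survivors.tsv", "subpop_summary.tsv",
                 "category_distribution.tsv", "associations.tsv", "selection.tsv"):
        manifest.output_digests[name] = _sha256(out / name)
    manifest.write(out / "manifest.json")
    return manifest
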