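"""Seeded synthetic-cohort generator.

The real cohort behind this analysis (6045 whole genomes with biobank
phenotypes, six ancestry subpopulations) is access-restricted, so the
package ships a generator that emulates the *decision structure* the
analysis assumes: a multi-ancestry sample table with realistic
subpopulation proportions, family clusters with known kinship, annotated
variant sites planted in the 59-gene panel, and phenotype records drawn
from a logistic-odds carrier model. It deliberately does not model LD,
site-frequency spectra or admixture genetics.

Every planted variant is assigned a *fate*: it satisfies every cascade
predicate except the one its fate names (``survives_all`` satisfies all
of them). One caveat is structural: a single-allele-count variant
necessarily also lacks two unrelated carriers, so ``fails_singleton``
variants violate the unrelated-carriers predicate too; in the cascade's
canonical order they are dropped at the singleton stage, and the fate
label records that first failing stage. The emitted truth table lets
tests check each stage's drop count exactly.

Generation is deterministic: one global seed feeds a splittable
generator per surface (samples, variants, phenotypes), and outputs are
byte-identical across runs with the same config. Infeasible configs --
e.g. a cohort too small for any allele count to be simultaneously >= 2
and below the rare-frequency ceiling -- raise instead of being silently
adjusted.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import cohort_io
from .cascade import CascadeParams
from .cohort_io import (
    SUBPOPULATIONS,
    GenotypeMatrix,
    PhenotypeRecord,
    SampleRecord,
    VariantRecord,
    chrom_sort_key,
)
from .errors import ConfigError, InfeasibleConfigError
from .panel import GenePanel, default_panel

FATES = (
    "fails_panel",
    "fails_novelty",
    "fails_cadd",
    "fails_gerp",
    "fails_maf",
    "fails_singleton",
    "fails_unrelated",
    "fails_impact_effect",
    "survives_all",
)

#: subpopulation sizes of the study cohort (n = 6045) used as weights
COHORT_SUBPOP_SIZES = {"ADM": 1180, "AFR": 92, "GAR": 2311, "PAR": 1052, "WEP": 1372, "SAS": 38}

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PhenotypeModel:
    """Background prevalences and carrier effect sizes.

    Background rates are free parameters of the emulation (the source
    biobank's rates are unpublished); defaults are chosen so the
    background CVD-rubric prevalence lands near 7%, a plausible adult
    population figure. The carrier odds ratios default to the published
    anchors for the two validated variants (6.619 on the CVD rubric,
    4.755 on parental history). ``math.inf`` is accepted as a
    full-penetrance switch: every carrier is phenotype-positive.
    """

    p_abnormal_ecg: float = 0.05
    p_borderline_ecg: float = 0.15
    p_chest_pain: float = 0.10
    p_condition: float = 0.03
    p_parental_history: float = 0.15
    p_ecg_missing: float = 0.0
    carrier_or: float = 6.6
    carrier_parental_or: float = 4.8
    condition_terms: tuple[str, ...] = ("angina", "heart attack", "heart failure", "arrhythmia")

    def validate(self) -> None:
        for name in (
            "p_abnormal_ecg",
            "p_borderline_ecg",
            "p_chest_pain",
            "p_condition",
            "p_parental_history",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0,1), got {v}")
        if not 0.0 <= self.p_ecg_missing < 1.0:
            raise ConfigError(f"p_ecg_missing must be in [0,1), got {self.p_ecg_missing}")
        if self.p_abnormal_ecg + self.p_borderline_ecg >= 1.0:
            raise ConfigError("ECG category probabilities exceed 1")
        for name in ("carrier_or", "carrier_parental_or"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")

    def background_cvd_prob(self) -> float:
        """P(rubric positive) for a non-carrier under this model."""
        p_sym = 1.0 - (1.0 - self.p_chest_pain) * (1.0 - self.p_condition)
        return self.p_abnormal_ecg + self.p_borderline_ecg * p_sym

    def carrier_cvd_prob(self) -> float:
        return _shift_by_odds(self.background_cvd_prob(), self.carrier_or)

    def carrier_parental_prob(self) -> float:
        return _shift_by_odds(self.p_parental_history, self.carrier_parental_or)


def _shift_by_odds(p0: float, odds_ratio: float) -> float:
    if math.isinf(odds_ratio):
        return 1.0
    odds = odds_ratio * p0 / (1.0 - p0)
    return odds / (1.0 + odds)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults scale the study cohort to a fifth of its size (1200
    samples) -- the smallest round size at which an allele count of 2
    still clears the MAF < 0.001 ceiling -- with subpopulation weights
    proportional to the published subpopulation sizes and ten variants
    planted per cascade fate.
    """

    n_samples: int = 1200
    subpop_weights: dict[str, float] = field(
        default_factory=lambda: {
            k: v / sum(COHORT_SUBPOP_SIZES.values()) for k, v in COHORT_SUBPOP_SIZES.items()
        }
    )
    n_variants: int = 90
    fate_mix: dict[str, float] = field(
        default_factory=lambda: {fate: 1.0 / len(FATES) for fate in FATES}
    )
    n_families: int = 60
    family_size_probs: dict[int, float] = field(default_factory=lambda: {2: 0.7, 3: 0.3})
    pheno_model: PhenotypeModel = field(default_factory=PhenotypeModel)
    cascade: CascadeParams = field(default_factory=CascadeParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")
        if set(self.subpop_weights) != set(SUBPOPULATIONS):
            raise ConfigError(f"subpop_weights must cover exactly {SUBPOPULATIONS}")
        if abs(sum(self.subpop_weights.values()) - 1.0) > 1e-9:
            raise ConfigError("subpop_weights must sum to 1")
        unknown = set(self.fate_mix) - set(FATES)
        if unknown:
            raise ConfigError(f"unknown fates in fate_mix: {sorted(unknown)}")
        if abs(sum(self.fate_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("fate_mix must sum to 1")
        if abs(sum(self.family_size_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("family_size_probs must sum to 1")
        self.pheno_model.validate()
        an = 2 * self.n_samples
        if self.cascade.min_ac / an >= self.cascade.maf_max:
            raise InfeasibleConfigError(
                f"no allele count can satisfy AC >= {self.cascade.min_ac} and "
                f"MAF < {self.cascade.maf_max} at n_samples = {self.n_samples}; "
                f"need n_samples > {self.cascade.min_ac / (2 * self.cascade.maf_max):.0f}"
            )

    def fate_counts(self) -> dict[str, int]:
        """Largest-remainder apportionment of n_variants over the fate mix."""
        raw = {f: self.n_variants * self.fate_mix.get(f, 0.0) for f in FATES}
        counts = {f: int(math.floor(x)) for f, x in raw.items()}
        short = self.n_variants - sum(counts.values())
        for f in sorted(FATES, key=lambda f: raw[f] - counts[f], reverse=True)[:short]:
            counts[f] += 1
        return counts

    def ac_above_maf(self) -> int:
        """Smallest alt allele count whose folded MAF is >= the ceiling."""
        an = 2 * self.n_samples
        return max(math.ceil(self.cascade.maf_max * an), self.cascade.min_ac)


def demo_config(seed: int = 0, n_samples: int = 1200) -> SimulationConfig:
    """Config of the end-to-end demo bundle.

    Planted survivor variants use the full-penetrance switch (infinite
    carrier odds) so the demo checks the pipeline's decision structure
    deterministically; stochastic behaviour at the published effect-size
    anchor is exercised by the statistical property checks instead.
    """
    return SimulationConfig(
        n_samples=n_samples,
        seed=seed,
        pheno_model=PhenotypeModel(carrier_or=math.inf, carrier_parental_or=math.inf),
    )


@dataclass(frozen=True)
class SimulatedBundle:
    """Paths of one generated input bundle."""

    out_dir: Path
    vcf: Path
    annotations: Path
    samples: Path
    kinship: Path
    phenotypes: Path
    truth: Path
    config_json: Path


# ---------------------------------------------------------------------------
# phenotype surface
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    carrier_flags: dict[str, bool],
    pheno_model: PhenotypeModel,
    seed: int | np.random.SeedSequence,
) -> list[PhenotypeRecord]:
    """Draw one phenotype record per sample under the logistic-odds model.

    Non-carriers draw ECG class, chest pain, self-reported conditions and
    parental history independently at background rates. Carriers first
    draw their CVD-rubric status as Bernoulli with the odds-shifted
    probability, then draw a component configuration consistent with that
    status (rejection sampling from the background component
    distribution), so P(rubric+ | carrier) follows the configured odds
    ratio exactly. Parental history is shifted the same way by its own
    odds ratio.
    """
    pheno_model.validate()
    ids = list(carrier_flags)
    n = len(ids)
    flags = np.array([bool(carrier_flags[s]) for s in ids])
    rng = np.random.default_rng(seed)
    m = pheno_model

    ecg_u = rng.random(n)
    chest = rng.random(n) < m.p_chest_pain
    cond = rng.random(n) < m.p_condition
    p1 = m.carrier_cvd_prob()
    target = rng.random(n) < p1  # consulted only for carriers

    def rubric(ecg_u_, chest_, cond_):
        abnormal = ecg_u_ < m.p_abnormal_ecg
        borderline = (~abnormal) & (ecg_u_ < m.p_abnormal_ecg + m.p_borderline_ecg)
        return abnormal | (borderline & (chest_ | cond_))

    mismatch = flags & (rubric(ecg_u, chest, cond) != target)
    guard = 0
    while mismatch.any():
        k = int(mismatch.sum())
        ecg_u[mismatch] = rng.random(k)
        chest[mismatch] = rng.random(k) < m.p_chest_pain
        cond[mismatch] = rng.random(k) < m.p_condition
        mismatch = flags & (rubric(ecg_u, chest, cond) != target)
        guard += 1
        if guard > 10_000:  # pragma: no cover - p0 in (0,1) guarantees progress
            raise RuntimeError("rejection sampling failed to converge")

    p_par = np.where(flags, m.carrier_parental_prob(), m.p_parental_history)
    parental = rng.random(n) < p_par
    missing = (~flags) & (rng.random(n) < m.p_ecg_missing)

    records = []
    for i, sid in enumerate(ids):
        if missing[i]:
            ecg = "missing"
        elif ecg_u[i] < m.p_abnormal_ecg:
            ecg = "abnormal"
        elif ecg_u[i] < m.p_abnormal_ecg + m.p_borderline_ecg:
            ecg = "borderline"
        else:
            ecg = "normal"
        conditions = frozenset({m.condition_terms[0]}) if cond[i] else frozenset()
        records.append(
            PhenotypeRecord(
                sample_id=sid,
                ecg=ecg,
                chest_pain=bool(chest[i]),
                parental_heart_disease=bool(parental[i]),
                self_reported_conditions=conditions,
            )
        )
    return records


# ---------------------------------------------------------------------------
# cohort surfaces
# ---------------------------------------------------------------------------


def _simulate_samples(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[SampleRecord], list[list[str]], nx.Graph]:
    """Sample table, family clusters, and the kinship graph."""
    ids = [f"S{i:05d}" for i in range(config.n_samples)]
    weights = [config.subpop_weights[p] for p in SUBPOPULATIONS]
    subpops = rng.choice(SUBPOPULATIONS, size=config.n_samples, p=weights)
    samples = [SampleRecord(i, p) for i, p in zip(ids, subpops)]

    order = list(rng.permutation(config.n_samples))
    sizes = list(rng.choice(
        sorted(config.family_size_probs),
        size=config.n_families,
        p=[config.family_size_probs[k] for k in sorted(config.family_size_probs)],
    ))
    families: list[list[str]] = []
    cursor = 0
    for size in sizes:
        if cursor + size > config.n_samples // 2:
            raise InfeasibleConfigError(
                "family structure would consume more than half the cohort; "
                "reduce n_families or family sizes"
            )
        families.append([ids[j] for j in order[cursor : cursor + size]])
        cursor += size

    kinship = nx.Graph()
    kinship.add_nodes_from(ids)
    for fam in families:
        for a_i in range(len(fam)):
            for b_i in range(a_i + 1, len(fam)):
                phi = float(rng.choice([0.25, 0.125]))
                kinship.add_edge(fam[a_i], fam[b_i], phi=phi)
    return samples, families, kinship


class _CarrierPicker:
    """Draws carrier sets from independent units (families or singletons),
    guaranteeing pairwise kinship 0 for carriers from distinct units."""

    def __init__(self, families: list[list[str]], all_ids: list[str], rng: np.random.Generator):
        in_family = {s for fam in families for s in fam}
        self.units: list[list[str]] = list(families) + [[s] for s in all_ids if s not in in_family]
        self.families = [f for f in families if len(f) >= 2]
        self.rng = rng

    def unrelated(self, k: int) -> list[str]:
        if k > len(self.units):
            raise InfeasibleConfigError(
                f"need {k} unrelated carriers but only {len(self.units)} independent units exist"
            )
        unit_idx = self.rng.choice(len(self.units), size=k, replace=False)
        return [self.units[i][self.rng.integers(len(self.units[i]))] for i in unit_idx]

    def related_pair(self) -> list[str]:
        if not self.families:
            raise InfeasibleConfigError("no family of size >= 2 available for a related pair")
        fam = self.families[self.rng.integers(len(self.families))]
        idx = self.rng.choice(len(fam), size=2, replace=False)
        return [fam[i] for i in idx]


def _plant_variants(
    config: SimulationConfig,
    panel: GenePanel,
    picker: _CarrierPicker,
    rng: np.random.Generator,
) -> tuple[list[VariantRecord], dict[cohort_io.VariantKey, list[str]], pd.DataFrame]:
    """Plant one variant per (fate, replicate) with exactly-targeted violations."""
    cardio_genes = sorted(panel.genes_in_category("cardiovascular"))
    all_genes = sorted(panel.genes)
    used_pos: set[tuple[str, int]] = set()
    off_panel_counter = 0

    variants: list[VariantRecord] = []
    carriers_of: dict[cohort_io.VariantKey, list[str]] = {}
    truth_rows: list[dict] = []

    def fresh_site(gene: str | None) -> tuple[str, int]:
        nonlocal off_panel_counter
        for _ in range(1000):
            if gene is None:  # off-panel site
                chrom = "2"
                pos = 150_000_000 + off_panel_counter * 101
                off_panel_counter += 1
                if panel.covers(chrom, pos):
                    continue
            else:
                ivs = panel.intervals[gene]
                chrom, start, end = ivs[rng.integers(len(ivs))]
                pos = int(rng.integers(start, end))
            if (chrom, pos) not in used_pos:
                used_pos.add((chrom, pos))
                return chrom, pos
        raise InfeasibleConfigError("could not find a fresh variant site")  # pragma: no cover

    for fate in FATES:
        for _ in range(config.fate_counts()[fate]):
            gene = (
                cardio_genes[rng.integers(len(cardio_genes))]
                if fate == "survives_all"
                else all_genes[rng.integers(len(all_genes))]
            )
            if fate == "fails_panel":
                gene = "OFFPANEL" + str(rng.integers(1, 4))
                chrom, pos = fresh_site(None)
            else:
                chrom, pos = fresh_site(gene)
            ref = _BASES[rng.integers(4)]
            alt = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]

            flags = {name: False for name in cohort_io.DB_NAMES}
            cadd = round(float(rng.uniform(22.0, 42.0)), 2)
            gerp = round(float(rng.uniform(3.2, 6.2)), 2)
            effect, impact = "missense_variant", "MODERATE"

            if fate == "fails_novelty":
                flags[cohort_io.DB_NAMES[rng.integers(len(cohort_io.DB_NAMES))]] = True
            elif fate == "fails_cadd":
                cadd = round(float(rng.uniform(2.0, 19.5)), 2)
            elif fate == "fails_gerp":
                gerp = round(float(rng.uniform(-4.0, 2.5)), 2)
            elif fate == "fails_impact_effect":
                effect, impact = [
                    ("intron_variant", "MODIFIER"),
                    ("stop_gained", "HIGH"),
                    ("frameshift_variant", "HIGH"),
                    ("synonymous_variant", "LOW"),
                ][rng.integers(4)]

            if fate == "fails_maf":
                carriers = picker.unrelated(config.ac_above_maf())
            elif fate == "fails_singleton":
                carriers = picker.unrelated(1)
            elif fate == "fails_unrelated":
                carriers = picker.related_pair()
            else:
                carriers = picker.unrelated(2)

            record = VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                effect=effect, impact=impact, cadd=cadd, gerp=gerp, db_membership=flags,
            )
            variants.append(record)
            carriers_of[record.key] = sorted(carriers)
            truth_rows.append(
                {
                    "chrom": chrom,
                    "pos": pos + 1,
                    "ref": ref,
                    "alt": alt,
                    "gene": gene,
                    "fate": fate,
                    "carriers": ";".join(sorted(carriers)),
                    "intended_or": (
                        config.pheno_model.carrier_or if fate == "survives_all" else 1.0
                    ),
                }
            )

    order = sorted(range(len(variants)), key=lambda i: (chrom_sort_key(variants[i].chrom), variants[i].pos))
    variants = [variants[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order])
    return variants, carriers_of, truth


def simulate_cohort(
    config: SimulationConfig,
    out_dir: str | Path,
    panel: GenePanel | None = None,
) -> tuple[SimulatedBundle, pd.DataFrame]:
    """Generate a full input bundle plus its ground-truth table.

    Writes the five input surfaces (VCF, annotation/sample/kinship/
    phenotype TSVs) in the exact dialects the ingest layer reads, plus
    ``truth.tsv`` and a JSON snapshot of the config. Returns the bundle
    paths and the truth table. Deterministic and byte-identical given
    the same config (including its seed).
    """
    config.validate()
    panel = panel or default_panel()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    root = np.random.SeedSequence(config.seed)
    ss_samples, ss_variants, ss_pheno = root.spawn(3)
    rng_samples = np.random.default_rng(ss_samples)
    rng_variants = np.random.default_rng(ss_variants)

    samples, families, kinship = _simulate_samples(config, rng_samples)
    picker = _CarrierPicker(families, [s.id for s in samples], rng_variants)
    variants, carriers_of, truth = _plant_variants(config, panel, picker, rng_variants)

    calls = np.zeros((len(samples), len(variants)), dtype=np.int8)
    sample_idx = {s.id: i for i, s in enumerate(samples)}
    for j, v in enumerate(variants):
        for sid in carriers_of[v.key]:
            calls[sample_idx[sid], j] = 1  # planted carriers are heterozygous
    matrix = GenotypeMatrix([s.id for s in samples], [v.key for v in variants], calls)

    survivor_carriers = {
        sid
        for v, fate in zip(variants, truth["fate"])
        if fate == "survives_all"
        for sid in carriers_of[v.key]
    }
    carrier_flags = {s.id: (s.id in survivor_carriers) for s in samples}
    phenotypes = simulate_phenotypes(carrier_flags, config.pheno_model, ss_pheno)

    bundle = SimulatedBundle(
        out_dir=out_dir,
        vcf=out_dir / "cohort.vcf",
        annotations=out_dir / "annotations.tsv",
        samples=out_dir / "samples.tsv",
        kinship=out_dir / "kinship.tsv",
        phenotypes=out_dir / "phenotypes.tsv",
        truth=out_dir / "truth.tsv",
        config_json=out_dir / "config.json",
    )
    cohort_io.write_vcf(bundle.vcf, variants, matrix)
    cohort_io.write_annotations(bundle.annotations, variants)
    cohort_io.write_samples(bundle.samples, samples)
    cohort_io.write_kinship(bundle.kinship, kinship)
    cohort_io.write_phenotypes(bundle.phenotypes, phenotypes)
    truth.to_csv(bundle.truth, sep="\t", index=False)

    snapshot = asdict(config)
    snapshot["pheno_model"]["carrier_or"] = _jsonable(config.pheno_model.carrier_or)
    snapshot["pheno_model"]["carrier_parental_or"] = _jsonable(
        config.pheno_model.carrier_parental_or
    )
    bundle.config_json.write_text(json.dumps(snapshot, indent=2, default=str) + "\n")
    return bundle, truth


def _jsonable(x: float) -> float | str:
    return "inf" if math.isinf(x) else x


def load_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
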