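"""Ingest and serialization of the five cohort input surfaces.

Surfaces: diploid genotypes (VCF 4.2), a per-variant annotation table
(TSV keyed by chrom/pos/ref/alt), a sample table with subpopulation
labels, a pairwise kinship table, and a phenotype table. Readers
normalize everything into the internal data model (multiallelic records
split to one alt per record, positions 0-based, missing genotypes kept
as missing); writers emit the same dialects with a stable column order
so that write -> read is the identity.

Annotation lives in a side TSV rather than VCF INFO so the filtering
cascade is testable without an annotation toolchain. File positions are
1-based (VCF convention) in both the VCF and the TSVs; the in-memory
model is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import cyvcf2
import networkx as nx
import numpy as np
import pandas as pd
import pysam

from .errors import (
    AnnotationError,
    KinshipBoundsError,
    MalformedGenotypeError,
    SampleMismatchError,
    UnsortedVCFError,
    VocabularyError,
)

log = logging.getLogger(__name__)

#: the eight databases whose joint absence defines a "novel" variant
DB_NAMES = ("dbsnp", "gnomad", "topmed", "kg1000", "exac", "gme", "hgmd", "clinvar")

SUBPOPULATIONS = ("ADM", "AFR", "GAR", "PAR", "WEP", "SAS")

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")

ECG_VALUES = ("normal", "borderline", "abnormal", "missing")

MISSING = -1  # genotype dosage sentinel

VariantKey = tuple[str, int, str, str]  # chrom, 0-based pos, ref, alt


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural contig order: 1..22 numerically, then X, Y, MT, then others."""
    c = chrom.removeprefix("chr")
    if c.isdigit():
        return (int(c), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    return (special.get(c, 99), c)


@dataclass
class VariantRecord:
    """One normalized alternate allele with (optionally) its annotation.

    ``pos`` is 0-based. Records straight off the VCF are *stubs*: the
    annotation fields are ``None`` until :func:`attach_annotations` joins
    the side table on (chrom, pos, ref, alt).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    effect: str | None = None
    impact: str | None = None
    cadd: float | None = None
    gerp: float | None = None
    db_membership: dict[str, bool] | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos + 1}")
        if self.impact is not None and self.impact not in IMPACT_CLASSES:
            raise VocabularyError(
                f"impact {self.impact!r} at {self.chrom}:{self.pos + 1} "
                f"not in {IMPACT_CLASSES}"
            )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def label(self) -> str:
        """Human-readable 1-based key, e.g. ``6:5006123 A>G``."""
        return f"{self.chrom}:{self.pos + 1} {self.ref}>{self.alt}"


@dataclass(frozen=True)
class SampleRecord:
    id: str
    subpopulation: str

    def __post_init__(self) -> None:
        if self.subpopulation not in SUBPOPULATIONS:
            raise VocabularyError(
                f"sample {self.id}: subpopulation {self.subpopulation!r} "
                f"not in {SUBPOPULATIONS}"
            )


@dataclass(frozen=True)
class PhenotypeRecord:
    """Cardiovascular phenotype surface for one participant."""

    sample_id: str
    ecg: str  # normal | borderline | abnormal | missing
    chest_pain: bool
    parental_heart_disease: bool
    self_reported_conditions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.ecg not in ECG_VALUES:
            raise VocabularyError(
                f"sample {self.sample_id}: ecg {self.ecg!r} not in {ECG_VALUES}"
            )


@dataclass
class GenotypeMatrix:
    """Samples x variants alt-allele dosages; ``-1`` marks a missing call."""

    samples: list[str]
    variants: list[VariantKey]
    calls: np.ndarray  # int8, shape (n_samples, n_variants)

    _sample_idx: dict[str, int] = field(default_factory=dict, repr=False)
    _variant_idx: dict[VariantKey, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise MalformedGenotypeError(f"dosages outside {{0,1,2,missing}}: {self.calls[bad][:5]}")
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}
        self._variant_idx = {v: j for j, v in enumerate(self.variants)}

    def dosages(self, key: VariantKey) -> np.ndarray:
        return self.calls[:, self._variant_idx[key]]

    def allele_counts(self, key: VariantKey) -> tuple[int, int]:
        """(AC, AN): alt alleles and non-missing alleles at ``key``.

        Missing genotypes are excluded from the AN denominator.
        """
        col = self.dosages(key)
        called = col != MISSING
        return int(col[called].sum()), int(2 * called.sum())

    def carriers(self, key: VariantKey, min_dosage: int = 1) -> list[str]:
        col = self.dosages(key)
        return [s for s, d in zip(self.samples, col) if d >= min_dosage]

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self._sample_idx[s] for s in keep]
        return GenotypeMatrix(list(keep), list(self.variants), self.calls[idx, :])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_samples(samples_tsv: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(samples_tsv, sep="\t", dtype=str)
    for col in ("sample_id", "subpopulation"):
        if col not in df.columns:
            raise VocabularyError(f"{samples_tsv}: missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SampleMismatchError(f"{samples_tsv}: duplicate sample id {dup!r}")
    return [SampleRecord(r.sample_id, r.subpopulation) for r in df.itertuples()]


def read_cohort(
    vcf_path: str | Path, samples_tsv: str | Path
) -> tuple[GenotypeMatrix, list[VariantRecord], list[SampleRecord]]:
    """Read genotypes + sample table into the internal model.

    Multiallelic sites are split into one record per alt allele; the
    dosage of each split record counts only its own allele. A genotype
    with any missing allele is recorded as missing. Phase ("|" vs "/")
    is ignored. The VCF must be coordinate-sorted within contigs.
    """
    sample_records = read_samples(samples_tsv)
    wanted = [s.id for s in sample_records]

    vcf = cyvcf2.VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    unknown = set(wanted) - set(vcf_samples)
    if unknown:
        raise SampleMismatchError(
            f"samples in {samples_tsv} absent from VCF: {sorted(unknown)[:5]}"
        )
    col_of = {s: i for i, s in enumerate(vcf_samples)}
    take = [col_of[s] for s in wanted]

    stubs: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    last_pos: dict[str, int] = {}
    seen_chroms: list[str] = []
    for rec in vcf:
        chrom = rec.CHROM
        if chrom not in last_pos:
            seen_chroms.append(chrom)
        elif seen_chroms[-1] != chrom:
            raise UnsortedVCFError(f"{vcf_path}: contig {chrom} records are not contiguous")
        if rec.start < last_pos.get(chrom, -1):
            raise UnsortedVCFError(
                f"{vcf_path}: {chrom}:{rec.POS} after position {last_pos[chrom] + 1}"
            )
        last_pos[chrom] = rec.start

        gts = rec.genotypes  # [allele0, allele1, phased] per sample
        for g in gts:
            if len(g) != 3:
                raise MalformedGenotypeError(
                    f"{vcf_path}: non-diploid GT at {chrom}:{rec.POS}"
                )
        for alt_i, alt in enumerate(rec.ALT, start=1):
            dos = np.empty(len(wanted), dtype=np.int8)
            for out_i, col in enumerate(take):
                a0, a1, _ = gts[col]
                if a0 < 0 or a1 < 0:
                    dos[out_i] = MISSING
                else:
                    dos[out_i] = (a0 == alt_i) + (a1 == alt_i)
            stubs.append(VariantRecord(chrom=chrom, pos=rec.start, ref=rec.REF, alt=alt))
            rows.append(dos)
    vcf.close()

    calls = (
        np.stack(rows, axis=1) if rows else np.empty((len(wanted), 0), dtype=np.int8)
    )
    matrix = GenotypeMatrix(wanted, [s.key for s in stubs], calls)
    log.info(
        "read_cohort: %d samples, %d split variant records from %s",
        len(wanted), len(stubs), vcf_path,
    )
    return matrix, stubs, sample_records


_FLAG_TRUE = {"1", "true", "True", "TRUE", "yes"}
_FLAG_FALSE = {"0", "false", "False", "FALSE", "no"}


def _parse_flag(value: str, context: str) -> bool:
    v = str(value).strip()
    if v in _FLAG_TRUE:
        return True
    if v in _FLAG_FALSE:
        return False
    raise VocabularyError(f"{context}: unparseable boolean flag {value!r}")


def attach_annotations(
    stubs: list[VariantRecord], annotations_tsv: str | Path
) -> list[VariantRecord]:
    """Join the side annotation table onto VCF stubs.

    The table is keyed by (chrom, pos[1-based], ref, alt) and must cover
    every stub exactly once; extra rows are ignored. Populates gene,
    effect, impact, CADD, GERP and the eight database-membership flags.
    """
    df = pd.read_csv(annotations_tsv, sep="\t", dtype={"chrom": str})
    needed = {"chrom", "pos", "ref", "alt", "gene", "effect", "impact", "cadd", "gerp", *DB_NAMES}
    missing_cols = needed - set(df.columns)
    if missing_cols:
        raise AnnotationError(f"{annotations_tsv}: missing columns {sorted(missing_cols)}")

    table: dict[VariantKey, pd.Series] = {}
    for row in df.itertuples():
        key = (str(row.chrom), int(row.pos) - 1, str(row.ref), str(row.alt))
        if key in table:
            raise AnnotationError(
                f"{annotations_tsv}: duplicate annotation for {key[0]}:{key[1] + 1} "
                f"{key[2]}>{key[3]}"
            )
        table[key] = row

    out: list[VariantRecord] = []
    for stub in stubs:
        row = table.get(stub.key)
        if row is None:
            raise AnnotationError(f"{annotations_tsv}: no annotation row for {stub.label}")
        out.append(
            replace(
                stub,
                gene=str(row.gene),
                effect=str(row.effect),
                impact=str(row.impact),
                cadd=float(row.cadd),
                gerp=float(row.gerp),
                db_membership={
                    name: _parse_flag(getattr(row, name), f"{stub.label} {name}")
                    for name in DB_NAMES
                },
            )
        )
    return out


def read_phenotypes(
    tsv: str | Path, known_samples: set[str] | None = None
) -> list[PhenotypeRecord]:
    """Read the phenotype table; ECG values are case-folded, empty -> missing."""
    df = pd.read_csv(tsv, sep="\t", dtype=str, keep_default_na=False)
    needed = {"sample_id", "ecg", "chest_pain", "parental_heart_disease", "self_reported_conditions"}
    missing_cols = needed - set(df.columns)
    if missing_cols:
        raise VocabularyError(f"{tsv}: missing columns {sorted(missing_cols)}")
    records = []
    for row in df.itertuples():
        if known_samples is not None and row.sample_id not in known_samples:
            raise SampleMismatchError(f"{tsv}: unknown sample {row.sample_id!r}")
        ecg = row.ecg.strip().lower() or "missing"
        conditions = frozenset(
            t.strip().lower() for t in row.self_reported_conditions.split(";") if t.strip()
        )
        records.append(
            PhenotypeRecord(
                sample_id=row.sample_id,
                ecg=ecg,
                chest_pain=_parse_flag(row.chest_pain, f"{tsv} sample {row.sample_id}"),
                parental_heart_disease=_parse_flag(
                    row.parental_heart_disease, f"{tsv} sample {row.sample_id}"
                ),
                self_reported_conditions=conditions,
            )
        )
    return records


def read_kinship(tsv: str | Path, known_samples: set[str] | None = None) -> nx.Graph:
    """Read pairwise kinship into an undirected graph.

    Nodes are sample ids, edge attribute ``phi`` is the kinship
    coefficient in [0, 0.5]. Pairs not listed are implicitly unrelated.
    The table is symmetrized; a pair listed twice with inconsistent phi
    is an error, as is a self-pair or out-of-bounds coefficient.
    """
    df = pd.read_csv(tsv, sep="\t", dtype={"sample_a": str, "sample_b": str})
    needed = {"sample_a", "sample_b", "phi"}
    if needed - set(df.columns):
        raise VocabularyError(f"{tsv}: missing columns {sorted(needed - set(df.columns))}")
    graph = nx.Graph()
    if known_samples is not None:
        graph.add_nodes_from(known_samples)
    for row in df.itertuples():
        a, b, phi = row.sample_a, row.sample_b, float(row.phi)
        if a == b:
            raise KinshipBoundsError(f"{tsv}: self-pair for sample {a!r}")
        if not (0.0 <= phi <= 0.5):
            raise KinshipBoundsError(f"{tsv}: phi={phi} for ({a},{b}) outside [0, 0.5]")
        if known_samples is not None and (a not in known_samples or b not in known_samples):
            raise SampleMismatchError(f"{tsv}: unknown sample in pair ({a},{b})")
        if graph.has_edge(a, b) and abs(graph[a][b]["phi"] - phi) > 1e-12:
            raise KinshipBoundsError(
                f"{tsv}: inconsistent phi for pair ({a},{b}): "
                f"{graph[a][b]['phi']} vs {phi}"
            )
        graph.add_edge(a, b, phi=phi)
    return graph


# ---------------------------------------------------------------------------
# writers (stable column order; write -> read round-trips)
# ---------------------------------------------------------------------------


def write_vcf(path: str | Path, variants: list[VariantRecord], matrix: GenotypeMatrix) -> None:
    """Write a minimal VCF 4.2 with GT calls for ``matrix.samples``.

    ``variants`` must be coordinate-sorted and aligned with
    ``matrix.variants``. Heterozygotes are written as ``0/1``,
    homozygotes ``1/1``, missing ``./.``.
    """
    if [v.key for v in variants] != list(matrix.variants):
        raise ValueError("variants not aligned with matrix columns")
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in sorted({v.chrom for v in variants}, key=chrom_sort_key):
        header.contigs.add(chrom)
    for s in matrix.samples:
        header.add_sample(s)
    gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, v in enumerate(variants):
            rec = out.new_record(
                contig=v.chrom, start=v.pos, alleles=(v.ref, v.alt), id=".", qual=None
            )
            rec.filter.add("PASS")
            for i, s in enumerate(matrix.samples):
                rec.samples[s]["GT"] = gt_of[int(matrix.calls[i, j])]
            out.write(rec)


def write_annotations(path: str | Path, variants: list[VariantRecord]) -> None:
    rows = []
    for v in variants:
        if v.db_membership is None or v.cadd is None or v.gerp is None:
            raise AnnotationError(f"cannot serialize unannotated stub {v.label}")
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos + 1,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "effect": v.effect,
                "impact": v.impact,
                "cadd": v.cadd,
                "gerp": v.gerp,
                **{name: int(v.db_membership[name]) for name in DB_NAMES},
            }
        )
    cols = ["chrom", "pos", "ref", "alt", "gene", "effect", "impact", "cadd", "gerp", *DB_NAMES]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_samples(path: str | Path, samples: list[SampleRecord]) -> None:
    pd.DataFrame(
        [{"sample_id": s.id, "subpopulation": s.subpopulation} for s in samples],
        columns=["sample_id", "subpopulation"],
    ).to_csv(path, sep="\t", index=False)


def write_kinship(path: str | Path, graph: nx.Graph) -> None:
    rows = [
        {"sample_a": a, "sample_b": b, "phi": data["phi"]}
        for a, b, data in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["sample_a", "sample_b", "phi"]).to_csv(
        path, sep="\t", index=False
    )


def write_phenotypes(path: str | Path, records: list[PhenotypeRecord]) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "ecg": r.ecg,
            "chest_pain": int(r.chest_pain),
            "parental_heart_disease": int(r.parental_heart_disease),
            "self_reported_conditions": ";".join(sorted(r.self_reported_conditions)),
        }
        for r in records
    ]
    cols = ["sample_id", "ecg", "chest_pain", "parental_heart_disease", "self_reported_conditions"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
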