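"""The secondary-findings gene panel.

The ACMG SF v2.0 panel lists 59 genes in which pathogenic variants are
medically actionable and should be reported as secondary findings. Each
gene belongs to exactly one of five disease categories (cardiovascular,
cancers, familial hypercholesteremia, malignant hyperthermia, others) and
carries one or more coding intervals used for positional filtering.

The mapping and intervals are data, not code: a default config ships with
the package (``data/acmg59_panel.yaml`` plus a companion BED of synthetic
stand-in coding intervals), and any compatible config can be substituted.
Coordinates are half-open and 0-based internally; BED is read as-is, VCF
positions are converted from 1-based on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import PanelValidationError, UnknownGeneError

CATEGORIES = frozenset(
    {
        "cardiovascular",
        "cancers",
        "familial_hypercholesteremia",
        "malignant_hyperthermia",
        "others",
    }
)

Interval = tuple[str, int, int]  # (chrom, start, end), half-open 0-based


@dataclass(frozen=True)
class GenePanel:
    """Validated gene panel: symbols, coding intervals, disease categories."""

    genes: frozenset[str]
    intervals: dict[str, list[Interval]]
    categories: dict[str, str]
    _by_chrom: dict[str, list[tuple[int, int, str]]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for gene, ivs in self.intervals.items():
            for chrom, start, end in ivs:
                by_chrom.setdefault(chrom, []).append((start, end, gene))
        for lst in by_chrom.values():
            lst.sort()
        object.__setattr__(self, "_by_chrom", by_chrom)

    def category_of(self, gene: str) -> str:
        """Return the single disease category for ``gene``."""
        try:
            return self.categories[gene]
        except KeyError:
            raise UnknownGeneError(f"gene {gene!r} is not in the panel") from None

    def covers(self, chrom: str, pos: int) -> bool:
        """True if 0-based ``pos`` falls inside any panel interval."""
        return any(start <= pos < end for start, end, _ in self._by_chrom.get(chrom, ()))

    def genes_at(self, chrom: str, pos: int) -> set[str]:
        return {g for start, end, g in self._by_chrom.get(chrom, ()) if start <= pos < end}

    def genes_in_category(self, category: str) -> set[str]:
        return {g for g, c in self.categories.items() if c == category}


def _read_bed(bed_path: Path) -> dict[str, list[Interval]]:
    intervals: dict[str, list[Interval]] = {}
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PanelValidationError(
                    f"{bed_path}:{lineno}: need chrom/start/end/gene, got {line!r}"
                )
            chrom, start_s, end_s, gene = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise PanelValidationError(
                    f"{bed_path}:{lineno}: non-integer coordinates in {line!r}"
                ) from None
            if start >= end:
                raise PanelValidationError(
                    f"{bed_path}:{lineno}: degenerate interval start >= end "
                    f"for gene {gene} ({start} >= {end})"
                )
            intervals.setdefault(gene, []).append((chrom, start, end))
    return intervals


def load_gene_panel(config_path: str | Path) -> GenePanel:
    """Load and validate a gene-panel config.

    ``config_path`` is a YAML file with a ``genes`` mapping (symbol ->
    category) and an ``intervals_bed`` entry naming a BED file, resolved
    relative to the config. Every gene must have exactly one category from
    the five-way vocabulary and at least one interval with start < end.

    Raises
    ------
    PanelValidationError
        Naming the offending gene, category, or interval.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "genes" not in raw:
        raise PanelValidationError(f"{config_path}: expected a mapping with a 'genes' key")
    genes_map = raw["genes"]
    if not isinstance(genes_map, dict) or not genes_map:
        raise PanelValidationError(f"{config_path}: 'genes' must be a non-empty mapping")
    categories: dict[str, str] = {}
    for gene, category in genes_map.items():
        if category is None:
            raise PanelValidationError(f"{config_path}: gene {gene} lacks a category")
        if category not in CATEGORIES:
            raise PanelValidationError(
                f"{config_path}: gene {gene} has unknown category {category!r} "
                f"(allowed: {sorted(CATEGORIES)})"
            )
        categories[str(gene)] = category

    bed_name = raw.get("intervals_bed")
    if not bed_name:
        raise PanelValidationError(f"{config_path}: missing 'intervals_bed' entry")
    bed_path = Path(bed_name)
    if not bed_path.is_absolute():
        bed_path = config_path.parent / bed_path
    intervals = _read_bed(bed_path)

    for gene in categories:
        if gene not in intervals:
            raise PanelValidationError(f"{config_path}: gene {gene} has no interval in {bed_path}")
    extra = set(intervals) - set(categories)
    if extra:
        raise PanelValidationError(
            f"{bed_path}: interval genes absent from the panel config: {sorted(extra)}"
        )
    return GenePanel(
        genes=frozenset(categories),
        intervals={g: intervals[g] for g in categories},
        categories=categories,
    )


def default_panel() -> GenePanel:
    """The shipped 59-gene ACMG SF v2.0 panel."""
    data_dir = resources.files("acmgsf") / "data"
    return load_gene_panel(Path(str(data_dir)) / "acmg59_panel.yaml")


def category_of(panel: GenePanel, gene: str) -> str:
    """Functional alias for :meth:`GenePanel.category_of`."""
    return panel.category_of(gene)
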