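"""The novel-variant prioritization cascade.

Eight ordered stages reduce an annotated cohort callset to rare,
previously unreported, predicted-deleterious variants with independent
segregation support:

1. panel       -- position inside a panel coding interval, gene on panel
2. novelty     -- absent from all eight databases (dbSNP, gnomAD, TOPMed,
                  1000G, ExAC, GME, HGMD, ClinVar)
3. deleterious -- CADD >= 20 and GERP >= 3 (inclusive)
4. frequency   -- folded cohort MAF = min(AC, AN-AC)/AN < 0.001 strict
5. singleton   -- cohort alt allele count >= 2
6. unrelated   -- carriers include >= 2 pairwise-unrelated participants
                  (kinship phi <= threshold, default 0.0884, the
                  3rd-degree cut-off of the KING threshold family)
7. impact/effect -- MODERATE impact; intron and loss-of-function
                  consequences removed

Each stage is a pure predicate over the variant plus cohort surfaces, so
the final surviving set is the intersection of all predicates and is
invariant to stage order; the order above (the narrative order of the
original analysis) matters only for the per-stage funnel counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .cohort_io import DB_NAMES, GenotypeMatrix, VariantKey, VariantRecord
from .errors import MissingFlagError, MissingScoreError
from .panel import GenePanel

log = logging.getLogger(__name__)

#: loss-of-function consequence terms removed at the impact/effect stage
LOF_EFFECTS = frozenset(
    {
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
    }
)

#: consequence vocabulary we recognise; unknown terms are kept with a warning
KNOWN_EFFECTS = LOF_EFFECTS | {
    "missense_variant",
    "synonymous_variant",
    "intron_variant",
    "splice_region_variant",
    "inframe_insertion",
    "inframe_deletion",
    "protein_altering_variant",
    "stop_retained_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
}

#: default kinship cut-off below which two samples count as unrelated
PHI_UNRELATED = 0.0884

STAGE_NAMES = (
    "panel",
    "novelty",
    "deleterious",
    "frequency",
    "singleton",
    "unrelated",
    "impact_effect",
)


@dataclass(frozen=True)
class CascadeParams:
    """Thresholds of the cascade; defaults are the published criteria."""

    cadd_min: float = 20.0
    gerp_min: float = 3.0
    maf_max: float = 0.001
    min_ac: int = 2
    phi_threshold: float = PHI_UNRELATED


# ---------------------------------------------------------------------------
# stage predicates / filters
# ---------------------------------------------------------------------------


def filter_panel_region(variants: list[VariantRecord], panel: GenePanel) -> list[VariantRecord]:
    """Keep variants inside any panel coding interval whose gene is on panel."""
    return [v for v in variants if v.gene in panel.genes and panel.covers(v.chrom, v.pos)]


def filter_novel(variants: list[VariantRecord]) -> list[VariantRecord]:
    """Keep variants absent from all eight databases.

    Membership in any single database disqualifies. Unpopulated flags are
    an error: novelty is a conjunction over definite booleans, not a
    three-valued logic.
    """
    out = []
    for v in variants:
        if v.db_membership is None or set(v.db_membership) != set(DB_NAMES):
            raise MissingFlagError(f"{v.label}: database-membership flags unpopulated")
        if not any(v.db_membership.values()):
            out.append(v)
    return out


def filter_deleterious(
    variants: list[VariantRecord], params: CascadeParams = CascadeParams()
) -> list[VariantRecord]:
    """Keep predicted-deleterious variants: CADD >= 20 and GERP >= 3, inclusive."""
    out = []
    for v in variants:
        if v.cadd is None or v.gerp is None:
            raise MissingScoreError(f"{v.label}: CADD/GERP score missing")
        if v.cadd >= params.cadd_min and v.gerp >= params.gerp_min:
            out.append(v)
    return out


def folded_maf(ac: int, an: int) -> float:
    return min(ac, an - ac) / an


def filter_frequency(
    variants: list[VariantRecord],
    genotypes: GenotypeMatrix,
    params: CascadeParams = CascadeParams(),
) -> list[VariantRecord]:
    """Keep cohort-rare variants: folded MAF < ``maf_max`` (strict).

    AN counts non-missing alleles only; a variant with AN = 0 is dropped
    with a warning rather than dividing by zero.
    """
    out = []
    for v in variants:
        ac, an = genotypes.allele_counts(v.key)
        if an == 0:
            log.warning("%s: all genotypes missing (AN=0); dropped at frequency stage", v.label)
            continue
        if folded_maf(ac, an) < params.maf_max:
            out.append(v)
    return out


def filter_singletons(
    variants: list[VariantRecord],
    genotypes: GenotypeMatrix,
    params: CascadeParams = CascadeParams(),
) -> list[VariantRecord]:
    """Remove single-allele-count variants: keep cohort alt AC >= 2.

    Note AC semantics: a single homozygote has AC = 2 and survives this
    stage (it is removed later for lacking two unrelated carriers).
    """
    return [v for v in variants if genotypes.allele_counts(v.key)[0] >= params.min_ac]


def _related_subgraph(
    carriers: list[str], kinship: nx.Graph, phi_threshold: float
) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(carriers)
    absent = [c for c in carriers if c not in kinship]
    if absent:
        log.warning(
            "%d carrier(s) absent from the kinship table; treated as unrelated to all",
            len(absent),
        )
    for a, b in combinations(carriers, 2):
        if kinship.has_edge(a, b) and kinship[a][b]["phi"] > phi_threshold:
            g.add_edge(a, b)
    return g


def max_unrelated_set(
    carriers: list[str], kinship: nx.Graph, phi_threshold: float = PHI_UNRELATED
) -> list[str]:
    """A maximum set of pairwise-unrelated carriers.

    Exact (maximum independent set of the relatedness graph, via cliques
    of its complement) for <= 20 carriers; deterministic greedy
    (lowest-degree-first, lexicographic tie-break) above, which is
    sufficient for the cascade's size >= 2 question.
    """
    g = _related_subgraph(carriers, kinship, phi_threshold)
    if len(carriers) <= 20:
        comp = nx.complement(g)
        best: list[str] = []
        for clique in nx.find_cliques(comp) if comp.number_of_nodes() else []:
            if len(clique) > len(best):
                best = clique
        return sorted(best)
    chosen: list[str] = []
    for node in sorted(g.nodes, key=lambda n: (g.degree(n), n)):
        if all(not g.has_edge(node, c) for c in chosen):
            chosen.append(node)
    return sorted(chosen)


def has_unrelated_pair(
    carriers: list[str], kinship: nx.Graph, phi_threshold: float = PHI_UNRELATED
) -> bool:
    """True iff some pair of carriers has kinship phi <= threshold.

    Equivalent to an independent set of size >= 2 existing in the
    relatedness graph (edge iff phi > threshold): such a set exists iff
    the carrier graph is not complete.
    """
    if len(carriers) < 2:
        return False
    g = _related_subgraph(carriers, kinship, phi_threshold)
    n = g.number_of_nodes()
    return g.number_of_edges() < n * (n - 1) // 2


def filter_unrelated_carriers(
    variants: list[VariantRecord],
    genotypes: GenotypeMatrix,
    kinship: nx.Graph,
    phi_threshold: float = PHI_UNRELATED,
) -> list[VariantRecord]:
    """Keep variants carried by at least two pairwise-unrelated participants."""
    out = []
    for v in variants:
        carriers = genotypes.carriers(v.key)
        if has_unrelated_pair(carriers, kinship, phi_threshold):
            out.append(v)
    return out


def filter_impact_effect(variants: list[VariantRecord]) -> list[VariantRecord]:
    """Keep MODERATE-impact variants, removing intron and LoF consequences.

    An unrecognised consequence term is kept (impact permitting) with a
    logged warning rather than silently dropped.
    """
    removed_effects = LOF_EFFECTS | {"intron_variant"}
    out = []
    for v in variants:
        if v.effect not in KNOWN_EFFECTS:
            log.warning("%s: unknown consequence term %r; kept", v.label, v.effect)
        if v.impact == "MODERATE" and v.effect not in removed_effects:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# cascade driver
# ---------------------------------------------------------------------------


@dataclass
class FilterFunnel:
    """Per-stage survivor counts plus the final surviving key set.

    ``sole_failure`` gives marginal attribution: for each stage, the
    number of initial variants that fail that predicate and no other.
    """

    initial: int
    stages: list[tuple[str, int]]
    final_keys: list[VariantKey]
    sole_failure: dict[str, int] = field(default_factory=dict)

    @property
    def drops(self) -> dict[str, int]:
        counts = {}
        prev = self.initial
        for name, n in self.stages:
            counts[name] = prev - n
            prev = n
        return counts

    def to_records(self) -> list[dict]:
        rows = [{"stage": "input", "surviving": self.initial, "dropped": 0, "sole_failure": 0}]
        prev = self.initial
        for name, n in self.stages:
            rows.append(
                {
                    "stage": name,
                    "surviving": n,
                    "dropped": prev - n,
                    "sole_failure": self.sole_failure.get(name, 0),
                }
            )
            prev = n
        return rows


def stage_predicates(
    variants: list[VariantRecord],
    genotypes: GenotypeMatrix,
    kinship: nx.Graph,
    panel: GenePanel,
    params: CascadeParams = CascadeParams(),
) -> dict[str, set[VariantKey]]:
    """Evaluate every stage predicate independently over all variants.

    Returns, per stage name, the set of variant keys passing that single
    predicate regardless of the others. Used for marginal attribution and
    as the order-invariance cross-check inside :func:`run_cascade`.
    """
    p = params
    return {
        "panel": {v.key for v in filter_panel_region(variants, panel)},
        "novelty": {v.key for v in filter_novel(variants)},
        "deleterious": {v.key for v in filter_deleterious(variants, p)},
        "frequency": {v.key for v in filter_frequency(variants, genotypes, p)},
        "singleton": {v.key for v in filter_singletons(variants, genotypes, p)},
        "unrelated": {
            v.key for v in filter_unrelated_carriers(variants, genotypes, kinship, p.phi_threshold)
        },
        "impact_effect": {v.key for v in filter_impact_effect(variants)},
    }


def run_cascade(
    variants: list[VariantRecord],
    genotypes: GenotypeMatrix,
    kinship: nx.Graph,
    panel: GenePanel,
    params: CascadeParams = CascadeParams(),
) -> FilterFunnel:
    """Apply all stages in order and report the funnel.

    The returned funnel's final key set equals the intersection of the
    independent stage predicates (asserted internally), so permuting
    stages changes only the per-stage counts, never the outcome.
    """
    passing = stage_predicates(variants, genotypes, kinship, panel, params)

    surviving = list(variants)
    stages: list[tuple[str, int]] = []
    for name in STAGE_NAMES:
        surviving = [v for v in surviving if v.key in passing[name]]
        stages.append((name, len(surviving)))
        log.info("cascade stage %-13s -> %d surviving", name, len(surviving))

    final = {v.key for v in surviving}
    intersection = set(v.key for v in variants)
    for keys in passing.values():
        intersection &= keys
    assert final == intersection, "sequential cascade diverged from predicate intersection"

    sole: dict[str, int] = {name: 0 for name in STAGE_NAMES}
    for v in variants:
        failed = [name for name in STAGE_NAMES if v.key not in passing[name]]
        if len(failed) == 1:
            sole[failed[0]] += 1

    return FilterFunnel(
        initial=len(variants),
        stages=stages,
        final_keys=[v.key for v in surviving],
        sole_failure=sole,
    )
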