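"""Independent brute-force oracles and random in-memory bundle generation.

The predicates here are deliberately written as plain loops over the raw
records — no reuse of the cascade module — so they can serve as an
independent re-implementation to check the cascade against.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np

from acmgsf.cohort_io import DB_NAMES, GenotypeMatrix, VariantRecord
from acmgsf.panel import GenePanel

# ---------------------------------------------------------------------------
# brute-force cascade predicates
# ---------------------------------------------------------------------------

_LOF = {
    "stop_gained", "stop_lost", "start_lost", "frameshift_variant",
    "splice_acceptor_variant", "splice_donor_variant",
}


def bf_panel(v: VariantRecord, panel: GenePanel) -> bool:
    if v.gene not in panel.genes:
        return False
    for ivs in panel.intervals.values():
        for chrom, start, end in ivs:
            if chrom == v.chrom and start <= v.pos < end:
                return True
    return False


def bf_novel(v: VariantRecord) -> bool:
    return not any(v.db_membership[name] for name in DB_NAMES)


def bf_deleterious(v: VariantRecord, cadd_min: float, gerp_min: float) -> bool:
    return v.cadd >= cadd_min and v.gerp >= gerp_min


def _ac_an(v, matrix: GenotypeMatrix):
    ac = an = 0
    j = matrix.variants.index(v.key)
    for i in range(len(matrix.samples)):
        d = int(matrix.calls[i, j])
        if d >= 0:
            ac += d
            an += 2
    return ac, an


def bf_frequency(v, matrix, maf_max: float) -> bool:
    ac, an = _ac_an(v, matrix)
    if an == 0:
        return False
    return min(ac, an - ac) / an < maf_max


def bf_singleton(v, matrix, min_ac: int) -> bool:
    return _ac_an(v, matrix)[0] >= min_ac


def bf_unrelated(v, matrix, kinship: nx.Graph, phi_threshold: float) -> bool:
    j = matrix.variants.index(v.key)
    carriers = [s for i, s in enumerate(matrix.samples) if matrix.calls[i, j] >= 1]
    for x in range(len(carriers)):
        for y in range(x + 1, len(carriers)):
            a, b = carriers[x], carriers[y]
            phi = kinship[a][b]["phi"] if kinship.has_edge(a, b) else 0.0
            if phi <= phi_threshold:
                return True
    return False


def bf_impact_effect(v: VariantRecord) -> bool:
    return v.impact == "MODERATE" and v.effect not in (_LOF | {"intron_variant"})


def bf_surviving_keys(variants, matrix, kinship, panel, params) -> set:
    """The final set by independent per-predicate evaluation."""
    out = set()
    for v in variants:
        if (
            bf_panel(v, panel)
            and bf_novel(v)
            and bf_deleterious(v, params.cadd_min, params.gerp_min)
            and bf_frequency(v, matrix, params.maf_max)
            and bf_singleton(v, matrix, params.min_ac)
            and bf_unrelated(v, matrix, kinship, params.phi_threshold)
            and bf_impact_effect(v)
        ):
            out.add(v.key)
    return out


def bf_max_independent_set(nodes: list[str], edges: set[frozenset]) -> int:
    """Exhaustive maximum independent set size for small graphs."""
    best = 0
    n = len(nodes)
    for mask in range(1 << n):
        chosen = [nodes[i] for i in range(n) if mask >> i & 1]
        if all(
            frozenset((a, b)) not in edges
            for i, a in enumerate(chosen)
            for b in chosen[i + 1 :]
        ):
            best = max(best, len(chosen))
    return best


# ---------------------------------------------------------------------------
# exact Fisher oracle
# ---------------------------------------------------------------------------


def fisher_two_sided_fraction(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p as an exact rational, by full enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return Fraction(1)
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom) for x in range(lo, hi + 1)}
    obs = probs[a]
    return sum((p for p in probs.values() if p <= obs), Fraction(0))


# ---------------------------------------------------------------------------
# random in-memory bundles
# ---------------------------------------------------------------------------


def random_bundle(
    rng: np.random.Generator,
    panel: GenePanel,
    n_samples: int = 40,
    n_variants: int = 80,
):
    """A random annotated cohort: variants, genotypes, kinship.

    Fields are drawn so every cascade predicate has both passing and
    failing mass: genes on and off the panel, positions inside and
    outside intervals, scores straddling the thresholds, dosage columns
    with missingness, and a random relatedness graph.
    """
    samples = [f"R{i:03d}" for i in range(n_samples)]
    genes = sorted(panel.genes)
    effects = [
        "missense_variant", "intron_variant", "stop_gained", "synonymous_variant",
        "frameshift_variant", "splice_region_variant",
    ]
    impacts = ["HIGH", "MODERATE", "LOW", "MODIFIER"]

    variants: list[VariantRecord] = []
    used = set()
    for _ in range(n_variants):
        if rng.random() < 0.85:
            gene = genes[rng.integers(len(genes))]
            ivs = panel.intervals[gene]
            chrom, start, end = ivs[rng.integers(len(ivs))]
            pos = int(rng.integers(start - 50, end + 50))  # sometimes just outside
        else:
            gene, chrom, pos = "NOTONPANEL", "3", int(rng.integers(1, 1_000_000))
        while (chrom, pos) in used:
            pos += 1
        used.add((chrom, pos))
        ref = "ACGT"[rng.integers(4)]
        alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
        flags = {name: bool(rng.random() < 0.08) for name in DB_NAMES}
        variants.append(
            VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                effect=effects[rng.integers(len(effects))],
                impact=impacts[rng.integers(len(impacts))],
                cadd=float(np.round(rng.uniform(0, 45), 2)),
                gerp=float(np.round(rng.uniform(-6, 7), 2)),
                db_membership=flags,
            )
        )
    variants.sort(key=lambda v: (v.chrom, v.pos))

    calls = np.zeros((n_samples, n_variants), dtype=np.int8)
    for j in range(n_variants):
        k = int(rng.integers(0, 6))
        for i in rng.choice(n_samples, size=k, replace=False):
            calls[i, j] = int(rng.integers(1, 3))
        n_miss = int(rng.integers(0, 3))
        for i in rng.choice(n_samples, size=n_miss, replace=False):
            calls[i, j] = -1
    matrix = GenotypeMatrix(samples, [v.key for v in variants], calls)

    kinship = nx.Graph()
    kinship.add_nodes_from(samples)
    for _ in range(int(rng.integers(0, n_samples))):
        i, j = rng.choice(n_samples, size=2, replace=False)
        phi = float(rng.choice([0.03, 0.0884, 0.125, 0.25, 0.5]))
        kinship.add_edge(samples[i], samples[j], phi=phi)
    return variants, matrix, kinship
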