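import numpy as np
import networkx as nx
import pytest

from acmgsf.cascade import (
    CascadeParams,
    STAGE_NAMES,
    filter_deleterious,
    filter_frequency,
    filter_impact_effect,
    filter_novel,
    filter_panel_region,
    filter_singletons,
    filter_unrelated_carriers,
    has_unrelated_pair,
    max_unrelated_set,
    run_cascade,
    stage_predicates,
)
from acmgsf.cohort_io import DB_NAMES, GenotypeMatrix, VariantRecord
from acmgsf.errors import MissingFlagError, MissingScoreError
from oracle_utils import bf_max_independent_set, bf_surviving_keys, random_bundle


def make_variant(pos=5_000_100, chrom="6", gene="DSP", cadd=24.5, gerp=5.79,
                 effect="missense_variant", impact="MODERATE", flags=None, ref="A", alt="G"):
    membership = {name: False for name in DB_NAMES}
    membership.update(flags or {})
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                         effect=effect, impact=impact, cadd=cadd, gerp=gerp,
                         db_membership=membership)


def matrix_for(dosage_rows, samples=None):
    """One variant per row of ``dosage_rows``; column order = row order."""
    arr = np.array(dosage_rows, dtype=np.int8).T
    samples = samples or [f"S{i}" for i in range(arr.shape[0])]
    keys = [("6", 5_000_100 + j, "A", "G") for j in range(arr.shape[1])]
    return GenotypeMatrix(samples, keys, arr), keys


# --- panel stage -----------------------------------------------------------


def test_panel_stage_boundary_semantics(panel):
    chrom, start, end = panel.intervals["DSP"][0]
    inside = make_variant(pos=end - 1, chrom=chrom)
    past_end = make_variant(pos=end, chrom=chrom)
    off_gene = make_variant(pos=end - 1, chrom=chrom, gene="NOTAPANELGENE")
    kept = filter_panel_region([inside, past_end, off_gene], panel)
    assert inside in kept and off_gene not in kept
    # half-open: 1 bp past the end is out unless another interval covers it
    assert (past_end in kept) == panel.covers(chrom, end)


# --- novelty stage ---------------------------------------------------------


def test_novelty_any_membership_disqualifies():
    clean = make_variant()
    hgmd_only = make_variant(pos=1, flags={"hgmd": True})
    assert filter_novel([clean, hgmd_only]) == [clean]


def test_novelty_requires_populated_flags():
    stub = VariantRecord("6", 5, "A", "G")
    with pytest.raises(MissingFlagError):
        filter_novel([stub])


def test_novelty_matches_conjunction_oracle():
    rng = np.random.default_rng(7)
    variants = [
        make_variant(pos=i, flags={n: bool(rng.random() < 0.3) for n in DB_NAMES})
        for i in range(200)
    ]
    kept = filter_novel(variants)
    expected = [v for v in variants if not any(v.db_membership.values())]
    assert kept == expected


# --- deleteriousness stage -------------------------------------------------


@pytest.mark.parametrize(
    "cadd,gerp,kept",
    [
        (24.5, 5.79, True),   # published DSP scores
        (25.9, 4.9, True),    # published LMNA scores
        (20.0, 3.0, True),    # inclusive boundary
        (19.99, 5.0, False),
        (30.0, 2.99, False),
    ],
)
def test_deleterious_thresholds_inclusive(cadd, gerp, kept):
    v = make_variant(cadd=cadd, gerp=gerp)
    assert (filter_deleterious([v]) == [v]) is kept


def test_deleterious_missing_score_raises():
    v = VariantRecord("6", 5, "A", "G", gene="DSP",
                      db_membership={n: False for n in DB_NAMES})
    with pytest.raises(MissingScoreError):
        filter_deleterious([v])


# --- frequency / singleton stages -----------------------------------------


def test_frequency_examples_at_cohort_scale():
    # AC 2 / AN 12000 -> 1.67e-4 kept; AC 13 -> 1.08e-3 dropped; AC 0 kept
    n = 6000
    rows = []
    for ac in (2, 13, 0):
        row = [0] * n
        for i in range(ac):
            row[i] = 1
        rows.append(row)
    matrix, keys = matrix_for(rows)
    variants = [make_variant(pos=100 + j) for j in range(3)]
    for v, k in zip(variants, keys):
        v.pos = k[1]
    kept = filter_frequency(variants, matrix)
    assert [v.key for v in kept] == [keys[0], keys[2]]


def test_frequency_all_missing_dropped_with_warning(caplog):
    matrix, keys = matrix_for([[-1, -1, -1]])
    v = make_variant(pos=keys[0][1])
    with caplog.at_level("WARNING"):
        assert filter_frequency([v], matrix) == []
    assert "AN=0" in caplog.text


def test_singleton_allele_count_semantics():
    rows = [
        [1, 0, 0],  # one het: AC 1, dropped
        [2, 0, 0],  # one hom: AC 2, kept at this stage
        [1, 1, 0],  # two hets: AC 2, kept
    ]
    matrix, keys = matrix_for(rows)
    variants = [make_variant(pos=k[1]) for k in keys]
    kept = filter_singletons(variants, matrix)
    assert [v.key for v in kept] == keys[1:]


# --- unrelated-carriers stage ----------------------------------------------


def kin(*edges):
    g = nx.Graph()
    for a, b, phi in edges:
        g.add_edge(a, b, phi=phi)
    return g


def test_unrelated_pair_logic():
    g = kin(("A", "B", 0.25))
    assert not has_unrelated_pair(["A", "B"], g)          # only related carriers
    assert has_unrelated_pair(["A", "B", "C"], g)         # {A,C} or {B,C}
    assert not has_unrelated_pair(["A"], g)               # single carrier
    assert has_unrelated_pair(["A", "B"], g, phi_threshold=0.3)  # threshold configurable


def test_carrier_absent_from_kinship_treated_unrelated(caplog):
    g = kin(("A", "B", 0.25))
    with caplog.at_level("WARNING"):
        assert has_unrelated_pair(["A", "X"], g)
    assert "absent" in caplog.text


def test_filter_unrelated_carriers_end_to_end():
    rows = [[1, 1, 0, 0], [1, 0, 0, 1]]
    matrix, keys = matrix_for(rows, samples=["A", "B", "C", "D"])
    variants = [make_variant(pos=k[1]) for k in keys]
    g = kin(("A", "B", 0.25))
    kept = filter_unrelated_carriers(variants, matrix, g)
    assert [v.key for v in kept] == [keys[1]]  # A,D unrelated; A,B related


def test_max_unrelated_set_matches_bruteforce():
    rng = np.random.default_rng(5)
    for _ in range(50):
        n = int(rng.integers(2, 9))
        nodes = [f"C{i}" for i in range(n)]
        g = nx.Graph()
        g.add_nodes_from(nodes)
        edges = set()
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.4:
                    g.add_edge(nodes[i], nodes[j], phi=0.25)
                    edges.add(frozenset((nodes[i], nodes[j])))
        got = max_unrelated_set(nodes, g)
        assert len(got) == bf_max_independent_set(nodes, edges)


# --- impact/effect stage ----------------------------------------------------


@pytest.mark.parametrize(
    "effect,impact,kept",
    [
        ("missense_variant", "MODERATE", True),
        ("stop_gained", "HIGH", False),
        ("intron_variant", "MODIFIER", False),
        ("synonymous_variant", "LOW", False),
        ("inframe_deletion", "MODERATE", True),
        ("frameshift_variant", "MODERATE", False),  # LoF removed regardless
    ],
)
def test_impact_effect_rules(effect, impact, kept):
    v = make_variant(effect=effect, impact=impact)
    assert (filter_impact_effect([v]) == [v]) is kept


def test_unknown_effect_term_kept_with_warning(caplog):
    v = make_variant(effect="weird_consequence", impact="MODERATE")
    with caplog.at_level("WARNING"):
        assert filter_impact_effect([v]) == [v]
    assert "weird_consequence" in caplog.text


# --- cascade driver ---------------------------------------------------------


def test_empty_input_gives_funnel_of_zeros(panel):
    matrix = GenotypeMatrix([], [], np.empty((0, 0), dtype=np.int8))
    funnel = run_cascade([], matrix, nx.Graph(), panel)
    assert funnel.initial == 0
    assert all(n == 0 for _, n in funnel.stages)
    assert funnel.final_keys == []


def test_funnel_monotone_and_matches_oracle_on_random_bundles(panel):
    rng = np.random.default_rng(2024)
    for rep in range(15):
        variants, matrix, kinship = random_bundle(rng, panel, n_samples=30, n_variants=60)
        params = CascadeParams(maf_max=float(rng.choice([0.01, 0.05, 0.2])))
        funnel = run_cascade(variants, matrix, kinship, panel, params)
        counts = [funnel.initial] + [n for _, n in funnel.stages]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert set(funnel.final_keys) == bf_surviving_keys(
            variants, matrix, kinship, panel, params
        )


def test_final_set_invariant_under_stage_permutation(panel):
    rng = np.random.default_rng(99)
    variants, matrix, kinship = random_bundle(rng, panel, n_samples=25, n_variants=50)
    params = CascadeParams(maf_max=0.05)
    passing = stage_predicates(variants, matrix, kinship, panel, params)
    reference = run_cascade(variants, matrix, kinship, panel, params).final_keys
    for _ in range(10):
        order = list(rng.permutation(list(STAGE_NAMES)))
        surviving = {v.key for v in variants}
        for name in order:
            surviving &= passing[name]
        assert surviving == set(reference)


def test_marginal_attribution_counts_sole_failures(panel):
    chrom, start, end = panel.intervals["DSP"][0]
    good = make_variant(pos=start, chrom=chrom)
    bad_cadd = make_variant(pos=start + 1, chrom=chrom, cadd=5.0)
    rows = [[1, 1, 0], [1, 0, 1]]
    matrix, keys = matrix_for(rows, samples=["A", "B", "C"])
    good.pos, bad_cadd.pos = keys[0][1], keys[1][1]
    # keys use pos offsets that fall inside the DSP interval window
    good = make_variant(pos=start, chrom=chrom)
    bad = make_variant(pos=start + 1, chrom=chrom, cadd=5.0)
    arr = np.array([[1, 1], [1, 0], [0, 1]], dtype=np.int8)
    matrix = GenotypeMatrix(["A", "B", "C"], [good.key, bad.key], arr)
    params = CascadeParams(maf_max=0.5)
    funnel = run_cascade([good, bad], matrix, nx.Graph(), panel, params)
    assert funnel.sole_failure["deleterious"] == 1
    assert set(funnel.final_keys) == {good.key}
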