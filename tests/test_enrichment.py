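import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lifecal as lc
from lifecal.datamodel import FeatureAnnotation
from lifecal.enrichment import SamplingGrid

from conftest import make_table


def exchangeable_scores(n=2000, seed=0):
    r = np.random.default_rng(seed)
    return pd.Series(r.exponential(1.0, n),
                     index=[f"g{i + 1:05d}" for i in range(n)])


# ---------------------------------------------------------------------------
# plain bootstrap
# ---------------------------------------------------------------------------

def test_target_equal_to_background_degenerate_p_one():
    scores = exchangeable_scores(100)
    res = lc.bootstrap_set_test(scores, list(scores.index), n_boot=50, seed=1)
    assert res.p_raw == 1.0
    assert "degenerate" in res.note


def test_top_scoring_target_attains_minimal_p():
    scores = exchangeable_scores(5000)
    target = list(scores.nlargest(50).index)
    res = lc.bootstrap_set_test(scores, target, n_boot=400, seed=2)
    assert res.p_raw == pytest.approx(1.0 / 401.0)


def test_unexpressed_target_members_dropped():
    scores = exchangeable_scores(200)
    target = list(scores.index[:20]) + ["not_expressed_1", "not_expressed_2"]
    res = lc.bootstrap_set_test(scores, target, n_boot=50, seed=3)
    assert res.observed_mean == pytest.approx(scores.iloc[:20].mean())


def test_empty_target_rejected():
    scores = exchangeable_scores(50)
    with pytest.raises(ValueError, match="empty"):
        lc.bootstrap_set_test(scores, ["nope"], n_boot=10, seed=0)


def test_identical_seed_reproduces_p_bitwise():
    scores = exchangeable_scores(500)
    target = list(scores.index[37:87])
    a = lc.bootstrap_set_test(scores, target, n_boot=300, seed=9)
    b = lc.bootstrap_set_test(scores, target, n_boot=300, seed=9)
    assert a.p_raw == b.p_raw and a.null_mean == b.null_mean


def test_null_p_values_roughly_uniform_quick():
    """Reduced-size calibration check (the full one runs in acceptance)."""
    scores = exchangeable_scores(800, seed=4)
    r = np.random.default_rng(5)
    pvals = [lc.bootstrap_set_test(scores, list(r.choice(scores.index, 40,
                                                         replace=False)),
                                   n_boot=200, seed=int(r.integers(2**31))).p_raw
             for _ in range(200)]
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# windows and per-set tests
# ---------------------------------------------------------------------------

def planted_window_table(n_bg=300, n_target=30, mu=24.0, sd=1.5, seed=0):
    r = np.random.default_rng(seed)
    bg_ages = r.uniform(1, 78, n_bg)
    t_ages = np.clip(r.normal(mu, sd, n_target), 1, 78)
    ages = np.r_[t_ages, bg_ages]
    table = make_table(ages, np.ones(len(ages)))
    target = list(table.table["feature_id"][:n_target])
    return table, target


def test_planted_window_recovered_and_centered():
    # n_boot must exceed n_ages/alpha for any age to clear Bonferroni
    table, target = planted_window_table()
    ali = lc.aliget_matrix(table)
    windows, per_age = lc.enrichment_windows(ali, target, n_boot=2000, seed=0)
    assert windows, "no significant window found"
    best = max(windows, key=lambda w: w.span)
    assert 24.0 in best
    # planted 24 +- 2 sd plus the exponential decay's bleed either side
    assert best.span <= 9.0


def test_window_shifts_with_the_planted_ages():
    table, target = planted_window_table(mu=28.0, seed=1)
    ali = lc.aliget_matrix(table)
    windows, _ = lc.enrichment_windows(ali, target, n_boot=2000, seed=1)
    best = max(windows, key=lambda w: w.span)
    assert abs(best.center - 28.0) <= 2.5


def test_deget_set_agrees_with_window_on_strong_signal():
    table, target = planted_window_table(seed=2)
    sets = lc.make_age_sets(table)
    deget = lc.deget_scores(table, sets)
    res = lc.deget_set_test(deget, target, n_boot=1000, seed=2)
    k = sets.set_of_age(24.0)
    assert res.loc[k, "significant"]
    assert res["significant"].sum() <= 3


def test_non_turning_target_scores_zero_in_every_set():
    table = make_table(np.random.default_rng(3).uniform(2, 70, 60),
                       n_simple=20)
    sets = lc.make_age_sets(table)
    deget = lc.deget_scores(table, sets)
    simple = list(table.table.loc[table.table["age"].isna(), "feature_id"])
    res = lc.deget_set_test(deget, simple, n_boot=200, seed=3)
    assert (res["observed_mean"] == 0).all()
    assert (res["p_raw"] > 0.5).all()


# ---------------------------------------------------------------------------
# matched bootstrap
# ---------------------------------------------------------------------------

def annotated_universe(n=1200, seed=6, confounded=False):
    r = np.random.default_rng(seed)
    genes = [f"g{i + 1:05d}" for i in range(n)]
    length = r.lognormal(8, 1, n)
    gc = r.uniform(0.3, 0.7, n)
    base = r.exponential(1.0, n)
    scores = base * (np.log(length) / 8.0) if confounded else base
    ann = FeatureAnnotation(pd.DataFrame(
        {"gene_symbol": genes, "transcript_length": length, "gc_content": gc},
        index=genes))
    return pd.Series(scores, index=genes), ann


def test_single_cell_grid_behaves_like_plain_bootstrap():
    scores, _ = annotated_universe()
    genes = scores.index
    grid = SamplingGrid(cell_of=pd.Series([(0, 0)] * len(genes), index=genes),
                        members={(0, 0): genes.to_numpy()})
    target = list(genes[:50])
    matched = lc.matched_bootstrap_test(scores, target, grid, n_boot=2000, seed=7)
    plain = lc.bootstrap_set_test(scores, target, n_boot=2000, seed=7)
    assert matched.null_mean == pytest.approx(plain.null_mean, rel=0.05)
    assert abs(matched.p_raw - plain.p_raw) < 0.05


def test_singleton_cell_forces_the_draw():
    scores, _ = annotated_universe(n=30)
    scores.iloc[29] = 100.0            # make the singleton's score dominate
    genes = scores.index
    cells = [(0, 0)] * 29 + [(9, 9)]
    grid = SamplingGrid(cell_of=pd.Series(cells, index=genes),
                        members={(0, 0): genes[:29].to_numpy(),
                                 (9, 9): genes[29:].to_numpy()})
    target = [genes[29], genes[0]]
    res = lc.matched_bootstrap_test(scores, target, grid, n_boot=500, seed=8)
    # the singleton enters every null list at its position, so every null
    # mean carries at least half its (dominant) score
    assert res.null_mean >= 50.0
    assert res.null_sd < 50.0


def test_matched_bootstrap_removes_length_confound():
    scores, ann = annotated_universe(confounded=True, seed=10)
    grid = SamplingGrid.from_annotation(ann, list(scores.index))
    r = np.random.default_rng(11)
    weights = ann.table["transcript_length"] / ann.table["transcript_length"].sum()
    p_plain, p_matched = [], []
    for k in range(60):
        target = list(r.choice(scores.index, 50, replace=False,
                               p=weights.to_numpy()))
        p_plain.append(lc.bootstrap_set_test(scores, target, n_boot=300,
                                             seed=k).p_raw)
        p_matched.append(lc.matched_bootstrap_test(scores, target, grid,
                                                   n_boot=300, seed=k).p_raw)
    # long-gene-biased targets inflate the plain test but not the matched one
    assert np.median(p_plain) < 0.25
    assert stats.kstest(p_matched, "uniform").pvalue > 0.01


def test_missing_annotation_in_grid_rejected():
    scores, ann = annotated_universe(n=50)
    grid = SamplingGrid.from_annotation(ann, list(scores.index[:40]))
    with pytest.raises(ValueError, match="grid cell"):
        lc.matched_bootstrap_test(scores, [scores.index[45]], grid,
                                  n_boot=10, seed=0)


# ---------------------------------------------------------------------------
# association shuffle test
# ---------------------------------------------------------------------------

def test_constant_z_is_exactly_degenerate():
    scores = exchangeable_scores(300, seed=12)
    assoc = lc.GeneAssociationTable(pd.DataFrame(
        {"zscore": np.ones(300)}, index=scores.index))
    res = lc.association_shuffle_test(scores, assoc, n_shuffle=200, seed=0)
    assert res.p_raw == 1.0


def test_shuffle_null_calibrated():
    scores = exchangeable_scores(500, seed=13)
    r = np.random.default_rng(14)
    pvals = []
    for k in range(150):
        assoc = lc.GeneAssociationTable(pd.DataFrame(
            {"zscore": r.standard_normal(500)}, index=scores.index))
        pvals.append(lc.association_shuffle_test(scores, assoc, n_shuffle=200,
                                                 seed=k).p_raw)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_shuffle_powered_under_linear_coupling():
    scores = exchangeable_scores(2000, seed=15)
    r = np.random.default_rng(16)
    hits = 0
    for k in range(30):
        z = scores.to_numpy() + r.standard_normal(2000)
        assoc = lc.GeneAssociationTable(pd.DataFrame({"zscore": z},
                                                     index=scores.index))
        hits += lc.association_shuffle_test(scores, assoc, n_shuffle=500,
                                            seed=k).p_raw < 0.01
    assert hits >= 27


def test_mhc_exclusion_applied():
    scores = exchangeable_scores(300, seed=17)
    spec = lc.SimulationSpec(seed=18, n_genes=300)
    assoc = lc.simulate_associations(spec, mhc_genes=list(scores.index[:50]))
    res = lc.association_shuffle_test(scores, assoc, n_shuffle=100, seed=0)
    assert res.note == "250 genes"


def test_too_few_matched_genes_rejected():
    scores = exchangeable_scores(50)
    assoc = lc.GeneAssociationTable(pd.DataFrame(
        {"zscore": np.zeros(50)}, index=scores.index))
    with pytest.raises(ValueError, match="matched"):
        lc.association_shuffle_test(scores, assoc, n_shuffle=10, seed=0)


# ---------------------------------------------------------------------------
# hypergeometric test
# ---------------------------------------------------------------------------

def test_hypergeometric_expected_count_closed_form():
    bg = [f"g{i}" for i in range(900)]
    res = lc.hypergeometric_test(bg[:99], bg[500:560], bg)
    assert res["expected"] == pytest.approx(99 * 60 / 900)


def test_target_equal_to_category_minimal_p():
    bg = [f"g{i}" for i in range(100)]
    cat = bg[:10]
    res = lc.hypergeometric_test(cat, cat, bg)
    assert res["p_value"] == pytest.approx(stats.hypergeom.sf(9, 100, 10, 10))
    assert res["observed"] == 10


def test_small_instance_matches_exhaustive_enumeration():
    """Brute-force oracle: enumerate all C(20, 6) draws."""
    bg = list(range(20))
    category = set(bg[:5])
    target = [0, 1, 2, 3, 10, 11]          # k = 4 hits
    res = lc.hypergeometric_test(target, category, bg)
    total = hits = 0
    for draw in itertools.combinations(bg, 6):
        total += 1
        hits += len(category.intersection(draw)) >= 4
    assert res["p_value"] == pytest.approx(hits / total)


def test_empty_background_rejected():
    with pytest.raises(ValueError, match="background"):
        lc.hypergeometric_test([1], [1], [])


# ---------------------------------------------------------------------------
# quantile-comparison data
# ---------------------------------------------------------------------------

def test_qq_shape_contract():
    scores = exchangeable_scores(400, seed=19)
    target = list(scores.index[:30])
    out = lc.qq_comparison_data(scores, target, n_lists=25, seed=20)
    assert len(out) == 30 * 25


def test_qq_random_target_scatters_about_identity():
    scores = exchangeable_scores(2000, seed=21)
    target = list(np.random.default_rng(22).choice(scores.index, 100,
                                                   replace=False))
    out = lc.qq_comparison_data(scores, target, n_lists=100, seed=23)
    above = (out["random_score"] > out["target_score"]).mean()
    # exchangeable, but correlated across ranks through the shared target
    assert 0.3 < above < 0.7


def test_qq_top_target_dominates_every_random_list():
    scores = exchangeable_scores(1000, seed=24)
    target = list(scores.nlargest(40).index)
    out = lc.qq_comparison_data(scores, target, n_lists=50, seed=25)
    assert (out["random_score"] <= out["target_score"] + 1e-12).all()
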