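import numpy as np
import pandas as pd
import pytest

import lifecal as lc
from lifecal.celltype import top_neuron_specific

from conftest import make_table

TYPES = ["pyramidal", "interneuron", "astrocyte", "microglia",
         "oligodendrocyte", "endothelial"]


def random_mean_expr(n=300, seed=0):
    r = np.random.default_rng(seed)
    return pd.DataFrame(r.gamma(2.0, 1.0, (n, len(TYPES))),
                        index=[f"g{i + 1:05d}" for i in range(n)], columns=TYPES)


# ---------------------------------------------------------------------------
# specificity
# ---------------------------------------------------------------------------

def test_single_type_gene_has_unit_specificity():
    me = pd.DataFrame([[3.0, 0, 0, 0, 0, 0]], index=["g"], columns=TYPES)
    spec = lc.compute_specificity(me)
    assert spec.values.loc["g", "pyramidal"] == 1.0
    assert spec.values.loc["g"].drop("pyramidal").sum() == 0.0


def test_uniform_expression_gives_equal_shares():
    me = pd.DataFrame([[2.0] * 6], index=["g"], columns=TYPES)
    assert np.allclose(lc.compute_specificity(me).values.loc["g"], 1 / 6)


def test_rows_sum_to_one_and_zero_rows_stay_zero():
    me = random_mean_expr()
    me.iloc[0] = 0.0
    spec = lc.compute_specificity(me)
    sums = spec.values.sum(axis=1).to_numpy()
    assert sums[0] == 0.0
    assert np.allclose(sums[1:], 1.0)


def test_negative_expression_rejected():
    me = random_mean_expr()
    me.iloc[1, 2] = -0.5
    with pytest.raises(ValueError, match="nonnegative"):
        lc.compute_specificity(me)


# ---------------------------------------------------------------------------
# directional target lists
# ---------------------------------------------------------------------------

def window_table(seed=1, n=100, n_up=60):
    """One hundred genes turning inside a single narrow window."""
    r = np.random.default_rng(seed)
    ages = r.uniform(24, 28, n)
    amps = np.abs(r.normal(1, 0.5, n)) + 0.01
    signs = np.r_[np.ones(n_up), -np.ones(n - n_up)]
    return make_table(ages, signs * amps)


def test_top_ten_percent_per_direction():
    table = window_table()
    # a single-window AgeSets stand-in: all genes in window 0
    from lifecal.scoring import AgeSets
    fids = table.turning["feature_id"]
    sets = AgeSets(edges=np.array([]), assignment=pd.Series(0, index=fids),
                   n_sets=1)
    spec = lc.compute_specificity(random_mean_expr(len(fids), seed=2).set_axis(fids))
    lists = lc.build_directional_lists(table, sets, spec)
    assert len(lists[(0, "upward")]) == 10
    assert len(lists[(0, "downward")]) == 10
    assert not set(lists[(0, "upward")]) & set(lists[(0, "downward")])


def test_all_upward_window_leaves_downward_empty():
    table = window_table(n_up=100)
    from lifecal.scoring import AgeSets
    fids = table.turning["feature_id"]
    sets = AgeSets(edges=np.array([]), assignment=pd.Series(0, index=fids), n_sets=1)
    spec = lc.compute_specificity(random_mean_expr(len(fids), seed=3).set_axis(fids))
    lists = lc.build_directional_lists(table, sets, spec)
    assert lists[(0, "downward")] == []


def test_list_members_outrank_non_members():
    table = window_table(seed=4)
    from lifecal.scoring import AgeSets
    fids = table.turning["feature_id"]
    sets = AgeSets(edges=np.array([]), assignment=pd.Series(0, index=fids), n_sets=1)
    spec = lc.compute_specificity(random_mean_expr(len(fids), seed=5).set_axis(fids))
    lists = lc.build_directional_lists(table, sets, spec)
    t = table.turning.set_index("feature_id")
    for direction, sign in (("upward", 1), ("downward", -1)):
        members = lists[(0, direction)]
        pool = t[t["pre_direction"] == direction]
        non = pool.drop(index=members)
        if members and len(non):
            assert (sign * t.loc[members, "delta_e"]).min() >= \
                (sign * non["delta_e"]).max() - 1e-12


# ---------------------------------------------------------------------------
# the enrichment test
# ---------------------------------------------------------------------------

def planted_spec(n=400, block=50, seed=6, boost=6.0):
    me = random_mean_expr(n, seed=seed)
    me.iloc[:block, me.columns.get_loc("pyramidal")] *= boost
    return lc.compute_specificity(me), list(me.index[:block])


def test_planted_markers_recovered():
    spec, markers = planted_spec()
    res = lc.ewce_test(markers[:50], list(spec.genes), spec, n_boot=1000, seed=0)
    assert res.table["d"].idxmax() == "pyramidal"
    assert res.table.at["pyramidal", "p_bonferroni"] < 0.05


def test_random_target_unenriched():
    spec, _ = planted_spec()
    r = np.random.default_rng(7)
    target = list(r.choice(spec.genes[60:], 40, replace=False))
    res = lc.ewce_test(target, list(spec.genes), spec, n_boot=1000, seed=1)
    assert (res.table["d"].abs() < 4).all()


def test_degenerate_null_flagged_as_zero():
    me = pd.DataFrame(np.ones((40, 6)), columns=TYPES,
                      index=[f"g{i}" for i in range(40)])
    spec = lc.compute_specificity(me)
    res = lc.ewce_test(list(spec.genes[:8]), list(spec.genes), spec,
                       n_boot=200, seed=2)
    assert (res.table["d"] == 0).all()
    assert set(res.degenerate_null) == set(TYPES)


def test_small_target_rejected():
    spec, markers = planted_spec()
    with pytest.raises(ValueError, match="too small"):
        lc.ewce_test(markers[:3], list(spec.genes), spec, n_boot=10, seed=0)


def test_d_invariant_to_constant_specificity_shift():
    spec, markers = planted_spec(seed=8)
    res1 = lc.ewce_test(markers[:40], list(spec.genes), spec, n_boot=500, seed=3)
    shifted = lc.SpecificityMatrix(spec.values + 0.25, kind="mean_expression")
    res2 = lc.ewce_test(markers[:40], list(spec.genes), shifted, n_boot=500, seed=3)
    assert np.allclose(res1.table["d"], res2.table["d"], atol=1e-9)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _fake_results(d_by_window):
    out = []
    for w, d in enumerate(d_by_window):
        table = pd.DataFrame({"d": [d], "p_raw": [0.5], "p_bonferroni": [1.0],
                              "normalized": [np.nan]}, index=["pyramidal"])
        out.append(lc.CellTypeEnrichment(w, "upward", table, 100))
    return out


def test_normalization_arithmetic():
    res = lc.normalize_enrichments(_fake_results([2.0, -4.0, 1.0]))
    assert [r.table.at["pyramidal", "normalized"] for r in res] == \
        pytest.approx([0.5, -1.0, 0.25])


def test_single_window_normalizes_to_unit():
    res = lc.normalize_enrichments(_fake_results([-1.7]))
    assert res[0].table.at["pyramidal", "normalized"] == pytest.approx(-1.0)


def test_normalization_scale_invariant():
    a = lc.normalize_enrichments(_fake_results([2.0, -4.0, 1.0]))
    b = lc.normalize_enrichments(_fake_results([6.0, -12.0, 3.0]))
    for ra, rb in zip(a, b):
        assert ra.table.at["pyramidal", "normalized"] == \
            pytest.approx(rb.table.at["pyramidal", "normalized"])


def test_all_zero_d_normalizes_to_zero():
    res = lc.normalize_enrichments(_fake_results([0.0, 0.0]))
    assert all(r.table.at["pyramidal", "normalized"] == 0.0 for r in res)


# ---------------------------------------------------------------------------
# neuron/glia restriction
# ---------------------------------------------------------------------------

NEURON = ["pyramidal", "interneuron"]
GLIA = ["astrocyte", "microglia", "oligodendrocyte", "endothelial"]


def test_neuron_only_gene_ranked_first():
    me = random_mean_expr(50, seed=9)
    me.loc[me.index[7], GLIA] = 0.0
    ratio = lc.neuron_glia_ratio(me, NEURON, GLIA)
    assert np.isinf(ratio.iloc[7])
    assert top_neuron_specific(ratio, 1) == [me.index[7]]


def test_equal_sums_give_ratio_one():
    me = pd.DataFrame([[1.0, 1.0, 0.5, 0.5, 0.5, 0.5]], index=["g"], columns=TYPES)
    assert lc.neuron_glia_ratio(me, NEURON, GLIA)["g"] == pytest.approx(1.0)


def test_planted_neuron_block_recovered_exactly():
    me = random_mean_expr(200, seed=10)
    block = list(me.index[30:70])
    me.loc[block, NEURON] *= 50.0
    ratio = lc.neuron_glia_ratio(me, NEURON, GLIA)
    assert set(top_neuron_specific(ratio, 40)) == set(block)


def test_unknown_cell_type_rejected():
    me = random_mean_expr(10, seed=11)
    with pytest.raises(ValueError, match="unknown cell types"):
        lc.neuron_glia_ratio(me, ["pyramidal"], ["nonexistent"])
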