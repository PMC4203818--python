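"""Frequency tables, contingency tests, AMOVA, F_ST, rank tests, FDR."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cyp2d6pop import (
    DiplotypeCall,
    activity_class_table,
    allele_frequencies,
    amova,
    bh_fdr,
    chi2_independence,
    g_test_independence,
    kruskal_wallis,
    mann_whitney,
    pairwise_fst,
    wc_theta,
)
from cyp2d6pop.popstats import _encode_pairs

from oracles import amova_oracle, wc_theta_oracle


def dip(i, a, b, cn=2):
    return DiplotypeCall(f"i{i}", a, b, cn)


# -- frequency tables --------------------------------------------------------


def test_single_individual_fifty_fifty():
    ft = allele_frequencies([dip(0, "*1", "*2")])
    assert ft.pct.loc["*1", "Total"] == pytest.approx(50.0)
    assert ft.pct.loc["*2", "Total"] == pytest.approx(50.0)


def test_percentages_close_per_stratum(preset_run):
    strata = {r.individual_id: r.region for r in preset_run.records}
    good = [c for c in preset_run.calls if not c.blocked]
    ft = allele_frequencies(good, strata)
    for col in ft.pct.columns:
        assert ft.pct[col].sum() == pytest.approx(100.0, abs=1e-9)
        assert ft.counts[col].sum() == ft.chromosomes[col]


def test_evaluable_denominator_identity(preset_run, defs):
    """Activity table denominator = 2N − ND-activity slots."""
    good = [c for c in preset_run.calls if not c.blocked]
    act = activity_class_table(good, defs)
    nd_slots = sum(
        1
        for c in good
        for s in c.slots
        if defs.classify_activity(s).value == "ND"
    )
    assert act.chromosomes["Total"] == 2 * len(good) - nd_slots


def test_all_normal_alleles():
    ft = allele_frequencies([dip(i, "*1", "*1") for i in range(5)])
    assert ft.pct.loc["*1", "Total"] == pytest.approx(100.0)


# -- contingency tests -------------------------------------------------------


def test_chi2_hand_computed_2x2():
    res = chi2_independence([[10, 20], [20, 10]])
    assert res.statistic == pytest.approx(20 / 3, abs=1e-9)
    assert res.df == 1


def test_chi2_proportional_rows_zero():
    res = chi2_independence([[10, 20], [20, 40]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_chi2_zero_margin_named():
    with pytest.raises(ValueError, match="column 1"):
        chi2_independence([[10, 0], [20, 0]])
    with pytest.raises(ValueError, match="row 0"):
        chi2_independence([[0, 0], [20, 10]])


def test_g_test_direct_evaluation():
    obs = np.array([[10.0, 20.0], [20.0, 10.0]])
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    g_hand = 2 * (obs * np.log(obs / expected)).sum()
    res = g_test_independence(obs)
    assert res.statistic == pytest.approx(g_hand, abs=1e-12)
    assert res.df == 1


def test_g_test_proportional_rows_zero():
    assert g_test_independence([[5, 10], [10, 20]]).statistic == pytest.approx(
        0.0, abs=1e-12
    )


def test_g_and_chi2_agree_asymptotically():
    rng = np.random.default_rng(4)
    for _ in range(5):
        table = rng.integers(15, 80, size=(3, 4))
        g = g_test_independence(table).statistic
        x2 = chi2_independence(table).statistic
        if x2 < 1e-6:
            continue
        assert abs(g - x2) / max(x2, g) < 0.15


# -- AMOVA -------------------------------------------------------------------


def test_amova_null_two_identical_groups():
    rng = np.random.default_rng(0)
    labels = np.array(["*1", "*2", "*4"])
    pairs = [tuple(labels[rng.choice(3, 2, p=[0.5, 0.3, 0.2])]) for _ in range(400)]
    groups = ["A"] * 200 + ["B"] * 200
    res = amova(pairs, groups, n_permutations=200, seed=1)
    assert res.pct_within > 99.0
    assert res.p_value > 0.01


def test_amova_fixed_difference():
    pairs = [("*1", "*1")] * 20 + [("*4", "*4")] * 20
    groups = ["A"] * 20 + ["B"] * 20
    res = amova(pairs, groups, n_permutations=99, seed=0)
    assert res.phi_st == pytest.approx(1.0)
    assert res.pct_among == pytest.approx(100.0)
    assert res.p_value < 0.05


def test_amova_matches_distance_matrix_oracle():
    rng = np.random.default_rng(7)
    labels = np.array(["*1", "*2", "*4", "*17"])
    pairs = [tuple(labels[rng.integers(0, 4, 2)]) for _ in range(30)]
    groups = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
    res = amova(pairs, groups, n_permutations=0, seed=0)
    sa, sw, phi = amova_oracle(pairs, groups)
    assert res.sigma_among == pytest.approx(sa, abs=1e-10)
    assert res.sigma_within == pytest.approx(sw, abs=1e-10)
    assert res.phi_st == pytest.approx(phi, abs=1e-10)
    assert res.pct_among + res.pct_within == pytest.approx(100.0, abs=1e-9)


def test_amova_requires_two_groups():
    with pytest.raises(ValueError):
        amova([("*1", "*1")] * 4, ["A"] * 4, n_permutations=0)


# -- Weir–Cockerham theta ----------------------------------------------------


def test_theta_matches_component_formula_oracle():
    rng = np.random.default_rng(3)
    labels = ["*1", "*2", "*4"]
    pa = [tuple(np.array(labels)[rng.choice(3, 2, p=[0.6, 0.3, 0.1])]) for _ in range(20)]
    pb = [tuple(np.array(labels)[rng.choice(3, 2, p=[0.3, 0.3, 0.4])]) for _ in range(20)]
    arr, _ = _encode_pairs(pa + pb)
    theta = wc_theta([arr[:20], arr[20:]])
    oracle = wc_theta_oracle([pa, pb])
    assert theta == pytest.approx(oracle, abs=1e-12)


def test_theta_fixed_difference_is_one():
    pa = [("*1", "*1")] * 15
    pb = [("*4", "*4")] * 15
    est = pairwise_fst(pa, pb, n_bootstrap=0)
    assert est.theta == pytest.approx(1.0)


def test_theta_monomorphic_is_zero_with_warning():
    pa = [("*1", "*1")] * 10
    pb = [("*1", "*1")] * 10
    with pytest.warns(UserWarning, match="monomorphic"):
        est = pairwise_fst(pa, pb, n_bootstrap=0)
    assert est.theta == 0.0


def test_identical_frequencies_theta_near_zero():
    rng = np.random.default_rng(9)
    labels = np.array(["*1", "*2", "*4"])
    p = [0.5, 0.3, 0.2]
    pa = [tuple(labels[rng.choice(3, 2, p=p)]) for _ in range(400)]
    pb = [tuple(labels[rng.choice(3, 2, p=p)]) for _ in range(400)]
    est = pairwise_fst(pa, pb, n_bootstrap=200, seed=0)
    assert abs(est.theta) < 0.01
    assert est.ci_low == 0.0  # truncated at zero


def test_fst_ci_orders_and_truncation(preset_run):
    strata = {r.individual_id: r.region for r in preset_run.records}
    by_group = {}
    for c in preset_run.calls:
        if c.blocked:
            continue
        by_group.setdefault(strata[c.individual_id], []).append(c.slots)
    regions = sorted(by_group)
    est = pairwise_fst(
        by_group[regions[0]], by_group[regions[1]], n_bootstrap=200, seed=3
    )
    assert est.ci_low <= est.ci_high
    assert est.ci_low >= 0.0


def test_amova_and_theta_coherent_on_two_groups():
    """Φ_ST and W&C θ agree in sign and within 0.02 for n ≥ 200."""
    rng = np.random.default_rng(21)
    labels = np.array(["*1", "*2", "*4", "*17"])
    p1 = [0.45, 0.30, 0.15, 0.10]
    p2 = [0.30, 0.30, 0.20, 0.20]
    pa = [tuple(labels[rng.choice(4, 2, p=p1)]) for _ in range(250)]
    pb = [tuple(labels[rng.choice(4, 2, p=p2)]) for _ in range(250)]
    res = amova(pa + pb, ["A"] * 250 + ["B"] * 250, n_permutations=0)
    est = pairwise_fst(pa, pb, n_bootstrap=0)
    assert abs(res.phi_st - est.theta) < 0.02
    assert math.copysign(1, res.phi_st) == math.copysign(1, est.theta)


# -- rank tests and FDR ------------------------------------------------------


def test_kruskal_wallis_hand_ranked():
    res = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
    assert res.statistic == pytest.approx(7.2, abs=1e-12)
    assert res.df == 2


def test_kruskal_wallis_identical_values():
    res = kruskal_wallis({"a": [5, 5], "b": [5, 5, 5]})
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_kruskal_wallis_rank_invariance():
    groups = {"a": [0.1, 0.4, 0.2], "b": [0.9, 0.5, 0.7]}
    transformed = {k: [math.exp(v) for v in vs] for k, vs in groups.items()}
    assert kruskal_wallis(groups).statistic == pytest.approx(
        kruskal_wallis(transformed).statistic
    )


def test_mann_whitney_complete_separation():
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value < 0.1


def test_mann_whitney_u_identity():
    a, b = [1.0, 3.0, 5.0, 7.0], [2.0, 4.0, 6.0]
    u_a = mann_whitney(a, b).statistic
    u_b = mann_whitney(b, a).statistic
    assert u_a + u_b == pytest.approx(len(a) * len(b))


def test_mann_whitney_identical_samples():
    res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.p_value == pytest.approx(1.0)


def test_bh_fdr_worked_example():
    adj = bh_fdr([0.01, 0.02, 0.03])
    assert np.allclose(adj, [0.03, 0.03, 0.03])


def test_bh_fdr_single_p_unchanged():
    assert bh_fdr([0.42])[0] == pytest.approx(0.42)


@given(
    ps=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12)
)
def test_bh_fdr_properties(ps):
    adj = bh_fdr(ps)
    assert ((adj >= np.asarray(ps) - 1e-12) & (adj <= 1.0 + 1e-12)).all()
    # step-up adjustment preserves the ordering of raw p-values
    order = np.argsort(ps)
    assert (np.diff(adj[order]) >= -1e-12).all()
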