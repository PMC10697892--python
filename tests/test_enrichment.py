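"""Oracle equivalence and calibration of the inferential core."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirmint.enrichment import (
    EnrichmentError,
    KS_EXACT_LIMIT,
    bh_adjust,
    hypergeometric_ora,
    ks_target_shift,
    overall_regulation_factor,
    permutation_pair_enrichment,
    process_regulation_test,
    _ks_one_sided_d,
)


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

def test_bh_hand_computed_oracle():
    np.testing.assert_allclose(bh_adjust([0.04]), [0.04])
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    # step-up with a distinct minimum
    np.testing.assert_allclose(
        bh_adjust([0.001, 0.02, 0.9]), [0.003, 0.03, 0.9]
    )


def test_bh_rejects_out_of_range():
    with pytest.raises(EnrichmentError):
        bh_adjust([0.5, 1.2])


def test_bh_handles_nan_without_counting_them():
    out = bh_adjust([0.01, np.nan, 0.02])
    assert np.isnan(out[1])
    np.testing.assert_allclose(out[[0, 2]], bh_adjust([0.01, 0.02]))


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_properties(pvals):
    adj = bh_adjust(pvals)
    assert (adj >= np.asarray(pvals) - 1e-12).all()
    assert (adj <= 1.0 + 1e-12).all()
    order = np.argsort(pvals, kind="stable")
    assert (np.diff(adj[order]) >= -1e-12).all()  # monotone in sorted order


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(0)
    for _ in range(10):
        p = rng.random(50)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


# ---------------------------------------------------------------------------
# Permutation pair enrichment
# ---------------------------------------------------------------------------

def _universe(n_mirna, n_mrna):
    return [(f"m{i}", f"g{j}") for i in range(n_mirna) for j in range(n_mrna)]


def test_saturated_predicted_set_gives_unit_enrichment():
    universe = _universe(2, 5)
    selected = universe[:4]
    for strategy in ("stratified", "pooled"):
        res = permutation_pair_enrichment(
            selected, universe, universe, n_perm=50, seed=1, strategy=strategy
        )
        assert res.enrichment == pytest.approx(1.0)
        assert res.p_perm >= 1 / 51


def test_selected_outside_universe_rejected():
    with pytest.raises(EnrichmentError, match="subset"):
        permutation_pair_enrichment(
            [("mX", "gX")], [], _universe(2, 2), n_perm=10, seed=0
        )


@pytest.mark.parametrize("strategy", ["stratified", "pooled"])
def test_null_matches_exhaustive_enumeration(strategy):
    """10-pair universe (one miRNA so both strategies coincide), 4 predicted,
    3 selected: null mean and p match enumeration over all C(10,3) subsets."""
    universe = _universe(1, 10)
    predicted = universe[:4]
    selected = [universe[0], universe[5], universe[6]]  # overlap 1
    observed = len(set(selected) & set(predicted))
    null = [
        len(set(sub) & set(predicted))
        for sub in itertools.combinations(universe, 3)
    ]
    exact_mean = np.mean(null)
    exact_p = (np.array(null) >= observed).mean()
    res = permutation_pair_enrichment(
        selected, predicted, universe, n_perm=10000, seed=3, strategy=strategy
    )
    assert res.observed_overlap == observed
    assert res.expected_overlap == pytest.approx(exact_mean, abs=0.05)
    assert res.p_perm == pytest.approx(exact_p, abs=0.03)


def test_permutation_p_respects_plus_one_bound():
    universe = _universe(3, 10)
    res = permutation_pair_enrichment(
        universe[:10], universe[:10], universe, n_perm=100, seed=0
    )
    assert res.p_perm >= 1 / 101


def test_strategies_agree_on_exchangeable_universe():
    """On a symmetric toy (same tested/predicted counts per miRNA) the two
    null schemes have the same expectation."""
    universe = _universe(4, 12)
    predicted = [(m, f"g{j}") for m in ("m0", "m1", "m2", "m3") for j in range(3)]
    rng = np.random.default_rng(0)
    idx = rng.choice(len(universe), size=12, replace=False)
    selected = [universe[i] for i in idx]
    res_s = permutation_pair_enrichment(
        selected, predicted, universe, n_perm=4000, seed=1, strategy="stratified"
    )
    res_p = permutation_pair_enrichment(
        selected, predicted, universe, n_perm=4000, seed=1, strategy="pooled"
    )
    assert res_s.expected_overlap == pytest.approx(res_p.expected_overlap,
                                                   rel=0.05)


# ---------------------------------------------------------------------------
# KS target shift
# ---------------------------------------------------------------------------

def _corr_frame(mirna, r_pred, r_non):
    rows = [{"mirna": mirna, "mrna": f"p{i}", "r": r}
            for i, r in enumerate(r_pred)]
    rows += [{"mirna": mirna, "mrna": f"n{i}", "r": r}
             for i, r in enumerate(r_non)]
    return pd.DataFrame(rows)


def test_ks_identical_samples():
    corr = _corr_frame("m", [0.1, 0.2], [0.1, 0.2])
    rec = ks_target_shift("m", corr, {"p0", "p1"})
    assert rec.D == pytest.approx(0.0)
    assert rec.p == pytest.approx(1.0)


def test_ks_fully_separated_small_sample():
    corr = _corr_frame("m", [-0.9, -0.8], [0.1, 0.2])
    rec = ks_target_shift("m", corr, {"p0", "p1"})
    assert rec.D == pytest.approx(1.0)
    # exact: only 1 of C(4,2)=6 labelings separates this perfectly
    assert rec.p == pytest.approx(1 / 6, abs=1e-12)


def test_ks_empty_group_is_an_error():
    corr = _corr_frame("m", [-0.9], [])
    with pytest.raises(EnrichmentError, match="m"):
        ks_target_shift("m", corr, {"p0"})


def test_ks_expression_filter_applies():
    corr = _corr_frame("m", [-0.9, -0.8], [0.1, 0.2, 0.3])
    expr = pd.Series(
        {"p0": 10.0, "p1": 10.0, "n0": 10.0, "n1": 10.0, "n2": 1.0}
    )
    rec = ks_target_shift("m", corr, {"p0", "p1"}, mrna_expr=expr,
                          mrna_expr_filter=3.0)
    assert rec.n_nonpredicted == 2   # n2 filtered out at CPM <= 3


def test_ks_agrees_with_reference_implementation():
    """100 random instances, exact and asymptotic regimes, to 1e-10."""
    rng = np.random.default_rng(12)
    for i in range(100):
        if i % 2:
            n1, n2 = rng.integers(2, 12, 2)      # exact regime
        else:
            n1, n2 = rng.integers(20, 60, 2)     # asymptotic regime
        x = rng.normal(-0.3, 1, n1)
        y = rng.normal(0.0, 1, n2)
        corr = _corr_frame("m", x, y)
        rec = ks_target_shift("m", corr, {f"p{j}" for j in range(n1)})
        method = "exact" if n1 + n2 <= KS_EXACT_LIMIT else "asymp"
        ref = stats.ks_2samp(x, y, alternative="greater", method=method)
        assert abs(rec.D - ref.statistic) < 1e-10
        assert abs(rec.p - ref.pvalue) < 1e-10


def test_ks_null_p_is_uniform():
    """Same-distribution draws give uniform p (KS test on the p-values)."""
    rng = np.random.default_rng(77)
    pvals = []
    for _ in range(500):
        x, y = rng.normal(size=30), rng.normal(size=40)
        d = _ks_one_sided_d(x, y)
        from mirmint.enrichment import _ks_asymp_p_one_sided

        pvals.append(_ks_asymp_p_one_sided(30, 40, d))
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# Gene-set regulation test
# ---------------------------------------------------------------------------

def test_process_regulation_no_target_set():
    sets = [("s1", {"gA", "gB"})]
    res = process_regulation_test(
        sets, ["m1"], {"m1": {"gZ"}}, ["m1", "m2", "m3"], n_perm=200, seed=0
    )
    rec = res.records.loc["s1"]
    assert rec["observed_score"] == 0
    assert rec["p_perm"] == pytest.approx(1.0)


def test_process_regulation_matches_exhaustive_oracle():
    """3 DE of 5 miRNAs, 2 tiny sets: p matches enumeration over C(5,3)."""
    mirnas = [f"m{i}" for i in range(5)]
    targets = {
        "m0": {"a", "b"}, "m1": {"b"}, "m2": {"c"},
        "m3": set(), "m4": {"d"},
    }
    sets = [("s1", {"a", "b"}), ("s2", {"c", "d"})]
    de = ["m0", "m1", "m2"]
    res = process_regulation_test(
        sets, de, targets, mirnas, n_perm=20000, seed=5
    )
    for set_id, members in sets:
        hits = [m for m in mirnas if targets[m] & set(members)]
        observed = len(set(de) & set(hits))
        null = [
            len(set(sub) & set(hits))
            for sub in itertools.combinations(mirnas, 3)
        ]
        exact_p = (np.array(null) >= observed).mean()
        assert res.records.loc[set_id, "observed_score"] == observed
        assert res.records.loc[set_id, "p_perm"] == pytest.approx(
            exact_p, abs=0.02
        )


def test_process_regulation_input_validation():
    with pytest.raises(EnrichmentError):
        process_regulation_test(
            [("s", {"a"})], ["mX"], {}, ["m1"], n_perm=10, seed=0
        )


def test_overall_regulation_factor():
    assert overall_regulation_factor(32, 270, 0.05) == pytest.approx(
        32 / 13.5
    )
    with pytest.raises(EnrichmentError):
        overall_regulation_factor(1, 0)


# ---------------------------------------------------------------------------
# Hypergeometric over-representation
# ---------------------------------------------------------------------------

def test_ora_matches_combinatorial_oracle():
    background = [f"g{i}" for i in range(20)]
    gene_sets = [("s1", set(background[:5]))]
    gene_list = background[1:5] + [background[10]]   # overlap 4
    out = hypergeometric_ora(gene_list, gene_sets, background)
    # direct tail enumeration: P(overlap >= 4) drawing 5 from 20 with 5 marked
    p_exact = sum(
        math.comb(5, k) * math.comb(15, 5 - k) / math.comb(20, 5)
        for k in range(4, 6)
    )
    assert out.loc["s1", "p"] == pytest.approx(p_exact, abs=1e-12)


def test_ora_edge_cases():
    background = [f"g{i}" for i in range(10)]
    sets = [("s1", set(background[:4]))]
    # zero overlap -> upper tail p = 1
    out = hypergeometric_ora(background[4:6], sets, background)
    assert out.loc["s1", "p"] == pytest.approx(1.0)
    # list = background -> overlap = set size, p = 1
    out = hypergeometric_ora(background, sets, background)
    assert out.loc["s1", "overlap"] == 4
    assert out.loc["s1", "p"] == pytest.approx(1.0)
    with pytest.raises(EnrichmentError):
        hypergeometric_ora([], sets, background)
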