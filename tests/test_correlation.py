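"""Pearson grid, pair classification, interaction building and summaries."""

import numpy as np
import pandas as pd
import pytest

from mirmint import datasets
from mirmint.correlation import (
    AnnotationError,
    build_interactions,
    classify_pairs,
    pearson_correlations,
    summarize_interactions,
)
from mirmint.diffexpr import ExpressionMatrix, compute_log2cpm
from mirmint.io_formats import CountMatrix
from mirmint.targets import PredictedPairSet


def _expr(values, prefix):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{i}" for i in range(values.shape[1])],
    )
    return ExpressionMatrix(log2cpm=df, cpm=2.0**df, prior_count=0.5)


def _predicted(pairs):
    rows = [
        {"mirna": m, "mrna": t, "sources": "miRDB,TargetScan",
         "n_prediction": 2, "n_validated": 0, "bitmask": 3}
        for m, t in pairs
    ]
    return PredictedPairSet(
        provenance=pd.DataFrame(
            rows,
            columns=["mirna", "mrna", "sources", "n_prediction",
                     "n_validated", "bitmask"],
        )
    )


def test_negated_profile_gives_minus_one():
    x = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
    mi = _expr(x, "m")
    m = _expr(-x, "g")
    rec = pearson_correlations(mi, m, ["m0"])
    assert rec["r"].iloc[0] == pytest.approx(-1.0)


def test_matches_closed_form_oracle():
    rng = np.random.default_rng(2)
    mi = _expr(rng.normal(size=(3, 5)), "m")
    m = _expr(rng.normal(size=(4, 5)), "g")
    rec = pearson_correlations(mi, m, ["m0", "m1", "m2"]).set_index(
        ["mirna", "mrna"]
    )
    for i in range(3):
        for j in range(4):
            x = mi.log2cpm.iloc[i].to_numpy()
            y = m.log2cpm.iloc[j].to_numpy()
            oracle = np.cov(x, y, bias=True)[0, 1] / (x.std() * y.std())
            assert rec.loc[(f"m{i}", f"g{j}"), "r"] == pytest.approx(
                oracle, abs=1e-12
            )
            from scipy import stats

            assert rec.loc[(f"m{i}", f"g{j}"), "p"] == pytest.approx(
                stats.pearsonr(x, y).pvalue, abs=1e-10
            )


def test_constant_profile_flagged_not_dropped():
    mi = _expr([[1.0, 2.0, 3.0, 4.0]], "m")
    m = _expr([[5.0, 5.0, 5.0, 5.0], [1.0, 0.0, 1.0, 0.0]], "g")
    rec = pearson_correlations(mi, m, ["m0"])
    assert len(rec) == 2
    const = rec[rec["mrna"] == "g0"].iloc[0]
    assert np.isnan(const["r"]) and np.isnan(const["fdr"])
    assert np.isfinite(rec[rec["mrna"] == "g1"].iloc[0]["fdr"])


def test_classification_is_strict_and_disjoint():
    rec = pd.DataFrame(
        {
            "mirna": ["m"] * 4,
            "mrna": list("abcd"),
            "r": [-0.463, -0.4, -0.9, 0.6],
            "p": [0.001] * 4,
            "fdr": [0.011, 0.01, 0.2, 0.01],
            "n": 64,
        }
    )
    neg, pos = classify_pairs(rec)
    assert list(neg["mrna"]) == ["a"]   # -0.4 exactly and fdr 0.2 excluded
    assert list(pos["mrna"]) == ["d"]
    assert set(zip(neg["mirna"], neg["mrna"])).isdisjoint(
        set(zip(pos["mirna"], pos["mrna"]))
    )


def test_build_interactions_subset_and_annotations():
    neg = pd.DataFrame(
        {
            "mirna": ["m1", "m1", "m2"],
            "mrna": ["a", "b", "a"],
            "r": [-0.5, -0.6, -0.7],
            "p": [0.001] * 3,
            "fdr": [0.01] * 3,
            "n": 64,
        }
    )
    predicted = _predicted([("m1", "a"), ("m3", "z")])
    inter = build_interactions(neg, predicted)
    assert list(zip(inter["mirna"], inter["mrna"])) == [("m1", "a")]
    # disjoint inputs -> empty
    assert len(build_interactions(neg, _predicted([("mX", "y")]))) == 0
    # missing DE annotation is an error
    de = pd.DataFrame({"ave_expr": [1.0]}, index=["m1"])
    with pytest.raises(AnnotationError):
        build_interactions(neg, predicted, mirna_de=de.drop(index="m1"))


@pytest.mark.parametrize("seed", range(3))
def test_intersection_matches_set_oracle(seed):
    rng = np.random.default_rng(seed)
    universe = [(f"m{i}", f"g{j}") for i in range(4) for j in range(6)]
    neg_pairs = [universe[i] for i in rng.choice(24, 10, replace=False)]
    pred_pairs = [universe[i] for i in rng.choice(24, 8, replace=False)]
    neg = pd.DataFrame(
        {
            "mirna": [m for m, _ in neg_pairs],
            "mrna": [t for _, t in neg_pairs],
            "r": -0.5, "p": 0.001, "fdr": 0.01, "n": 64,
        }
    )
    inter = build_interactions(neg, _predicted(pred_pairs))
    assert len(inter) == len(set(neg_pairs) & set(pred_pairs))
    assert set(zip(inter["mirna"], inter["mrna"])) <= set(neg_pairs)


def test_reference_interactions_multi_mirna_targets():
    table = datasets.load_top_interactions()
    summary = summarize_interactions(table, set(table["mirna"]))
    assert summary["multi_mirna_targets"] == ["AJUBA", "ITPRIP", "MFAP3L"]


def test_target_count_flag_is_strict():
    rows = [
        {"mirna": "m1", "mrna": f"g{i}", "r": -0.5, "p": 0.01, "fdr": 0.01}
        for i in range(11)
    ] + [
        {"mirna": "m2", "mrna": f"g{i}", "r": -0.5, "p": 0.01, "fdr": 0.01}
        for i in range(10)
    ]
    summary = summarize_interactions(pd.DataFrame(rows), {"m1", "m2"})
    assert summary["flagged_mirnas"] == ["m1"]      # 11 > 10, 10 is not


def test_empty_interactions_give_empty_summaries():
    empty = pd.DataFrame(columns=["mirna", "mrna", "r", "p", "fdr"])
    summary = summarize_interactions(empty, {"m1"})
    assert summary["multi_mirna_targets"] == []
    assert summary["flagged_mirnas"] == []
    assert len(summary["top_table"]) == 0


def test_planted_pairs_recovered_better_than_random(small_cohort, small_config):
    """Interactions recall planted pairs better than equal-size random draws
    (sign test across seeds)."""
    from dataclasses import replace

    from mirmint.config import SimConfig
    from mirmint.diffexpr import fit_linear_de, select_de
    from mirmint.synthetic import simulate_cohort, simulate_target_evidence
    from mirmint.targets import apply_source_thresholds, vote_predicted_pairs

    wins = 0
    n_seeds = 8
    for seed in range(n_seeds):
        cfg = SimConfig(n_mirna=40, n_mrna=200, n_true_pairs=60, seed=50 + seed)
        samples, cm_mi, cm_m, truth = simulate_cohort(cfg)
        predicted = vote_predicted_pairs(
            apply_source_thresholds(simulate_target_evidence(truth, cfg))
        )
        emi, em = compute_log2cpm(cm_mi), compute_log2cpm(cm_m)
        de_mi = select_de(fit_linear_de(emi, samples))
        if not de_mi:
            continue
        corr = pearson_correlations(emi, em, de_mi)
        neg, _ = classify_pairs(corr)
        inter = build_interactions(neg, predicted)
        inter_pairs = set(zip(inter["mirna"], inter["mrna"]))
        tested = corr.dropna(subset=["r"])
        universe = list(zip(tested["mirna"], tested["mrna"]))
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(universe), size=len(inter_pairs), replace=False)
        random_pairs = {universe[i] for i in idx}
        truth_pairs = set(truth.true_pairs)
        if len(inter_pairs & truth_pairs) > len(random_pairs & truth_pairs):
            wins += 1
    assert wins >= n_seeds - 1
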