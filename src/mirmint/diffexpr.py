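"""Per-feature linear-model differential expression on log2-CPM.

For every feature, an ordinary-least-squares model

    log2cpm ~ intercept + I(parAF) + I(persAF) + age + gender

is fit across samples, and the three pairwise group contrasts
(persAF-nonAF, parAF-nonAF, persAF-parAF) are reported with t-based
p-values and Benjamini-Hochberg FDR computed within each contrast across
features.  Empirical-Bayes variance moderation and precision weights are
deliberately not applied; plain OLS on pseudo-counted log2-CPM keeps the
estimator transparent and its sampling behaviour testable on synthetic
cohorts.

The "CPM > 1" expression cut-off of the top-miRNA selection is applied to
the feature's average log2-CPM (AveExpr), matching the reporting convention
of the reference tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Set

import numpy as np
import pandas as pd
from scipy import stats

from .config import CONTRASTS, GROUPS
from .io_formats import CountMatrix, FormatError
from .enrichment import bh_adjust


class DesignError(ValueError):
    """Raised for singular or under-determined design matrices."""


@dataclass
class ExpressionMatrix:
    """CPM and pseudo-counted log2-CPM views of a count matrix."""

    log2cpm: pd.DataFrame
    cpm: pd.DataFrame
    prior_count: float

    @property
    def feature_ids(self) -> pd.Index:
        return self.log2cpm.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.log2cpm.columns

    def ave_expr(self) -> pd.Series:
        """Mean log2-CPM per feature across all samples (AveExpr)."""
        return self.log2cpm.mean(axis=1)


def compute_log2cpm(counts: CountMatrix, prior_count: float = 0.5) -> ExpressionMatrix:
    """Library-size normalise counts to CPM and pseudo-counted log2-CPM.

    cpm = count / libsize * 1e6;
    log2cpm = log2((count + prior) / (libsize + 2 * prior) * 1e6).
    Library size is the raw column sum.
    """
    lib = counts.library_sizes().to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = counts.sample_ids[np.flatnonzero(lib <= 0)[0]]
        raise FormatError(f"zero library size for sample {bad!r}")
    raw = counts.counts.to_numpy(dtype=float)
    cpm = raw / lib[None, :] * 1e6
    log2cpm = np.log2((raw + prior_count) / (lib + 2 * prior_count)[None, :] * 1e6)
    idx, cols = counts.feature_ids, counts.sample_ids
    return ExpressionMatrix(
        log2cpm=pd.DataFrame(log2cpm, index=idx, columns=cols),
        cpm=pd.DataFrame(cpm, index=idx, columns=cols),
        prior_count=prior_count,
    )


def _design_matrix(samples: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = ["intercept", "parAF", "persAF", "age", "gender"]
    g = samples["group"].to_numpy()
    X = np.column_stack(
        [
            np.ones(len(samples)),
            (g == "parAF").astype(float),
            (g == "persAF").astype(float),
            samples["age"].to_numpy(dtype=float),
            samples["gender"].to_numpy(dtype=float),
        ]
    )
    return X, cols


def fit_linear_de(expr: ExpressionMatrix, samples: pd.DataFrame) -> pd.DataFrame:
    """OLS differential expression with age and gender correction.

    Returns one row per feature with ``ave_expr`` and, for each contrast,
    ``logfc_*``, ``p_*`` and ``fdr_*`` columns (BH within contrast).
    """
    samples = samples.set_index("sample_id").loc[expr.sample_ids].reset_index()
    for group in GROUPS:
        n = int((samples["group"] == group).sum())
        if n < 2:
            raise DesignError(f"need >=2 samples in group {group!r}, found {n}")
    X, cols = _design_matrix(samples)
    # Reject singular designs with the offending column named.
    for j in range(1, X.shape[1]):
        if np.allclose(X[:, j], X[0, j]):
            raise DesignError(f"design column {cols[j]!r} is constant")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DesignError("design matrix is singular")

    Y = expr.log2cpm.to_numpy(dtype=float).T  # samples x features
    n, p = X.shape
    df_resid = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # p x features
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df_resid

    # Contrast vectors on (intercept, parAF, persAF, age, gender).
    contrast_vecs = {
        "parAF_vs_nonAF": np.array([0.0, 1.0, 0.0, 0.0, 0.0]),
        "persAF_vs_nonAF": np.array([0.0, 0.0, 1.0, 0.0, 0.0]),
        "persAF_vs_parAF": np.array([0.0, -1.0, 1.0, 0.0, 0.0]),
    }
    out = {"ave_expr": expr.ave_expr().to_numpy()}
    for name in CONTRASTS:
        c = contrast_vecs[name]
        est = c @ beta
        se = np.sqrt(sigma2 * (c @ xtx_inv @ c))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
        pvals = 2.0 * stats.t.sf(np.abs(t), df_resid)
        out[f"logfc_{name}"] = est
        out[f"p_{name}"] = pvals
        out[f"fdr_{name}"] = bh_adjust(pvals)
    return pd.DataFrame(out, index=expr.feature_ids)


def select_de(records: pd.DataFrame, fdr_threshold: float = 0.05) -> Set[str]:
    """Features with FDR strictly below the threshold in >=1 contrast."""
    if records.empty:
        return set()
    fdr_cols = [f"fdr_{c}" for c in CONTRASTS]
    mask = (records[fdr_cols] < fdr_threshold).any(axis=1)
    return set(records.index[mask])


def select_top_de(
    records: pd.DataFrame,
    logfc_threshold: float = 1.0,
    aveexpr_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> Set[str]:
    """The top-DE selection: a large, significant fold change in the same
    contrast (|log2FC| > threshold and FDR < threshold), plus average
    log2-CPM above the expression cut-off."""
    if records.empty:
        return set()
    hit = np.zeros(len(records), dtype=bool)
    for c in CONTRASTS:
        hit |= (
            (records[f"fdr_{c}"] < fdr_threshold)
            & (records[f"logfc_{c}"].abs() > logfc_threshold)
        ).to_numpy()
    hit &= (records["ave_expr"] > aveexpr_threshold).to_numpy()
    return set(records.index[hit])


def classify_trend(records: pd.DataFrame, tolerance: float = 0.0) -> pd.Series:
    """Classify each feature's stage profile as ordinal or not.

    ordinal_up if both incremental contrasts (nonAF->parAF and
    parAF->persAF) exceed ``tolerance``; ordinal_down if both fall below
    ``-tolerance``; non_ordinal otherwise.
    """
    inc1 = records["logfc_parAF_vs_nonAF"]
    inc2 = records["logfc_persAF_vs_parAF"]
    up = (inc1 > tolerance) & (inc2 > tolerance)
    down = (inc1 < -tolerance) & (inc2 < -tolerance)
    trend = np.where(up, "ordinal_up", np.where(down, "ordinal_down", "non_ordinal"))
    return pd.Series(trend, index=records.index, name="trend")


def ordinal_fraction(trend: pd.Series, features: Iterable[str] | None = None) -> float:
    """Fraction of (selected) features with an ordinal trend."""
    if features is not None:
        trend = trend.loc[sorted(set(features) & set(trend.index))]
    if len(trend) == 0:
        return float("nan")
    return float((trend != "non_ordinal").mean())


def write_de_table(records: pd.DataFrame, path) -> None:
    """Write a top-table TSV: feature, AveExpr, then per-contrast LogFC/FDR."""
    cols = ["ave_expr"]
    header = {"ave_expr": "AveExpr"}
    for c in CONTRASTS:
        pretty = c.replace("_vs_", " vs. ")
        cols += [f"logfc_{c}", f"fdr_{c}"]
        header[f"logfc_{c}"] = f"LogFC {pretty}"
        header[f"fdr_{c}"] = f"FDR {pretty}"
    records[cols].rename(columns=header).to_csv(path, sep="\t", index_label="feature")
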