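"""Pearson correlation of DE miRNAs against all mRNAs, pair classification,
intersection with target predictions and the interaction summaries.

Correlations are computed on log2-CPM across all samples pooled (no
covariate adjustment), with two-sided p-values from the t transform of r
and BH FDR across the full DE-miRNA x mRNA grid as a single family.
Zero-variance profiles yield records with undefined r that are excluded
from the FDR family but never silently dropped.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import ExpressionMatrix
from .enrichment import bh_adjust
from .targets import PredictedPairSet


class AnnotationError(KeyError):
    """Raised when a pair member lacks the required DE annotation."""


def pearson_correlations(
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    de_mirnas: Iterable[str],
) -> pd.DataFrame:
    """One record per (DE miRNA, mRNA): Pearson r on log2-CPM, p and FDR.

    Returns a frame with columns ``mirna``, ``mrna``, ``r``, ``p``, ``fdr``
    and ``n``.  r is NaN for zero-variance profiles; those records carry
    NaN p/fdr and do not count towards the BH family.
    """
    if list(mirna_expr.sample_ids) != list(mrna_expr.sample_ids):
        raise ValueError("miRNA and mRNA matrices must share the sample set")
    de = sorted(set(de_mirnas))
    missing = set(de) - set(mirna_expr.feature_ids)
    if missing:
        raise KeyError(f"DE miRNAs absent from the matrix: {sorted(missing)}")
    X = mirna_expr.log2cpm.loc[de].to_numpy(dtype=float)
    Y = mrna_expr.log2cpm.to_numpy(dtype=float)
    n = X.shape[1]

    def standardise(A: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        mu = A.mean(axis=1, keepdims=True)
        sd = A.std(axis=1, keepdims=True)
        ok = sd[:, 0] > 0
        Z = np.where(sd > 0, (A - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        return Z, ok

    Zx, ok_x = standardise(X)
    Zy, ok_y = standardise(Y)
    R = Zx @ Zy.T / n
    R = np.clip(R, -1.0, 1.0)
    defined = np.outer(ok_x, ok_y)
    R[~defined] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / np.maximum(1.0 - R**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[~defined] = np.nan

    mirna_col = np.repeat(de, Y.shape[0])
    mrna_col = np.tile(mrna_expr.feature_ids.to_numpy(), len(de))
    out = pd.DataFrame(
        {
            "mirna": mirna_col,
            "mrna": mrna_col,
            "r": R.ravel(),
            "p": p.ravel(),
            "n": n,
        }
    )
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def classify_pairs(
    records: pd.DataFrame,
    r_threshold: float = 0.4,
    fdr_threshold: float = 0.05,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (negative, positive) significantly correlated sets.

    negative: r < -r_threshold and FDR < fdr_threshold (strict);
    positive: r > +r_threshold and FDR < fdr_threshold.
    """
    defined = records.dropna(subset=["r", "fdr"])
    sig = defined["fdr"] < fdr_threshold
    negative = defined[(defined["r"] < -r_threshold) & sig]
    positive = defined[(defined["r"] > r_threshold) & sig]
    return negative.reset_index(drop=True), positive.reset_index(drop=True)


def build_interactions(
    negative_pairs: pd.DataFrame,
    predicted: PredictedPairSet,
    mirna_de: pd.DataFrame | None = None,
    mrna_de: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Intersect negatively correlated pairs with the predicted pair set.

    Returns the interaction records annotated with provenance and, when DE
    tables are given, both members' DE statistics (every interacting
    feature must then be present in its DE table).
    """
    pred_pairs = predicted.pairs
    keys = list(zip(negative_pairs["mirna"], negative_pairs["mrna"]))
    mask = [k in pred_pairs for k in keys]
    inter = negative_pairs[mask].copy().reset_index(drop=True)
    if len(inter):
        prov = predicted.provenance.set_index(["mirna", "mrna"])
        inter["sources"] = [
            prov.loc[(m, t), "sources"]
            for m, t in zip(inter["mirna"], inter["mrna"])
        ]
        inter["n_validated"] = [
            int(prov.loc[(m, t), "n_validated"])
            for m, t in zip(inter["mirna"], inter["mrna"])
        ]
    else:
        inter["sources"] = pd.Series(dtype=str)
        inter["n_validated"] = pd.Series(dtype=int)
    for side, table in (("mirna", mirna_de), ("mrna", mrna_de)):
        if table is None:
            continue
        missing = set(inter[side]) - set(table.index)
        if missing:
            raise AnnotationError(
                f"{side} ids missing from DE annotations: {sorted(missing)[:5]}"
            )
        for col in table.columns:
            inter[f"{side}_{col}"] = table[col].reindex(inter[side]).to_numpy()
    return inter


def summarize_interactions(
    interactions: pd.DataFrame,
    mirna_top_de: Iterable[str],
    mrna_de_logfc: Mapping[str, float] | pd.Series | None = None,
    mrna_de_fdr: Mapping[str, float] | pd.Series | None = None,
    mrna_logfc_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
    target_count_flag: int = 10,
) -> Dict[str, object]:
    """Interaction summaries: the top table, per-miRNA target counts and
    multi-miRNA target genes.

    The top table keeps interactions whose miRNA is in the top-DE selection
    and whose mRNA is DE with |log2FC| above the mRNA threshold at the FDR
    cut-off.  Per-miRNA counts flag miRNAs with strictly more than
    ``target_count_flag`` interactions.  Multi-miRNA targets are mRNAs
    targeted by >=2 distinct miRNAs in the top table.
    """
    top_mirnas = set(mirna_top_de)
    if interactions.empty:
        counts = pd.Series(dtype=int, name="n_targets")
        return {
            "top_table": interactions.copy(),
            "target_counts": pd.DataFrame(
                {"n_targets": counts, "flagged": counts.astype(bool)}
            ),
            "flagged_mirnas": [],
            "multi_mirna_targets": [],
        }

    keep = interactions["mirna"].isin(top_mirnas)
    if mrna_de_logfc is not None:
        logfc = pd.Series(mrna_de_logfc)
        keep &= interactions["mrna"].map(
            lambda g: abs(logfc.get(g, 0.0)) > mrna_logfc_threshold
        )
    if mrna_de_fdr is not None:
        fdr = pd.Series(mrna_de_fdr)
        keep &= interactions["mrna"].map(
            lambda g: fdr.get(g, 1.0) < fdr_threshold
        )
    top_table = interactions[keep].reset_index(drop=True)

    counts = (
        interactions.groupby("mirna")["mrna"].nunique().rename("n_targets")
    )
    target_counts = pd.DataFrame(
        {"n_targets": counts, "flagged": counts > target_count_flag}
    ).sort_values("n_targets", ascending=False)

    by_target = top_table.groupby("mrna")["mirna"].nunique()
    multi = sorted(by_target.index[by_target >= 2])
    return {
        "top_table": top_table,
        "target_counts": target_counts,
        "flagged_mirnas": sorted(counts.index[counts > target_count_flag]),
        "multi_mirna_targets": multi,
    }


def write_interaction_table(interactions: pd.DataFrame, path) -> None:
    """Write a compact interaction TSV: miRNA, Target, Pearson R, FDR,
    mRNA log2FC/FDR when annotated, and Validated/Predicted flags."""
    out = pd.DataFrame(
        {
            "miRNA": interactions["mirna"],
            "Target": interactions["mrna"],
            "Pearson R": interactions["r"].round(3),
            "FDR": interactions["fdr"].round(4),
        }
    )
    if "mrna_logfc_persAF_vs_nonAF" in interactions:
        out["Log2FC mRNA persAF vs. nonAF"] = interactions[
            "mrna_logfc_persAF_vs_nonAF"
        ].round(3)
    if "mrna_fdr_persAF_vs_nonAF" in interactions:
        out["FDR mRNA persAF vs. nonAF"] = interactions[
            "mrna_fdr_persAF_vs_nonAF"
        ].round(4)
    if "n_validated" in interactions:
        out["Validated"] = np.where(interactions["n_validated"] > 0, "Yes", "No")
    if "sources" in interactions:
        out["Predicted"] = "Yes"
    out.to_csv(path, sep="\t", index=False)
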