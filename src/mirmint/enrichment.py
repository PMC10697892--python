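"""Inferential statistics: BH adjustment, permutation enrichment of
predicted pairs among anti-correlated pairs, one-sided KS target-shift
tests, the gene-set miRNA-regulation permutation test and a self-contained
hypergeometric over-representation test.

Permutation nulls
-----------------
The pair-enrichment null resamples the *selected* pair set.  Two schemes
are provided:

``stratified`` (default)
    For each miRNA, its number of selected mRNAs is redrawn uniformly
    without replacement from that miRNA's tested mRNAs.  This preserves the
    per-miRNA selection counts, removing the dominant confounder (predicted
    target counts vary strongly between miRNAs).
``pooled``
    The total number of selected pairs is redrawn uniformly from the whole
    tested universe.

Under either scheme the null overlap with the predicted set is a sum of
independent hypergeometric draws, which is how the permutations are
realised (mathematically identical to explicit resampling, and fast).
All permutation p-values use the +1 correction
p = (1 + #{null >= observed}) / (n_perm + 1).

Per-unit random streams are derived from (seed, test label, unit id) so
results do not depend on evaluation order.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

#: Combined sample size at or below which the KS p-value is exact.
KS_EXACT_LIMIT = 25


class EnrichmentError(ValueError):
    """Raised for inconsistent inputs to an enrichment test."""


def _derived_rng(seed: int, *labels) -> np.random.Generator:
    """Deterministic child stream keyed by (seed, labels...)."""
    key = [int(seed)] + [zlib.crc32(str(x).encode()) for x in labels]
    return np.random.default_rng(np.random.SeedSequence(key))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjustment.

    Sorted ascending, adj_i = min_{j>=i}(p_j * m / j), capped at 1 and
    mapped back to the input order.  NaNs propagate and do not count
    towards m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise EnrichmentError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[valid] = restored
    return out


# ---------------------------------------------------------------------------
# Permutation enrichment of predicted pairs among selected pairs
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Observed vs. permutation-null overlap of selected and predicted pairs."""

    observed_overlap: int
    expected_overlap: float
    enrichment: float
    p_perm: float
    n_perm: int
    seed: int
    strategy: str
    n_selected: int = 0
    n_predicted: int = 0
    n_universe: int = 0

    def to_dict(self) -> dict:
        return {
            "observed_overlap": self.observed_overlap,
            "expected_overlap": self.expected_overlap,
            "enrichment": self.enrichment,
            "p_perm": self.p_perm,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "strategy": self.strategy,
            "n_selected": self.n_selected,
            "n_predicted": self.n_predicted,
            "n_universe": self.n_universe,
        }


def permutation_pair_enrichment(
    selected_pairs: Iterable[Tuple[str, str]],
    predicted_pairs: Iterable[Tuple[str, str]],
    universe: Iterable[Tuple[str, str]],
    n_perm: int = 1000,
    seed: int = 0,
    strategy: str = "stratified",
) -> EnrichmentResult:
    """Test whether predicted pairs are over-represented among selected pairs.

    ``universe`` is the full tested grid (DE miRNA x tested mRNA);
    ``selected_pairs`` must be a subset of it.  Predicted pairs outside the
    universe are ignored.  enrichment = observed / mean(null overlap).
    """
    universe_set = set(universe)
    selected = set(selected_pairs)
    predicted = set(predicted_pairs) & universe_set
    if not selected <= universe_set:
        raise EnrichmentError("selected pairs are not a subset of the universe")
    if strategy not in ("stratified", "pooled"):
        raise EnrichmentError(f"unknown strategy {strategy!r}")

    observed = len(selected & predicted)
    rng = _derived_rng(seed, "pair_enrichment", strategy)

    if strategy == "pooled":
        N = len(universe_set)
        K = len(predicted)
        k = len(selected)
        null = (
            rng.hypergeometric(K, N - K, k, size=n_perm)
            if k and K
            else np.zeros(n_perm)
        )
    else:
        per_mirna: Dict[str, List[int]] = {}
        tested: Dict[str, int] = {}
        pred_ct: Dict[str, int] = {}
        sel_ct: Dict[str, int] = {}
        for m, t in universe_set:
            tested[m] = tested.get(m, 0) + 1
        for m, t in predicted:
            pred_ct[m] = pred_ct.get(m, 0) + 1
        for m, t in selected:
            sel_ct[m] = sel_ct.get(m, 0) + 1
        mirnas = sorted(m for m in sel_ct if sel_ct[m] > 0)
        if mirnas:
            ngood = np.array([pred_ct.get(m, 0) for m in mirnas])
            nbad = np.array([tested[m] - pred_ct.get(m, 0) for m in mirnas])
            nsamp = np.array([sel_ct[m] for m in mirnas])
            null = rng.hypergeometric(
                ngood, nbad, nsamp, size=(n_perm, len(mirnas))
            ).sum(axis=1)
        else:
            null = np.zeros(n_perm)

    expected = float(null.mean()) if n_perm else float("nan")
    enrichment = observed / expected if expected > 0 else 0.0
    p_perm = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return EnrichmentResult(
        observed_overlap=observed,
        expected_overlap=expected,
        enrichment=float(enrichment),
        p_perm=float(p_perm),
        n_perm=n_perm,
        seed=seed,
        strategy=strategy,
        n_selected=len(selected),
        n_predicted=len(predicted),
        n_universe=len(universe_set),
    )


# ---------------------------------------------------------------------------
# One-sided two-sample Kolmogorov-Smirnov target-shift test
# ---------------------------------------------------------------------------

@dataclass
class KSRecord:
    """One-sided KS comparison of predicted vs. non-predicted correlations."""

    mirna: str
    D: float
    p: float
    n_predicted: int
    n_nonpredicted: int
    direction: str = "predicted_more_negative"

    def to_dict(self) -> dict:
        return {
            "mirna": self.mirna,
            "D": self.D,
            "p": self.p,
            "n_predicted": self.n_predicted,
            "n_nonpredicted": self.n_nonpredicted,
            "direction": self.direction,
        }


def _ks_one_sided_d(x: np.ndarray, y: np.ndarray) -> float:
    """D+ = sup_t (F_x(t) - F_y(t)); positive when x is shifted left of y."""
    n1, n2 = len(x), len(y)
    xs, ys = np.sort(x), np.sort(y)
    grid = np.concatenate([xs, ys])
    cdf1 = np.searchsorted(xs, grid, side="right") / n1
    cdf2 = np.searchsorted(ys, grid, side="right") / n2
    return float(np.max(cdf1 - cdf2))


def _ks_exact_p_one_sided(n1: int, n2: int, d: float) -> float:
    """Exact P(D+ >= d) by integer lattice-path counting.

    Counts monotone paths (0,0)->(n1,n2) through the pooled order statistics;
    a path step takes the next smallest observation from sample 1 (right) or
    sample 2 (up).  D+ >= d iff the path reaches i*n2 - j*n1 >= h where
    h = ceil-equivalent integer threshold of d*n1*n2 (exact integer
    arithmetic, no floating-point boundary issues for empirical d values of
    the form a/n1 - b/n2).
    """
    # observed d is (i*n2 - j*n1)/(n1*n2) for integers; recover the integer
    # numerator robustly
    h = int(round(d * n1 * n2))
    if h <= 0:
        return 1.0
    # count paths that always stay strictly below the barrier i*n2 - j*n1 >= h
    prev = np.zeros(n2 + 1, dtype=float)
    # f(i, j): number of sub-paths from (0,0) to (i,j) avoiding the barrier
    prev[:] = [1.0 if (0 - j * n1) < h else 0.0 for j in range(n2 + 1)]
    for i in range(1, n1 + 1):
        cur = np.zeros(n2 + 1)
        for j in range(n2 + 1):
            if i * n2 - j * n1 >= h:
                cur[j] = 0.0
            else:
                cur[j] = prev[j] + (cur[j - 1] if j else 0.0)
        prev = cur
    total = math.comb(n1 + n2, n1)
    return float(1.0 - prev[n2] / total)


def _ks_asymp_p_one_sided(n1: int, n2: int, d: float) -> float:
    # Smirnov's one-sided tail with Hodges' continuity correction
    # (m must be the larger sample size).
    m, n = sorted((float(n1), float(n2)), reverse=True)
    en = m * n / (m + n)
    z = math.sqrt(en) * d
    expt = -2.0 * z**2 - 2.0 * z * (m + 2 * n) / math.sqrt(m * n * (m + n)) / 3.0
    return float(min(1.0, max(0.0, math.exp(expt))))


def ks_target_shift(
    mirna: str,
    correlations: pd.DataFrame,
    predicted_targets: Iterable[str],
    mrna_expr: pd.Series | None = None,
    mrna_expr_filter: float = 3.0,
) -> KSRecord:
    """One-sided KS test: are predicted targets' correlations shifted negative?

    ``correlations`` must hold columns ``mirna``, ``mrna`` and ``r``;
    ``mrna_expr`` gives each mRNA's average CPM, and mRNAs at or below
    ``mrna_expr_filter`` are dropped before the comparison.  The exact
    small-sample null distribution is used when the combined group size is
    at most ``KS_EXACT_LIMIT``; the one-sided asymptotic formula otherwise.
    """
    sub = correlations[correlations["mirna"] == mirna]
    sub = sub.dropna(subset=["r"])
    if mrna_expr is not None:
        keep = mrna_expr[mrna_expr > mrna_expr_filter].index
        sub = sub[sub["mrna"].isin(keep)]
    predicted = set(predicted_targets)
    is_pred = sub["mrna"].isin(predicted).to_numpy()
    r_pred = sub.loc[is_pred, "r"].to_numpy(dtype=float)
    r_non = sub.loc[~is_pred, "r"].to_numpy(dtype=float)
    if len(r_pred) == 0 or len(r_non) == 0:
        raise EnrichmentError(
            f"miRNA {mirna!r}: empty predicted or non-predicted group "
            "after expression filtering"
        )
    d = _ks_one_sided_d(r_pred, r_non)
    n1, n2 = len(r_pred), len(r_non)
    ties = len(np.intersect1d(r_pred, r_non)) > 0
    if n1 + n2 <= KS_EXACT_LIMIT and not ties:
        p = _ks_exact_p_one_sided(n1, n2, d)
    else:
        p = _ks_asymp_p_one_sided(n1, n2, d)
    return KSRecord(
        mirna=mirna, D=d, p=p, n_predicted=n1, n_nonpredicted=n2
    )


def ks_cdf_coordinates(
    mirna: str,
    correlations: pd.DataFrame,
    predicted_targets: Iterable[str],
    mrna_expr: pd.Series | None = None,
    mrna_expr_filter: float = 3.0,
) -> pd.DataFrame:
    """Empirical CDF coordinates of r for predicted vs. non-predicted targets,
    for external plotting."""
    sub = correlations[correlations["mirna"] == mirna].dropna(subset=["r"])
    if mrna_expr is not None:
        keep = mrna_expr[mrna_expr > mrna_expr_filter].index
        sub = sub[sub["mrna"].isin(keep)]
    predicted = set(predicted_targets)
    frames = []
    for label, mask in (
        ("predicted", sub["mrna"].isin(predicted)),
        ("non_predicted", ~sub["mrna"].isin(predicted)),
    ):
        r = np.sort(sub.loc[mask, "r"].to_numpy(dtype=float))
        if len(r) == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "mirna": mirna,
                    "group": label,
                    "r": r,
                    "cdf": np.arange(1, len(r) + 1) / len(r),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Gene-set miRNA-regulation permutation test
# ---------------------------------------------------------------------------

@dataclass
class ProcessRegulationResult:
    records: pd.DataFrame
    overall_factor: float
    overall_factor_note: str = (
        "observed significant sets / expected significant sets at alpha "
        "(interpretative summary)"
    )
    n_perm: int = 1000
    seed: int = 0


def process_regulation_test(
    gene_sets,
    de_mirnas: Iterable[str],
    predicted_targets: Mapping[str, Set[str]],
    all_mirnas: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    score: str = "distinct_mirnas",
) -> ProcessRegulationResult:
    """Per gene set, test over-representation of DE miRNAs with predicted
    targets in the set.

    observed score (default) = number of distinct DE miRNAs with >=1
    predicted target inside the set; the alternative ``score='total_hits'``
    counts total predicted-target hits.  The null redraws equally many
    miRNAs uniformly from ``all_mirnas``; per-set streams are derived from
    (seed, set id) so results are order-independent.  ``overall_factor`` is
    the number of sets with p below ``alpha`` over the count expected at
    ``alpha``.
    """
    de = sorted(set(de_mirnas))
    allm = sorted(set(all_mirnas))
    if not set(de) <= set(allm):
        raise EnrichmentError("de_mirnas must be a subset of all_mirnas")
    if len(de) > len(allm):
        raise EnrichmentError("more DE miRNAs than miRNAs")
    if score not in ("distinct_mirnas", "total_hits"):
        raise EnrichmentError(f"unknown score {score!r}")
    targets = {m: set(predicted_targets.get(m, ())) for m in allm}
    de_set = set(de)

    rows = []
    for set_id, members in gene_sets:
        members = set(members)
        if score == "distinct_mirnas":
            per_mirna = np.array(
                [1 if targets[m] & members else 0 for m in allm]
            )
        else:
            per_mirna = np.array([len(targets[m] & members) for m in allm])
        observed = int(per_mirna[[m in de_set for m in allm]].sum())
        rng = _derived_rng(seed, "process_regulation", set_id)
        if score == "distinct_mirnas":
            # score of a random subset is hypergeometric in the hit count
            n_hit = int(per_mirna.sum())
            null = rng.hypergeometric(
                n_hit, len(allm) - n_hit, len(de), size=n_perm
            ) if n_hit else np.zeros(n_perm)
        else:
            idx = np.arange(len(allm))
            null = np.array(
                [
                    per_mirna[rng.choice(idx, size=len(de), replace=False)].sum()
                    for _ in range(n_perm)
                ]
            )
        null_mean = float(null.mean())
        p_perm = (1 + int((null >= observed).sum())) / (n_perm + 1)
        rows.append(
            {
                "set_id": set_id,
                "observed_score": observed,
                "null_mean": null_mean,
                "p_perm": p_perm,
            }
        )
    records = pd.DataFrame(rows).set_index("set_id")
    records["fdr"] = bh_adjust(records["p_perm"].to_numpy())
    n_sig = int((records["p_perm"] < alpha).sum())
    factor = overall_regulation_factor(n_sig, len(records), alpha)
    return ProcessRegulationResult(
        records=records, overall_factor=factor, n_perm=n_perm, seed=seed
    )


def overall_regulation_factor(
    n_significant: int, n_sets: int, alpha: float = 0.05
) -> float:
    """Observed significant sets over the count expected by chance at alpha."""
    if n_sets <= 0:
        raise EnrichmentError("n_sets must be positive")
    return n_significant / (alpha * n_sets)


# ---------------------------------------------------------------------------
# Hypergeometric over-representation
# ---------------------------------------------------------------------------

def hypergeometric_ora(
    gene_list: Iterable[str],
    gene_sets,
    background: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a gene list in each
    set, with BH FDR across sets.

    The test conditions on the background universe: p = P(overlap >= k)
    for a uniform draw of |gene_list| genes from the background.
    """
    background = set(background)
    genes = set(gene_list)
    if not genes:
        raise EnrichmentError("gene list is empty")
    if not genes <= background:
        raise EnrichmentError("gene list is not a subset of the background")
    M, N = len(background), len(genes)
    rows = []
    for set_id, members in gene_sets:
        members_bg = set(members) & background
        n = len(members_bg)
        k = len(members_bg & genes)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append(
            {"set_id": set_id, "set_size": n, "overlap": k, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows).set_index("set_id")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out
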