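"""Synthetic cohorts with planted miRNA->mRNA repression, plus matching
target-evidence databases and gene-set collections, with full ground truth.

The generative model
--------------------
Each feature f has a latent per-sample log2 abundance

    lambda[f, s] = base_f + effect_f(group_s) + b_age*(age_s - 65)
                   + b_sex*gender_s + eps[f, s]

with eps ~ N(0, latent_sd^2) biological variation and small random covariate
coefficients (so age/gender correction downstream is exercised).  For a
planted coupling (m -> t) the target's latent mean is repressed by

    lambda[t, s] -= coupling_k * (lambda[m, s] - mean_s lambda[m, s])

i.e. the repression acts through the regulator's *latent* (count-noise-free)
log2 expression, which keeps the sign of the planted correlation analytically
known.  Observed counts are negative-binomial draws with mean
libsize_s * 2^lambda / 1e6 and variance mu + dispersion * mu^2.

Group effects follow the three-stage design (nonAF -> parAF -> persAF):
ordinal features move by ``effect_log2fc`` per stage in a consistent
direction; non-ordinal features get a transient up-then-back pattern.

One global seed drives independent child streams for the cohort, database
and gene-set stages, so each stage can be regenerated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Set, Tuple

import numpy as np
import pandas as pd

from .config import CONTRASTS, GROUPS, ConfigurationError, SimConfig
from .io_formats import (
    CountMatrix,
    GeneSetCollection,
    PREDICTION_SOURCES,
    VALIDATED_SOURCES,
    validate_target_evidence,
)

_AGE_RANGE = (50.0, 80.0)
_BASE_RANGE = (2.0, 10.0)
_AGE_BETA_SD = 0.01   # log2 units per year
_SEX_BETA_SD = 0.1    # log2 units


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort.

    ``de_mirnas`` / ``de_mrnas`` map each planted-DE feature to its true
    per-contrast log2 fold change; ``true_pairs`` are the planted repressive
    couplings; ``enriched_sets`` is filled by :func:`simulate_gene_sets`.
    """

    mirna_ids: Tuple[str, ...]
    mrna_ids: Tuple[str, ...]
    true_pairs: FrozenSet[Tuple[str, str]]
    de_mirnas: Dict[str, Dict[str, float]]
    de_mrnas: Dict[str, Dict[str, float]]
    ordinal_flags: Dict[str, bool]
    coupling_k: float
    enriched_sets: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        mirna_set, mrna_set = set(self.mirna_ids), set(self.mrna_ids)
        for m, t in self.true_pairs:
            if m not in mirna_set or t not in mrna_set:
                raise ConfigurationError(
                    f"planted pair ({m}, {t}) outside the feature universe"
                )
        for feature, effects in {**self.de_mirnas, **self.de_mrnas}.items():
            if set(effects) != set(CONTRASTS):
                raise ConfigurationError(
                    f"planted-DE feature {feature!r} lacks a full effect record"
                )

    @property
    def target_mrnas(self) -> Set[str]:
        return {t for _, t in self.true_pairs}

    def to_dict(self) -> dict:
        return {
            "mirna_ids": list(self.mirna_ids),
            "mrna_ids": list(self.mrna_ids),
            "true_pairs": sorted(list(p) for p in self.true_pairs),
            "de_mirnas": self.de_mirnas,
            "de_mrnas": self.de_mrnas,
            "ordinal_flags": self.ordinal_flags,
            "coupling_k": self.coupling_k,
            "enriched_sets": sorted(self.enriched_sets),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            mirna_ids=tuple(d["mirna_ids"]),
            mrna_ids=tuple(d["mrna_ids"]),
            true_pairs=frozenset(tuple(p) for p in d["true_pairs"]),
            de_mirnas=d["de_mirnas"],
            de_mrnas=d["de_mrnas"],
            ordinal_flags=d["ordinal_flags"],
            coupling_k=d["coupling_k"],
            enriched_sets=set(d.get("enriched_sets", [])),
        )


def _stage_rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stage)))


def _plant_effects(
    rng: np.random.Generator,
    feature_ids: List[str],
    n_de: int,
    effect: float,
    frac_ordinal: float,
) -> Tuple[np.ndarray, Dict[str, Dict[str, float]], Dict[str, bool]]:
    """Pick DE features and build their per-group latent offsets.

    Returns (group_offsets[n_features, 3], effects-by-contrast, ordinal flags).
    """
    n = len(feature_ids)
    offsets = np.zeros((n, 3))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    ordinal = rng.random(n_de) < frac_ordinal
    effects: Dict[str, Dict[str, float]] = {}
    flags: Dict[str, bool] = {}
    for j, (i, s, is_ord) in enumerate(zip(de_idx, signs, ordinal)):
        d = s * effect
        if is_ord:
            offsets[i] = [0.0, d, 2 * d]
            per_contrast = {"parAF_vs_nonAF": d, "persAF_vs_nonAF": 2 * d,
                            "persAF_vs_parAF": d}
        else:
            offsets[i] = [0.0, d, 0.0]
            per_contrast = {"parAF_vs_nonAF": d, "persAF_vs_nonAF": 0.0,
                            "persAF_vs_parAF": -d}
        fid = feature_ids[i]
        effects[fid] = per_contrast
        flags[fid] = bool(is_ord)
    return offsets, effects, flags


def _nb_counts(
    rng: np.random.Generator,
    latent: np.ndarray,
    libsizes: np.ndarray,
    dispersion: float,
) -> np.ndarray:
    mu = libsizes[None, :] * np.exp2(latent) / 1e6
    shape = 1.0 / dispersion
    p = shape / (shape + mu)
    return rng.negative_binomial(shape, p)


def simulate_cohort(
    config: SimConfig,
) -> Tuple[pd.DataFrame, CountMatrix, CountMatrix, SyntheticTruth]:
    """Generate a three-group cohort with planted DE and miRNA repression.

    Returns the sample sheet, the miRNA and mRNA count matrices and the
    ground truth.  Planted couplings preferentially use planted-DE miRNAs
    as regulators and non-DE mRNAs as targets, so a target's expression
    shift is attributable to the coupling alone.
    """
    rng = _stage_rng(config, 0)
    n_samples = sum(config.n_per_group)
    groups = np.repeat(np.arange(3), config.n_per_group)
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": [GROUPS[g] for g in groups],
            "age": np.round(rng.uniform(*_AGE_RANGE, size=n_samples), 1),
            "gender": rng.integers(0, 2, size=n_samples),
        }
    )

    mirna_ids = [f"miR-{i:04d}" for i in range(config.n_mirna)]
    mrna_ids = [f"GENE{i:04d}" for i in range(config.n_mrna)]

    n_de_mi = int(round(config.frac_de_mirna * config.n_mirna))
    n_de_m = int(round(config.frac_de_mrna * config.n_mrna))
    mi_offsets, de_mirnas, mi_flags = _plant_effects(
        rng, mirna_ids, n_de_mi, config.effect_log2fc, config.frac_ordinal
    )
    m_offsets, de_mrnas, m_flags = _plant_effects(
        rng, mrna_ids, n_de_m, config.effect_log2fc, config.frac_ordinal
    )

    def latent_matrix(n_feat: int, offsets: np.ndarray) -> np.ndarray:
        base = rng.uniform(*_BASE_RANGE, size=n_feat)
        b_age = rng.normal(0.0, _AGE_BETA_SD, size=n_feat)
        b_sex = rng.normal(0.0, _SEX_BETA_SD, size=n_feat)
        lam = (
            base[:, None]
            + offsets[:, groups]
            + b_age[:, None] * (samples["age"].to_numpy() - 65.0)[None, :]
            + b_sex[:, None] * samples["gender"].to_numpy()[None, :]
            + rng.normal(0.0, config.latent_sd, size=(n_feat, n_samples))
        )
        return lam

    lam_mi = latent_matrix(config.n_mirna, mi_offsets)
    lam_m = latent_matrix(config.n_mrna, m_offsets)

    # Planted couplings: regulators from the planted-DE miRNAs (all miRNAs
    # if none were planted), targets distinct non-DE mRNAs where possible.
    if config.n_true_pairs > config.n_mrna:
        raise ConfigurationError("n_true_pairs exceeds the mRNA universe")
    de_mi_idx = sorted(mirna_ids.index(f) for f in de_mirnas)
    regulator_pool = de_mi_idx if de_mi_idx else list(range(config.n_mirna))
    non_de_m_idx = [i for i, f in enumerate(mrna_ids) if f not in de_mrnas]
    target_pool = non_de_m_idx if len(non_de_m_idx) >= config.n_true_pairs \
        else list(range(config.n_mrna))
    regulators = rng.choice(regulator_pool, size=config.n_true_pairs)
    targets = rng.choice(target_pool, size=config.n_true_pairs, replace=False)
    true_pairs = frozenset(
        (mirna_ids[m], mrna_ids[t]) for m, t in zip(regulators, targets)
    )
    centred = lam_mi - lam_mi.mean(axis=1, keepdims=True)
    for m, t in zip(regulators, targets):
        lam_m[t] -= config.coupling_k * centred[m]

    lib_mi = rng.uniform(*config.libsize_range, size=n_samples)
    lib_m = rng.uniform(*config.libsize_range, size=n_samples)
    counts_mi = _nb_counts(rng, lam_mi, lib_mi, config.dispersion)
    counts_m = _nb_counts(rng, lam_m, lib_m, config.dispersion)

    cm_mi = CountMatrix(
        counts=pd.DataFrame(counts_mi, index=mirna_ids, columns=sample_ids),
        kind="miRNA",
    )
    cm_m = CountMatrix(
        counts=pd.DataFrame(counts_m, index=mrna_ids, columns=sample_ids),
        kind="mRNA",
    )
    truth = SyntheticTruth(
        mirna_ids=tuple(mirna_ids),
        mrna_ids=tuple(mrna_ids),
        true_pairs=true_pairs,
        de_mirnas=de_mirnas,
        de_mrnas=de_mrnas,
        ordinal_flags={**mi_flags, **m_flags},
        coupling_k=config.coupling_k,
    )
    return samples, cm_mi, cm_m, truth


# Score generators per source emit values that pass the reference thresholds.
_SCORE_RANGES = {
    "miRDB": (75.0, 100.0),
    "TargetScan": (-0.30, -0.01),
    "DIANA-microT": (0.85, 1.0),
    "RNA22": (0.02, 0.30),
}
_RNA22_FE_RANGE = (-35.0, -18.0)


def simulate_target_evidence(
    truth: SyntheticTruth, config: SimConfig
) -> pd.DataFrame:
    """Emit per-source interaction evidence for planted pairs and decoys.

    Each of the four prediction sources and two validated sources emits each
    planted pair independently with probability ``db_sensitivity``; decoy
    (unplanted) pairs are emitted at rate ``db_decoy_rate`` per source.
    Scores are drawn so that emitted records pass the reference per-source
    thresholds.
    """
    if len(truth.mirna_ids) != config.n_mirna or len(truth.mrna_ids) != config.n_mrna:
        raise ConfigurationError("truth does not match the configured universe")
    rng = _stage_rng(config, 1)
    n_mi, n_m = config.n_mirna, config.n_mrna
    mirna_ids = np.asarray(truth.mirna_ids)
    mrna_ids = np.asarray(truth.mrna_ids)

    mi_index = {f: i for i, f in enumerate(truth.mirna_ids)}
    m_index = {f: i for i, f in enumerate(truth.mrna_ids)}
    true_sorted = sorted(truth.true_pairs)
    true_lin = np.array(
        [mi_index[m] * n_m + m_index[t] for m, t in true_sorted], dtype=np.int64
    )
    decoy_pool = np.setdiff1d(np.arange(n_mi * n_m, dtype=np.int64), true_lin)

    records = []
    for source in PREDICTION_SOURCES + VALIDATED_SOURCES:
        emitted = true_lin[rng.random(len(true_lin)) < config.db_sensitivity]
        n_decoys = rng.binomial(len(decoy_pool), config.db_decoy_rate)
        decoys = rng.choice(decoy_pool, size=n_decoys, replace=False)
        lin = np.concatenate([emitted, decoys])
        if len(lin) == 0:
            continue
        mirnas = mirna_ids[lin // n_m]
        mrnas = mrna_ids[lin % n_m]
        df = pd.DataFrame({"mirna": mirnas, "mrna": mrnas, "source": source})
        if source in _SCORE_RANGES:
            lo, hi = _SCORE_RANGES[source]
            df["score"] = rng.uniform(lo, hi, size=len(df))
        else:
            df["score"] = np.nan
        if source == "RNA22":
            df["free_energy"] = rng.uniform(*_RNA22_FE_RANGE, size=len(df))
        else:
            df["free_energy"] = np.nan
        records.append(df)

    if not records:
        evidence = pd.DataFrame(
            columns=["mirna", "mrna", "source", "score", "free_energy"]
        )
        return evidence
    evidence = pd.concat(records, ignore_index=True)
    return validate_target_evidence(evidence)


def simulate_gene_sets(
    truth: SyntheticTruth, config: SimConfig
) -> GeneSetCollection:
    """Build a gene-set collection; enriched sets over-sample planted targets.

    A fraction ``frac_enriched_sets`` of the sets samples planted target
    mRNAs with weight ``set_enrichment`` relative to background genes.
    The chosen enriched set ids are recorded in ``truth.enriched_sets``.
    """
    rng = _stage_rng(config, 2)
    universe = np.asarray(truth.mrna_ids)
    lo, hi = config.set_size_range
    if hi > len(universe):
        raise ConfigurationError("set size range exceeds the mRNA universe")
    n_sets = config.n_gene_sets
    n_enriched = int(round(config.frac_enriched_sets * n_sets))
    enriched_idx = set(
        rng.choice(n_sets, size=n_enriched, replace=False).tolist()
    )
    planted = np.isin(universe, sorted(truth.target_mrnas))

    sets: Dict[str, FrozenSet[str]] = {}
    names: Dict[str, str] = {}
    scores: Dict[str, float] = {}
    truth.enriched_sets = set()
    for i in range(n_sets):
        set_id = f"GS{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        if i in enriched_idx:
            w = np.where(planted, config.set_enrichment, 1.0)
            members = rng.choice(
                universe, size=size, replace=False, p=w / w.sum()
            )
            truth.enriched_sets.add(set_id)
        else:
            members = rng.choice(universe, size=size, replace=False)
        sets[set_id] = frozenset(members.tolist())
        names[set_id] = f"process_{i}"
        scores[set_id] = float(rng.normal(0.0, 2.0))
    return GeneSetCollection(sets=sets, names=names, direction_score=scores)
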