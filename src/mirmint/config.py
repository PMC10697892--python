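"""Configuration objects for simulation and analysis runs.

All thresholds default to the settings used throughout the package's
reference analysis of atrial tissue: BH FDR 0.05, |log2FC| cut-offs of 1
(miRNA) and 0.5 (mRNA), average log2-CPM > 1 for the top-miRNA selection,
a CPM > 3 expression filter for the KS target-shift test, |Pearson R| > 0.4
for correlation calls, the per-database prediction-score thresholds, and
1000 permutations for the enrichment nulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

GROUPS = ("nonAF", "parAF", "persAF")

#: Pairwise group contrasts, in reporting order.
CONTRASTS = ("persAF_vs_nonAF", "parAF_vs_nonAF", "persAF_vs_parAF")


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    The defaults emulate the reference atrial-tissue cohort (22 nonAF,
    22 paroxysmal-AF and 20 persistent-AF patients) at a desk-scale feature
    universe, with a planted repressive miRNA->mRNA coupling structure,
    six target-evidence sources of tunable sensitivity/decoy rate, and a
    gene-set collection partially enriched in planted targets.

    Parameters
    ----------
    n_per_group:
        Samples for (nonAF, parAF, persAF).
    n_mirna, n_mrna:
        Feature-universe sizes.
    frac_de_mirna, frac_de_mrna:
        Fractions of features with a planted group effect.
    effect_log2fc:
        Planted per-stage log2 increment (nonAF->parAF and parAF->persAF
        each move the mean by this much for ordinal features).
    frac_ordinal:
        Fraction of planted-DE features whose effect is monotone across the
        three stages; the rest get a transient (up-then-back) pattern.
    coupling_k:
        Repression strength: log2-CPM units of target decrease per unit of
        its regulator miRNA's centred latent log2 expression.
    n_true_pairs:
        Number of planted miRNA->mRNA repressive couplings.
    dispersion:
        Negative-binomial dispersion (var = mu + dispersion * mu^2).
    libsize_range:
        Library sizes are drawn uniformly from this interval.
    latent_sd:
        Standard deviation of per-sample biological (latent) log2 variation.
    db_sensitivity:
        Probability that each source emits a planted pair.
    db_decoy_rate:
        Per-source probability that an unplanted candidate pair is emitted.
    n_gene_sets, set_size_range, set_enrichment, frac_enriched_sets:
        Gene-set collection parameters; enriched sets over-sample planted
        target mRNAs with weight ``set_enrichment``.
    seed:
        Global seed; cohort, database and gene-set stages draw from
        independent child streams so each can be regenerated on its own.
    """

    n_per_group: Tuple[int, int, int] = (22, 22, 20)
    n_mirna: int = 120
    n_mrna: int = 800
    frac_de_mirna: float = 0.12
    frac_de_mrna: float = 0.20
    effect_log2fc: float = 1.0
    frac_ordinal: float = 0.79
    coupling_k: float = 1.0
    n_true_pairs: int = 150
    dispersion: float = 0.2
    libsize_range: Tuple[float, float] = (1e6, 3e6)
    latent_sd: float = 0.8
    db_sensitivity: float = 0.8
    db_decoy_rate: float = 0.01
    n_gene_sets: int = 270
    set_size_range: Tuple[int, int] = (10, 40)
    set_enrichment: float = 3.0
    frac_enriched_sets: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 3 or any(n <= 0 for n in self.n_per_group):
            raise ConfigurationError(
                "n_per_group must hold three positive sample counts"
            )
        for name in ("n_mirna", "n_mrna", "n_true_pairs", "n_gene_sets"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in (
            "frac_de_mirna",
            "frac_de_mrna",
            "frac_ordinal",
            "db_sensitivity",
            "db_decoy_rate",
            "frac_enriched_sets",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.latent_sd < 0:
            raise ConfigurationError("latent_sd must be >= 0")
        lo, hi = self.libsize_range
        if not 0 < lo <= hi:
            raise ConfigurationError("libsize_range must satisfy 0 < lo <= hi")
        lo, hi = self.set_size_range
        if not 0 < lo <= hi:
            raise ConfigurationError("set_size_range must satisfy 0 < lo <= hi")
        if hi > self.n_mrna:
            raise ConfigurationError(
                "set_size_range exceeds the mRNA universe size"
            )
        if self.set_enrichment <= 0:
            raise ConfigurationError("set_enrichment must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_per_group"] = list(self.n_per_group)
        d["libsize_range"] = list(self.libsize_range)
        d["set_size_range"] = list(self.set_size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("n_per_group", "libsize_range", "set_size_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ThresholdConfig:
    """Per-source score thresholds for target-prediction evidence.

    ``targetscan_keep_weaker`` keeps TargetScan records with total context
    score >= ``targetscan_context`` (the literal published rule).  More
    negative context scores indicate stronger predicted repression, so
    setting the flag to False flips the comparison to <= and keeps the
    stronger predictions instead.
    """

    mirdb_min: float = 75.0
    targetscan_context: float = -0.30
    targetscan_keep_weaker: bool = True
    microt_min: float = 0.85
    rna22_min: float = 0.02
    rna22_free_energy_max: float = -18.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdConfig":
        return cls(**d)


@dataclass
class AnalysisConfig:
    """Every knob of the full pipeline, with reference defaults.

    A self-contained run generates its inputs from ``sim``; alternatively
    the count matrices / sample sheet / evidence / gene sets can be given
    as file paths.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    mirna_counts_path: str | None = None
    mrna_counts_path: str | None = None
    sample_sheet_path: str | None = None
    evidence_path: str | None = None
    gene_sets_path: str | None = None

    fdr_threshold: float = 0.05
    mirna_logfc_threshold: float = 1.0
    mrna_logfc_threshold: float = 0.5
    aveexpr_threshold: float = 1.0
    mrna_expr_filter: float = 3.0
    r_threshold: float = 0.4
    trend_tolerance: float = 0.0
    prior_count: float = 0.5
    target_count_flag: int = 10
    n_perm: int = 1000
    enrichment_strategy: str = "stratified"
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        d["thresholds"] = self.thresholds.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = ThresholdConfig.from_dict(d["thresholds"])
        return cls(**d)
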