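"""Pipeline orchestration: simulate -> DE -> integrate -> correlate ->
enrich -> report, as seeded, logged, reproducible runs.

A run is fully determined by its :class:`~mirmint.config.AnalysisConfig`
(including the seed): the same config produces byte-identical outputs.
Each stage can also be run separately on the files a previous stage wrote
(see :mod:`mirmint.cli`); stage-wise and monolithic runs produce identical
results because every random stream is derived from the global seed, never
from execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import AnalysisConfig, CONTRASTS
from . import io_formats
from .io_formats import CountMatrix, GeneSetCollection, write_json
from .synthetic import (
    SyntheticTruth,
    simulate_cohort,
    simulate_gene_sets,
    simulate_target_evidence,
)
from . import diffexpr as de_mod
from .targets import PredictedPairSet, apply_source_thresholds, vote_predicted_pairs
from . import correlation as corr_mod
from . import enrichment as enr_mod


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunSummary:
    """Figures of merit of a full run, JSON-serialisable."""

    counts: Dict[str, int]
    enrichment: Dict[str, dict]
    ks: List[dict]
    regulation: Dict[str, object]
    trend: Dict[str, object]
    multi_mirna_targets: List[str]
    flagged_mirnas: List[str]
    recovery: Dict[str, object]
    config: dict
    seed: int
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "enrichment": self.enrichment,
            "ks": self.ks,
            "regulation": self.regulation,
            "trend": self.trend,
            "multi_mirna_targets": self.multi_mirna_targets,
            "flagged_mirnas": self.flagged_mirnas,
            "recovery": self.recovery,
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
        }


@dataclass
class PipelineData:
    """In-memory carrier of all stage inputs/outputs."""

    samples: pd.DataFrame
    mirna_counts: CountMatrix
    mrna_counts: CountMatrix
    evidence: pd.DataFrame
    gene_sets: GeneSetCollection
    truth: Optional[SyntheticTruth] = None
    mirna_de: Optional[pd.DataFrame] = None
    mrna_de: Optional[pd.DataFrame] = None
    predicted: Optional[PredictedPairSet] = None
    correlations: Optional[pd.DataFrame] = None


def _stamp(config: AnalysisConfig) -> str:
    return f"mirmint={__version__} seed={config.seed}"


def prepare_inputs(config: AnalysisConfig) -> PipelineData:
    """Load inputs from the configured paths, or simulate them."""
    if config.mirna_counts_path:
        samples = io_formats.read_sample_table(config.sample_sheet_path)
        cm_mi = io_formats.read_count_matrix(config.mirna_counts_path, "miRNA")
        cm_m = io_formats.read_count_matrix(config.mrna_counts_path, "mRNA")
        evidence = io_formats.read_target_evidence(config.evidence_path)
        gene_sets = io_formats.read_gmt(config.gene_sets_path)
        truth = None
    else:
        sim = config.sim
        samples, cm_mi, cm_m, truth = simulate_cohort(sim)
        evidence = simulate_target_evidence(truth, sim)
        gene_sets = simulate_gene_sets(truth, sim)
    return PipelineData(
        samples=samples,
        mirna_counts=cm_mi,
        mrna_counts=cm_m,
        evidence=evidence,
        gene_sets=gene_sets,
        truth=truth,
    )


def run_pipeline(
    config: AnalysisConfig, outdir: str | Path | None = None
) -> RunSummary:
    """Execute the full analysis and return (and optionally write) a summary."""
    log: List[str] = [f"mirmint {__version__} seed={config.seed}"]
    data = prepare_inputs(config)
    summary = analyse(config, data, log)
    if outdir is not None:
        write_outputs(config, data, summary, Path(outdir), log)
    return summary


def analyse(
    config: AnalysisConfig, data: PipelineData, log: Optional[List[str]] = None
) -> RunSummary:
    """All analysis stages on prepared inputs."""
    log = log if log is not None else []

    def note(msg: str) -> None:
        log.append(msg)

    # --- differential expression -----------------------------------------
    try:
        expr_mi = de_mod.compute_log2cpm(data.mirna_counts, config.prior_count)
        expr_m = de_mod.compute_log2cpm(data.mrna_counts, config.prior_count)
        data.mirna_de = de_mod.fit_linear_de(expr_mi, data.samples)
        data.mrna_de = de_mod.fit_linear_de(expr_m, data.samples)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("diffexpr", str(exc)) from exc

    de_mirnas = de_mod.select_de(data.mirna_de, config.fdr_threshold)
    top_mirnas = de_mod.select_top_de(
        data.mirna_de,
        logfc_threshold=config.mirna_logfc_threshold,
        aveexpr_threshold=config.aveexpr_threshold,
        fdr_threshold=config.fdr_threshold,
    )
    de_mrnas = de_mod.select_de(data.mrna_de, config.fdr_threshold)
    note(
        f"DE selection: fdr<{config.fdr_threshold}; top selection: "
        f"|log2FC|>{config.mirna_logfc_threshold}, "
        f"AveExpr>{config.aveexpr_threshold}"
    )
    trend_all = de_mod.classify_trend(data.mirna_de, config.trend_tolerance)
    trend_de = trend_all.loc[sorted(de_mirnas)]
    n_ordinal = int((trend_de != "non_ordinal").sum())
    trend_summary = {
        "n_de": len(de_mirnas),
        "n_ordinal": n_ordinal,
        "fraction": (n_ordinal / len(de_mirnas)) if de_mirnas else float("nan"),
        "percent": round(100.0 * n_ordinal / len(de_mirnas), 1)
        if de_mirnas
        else float("nan"),
        "tolerance": config.trend_tolerance,
    }

    # --- target integration ----------------------------------------------
    try:
        filtered = apply_source_thresholds(data.evidence, config.thresholds)
        data.predicted = vote_predicted_pairs(filtered)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("targets", str(exc)) from exc
    note(
        "thresholds: miRDB>=%.3g TargetScan%s%.3g microT>=%.3g "
        "RNA22>=%.3g/FE<=%.3g"
        % (
            config.thresholds.mirdb_min,
            ">=" if config.thresholds.targetscan_keep_weaker else "<=",
            config.thresholds.targetscan_context,
            config.thresholds.microt_min,
            config.thresholds.rna22_min,
            config.thresholds.rna22_free_energy_max,
        )
    )

    # --- correlation network ---------------------------------------------
    try:
        data.correlations = corr_mod.pearson_correlations(
            expr_mi, expr_m, de_mirnas
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("correlate", str(exc)) from exc
    negative, positive = corr_mod.classify_pairs(
        data.correlations, config.r_threshold, config.fdr_threshold
    )
    interactions = corr_mod.build_interactions(
        negative, data.predicted, data.mirna_de, data.mrna_de
    )
    inter_summary = corr_mod.summarize_interactions(
        interactions,
        top_mirnas,
        mrna_de_logfc=_best_abs_logfc(data.mrna_de),
        mrna_de_fdr=_min_fdr(data.mrna_de),
        mrna_logfc_threshold=config.mrna_logfc_threshold,
        fdr_threshold=config.fdr_threshold,
        target_count_flag=config.target_count_flag,
    )

    # --- enrichment statistics -------------------------------------------
    tested = data.correlations.dropna(subset=["r"])
    universe = set(zip(tested["mirna"], tested["mrna"]))
    predicted_pairs = data.predicted.pairs
    neg_pairs = set(zip(negative["mirna"], negative["mrna"]))
    pos_pairs = set(zip(positive["mirna"], positive["mrna"]))
    enrichment = {}
    for label, selected in (("negative", neg_pairs), ("positive", pos_pairs)):
        res = enr_mod.permutation_pair_enrichment(
            selected,
            predicted_pairs,
            universe,
            n_perm=config.n_perm,
            seed=config.seed,
            strategy=config.enrichment_strategy,
        )
        enrichment[label] = res.to_dict()

    mean_cpm = expr_m.cpm.mean(axis=1)
    targets_by_mirna = data.predicted.targets_by_mirna()
    ks_records: List[dict] = []
    for mirna in sorted(top_mirnas & de_mirnas):
        try:
            rec = enr_mod.ks_target_shift(
                mirna,
                data.correlations,
                targets_by_mirna.get(mirna, set()),
                mrna_expr=mean_cpm,
                mrna_expr_filter=config.mrna_expr_filter,
            )
            ks_records.append(rec.to_dict())
        except enr_mod.EnrichmentError as exc:
            note(f"KS skipped: {exc}")

    regulation = enr_mod.process_regulation_test(
        data.gene_sets,
        de_mirnas,
        targets_by_mirna,
        all_mirnas=list(data.mirna_counts.feature_ids),
        n_perm=config.n_perm,
        seed=config.seed,
        alpha=config.fdr_threshold,
    )
    regulation_summary = {
        "n_sets": int(len(regulation.records)),
        "n_significant": int(
            (regulation.records["p_perm"] < config.fdr_threshold).sum()
        ),
        "n_significant_fdr": int(
            (regulation.records["fdr"] < config.fdr_threshold).sum()
        ),
        "overall_factor": regulation.overall_factor,
        "overall_factor_note": regulation.overall_factor_note,
    }

    interaction_genes = sorted(set(interactions["mrna"])) if len(interactions) else []
    if interaction_genes:
        ora = enr_mod.hypergeometric_ora(
            interaction_genes,
            data.gene_sets,
            background=list(data.mrna_counts.feature_ids),
        )
        n_ora_sig = int((ora["fdr"] < config.fdr_threshold).sum())
    else:
        ora = None
        n_ora_sig = 0

    # --- ground-truth recovery (synthetic runs only) ----------------------
    recovery: Dict[str, object] = {}
    if data.truth is not None:
        truth = data.truth
        inter_pairs = set(zip(interactions["mirna"], interactions["mrna"]))
        truth_in_universe = set(truth.true_pairs) & universe
        recovery = {
            "n_true_pairs": len(truth.true_pairs),
            "n_true_pairs_tested": len(truth_in_universe),
            "planted_pair_recall": (
                len(inter_pairs & truth_in_universe) / len(truth_in_universe)
                if truth_in_universe
                else float("nan")
            ),
            "de_mirna_recall": (
                len(de_mirnas & set(truth.de_mirnas)) / len(truth.de_mirnas)
                if truth.de_mirnas
                else float("nan")
            ),
            "enriched_set_recall": (
                int(
                    (
                        regulation.records.loc[
                            sorted(
                                set(truth.enriched_sets)
                                & set(regulation.records.index)
                            ),
                            "fdr",
                        ]
                        < config.fdr_threshold
                    ).sum()
                )
                / len(truth.enriched_sets)
                if truth.enriched_sets
                else float("nan")
            ),
        }

    summary = RunSummary(
        counts={
            "samples": int(len(data.samples)),
            "mirnas": int(len(data.mirna_counts.feature_ids)),
            "mrnas": int(len(data.mrna_counts.feature_ids)),
            "de_mirnas": len(de_mirnas),
            "top_de_mirnas": len(top_mirnas),
            "de_mrnas": len(de_mrnas),
            "evidence_records": int(len(data.evidence)),
            "predicted_pairs": len(data.predicted),
            "negative_pairs": int(len(negative)),
            "positive_pairs": int(len(positive)),
            "interactions": int(len(interactions)),
            "top_interactions": int(len(inter_summary["top_table"])),
            "undefined_correlations": int(
                data.correlations["r"].isna().sum()
            ),
            "ora_significant_sets": n_ora_sig,
        },
        enrichment=enrichment,
        ks=ks_records,
        regulation=regulation_summary,
        trend=trend_summary,
        multi_mirna_targets=list(inter_summary["multi_mirna_targets"]),
        flagged_mirnas=list(inter_summary["flagged_mirnas"]),
        recovery=recovery,
        config=config.to_dict(),
        seed=config.seed,
    )
    # stash frames for the writer
    summary._frames = {  # type: ignore[attr-defined]
        "negative": negative,
        "positive": positive,
        "interactions": interactions,
        "top_table": inter_summary["top_table"],
        "target_counts": inter_summary["target_counts"],
        "regulation": regulation.records,
        "ora": ora,
        "mean_cpm": mean_cpm,
        "targets_by_mirna": targets_by_mirna,
        "top_mirnas": top_mirnas,
        "log": log,
    }
    return summary


def _best_abs_logfc(de_table: pd.DataFrame) -> pd.Series:
    cols = [f"logfc_{c}" for c in CONTRASTS]
    arr = de_table[cols].to_numpy()
    best = arr[np.arange(len(arr)), np.abs(arr).argmax(axis=1)]
    return pd.Series(best, index=de_table.index)


def _min_fdr(de_table: pd.DataFrame) -> pd.Series:
    cols = [f"fdr_{c}" for c in CONTRASTS]
    return de_table[cols].min(axis=1)


def write_outputs(
    config: AnalysisConfig,
    data: PipelineData,
    summary: RunSummary,
    outdir: Path,
    log: List[str],
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(config)
    frames = getattr(summary, "_frames", {})

    io_formats.write_sample_table(data.samples, outdir / "samples.csv")
    io_formats.write_count_matrix(
        data.mirna_counts, outdir / "mirna_counts.tsv", stamp=stamp
    )
    io_formats.write_count_matrix(
        data.mrna_counts, outdir / "mrna_counts.tsv", stamp=stamp
    )
    io_formats.write_target_evidence(
        data.evidence, outdir / "evidence.tsv", stamp=stamp
    )
    io_formats.write_gmt(data.gene_sets, outdir / "gene_sets.gmt")
    if data.truth is not None:
        io_formats.write_truth(data.truth, outdir / "truth.json")

    de_mod.write_de_table(data.mirna_de, outdir / "mirna_de.tsv")
    de_mod.write_de_table(data.mrna_de, outdir / "mrna_de.tsv")
    data.predicted.write(outdir / "predicted_pairs.tsv")

    # full correlation table gated by |r| to bound file size
    gated = data.correlations[
        data.correlations["r"].abs() > min(0.3, config.r_threshold)
    ]
    gated.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    frames["negative"].to_csv(outdir / "negative_pairs.tsv", sep="\t", index=False)
    frames["positive"].to_csv(outdir / "positive_pairs.tsv", sep="\t", index=False)
    corr_mod.write_interaction_table(
        frames["interactions"], outdir / "interactions.tsv"
    )
    corr_mod.write_interaction_table(
        frames["top_table"], outdir / "top_interactions.tsv"
    )
    frames["target_counts"].to_csv(outdir / "target_counts.tsv", sep="\t")

    write_json(summary.enrichment, outdir / "enrichment.json")
    pd.DataFrame(summary.ks).to_csv(outdir / "ks_table.tsv", sep="\t", index=False)
    frames["regulation"].to_csv(outdir / "process_regulation.tsv", sep="\t")
    if frames.get("ora") is not None:
        frames["ora"].to_csv(outdir / "ora.tsv", sep="\t")

    cdf_frames = []
    for mirna in sorted(frames.get("top_mirnas", set())):
        targets = frames["targets_by_mirna"].get(mirna, set())
        if not targets:
            continue
        cdf_frames.append(
            enr_mod.ks_cdf_coordinates(
                mirna,
                data.correlations,
                targets,
                mrna_expr=frames["mean_cpm"],
                mrna_expr_filter=config.mrna_expr_filter,
            )
        )
    if cdf_frames:
        pd.concat(cdf_frames, ignore_index=True).to_csv(
            outdir / "ks_cdf.tsv", sep="\t", index=False
        )

    write_json(summary.to_dict(), outdir / "summary.json")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    with open(outdir / "log.txt", "w") as fh:
        fh.write("\n".join(log) + "\n")
    with open(outdir / "report.txt", "w") as fh:
        fh.write(report_summary(summary))


def report_summary(summary: RunSummary) -> str:
    """Render a human-readable report of a run."""
    s = summary.to_dict()
    lines = [
        f"mirmint {s['version']} run report (seed {s['seed']})",
        "=" * 50,
        "",
        "Stage counts",
        "-" * 12,
    ]
    for key, val in s["counts"].items():
        lines.append(f"{key:>24}: {val}")
    lines += ["", "Ordinal trend", "-" * 13]
    t = s["trend"]
    if t["n_de"]:
        lines.append(
            f"{t['n_ordinal']} of {t['n_de']} DE miRNAs "
            f"({t['percent']:.0f}%) follow an ordinal stage trend"
        )
    else:
        lines.append("(no DE miRNAs)")
    lines += ["", "Pair enrichment", "-" * 15]
    for label, e in s["enrichment"].items():
        lines.append(
            f"{label}: observed {e['observed_overlap']} vs expected "
            f"{e['expected_overlap']:.1f} -> enrichment {e['enrichment']:.2f} "
            f"(p={e['p_perm']:.4g}, {e['n_perm']}x {e['strategy']})"
        )
    lines += ["", "KS target shift", "-" * 15]
    if s["ks"]:
        for rec in s["ks"]:
            lines.append(
                f"{rec['mirna']}: D={rec['D']:.3f} p={rec['p']:.3g} "
                f"(n={rec['n_predicted']}/{rec['n_nonpredicted']})"
            )
    else:
        lines.append("(no testable miRNAs)")
    lines += ["", "Gene-set regulation", "-" * 19]
    r = s["regulation"]
    lines.append(
        f"{r['n_significant']} of {r['n_sets']} sets significant "
        f"(factor {r['overall_factor']:.2f} over chance)"
    )
    lines += ["", "miRNAs with >10 correlated predicted targets", "-" * 44]
    lines.append(", ".join(s["flagged_mirnas"]) or "(none)")
    lines += ["", "mRNAs targeted by >=2 miRNAs in the top table", "-" * 45]
    lines.append(", ".join(s["multi_mirna_targets"]) or "(none)")
    if s["recovery"]:
        lines += ["", "Ground-truth recovery", "-" * 21]
        for key, val in s["recovery"].items():
            if isinstance(val, float):
                lines.append(f"{key:>24}: {val:.3f}")
            else:
                lines.append(f"{key:>24}: {val}")
    lines.append("")
    return "\n".join(lines)
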