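"""Per-source score thresholds and the voting rule that defines a
"predicted" miRNA-mRNA pair.

A pair is predicted iff it is supported by at least two of the four
prediction databases (miRDB, TargetScan, DIANA-microT, RNA22, after each
source's score threshold), or by one prediction database together with at
least one validated database (miRTarBase, DIANA-TarBase).

Note the deliberate asymmetry: evidence from validated databases alone
does NOT qualify a pair — the rule requires at least one in-silico
prediction.  Duplicate records from one source count once.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import FrozenSet, Set, Tuple

import numpy as np
import pandas as pd

from .config import ThresholdConfig
from .io_formats import (
    ALL_SOURCES,
    PREDICTION_SOURCES,
    VALIDATED_SOURCES,
    validate_target_evidence,
)

#: Bit assigned to each source in the provenance bitmask, in canonical order.
SOURCE_BITS = {source: 1 << i for i, source in enumerate(ALL_SOURCES)}


def apply_source_thresholds(
    evidence: pd.DataFrame, config: ThresholdConfig | None = None
) -> pd.DataFrame:
    """Drop prediction records that fail their source's score threshold.

    miRDB: score >= ``mirdb_min``; DIANA-microT: score >= ``microt_min``;
    RNA22: score >= ``rna22_min`` AND free energy <= ``rna22_free_energy_max``;
    TargetScan: total context score >= ``targetscan_context`` when
    ``targetscan_keep_weaker`` (the literal published comparison), else <=.
    Validated-source records pass unfiltered.
    """
    if config is None:
        config = ThresholdConfig()
    ev = validate_target_evidence(evidence)
    source = ev["source"]
    score = ev["score"]
    keep = pd.Series(True, index=ev.index)
    keep &= ~((source == "miRDB") & (score < config.mirdb_min))
    keep &= ~((source == "DIANA-microT") & (score < config.microt_min))
    if config.targetscan_keep_weaker:
        keep &= ~((source == "TargetScan") & (score < config.targetscan_context))
    else:
        keep &= ~((source == "TargetScan") & (score > config.targetscan_context))
    rna22_fail = (score < config.rna22_min) | (
        ev["free_energy"] > config.rna22_free_energy_max
    )
    keep &= ~((source == "RNA22") & rna22_fail)
    return ev[keep].reset_index(drop=True)


@dataclass
class PredictedPairSet:
    """The post-voting predicted pairs with per-pair source provenance."""

    provenance: pd.DataFrame  # columns: mirna, mrna, sources, n_prediction,
    #                           n_validated, bitmask

    @property
    def pairs(self) -> FrozenSet[Tuple[str, str]]:
        return frozenset(
            zip(self.provenance["mirna"], self.provenance["mrna"])
        )

    def targets_of(self, mirna: str) -> Set[str]:
        sel = self.provenance["mirna"] == mirna
        return set(self.provenance.loc[sel, "mrna"])

    def targets_by_mirna(self) -> dict:
        out: dict = {}
        for m, t in zip(self.provenance["mirna"], self.provenance["mrna"]):
            out.setdefault(m, set()).add(t)
        return out

    def __len__(self) -> int:
        return len(self.provenance)

    def write(self, path: str | Path) -> None:
        self.provenance.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "PredictedPairSet":
        df = pd.read_csv(path, sep="\t")
        return cls(provenance=df)


def voting_rule(supporting_sources: Set[str]) -> bool:
    """The pair-inclusion rule on a set of supporting sources."""
    n_pred = len(supporting_sources & set(PREDICTION_SOURCES))
    n_val = len(supporting_sources & set(VALIDATED_SOURCES))
    return n_pred >= 2 or (n_pred >= 1 and n_val >= 1)


def vote_predicted_pairs(filtered_evidence: pd.DataFrame) -> PredictedPairSet:
    """Apply the voting rule to thresholded evidence."""
    ev = filtered_evidence.drop_duplicates(["mirna", "mrna", "source"])
    if ev.empty:
        empty = pd.DataFrame(
            columns=[
                "mirna", "mrna", "sources", "n_prediction", "n_validated",
                "bitmask",
            ]
        )
        return PredictedPairSet(provenance=empty)
    pred_set = set(PREDICTION_SOURCES)
    val_set = set(VALIDATED_SOURCES)
    grouped = ev.groupby(["mirna", "mrna"], sort=True)["source"].agg(
        lambda s: frozenset(s)
    )
    rows = []
    for (mirna, mrna), sources in grouped.items():
        if not voting_rule(set(sources)):
            continue
        ordered = [s for s in ALL_SOURCES if s in sources]
        rows.append(
            {
                "mirna": mirna,
                "mrna": mrna,
                "sources": ",".join(ordered),
                "n_prediction": len(sources & pred_set),
                "n_validated": len(sources & val_set),
                "bitmask": int(np.bitwise_or.reduce(
                    [SOURCE_BITS[s] for s in sources]
                )),
            }
        )
    provenance = pd.DataFrame(
        rows,
        columns=[
            "mirna", "mrna", "sources", "n_prediction", "n_validated",
            "bitmask",
        ],
    )
    return PredictedPairSet(provenance=provenance)
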