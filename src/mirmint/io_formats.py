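"""Readers and writers for every table the pipeline touches.

All formats are plain text: count matrices and target evidence as TSV,
the sample sheet as CSV, gene sets as GMT, ground truth and run summaries
as JSON.  Every reader validates its input strictly and raises
:class:`FormatError` with row/column context; every read/write pair is an
inverse on valid inputs.

Gene and miRNA identifiers are treated as opaque strings throughout; no
nomenclature validation or identifier remapping is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, Mapping, Set, Tuple

import numpy as np
import pandas as pd

from .config import GROUPS

#: In-silico prediction sources, filtered by a per-source score threshold.
PREDICTION_SOURCES = ("miRDB", "TargetScan", "DIANA-microT", "RNA22")
#: Experimentally validated sources, used without score filtering.
VALIDATED_SOURCES = ("miRTarBase", "DIANA-TarBase")
ALL_SOURCES = PREDICTION_SOURCES + VALIDATED_SOURCES

EVIDENCE_COLUMNS = ("mirna", "mrna", "source", "score", "free_energy")

GENDER_SYNONYMS = {
    "0": 0, "1": 1,
    "m": 0, "male": 0,
    "f": 1, "female": 1,
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet: unique ids, known groups, positive ages.

    Expected columns: ``sample_id``, ``group``, ``age``, ``gender``.
    Returns the validated frame (gender coerced to int 0/1).
    """
    required = {"sample_id", "group", "age", "gender"}
    missing = required - set(samples.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"]
        raise FormatError(f"duplicate sample ids: {sorted(set(dup))}")
    bad_groups = set(samples["group"]) - set(GROUPS)
    if bad_groups:
        raise FormatError(
            f"unknown group labels {sorted(bad_groups)}; expected {GROUPS}"
        )
    if (samples["age"] <= 0).any():
        raise FormatError("ages must be positive")
    gender = samples["gender"].astype(str).str.strip().str.lower()
    unknown = set(gender) - set(GENDER_SYNONYMS)
    if unknown:
        raise FormatError(f"unrecognised gender codes: {sorted(unknown)}")
    out = samples.copy()
    out["gender"] = gender.map(GENDER_SYNONYMS).astype(int)
    out["age"] = out["age"].astype(float)
    return out.reset_index(drop=True)


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# gender: 0=male, 1=female\n")
        samples.to_csv(fh, index=False)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise FormatError(f"{path}: empty sample sheet")
    return validate_sample_table(df)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Integer feature x sample count matrix.

    ``counts`` is indexed by feature id with sample ids as columns; ``kind``
    records whether the features are miRNAs or mRNAs.
    """

    counts: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("miRNA", "mRNA"):
            raise FormatError(f"kind must be 'miRNA' or 'mRNA', got {self.kind!r}")
        if self.counts.empty:
            raise FormatError("count matrix is empty")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()]
            raise FormatError(f"duplicate feature ids: {sorted(set(dup))}")
        if self.counts.columns.duplicated().any():
            raise FormatError("duplicate sample ids in count matrix")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            raise FormatError("count matrix must hold integers")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at feature {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def write_count_matrix(
    matrix: CountMatrix, path: str | Path, stamp: str | None = None
) -> None:
    with open(path, "w") as fh:
        if stamp:
            fh.write(f"# {stamp}\n")
        matrix.counts.to_csv(fh, sep="\t", index_label="feature_id")


def read_count_matrix(path: str | Path, kind: str) -> CountMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty count matrix file") from None
    if df.empty:
        raise FormatError(f"{path}: count matrix has no data rows")
    df.index.name = None
    for col in df.columns:
        column = df[col]
        if not np.issubdtype(column.dtype, np.number):
            bad = column[pd.to_numeric(column, errors="coerce").isna()]
            raise FormatError(
                f"{path}: non-numeric count in sample {col!r}, "
                f"feature {bad.index[0]!r}"
            )
        as_float = column.astype(float)
        if not np.all(np.isfinite(as_float)):
            raise FormatError(f"{path}: non-finite count in sample {col!r}")
        if not np.all(as_float == np.floor(as_float)):
            bad_idx = column.index[as_float != np.floor(as_float)][0]
            raise FormatError(
                f"{path}: non-integer count at feature {bad_idx!r}, "
                f"sample {col!r}"
            )
    return CountMatrix(counts=df.astype(np.int64), kind=kind)


# ---------------------------------------------------------------------------
# Target evidence
# ---------------------------------------------------------------------------

def validate_target_evidence(evidence: pd.DataFrame) -> pd.DataFrame:
    """Validate per-source interaction evidence.

    Prediction-source rows must carry a score; RNA22 rows additionally a
    binding free energy (kcal/mol).  Validated sources carry no score.
    """
    missing = set(EVIDENCE_COLUMNS[:3]) - set(evidence.columns)
    if missing:
        raise FormatError(f"evidence table missing columns: {sorted(missing)}")
    ev = evidence.copy()
    for col in ("score", "free_energy"):
        if col not in ev.columns:
            ev[col] = np.nan
        ev[col] = pd.to_numeric(ev[col], errors="coerce")
    unknown = set(ev["source"]) - set(ALL_SOURCES)
    if unknown:
        raise FormatError(
            f"unknown evidence source(s) {sorted(unknown)}; "
            f"expected one of {ALL_SOURCES}"
        )
    pred = ev["source"].isin(PREDICTION_SOURCES)
    if ev.loc[pred, "score"].isna().any():
        row = ev.loc[pred & ev["score"].isna()].iloc[0]
        raise FormatError(
            f"prediction-source record without score: "
            f"{row['mirna']}/{row['mrna']} ({row['source']})"
        )
    rna22 = ev["source"] == "RNA22"
    if ev.loc[rna22, "free_energy"].isna().any():
        row = ev.loc[rna22 & ev["free_energy"].isna()].iloc[0]
        raise FormatError(
            f"RNA22 record without free energy: {row['mirna']}/{row['mrna']}"
        )
    return ev[list(EVIDENCE_COLUMNS)].reset_index(drop=True)


def write_target_evidence(
    evidence: pd.DataFrame, path: str | Path, stamp: str | None = None
) -> None:
    with open(path, "w") as fh:
        if stamp:
            fh.write(f"# {stamp}\n")
        evidence.to_csv(fh, sep="\t", index=False)


def read_target_evidence(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty evidence file") from None
    return validate_target_evidence(df)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """A named collection of gene sets with optional per-set direction scores.

    ``direction_score`` carries each set's sign(log2FC) * -log10(FDR)
    summary from the upstream expression analysis (stored in the GMT
    description field on disk).
    """

    sets: Dict[str, FrozenSet[str]]
    names: Dict[str, str] = field(default_factory=dict)
    direction_score: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {set_id!r} has no members")
            self.sets[set_id] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def universe(self) -> Set[str]:
        out: Set[str] = set()
        for members in self.sets.values():
            out |= members
        return out


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, members in collection.sets.items():
            score = collection.direction_score.get(set_id)
            name = collection.names.get(set_id, set_id)
            desc = name if score is None else f"{name}|score={score:.6g}"
            fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: Dict[str, FrozenSet[str]] = {}
    names: Dict[str, str] = {}
    scores: Dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "need id, description and >=1 member"
                )
            set_id, desc, members = fields[0], fields[1], fields[2:]
            if set_id in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            if "|score=" in desc:
                name, _, score_txt = desc.rpartition("|score=")
                try:
                    scores[set_id] = float(score_txt)
                    desc = name
                except ValueError:
                    pass
            sets[set_id] = frozenset(members)
            names[set_id] = desc
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, names=names, direction_score=scores)


# ---------------------------------------------------------------------------
# Ground truth (JSON)
# ---------------------------------------------------------------------------

def write_truth(truth: "SyntheticTruth", path: str | Path) -> None:
    from .synthetic import SyntheticTruth  # local import to avoid a cycle

    assert isinstance(truth, SyntheticTruth)
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def read_truth(path: str | Path) -> "SyntheticTruth":
    from .synthetic import SyntheticTruth

    with open(path) as fh:
        return SyntheticTruth.from_dict(json.load(fh))


def write_json(obj: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)}")


def pairs_to_frame(pairs: Iterable[Tuple[str, str]]) -> pd.DataFrame:
    return pd.DataFrame(sorted(pairs), columns=["mirna", "mrna"])
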