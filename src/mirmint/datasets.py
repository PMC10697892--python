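"""Reference result tables from the atrial-tissue miRNA-mRNA analysis,
shipped with the package as worked-example inputs.

``load_top_de_mirnas`` returns the 36 most differentially expressed atrial
miRNAs (those passing FDR < 0.05 with |log2FC| > 1 in at least one of the
three AF-stage contrasts), in the same shape that
:func:`mirmint.diffexpr.fit_linear_de` produces (AveExpr plus per-contrast
log2FC and FDR).  ``load_top_interactions`` returns the 31 top predicted
and anti-correlated miRNA-mRNA interactions with Pearson r, FDR, the
target's DE statistics and validated/predicted provenance flags.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .config import CONTRASTS


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("mirmint.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_top_de_mirnas() -> pd.DataFrame:
    """The 36-row top differential-expression table, indexed by miRNA."""
    df = _read("af_top_de_mirnas.tsv").set_index("feature")
    expected = ["ave_expr"] + [
        f"{kind}_{c}" for c in CONTRASTS for kind in ("logfc", "fdr")
    ]
    assert set(expected) <= set(df.columns)
    return df


def load_top_interactions() -> pd.DataFrame:
    """The 31-row top interaction table (miRNA, target, r, FDR, flags)."""
    return _read("af_top_interactions.tsv")
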