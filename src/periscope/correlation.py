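"""Correlation of peripheral immune scores with external patient annotations.

Bridges peripheral signature matrices (enrichment scores or cell
fractions) to per-patient numeric annotations such as tumor-derived
immune scores, lineage scores, or hormone-receptor expression.  Each
(peripheral row × annotation column) pair is tested with two-sided
Pearson correlation; pairs are flagged at numerical p < 0.05 and a
Benjamini-Hochberg column is emitted additionally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ValidationError

__all__ = ["correlate_matrix"]


def correlate_matrix(
    peripheral: pd.DataFrame,
    annotations: pd.DataFrame,
    method: str = "pearson",
    flag_alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise correlation of peripheral rows against annotation columns.

    ``peripheral``: feature × patient matrix; ``annotations``: patient ×
    variable table; patients are matched by identifier, and each pair
    needs at least 3 matched patients.  Zero-variance vectors give a
    missing (NaN) correlation rather than 0.
    """
    if method not in {"pearson", "spearman"}:
        raise ValueError(f"unsupported method {method!r}")
    common = [p for p in peripheral.columns if p in annotations.index]
    if len(common) < 3:
        raise ValidationError("fewer than 3 matched patients")
    per = peripheral[common]
    ann = annotations.loc[common]
    rows = []
    for feat in per.index:
        x_full = per.loc[feat].astype(float)
        for var in ann.columns:
            y_full = pd.to_numeric(ann[var], errors="coerce")
            mask = x_full.notna() & y_full.notna()
            x, y = x_full[mask].to_numpy(), y_full[mask].to_numpy()
            if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
                r, p = np.nan, np.nan
            elif method == "pearson":
                r, p = stats.pearsonr(x, y)
            else:
                r, p = stats.spearmanr(x, y)
            rows.append({"peripheral": feat, "annotation": var, "n": int(len(x)), "r": r, "p": p})
    out = pd.DataFrame(rows)
    padj = np.full(len(out), np.nan)
    ok = out["p"].notna().to_numpy()
    if ok.any():
        padj[ok] = multipletests(out.loc[ok, "p"].to_numpy(), method="fdr_bh")[1]
    out["padj"] = padj
    out["flag"] = (out["p"] < flag_alpha).fillna(False)
    return out
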