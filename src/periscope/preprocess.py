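"""Gene filtering, normalization and variance-stabilizing transform.

Every expression-based stage consumes a :class:`TransformedMatrix`.  The
filter drops genes detected (count > 0) in fewer than half of the
samples; ``log_cpm`` is ``log2(1e6 * count / library_size + 1)``;
``vst_like`` additionally flattens the pooled mean-variance trend with a
single monotone elementwise rescaling, so per-sample gene ranks are
preserved by both transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, ValidationError

__all__ = ["TransformedMatrix", "filter_genes", "normalize_transform", "batch_center"]


@dataclass
class TransformedMatrix:
    """Gene × sample real-valued matrix on a log-like scale."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("values shape inconsistent with id lists")
        if not np.isfinite(arr).all():
            raise ValidationError("non-finite values in transformed matrix")
        self.values = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, samples) -> "TransformedMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in samples]
        return TransformedMatrix(
            list(self.gene_ids), list(samples), self.values[:, cols], dict(self.provenance)
        )


def filter_genes(counts: CountMatrix, min_expressed_fraction: float = 0.5) -> CountMatrix:
    """Keep genes expressed (count > 0) in at least the given fraction of samples.

    The boundary is inclusive: a gene detected in exactly 50% of samples
    is kept (removal applies to *less than* the threshold).  Idempotent.
    """
    n = len(counts.sample_ids)
    frac = (counts.counts > 0).sum(axis=1) / n
    keep = frac >= min_expressed_fraction
    if not keep.any():
        raise ValidationError(
            "gene filter removed every gene; lower min_expressed_fraction "
            f"(currently {min_expressed_fraction})"
        )
    kept = [g for g, k in zip(counts.gene_ids, keep) if k]
    return CountMatrix(kept, list(counts.sample_ids), counts.counts[keep])


def _log_cpm(counts: CountMatrix) -> np.ndarray:
    lib = counts.counts.sum(axis=0).astype(float)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValidationError(f"zero library size for sample {counts.sample_ids[zero[0]]!r}")
    return np.log2(1e6 * counts.counts / lib + 1.0)


def _vst_rescale(values: np.ndarray) -> np.ndarray:
    """Flatten the pooled mean-variance trend of log-scale values.

    Fits a smoothed variance trend v(m) over per-gene means by a running
    median on mean-sorted genes, then applies the classic variance-
    stabilizing map ``t(x) = integral dx / sqrt(v(x))`` — one strictly
    increasing elementwise function, so all rank structure survives.
    """
    n_genes, n_samples = values.shape
    if n_samples < 3 or n_genes < 10:
        return values.copy()
    means = values.mean(axis=1)
    variances = values.var(axis=1, ddof=1)
    order = np.argsort(means, kind="stable")
    m_sorted = means[order]
    v_sorted = variances[order]
    window = max(5, n_genes // 20)
    kernel = np.ones(window) / window
    v_smooth = np.convolve(np.pad(v_sorted, window // 2, mode="edge"), kernel, mode="same")
    v_smooth = v_smooth[window // 2 : window // 2 + n_genes]
    floor = max(1e-3, 0.05 * float(np.median(v_sorted[v_sorted > 0])) if (v_sorted > 0).any() else 1e-3)
    v_smooth = np.maximum(v_smooth, floor)
    # integrate 1/sqrt(v) on a grid spanning the data range
    lo, hi = float(values.min()), float(values.max())
    grid = np.linspace(lo, hi, 512)
    inv_sd = 1.0 / np.sqrt(np.interp(grid, m_sorted, v_smooth))
    t = np.concatenate([[0.0], np.cumsum((inv_sd[1:] + inv_sd[:-1]) / 2 * np.diff(grid))])
    # rescale so the transform roughly preserves the original span
    if t[-1] > 0:
        t = lo + (hi - lo) * t / t[-1]
    return np.interp(values, grid, t)


def normalize_transform(counts: CountMatrix, method: str = "vst_like") -> TransformedMatrix:
    """Normalize library size and transform to a log-like scale.

    ``log_cpm``: ``log2(1e6 * count / library_size + 1)``.
    ``vst_like``: log-CPM followed by a monotone rescaling that flattens
    the pooled mean-variance trend.
    """
    if method not in {"log_cpm", "vst_like"}:
        raise ValueError(f"unknown transform {method!r}")
    values = _log_cpm(counts)
    if method == "vst_like":
        values = _vst_rescale(values)
    return TransformedMatrix(
        list(counts.gene_ids),
        list(counts.sample_ids),
        values,
        provenance={"transform": method, "pseudocount": 1, "log_base": 2},
    )


def batch_center(
    values: TransformedMatrix,
    batches: pd.Series | dict,
    protected: pd.Series | dict | None = None,
) -> TransformedMatrix:
    """Per-gene, per-batch mean centering (grand mean restored).

    A simplified location-only batch adjustment: for each gene, each
    batch's mean is shifted onto the pooled mean.  If ``protected`` gives
    a grouping to preserve (e.g. clinical subtype), the per-group gene
    means present before centering are restored afterwards, so the
    protected contrast is not removed along with the batch effect.
    Batches with one sample are passed through with a warning.
    """
    b = pd.Series(batches)
    missing = [s for s in values.sample_ids if s not in b.index]
    if missing:
        raise ValidationError(f"samples without batch assignment: {missing[:5]}")
    b = b.loc[values.sample_ids]
    out = values.values.copy()
    grand = out.mean(axis=1, keepdims=True)
    prot = None
    prot_means_before = {}
    if protected is not None:
        prot = pd.Series(protected).loc[values.sample_ids]
        for grp in prot.unique():
            cols = np.flatnonzero((prot == grp).to_numpy())
            prot_means_before[grp] = out[:, cols].mean(axis=1, keepdims=True)
    for batch in b.unique():
        cols = np.flatnonzero((b == batch).to_numpy())
        if cols.size == 1:
            warnings.warn(f"batch {batch!r} has a single sample; passed through", stacklevel=2)
            continue
        out[:, cols] += grand - out[:, cols].mean(axis=1, keepdims=True)
    if prot is not None:
        for grp, before in prot_means_before.items():
            cols = np.flatnonzero((prot == grp).to_numpy())
            out[:, cols] += before - out[:, cols].mean(axis=1, keepdims=True)
    prov = dict(values.provenance)
    prov["batch_center"] = {"protected": protected is not None}
    return TransformedMatrix(list(values.gene_ids), list(values.sample_ids), out, prov)
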