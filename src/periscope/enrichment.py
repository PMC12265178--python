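"""Single-sample gene-set scoring and preranked gene-set enrichment.

Two running-sum statistics are implemented from first principles:

* :func:`ssgsea_scores` — the single-sample weighted running-sum score:
  per sample, genes are ranked by expression, the running sum increments
  by ``rank^w`` (normalized over in-set genes) at in-set positions and
  decrements by ``1/(N - m)`` elsewhere, and the score is the integral
  (sum) of the curve.
* :func:`preranked_gsea` — the weighted Kolmogorov-Smirnov enrichment
  statistic of a preranked list with a gene-label permutation null,
  normalized enrichment scores, Benjamini-Hochberg adjustment and
  leading-edge extraction.

Gene ranking for two-group and paired longitudinal contrasts uses Welch
or paired t statistics (:func:`rank_genes`), and the subsampling
stability of a contrast's enrichment calls is measured by
:func:`bootstrap_stability`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection, ValidationError
from .preprocess import TransformedMatrix

__all__ = [
    "EnrichmentMatrix",
    "RankedList",
    "GseaResult",
    "StabilityResult",
    "MAX_FINITE_STATISTIC",
    "ssgsea_scores",
    "rank_genes",
    "preranked_gsea",
    "leading_edge_genes",
    "bootstrap_stability",
]

#: Sentinel magnitude for zero-variance genes in :func:`rank_genes`.
#: Large enough to rank first/last, small enough that powers and sums of
#: a handful of sentinels stay finite.
MAX_FINITE_STATISTIC = 1e12


@dataclass
class EnrichmentMatrix:
    """Gene-set × sample single-sample enrichment scores."""

    set_names: list[str]
    sample_ids: list[str]
    scores: np.ndarray
    method: str = "ssgsea"
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float)
        if arr.shape != (len(self.set_names), len(self.sample_ids)):
            raise ValidationError("score shape inconsistent with labels")
        if not np.isfinite(arr).all():
            raise ValidationError("non-finite enrichment scores")
        self.scores = arr

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.set_names, columns=self.sample_ids)


@dataclass
class RankedList:
    """Genes strictly ordered by a signed ranking statistic (descending)."""

    gene_ids: list[str]
    statistics: np.ndarray

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.statistics):
            raise ValidationError("gene list and statistics length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate genes in ranked list")
        self.statistics = np.asarray(self.statistics, dtype=float)
        d = np.diff(self.statistics)
        if (d > 0).any():
            raise ValidationError("statistics must be sorted descending")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class GseaResult:
    """Per-set enrichment statistics plus stored leading edges."""

    table: pd.DataFrame  # index: set name; columns es, nes, pval, padj, set_size
    leading_edges: dict[str, list[str]]
    ranked: RankedList
    n_perm: int


@dataclass
class StabilityResult:
    """Bootstrap enrichment-call stability per set."""

    table: pd.DataFrame  # columns n_iterations, n_enriched_positive, n_enriched_negative, stability_fraction


# ---------------------------------------------------------------------------
# single-sample scoring


def _running_sum(in_set: np.ndarray, rank_values: np.ndarray, weight: float) -> np.ndarray:
    """Weighted running sum over a ranked universe.

    ``in_set`` is a boolean mask aligned with the ranking (best first);
    ``rank_values`` the per-position weighting values.  When the set
    equals the universe the decrement is defined as 0 (the curve is then
    uninformative, flagged by the caller).
    """
    w = np.abs(rank_values, dtype=float) ** weight
    m = int(in_set.sum())
    n = len(in_set)
    denom = w[in_set].sum()
    steps = np.where(in_set, np.divide(w, denom, out=np.zeros_like(w), where=denom > 0), 0.0)
    if n > m:
        steps[~in_set] = -1.0 / (n - m)
    return np.cumsum(steps)


def _sample_order(values: np.ndarray, gene_ids: Sequence[str]) -> np.ndarray:
    """Indices ordering one sample's genes by expression descending,
    ties broken by gene id ascending (stable and order-independent)."""
    id_rank = np.argsort(np.argsort(np.asarray(gene_ids, dtype=object), kind="stable"))
    return np.lexsort((id_rank, -values))


def ssgsea_scores(
    values: TransformedMatrix,
    sets: GeneSetCollection,
    weight: float = 0.25,
    min_set_size: int = 5,
    normalize: bool = True,
) -> EnrichmentMatrix:
    """Single-sample running-sum enrichment scores per set and sample.

    Per sample, genes are ranked by expression descending (rank value N
    for the top gene down to 1); the raw score of a set is the sum of the
    running-sum curve.  With ``normalize``, all raw scores are divided by
    the (max - min) spread over the whole matrix.  Sets with fewer than
    ``min_set_size`` genes present in the matrix are dropped with a
    warning; scores depend on expression only through ranks.
    """
    n_genes, n_samples = values.shape
    if n_genes == 0:
        raise ValidationError("empty expression universe")
    universe = set(values.gene_ids)
    kept_sets: list[str] = []
    masks: list[np.ndarray] = []
    gene_pos = {g: i for i, g in enumerate(values.gene_ids)}
    for name, gs in sets.items():
        present = [g for g in gs.genes if g in universe]
        if len(present) < min_set_size:
            warnings.warn(
                f"gene set {name!r} has {len(present)} genes in the matrix "
                f"(< {min_set_size}); dropped",
                stacklevel=2,
            )
            continue
        mask = np.zeros(n_genes, dtype=bool)
        mask[[gene_pos[g] for g in present]] = True
        kept_sets.append(name)
        masks.append(mask)
    if not kept_sets:
        raise ValidationError("no gene set passes min_set_size in this matrix")
    rank_values = np.arange(n_genes, 0, -1, dtype=float)
    scores = np.empty((len(kept_sets), n_samples))
    for j in range(n_samples):
        order = _sample_order(values.values[:, j], values.gene_ids)
        for i, mask in enumerate(masks):
            rs = _running_sum(mask[order], rank_values, weight)
            scores[i, j] = rs.sum()
    if normalize:
        spread = scores.max() - scores.min()
        if spread > 0:
            scores = scores / spread
    return EnrichmentMatrix(
        kept_sets,
        list(values.sample_ids),
        scores,
        method="ssgsea",
        parameters={"weight": weight, "min_set_size": min_set_size, "normalize": normalize},
    )


# ---------------------------------------------------------------------------
# gene ranking


def rank_genes(
    values: TransformedMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    paired_by: Mapping[str, str] | None = None,
) -> RankedList:
    """Rank genes by a signed two-group statistic (group a high -> positive).

    Unpaired: Welch t statistic.  Paired (``paired_by`` maps each sample
    id to a patient id): one-sample t on per-patient (a - b) differences.
    Zero-variance genes receive the sentinel ``±MAX_FINITE_STATISTIC``
    with the sign of the mean difference (0 if the means agree); ties are
    broken by gene id.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("need >= 2 samples per group")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValidationError(f"samples in both groups: {sorted(overlap)[:5]}")
    idx = {s: i for i, s in enumerate(values.sample_ids)}
    a = values.values[:, [idx[s] for s in group_a]]
    b = values.values[:, [idx[s] for s in group_b]]
    if paired_by is not None:
        pa = {paired_by[s]: i for i, s in enumerate(group_a)}
        pb = {paired_by[s]: i for i, s in enumerate(group_b)}
        if set(pa) != set(pb):
            raise ValidationError("paired mode requires complete pairs")
        patients = sorted(pa)
        diffs = a[:, [pa[p] for p in patients]] - b[:, [pb[p] for p in patients]]
        mean = diffs.mean(axis=1)
        sd = diffs.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(diffs.shape[1]))
        degenerate = sd == 0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t, _ = stats.ttest_ind(a, b, axis=1, equal_var=False)
        mean = a.mean(axis=1) - b.mean(axis=1)
        degenerate = (a.std(axis=1, ddof=1) == 0) & (b.std(axis=1, ddof=1) == 0)
    t = np.asarray(t, dtype=float)
    sentinel = np.sign(mean) * MAX_FINITE_STATISTIC
    t = np.where(degenerate | ~np.isfinite(t), sentinel, t)
    t[np.isnan(t)] = 0.0
    id_rank = np.argsort(np.argsort(np.asarray(values.gene_ids, dtype=object), kind="stable"))
    order = np.lexsort((id_rank, -t))
    return RankedList([values.gene_ids[i] for i in order], t[order])


# ---------------------------------------------------------------------------
# preranked GSEA


def _es_from_running(rs: np.ndarray) -> tuple[float, int]:
    # earliest extremum within a float tolerance, so near-ties between the
    # positive and negative excursions resolve deterministically
    a = np.abs(rs)
    k = int(np.flatnonzero(a >= a.max() - 1e-12)[0])
    return float(rs[k]), k


def _null_es(
    stats_abs_w: np.ndarray, m: int, n_perm: int, rng: np.random.Generator, chunk: int = 250
) -> np.ndarray:
    """Gene-label permutation null: ES for random m-subsets of positions."""
    n = len(stats_abs_w)
    dec = 0.0 if n == m else 1.0 / (n - m)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        # random m positions per permutation via argpartition of uniforms
        u = rng.random((k, n))
        idx = np.argpartition(u, m - 1, axis=1)[:, :m]
        steps = np.full((k, n), -dec)
        sel = stats_abs_w[idx]
        denom = sel.sum(axis=1, keepdims=True)
        steps[np.arange(k)[:, None], idx] = np.divide(
            sel, denom, out=np.zeros_like(sel), where=denom > 0
        )
        rs = np.cumsum(steps, axis=1)
        ext = np.argmax(np.abs(rs), axis=1)
        out[done : done + k] = rs[np.arange(k), ext]
        done += k
    return out


def preranked_gsea(
    ranked: RankedList,
    sets: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    min_set_size: int = 1,
) -> GseaResult:
    """Preranked GSEA with a gene-label permutation null.

    ES is the extremum of the weighted Kolmogorov running sum; NES is
    ES divided by the mean |null ES| of the same sign; the permutation
    p-value uses additive smoothing ``(1 + hits) / (1 + n_same_sign)``
    and is therefore never 0; BH adjustment is applied across exactly
    the sets scored in this call.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(ranked)
    universe = set(ranked.gene_ids)
    pos = {g: i for i, g in enumerate(ranked.gene_ids)}
    w_abs = np.abs(ranked.statistics) ** weight
    rows = []
    leading: dict[str, list[str]] = {}
    null_cache: dict[int, np.ndarray] = {}
    for name, gs in sets.items():
        absent = [g for g in gs.genes if g not in universe]
        if len(gs.genes) > n:
            raise ValidationError(f"set {name!r} larger than the ranked universe")
        present = [g for g in gs.genes if g in universe]
        if len(present) < min_set_size or not present:
            warnings.warn(f"set {name!r}: {len(present)} genes in universe; dropped", stacklevel=2)
            continue
        if absent:
            warnings.warn(
                f"set {name!r}: {len(absent)} genes absent from the ranked universe", stacklevel=2
            )
        mask = np.zeros(n, dtype=bool)
        mask[[pos[g] for g in present]] = True
        rs = _running_sum(mask, ranked.statistics, weight)
        es, ext = _es_from_running(rs)
        m = len(present)
        if m not in null_cache:
            null_cache[m] = _null_es(w_abs, m, n_perm, rng)
        null = null_cache[m]
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        n_same = len(same)
        pval = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + n_same)
        mean_mag = np.abs(same).mean() if n_same else np.abs(null).mean()
        nes = es / mean_mag if mean_mag > 0 else 0.0
        set_positions = np.flatnonzero(mask)
        if es >= 0:
            le = [ranked.gene_ids[i] for i in set_positions if i <= ext]
        else:
            le = [ranked.gene_ids[i] for i in set_positions if i > ext]
        rows.append({"set": name, "es": es, "nes": nes, "pval": pval, "set_size": m})
        leading[name] = le
    if not rows:
        raise ValidationError("no scoreable sets")
    table = pd.DataFrame(rows).set_index("set")
    table["padj"] = multipletests(table["pval"].to_numpy(), method="fdr_bh")[1]
    table["padj"] = np.maximum(table["padj"], table["pval"])
    return GseaResult(table=table, leading_edges=leading, ranked=ranked, n_perm=n_perm)


def leading_edge_genes(result: GseaResult, set_name: str) -> list[str]:
    """The in-set genes contributing to the enrichment extremum."""
    if set_name not in result.leading_edges:
        raise KeyError(f"set {set_name!r} was not scored")
    return list(result.leading_edges[set_name])


# ---------------------------------------------------------------------------
# bootstrap stability


def bootstrap_stability(
    values: TransformedMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    sets: GeneSetCollection,
    n_iter: int = 50,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    n_perm: int = 200,
    strata: Mapping[str, str] | None = None,
) -> StabilityResult:
    """Stability of enrichment calls under within-group resampling.

    Each iteration resamples samples with replacement within each group
    (stratified by ``strata`` when given), reruns ranking plus preranked
    GSEA, and counts a set as enriched when ``padj < alpha``; the
    stability fraction is ``max(n_pos, n_neg) / n_iter``.
    """
    if len(group_a) < 5 or len(group_b) < 5:
        raise ValidationError("contrast groups must each have >= 5 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def resample(group: Sequence[str]) -> list[str]:
        for _ in range(10):
            if strata is None:
                draw = [group[i] for i in rng.integers(0, len(group), len(group))]
            else:
                draw = []
                by_stratum: dict[str, list[str]] = {}
                for s in group:
                    by_stratum.setdefault(strata[s], []).append(s)
                for members in by_stratum.values():
                    draw += [members[i] for i in rng.integers(0, len(members), len(members))]
            if len(set(draw)) > 1:
                return draw
        raise ValidationError("bootstrap draw collapsed to one distinct sample 10 times")

    counts = {name: [0, 0] for name in sets}
    scored: set[str] = set()
    for _ in range(n_iter):
        draw_a = resample(list(group_a))
        draw_b = resample(list(group_b))
        # duplicate-sample draws get unique column aliases
        sub = values.subset_samples(list(values.sample_ids))
        idx = {s: i for i, s in enumerate(values.sample_ids)}
        cols = [idx[s] for s in draw_a + draw_b]
        aliases = [f"bs{i}" for i in range(len(cols))]
        boot = TransformedMatrix(list(values.gene_ids), aliases, sub.values[:, cols])
        a_ids = aliases[: len(draw_a)]
        b_ids = aliases[len(draw_a) :]
        ranked = rank_genes(boot, a_ids, b_ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = preranked_gsea(ranked, sets, n_perm=n_perm, seed=rng)
        scored |= set(res.table.index)
        sig = res.table[res.table["padj"] < alpha]
        for name, row in sig.iterrows():
            counts[name][0 if row["es"] > 0 else 1] += 1
    rows = []
    for name in sets:
        if name not in scored:
            continue
        n_pos, n_neg = counts[name]
        rows.append(
            {
                "set": name,
                "n_iterations": n_iter,
                "n_enriched_positive": n_pos,
                "n_enriched_negative": n_neg,
                "stability_fraction": max(n_pos, n_neg) / n_iter,
            }
        )
    return StabilityResult(pd.DataFrame(rows).set_index("set"))
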