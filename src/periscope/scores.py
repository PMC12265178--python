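"""Composite immune scores: the 19-gene T-cell panel and leukocyte chemotaxis.

The T-cell composite score summarizes a panel of effector/maturation
genes (e.g. GZMB, PRF1, NKG7, KLRD1, TBX21) as the mean of per-gene
z-scores across the scoring cohort.  The leukocyte-chemotaxis score is
the single-set single-sample enrichment score of a chemotaxis program.
Longitudinal deltas (early treatment minus baseline) feed the response
model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import ssgsea_scores
from .io_formats import GeneSet, GeneSetCollection, SampleTable, ValidationError
from .preprocess import TransformedMatrix

__all__ = ["CompositeScoreTable", "composite_score", "chemotaxis_score", "score_delta"]

log = logging.getLogger(__name__)


@dataclass
class CompositeScoreTable:
    scores: pd.Series  # sample_id -> score
    gene_panel: list[str]
    method: str
    missing_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValidationError("non-finite composite scores")


def composite_score(values: TransformedMatrix, panel: Sequence[str]) -> CompositeScoreTable:
    """Mean of per-gene cohort z-scores over the panel, per sample.

    The z-score cohort is all samples in ``values`` (so baseline and
    on-treatment samples scored in one call are directly comparable).
    Panel genes missing from the matrix are logged and skipped; a
    zero-variance gene contributes 0.
    """
    present = [g for g in panel if g in values.gene_ids]
    missing = [g for g in panel if g not in values.gene_ids]
    if missing:
        log.warning("composite panel genes missing from matrix: %s", missing)
    if not present:
        raise ValidationError("no panel gene present in the expression matrix")
    idx = {g: i for i, g in enumerate(values.gene_ids)}
    x = values.values[[idx[g] for g in present]]
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True) if x.shape[1] > 1 else np.ones_like(mean)
    flat = (sd == 0).ravel()
    if flat.any():
        log.warning("zero-variance panel genes contribute 0: %s", [present[i] for i in np.flatnonzero(flat)])
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - mean) / sd
    scores = pd.Series(z.mean(axis=0), index=values.sample_ids, name="composite_score")
    return CompositeScoreTable(scores, list(panel), method="mean_z", missing_genes=missing)


def chemotaxis_score(
    values: TransformedMatrix,
    sets: GeneSetCollection | GeneSet,
    set_name: str | None = None,
) -> CompositeScoreTable:
    """Single-set single-sample enrichment score (rank-based)."""
    if isinstance(sets, GeneSet):
        gs = sets
    else:
        name = set_name if set_name is not None else next(iter(sets))
        if name not in sets:
            raise ValidationError(f"gene set {name!r} not in collection")
        gs = sets[name]
    em = ssgsea_scores(values, GeneSetCollection([gs]), normalize=True)
    scores = pd.Series(em.scores[0], index=em.sample_ids, name=gs.name)
    return CompositeScoreTable(scores, list(gs.genes), method="ssgsea_single_set")


def score_delta(
    table: CompositeScoreTable,
    metadata: SampleTable,
    from_tp: str = "Baseline",
    to_tp: str = "EarlyTreatment",
) -> pd.DataFrame:
    """Per-patient ``score(to) - score(from)``; incomplete patients omitted."""
    rows = []
    for pid, grp in metadata.frame.groupby("patient_id", sort=True):
        by_tp = grp.set_index("timepoint")["sample_id"].to_dict()
        s_from, s_to = by_tp.get(from_tp), by_tp.get(to_tp)
        if s_from not in table.scores.index or s_to not in table.scores.index:
            log.info("patient %s omitted from score delta (missing timepoint)", pid)
            continue
        rows.append(
            {
                "patient_id": pid,
                "score_from": table.scores[s_from],
                "score_to": table.scores[s_to],
                "delta": table.scores[s_to] - table.scores[s_from],
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "score_from", "score_to", "delta"])
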