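"""PBMC immune-composition subtype (PICS) clustering.

Samples are clustered by hierarchical agglomeration on Euclidean
distances between their immune-cell enrichment-score vectors; the tree
is cut to a requested number of clusters (seven for the PICS-7 scheme).
Each cluster is annotated by the immune-cell supertypes (T cell,
myeloid, B cell, NK) whose member sets score above the global mean at
the cluster centroid.  New samples are assigned by nearest centroid,
and longitudinal composition change is the fraction of patients whose
cluster label differs between two timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .io_formats import SampleTable, ValidationError
from .enrichment import EnrichmentMatrix

__all__ = ["PicsModel", "fit_pics", "annotate_clusters", "assign_pics", "composition_change"]


@dataclass
class PicsModel:
    set_names: list[str]
    k: int
    linkage_method: str
    training_samples: list[str]
    labels: pd.Series  # sample -> cluster 1..k
    centroids: np.ndarray  # k x n_sets, on the (possibly standardized) score scale
    standardize: bool
    scale_means: np.ndarray
    scale_sds: np.ndarray
    annotations: dict[int, str] = field(default_factory=dict)

    def transform(self, scores: EnrichmentMatrix) -> np.ndarray:
        """Project sample scores onto the model's (standardized) space."""
        if list(scores.set_names) != self.set_names:
            raise ValidationError("score rows differ from the training rows")
        x = scores.scores.T.astype(float)
        if self.standardize:
            x = (x - self.scale_means) / self.scale_sds
        return x


def fit_pics(
    scores: EnrichmentMatrix,
    k: int = 7,
    linkage_method: str = "complete",
    standardize: bool = True,
) -> PicsModel:
    """Hierarchical clustering of samples on immune-cell scores, cut to k.

    Scores are per-set z-scored before Euclidean distances unless
    ``standardize`` is off.  Samples are processed in sorted-id order so
    the partition is independent of input column order.
    """
    if linkage_method not in {"complete", "ward", "average"}:
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    n = len(scores.sample_ids)
    if n < k:
        raise ValidationError(f"{n} samples < k={k}")
    order = np.argsort(np.asarray(scores.sample_ids, dtype=object), kind="stable")
    samples = [scores.sample_ids[i] for i in order]
    x = scores.scores[:, order].T.astype(float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    sds = np.where(sds > 0, sds, 1.0)
    if standardize:
        x = (x - means) / sds
    z = linkage(x, method=linkage_method, metric="euclidean")
    raw = fcluster(z, t=k, criterion="maxclust")
    # relabel clusters 1..k by order of first appearance for determinism
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    labels = pd.Series([relabel[l] for l in raw], index=samples, name="pics_cluster")
    if labels.nunique() != k:
        raise ValidationError(f"tree cut produced {labels.nunique()} clusters, expected {k}")
    centroids = np.vstack([x[labels.to_numpy() == c].mean(axis=0) for c in range(1, k + 1)])
    return PicsModel(
        set_names=list(scores.set_names),
        k=k,
        linkage_method=linkage_method,
        training_samples=samples,
        labels=labels,
        centroids=centroids,
        standardize=standardize,
        scale_means=means,
        scale_sds=sds,
    )


def annotate_clusters(
    model: PicsModel,
    supertype_map: Mapping[str, Sequence[str]],
    margin: float = 0.0,
) -> PicsModel:
    """Name each cluster by the supertypes elevated at its centroid.

    A supertype is included when the mean centroid score of its member
    sets exceeds the global (training) mean by more than ``margin``;
    included supertypes are ordered by decreasing excess and joined with
    hyphens (e.g. ``"Myeloid-NK-T cell"``).  A cluster with no elevated
    supertype is named ``"Mixed"``.
    """
    global_mean = np.zeros(len(model.set_names))  # training scores are centered per set
    if not model.standardize:
        # centroid scale is the raw score scale; compare against the
        # across-cluster mean weighted by cluster sizes
        sizes = model.labels.value_counts().sort_index().to_numpy()
        global_mean = (model.centroids * sizes[:, None]).sum(axis=0) / sizes.sum()
    set_idx = {s: i for i, s in enumerate(model.set_names)}
    annotations: dict[int, str] = {}
    for c in range(1, model.k + 1):
        excesses = []
        for supertype, members in supertype_map.items():
            idx = [set_idx[m] for m in members if m in set_idx]
            if not idx:
                continue
            excess = float(np.mean(model.centroids[c - 1, idx] - global_mean[idx]))
            if excess > margin:
                excesses.append((excess, supertype))
        if excesses:
            excesses.sort(key=lambda t: (-t[0], t[1]))
            annotations[c] = "-".join(name for _, name in excesses)
        else:
            annotations[c] = "Mixed"
    model.annotations = annotations
    return model


def assign_pics(model: PicsModel, scores: EnrichmentMatrix) -> pd.Series:
    """Nearest-centroid cluster assignment; ties go to the lower index."""
    x = model.transform(scores)
    d = np.linalg.norm(x[:, None, :] - model.centroids[None, :, :], axis=2)
    labels = np.argmin(d, axis=1) + 1  # argmin takes the first (lowest) index on ties
    return pd.Series(labels, index=scores.sample_ids, name="pics_cluster")


def composition_change(
    labels: pd.Series,
    metadata: SampleTable,
    from_tp: str = "Baseline",
    to_tp: str = "EarlyTreatment",
) -> pd.DataFrame:
    """Fraction of patients per (subtype × arm) whose cluster changed.

    Patients missing a labeled sample at either timepoint are omitted.
    """
    meta = metadata.frame
    rows = []
    for (subtype, arm), grp in meta.groupby(["clinical_subtype", "arm"], sort=True):
        n_paired = 0
        n_changed = 0
        for _, pgrp in grp.groupby("patient_id"):
            by_tp = pgrp.set_index("timepoint")["sample_id"].to_dict()
            s_from, s_to = by_tp.get(from_tp), by_tp.get(to_tp)
            if s_from not in labels.index or s_to not in labels.index:
                continue
            n_paired += 1
            n_changed += int(labels[s_from] != labels[s_to])
        if n_paired:
            rows.append(
                {
                    "clinical_subtype": subtype,
                    "arm": arm,
                    "n_patients": n_paired,
                    "n_changed": n_changed,
                    "changed_fraction": n_changed / n_paired,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["clinical_subtype", "arm", "n_patients", "n_changed", "changed_fraction"],
    )
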