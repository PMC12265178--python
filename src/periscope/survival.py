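"""Kaplan-Meier estimation and log-rank comparison of distant
recurrence-free survival between immune-score-high and -low groups.

Product-limit estimation and the log-rank test are delegated to
``lifelines``; events are taken to precede censoring at tied times
(the estimator's standard convention).  Group membership comes from
thresholding model probabilities at an inclusive cutoff
(high iff probability >= cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test

from .io_formats import ValidationError

__all__ = ["SurvivalFit", "km_fit", "stratify_by_score"]


@dataclass
class SurvivalFit:
    curves: dict[str, pd.DataFrame]  # group -> columns time, survival, at_risk
    group_sizes: dict[str, int]
    chi_square: float | None
    p_value: float | None


def km_fit(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str],
) -> SurvivalFit:
    """Per-group Kaplan-Meier curves plus the log-rank test across groups.

    With one group, only the curve is returned (no test); with two or
    more groups the standard observed-minus-expected chi-square statistic
    is computed (1 df for two groups).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups, dtype=object)
    if t.size == 0:
        raise ValidationError("no subjects")
    if (t < 0).any():
        raise ValidationError("negative survival times")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValidationError("events must be 0/1")
    labels = sorted(set(g))
    curves = {}
    sizes = {}
    for lab in labels:
        mask = g == lab
        if mask.sum() == 0:
            raise ValidationError(f"group {lab!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=str(lab))
        table = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        curves[str(lab)] = pd.DataFrame(
            {
                "time": surv.index.to_numpy(dtype=float),
                "survival": surv.to_numpy(dtype=float),
                "at_risk": table["at_risk"].reindex(surv.index).to_numpy(dtype=float),
            }
        )
        sizes[str(lab)] = int(mask.sum())
    chi2 = p = None
    if len(labels) == 2:
        m0, m1 = (g == labels[0]), (g == labels[1])
        res = logrank_test(t[m0], t[m1], e[m0], e[m1])
        chi2, p = float(res.test_statistic), float(res.p_value)
    elif len(labels) > 2:
        res = multivariate_logrank_test(t, g, e)
        chi2, p = float(res.test_statistic), float(res.p_value)
    return SurvivalFit(curves=curves, group_sizes=sizes, chi_square=chi2, p_value=p)


def stratify_by_score(probabilities: Sequence[float], cutoff: float) -> np.ndarray:
    """Label each subject 'high' iff probability >= cutoff (inclusive), else 'low'."""
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("probabilities must lie in [0, 1]")
    return np.where(p >= cutoff, "high", "low")
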