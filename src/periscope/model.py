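"""Subtype-conditional logistic model of immunotherapy response.

The model predicts pathological complete response (pCR vs residual
disease) from peripheral immune features with subtype-conditional
terms::

    response ~ subtype
             + delta T-cell composite (early - baseline)   [TNBC only]
             + baseline T-cell composite                   [HR+ only]
             + baseline TCR Shannon diversity              [all]
             + delta leukocyte-chemotaxis score            [HR+ only]

Subtype conditioning is operationalized as interaction masking: each raw
feature is centered on the training cohort (over the patients it applies
to) and zeroed for the non-applicable subtype.  Evaluation artifacts:
Mann-Whitney AUC with DeLong confidence interval and test against 0.5,
Youden-J optimal cutoff, stratified 10-fold cross-validation with
Cohen's kappa on pooled out-of-fold predictions, and cross-cohort
train/test validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import cohen_kappa_score
from sklearn.model_selection import StratifiedKFold

from .io_formats import SampleTable, ValidationError
from .scores import CompositeScoreTable
from .tcr import DiversityRecord

__all__ = [
    "FEATURES",
    "FeatureTable",
    "FittedResponseModel",
    "RocResult",
    "CvResult",
    "build_features",
    "fit_model",
    "predict_prob",
    "roc_auc",
    "cross_validate",
    "train_test",
]

log = logging.getLogger(__name__)

#: (feature name, applicable subtype or None for all)
FEATURES: list[tuple[str, str | None]] = [
    ("subtype_tnbc", None),
    ("f_tnbc_delta_tcell", "TNBC"),
    ("f_hr_baseline_tcell", "HRpos"),
    ("f_baseline_shannon", None),
    ("f_hr_delta_chemotaxis", "HRpos"),
]


@dataclass
class FeatureTable:
    """Per-patient features; subtype-masked columns are NaN where inapplicable."""

    frame: pd.DataFrame  # index patient_id; feature columns + subtype + response

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.frame)
        needed = {"clinical_subtype", "response"} | {name for name, _ in FEATURES}
        missing = needed - set(df.columns)
        if missing:
            raise ValidationError(f"feature table missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            raise ValidationError("duplicate patients in feature table")
        if not df["response"].isin([0, 1]).all():
            raise ValidationError("response must be binary 0/1")
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    def feature_names(self) -> list[str]:
        return [name for name, _ in FEATURES]

    def compute_centers(self) -> dict[str, float]:
        """Per-feature mean over the patients the feature applies to."""
        centers = {}
        for name, subtype in FEATURES:
            col = self.frame[name]
            if subtype is not None:
                col = col[self.frame["clinical_subtype"] == subtype]
            col = col.dropna()
            centers[name] = float(col.mean()) if len(col) else 0.0
        return centers

    def design_matrix(self, centers: dict[str, float]) -> pd.DataFrame:
        """Centered, subtype-masked design matrix (masked entries exactly 0)."""
        out = {}
        for name, subtype in FEATURES:
            col = self.frame[name].astype(float) - centers[name]
            if subtype is not None:
                applies = (self.frame["clinical_subtype"] == subtype).to_numpy()
                col = col.where(applies, 0.0)
            out[name] = col.fillna(0.0)
        return pd.DataFrame(out, index=self.frame.index)


@dataclass
class FittedResponseModel:
    coefficients: pd.Series  # includes 'intercept'
    centers: dict[str, float]
    converged: bool
    separable: bool
    cohort_id: str = ""
    std_errors: pd.Series | None = None

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        if self.std_errors is None:
            raise ValidationError("no standard errors available (ridge-stabilized fit)")
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.coefficients - z * self.std_errors
        hi = self.coefficients + z * self.std_errors
        return pd.DataFrame({"low": lo, "high": hi})


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    p_vs_half: float
    roc_points: pd.DataFrame  # columns fpr, tpr, threshold
    optimal_cutoff: float
    youden_j: float


@dataclass
class CvResult:
    n_folds: int
    fold_assignment: pd.Series
    oof_probabilities: pd.Series
    kappa: float
    confusion: np.ndarray  # rows true (0,1), cols predicted (0,1)
    threshold: float
    kappa_youden: float = float("nan")


def build_features(
    tcell_scores: CompositeScoreTable,
    chemotaxis_scores: CompositeScoreTable,
    diversity: Sequence[DiversityRecord],
    metadata: SampleTable,
    from_tp: str = "Baseline",
    to_tp: str = "EarlyTreatment",
) -> FeatureTable:
    """Assemble the per-patient feature table.

    Patients need a pCR/RD label, baseline + early-treatment composite
    and chemotaxis scores, and a retained baseline TCR repertoire;
    patients missing any required input are dropped with a log entry.
    """
    shannon = {r.sample_id: r.shannon for r in diversity if not r.excluded}
    rows = []
    for pid, grp in metadata.frame.groupby("patient_id", sort=True):
        resp = grp["response"].iloc[0]
        if resp not in ("pCR", "RD"):
            log.info("patient %s dropped: unknown response", pid)
            continue
        by_tp = grp.set_index("timepoint")["sample_id"].to_dict()
        s0, s1 = by_tp.get(from_tp), by_tp.get(to_tp)
        subtype = grp["clinical_subtype"].iloc[0]
        tc, cx = tcell_scores.scores, chemotaxis_scores.scores
        if s0 is None or s0 not in tc.index or s0 not in cx.index:
            log.info("patient %s dropped: missing %s scores", pid, from_tp)
            continue
        if s1 is None or s1 not in tc.index or s1 not in cx.index:
            log.info("patient %s dropped: missing %s scores", pid, to_tp)
            continue
        if s0 not in shannon:
            log.info("patient %s dropped: no retained baseline TCR repertoire", pid)
            continue
        rows.append(
            {
                "patient_id": pid,
                "clinical_subtype": subtype,
                "arm": grp["arm"].iloc[0],
                "response": int(resp == "pCR"),
                "subtype_tnbc": float(subtype == "TNBC"),
                "f_tnbc_delta_tcell": tc[s1] - tc[s0] if subtype == "TNBC" else np.nan,
                "f_hr_baseline_tcell": tc[s0] if subtype == "HRpos" else np.nan,
                "f_baseline_shannon": shannon[s0],
                "f_hr_delta_chemotaxis": cx[s1] - cx[s0] if subtype == "HRpos" else np.nan,
            }
        )
    if not rows:
        raise ValidationError("no eligible patient for the feature table")
    return FeatureTable(pd.DataFrame(rows).set_index("patient_id"))


_SEPARATION_COEF = 30.0  # |coefficient| beyond which a logit fit is deemed separated
_SEPARATION_SE = 1e3  # Wald SEs explode under (quasi-)separation


def fit_model(
    features: FeatureTable,
    centers: dict[str, float] | None = None,
    cohort_id: str = "",
) -> FittedResponseModel:
    """Maximum-likelihood logistic fit (binomial family, logit link).

    Perfect separation is flagged and the coefficients replaced by a
    ridge-stabilized refit (L2 penalty 1e-4), which carries no Wald
    standard errors.
    """
    y = features.frame["response"].to_numpy()
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValidationError("need >= 2 patients per response class")
    if centers is None:
        centers = features.compute_centers()
    x = features.design_matrix(centers)
    exog = sm.add_constant(x.to_numpy(), has_constant="add")
    names = ["intercept", *x.columns]
    separable = False
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, exog, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
        params = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        converged = bool(res.converged)
        if (
            not np.isfinite(params).all()
            or np.abs(params).max() > _SEPARATION_COEF
            or not np.isfinite(bse).all()
            or np.abs(bse).max() > _SEPARATION_SE
        ):
            separable = True
    except Exception:  # PerfectSeparation and numerical failures
        separable = True
    if separable:
        log.warning("separation detected; ridge-stabilized refit (penalty 1e-4)")
        clf = LogisticRegression(C=1e4, solver="lbfgs", max_iter=1000)
        clf.fit(x.to_numpy(), y)
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        return FittedResponseModel(
            pd.Series(params, index=names),
            centers,
            converged=True,
            separable=True,
            cohort_id=cohort_id,
        )
    return FittedResponseModel(
        pd.Series(params, index=names),
        centers,
        converged=converged,
        separable=False,
        cohort_id=cohort_id,
        std_errors=pd.Series(bse, index=names),
    )


def predict_prob(model: FittedResponseModel, features: FeatureTable) -> pd.Series:
    """Response probabilities: inverse logit of the linear predictor.

    Test features are centered with the *training* means stored in the
    model.
    """
    x = features.design_matrix(model.centers)
    eta = model.coefficients["intercept"] + x.to_numpy() @ model.coefficients[
        x.columns
    ].to_numpy()
    return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=features.frame.index, name="probability")


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong variance


def _midranks(x: np.ndarray) -> np.ndarray:
    sorter = np.argsort(x, kind="mergesort")
    xs = x[sorter]
    n = len(x)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = (i + j - 1) / 2.0 + 1
        i = j
    out = np.empty(n)
    out[sorter] = ranks
    return out


def _delong(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance (ties count one half)."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    r_all = _midranks(allv)
    r_pos = _midranks(pos)
    r_neg = _midranks(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n  # placement of each positive among negatives
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_auc(labels: Sequence[int], probabilities: Sequence[float]) -> RocResult:
    """Mann-Whitney AUC with DeLong CI/p and the Youden-J optimal cutoff.

    The optimal cutoff maximizes sensitivity + specificity - 1 over all
    observed score thresholds (classification rule: positive iff score
    >= threshold); ties pick the lower threshold.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if set(np.unique(y)) != {0, 1}:
        raise ValidationError("roc_auc needs both classes present")
    pos, neg = p[y == 1], p[y == 0]
    auc, var = _delong(pos, neg)
    se = float(np.sqrt(max(var, 0.0)))
    z975 = stats.norm.ppf(0.975)
    ci_low = max(0.0, auc - z975 * se)
    ci_high = min(1.0, auc + z975 * se)
    if se > 0:
        p_vs_half = float(2 * stats.norm.sf(abs(auc - 0.5) / se))
    else:
        p_vs_half = 1.0 if auc == 0.5 else 0.0
    thresholds = np.unique(p)  # ascending; rule is score >= threshold
    tpr = np.array([(pos >= t).mean() for t in thresholds])
    fpr = np.array([(neg >= t).mean() for t in thresholds])
    j = tpr - fpr
    best = int(np.argmax(j))  # argmax picks first (lowest threshold) on ties
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return RocResult(
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        p_vs_half=p_vs_half,
        roc_points=roc_points,
        optimal_cutoff=float(thresholds[best]),
        youden_j=float(j[best]),
    )


# ---------------------------------------------------------------------------
# cross-validation


def _pooled_kappa(y: np.ndarray, prob: np.ndarray, threshold: float) -> tuple[float, np.ndarray]:
    pred = (prob >= threshold).astype(int)
    kappa = 0.0 if (pred == pred[0]).all() else float(cohen_kappa_score(y, pred))
    confusion = np.zeros((2, 2), dtype=int)
    for t, q in zip(y, pred):
        confusion[t, q] += 1
    return kappa, confusion


def cross_validate(
    features: FeatureTable,
    n_folds: int = 10,
    threshold: float = 0.5,
    seed: int = 0,
) -> CvResult:
    """Stratified k-fold CV; kappa on pooled out-of-fold predictions.

    Each training fold re-centers features on its own patients, so no
    information from the held-out fold leaks into the fit.  A fold whose
    training part lacks a class is skipped with a warning.  The kappa at
    the pooled Youden-optimal cutoff is reported alongside the fixed
    threshold.
    """
    df = features.frame
    y = df["response"].to_numpy()
    n_min = min(int(y.sum()), int((1 - y).sum()))
    if n_min < n_folds:
        warnings.warn(
            f"minority class ({n_min}) smaller than n_folds ({n_folds}); "
            "some folds get no minority members",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = pd.Series(np.nan, index=df.index)
    fold_of = pd.Series(-1, index=df.index)
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(df)), y)):
        assert len(set(tr) & set(te)) == 0
        y_tr = y[tr]
        if y_tr.sum() < 2 or (1 - y_tr).sum() < 2:
            warnings.warn(f"fold {fold}: a class is (nearly) absent from training; skipped", stacklevel=2)
            continue
        train_ft = FeatureTable(df.iloc[tr])
        test_ft = FeatureTable(df.iloc[te]) if len(te) > 1 else FeatureTable(df.iloc[list(te)])
        model = fit_model(train_ft)
        oof.iloc[te] = predict_prob(model, test_ft).to_numpy()
        fold_of.iloc[te] = fold
    mask = oof.notna().to_numpy()
    kappa, confusion = _pooled_kappa(y[mask], oof.to_numpy()[mask], threshold)
    youden_cut = roc_auc(y[mask], oof.to_numpy()[mask]).optimal_cutoff
    kappa_youden, _ = _pooled_kappa(y[mask], oof.to_numpy()[mask], youden_cut)
    return CvResult(
        n_folds=n_folds,
        fold_assignment=fold_of,
        oof_probabilities=oof,
        kappa=kappa,
        confusion=confusion,
        threshold=threshold,
        kappa_youden=kappa_youden,
    )


def train_test(features_train: FeatureTable, features_test: FeatureTable) -> RocResult:
    """Fit on the training cohort, evaluate ROC/AUC on the test cohort.

    Train/test disjointness is not required (pooled train = test
    evaluation is a supported design), but any overlap is logged
    prominently as an overfitting caveat.
    """
    overlap = set(features_train.frame.index) & set(features_test.frame.index)
    if overlap:
        log.warning(
            "train and test cohorts share %d patients; the resulting AUC is optimistic",
            len(overlap),
        )
    model = fit_model(features_train)
    probs = predict_prob(model, features_test)
    return roc_auc(features_test.frame["response"].to_numpy(), probs.to_numpy())
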