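import numpy as np
import pandas as pd
import pytest
from scipy import stats

from periscope.io_formats import SampleTable, ValidationError
from periscope.model import (
    FEATURES,
    FeatureTable,
    build_features,
    cross_validate,
    fit_model,
    predict_prob,
    roc_auc,
    train_test,
)
from periscope.scores import CompositeScoreTable
from periscope.tcr import DiversityRecord

from _oracles import brute_auc


def _feature_table(n=100, coefs=None, seed=0, null=False):
    """Features drawn from a known logistic model (for parameter recovery)."""
    rng = np.random.default_rng(seed)
    subtype = rng.integers(0, 2, n)  # 1 = TNBC
    raw = {
        "subtype_tnbc": subtype.astype(float),
        "f_tnbc_delta_tcell": np.where(subtype == 1, rng.normal(size=n), np.nan),
        "f_hr_baseline_tcell": np.where(subtype == 0, rng.normal(size=n), np.nan),
        "f_baseline_shannon": rng.normal(4.0, 1.0, n),
        "f_hr_delta_chemotaxis": np.where(subtype == 0, rng.normal(size=n), np.nan),
    }
    if coefs is None:
        coefs = {"intercept": 0.0, "subtype_tnbc": 1.0, "f_tnbc_delta_tcell": 1.5,
                 "f_hr_baseline_tcell": 1.0, "f_baseline_shannon": 0.8,
                 "f_hr_delta_chemotaxis": -1.2}
    eta = np.full(n, coefs["intercept"])
    for name, applies in FEATURES:
        centered = np.nan_to_num(raw[name] - np.nanmean(raw[name]))
        if not null:
            eta = eta + coefs[name] * centered
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    df = pd.DataFrame(raw, index=[f"P{i:04d}" for i in range(n)])
    df["clinical_subtype"] = np.where(subtype == 1, "TNBC", "HRpos")
    df["response"] = y.astype(int)
    return FeatureTable(df), coefs


class TestBuildFeatures:
    def _inputs(self):
        rows = []
        patients = [("P1", "TNBC", "pCR"), ("P2", "HRpos", "RD"), ("P3", "TNBC", "RD")]
        for pid, subtype, resp in patients:
            for tp in ("Baseline", "EarlyTreatment"):
                rows.append({"sample_id": f"{pid}_{tp}", "patient_id": pid,
                             "timepoint": tp, "arm": "ChemoPembro",
                             "clinical_subtype": subtype, "response": resp})
        meta = SampleTable(pd.DataFrame(rows))
        sids = meta.frame["sample_id"]
        tc = CompositeScoreTable(
            pd.Series(np.linspace(-1, 1, len(sids)), index=sids), ["G0"], "mean_z")
        cx = CompositeScoreTable(
            pd.Series(np.linspace(1, -1, len(sids)), index=sids), ["G1"], "ssgsea_single_set")
        records = [DiversityRecord(s, 50, 1000, 3.0 + i * 0.1) for i, s in enumerate(sids)]
        return tc, cx, records, meta

    def test_subtype_masking_nan_pattern(self):
        tc, cx, records, meta = self._inputs()
        ft = build_features(tc, cx, records, meta)
        assert np.isnan(ft.frame.loc["P2", "f_tnbc_delta_tcell"])
        assert np.isnan(ft.frame.loc["P1", "f_hr_baseline_tcell"])
        assert not np.isnan(ft.frame.loc["P1", "f_tnbc_delta_tcell"])

    def test_masked_entries_exactly_zero_in_design(self):
        tc, cx, records, meta = self._inputs()
        ft = build_features(tc, cx, records, meta)
        x = ft.design_matrix(ft.compute_centers())
        assert x.loc["P2", "f_tnbc_delta_tcell"] == 0.0
        assert x.loc["P1", "f_hr_delta_chemotaxis"] == 0.0

    def test_centering_on_training_cohort(self):
        tc, cx, records, meta = self._inputs()
        ft = build_features(tc, cx, records, meta)
        centers = ft.compute_centers()
        x = ft.design_matrix(centers)
        raw_delta = ft.frame.loc["P1", "f_tnbc_delta_tcell"]
        assert x.loc["P1", "f_tnbc_delta_tcell"] == pytest.approx(
            raw_delta - centers["f_tnbc_delta_tcell"]
        )

    def test_excluded_tcr_sample_drops_patient(self):
        tc, cx, records, meta = self._inputs()
        records = [
            DiversityRecord(r.sample_id, 5, r.total_reads, r.shannon, True, "fewer than 10 clones")
            if r.sample_id == "P1_Baseline" else r
            for r in records
        ]
        ft = build_features(tc, cx, records, meta)
        assert "P1" not in ft.frame.index


class TestFitModel:
    def test_separation_flagged(self):
        n = 40
        df = pd.DataFrame(
            {name: 0.0 for name, _ in FEATURES}, index=[f"P{i}" for i in range(n)]
        )
        df["f_baseline_shannon"] = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        df["clinical_subtype"] = "TNBC"
        df["subtype_tnbc"] = 1.0
        df["response"] = (df["f_baseline_shannon"] > 0.5).astype(int)
        model = fit_model(FeatureTable(df))
        assert model.separable

    def test_null_features_intercept_prevalence(self):
        n = 40
        df = pd.DataFrame({name: 0.0 for name, _ in FEATURES}, index=[f"P{i}" for i in range(n)])
        df["clinical_subtype"] = "HRpos"
        df["response"] = np.r_[np.ones(10), np.zeros(30)].astype(int)
        model = fit_model(FeatureTable(df))
        probs = predict_prob(model, FeatureTable(df))
        assert np.allclose(probs, 0.25, atol=1e-6)

    def test_sign_and_ci_coverage_over_replicates(self):
        """Coefficient signs recovered and 95% Wald CIs cover the truth in
        >= 90 of 100 replicates at n=200."""
        n_rep = 100
        hits = {name: 0 for name, _ in FEATURES}
        signs = {name: 0 for name, _ in FEATURES}
        n_ok = 0
        for rep in range(n_rep):
            ft, coefs = _feature_table(n=200, seed=1000 + rep)
            model = fit_model(ft)
            if model.separable:
                continue
            n_ok += 1
            ci = model.conf_int()
            for name, _ in FEATURES:
                if ci.loc[name, "low"] <= coefs[name] <= ci.loc[name, "high"]:
                    hits[name] += 1
                if np.sign(model.coefficients[name]) == np.sign(coefs[name]):
                    signs[name] += 1
        assert n_ok >= 95
        for name, _ in FEATURES:
            assert hits[name] / n_ok >= 0.90, (name, hits[name], n_ok)
            assert signs[name] / n_ok >= 0.90, (name, signs[name], n_ok)

    def test_too_few_per_class_rejected(self):
        ft, _ = _feature_table(n=20, seed=3)
        df = ft.frame.copy()
        df["response"] = 0
        df.iloc[0, df.columns.get_loc("response")] = 1
        with pytest.raises(ValidationError):
            fit_model(FeatureTable(df))


class TestPredict:
    def test_monotone_in_positive_coefficient_feature(self):
        ft, _ = _feature_table(n=200, seed=5)
        model = fit_model(ft)
        base = ft.frame.copy()
        grid = np.linspace(-2, 2, 9)
        probs = []
        for v in grid:
            df = base.iloc[[0]].copy()
            df["clinical_subtype"] = "TNBC"
            df["subtype_tnbc"] = 1.0
            df["f_baseline_shannon"] = v
            probs.append(predict_prob(model, FeatureTable(df)).iloc[0])
        diffs = np.diff(probs) * np.sign(model.coefficients["f_baseline_shannon"])
        assert (diffs > 0).all()


class TestRocAuc:
    def test_small_pairwise_example(self):
        res = roc_auc([1, 1, 0, 0], [0.9, 0.4, 0.5, 0.1])
        assert res.auc == pytest.approx(0.75)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0], y[1] = 0, 1
            p = np.round(rng.random(n), 2)  # induce ties
            res = roc_auc(y, p)
            assert res.auc == pytest.approx(brute_auc(list(y), list(p)), abs=1e-12)

    def test_perfect_separation(self):
        res = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert res.auc == 1.0
        assert 0.2 < res.optimal_cutoff <= 0.8
        assert res.youden_j == 1.0

    def test_all_ties_half(self):
        res = roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert res.auc == 0.5

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        p = rng.random(50)
        res = roc_auc(y, p)
        assert res.ci_low <= res.auc <= res.ci_high

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_delong_p_uniform_under_permutation(self):
        """DeLong p against AUC=0.5 is uniform when labels are permuted."""
        rng = np.random.default_rng(10)
        scores = rng.random(60)
        labels = np.r_[np.ones(30, int), np.zeros(30, int)]
        pvals = []
        for _ in range(200):
            perm = rng.permutation(labels)
            pvals.append(roc_auc(perm, scores).p_vs_half)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestCrossValidate:
    @pytest.mark.parametrize(
        "confusion, expected",
        [((10, 0, 0, 10), 1.0), ((5, 5, 5, 5), 0.0), ((8, 2, 3, 7), 0.5)],
    )
    def test_kappa_hand_cases(self, confusion, expected):
        from periscope.model import _pooled_kappa

        tn, fp, fn, tp = confusion
        y = np.r_[np.zeros(tn + fp, int), np.ones(fn + tp, int)]
        prob = np.r_[np.zeros(tn), np.ones(fp), np.zeros(fn), np.ones(tp)]
        kappa, table = _pooled_kappa(y, prob, 0.5)
        assert kappa == pytest.approx(expected, abs=1e-12)
        assert table[0, 0] == tn and table[1, 1] == tp

    def test_cv_recovers_signal(self):
        ft, _ = _feature_table(n=200, seed=21)
        cv = cross_validate(ft, n_folds=10, seed=0)
        res = roc_auc(ft.frame["response"], cv.oof_probabilities)
        assert res.auc > 0.7
        assert cv.kappa > 0.2

    def test_null_features_kappa_near_zero(self):
        kappas = []
        aucs = []
        for rep in range(30):
            ft, _ = _feature_table(n=200, seed=400 + rep, null=True)
            cv = cross_validate(ft, n_folds=10, seed=rep)
            kappas.append(cv.kappa)
            aucs.append(roc_auc(ft.frame["response"], cv.oof_probabilities).auc)
        assert abs(np.mean(kappas)) < 0.1
        assert 0.45 < np.mean(aucs) < 0.55

    def test_folds_partition_patients(self):
        ft, _ = _feature_table(n=60, seed=2)
        cv = cross_validate(ft, n_folds=5, seed=0)
        assert (cv.fold_assignment >= 0).all()
        assert cv.oof_probabilities.notna().all()


class TestTrainTest:
    def test_same_train_test_overfits_with_warning(self, caplog):
        ft, _ = _feature_table(n=120, seed=30)
        import logging

        with caplog.at_level(logging.WARNING, logger="periscope.model"):
            res = train_test(ft, ft)
        assert any("share" in r.message for r in caplog.records)
        assert res.auc > 0.7

    def test_disjoint_split_with_effect_beats_null_band(self):
        ft_train, _ = _feature_table(n=100, seed=31)
        ft_test, _ = _feature_table(n=100, seed=32)
        res = train_test(ft_train, ft_test)
        assert res.auc > 0.6

    def test_null_split_auc_within_band(self):
        """Null train/test splits give AUC in [0.4, 0.6] in ~95% of replicates."""
        inside = 0
        n_rep = 60
        for rep in range(n_rep):
            tr, _ = _feature_table(n=100, seed=600 + rep, null=True)
            te, _ = _feature_table(n=100, seed=9600 + rep, null=True)
            res = train_test(tr, te)
            inside += 0.4 <= res.auc <= 0.6
        assert inside / n_rep >= 0.9
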