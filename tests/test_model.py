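"""ICC stability, univariate screen, LASSO, score, cutoff, evaluation."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import angiorad as ar
from angiorad.model import _standardize, score_table

import oracles


class TestICCFilter:
    def test_identical_raters_perfect_agreement(self):
        rng = np.random.default_rng(0)
        f1 = pd.DataFrame(rng.normal(size=(30, 5)),
                          columns=[f"f{i}" for i in range(5)])
        report = ar.icc_filter(f1, f1.copy())
        assert np.allclose(report["icc"], 1.0)
        assert report["stable"].all()

    def test_independent_raters_near_zero(self):
        """Independent ratings at n=500: ICC centered on 0 (each feature
        within sampling noise, the average within +-0.03)."""
        rng = np.random.default_rng(2)
        cols = [f"f{i}" for i in range(10)]
        f1 = pd.DataFrame(rng.normal(size=(500, 10)), columns=cols)
        f2 = pd.DataFrame(rng.normal(size=(500, 10)), columns=cols)
        report = ar.icc_filter(f1, f2)
        assert np.all(np.abs(report["icc"]) < 0.2)
        assert abs(report["icc"].mean()) < 0.03
        assert not report["stable"].any()

    def test_variance_component_recovery(self):
        """sigma2_case=4, sigma2_error=1 gives ICC ~ 4/5 = 0.8 (n=500)."""
        rng = np.random.default_rng(2)
        case_effect = rng.normal(0, 2.0, size=(500, 1))
        f1 = pd.DataFrame(case_effect + rng.normal(0, 1.0, (500, 1)),
                          columns=["f"])
        f2 = pd.DataFrame(case_effect + rng.normal(0, 1.0, (500, 1)),
                          columns=["f"])
        icc = ar.icc_filter(f1, f2)["icc"].iloc[0]
        assert icc == pytest.approx(0.8, abs=0.05)

    def test_constant_feature_flagged_zero(self):
        f1 = pd.DataFrame({"f": np.ones(20)})
        report = ar.icc_filter(f1, f1.copy())
        assert report["icc"].iloc[0] == 0.0
        assert not report["stable"].iloc[0]

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        case_effect = rng.normal(0, 1.5, size=(40, 1))
        f1 = pd.DataFrame(case_effect + rng.normal(0, 1, (40, 1)),
                          columns=["f"])
        f2 = pd.DataFrame(0.3 + case_effect + rng.normal(0, 1, (40, 1)),
                          columns=["f"])
        ours = ar.icc_filter(f1, f2)["icc"].iloc[0]
        long = pd.DataFrame({
            "case": list(range(40)) * 2,
            "rater": ["r1"] * 40 + ["r2"] * 40,
            "value": np.concatenate([f1["f"], f2["f"]])})
        ref = pingouin.intraclass_corr(long, targets="case", raters="rater",
                                       ratings="value")
        # two-way random, absolute agreement, single rater
        sel = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = ref.loc[sel, "ICC"].iloc[0]
        assert ours == pytest.approx(icc2, abs=1e-6)


class TestUnivariateScreen:
    def test_type_one_error_calibrated(self):
        """Null features are kept at ~alpha (binomial 99% bounds)."""
        rng = np.random.default_rng(4)
        n_feat = 200
        X = pd.DataFrame(rng.normal(size=(64, n_feat)),
                         columns=[f"f{i}" for i in range(n_feat)])
        y = np.array([1] * 32 + [0] * 32)
        report = ar.univariate_screen(X, y, alpha=0.05)
        kept = int(report["kept"].sum())
        lo = stats.binom.ppf(0.005, n_feat, 0.05)
        hi = stats.binom.ppf(0.995, n_feat, 0.05)
        assert lo <= kept <= hi

    def test_strong_separation_kept(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 1, 32), rng.normal(3, 1, 32)])
        y = np.array([0] * 32 + [1] * 32)
        report = ar.univariate_screen(pd.DataFrame({"f": x}), y)
        assert report.loc["f", "kept"]
        assert report.loc["f", "p"] < 1e-6

    def test_constant_feature_excluded(self):
        y = np.array([0] * 10 + [1] * 10)
        report = ar.univariate_screen(pd.DataFrame({"f": np.ones(20)}), y)
        assert report.loc["f", "p"] == 1.0
        assert not report.loc["f", "kept"]
        assert report.loc["f", "test"] == "none"

    def test_routing_normal_vs_skewed(self):
        rng = np.random.default_rng(6)
        y = np.array([0] * 40 + [1] * 40)
        X = pd.DataFrame({
            "gaussian": rng.normal(0, 1, 80),
            "lognormal": rng.lognormal(0, 1.0, 80)})
        report = ar.univariate_screen(X, y)
        assert report.loc["gaussian", "test"] == "t"
        assert report.loc["lognormal", "test"] == "mann_whitney"

    def test_groups_too_small_rejected(self):
        with pytest.raises(ValueError):
            ar.univariate_screen(pd.DataFrame({"f": np.arange(4.0)}),
                                 np.array([0, 0, 1, 1]))


def _informative_design(seed, n=48, n_noise=50, effect=1.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_noise + 2))
    logits = effect * X[:, 0] + effect * X[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
    if y.sum() < 5 or y.sum() > n - 5:  # re-balance pathological draws
        return _informative_design(seed + 1000, n, n_noise, effect)
    cols = ["inf0", "inf1"] + [f"noise{i}" for i in range(n_noise)]
    return pd.DataFrame(X, columns=cols), y


class TestLassoSelect:
    def test_full_shrinkage_at_lambda_max(self):
        X, y = _informative_design(0)
        model = ar.lasso_select(X, y, seed=0)
        lam_max = model.cv_lambdas[0]
        Xs, _, _ = _standardize(X.to_numpy(float))
        from angiorad.model import _l1_refit
        clf = _l1_refit(Xs, y.astype(float), lam_max * 1.0001, seed=0)
        assert np.all(clf.coef_ == 0.0)

    def test_informative_features_recovered(self):
        """Both informative features selected in >= 90% of 20 seeds."""
        hits = 0
        for seed in range(20):
            X, y = _informative_design(seed)
            model = ar.lasso_select(X, y, seed=seed)
            if {"inf0", "inf1"} <= set(model.selected):
                hits += 1
        assert hits >= 18

    def test_kkt_conditions_at_lambda_star(self):
        """The refit solution satisfies the L1-logistic subgradient
        conditions within 1e-6."""
        for seed in (0, 1, 2):
            X, y = _informative_design(seed)
            model = ar.lasso_select(X, y, seed=seed)
            Xs = (X.to_numpy(float) - model.mean) / model.sd
            viol = oracles.kkt_violation(Xs, y.astype(float), model.coef,
                                         model.intercept, model.lambda_)
            assert viol < 1e-6

    def test_cv_curve_recorded(self):
        X, y = _informative_design(3)
        model = ar.lasso_select(X, y, seed=0, n_lambdas=40)
        assert len(model.cv_lambdas) == 40
        assert len(model.cv_auc) == 40
        assert np.all(np.diff(model.cv_lambdas) < 0)
        assert model.lambda_ in model.cv_lambdas

    def test_serialization_bit_identical_scores(self, tmp_path):
        X, y = _informative_design(4)
        model = ar.lasso_select(X, y, seed=0)
        model.cutoff = ar.youden_cutoff(score_table(X, model), y)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ar.ScoreModel.from_json(path)
        s1 = score_table(X, model)
        s2 = score_table(X, back)
        assert np.array_equal(s1.to_numpy(), s2.to_numpy())
        assert back.cutoff.threshold == model.cutoff.threshold


class TestSpearmanRedundancy:
    def test_duplicate_flagged(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=43)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=43)})
        report = ar.spearman_redundancy(X)
        row = report[(report.feature_a == "a") & (report.feature_b == "b")]
        assert row["rho"].iloc[0] == pytest.approx(1.0)
        assert bool(row["flagged"].iloc[0])

    def test_monotone_transform_rank_invariant(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(1, 10, 43)
        X = pd.DataFrame({"a": x, "b": np.exp(x)})
        report = ar.spearman_redundancy(X)
        assert report["rho"].iloc[0] == pytest.approx(1.0)

    def test_independent_features_rarely_flagged(self):
        rng = np.random.default_rng(9)
        flagged = 0
        total = 0
        for _ in range(40):
            X = pd.DataFrame(rng.normal(size=(43, 5)),
                             columns=list("abcde"))
            report = ar.spearman_redundancy(X)
            flagged += int(report["flagged"].sum())
            total += len(report)
        assert flagged / total < 0.01

    def test_pruning_keeps_smaller_p(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=43)
        X = pd.DataFrame({"a": x, "b": x + 1e-9 * rng.normal(size=43)})
        p = pd.Series({"a": 0.001, "b": 0.01})
        _, kept = ar.spearman_redundancy(X, p_values=p, prune=True)
        assert kept == ["a"]


class TestScoreAndCutoff:
    def test_zero_coefficients_give_intercept(self):
        model = ar.ScoreModel(["a", "b"], np.zeros(2), intercept=1.25,
                              mean=np.zeros(2), sd=np.ones(2), lambda_=0.1)
        assert ar.compute_score({"a": 5.0, "b": -2.0}, model) == 1.25

    def test_linearity_in_standardized_units(self):
        model = ar.ScoreModel(["a", "b"], np.array([0.7, -0.2]),
                              intercept=0.5, mean=np.array([1.0, 2.0]),
                              sd=np.array([2.0, 4.0]), lambda_=0.1)
        s0 = ar.compute_score({"a": 1.0, "b": 2.0}, model)
        s1 = ar.compute_score({"a": 1.0 + 2.0 * 0.5, "b": 2.0}, model)
        assert s1 - s0 == pytest.approx(0.7 * 0.5, rel=1e-12)

    def test_missing_feature_rejected(self):
        model = ar.ScoreModel(["a"], np.ones(1), 0.0, np.zeros(1),
                              np.ones(1), 0.1)
        with pytest.raises(KeyError):
            ar.compute_score({"b": 1.0}, model)

    def test_perfect_separation(self):
        scores = np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        cut = ar.youden_cutoff(scores, labels)
        assert cut.j == 1.0
        assert -1.0 < cut.threshold < 1.0

    def test_identical_distributions_give_no_information(self):
        scores = np.tile(np.arange(10.0), 2)
        labels = np.array([0] * 10 + [1] * 10)
        cut = ar.youden_cutoff(scores, labels)
        assert cut.j == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_threshold_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            scores = np.round(rng.normal(size=30), 1)  # force ties
            labels = rng.integers(0, 2, 30)
            if labels.sum() in (0, 30):
                continue
            if ar.roc_auc(scores, labels) < 0.5:
                continue  # oracle assumes the positive-above orientation
            cut = ar.youden_cutoff(scores, labels)
            j_brute, _ = oracles.youden_brute(scores, labels)
            assert cut.j == pytest.approx(j_brute, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ar.youden_cutoff(np.arange(5.0), np.ones(5))


class TestEvaluate:
    def test_perfect_ranking_auc_one(self):
        scores = np.arange(10.0)
        labels = np.array([0] * 5 + [1] * 5)
        rep = ar.evaluate(scores, labels, ar.CutoffResult(4.5))
        assert rep.auc == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.youden_j == 1.0

    def test_auc_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            scores = np.round(rng.normal(size=40), 1)
            labels = rng.integers(0, 2, 40)
            if labels.sum() in (0, 40):
                continue
            assert ar.roc_auc(scores, labels) == pytest.approx(
                oracles.auc_brute(scores, labels), abs=1e-12)

    def test_permutation_null_auc_centered(self):
        """Shuffled labels (500 reps): mean AUC within 0.03 of 0.5."""
        rng = np.random.default_rng(13)
        scores = rng.normal(size=60)
        labels = np.array([1] * 20 + [0] * 40)
        aucs = [ar.roc_auc(scores, rng.permutation(labels))
                for _ in range(500)]
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_confusion_matrix_identities(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(size=50)
        labels = (scores + rng.normal(0, 1, 50)) > 0
        cut = ar.youden_cutoff(scores, labels)
        rep = ar.evaluate(scores, labels, cut)
        cm = rep.confusion
        assert cm["tp"] + cm["fn"] == labels.sum()
        assert cm["tn"] + cm["fp"] == (~labels).sum()
        assert rep.youden_j == pytest.approx(
            rep.sensitivity + rep.specificity - 1.0, rel=1e-12)
        assert 0 <= rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1] <= 1

    def test_delong_ci_matches_r_proc(self, tmp_path):
        """DeLong CI cross-checked against the R pROC implementation."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(15)
        scores = rng.normal(size=60) + np.array([1.0] * 25 + [0.0] * 35)
        labels = np.array([1] * 25 + [0] * 35)
        auc, lo, hi = ar.delong_ci(scores, labels)
        csv = tmp_path / "d.csv"
        pd.DataFrame({"s": scores, "y": labels}).to_csv(csv, index=False)
        r = subprocess.run(
            ["Rscript", "-e",
             f'd<-read.csv("{csv}");suppressMessages(library(pROC));'
             'r<-roc(d$y,d$s,quiet=TRUE);ci<-ci.auc(r,method="delong");'
             'cat(sprintf("%.10f %.10f %.10f",ci[1],ci[2],ci[3]))'],
            capture_output=True, text=True, timeout=120)
        if r.returncode != 0:
            pytest.skip(f"pROC unavailable: {r.stderr[:200]}")
        r_lo, r_auc, r_hi = map(float, r.stdout.split())
        assert auc == pytest.approx(r_auc, abs=1e-9)
        assert lo == pytest.approx(r_lo, abs=1e-6)
        assert hi == pytest.approx(r_hi, abs=1e-6)
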