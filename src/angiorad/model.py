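"""Feature selection, the radiomics score, and its evaluation.

Selection runs in three stages on the training cohort:

1. **Stability** — the intraclass correlation coefficient ICC(2,1)
   (two-way random effects, absolute agreement, single measurement) of each
   feature between the two raters' ROI contours, across all cases; only
   features with ICC >= 0.8 are retained.
2. **Univariate screen** — per feature, Shapiro-Wilk normality in each
   group and an F-test of variance homogeneity route the comparison to an
   independent-samples t-test (both normal and homoscedastic) or a
   two-sided Mann-Whitney U test; features with p < alpha survive.
3. **LASSO** — L1-penalized logistic regression on standardized features,
   with lambda tuned by stratified 5-fold cross-validated AUC over a
   100-point grid descending four decades from lambda_max; the refit
   nonzero coefficients define the radiomics score
   ``score(x) = sum_i beta_i x_i* + intercept`` on standardized features.

A Spearman redundancy report flags selected pairs with |rho| in
[0.90, 1.00]. The classification cutoff maximizes Youden's
J = sensitivity + specificity - 1; evaluation reports the empirical ROC
AUC (tie-corrected Mann-Whitney form) with a DeLong 95% CI and the
confusion-matrix metrics at the cutoff.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "icc_filter", "univariate_screen", "lasso_select",
    "spearman_redundancy", "compute_score", "youden_cutoff", "evaluate",
    "roc_auc", "delong_ci", "ScoreModel", "CutoffResult", "EvalReport",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ICC(2,1) stability filter
# ---------------------------------------------------------------------------

def icc_filter(features_r1: pd.DataFrame, features_r2: pd.DataFrame,
               threshold: float = 0.8) -> pd.DataFrame:
    """Per-feature ICC(2,1) between two raters across cases.

    Returns a DataFrame indexed by feature with columns ``icc`` and
    ``stable``. Features with zero between-case variance are flagged with
    ICC 0 (no agreement information).
    """
    if not features_r1.columns.equals(features_r2.columns):
        raise ValueError("rater tables must share columns")
    r2 = features_r2.loc[features_r1.index]
    Y = np.stack([features_r1.to_numpy(float), r2.to_numpy(float)], axis=2)
    n, _, k = Y.shape  # cases x features x raters
    if n < 2:
        raise ValueError("need at least 2 cases for ICC")

    grand = Y.mean(axis=(0, 2))
    row_means = Y.mean(axis=2)      # n x f
    col_means = Y.mean(axis=0)      # f x k
    ssr = k * ((row_means - grand) ** 2).sum(axis=0)
    ssc = n * ((col_means - grand[:, None]) ** 2).sum(axis=1)
    sst = ((Y - grand[None, :, None]) ** 2).sum(axis=(0, 2))
    sse = sst - ssr - ssc

    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (msr - mse) / denom
    degenerate = (denom <= np.finfo(float).tiny * 100) | ~np.isfinite(icc)
    if degenerate.any():
        logger.debug("%d features with zero between-case variance; ICC set to 0",
                     int(degenerate.sum()))
    icc = np.where(degenerate, 0.0, np.clip(icc, -1.0, 1.0))
    return pd.DataFrame({"icc": icc, "stable": icc >= threshold},
                        index=features_r1.columns)


# ---------------------------------------------------------------------------
# Univariate screen
# ---------------------------------------------------------------------------

def _shapiro_p(x: np.ndarray) -> float:
    if len(x) < 3 or np.ptp(x) == 0:
        return 0.0  # degenerate: treat as non-normal
    return float(stats.shapiro(x).pvalue)


def univariate_screen(X: pd.DataFrame, labels, alpha: float = 0.05) -> pd.DataFrame:
    """Route each feature to a t-test or Mann-Whitney U and screen at alpha.

    Both groups normal (Shapiro-Wilk p > 0.05) and homoscedastic (two-sided
    F-test p > 0.05) -> equal-variance t-test; otherwise the two-sided
    Mann-Whitney U with normal approximation and tie correction. Constant
    features get p = 1 and are excluded.
    """
    y = np.asarray(labels).astype(bool)
    if y.sum() < 3 or (~y).sum() < 3:
        raise ValueError("each group needs at least 3 samples")
    rows = []
    for name in X.columns:
        x = X[name].to_numpy(float)
        a, b = x[y], x[~y]
        if np.ptp(x) == 0:
            rows.append(dict(feature=name, normal_p=0.0, levene_p=1.0,
                             test="none", p=1.0, kept=False))
            continue
        pn = min(_shapiro_p(a), _shapiro_p(b))
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va > 0 and vb > 0:
            F = va / vb
            cdf = stats.f.cdf(F, len(a) - 1, len(b) - 1)
            pv = 2 * min(cdf, 1 - cdf)
        else:
            pv = 0.0
        if pn > 0.05 and pv > 0.05:
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
            test = "t"
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method="asymptotic").pvalue)
            test = "mann_whitney"
        if not np.isfinite(p):
            p = 1.0
        rows.append(dict(feature=name, normal_p=pn, levene_p=pv, test=test,
                         p=p, kept=p < alpha))
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# LASSO logistic selection and the radiomics score
# ---------------------------------------------------------------------------

@dataclass
class CutoffResult:
    """Classification cutoff: scores above ``threshold`` predict positive
    when ``positive_above`` (orientation auto-detected from the AUC)."""

    threshold: float
    positive_above: bool = True
    j: float = float("nan")

    def predict(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        return s > self.threshold if self.positive_above else s < self.threshold


@dataclass
class ScoreModel:
    """Linear radiomics score over LASSO-selected standardized features."""

    feature_names: list[str]
    coef: np.ndarray
    intercept: float
    mean: np.ndarray
    sd: np.ndarray
    lambda_: float
    cv_lambdas: np.ndarray = field(default_factory=lambda: np.array([]))
    cv_auc: np.ndarray = field(default_factory=lambda: np.array([]))
    cutoff: CutoffResult | None = None

    @property
    def selected(self) -> list[str]:
        return [n for n, b in zip(self.feature_names, self.coef) if b != 0.0]

    def to_json(self, path=None) -> str:
        payload = {
            "feature_names": self.feature_names,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "lambda": self.lambda_,
            "cv_lambdas": self.cv_lambdas.tolist(),
            "cv_auc": self.cv_auc.tolist(),
            "cutoff": None if self.cutoff is None else {
                "threshold": self.cutoff.threshold,
                "positive_above": self.cutoff.positive_above,
                "j": self.cutoff.j},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ScoreModel":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            source = Path(source).read_text()
        d = json.loads(source)
        cut = d.get("cutoff")
        return cls(
            feature_names=list(d["feature_names"]),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            lambda_=float(d["lambda"]),
            cv_lambdas=np.asarray(d["cv_lambdas"], dtype=float),
            cv_auc=np.asarray(d["cv_auc"], dtype=float),
            cutoff=None if cut is None else CutoffResult(
                cut["threshold"], cut["positive_above"], cut["j"]),
        )


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def _l1_logistic(n: int, lam: float, tol: float, seed: int) -> LogisticRegression:
    # liblinear: fast coordinate descent for the CV path; the large
    # intercept_scaling keeps its intercept penalty negligible.
    return LogisticRegression(l1_ratio=1.0, solver="liblinear",
                              C=1.0 / (n * lam), tol=tol, max_iter=20_000,
                              intercept_scaling=100.0, random_state=seed)


def _l1_refit(Xs: np.ndarray, y: np.ndarray, lam: float, seed: int) -> LogisticRegression:
    """Final fit at lambda*: liblinear solution polished by saga.

    saga minimizes the exact penalized objective (unpenalized intercept),
    so the returned solution satisfies the subgradient KKT conditions to
    high precision; warm-starting from liblinear makes the polish cheap.
    """
    n = len(y)
    init = _l1_logistic(n, lam, 1e-8, seed).fit(Xs, y)
    polish = LogisticRegression(l1_ratio=1.0, solver="saga",
                                C=1.0 / (n * lam), tol=1e-8,
                                max_iter=30_000, warm_start=True,
                                random_state=seed)
    polish.coef_ = init.coef_.copy()
    polish.intercept_ = init.intercept_.copy()
    with warnings.catch_warnings():
        # On separable training data the L1 optimum has large coefficients
        # and saga may exhaust its (deliberately bounded) budget; the
        # warm-started solution is already accurate where it matters.
        warnings.simplefilter("ignore", ConvergenceWarning)
        polish.fit(Xs, y)
    return polish


def lasso_select(X: pd.DataFrame, labels, folds: int = 5, seed: int = 0,
                 n_lambdas: int = 100, decades: float = 4.0,
                 one_se: bool = False) -> ScoreModel:
    """L1-penalized logistic selection with CV-tuned lambda.

    Features are standardized on the training data (parameters frozen into
    the returned model). The grid descends ``decades`` decades from
    lambda_max (the smallest lambda that zeroes every coefficient); the
    tuning criterion is mean stratified k-fold CV AUC, ties resolved toward
    the sparser (larger) lambda. ``one_se`` applies the one-standard-error
    rule instead of the CV optimum.
    """
    y = np.asarray(labels).astype(float)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain two classes")
    n = len(y)
    if n <= folds:
        raise ValueError("need more samples than folds")
    names = list(X.columns)
    Xs, mean, sd = _standardize(X.to_numpy(float))

    lam_max = np.abs(Xs.T @ (y - y.mean())).max() / n
    lambdas = np.logspace(math.log10(lam_max), math.log10(lam_max) - decades,
                          n_lambdas)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs = np.full((folds, n_lambdas), 0.5)
    for f, (tr, va) in enumerate(skf.split(Xs, y)):
        for j, lam in enumerate(lambdas):
            clf = _l1_logistic(len(tr), lam, 1e-6, seed)
            clf.fit(Xs[tr], y[tr])
            s = Xs[va] @ clf.coef_[0] + clf.intercept_[0]
            fold_aucs[f, j] = roc_auc(s, y[va]) if np.ptp(s) > 0 else 0.5
    cv_auc = fold_aucs.mean(axis=0)

    if one_se:
        se = fold_aucs.std(axis=0, ddof=1) / math.sqrt(folds)
        best = int(np.argmax(cv_auc))
        ok = np.nonzero(cv_auc >= cv_auc[best] - se[best])[0]
        j_star = int(ok.min())  # sparsest lambda within one SE
    else:
        j_star = int(np.argmax(cv_auc))  # argmax returns the first (largest
        # lambda, sparsest model) among exact ties
    lam_star = float(lambdas[j_star])

    final = _l1_refit(Xs, y, lam_star, seed)
    return ScoreModel(feature_names=names, coef=final.coef_[0].copy(),
                      intercept=float(final.intercept_[0]), mean=mean, sd=sd,
                      lambda_=lam_star, cv_lambdas=lambdas, cv_auc=cv_auc)


def spearman_redundancy(X: pd.DataFrame, lo: float = 0.90, hi: float = 1.00,
                        p_values: pd.Series | None = None,
                        prune: bool = False):
    """Flag selected-feature pairs with |Spearman rho| in [lo, hi].

    Returns a pair report (DataFrame); with ``prune=True`` also returns the
    list of features kept after dropping, from each flagged pair, the
    member with the larger univariate p (requires ``p_values``).
    """
    names = list(X.columns)
    if len(names) < 2:
        report = pd.DataFrame(columns=["feature_a", "feature_b", "rho", "flagged"])
        return (report, names) if prune else report
    rho = stats.spearmanr(X.to_numpy(float)).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly 2 columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = float(rho[i, j])
            rows.append(dict(feature_a=names[i], feature_b=names[j], rho=r,
                             flagged=lo <= abs(r) <= hi))
    report = pd.DataFrame(rows)
    if not prune:
        return report
    if p_values is None:
        raise ValueError("pruning requires univariate p-values")
    dropped: set[str] = set()
    for _, row in report[report["flagged"]].iterrows():
        a, b = row["feature_a"], row["feature_b"]
        if a in dropped or b in dropped:
            continue
        dropped.add(a if p_values[a] > p_values[b] else b)
    return report, [n for n in names if n not in dropped]


def compute_score(x, model: ScoreModel) -> float:
    """Radiomics score: linear predictor on standardized features."""
    if isinstance(x, (pd.Series, dict)):
        try:
            vec = np.array([float(x[n]) for n in model.feature_names])
        except KeyError as err:
            raise KeyError(f"missing selected feature {err}") from None
    else:
        vec = np.asarray(x, dtype=float)
        if vec.shape[-1] != len(model.feature_names):
            raise ValueError("feature vector length mismatch")
    z = (vec - model.mean) / model.sd
    return float(z @ model.coef + model.intercept)


def score_table(X: pd.DataFrame, model: ScoreModel) -> pd.Series:
    """Vectorized :func:`compute_score` over a case x feature table."""
    missing = [n for n in model.feature_names if n not in X.columns]
    if missing:
        raise KeyError(f"missing selected features {missing}")
    Z = (X[model.feature_names].to_numpy(float) - model.mean) / model.sd
    return pd.Series(Z @ model.coef + model.intercept, index=X.index,
                     name="radiomics_score")


# ---------------------------------------------------------------------------
# Cutoff and evaluation
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """Empirical ROC AUC (Mann-Whitney form with tie correction)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def youden_cutoff(scores, labels) -> CutoffResult:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Scans all midpoints between adjacent sorted unique scores plus +-inf;
    ties break toward higher specificity. Orientation (whether high scores
    predict the positive class) is auto-detected from the AUC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    positive_above = roc_auc(s, y) >= 0.5
    sign = 1.0 if positive_above else -1.0
    ss = sign * s

    uniq = np.unique(ss)
    cands = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    pred = ss[None, :] > cands[:, None]
    sens = (pred & y[None, :]).sum(axis=1) / y.sum()
    spec = (~pred & ~y[None, :]).sum(axis=1) / (~y).sum()
    j = sens + spec - 1.0
    # ties toward higher specificity = larger oriented threshold
    best = np.nonzero(j == j.max())[0].max()
    thr = float(sign * cands[best])
    return CutoffResult(threshold=thr, positive_above=positive_above,
                        j=float(j[best]))


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a DeLong confidence interval: (auc, lo, hi)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")

    def midrank(x):
        return stats.rankdata(x, method="average")

    allr = midrank(np.concatenate([pos, neg]))
    rp, rn = midrank(pos), midrank(neg)
    auc = (allr[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (allr[:m] - rp) / n          # structural components, positives
    v10 = 1.0 - (allr[m:] - rn) / m    # structural components, negatives
    var = (np.var(v01, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v10, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


@dataclass(frozen=True)
class EvalReport:
    """Discrimination metrics at a fixed cutoff."""

    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden_j: float
    confusion: dict[str, int]  # tp, fp, fn, tn

    def as_dict(self) -> dict:
        d = dict(auc=self.auc, auc_ci_low=self.auc_ci[0],
                 auc_ci_high=self.auc_ci[1], sensitivity=self.sensitivity,
                 specificity=self.specificity, ppv=self.ppv, npv=self.npv,
                 youden_j=self.youden_j)
        d.update(self.confusion)
        return d


def evaluate(scores, labels, cutoff: CutoffResult | float) -> EvalReport:
    """Evaluate a score against binary labels at a supplied cutoff."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    if not isinstance(cutoff, CutoffResult):
        cutoff = CutoffResult(float(cutoff))
    pred = cutoff.predict(s)
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    auc, lo, hi = delong_ci(s if cutoff.positive_above else -s, y)
    return EvalReport(
        auc=auc, auc_ci=(lo, hi), sensitivity=sens, specificity=spec,
        ppv=tp / (tp + fp) if tp + fp else 0.0,
        npv=tn / (tn + fn) if tn + fn else 0.0,
        youden_j=sens + spec - 1.0,
        confusion=dict(tp=tp, fp=fp, fn=fn, tn=tn))
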