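"""Propensity-score matching (1:3) and stratified train/test splitting.

The propensity score is a logistic regression of group membership on the
five clinical/morphological covariates (age, sex, aneurysm size, location,
number of flow-diverting devices). Each rupture case is greedily matched,
in descending order of propensity, to its nearest available controls on
the logit scale, without replacement; ties break by case id so the result
is stable under permutation of the input rows. Covariate balance is
summarized by the absolute standardized mean difference (SMD) before and
after matching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

__all__ = ["COVARIATES", "MatchedCohort", "MatchingError", "propensity_match",
           "split_train_test", "standardized_mean_differences",
           "balance_report"]

COVARIATES = ("age", "sex", "aneurysm_size_mm", "location", "ped_count")
_CATEGORICAL = ("sex", "location", "ped_count")
_POSITIVE_GROUP = "PIR"


class MatchingError(ValueError):
    """Raised when cases cannot be matched within the requested constraints."""


@dataclass(frozen=True)
class MatchedCohort:
    """Matched case/control ids with per-subject propensity scores."""

    pairs: dict[str, tuple[str, ...]]  # case id -> matched control ids
    propensity: pd.Series
    logit: pd.Series
    ratio: int

    @property
    def case_ids(self) -> list[str]:
        return list(self.pairs)

    @property
    def control_ids(self) -> list[str]:
        return [c for ctrls in self.pairs.values() for c in ctrls]

    @property
    def matched_ids(self) -> list[str]:
        return self.case_ids + self.control_ids

    def to_frame(self) -> pd.DataFrame:
        rows = [{"case_id": cid, "control_id": ctl, "k": k + 1}
                for cid, ctrls in self.pairs.items()
                for k, ctl in enumerate(ctrls)]
        return pd.DataFrame(rows)


def _design_matrix(table: pd.DataFrame) -> np.ndarray:
    cols = [pd.get_dummies(table[c], prefix=c, drop_first=True).astype(float)
            if c in _CATEGORICAL else table[[c]].astype(float)
            for c in COVARIATES]
    return pd.concat(cols, axis=1).to_numpy()


def propensity_match(table: pd.DataFrame, ratio: int = 3, seed: int = 0,
                     caliper_sd: float | None = None) -> MatchedCohort:
    """Greedy 1:ratio nearest-neighbor matching on the propensity logit.

    Parameters
    ----------
    table : DataFrame indexed by case_id with the covariates and a
        ``group`` column ({"PIR", "PIU"}).
    caliper_sd : optional caliper as a multiple of the SD of the logit
        propensity (e.g. 0.2); cases without enough controls inside the
        caliper raise :class:`MatchingError` listing them.
    """
    missing = [c for c in COVARIATES + ("group",) if c not in table.columns]
    if missing:
        raise ValueError(f"covariate table lacks columns {missing}")
    if table[list(COVARIATES)].isna().any().any():
        raise ValueError("covariate table contains missing values")
    cases = table.index[table["group"] == _POSITIVE_GROUP]
    controls = table.index[table["group"] != _POSITIVE_GROUP]
    if len(controls) < ratio * len(cases):
        raise MatchingError(
            f"need >= {ratio * len(cases)} controls, have {len(controls)}")

    X = StandardScaler().fit_transform(_design_matrix(table))
    y = (table["group"] == _POSITIVE_GROUP).astype(int).to_numpy()
    lr = LogisticRegression(C=np.inf, max_iter=2000, random_state=seed)
    lr.fit(X, y)
    p = np.clip(lr.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
    propensity = pd.Series(p, index=table.index, name="propensity")
    logit = pd.Series(np.log(p / (1 - p)), index=table.index, name="logit")

    caliper = (caliper_sd * float(logit.std(ddof=1))
               if caliper_sd is not None else math.inf)

    # process cases in descending propensity, ties broken by id
    order = sorted(cases, key=lambda cid: (-propensity[cid], cid))
    available = set(controls)
    pairs: dict[str, tuple[str, ...]] = {}
    unmatched: list[str] = []
    for cid in order:
        cands = sorted(available,
                       key=lambda k: (abs(logit[k] - logit[cid]), k))
        chosen = [k for k in cands[:ratio]
                  if abs(logit[k] - logit[cid]) <= caliper]
        if len(chosen) < ratio:
            unmatched.append(cid)
            continue
        pairs[cid] = tuple(chosen)
        available -= set(chosen)
    if unmatched:
        raise MatchingError(
            f"no controls within caliper for cases: {sorted(unmatched)}")
    pairs = {cid: pairs[cid] for cid in sorted(pairs)}
    return MatchedCohort(pairs, propensity, logit, ratio)


def standardized_mean_differences(table: pd.DataFrame) -> pd.Series:
    """Absolute SMD per covariate between the two groups.

    Continuous covariates use (m1-m0)/sqrt((s1^2+s0^2)/2); categorical
    covariates are expanded to indicator levels first.
    """
    g1 = table["group"] == _POSITIVE_GROUP
    out = {}
    expanded = pd.concat(
        [pd.get_dummies(table[c], prefix=c).astype(float)
         if c in _CATEGORICAL else table[[c]].astype(float)
         for c in COVARIATES], axis=1)
    for col in expanded.columns:
        a, b = expanded.loc[g1, col], expanded.loc[~g1, col]
        pooled = math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        out[col] = abs(a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
    return pd.Series(out, name="smd")


def balance_report(table: pd.DataFrame, matched: MatchedCohort) -> pd.DataFrame:
    """Pre- vs post-matching SMD per covariate level."""
    pre = standardized_mean_differences(table)
    post = standardized_mean_differences(table.loc[matched.matched_ids])
    return pd.DataFrame({"smd_pre": pre, "smd_post": post})


def split_train_test(table: pd.DataFrame, test_fraction: float = 1.0 / 3.0,
                     seed: int = 0) -> tuple[list[str], list[str]]:
    """Outcome-stratified random split into training and test ids.

    The number of rupture cases in the test set is round(n_pir * fraction)
    and the overall test size is round(n * fraction); controls fill the
    remainder, so a 64-case cohort with 16 ruptures at fraction 1/3 splits
    43/21 with 11 ruptures in training.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    cases = sorted(table.index[table["group"] == _POSITIVE_GROUP])
    controls = sorted(table.index[table["group"] != _POSITIVE_GROUP])
    n = len(table)
    n_test = int(round(n * test_fraction))
    n_test_cases = int(round(len(cases) * test_fraction))
    n_test_controls = n_test - n_test_cases
    if not (0 < n_test_cases < len(cases)) or not (0 < n_test_controls < len(controls)):
        raise ValueError("cohort too small for a stratified split")

    rng = np.random.default_rng(seed)
    cases = list(rng.permutation(cases))
    controls = list(rng.permutation(controls))
    test = sorted(cases[:n_test_cases] + controls[:n_test_controls])
    train = sorted(cases[n_test_cases:] + controls[n_test_controls:])
    return train, test
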