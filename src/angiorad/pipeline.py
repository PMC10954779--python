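"""End-to-end pipeline: cohort -> maps -> features -> selection -> score.

``run_pipeline`` is the single programmatic entry point used by the CLI,
the test suite, and the reproduction script. Stages:

1. generate a synthetic cohort (rupture cases + candidate-control pool)
2. propensity-match 1:ratio and render the matched cases
3. build the five perfusion maps per case over the union of the two
   raters' ROIs, then extract the 1,459-feature vector per case and rater
4. ICC(2,1) stability filter across all matched cases (rater agreement is
   outcome-blind, so it precedes the split)
5. stratified train/test split; univariate screen and LASSO on training
   (rater-1 features); Youden cutoff on the training scores
6. evaluate on training and test

The master seed fans out deterministically to per-stage seeds through
``numpy.random.SeedSequence``, so a fixed seed reproduces every artifact
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import model as model_mod
from .features import FeatureConfig, extract_all
from .maps import build_maps
from .perfusion import TDCFitConfig
from .synthetic import (AcquisitionSpec, BolusModel, EffectConfig,
                        SyntheticCohort, generate_cohort)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "extract_cohort_features", "stage_seed"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "match", "maps", "extract", "select", "score",
           "evaluate")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run depends on, validated on load."""

    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    bolus: BolusModel = field(default_factory=BolusModel)
    effect: EffectConfig = field(default_factory=EffectConfig)
    fit: TDCFitConfig = field(default_factory=TDCFitConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    n_pir: int = 16
    pool_size: int = 292
    rater_severity: float = 1.0
    icc_threshold: float = 0.8
    screen_alpha: float = 0.05
    cv_folds: int = 5
    match_ratio: int = 3
    test_fraction: float = 1.0 / 3.0
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        nested = {"acquisition": AcquisitionSpec, "bolus": BolusModel,
                  "effect": EffectConfig, "fit": TDCFitConfig,
                  "features": FeatureConfig}
        for key, typ in nested.items():
            if key in d:
                sub = d.pop(key)
                known = {f.name for f in dataclasses.fields(typ)}
                unknown = set(sub) - known
                if unknown:
                    raise ValueError(f"unknown {key} keys: {sorted(unknown)}")
                if key == "bolus":
                    from .synthetic import GammaBolus
                    for region in ("background", "artery", "sac"):
                        if region in sub:
                            sub[region] = GammaBolus(**sub[region])
                kwargs[key] = typ(**sub)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything a full run produces."""

    config: PipelineConfig
    cohort: SyntheticCohort
    matched: cohort_mod.MatchedCohort
    covariates: pd.DataFrame           # matched cases only
    features_r1: pd.DataFrame
    features_r2: pd.DataFrame
    icc_report: pd.DataFrame
    train_ids: list[str]
    test_ids: list[str]
    screen_report: pd.DataFrame
    model: model_mod.ScoreModel
    redundancy: pd.DataFrame
    scores: pd.Series                  # all matched cases
    train_eval: model_mod.EvalReport
    test_eval: model_mod.EvalReport

    @property
    def labels(self) -> pd.Series:
        return (self.covariates["group"] == "PIR").astype(int)


def extract_cohort_features(cohort: SyntheticCohort, case_ids,
                            fit_config: TDCFitConfig,
                            feature_config: FeatureConfig
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render cases, build maps over the union ROI, extract both raters.

    Maps are fitted once per case on the union of the two contours; each
    rater's features then use their own mask intersected with fit validity.
    """
    rows1, rows2 = [], []
    for cid in case_ids:
        case = cohort.render(cid)
        union = case.mask_rater1 | case.mask_rater2
        mapset = build_maps(case.frames, union, fit_config)
        rows1.append(pd.Series(
            extract_all(mapset, case.mask_rater1, feature_config), name=cid))
        rows2.append(pd.Series(
            extract_all(mapset, case.mask_rater2, feature_config), name=cid))
    return pd.DataFrame(rows1), pd.DataFrame(rows2)


def run_pipeline(config: PipelineConfig | None = None,
                 seed: int | None = None) -> PipelineResult:
    """Run the complete analysis; see the module docstring for the stages."""
    config = config or PipelineConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    master = config.seed

    cohort = generate_cohort(
        n_pir=config.n_pir, pool_size=config.pool_size, effect=config.effect,
        acq=config.acquisition, bolus=config.bolus,
        seed=stage_seed(master, "simulate"),
        rater_severity=config.rater_severity)

    matched = cohort_mod.propensity_match(
        cohort.covariates, ratio=config.match_ratio,
        seed=stage_seed(master, "match"))
    matched_ids = sorted(matched.matched_ids)
    covariates = cohort.covariates.loc[matched_ids]

    f1, f2 = extract_cohort_features(cohort, matched_ids, config.fit,
                                     config.features)

    icc_report = model_mod.icc_filter(f1, f2, config.icc_threshold)
    stable = icc_report.index[icc_report["stable"]].tolist()
    logger.info("stable features: %d/%d", len(stable), len(icc_report))

    train_ids, test_ids = cohort_mod.split_train_test(
        covariates, config.test_fraction, seed=stage_seed(master, "split"))
    y_train = (covariates.loc[train_ids, "group"] == "PIR").astype(int)

    screen = model_mod.univariate_screen(
        f1.loc[train_ids, stable], y_train, config.screen_alpha)
    kept = screen.index[screen["kept"]].tolist()
    logger.info("screened features: %d/%d", len(kept), len(stable))
    if not kept:
        raise RuntimeError("no features survived the univariate screen")

    score_model = model_mod.lasso_select(
        f1.loc[train_ids, kept], y_train, folds=config.cv_folds,
        seed=stage_seed(master, "lasso"))
    selected = score_model.selected
    logger.info("LASSO selected %d features: %s", len(selected), selected)

    if len(selected) >= 2:
        redundancy = model_mod.spearman_redundancy(f1.loc[train_ids, selected])
    else:
        redundancy = pd.DataFrame(
            columns=["feature_a", "feature_b", "rho", "flagged"])

    scores = model_mod.score_table(f1.loc[matched_ids], score_model)
    cut = model_mod.youden_cutoff(scores.loc[train_ids], y_train)
    score_model.cutoff = cut

    y_all = (covariates["group"] == "PIR").astype(int)
    train_eval = model_mod.evaluate(scores.loc[train_ids],
                                    y_all.loc[train_ids], cut)
    test_eval = model_mod.evaluate(scores.loc[test_ids],
                                   y_all.loc[test_ids], cut)

    return PipelineResult(
        config=config, cohort=cohort, matched=matched, covariates=covariates,
        features_r1=f1, features_r2=f2, icc_report=icc_report,
        train_ids=train_ids, test_ids=test_ids, screen_report=screen,
        model=score_model, redundancy=redundancy, scores=scores,
        train_eval=train_eval, test_eval=test_eval)
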