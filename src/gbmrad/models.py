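"""Cross-validation engine, signature models and clinical integration.

The scheme is 5 repetitions of stratified 5-fold cross-validation (25
folds): every subject is held out exactly once per repeat, so it sits in
the training split of exactly 20 fold-models and the validation split of
exactly 5.  Ensemble predictions average model outputs accordingly
(train-ensemble over the 20, validation-ensemble over the 5, and the
test-ensemble over all 25 models applied to unseen data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .coxph import CoxFit, fit_cox_breslow
from .signature import (Endpoint, FeatureTransform, SelectionConfig,
                        RANK_METHODS, rank_features_per_fold)

__all__ = [
    "CvScheme",
    "CvSplit",
    "EnsemblePrediction",
    "LogisticFit",
    "make_cv_splits",
    "fit_logistic",
    "fit_cox",
    "run_cv_pipeline",
    "combine_clinical",
]


@dataclass
class CvScheme:
    repeats: int = 5
    folds: int = 5
    master_seed: int = 0


@dataclass
class CvSplit:
    repeat: int
    fold: int
    train_ids: pd.Index
    valid_ids: pd.Index


@dataclass
class EnsemblePrediction:
    """Per-subject ensemble bookkeeping over the repeats x folds models."""

    table: pd.DataFrame          # train_ensemble, valid_ensemble, counts
    test_table: pd.DataFrame | None = None  # test_ensemble over all models

    def check_invariants(self, n_models: int) -> None:
        counts = self.table["n_train_models"] + self.table["n_valid_models"]
        if not (counts == n_models).all():
            raise AssertionError("train/valid model counts do not partition "
                                 f"the {n_models} models")


def make_cv_splits(strata: pd.Series, scheme: CvScheme | None = None
                   ) -> list[CvSplit]:
    """Stratified repeats x folds splits; seeded and deterministic."""
    scheme = scheme or CvScheme()
    strata = strata.astype(int)
    counts = strata.value_counts()
    if (counts < scheme.folds).any():
        small = counts[counts < scheme.folds]
        raise ValueError(f"stratum smaller than fold count: {dict(small)}")
    splits = []
    ids = strata.index.to_numpy()
    for rep in range(scheme.repeats):
        seed = int(np.random.SeedSequence([scheme.master_seed, rep])
                   .generate_state(1)[0] % (2**31))
        skf = StratifiedKFold(n_splits=scheme.folds, shuffle=True,
                              random_state=seed)
        for fold, (tr, va) in enumerate(skf.split(ids, strata.to_numpy())):
            splits.append(CvSplit(rep, fold,
                                  pd.Index(ids[tr]), pd.Index(ids[va])))
    return splits


@dataclass
class LogisticFit:
    coef: np.ndarray
    intercept: float
    probs: np.ndarray
    separation: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        lin = np.asarray(X, float) @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-lin))


def fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticFit:
    """Maximum-likelihood logistic regression with a ridge fallback when the
    classes are (quasi-)separable."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    model = LogisticRegression(C=np.inf, max_iter=2000)
    model.fit(X, y)
    coef = model.coef_.ravel()
    # scale-aware blow-up check: |beta_j| * sd(x_j) ~ log-odds per SD
    sds = X.std(axis=0)
    separation = bool(np.max(np.abs(coef) * np.where(sds > 0, sds, 1.0)) > 8.0)
    if separation:
        model = LogisticRegression(C=1.0, max_iter=2000)
        model.fit(X, y)
        coef = model.coef_.ravel()
    return LogisticFit(coef=coef, intercept=float(model.intercept_[0]),
                       probs=model.predict_proba(X)[:, 1],
                       separation=separation)


def fit_cox(X: np.ndarray, times: np.ndarray, events: np.ndarray,
            names: list[str] | None = None) -> CoxFit:
    """Cox partial-likelihood MLE with Breslow ties (see :mod:`coxph`)."""
    return fit_cox_breslow(X, times, events, names=names)


def _fit_endpoint_model(Xt: pd.DataFrame, endpoint: Endpoint):
    if endpoint.kind == "binary":
        fit = fit_logistic(Xt.to_numpy(), endpoint.y.to_numpy())
        return fit, lambda Z: fit.predict(Z.to_numpy())
    fit = fit_cox(Xt.to_numpy(), endpoint.time.to_numpy(),
                  endpoint.event.to_numpy())
    return fit, lambda Z: Z.to_numpy() @ fit.coef


def run_cv_pipeline(features: pd.DataFrame, endpoint: Endpoint,
                    cfg: SelectionConfig | None = None,
                    scheme: CvScheme | None = None,
                    test_features: pd.DataFrame | None = None,
                    model_method: str = "mim",
                    methods: tuple[str, ...] = RANK_METHODS,
                    max_refolds: int = 5) -> dict:
    """Per-fold transform + selection + model, with ensemble assembly.

    Each fold fits the Yeo-Johnson/z transform and the four selectors on
    its internal training part only.  The fold model is fitted on the
    ``model_method`` selector's top-k features and applied to the held-out
    part (and to ``test_features`` if given).  Degenerate folds (a single
    class or no events in training) trigger a reseeded refold.
    """
    cfg = cfg or SelectionConfig()
    scheme = scheme or CvScheme(repeats=cfg.cv_repeats, folds=cfg.cv_folds)
    strata = endpoint.stratum().astype(int)
    refolds = 0
    while True:
        sch = CvScheme(scheme.repeats, scheme.folds,
                       scheme.master_seed + 1000 * refolds)
        splits = make_cv_splits(strata, sch)
        degenerate = any(
            endpoint.subset(s.train_ids).stratum().nunique() < 2
            for s in splits)
        if not degenerate:
            break
        refolds += 1
        if refolds > max_refolds:
            raise ValueError("could not build non-degenerate CV folds")

    ids = features.index
    n_models = len(splits)
    sum_train = pd.Series(0.0, index=ids)
    n_train = pd.Series(0, index=ids)
    sum_valid = pd.Series(0.0, index=ids)
    n_valid = pd.Series(0, index=ids)
    sum_test = pd.Series(0.0, index=test_features.index) \
        if test_features is not None else None
    cv_rankings: list[dict[str, list[str]]] = []
    fold_models = []
    fold_transforms = []

    for split in splits:
        X_tr = features.loc[split.train_ids]
        ep_tr = endpoint.subset(split.train_ids)
        transform = FeatureTransform.fit(X_tr)
        Xt_tr = transform.transform(X_tr)
        ranking = {m: rank_features_per_fold(Xt_tr, ep_tr, m, cfg.top_k,
                                             cfg.mi_bins)
                   for m in methods}
        cv_rankings.append(ranking)
        sel = ranking[model_method]
        fit, predict = _fit_endpoint_model(Xt_tr[sel], ep_tr)
        fold_models.append((sel, fit))
        fold_transforms.append(transform)

        Xt_va = transform.transform(features.loc[split.valid_ids])
        sum_valid.loc[split.valid_ids] += predict(Xt_va[sel])
        n_valid.loc[split.valid_ids] += 1
        sum_train.loc[split.train_ids] += predict(Xt_tr[sel])
        n_train.loc[split.train_ids] += 1
        if sum_test is not None:
            Xt_te = transform.transform(test_features)
            sum_test += predict(Xt_te[sel])

    table = pd.DataFrame({
        "train_ensemble": sum_train / n_train.replace(0, np.nan),
        "valid_ensemble": sum_valid / n_valid.replace(0, np.nan),
        "n_train_models": n_train,
        "n_valid_models": n_valid,
    })
    test_table = None
    if sum_test is not None:
        test_table = pd.DataFrame({"test_ensemble": sum_test / n_models})
    ens = EnsemblePrediction(table=table, test_table=test_table)
    ens.check_invariants(n_models)
    return {
        "splits": splits,
        "cv_rankings": cv_rankings,
        "fold_models": fold_models,
        "fold_transforms": fold_transforms,
        "ensemble": ens,
        "n_refolds": refolds,
    }


@dataclass
class ClinicalModelSpec:
    candidates: list[str] = field(default_factory=lambda: ["age", "mgmt"])
    alpha: float = 0.05
    rho_cap: float = 0.5


def combine_clinical(clinical: pd.DataFrame, image_scores: pd.Series,
                     times: pd.Series, events: pd.Series,
                     spec: ClinicalModelSpec | None = None) -> dict:
    """Screen clinical covariates (univariable Cox, alpha), cap correlation
    between predictors at |rho| < 0.5 (clinical takes priority over the
    image predictor), and fit the joint multivariable Cox model."""
    spec = spec or ClinicalModelSpec()
    screened = []
    pv = {}
    for c in [c for c in spec.candidates if c in clinical.columns]:
        x = clinical[c].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        fit = fit_cox_breslow(x[:, None], times.to_numpy(), events.to_numpy())
        pv[c] = float(fit.pvals[0])
        if pv[c] < spec.alpha:
            screened.append(c)
    screened.sort(key=lambda c: (pv[c], c))

    retained = []
    for c in screened:
        if all(abs(stats.spearmanr(clinical[c], clinical[p]).statistic)
               < spec.rho_cap for p in retained):
            retained.append(c)
    image_kept = all(
        abs(stats.spearmanr(image_scores, clinical[c]).statistic) < spec.rho_cap
        for c in retained)
    predictors = pd.DataFrame(index=clinical.index)
    for c in retained:
        predictors[c] = clinical[c].astype(float)
    if image_kept:
        predictors["image"] = image_scores.astype(float)
    note = None
    if predictors.shape[1] == 0:
        predictors["image"] = image_scores.astype(float)
        image_kept = True
    if not retained:
        note = "no clinical covariate passed screening; image-only model"
    elif not image_kept:
        note = "image predictor dropped by the correlation cap; clinical-only model"
    fit = fit_cox_breslow(predictors.to_numpy(), times.to_numpy(),
                          events.to_numpy(), names=list(predictors.columns))
    return {"fit": fit, "predictors": list(predictors.columns),
            "screened": screened, "screen_pvalues": pv,
            "image_kept": image_kept, "note": note}
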