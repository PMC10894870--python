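"""Evaluation statistics: discrimination, cutoffs, risk stratification,
calibration and univariable screening.

All tests are two-sided at significance level 0.05.  Confidence
intervals for AUC and Harrell's C use seeded bootstrap percentiles
(stratified by class for the AUC, plain subject resampling for C).
Cutoffs are always derived on training data and carried over unchanged;
the returned objects carry a ``training_derived`` flag that downstream
evaluation asserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats
from sklearn.metrics import roc_auc_score

from .coxph import fit_cox_breslow

__all__ = [
    "EvalMetrics",
    "CutoffResult",
    "CalibrationResult",
    "roc_auc_ci",
    "harrell_c",
    "youden_cutoff",
    "maxsel_rank_cutoff",
    "apply_cutoff",
    "km_logrank",
    "hosmer_lemeshow",
    "gnd_test",
    "univariable_cox_screen",
]


@dataclass
class EvalMetrics:
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    metric: str


@dataclass
class CutoffResult:
    cutoff: float
    criterion: str                    # "youden" | "maxsel_rank"
    training_derived: bool = True
    statistic: float | None = None


@dataclass
class CalibrationResult:
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame


def roc_auc_ci(scores, labels, n_boot: int = 2000, seed: int = 0) -> EvalMetrics:
    """AUC (Mann-Whitney with half tie credit) with a stratified bootstrap
    percentile 95% CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    rng = np.random.default_rng(seed)
    pos = np.where(labels == 1)[0]
    neg = np.where(labels == 0)[0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([bp, bn])
        boots[b] = roc_auc_score(labels[idx], scores[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return EvalMetrics(auc, float(lo), float(hi), len(labels), "auc")


def harrell_c(scores, times, events, n_boot: int = 0, seed: int = 0):
    """Harrell's concordance index for risk scores (higher score = higher
    risk); tied scores get half credit.  With ``n_boot`` > 0 a subject
    bootstrap percentile CI is attached."""
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if events.sum() == 0:
        raise ValueError("no comparable pairs (no events)")
    # lifelines' concordance is for predicted survival times: negate risk
    c = float(concordance_index(times, -scores, events))
    if n_boot <= 0:
        return EvalMetrics(c, np.nan, np.nan, len(times), "c_index")
    rng = np.random.default_rng(seed)
    boots = []
    n = len(times)
    while len(boots) < n_boot:
        idx = rng.integers(0, n, size=n)
        if events[idx].sum() == 0:
            continue
        boots.append(concordance_index(times[idx], -scores[idx], events[idx]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return EvalMetrics(c, float(lo), float(hi), n, "c_index")


def _candidate_cutpoints(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    return (u[:-1] + u[1:]) / 2.0


def youden_cutoff(scores, labels) -> CutoffResult:
    """Training cutoff maximising J = sensitivity + specificity - 1 over the
    midpoints of adjacent observed scores; ties take the lower cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    cands = _candidate_cutpoints(scores)
    if cands.size == 0:
        return CutoffResult(float(scores[0]), "youden", statistic=0.0)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_j, best_c = -np.inf, cands[0]
    for c in cands:
        pred = scores > c
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return CutoffResult(float(best_c), "youden", statistic=float(best_j))


def logrank_z(group: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Standardized two-group log-rank statistic (O - E) / sqrt(V) for the
    ``group == 1`` arm."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    group = np.asarray(group).astype(bool)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & group).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0
    return float(o_minus_e / np.sqrt(var))


def maxsel_rank_cutoff(scores, times, events,
                       quantile_range: tuple[float, float] = (0.10, 0.90)
                       ) -> CutoffResult:
    """Maximally selected rank statistics: the cutoff maximising the
    absolute standardized log-rank statistic over candidate cutpoints
    between the 10th and 90th score percentiles."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 10:
        raise ValueError("need at least 10 subjects")
    if np.ptp(scores) == 0:
        raise ValueError("all scores equal: no admissible cutpoint")
    lo, hi = np.quantile(scores, quantile_range)
    cands = _candidate_cutpoints(scores)
    cands = cands[(cands >= lo) & (cands <= hi)]
    if cands.size == 0:
        cands = _candidate_cutpoints(scores)
    best_z, best_c = -np.inf, cands[0]
    for c in cands:
        z = abs(logrank_z(scores > c, times, events))
        if z > best_z + 1e-12:
            best_z, best_c = z, c
    return CutoffResult(float(best_c), "maxsel_rank", statistic=float(best_z))


def apply_cutoff(scores, cutoff: CutoffResult) -> np.ndarray:
    """Dichotomise test scores with a training-derived cutoff."""
    if not cutoff.training_derived:
        raise ValueError("cutoff must be training-derived before transfer")
    return (np.asarray(scores, dtype=float) > cutoff.cutoff).astype(int)


def km_logrank(groups, times, events) -> dict:
    """Kaplan-Meier curves per group plus the log-rank test."""
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 nonempty groups")
    curves = {}
    for g in np.unique(groups):
        sel = groups == g
        if sel.sum() == 0:
            raise ValueError(f"group {g!r} is empty")
        km = KaplanMeierFitter()
        km.fit(times[sel], events[sel])
        curves[g] = km
    res = multivariate_logrank_test(times, groups, events)
    return {"curves": curves, "chi2": float(res.test_statistic),
            "p_value": float(res.p_value)}


def hosmer_lemeshow(pred_probs, labels, g: int = 10) -> CalibrationResult:
    """Hosmer-Lemeshow goodness of fit: H = sum (O-E)^2 / (E (1 - E/n_g))
    over g groups of predicted risk, df = g - 2."""
    p = np.asarray(pred_probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(p) < 2 * g:
        raise ValueError("need n >= 2 g")
    order = np.argsort(p, kind="stable")
    bins = np.array_split(order, g)
    rows = []
    for idx in bins:
        if len(idx) == 0:
            continue
        rows.append({"n": len(idx), "obs": int(y[idx].sum()),
                     "exp": float(p[idx].sum()),
                     "mean_pred": float(p[idx].mean())})
    table = pd.DataFrame(rows)
    # merge degenerate bins (zero-variance expectation) into the neighbour
    merged, skipped = [], 0
    for _, r in table.iterrows():
        var = r["exp"] * (1.0 - r["exp"] / r["n"])
        if var <= 1e-12 and merged:
            for k in ("n", "obs", "exp"):
                merged[-1][k] += r[k]
            skipped += 1
        else:
            merged.append(dict(r))
    table = pd.DataFrame(merged)
    h = 0.0
    for _, r in table.iterrows():
        var = r["exp"] * (1.0 - r["exp"] / r["n"])
        if var > 0:
            h += (r["obs"] - r["exp"]) ** 2 / var
    df = max(len(table) - 2, 1)
    pval = float(stats.chi2.sf(h, df))
    return CalibrationResult(float(h), df, pval, table)


def _km_at(times, events, t_star):
    """KM survival estimate and Greenwood variance at t*."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    s, gw = 1.0, 0.0
    for t in np.sort(np.unique(times[events & (times <= t_star)])):
        n = (times >= t).sum()
        d = (events & (times == t)).sum()
        if n == 0 or d == 0:
            continue
        s *= 1.0 - d / n
        if n > d:
            gw += d / (n * (n - d))
    return s, (s**2) * gw


def gnd_test(pred_surv_at_t, times, events, t_star: float,
             g: int = 5, min_events: int = 5) -> CalibrationResult:
    """Greenwood-Nam-d'Agostino calibration test at horizon t*.

    Subjects are grouped by predicted survival at t*; per group the
    KM-observed survival is compared with the mean predicted survival,
    chi2 = sum (S_KM - S_pred)^2 / Var_Greenwood, df = groups - 1.
    Groups with fewer than ``min_events`` events by t* are merged into
    their neighbour.
    """
    p = np.asarray(pred_surv_at_t, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if not (times.min() <= t_star <= times.max()):
        raise ValueError("evaluation horizon outside follow-up")
    order = np.argsort(p, kind="stable")
    groups = [list(idx) for idx in np.array_split(order, g) if len(idx)]
    # merge sparse groups into the next neighbour
    merged: list[list[int]] = []
    for grp in groups:
        ev = int(((events == 1) & (times <= t_star))[grp].sum())
        if merged and ev < min_events:
            merged[-1].extend(grp)
        else:
            merged.append(list(grp))
    if len(merged) > 1:
        ev0 = int(((events == 1) & (times <= t_star))[merged[0]].sum())
        if ev0 < min_events:
            merged[1] = merged[0] + merged[1]
            merged = merged[1:]
    if len(merged) < 2:
        raise ValueError("fewer than 2 admissible groups (df = 0)")
    rows, chi2 = [], 0.0
    for grp in merged:
        idx = np.asarray(grp)
        s_km, var = _km_at(times[idx], events[idx], t_star)
        s_pred = float(p[idx].mean())
        if var > 0:
            chi2 += (s_km - s_pred) ** 2 / var
        rows.append({"n": len(idx), "observed_surv": s_km,
                     "expected_surv": s_pred, "greenwood_var": var})
    df = len(merged) - 1
    pval = float(stats.chi2.sf(chi2, df))
    return CalibrationResult(float(chi2), df, pval,
                             pd.DataFrame(rows))


def univariable_cox_screen(covariates: pd.DataFrame, times, events,
                           alpha: float = 0.05) -> dict:
    """Per-covariate univariable Cox fits with two-sided Wald p-values;
    covariates with p < alpha are admitted.  Constant covariates are
    skipped (reported separately)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if events.sum() < 1:
        raise ValueError("need at least one event")
    pvals, admitted, skipped = {}, [], []
    for c in covariates.columns:
        x = covariates[c].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            skipped.append(c)
            continue
        fit = fit_cox_breslow(x[:, None], times, events)
        pvals[c] = float(fit.pvals[0])
        if pvals[c] < alpha:
            admitted.append(c)
    return {"admitted": admitted, "p_values": pvals, "skipped": skipped}
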