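"""Cox proportional-hazards fitting via the Breslow partial likelihood.

A compact Newton–Raphson solver used by the modelling and screening
stages.  Breslow tie handling is used throughout, matching the batch
survival loss of the network pathway.  For continuous synthetic times
(no ties) this coincides with the Efron likelihood of reference survival
libraries, which serve as an independent cross-check in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CoxFit", "breslow_neg_loglik", "fit_cox_breslow",
           "breslow_baseline_cumhaz"]


@dataclass
class CoxFit:
    coef: np.ndarray
    se: np.ndarray
    zvals: np.ndarray
    pvals: np.ndarray
    loglik: float
    linear_predictor: np.ndarray
    converged: bool
    names: list[str] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef


def _risk_set_sizes(times_desc: np.ndarray, event_pos: np.ndarray) -> np.ndarray:
    """Number of subjects with T_j >= T_i for each event, times sorted desc."""
    return np.searchsorted(-times_desc, -times_desc[event_pos], side="right")


def breslow_neg_loglik(beta: np.ndarray, X: np.ndarray, times: np.ndarray,
                       events: np.ndarray):
    """Negative Breslow partial log-likelihood with gradient and Hessian."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    order = np.argsort(-np.asarray(times, dtype=float), kind="stable")
    Xs = X[order]
    ts = np.asarray(times, dtype=float)[order]
    es = np.asarray(events)[order].astype(bool)
    eta = Xs @ beta
    eta_c = eta - eta.max()  # overflow guard; cancels in ratios, tracked in log
    w = np.exp(eta_c)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * Xs, axis=0)
    s2 = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
    ev_pos = np.where(es)[0]
    m = _risk_set_sizes(ts, ev_pos) - 1  # index into cumsums
    s0e = s0[m]
    # log S0 in the original scale is log(s0e) + max(eta)
    nll = float(-(eta[ev_pos] - np.log(s0e) - eta.max()).sum())
    ratio1 = s1[m] / s0e[:, None]
    grad = -(Xs[ev_pos] - ratio1).sum(axis=0)
    ratio2 = s2[m] / s0e[:, None, None]
    hess = (ratio2 - ratio1[:, :, None] * ratio1[:, None, :]).sum(axis=0)
    return nll, grad, hess


def fit_cox_breslow(X: np.ndarray, times: np.ndarray, events: np.ndarray,
                    names: list[str] | None = None, max_iter: int = 50,
                    tol: float = 1e-9, ridge: float = 0.0) -> CoxFit:
    """Newton–Raphson fit of the Breslow partial likelihood.

    ``ridge`` adds an optional small L2 penalty used as a fallback when
    the likelihood is monotone (infinite-coefficient data).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    events = np.asarray(events).astype(bool)
    if events.sum() < 1:
        raise ValueError("need at least one observed event")
    p = X.shape[1]
    beta = np.zeros(p)
    nll, grad, hess = breslow_neg_loglik(beta, X, times, events)
    nll += 0.5 * ridge * beta @ beta
    converged = False
    for _ in range(max_iter):
        g = grad + ridge * beta
        h = hess + ridge * np.eye(p)
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(h, g, rcond=None)[0]
        # step halving
        t = 1.0
        for _ in range(30):
            cand = beta - t * step
            nll_c, grad_c, hess_c = breslow_neg_loglik(cand, X, times, events)
            nll_c += 0.5 * ridge * cand @ cand
            if np.isfinite(nll_c) and nll_c <= nll + 1e-12:
                break
            t /= 2.0
        if np.max(np.abs(beta - cand)) < tol or abs(nll - nll_c) < tol:
            beta, nll, grad, hess = cand, nll_c, grad_c, hess_c
            converged = True
            break
        beta, nll, grad, hess = cand, nll_c, grad_c, hess_c
    if not converged and np.max(np.abs(beta)) > 50 and ridge == 0.0:
        return fit_cox_breslow(X, times, events, names=names,
                               max_iter=max_iter, tol=tol, ridge=1e-2)
    h = hess + ridge * np.eye(p)
    try:
        cov = np.linalg.inv(h)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(coef=beta, se=se, zvals=z, pvals=pvals, loglik=float(-nll),
                  linear_predictor=X @ beta, converged=converged, names=names)


def breslow_baseline_cumhaz(linear_predictor: np.ndarray, times: np.ndarray,
                            events: np.ndarray, t_star: float) -> float:
    """Breslow estimate of the baseline cumulative hazard H0(t*):
    sum over event times <= t* of d_i / sum_{j in risk set} exp(eta_j).
    Predicted survival at t* is then exp(-H0(t*) * exp(eta))."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    w = np.exp(np.asarray(linear_predictor, dtype=float))
    h0 = 0.0
    for t in np.unique(times[events]):
        if t > t_star:
            continue
        d = int((events & (times == t)).sum())
        h0 += d / w[times >= t].sum()
    return float(h0)
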