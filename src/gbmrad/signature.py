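"""Feature de-redundancy, transformation, per-fold selection and the
cross-validation consensus signature rule.

Workflow (training data only at every step):

1. agglomerative clustering of robust features on 1 - |Spearman rho|
   (average linkage, clusters merged while average |rho| >= 0.8), keeping
   the member with the highest mutual information with the endpoint;
2. per CV fold: Yeo-Johnson then z-transform fitted on the internal
   training part; four selectors (MRMR, MIM, elastic net, univariate
   regression) each nominate their top five features;
3. consensus: per selector, features are ranked by occurrence across the
   25 folds; features in the top five of at least 3 of 4 selectors are
   eligible; the five most frequent eligible features are decorrelated at
   Spearman rho > 0.5 (keeping the feature more associated with the
   endpoint) and the final model is refitted on the full training data.

Mutual information uses ten equal-frequency bins per feature; for
survival endpoints the MI partner is the event indicator.  Ties
everywhere break lexicographically by feature name for determinism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.linear_model import LogisticRegressionCV

from .coxph import fit_cox_breslow

__all__ = [
    "Endpoint",
    "SelectionConfig",
    "FeatureTransform",
    "Signature",
    "mutual_information",
    "cluster_features",
    "yeo_johnson_apply",
    "rank_features_per_fold",
    "consensus_signature",
]

RANK_METHODS = ("mrmr", "mim", "en", "ur")


@dataclass
class Endpoint:
    """A binary label or a right-censored (time, event) endpoint."""

    kind: str                       # "binary" | "survival"
    y: pd.Series | None = None
    time: pd.Series | None = None
    event: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "survival"):
            raise ValueError(f"unknown endpoint kind {self.kind!r}")
        if self.kind == "binary" and self.y is None:
            raise ValueError("binary endpoint needs labels")
        if self.kind == "survival" and (self.time is None or self.event is None):
            raise ValueError("survival endpoint needs time and event")

    def subset(self, ids) -> "Endpoint":
        if self.kind == "binary":
            return Endpoint("binary", y=self.y.loc[ids])
        return Endpoint("survival", time=self.time.loc[ids],
                        event=self.event.loc[ids])

    @property
    def ids(self) -> pd.Index:
        return self.y.index if self.kind == "binary" else self.time.index

    def mi_target(self) -> np.ndarray:
        """Discrete target used for mutual-information estimation."""
        return (self.y if self.kind == "binary" else self.event).to_numpy().astype(int)

    def stratum(self) -> pd.Series:
        return self.y if self.kind == "binary" else self.event


@dataclass
class SelectionConfig:
    cluster_rho: float = 0.8
    top_k: int = 5
    method_fraction: float = 0.75
    decorrelation_rho: float = 0.5
    cv_repeats: int = 5
    cv_folds: int = 5
    mi_bins: int = 10

    def __post_init__(self) -> None:
        for t in (self.cluster_rho, self.method_fraction, self.decorrelation_rho):
            if not 0.0 < t < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def _equal_freq_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def _mi_discrete(a: np.ndarray, b: np.ndarray) -> float:
    """MI (nats) between two small-alphabet discrete vectors."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    na, nb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb) / a.size
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def mutual_information(x: np.ndarray, target: np.ndarray,
                       n_bins: int = 10) -> float:
    """MI (nats) between a continuous feature (equal-frequency binned) and a
    discrete target."""
    return _mi_discrete(_equal_freq_bins(np.asarray(x, float), n_bins),
                        np.asarray(target))


def _feature_mi(X: pd.DataFrame, endpoint: Endpoint, n_bins: int = 10) -> pd.Series:
    t = endpoint.mi_target()
    return pd.Series({c: mutual_information(X[c].to_numpy(), t, n_bins)
                      for c in X.columns})


def cluster_features(X: pd.DataFrame, endpoint: Endpoint,
                     cfg: SelectionConfig | None = None
                     ) -> tuple[list[str], dict[str, list[str]]]:
    """Average-linkage clustering on 1 - |Spearman rho|; returns the sorted
    representative names and the cluster membership map."""
    cfg = cfg or SelectionConfig()
    cols = list(X.columns)
    if len(cols) < 2:
        return sorted(cols), {c: [c] for c in cols}
    rho = X.corr(method="spearman").to_numpy()
    dist = 1.0 - np.abs(rho)
    dist = np.nan_to_num(dist, nan=1.0)  # constant features: no correlation
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=1.0 - cfg.cluster_rho, criterion="distance")
    mi = _feature_mi(X, endpoint, cfg.mi_bins)
    reps, members = [], {}
    for lab in np.unique(labels):
        group = sorted([cols[i] for i in np.where(labels == lab)[0]])
        rep = min(group, key=lambda c: (-mi[c], c))  # tie -> lexicographic
        reps.append(rep)
        members[rep] = group
    return sorted(reps), members


# ---------------------------------------------------------------------------
# Yeo-Johnson + z transform
# ---------------------------------------------------------------------------

def yeo_johnson_apply(y: np.ndarray, lam: float) -> np.ndarray:
    """Standard Yeo-Johnson transform (defined on all reals)."""
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    pos = y >= 0
    if abs(lam) > 1e-12:
        out[pos] = ((y[pos] + 1.0) ** lam - 1.0) / lam
    else:
        out[pos] = np.log1p(y[pos])
    if abs(lam - 2.0) > 1e-12:
        out[~pos] = -(((-y[~pos] + 1.0) ** (2.0 - lam)) - 1.0) / (2.0 - lam)
    else:
        out[~pos] = -np.log1p(-y[~pos])
    return out


@dataclass
class FeatureTransform:
    """Per-feature Yeo-Johnson lambda (maximum likelihood) followed by a
    z-transform; fitted on training data only, applied unchanged."""

    lambdas: dict[str, float] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "FeatureTransform":
        t = cls()
        for c in X.columns:
            v = X[c].to_numpy(dtype=float)
            if np.ptp(v) == 0:
                lam = 1.0
            else:
                lam = float(stats.yeojohnson_normmax(v))
            tv = yeo_johnson_apply(v, lam)
            sd = tv.std()
            t.lambdas[c] = lam
            t.means[c] = float(tv.mean())
            t.sds[c] = float(sd if sd > 0 else 1.0)
        return t

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for c in X.columns:
            tv = yeo_johnson_apply(X[c].to_numpy(dtype=float), self.lambdas[c])
            out[c] = (tv - self.means[c]) / self.sds[c]
        return pd.DataFrame(out, index=X.index)


# ---------------------------------------------------------------------------
# per-fold selectors
# ---------------------------------------------------------------------------

def _rank_mim(X, endpoint, top_k, n_bins):
    mi = _feature_mi(X, endpoint, n_bins)
    order = sorted(X.columns, key=lambda c: (-mi[c], c))
    return order[:top_k]


def _rank_mrmr(X, endpoint, top_k, n_bins):
    t = endpoint.mi_target()
    cols = list(X.columns)
    binned = {c: _equal_freq_bins(X[c].to_numpy(float), n_bins) for c in cols}
    relevance = {c: _mi_discrete(binned[c], t) for c in cols}
    pair_mi: dict[tuple[str, str], float] = {}

    def _pair(a, b):
        key = (a, b) if a < b else (b, a)
        if key not in pair_mi:
            pair_mi[key] = _mi_discrete(binned[a], binned[b])
        return pair_mi[key]

    selected: list[str] = []
    remaining = set(cols)
    while remaining and len(selected) < top_k:
        def score(c):
            if not selected:
                return relevance[c]
            return relevance[c] - np.mean([_pair(c, s) for s in selected])
        best = min(remaining, key=lambda c: (-score(c), c))
        selected.append(best)
        remaining.discard(best)
    return selected


def _rank_en(X, endpoint, top_k):
    cols = list(X.columns)
    if endpoint.kind == "binary":
        y = endpoint.y.to_numpy().astype(int)
        model = LogisticRegressionCV(
            Cs=[0.01, 0.1, 1.0, 10.0], cv=3, solver="saga", l1_ratios=[0.5],
            max_iter=5000, tol=1e-4, scoring="neg_log_loss", random_state=0)
        model.fit(X.to_numpy(), y)
        coef = model.coef_.ravel()
    else:
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv
        y = Surv.from_arrays(endpoint.event.to_numpy().astype(bool),
                             endpoint.time.to_numpy())
        net = CoxnetSurvivalAnalysis(l1_ratio=0.5, n_alphas=20,
                                     alpha_min_ratio=0.01)
        net.fit(X.to_numpy(), y)
        alphas = net.alphas_
        # internal 3-fold CV over the path by partial-likelihood concordance
        from sklearn.model_selection import KFold
        scores = np.zeros(len(alphas))
        for tr, va in KFold(3, shuffle=True, random_state=0).split(X):
            if endpoint.event.iloc[tr].sum() == 0 or endpoint.event.iloc[va].sum() == 0:
                continue
            m = CoxnetSurvivalAnalysis(l1_ratio=0.5, alphas=alphas,
                                       fit_baseline_model=False)
            m.fit(X.iloc[tr].to_numpy(), y[tr])
            from sksurv.metrics import concordance_index_censored
            for ai, a in enumerate(alphas):
                pred = m.predict(X.iloc[va].to_numpy(), alpha=a)
                try:
                    c = concordance_index_censored(
                        endpoint.event.iloc[va].to_numpy().astype(bool),
                        endpoint.time.iloc[va].to_numpy(), pred)[0]
                except Exception:
                    c = 0.5
                scores[ai] += c
        best_alpha = alphas[int(np.argmax(scores))]
        coef = CoxnetSurvivalAnalysis(l1_ratio=0.5, alphas=[best_alpha]) \
            .fit(X.to_numpy(), y).coef_.ravel()
    nz = [(abs(coef[i]), cols[i]) for i in range(len(cols)) if coef[i] != 0]
    nz.sort(key=lambda t: (-t[0], t[1]))
    return [name for _, name in nz[:top_k]]


def _rank_ur(X, endpoint, top_k):
    import warnings

    import statsmodels.api as sm

    pvals = {}
    for c in X.columns:
        x = X[c].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            pvals[c] = 1.0
            continue
        if endpoint.kind == "binary":
            y = endpoint.y.to_numpy().astype(int)
            try:
                with np.errstate(all="ignore"), warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Logit(y, sm.add_constant(x)).fit(disp=0, maxiter=100)
                p = float(res.pvalues[1])
                # (quasi-)separation: the Wald p is meaningless (huge SE);
                # a perfectly separating feature is maximally significant
                if (not np.isfinite(p)
                        or not res.mle_retvals.get("converged", True)
                        or np.abs(res.params).max() > 20.0):
                    p = 0.0
            except Exception:
                p = 0.0
        else:
            try:
                fit = fit_cox_breslow(x[:, None], endpoint.time.to_numpy(),
                                      endpoint.event.to_numpy())
                p = float(fit.pvals[0])
                if not np.isfinite(p):
                    p = 1.0
            except Exception:
                p = 1.0
        pvals[c] = p
    order = sorted(X.columns, key=lambda c: (pvals[c], c))
    return order[:top_k]


def rank_features_per_fold(X: pd.DataFrame, endpoint: Endpoint, method: str,
                           top_k: int = 5, mi_bins: int = 10) -> list[str]:
    """Top-k feature names for one fold-training set under one selector."""
    method = method.lower()
    if method == "mim":
        return _rank_mim(X, endpoint, top_k, mi_bins)
    if method == "mrmr":
        return _rank_mrmr(X, endpoint, top_k, mi_bins)
    if method == "en":
        return _rank_en(X, endpoint, top_k)
    if method == "ur":
        return _rank_ur(X, endpoint, top_k)
    raise ValueError(f"unknown selection method {method!r}")


# ---------------------------------------------------------------------------
# consensus rule and final signature
# ---------------------------------------------------------------------------

@dataclass
class Signature:
    features: list[str]
    endpoint_kind: str
    transform: FeatureTransform
    coef: list[float]
    intercept: float = 0.0
    model_kind: str = "logistic"    # "logistic" | "cox"

    def predict(self, X: pd.DataFrame) -> pd.Series:
        Xt = self.transform.transform(X[self.features])
        lin = Xt.to_numpy() @ np.asarray(self.coef) + self.intercept
        if self.model_kind == "logistic":
            return pd.Series(1.0 / (1.0 + np.exp(-lin)), index=X.index)
        return pd.Series(lin, index=X.index)

    def to_json(self) -> str:
        d = {"features": self.features, "endpoint_kind": self.endpoint_kind,
             "model_kind": self.model_kind, "coef": list(self.coef),
             "intercept": self.intercept,
             "transform": {"lambdas": self.transform.lambdas,
                           "means": self.transform.means,
                           "sds": self.transform.sds}}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "Signature":
        d = json.loads(s)
        t = FeatureTransform(**d["transform"])
        return cls(features=d["features"], endpoint_kind=d["endpoint_kind"],
                   transform=t, coef=d["coef"], intercept=d["intercept"],
                   model_kind=d["model_kind"])


def occurrence_table(cv_rankings: list[dict[str, list[str]]]) -> pd.DataFrame:
    """Occurrence counts per (feature, method) across CV folds."""
    counts: dict[str, dict[str, int]] = {}
    for fold in cv_rankings:
        for method, names in fold.items():
            for nm in names:
                counts.setdefault(nm, {}).setdefault(method, 0)
                counts[nm][method] += 1
    methods = sorted({m for fold in cv_rankings for m in fold})
    df = pd.DataFrame(0, index=sorted(counts), columns=methods, dtype=int)
    for nm, per in counts.items():
        for m, c in per.items():
            df.loc[nm, m] = c
    return df


def consensus_features(cv_rankings: list[dict[str, list[str]]],
                       X_train: pd.DataFrame, endpoint: Endpoint,
                       cfg: SelectionConfig | None = None
                       ) -> tuple[list[str], pd.DataFrame]:
    """Apply the consensus rule; returns (selected names, occurrence table).

    Invariant to fold and method ordering: the rule only consumes
    per-(feature, method) occurrence counts and training-data statistics.
    """
    cfg = cfg or SelectionConfig()
    occ = occurrence_table(cv_rankings)
    if occ.empty:
        raise ValueError("no features were ever selected across CV folds")
    methods = list(occ.columns)
    need = int(np.ceil(cfg.method_fraction * len(methods)))
    top_per_method: dict[str, set[str]] = {}
    for m in methods:
        ranked = sorted(occ.index[occ[m] > 0],
                        key=lambda nm: (-occ.loc[nm, m], nm))
        top_per_method[m] = set(ranked[:cfg.top_k])
    support = {nm: sum(nm in top_per_method[m] for m in methods)
               for nm in occ.index}
    eligible = [nm for nm in occ.index if support[nm] >= need]
    if not eligible:
        raise ValueError(
            "consensus rule found no feature in the top "
            f"{cfg.top_k} of >= {need}/{len(methods)} methods; "
            f"occurrence table:\n{occ}")
    total = occ.sum(axis=1)
    eligible.sort(key=lambda nm: (-total[nm], nm))
    kept = eligible[:cfg.top_k]

    # decorrelation at rho > threshold, keeping the feature with the
    # higher training association with the endpoint
    mi = _feature_mi(X_train[kept], endpoint, cfg.mi_bins)
    by_assoc = sorted(kept, key=lambda nm: (-mi[nm], nm))
    final: list[str] = []
    for nm in by_assoc:
        ok = True
        for prev in final:
            rho = stats.spearmanr(X_train[nm], X_train[prev]).statistic
            if abs(rho) > cfg.decorrelation_rho:
                ok = False
                break
        if ok:
            final.append(nm)
    return sorted(final), occ


def consensus_signature(cv_rankings: list[dict[str, list[str]]],
                        X_train: pd.DataFrame, endpoint: Endpoint,
                        cfg: SelectionConfig | None = None) -> Signature:
    """Consensus feature set plus a final model refitted on full training."""
    from .models import fit_logistic  # lazy: models imports this module too

    cfg = cfg or SelectionConfig()
    final, _ = consensus_features(cv_rankings, X_train, endpoint, cfg)
    transform = FeatureTransform.fit(X_train[final])
    Xt = transform.transform(X_train[final])
    if endpoint.kind == "binary":
        fit = fit_logistic(Xt.to_numpy(), endpoint.y.to_numpy().astype(int))
        return Signature(features=final, endpoint_kind="binary",
                         transform=transform, coef=list(fit.coef),
                         intercept=float(fit.intercept), model_kind="logistic")
    fit = fit_cox_breslow(Xt.to_numpy(), endpoint.time.to_numpy(),
                          endpoint.event.to_numpy(), names=final)
    return Signature(features=final, endpoint_kind="survival",
                     transform=transform, coef=list(fit.coef),
                     intercept=0.0, model_kind="cox")
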