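"""Survival deep-learning machinery at desk scale.

The network's raw scalar output is passed through a tanh activation,
restricting the per-subject log-hazard to (-1, 1) and hence the hazard
multiplier exp(eta) to (exp(-1), exp(1)).  The survival head minimises
the negative Breslow partial log-likelihood per event over each batch;
the binary head maps the tanh output affinely onto (0, 1) before binary
cross-entropy (tanh + BCE is undefined on (-1, 1) without such a map).

The 3-D network is a deliberately tiny numpy implementation (one conv
block, ReLU, global average pooling, linear head) with analytic
backpropagation and Adam — enough to exercise the loss machinery and the
25-model cross-validation ensemble end-to-end on phantom patches.
Full-scale architectures (VGG/ResNet/DenseNet variants) are represented
by the config schema only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .models import CvScheme, EnsemblePrediction, make_cv_splits

__all__ = [
    "cox_ph_loss",
    "binary_head_loss",
    "AugmentationConfig",
    "augment",
    "NetConfig",
    "TinyConv3D",
    "train_tiny_ensemble",
]


def cox_ph_loss(raw: np.ndarray, times: np.ndarray, events: np.ndarray,
                restrict: bool = True):
    """Batch negative Cox partial log-likelihood with restricted hazards.

    eta = tanh(raw) (unless ``restrict`` is False); the loss is
    -(1/D) * sum_{i: event} [eta_i - log sum_{j: T_j >= T_i} exp(eta_j)]
    with D the number of events in the batch and Breslow tie handling.
    Returns ``(loss, gradient w.r.t. raw)``.  A batch without events has
    loss 0 and zero gradient (skipped for optimisation purposes).
    """
    raw = np.asarray(raw, dtype=float).ravel()
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).ravel().astype(bool)
    n = raw.size
    d = int(events.sum())
    if d == 0:
        return 0.0, np.zeros(n)
    eta = np.tanh(raw) if restrict else raw
    order = np.argsort(-times, kind="stable")
    eta_s = eta[order]
    t_s = times[order]
    e_s = events[order]
    w = np.exp(eta_s)
    s0 = np.cumsum(w)
    ev_pos = np.where(e_s)[0]
    m = np.searchsorted(-t_s, -t_s[ev_pos], side="right") - 1
    loss = float(-(eta_s[ev_pos] - np.log(s0[m])).sum() / d)
    # gradient wrt eta (sorted): -1/D [ 1{event} - w_j * sum_{events with risk set containing j} 1/S0 ]
    inv_s0 = np.zeros(n)
    np.add.at(inv_s0, m, 1.0 / s0[m])
    # suffix-to-prefix: voxel j is in the risk set of event i iff j <= m_i
    cum = np.cumsum(inv_s0[::-1])[::-1]
    grad_eta_s = -(e_s.astype(float) - w * cum) / d
    grad_eta = np.empty(n)
    grad_eta[order] = grad_eta_s
    if restrict:
        return loss, grad_eta * (1.0 - np.tanh(raw) ** 2)
    return loss, grad_eta


def binary_head_loss(raw: np.ndarray, labels: np.ndarray, eps: float = 1e-12):
    """Mean BCE of p = (tanh(raw) + 1) / 2; returns (loss, grad wrt raw)."""
    raw = np.asarray(raw, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    p = np.clip((np.tanh(raw) + 1.0) / 2.0, eps, 1.0 - eps)
    loss = float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())
    # d/draw BCE(p(raw)) = 2 (p - y)  since dp/draw = (1 - tanh^2)/2 = 2 p (1-p)
    grad = 2.0 * (p - y) / raw.size
    return loss, grad


@dataclass
class AugmentationConfig:
    """Image-only training augmentation: contrast, brightness, gamma,
    Gaussian noise and Gaussian blur, each applied with a probability and a
    parameter drawn from its range."""

    contrast_range: tuple[float, float] = (0.8, 1.2)
    brightness_range: tuple[float, float] = (-0.1, 0.1)
    gamma_range: tuple[float, float] = (0.8, 1.2)
    noise_sd_range: tuple[float, float] = (0.0, 0.05)
    blur_sigma_range: tuple[float, float] = (0.0, 1.0)
    p_per_op: float = 0.5

    def __post_init__(self) -> None:
        for r in (self.contrast_range, self.brightness_range, self.gamma_range,
                  self.noise_sd_range, self.blur_sigma_range):
            if not np.all(np.isfinite(r)) or r[0] > r[1]:
                raise ValueError(f"invalid augmentation range {r}")
        if not 0.0 <= self.p_per_op <= 1.0:
            raise ValueError("p_per_op must lie in [0, 1]")


def augment(patch: np.ndarray, cfg: AugmentationConfig | None = None,
            seed: int = 0) -> np.ndarray:
    """Seeded, label-free intensity augmentation of a normalized patch."""
    cfg = cfg or AugmentationConfig()
    rng = np.random.default_rng(seed)
    x = np.asarray(patch, dtype=float).copy()
    if rng.uniform() < cfg.p_per_op:                      # contrast
        f = rng.uniform(*cfg.contrast_range)
        mu = x.mean()
        x = mu + f * (x - mu)
    if rng.uniform() < cfg.p_per_op:                      # brightness
        x = x + rng.uniform(*cfg.brightness_range)
    if rng.uniform() < cfg.p_per_op:                      # gamma
        g = rng.uniform(*cfg.gamma_range)
        lo, span = x.min(), np.ptp(x)
        if span > 0:
            x = lo + span * ((x - lo) / span) ** g
    if rng.uniform() < cfg.p_per_op:                      # noise
        sd = rng.uniform(*cfg.noise_sd_range)
        if sd > 0:
            x = x + rng.normal(0.0, sd, size=x.shape)
    if rng.uniform() < cfg.p_per_op:                      # blur
        sg = rng.uniform(*cfg.blur_sigma_range)
        if sg > 0:
            x = ndimage.gaussian_filter(x, sg)
    return x


@dataclass
class NetConfig:
    """Config schema for the 3-D networks.  Only the tiny net is trainable
    here; the named full-scale architectures are schema placeholders."""

    architecture: str = "tiny"      # "tiny" | "vgg3d" | "resnet18-3d" | "densenet121-3d"
    n_filters: int = 4
    kernel: int = 3
    head: str = "binary"            # "binary" | "cox"
    lr: float = 1e-2
    batch_size: int = 16
    max_epochs: int = 60
    patience: int = 10
    seed: int = 0


class TinyConv3D:
    """One 3x3x3 conv block + ReLU + global average pooling + linear head,
    trained with Adam on analytic gradients."""

    def __init__(self, cfg: NetConfig):
        if cfg.architecture != "tiny":
            raise NotImplementedError(
                f"{cfg.architecture!r} is a schema placeholder; only 'tiny' trains")
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        k, c = cfg.kernel, cfg.n_filters
        scale = 1.0 / np.sqrt(k**3)
        self.W = rng.normal(0.0, scale, size=(c, k, k, k))
        self.b = np.zeros(c)
        self.v = rng.normal(0.0, 1.0 / np.sqrt(c), size=c)
        self.c0 = 0.0
        self._adam = {n: [np.zeros_like(p), np.zeros_like(p)]
                      for n, p in self._params().items()}
        self._adam_t = 0

    def _params(self):
        return {"W": self.W, "b": self.b, "v": self.v,
                "c0": np.atleast_1d(self.c0)}

    def _forward(self, x: np.ndarray):
        z = np.stack([signal.correlate(x, self.W[c], mode="valid")
                      for c in range(self.cfg.n_filters)])
        z += self.b[:, None, None, None]
        a = np.maximum(z, 0.0)
        g = a.reshape(self.cfg.n_filters, -1).mean(axis=1)
        raw = float(self.v @ g + self.c0)
        return raw, (x, z, a, g)

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        return np.array([self._forward(x)[0] for x in X])

    def _backward(self, cache, draw: float):
        x, z, a, g = cache
        dv = draw * g
        dc0 = draw
        nvox = a[0].size
        dg = draw * self.v
        da = (dg / nvox)[:, None, None, None] * np.ones_like(a)
        dz = da * (z > 0)
        dW = np.stack([signal.correlate(x, dz[c], mode="valid")
                       for c in range(self.cfg.n_filters)])
        db = dz.reshape(self.cfg.n_filters, -1).sum(axis=1)
        return {"W": dW, "b": db, "v": dv, "c0": np.atleast_1d(dc0)}

    def _adam_step(self, grads, lr):
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for name, p in self._params().items():
            m, v2 = self._adam[name]
            grad = grads[name]
            m[:] = b1 * m + (1 - b1) * grad
            v2[:] = b2 * v2 + (1 - b2) * grad**2
            mhat = m / (1 - b1**self._adam_t)
            vhat = v2 / (1 - b2**self._adam_t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
        self.c0 = float(np.atleast_1d(self.c0)[0])

    def _batch_loss_and_grads(self, X, target):
        raws, caches = [], []
        for x in X:
            r, cache = self._forward(x)
            raws.append(r)
            caches.append(cache)
        raws = np.asarray(raws)
        if self.cfg.head == "binary":
            loss, draw = binary_head_loss(raws, target["y"])
        else:
            loss, draw = cox_ph_loss(raws, target["time"], target["event"])
        total = None
        for cache, d in zip(caches, draw):
            g = self._backward(cache, float(d))
            total = g if total is None else {k: total[k] + g[k] for k in g}
        if total is None:
            total = {n: np.zeros_like(p) for n, p in self._params().items()}
        return loss, total

    def _eval_loss(self, X, target):
        raws = self.predict_raw(X)
        if self.cfg.head == "binary":
            return binary_head_loss(raws, target["y"])[0]
        return cox_ph_loss(raws, target["time"], target["event"])[0]

    def fit(self, X_train, target_train, X_val=None, target_val=None,
            augment_cfg: AugmentationConfig | None = None):
        """Mini-batch Adam with early stopping on the validation loss."""
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed + 1)
        n = len(X_train)
        best_val, best_state, wait = np.inf, None, 0
        history = []
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                if cfg.head == "cox" and len(idx) < 2:
                    continue
                Xb = [X_train[i] for i in idx]
                if augment_cfg is not None:
                    Xb = [augment(x, augment_cfg,
                                  seed=int(rng.integers(2**31)))
                          for x in Xb]
                tb = ({"y": np.asarray(target_train["y"])[idx]}
                      if cfg.head == "binary" else
                      {"time": np.asarray(target_train["time"])[idx],
                       "event": np.asarray(target_train["event"])[idx]})
                loss, grads = self._batch_loss_and_grads(Xb, tb)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"divergent loss ({loss}) at epoch {epoch}")
                self._adam_step(grads, cfg.lr)
            if X_val is not None and len(X_val):
                val = self._eval_loss(X_val, target_val)
                history.append(val)
                if val < best_val - 1e-9:
                    best_val, wait = val, 0
                    best_state = {n_: p.copy() for n_, p
                                  in self._params().items()}
                else:
                    wait += 1
                    if wait >= cfg.patience:
                        break
        if best_state is not None:
            self.W[:] = best_state["W"]
            self.b[:] = best_state["b"]
            self.v[:] = best_state["v"]
            self.c0 = float(best_state["c0"][0])
        return history

    def predict(self, X) -> np.ndarray:
        """Restricted output: probability for the binary head, restricted
        log-hazard eta = tanh(raw) in (-1, 1) for the survival head."""
        raw = self.predict_raw(X)
        if self.cfg.head == "binary":
            return (np.tanh(raw) + 1.0) / 2.0
        return np.tanh(raw)


def train_tiny_ensemble(patches: np.ndarray, outcomes, scheme: CvScheme,
                        net_cfg: NetConfig,
                        test_patches: np.ndarray | None = None,
                        augment_cfg: AugmentationConfig | None = None) -> dict:
    """Train the repeats x folds tiny-net ensemble.

    ``outcomes`` is a DataFrame indexed by subject id with either a
    ``label`` column (binary head) or ``time``/``event`` columns (cox
    head).  Returns the fitted models and the :class:`EnsemblePrediction`
    bookkeeping (train ensemble over the 20 in-training models per
    subject, validation ensemble over the 5 held-out models, test
    ensemble over all 25).
    """
    ids = outcomes.index
    pos = {sid: i for i, sid in enumerate(ids)}
    strata = (outcomes["label"] if net_cfg.head == "binary"
              else outcomes["event"]).astype(int)
    splits = make_cv_splits(strata, scheme)
    n_models = len(splits)
    sum_train = np.zeros(len(ids)); n_train = np.zeros(len(ids), dtype=int)
    sum_valid = np.zeros(len(ids)); n_valid = np.zeros(len(ids), dtype=int)
    sum_test = np.zeros(len(test_patches)) if test_patches is not None else None
    models = []
    for k, split in enumerate(splits):
        tr = [pos[s] for s in split.train_ids]
        va = [pos[s] for s in split.valid_ids]
        if net_cfg.head == "binary":
            t_tr = {"y": outcomes["label"].to_numpy()[tr]}
            t_va = {"y": outcomes["label"].to_numpy()[va]}
        else:
            t_tr = {"time": outcomes["time"].to_numpy()[tr],
                    "event": outcomes["event"].to_numpy()[tr]}
            t_va = {"time": outcomes["time"].to_numpy()[va],
                    "event": outcomes["event"].to_numpy()[va]}
        cfg_k = NetConfig(**{**net_cfg.__dict__, "seed": net_cfg.seed + k})
        net = TinyConv3D(cfg_k)
        net.fit([patches[i] for i in tr], t_tr,
                [patches[i] for i in va], t_va, augment_cfg=augment_cfg)
        models.append(net)
        p_tr = net.predict([patches[i] for i in tr])
        p_va = net.predict([patches[i] for i in va])
        sum_train[tr] += p_tr; n_train[tr] += 1
        sum_valid[va] += p_va; n_valid[va] += 1
        if sum_test is not None:
            sum_test += net.predict(test_patches)
    import pandas as pd
    table = pd.DataFrame({
        "train_ensemble": sum_train / np.maximum(n_train, 1),
        "valid_ensemble": sum_valid / np.maximum(n_valid, 1),
        "n_train_models": n_train,
        "n_valid_models": n_valid,
    }, index=ids)
    test_table = None
    if sum_test is not None:
        test_table = pd.DataFrame({"test_ensemble": sum_test / n_models})
    ens = EnsemblePrediction(table=table, test_table=test_table)
    ens.check_invariants(n_models)
    return {"models": models, "ensemble": ens, "splits": splits}
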