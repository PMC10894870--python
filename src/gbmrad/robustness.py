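"""Perturbation-based feature robustness screening.

Each original image/mask pair is re-acquired under a grid of simulated
perturbations: CTV volume changes of {0%, -15%, +15%}, sub-voxel
translations of {0.0, 0.25, 0.75} mm applied independently along each
spatial axis (3 x 3^3 = 81 settings), with Gaussian noise (mean 0, SD
equal to that of the foreground intensities) added in every combination.
Per-feature agreement across the perturbed copies is quantified by the
one-way random-effects single-measurement intraclass correlation
coefficient; features whose 95% CI lower bound falls below 0.8 are
removed.  Screening is restricted to training subjects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume import RoiMask, Volume

__all__ = [
    "PerturbationSpec",
    "IccResult",
    "build_grid",
    "apply_perturbation",
    "icc_one_way",
    "icc_table",
    "filter_robust",
]


@dataclass
class PerturbationSpec:
    volume_changes: tuple[float, ...] = (0.0, -0.15, 0.15)
    translation_offsets_mm: tuple[float, ...] = (0.0, 0.25, 0.75)
    noise_sd: str | float = "foreground"  # "foreground" SD or explicit value

    def __post_init__(self) -> None:
        if len(self.volume_changes) == 0 or len(self.translation_offsets_mm) == 0:
            raise ValueError("perturbation level sets must be nonempty")


@dataclass
class IccResult:
    feature_name: str
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int
    degenerate: bool = False


def build_grid(spec: PerturbationSpec | None = None) -> list[dict]:
    """Cartesian product of volume changes x per-axis translations.

    Noise is applied in every combination (one realisation per setting),
    so the default grid has |V| * |T|^3 = 3 * 27 = 81 settings.
    """
    spec = spec or PerturbationSpec()
    grid = []
    for vc, tx, ty, tz in itertools.product(spec.volume_changes,
                                            spec.translation_offsets_mm,
                                            spec.translation_offsets_mm,
                                            spec.translation_offsets_mm):
        grid.append({"volume_change": vc, "translation_mm": (tx, ty, tz),
                     "noise_sd": spec.noise_sd})
    return grid


def _adapt_mask_volume(mask: np.ndarray, spacing, fraction: float) -> np.ndarray:
    """Grow/shrink a mask toward (1 + fraction) x volume by thresholding its
    signed Euclidean distance transform (positive inside)."""
    if fraction == 0.0:
        return mask.copy()
    target = int(round(mask.sum() * (1.0 + fraction)))
    inner = ndimage.distance_transform_edt(mask, sampling=spacing)
    outer = ndimage.distance_transform_edt(~mask, sampling=spacing)
    signed = np.where(mask, inner, -outer)
    if target < 1 or target > signed.size:
        raise ValueError("volume change eliminates or overflows the mask")
    # ties (whole equidistant shells) broken by voxel index for determinism
    keep = np.argsort(-signed.ravel(), kind="stable")[:target]
    out = np.zeros(signed.size, dtype=bool)
    out[keep] = True
    out = out.reshape(mask.shape)
    if not out.any():
        raise ValueError("volume shrink eliminated the mask")
    return out


def apply_perturbation(vol: Volume, mask: RoiMask, setting: dict, seed: int,
                       foreground: np.ndarray | None = None
                       ) -> tuple[Volume, RoiMask]:
    """One perturbed acquisition: translate (trilinear), adapt CTV volume,
    then add Gaussian noise with foreground-SD last.  Seeded."""
    rng = np.random.default_rng(seed)
    shift_vox = [-t / s for t, s in zip(setting["translation_mm"], vol.spacing)]
    data = vol.data
    mdata = mask.data
    if any(abs(s) > 0 for s in shift_vox):
        data = ndimage.shift(data, shift_vox, order=1, mode="nearest")
        mdata = ndimage.shift(mdata.astype(float), shift_vox,
                              order=1, mode="nearest") > 0.5
    mdata = _adapt_mask_volume(mdata, vol.spacing, setting["volume_change"])
    sd_spec = setting.get("noise_sd", "foreground")
    if sd_spec == "foreground":
        fg = foreground if foreground is not None else (vol.data > 0)
        sd = float(vol.data[fg].std()) if fg.any() else float(vol.data.std())
    else:
        sd = float(sd_spec)
    if sd > 0:
        data = data + rng.normal(0.0, sd, size=data.shape)
    return vol.copy_with(data), mask.copy_with(mdata)


def icc_one_way(values: np.ndarray, feature_name: str = "",
                alpha: float = 0.05) -> IccResult:
    """One-way random-effects single-measurement ICC, ICC(1,1).

    ``values`` is a subjects x perturbations matrix.  The estimate is
    (MSB - MSW) / (MSB + (k-1) MSW) with the 95% CI from F-distribution
    bounds on MSB/MSW.  A matrix with (numerically) zero total variance
    is flagged degenerate.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a subjects x perturbations matrix, both >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing values in the ICC matrix")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    ssb = k * ((row_means - grand) ** 2).sum()
    ssw = ((x - row_means[:, None]) ** 2).sum()
    scale = max((x - grand).std() ** 2, 1e-300)
    if (ssb + ssw) / (n * k) <= 1e-12 * max(abs(grand), 1.0) ** 2 + 1e-300:
        return IccResult(feature_name, np.nan, np.nan, np.nan, n, k,
                         degenerate=True)
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if msw == 0:
        return IccResult(feature_name, 1.0, 1.0, 1.0, n, k)
    f_obs = msb / msw
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f_low = f_obs / stats.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
    f_up = f_obs * stats.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
    ci_low = (f_low - 1) / (f_low + k - 1)
    ci_high = (f_up - 1) / (f_up + k - 1)
    return IccResult(feature_name, float(icc), float(ci_low), float(ci_high), n, k)


def icc_table(feature_arrays: dict[str, np.ndarray],
              splits: pd.Series | None = None) -> pd.DataFrame:
    """ICC per feature from {name: subjects x perturbations} arrays.

    If ``splits`` (indexed like the matrix rows) is given, any row tagged
    other than 'train' is rejected: robustness screening must only ever
    see training subjects.
    """
    if splits is not None and (splits != "train").any():
        bad = splits.index[splits != "train"].tolist()
        raise ValueError(f"robustness screening fed non-training subjects: {bad}")
    rows = []
    for name, mat in feature_arrays.items():
        r = icc_one_way(np.asarray(mat), name)
        rows.append({"feature": r.feature_name, "icc": r.icc,
                     "ci_low": r.ci_low, "ci_high": r.ci_high,
                     "n_subjects": r.n_subjects, "n_raters": r.n_raters,
                     "degenerate": r.degenerate})
    return pd.DataFrame(rows).set_index("feature")


def filter_robust(icc_results: pd.DataFrame, threshold: float = 0.8) -> list[str]:
    """Retain features whose ICC 95% CI lower bound is >= threshold.

    Degenerate (zero-variance) features are removed regardless.
    """
    ok = (~icc_results["degenerate"].astype(bool)) & \
         (icc_results["ci_low"] >= threshold)
    return sorted(icc_results.index[ok])
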