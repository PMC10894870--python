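"""Synthetic postoperative PET/MRI phantom cohorts with known ground truth.

The generator emulates the study setting: an amino-acid-PET volume in SUV
units showing a low-uptake resection cavity with an optional focal
high-uptake residual lesion on its rim, a contrast-enhanced T1-weighted
MRI volume with a dark cavity, enhancing rim and the same optional
residual nodule under a smooth multiplicative bias field, and a CTV mask
(cavity plus margin) in which all features are computed.  Binary residual
status is tied to lesion presence, and right-censored recurrence/survival
times follow a proportional-hazards model driven by the planted lesion
burden plus age and MGMT effects with independent exponential censoring.

Geometry uses spheres/ellipsoids with Gaussian-tapered edges so that
histogram and texture features are exercised non-trivially.  Everything is
deterministic given the master seed; per-subject seeds are derived from it
through a counter-based ``SeedSequence`` so individual subjects are
reproducible in isolation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .volume import RoiMask, Volume

__all__ = [
    "PhantomParams",
    "SurvivalGenParams",
    "SubjectRecord",
    "FeatureCohort",
    "generate_subject",
    "generate_cohort",
    "cohort_outcome_table",
    "write_cohort",
    "feature_cohort",
]


@dataclass
class PhantomParams:
    """Geometry and intensity parameters of the two-modality phantom.

    Intensities: PET background is ``background_suv`` (SUV) inside the
    head, the cavity drops to 30% of it, and a planted lesion peaks at a
    value drawn from ``lesion_suv_range``.  MRI uses arbitrary units
    (head 100, cavity 25, rim 170, lesion 190) under a multiplicative
    degree-2 polynomial bias field of relative amplitude
    ``mri_bias_amplitude``.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 40)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    cavity_radius_mm: float = 12.0
    lesion_radius_mm: float = 6.0
    ctv_margin_mm: float = 8.0
    lesion_prob: float = 0.5
    lesion_suv_range: tuple[float, float] = (4.0, 8.0)
    background_suv: float = 1.0
    mri_bias_amplitude: float = 0.2
    noise_sd: tuple[float, float] = (0.05, 2.0)  # (PET in SUV, MRI in a.u.)
    edge_taper_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.cavity_radius_mm <= 0 or self.lesion_radius_mm <= 0:
            raise ValueError("radii must be positive")
        if not 0.0 <= self.lesion_prob <= 1.0:
            raise ValueError("lesion_prob must lie in [0, 1]")
        if self.lesion_suv_range[0] > self.lesion_suv_range[1]:
            raise ValueError("lesion_suv_range must be (min, max)")


@dataclass
class SurvivalGenParams:
    """Proportional-hazards generator: h(x) = h0 * exp(beta . x).

    ``baseline_hazard`` is per month; lesion burden enters as the planted
    peak SUV (0 for lesion-free subjects), age as years centred at 60,
    MGMT methylation as a 0/1 indicator.  Overall survival uses the same
    linear predictor with a hazard multiplier ``os_hazard_factor`` < 1
    (death occurs later than recurrence on average).  Censoring is an
    independent exponential clock.
    """

    baseline_hazard: float = 0.05
    beta_lesion: float = 0.15
    beta_age: float = 0.03
    beta_mgmt: float = -0.7
    censor_rate: float = 0.02
    os_hazard_factor: float = 0.7

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")


@dataclass
class SubjectRecord:
    id: str
    pet: Volume
    mri: Volume
    ctv: RoiMask
    residual_label: int
    ttr_time: float
    ttr_event: int
    os_time: float
    os_event: int
    age: float
    mgmt: str  # "wildtype" | "methylated"
    truth: dict = field(default_factory=dict)


def _tapered_ball(radius_mm, centre_vox, shape, spacing, taper_mm):
    """Smooth indicator of a sphere: 1 inside, Gaussian tail outside."""
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, centre_vox, spacing))
    r = np.sqrt(r2)
    out = np.ones(shape)
    outside = r > radius_mm
    out[outside] = np.exp(-((r[outside] - radius_mm) ** 2) / (2.0 * taper_mm**2))
    return out, r


def _head_ellipsoid(shape, spacing):
    centre = [(n - 1) / 2.0 for n in shape]
    semi = [0.46 * (n - 1) * s for n, s in zip(shape, spacing)]
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    q = sum((((g - c) * s) / a) ** 2
            for g, c, s, a in zip(grids, centre, spacing, semi))
    return q <= 1.0


def _bias_field(shape, spacing, amplitude, rng):
    """Multiplicative degree-2 polynomial field, positive, mean ~= 1."""
    coords = [(np.arange(n) - (n - 1) / 2.0) / max(n - 1, 1) for n in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    terms = [x, y, z, x * y, x * z, y * z, x * x, y * y, z * z]
    coef = rng.normal(size=len(terms))
    p = sum(c * t for c, t in zip(coef, terms))
    p = p / max(np.abs(p).max(), 1e-12)
    return 1.0 + amplitude * p


def generate_subject(params: PhantomParams, surv: SurvivalGenParams,
                     seed: int, subject_id: str | None = None) -> SubjectRecord:
    """Generate one phantom subject; bitwise deterministic given ``seed``."""
    shape, spacing = params.grid_shape, params.spacing_mm
    half_extent = min((n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    needed = params.cavity_radius_mm + params.lesion_radius_mm + params.ctv_margin_mm
    if needed >= half_extent:
        raise ValueError(
            f"grid too small: cavity + lesion + margin needs {needed:.1f} mm "
            f"but half-extent is {half_extent:.1f} mm")

    rng = np.random.default_rng(seed)
    head = _head_ellipsoid(shape, spacing)
    centre = np.array([(n - 1) / 2.0 for n in shape], dtype=float)

    # cavity centre jittered around the grid centre
    cavity_centre = centre + rng.uniform(-2.0, 2.0, size=3) / np.asarray(spacing)
    cavity, r_cav = _tapered_ball(params.cavity_radius_mm, cavity_centre,
                                  shape, spacing, params.edge_taper_mm)

    has_lesion = bool(rng.uniform() < params.lesion_prob)
    lesion_peak = 0.0
    lesion = np.zeros(shape)
    if has_lesion:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        lesion_centre = cavity_centre + direction * params.cavity_radius_mm / np.asarray(spacing)
        lesion_peak = float(rng.uniform(*params.lesion_suv_range))
        lesion, _ = _tapered_ball(params.lesion_radius_mm, lesion_centre,
                                  shape, spacing, params.edge_taper_mm)

    bg = params.background_suv
    pet = bg * head.astype(float)
    pet = pet * (1.0 - 0.7 * cavity)            # cavity uptake drops to 0.3 bg
    if has_lesion:
        pet = np.maximum(pet, lesion_peak * lesion * head)
    pet += rng.normal(0.0, params.noise_sd[0], size=shape)

    rim = np.exp(-((r_cav - params.cavity_radius_mm) ** 2)
                 / (2.0 * params.edge_taper_mm**2))
    mri = 100.0 * head.astype(float)
    mri = mri * (1.0 - 0.75 * cavity)           # cavity signal drops to 25
    mri = np.maximum(mri, 170.0 * rim * head)
    if has_lesion:
        mri = np.maximum(mri, 190.0 * lesion * head)
    bias = _bias_field(shape, spacing, params.mri_bias_amplitude, rng)
    mri = mri * bias
    mri += rng.normal(0.0, params.noise_sd[1], size=shape)

    ctv_ball, _ = _tapered_ball(params.cavity_radius_mm + params.ctv_margin_mm,
                                cavity_centre, shape, spacing, params.edge_taper_mm)
    ctv = (ctv_ball >= 1.0) & head
    if not ctv.any():
        raise ValueError("CTV empty: grid/head too small for cavity + margin")

    age = float(np.clip(rng.normal(60.0, 10.0), 30.0, 85.0))
    mgmt = "methylated" if rng.uniform() < 0.5 else "wildtype"
    lp = (surv.beta_lesion * lesion_peak
          + surv.beta_age * (age - 60.0)
          + surv.beta_mgmt * (1.0 if mgmt == "methylated" else 0.0))

    def _draw(hazard):
        t_event = rng.exponential(1.0 / hazard)
        if surv.censor_rate > 0:
            t_cens = rng.exponential(1.0 / surv.censor_rate)
        else:
            t_cens = np.inf
        if t_event <= t_cens:
            return float(t_event), 1
        return float(t_cens), 0

    h_ttr = surv.baseline_hazard * np.exp(lp)
    ttr_time, ttr_event = _draw(h_ttr)
    os_time, os_event = _draw(surv.os_hazard_factor * h_ttr)

    return SubjectRecord(
        id=subject_id or f"sub-{seed:010d}",
        pet=Volume(pet, spacing),
        mri=Volume(mri, spacing),
        ctv=RoiMask(ctv, spacing),
        residual_label=int(has_lesion),
        ttr_time=ttr_time, ttr_event=ttr_event,
        os_time=os_time, os_event=os_event,
        age=age, mgmt=mgmt,
        truth={
            "lesion_peak_suv": lesion_peak,
            "cavity_centre_vox": cavity_centre.tolist(),
            "bias_field": bias,
            "linear_predictor": float(lp),
        },
    )


def subject_seed(master_seed: int, index: int) -> int:
    """Counter-based per-subject seed derivation (reproducible per subject)."""
    return int(np.random.SeedSequence([int(master_seed), int(index)])
               .generate_state(1)[0] % (2**31))


def generate_cohort(n: int, params: PhantomParams, surv: SurvivalGenParams,
                    seed: int) -> list[SubjectRecord]:
    if n < 2:
        raise ValueError("need n >= 2 subjects (stratified CV is impossible below)")
    return [generate_subject(params, surv, subject_seed(seed, i),
                             subject_id=f"sub-{i:03d}")
            for i in range(n)]


def cohort_outcome_table(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = [{
        "id": r.id,
        "residual_pet": r.residual_label,
        "residual_mri": r.residual_label,
        "ttr_time": r.ttr_time, "ttr_event": r.ttr_event,
        "os_time": r.os_time, "os_event": r.os_event,
        "age": r.age, "mgmt": r.mgmt,
    } for r in records]
    return pd.DataFrame(rows).set_index("id")


def write_cohort(records: list[SubjectRecord], out_dir: str) -> None:
    """Write per-subject NIfTI volumes and the outcome/clinical CSV."""
    os.makedirs(out_dir, exist_ok=True)
    for r in records:
        r.pet.save(os.path.join(out_dir, f"{r.id}_pet.nii.gz"))
        r.mri.save(os.path.join(out_dir, f"{r.id}_mri.nii.gz"))
        r.ctv.save(os.path.join(out_dir, f"{r.id}_ctv.nii.gz"))
    cohort_outcome_table(records).to_csv(os.path.join(out_dir, "outcomes.csv"))


# ---------------------------------------------------------------------------
# Feature-level cohort: the modelling stages operate on feature tables, so a
# direct feature-table generator with one planted informative feature (plus a
# correlated cluster and independent noise features) gives exact control over
# the Bayes-optimal AUC and keeps repeated-run experiments fast.
# ---------------------------------------------------------------------------

@dataclass
class FeatureCohort:
    features: pd.DataFrame       # subjects x features, train + test stacked
    outcomes: pd.DataFrame       # label, ttr/os (time, event), age, mgmt, split
    planted: str                 # name of the label-driving feature
    cluster: list[str]           # planted feature + its correlated companions

    @property
    def train_ids(self) -> pd.Index:
        return self.outcomes.index[self.outcomes["split"] == "train"]

    @property
    def test_ids(self) -> pd.Index:
        return self.outcomes.index[self.outcomes["split"] == "test"]


def feature_cohort(n_train: int = 85, n_test: int = 47, n_noise: int = 15,
                   n_cluster: int = 2, bayes_auc: float = 0.95,
                   surv: SurvivalGenParams | None = None,
                   seed: int = 0) -> FeatureCohort:
    """Cohort of radiomics-like feature vectors with known structure.

    The planted feature separates the two residual-status classes at the
    requested Bayes-optimal AUC (class-conditional unit-variance normals
    shifted by ``sqrt(2) * Phi^-1(AUC)``).  ``n_cluster`` companions are
    noisy copies of it (Pearson rho ~ 0.8); the remaining features are
    independent standard-normal noise.  Survival follows the same
    proportional-hazards generator as the image cohort, driven by the
    planted feature.
    """
    surv = surv or SurvivalGenParams()
    rng = np.random.default_rng(seed)
    n = n_train + n_test
    delta = float(np.sqrt(2.0) * norm.ppf(bayes_auc))

    labels = (rng.uniform(size=n) < 0.5).astype(int)
    planted = rng.normal(0.0, 1.0, size=n) + delta * labels
    cols = {"stat_max": planted}
    cluster = ["stat_max"]
    for j in range(n_cluster):
        name = f"stat_corr_{j:02d}"
        cols[name] = 0.8 * planted + 0.6 * rng.normal(size=n)
        cluster.append(name)
    for j in range(n_noise):
        cols[f"tex_noise_{j:02d}"] = rng.normal(size=n)

    ids = [f"sub-{i:03d}" for i in range(n)]
    feats = pd.DataFrame(cols, index=pd.Index(ids, name="id"))

    age = np.clip(rng.normal(60.0, 10.0, size=n), 30.0, 85.0)
    mgmt = (rng.uniform(size=n) < 0.5).astype(int)
    z = (planted - planted.mean()) / planted.std()
    lp = (surv.beta_lesion * 5.0 * (z + delta / 2) / 2
          + surv.beta_age * (age - 60.0) + surv.beta_mgmt * mgmt)

    def _draw_times(factor):
        h = factor * surv.baseline_hazard * np.exp(lp)
        t_event = rng.exponential(1.0 / h)
        if surv.censor_rate > 0:
            t_cens = rng.exponential(1.0 / surv.censor_rate, size=n)
        else:
            t_cens = np.full(n, np.inf)
        event = (t_event <= t_cens).astype(int)
        return np.minimum(t_event, t_cens), event

    ttr_time, ttr_event = _draw_times(1.0)
    os_time, os_event = _draw_times(surv.os_hazard_factor)

    out = pd.DataFrame({
        "residual_label": labels,
        "ttr_time": ttr_time, "ttr_event": ttr_event,
        "os_time": os_time, "os_event": os_event,
        "age": age, "mgmt": mgmt,
        "split": ["train"] * n_train + ["test"] * n_test,
    }, index=feats.index)
    return FeatureCohort(features=feats, outcomes=out,
                         planted="stat_max", cluster=cluster)
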