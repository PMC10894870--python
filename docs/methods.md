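# Methods

`gbmrad` re-implements, as a tested pipeline over synthetic phantom
cohorts, a radiomics workflow for detecting residual tumour after
glioblastoma surgery and prognosticating time-to-recurrence (TTR) and
overall survival (OS) from postoperative amino-acid PET and
contrast-enhanced T1-weighted MRI. Comparable clinical imaging cohorts
are not publicly available, so every stage here runs on
generated phantoms with known ground truth; passing tests certify the
*machinery* (preprocessing, feature definitions, screening, selection,
models, statistics), not clinical performance on real images.

## Synthetic cohorts

Each phantom subject carries a PET-like volume in SUV units (homogeneous
head background, a low-uptake spherical resection cavity, and — with
probability `lesion_prob` — a focal high-uptake lesion of peak SUV drawn
from `lesion_suv_range` on the cavity rim), an MRI-like volume (dark
cavity, enhancing rim, the same optional nodule) under a multiplicative
degree-2 polynomial bias field, and a CTV mask (cavity + margin). All
shapes are spheres/ellipsoids with Gaussian-tapered edges so histogram
and texture features are non-trivial. Defaults: 2 mm isotropic voxels on
a 48×48×40 grid, cavity radius 12 mm, lesion radius 6 mm, CTV margin
8 mm, lesion probability 0.5, lesion SUV in [4, 8] against background
SUV 1 (so the SUV truncation range [0, 10] is only exercised when
configured hotter), bias amplitude 0.2, additive noise SD 0.05 SUV /
2 a.u.

Outcomes follow a proportional-hazards model
`h = h0 · exp(β_lesion·SUVpeak + β_age·(age−60) + β_mgmt·MGMT)` with
`h0 = 0.05` per month (median ≈ 14 months at baseline), `β_lesion =
0.15` per SUV, `β_age = 0.03` per year, `β_mgmt = −0.7` for methylated
status, independent exponential censoring at rate 0.02, and OS drawn at
0.7× the TTR hazard. Residual-status labels equal lesion presence.
Per-subject seeds derive from the master seed through a counter-based
`SeedSequence`, so cohorts and individual subjects are exactly
reproducible.

A feature-level generator (`feature_cohort`) produces radiomics-like
feature tables directly: one planted feature separating the classes at a
chosen Bayes-optimal AUC (class-conditional unit normals shifted by
√2·Φ⁻¹(AUC); default 0.95), two companions at Pearson ρ ≈ 0.8, and
independent noise features, with survival driven by the planted feature.
The selection/modelling experiments use this generator at the default
cohort sizes (85 training / 47 test) because they probe the consensus
rule, not image processing; the image route is exercised end-to-end
separately at smaller n.

What the phantoms deliberately lack: anatomy, attenuation/scatter
physics, registration error, scanner-specific noise texture, and any
correlation structure between hundreds of real radiomics features.
Performance numbers on phantoms are therefore upper bounds produced by
construction, not estimates of clinical performance.

## Preprocessing

PET: SUV clamp to [0, 10] then division by 10 (idempotent under
re-application); trilinear resampling to 2 mm isotropic. MRI: bias
correction → Canny-based soft-tissue masking → z-scoring (population SD)
inside the mask → 1 mm resampling. Bias correction fits a degree-2
polynomial to the log-intensity inside the mask by least squares and
divides out the exponentiated, geometric-mean-normalised field; it is a
deliberately simple smooth-field estimator matched to the phantom's
low-order fields, and can be bypassed. The Canny step runs per axial
slice (σ = 1 voxel, hysteresis 10%/20% of the slice maximum), closes and
hole-fills each slice, and keeps the largest 3-D component; an edge-free
volume falls back to the full grid. LoG filtering (σ in mm, converted by
voxel spacing; 2 mm for PET, 1 mm for MRI) requires isotropic input and
filters the mean-removed image, which is analytically identical but
avoids DC leakage from kernel truncation. Patches (default 60×60×44)
are centred on the CTV centre of mass, rounded toward the lower index,
and zero-padded at boundaries.

## Feature extraction

Features follow the IBSI definitions with fixed-bin-number
discretisation (`level = min(floor(n(v−min)/(max−min))+1, n)`; default
16 and 32 bins), population moments, excess kurtosis, and 3-D
merged-direction aggregation over the 13 unique offsets for GLCM and
GLRLM. Zones (GLSZM/GLDZM) are 26-connected; GLDZM zone distance is the
city-block distance to the ROI border with border voxels (including the
image edge) at distance 1. IVH `I_x` is the minimum intensity of the x%
most intense voxels; `V_x` the volume fraction at or above
`min + x·range`. The intensity peak averages over a sphere of 1 cm³
(clipped to the grid) around every ROI voxel. Names use the MIRP-style
dialect (`stat_max`, `ih_rmad_fbn_n32`, `dzm_ldhge_3d_fbn_n32`,
`ivh_diff_i25_i75`, `loc_peak_glob`, `log_` prefix for LoG-image
first-order features). Degenerate values (constant ROI) are flagged and
excluded downstream rather than silently zeroed. The inventory covers
every signature feature plus a complete set per family (~300 features
per image); it does not reproduce any particular historical count, which
depended on study-specific configuration.

Every matrix-based feature is verified against an independent
enumeration implementation (explicit loops, BFS flood fill, exhaustive
scans) on random ≤ 5×5×5 grids to 1e−9.

## Robustness screening

Each training image is re-acquired under the full perturbation grid: CTV
volume changes {0, −15%, +15%} × translations {0.0, 0.25, 0.75} mm per
axis = 3·3³ = 81 settings, with one Gaussian-noise realisation (SD equal
to the foreground intensity SD) in every combination. Translation is a
sub-voxel trilinear shift; volume adaptation thresholds the signed
Euclidean distance transform and hits the target voxel count exactly
(ties within an equidistant shell broken by voxel index). Per-feature
agreement uses the one-way random-effects single-measurement ICC
(perturbations are not meaningful "raters" with systematic identity)
with the F-bound 95% CI; features whose CI lower bound falls below 0.8
are removed, and the API rejects non-training subjects outright. The
81-image grid count forces one noise realisation per setting — noise does
not multiply the 81.

## Signature selection

Robust features are clustered by average linkage on 1 − |Spearman ρ|,
cut at ρ ≥ 0.8; each cluster is represented by the member with the
highest mutual information with the endpoint. MI uses ten
equal-frequency bins; for survival endpoints the MI partner is the event
indicator (the estimator is otherwise unspecified — a stated assumption
of this implementation). Within each of 5×5 stratified CV folds:
Yeo-Johnson (maximum-likelihood λ) then z-transform, both fitted on the
fold-training part only; four selectors each nominate five features —
MIM (top MI), MRMR (greedy MI relevance minus mean redundancy), elastic
net (mixing 0.5, penalty by internal 3-fold CV; logistic via saga,
survival via Coxnet), and univariate regression (logistic/Cox Wald p,
with perfect separation treated as maximally significant). Consensus:
per selector, features rank by occurrence across the 25 folds; features
in the top five of ≥ 3 of 4 selectors are eligible; the five most
frequent eligible features are decorrelated at Spearman ρ > 0.5, keeping
the feature more associated with the endpoint; the final logistic or Cox
model refits on the full training data. Ties everywhere break
lexicographically. The final refit keeps the consensus feature set fixed
and re-estimates coefficients only.

## Models and ensembles

Cox models are fitted in-house by Newton–Raphson on the Breslow partial
likelihood (step-halving, ridge fallback for monotone likelihoods, Wald
statistics from the inverse Hessian); with continuous synthetic times
this coincides with the Efron fits of reference libraries, which serve
as cross-checks. Logistic fits are unpenalised maximum likelihood with a
scale-aware separation check (log-odds per SD > 8) that flags and
refits with an L2 ridge. The CV engine guarantees the ensemble
bookkeeping: per subject, 20 in-training models, 5 held-out models, and
25-model test ensembles; degenerate folds trigger a reseeded refold.
Clinical integration screens covariates by univariable Cox at α = 0.05,
caps predictor correlations at |ρ| < 0.5 with clinical covariates taking
priority over the image predictor, and falls back (logged) to image-only
or clinical-only models when a side is empty.

The learner menu is restricted to logistic and Cox; random-forest /
boosting variants are extension points, not implemented paths.

## Survival loss and the tiny network

The network's scalar output passes through tanh, restricting the
log-hazard to (−1, 1) and the hazard multiplier to (exp(−1), exp(1)).
The batch loss is the negative Breslow partial log-likelihood per event;
batches without events contribute zero loss and gradient. The binary
head maps the tanh output affinely onto (0, 1) before BCE (tanh + BCE is
undefined on (−1, 1) without such a map; the gradient is then simply
2(p − y)). Augmentation (contrast, brightness, gamma, Gaussian noise,
Gaussian blur) is seeded, image-only, and shape-preserving.

The trainable network is one 3×3×3 conv block + ReLU + global average
pooling + linear head, implemented in numpy with analytic
backpropagation and Adam, trained with early stopping on the
internal-validation loss. It is the desk-scale testbed for the loss and
ensemble machinery; the named large architectures exist only as config
schema and refuse to instantiate.

## Evaluation statistics

AUC is the Mann–Whitney statistic with half tie credit (CI: stratified
bootstrap percentile, default 2000 draws, seeded); Harrell's C uses half
credit for score ties and subject-bootstrap CIs. Cutoffs are derived on
training data only (the objects carry a flag that transfer asserts):
Youden over observed-score midpoints (ties → lower cutoff) for binary
endpoints, and maximally selected rank statistics — the argmax of the
absolute standardized log-rank statistic over candidate midpoints
between the 10th and 90th score percentiles — for survival. Risk groups
are compared by Kaplan–Meier curves and the log-rank test.

Calibration: Hosmer–Lemeshow with `H = Σ(O−E)²/(E(1−E/n_g))`, df = g−2,
degenerate bins merged; Greenwood–Nam–d'Agostino at a horizon t*
(default: median follow-up) comparing group-level KM survival with mean
predicted survival, variance by Greenwood, df = groups−1, groups with
fewer than five events merged. Both df conventions presume
*model-fitted* predictions; with truth-supplied external probabilities
the statistics behave as χ² with g (not g−k) degrees of freedom, so the
type-I-error simulations fit the model per replicate (logistic for HL;
Breslow Cox plus baseline cumulative hazard for GND) — exactly the
route by which the pipeline produces predictions.

A caveat on maximally selected cutpoints: even under perfect survival
separation the argmax cutpoint is noisy at the single-subject level (a
wrong-by-one split can carry a larger standardized statistic), so
recovery of a planted dichotomy is asserted as closeness of the induced
partition (≤ 5% misclassified), not as exact containment in the
between-group score gap.

## Problem sizes

The test suite and the acceptance script scale the experiments to a
single CPU: phantom grids of 24³–32³ voxels, image cohorts of 40–64
subjects, feature-level cohorts at the default 85/47 split, 25–50
repeated selection runs, 150–500 replicates for the type-I simulations,
and 16×16×12 patches with 2-filter networks for the ensemble. These
sizes are the package's own defaults for its synthetic studies; all are
parameters.

## Known limitations

* The bias-field estimator is a low-order polynomial fit, not a full
  histogram-sharpening method; it is adequate for the generator's
  fields only.
* Translation perturbations are interpreted literally in millimetres
  (0.0/0.25/0.75 mm), which is sub-voxel at 1–2 mm spacing; the offsets
  are configurable if voxel-fraction semantics are preferred.
* The survival-endpoint MI estimator ignores censoring times.
* The feature inventory is complete per family but not tied to any
  particular historical feature count.
* Phantom results certify implementation correctness, not clinical
  discrimination; no claim in this repository transfers to patient data
  without revalidation.
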