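# gbmrad

Radiomics machinery for residual-tumour detection and outcome prognosis
in newly diagnosed glioblastoma from **postoperative amino-acid PET and
contrast-enhanced T1-weighted MRI** — reimplemented as a tested Python
pipeline and exercised end-to-end on synthetic 3-D phantom cohorts with
known ground truth.

After surgery, residual tumour burden is a prognostic imaging biomarker,
but its assessment is manual and rater-dependent. The quantitative
alternative extracts IBSI-style radiomics features from the clinical
target volume (CTV), screens them for stability under image
perturbations, selects a compact signature by consensus over repeated
cross-validation, and models three endpoints: binary residual-tumour
status (logistic regression, AUC), and time-to-recurrence / overall
survival (Cox regression, Harrell's C), optionally combined with age
and MGMT promoter-methylation status. A parallel deep-learning pathway
trains 3-D conv-nets on CTV-centred patches with a survival-specific
batch loss. Comparable clinical cohorts are not publicly available, so
this package ships a phantom generator and validates every stage against
independent oracles instead.

## What is implemented

| stage | module |
|---|---|
| Phantom PET/MRI cohorts + proportional-hazards outcomes | `gbmrad.synthcohort` |
| SUV normalisation, bias correction, masking, resampling, LoG, patches | `gbmrad.imgproc` |
| IBSI feature families (first-order, histogram, IVH, peak, GLCM, GLRLM, GLSZM, GLDZM, NGTDM) | `gbmrad.ibsi` |
| 81-setting perturbation grid + one-way ICC screening (CI lower bound ≥ 0.8) | `gbmrad.robustness` |
| Clustering, Yeo-Johnson/z transforms, MRMR/MIM/EN/UR selectors, consensus rule | `gbmrad.signature` |
| 5×5 stratified CV engine, logistic/Breslow-Cox fits, ensembles, clinical integration | `gbmrad.models`, `gbmrad.coxph` |
| tanh-restricted Cox batch loss, BCE head, augmentation, tiny 3-D conv net | `gbmrad.survloss` |
| AUC/C-index + CIs, Youden & maximally-selected-rank cutoffs, KM/log-rank, HL & GND calibration, univariable Cox screening | `gbmrad.evalstats` |

The survival head restricts the per-subject log-hazard with a tanh
activation, `η = tanh(raw) ∈ (−1, 1)`, and minimises the negative
Breslow partial log-likelihood per batch,

```
L = −(1/D) Σ_{i: event} [ η_i − log Σ_{j: T_j ≥ T_i} exp(η_j) ],
```

so hazard multipliers stay strictly inside `(e⁻¹, e)`. The consensus
rule keeps the five features most frequently in the per-fold top five of
at least 3 of 4 selectors across the 25 folds, decorrelated at Spearman
ρ > 0.5.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
cohorts and write their tables under `results/` (volumes go to
`scratch/`):

```bash
python analysis/01_simulate_cohort.py      # 40 + 20 phantom subjects
python analysis/02_extract_features.py     # ~300 features x 2 modalities
python analysis/03_robustness_screen.py    # 81 perturbations x 10 subjects
python analysis/04_consensus_signature.py  # CV consensus signatures
python analysis/05_deep_ensemble.py        # 25-model tiny-net ensemble
python analysis/06_evaluate.py             # full evaluation stack
```

Output of `04`/`05`/`06` on the default seeds:

```
clustering: 18 features -> 16 representatives
binary signature: ['stat_max', 'tex_noise_10', 'tex_noise_11'] (planted driver: stat_max); test AUC 0.964
TTR signature: ['stat_corr_00', 'tex_noise_01', 'tex_noise_08']; test C-index 0.570

trained 25 models (20 train / 5 held-out per subject)
validation-ensemble AUC 0.934; test-ensemble AUC 1.000

residual status: test AUC 0.964 [0.913, 0.995]; sens/spec at Youden cutoff 0.87/0.88; HL p = 0.36
TTR: test C-index 0.570 [0.440, 0.689]; log-rank p (risk groups) = 0.0000
```

Reading this: the consensus rule recovers the planted diagnostic
feature (`stat_max`, the maximum SUV inside the CTV) and the final
logistic model discriminates residual status on held-out subjects at
AUC 0.96 — close to the planted Bayes optimum of 0.95, as it should be
by construction. The prognostic signal in the generator is deliberately
weaker, so the TTR C-index (0.57 with a wide CI at n = 47) is modest
while the maximally-selected-rank risk groups still separate clearly in
the log-rank test. The tiny-net ensemble shows the 20/5/25 bookkeeping:
every subject is averaged over the 20 models that trained on it, the 5
that held it out, and all 25 on independent test data.

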