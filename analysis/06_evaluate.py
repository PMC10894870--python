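"""Full evaluation and calibration stack on the signature predictions.

Re-runs the consensus-signature chain on the feature-level cohort, then:
AUC with bootstrap CI and a training-derived Youden cutoff for residual
status (with Hosmer-Lemeshow calibration); C-index, a maximally-
selected-rank cutoff with Kaplan-Meier/log-rank risk stratification, the
Greenwood-Nam-d'Agostino calibration test, and the clinical-covariate
integration (univariable Cox screen at alpha 0.05, correlation cap 0.5)
for recurrence.
"""

import json
import os
import sys
import warnings

import numpy as np

warnings.filterwarnings("ignore")
import pandas as pd
from sklearn.metrics import roc_auc_score

from gbmrad.coxph import breslow_baseline_cumhaz
from gbmrad.evalstats import (apply_cutoff, gnd_test, harrell_c,
                              hosmer_lemeshow, km_logrank, maxsel_rank_cutoff,
                              roc_auc_ci, youden_cutoff)
from gbmrad.models import combine_clinical, run_cv_pipeline
from gbmrad.signature import Endpoint, cluster_features, consensus_signature
from gbmrad.synthcohort import feature_cohort

SEED = 7


def main(out_root="."):
    results = os.path.join(out_root, "results")
    os.makedirs(results, exist_ok=True)
    fc = feature_cohort(n_train=85, n_test=47, bayes_auc=0.95, seed=SEED)
    tr, te = fc.train_ids, fc.test_ids
    out = fc.outcomes
    report = {}

    # residual status -------------------------------------------------------
    ep = Endpoint("binary", y=out.loc[tr, "residual_label"])
    reps, _ = cluster_features(fc.features.loc[tr], ep)
    res = run_cv_pipeline(fc.features.loc[tr][reps], ep)
    sig = consensus_signature(res["cv_rankings"], fc.features.loc[tr][reps], ep)
    p_tr = sig.predict(fc.features.loc[tr])
    p_te = sig.predict(fc.features.loc[te])
    m = roc_auc_ci(p_te, out.loc[te, "residual_label"], n_boot=2000, seed=1)
    cut = youden_cutoff(p_tr, out.loc[tr, "residual_label"])
    pred_class = apply_cutoff(p_te, cut)
    y_te = out.loc[te, "residual_label"].to_numpy()
    sens = (pred_class[y_te == 1] == 1).mean()
    spec = (pred_class[y_te == 0] == 0).mean()
    hl = hosmer_lemeshow(p_tr, out.loc[tr, "residual_label"], g=8)
    report["residual"] = {
        "signature": sig.features,
        "test_auc": m.estimate, "auc_ci": [m.ci_low, m.ci_high],
        "youden_cutoff": cut.cutoff,
        "test_sensitivity": float(sens), "test_specificity": float(spec),
        "hl_statistic": hl.statistic, "hl_p": hl.p_value,
    }
    print(f"residual status: test AUC {m.estimate:.3f} "
          f"[{m.ci_low:.3f}, {m.ci_high:.3f}]; "
          f"sens/spec at Youden cutoff {sens:.2f}/{spec:.2f}; "
          f"HL p = {hl.p_value:.2f}")

    # recurrence ------------------------------------------------------------
    eps = Endpoint("survival", time=out.loc[tr, "ttr_time"],
                   event=out.loc[tr, "ttr_event"])
    reps_s, _ = cluster_features(fc.features.loc[tr], eps)
    res_s = run_cv_pipeline(fc.features.loc[tr][reps_s], eps)
    sig_s = consensus_signature(res_s["cv_rankings"],
                                fc.features.loc[tr][reps_s], eps)
    r_tr = sig_s.predict(fc.features.loc[tr])
    r_te = sig_s.predict(fc.features.loc[te])
    c = harrell_c(r_te, out.loc[te, "ttr_time"], out.loc[te, "ttr_event"],
                  n_boot=2000, seed=2)
    cut_s = maxsel_rank_cutoff(r_tr, out.loc[tr, "ttr_time"],
                               out.loc[tr, "ttr_event"])
    groups_te = apply_cutoff(r_te, cut_s)
    km = km_logrank(groups_te, out.loc[te, "ttr_time"],
                    out.loc[te, "ttr_event"])
    # GND at the training median follow-up, with training-fitted survival
    t_star = float(np.median(out.loc[tr, "ttr_time"]))
    cumh = breslow_baseline_cumhaz(r_tr.to_numpy(),
                                   out.loc[tr, "ttr_time"].to_numpy(),
                                   out.loc[tr, "ttr_event"].to_numpy(), t_star)
    pred_surv = np.exp(-cumh * np.exp(r_te.to_numpy() - r_tr.mean()))
    try:
        gnd = gnd_test(pred_surv, out.loc[te, "ttr_time"].to_numpy(),
                       out.loc[te, "ttr_event"].to_numpy(), t_star, g=3,
                       min_events=3)
        gnd_out = {"statistic": gnd.statistic, "p": gnd.p_value}
    except ValueError as exc:
        gnd_out = {"error": str(exc)}
    report["ttr"] = {
        "signature": sig_s.features,
        "test_c_index": c.estimate, "c_ci": [c.ci_low, c.ci_high],
        "maxsel_cutoff": cut_s.cutoff,
        "logrank_chi2": km["chi2"], "logrank_p": km["p_value"],
        "gnd": gnd_out,
    }
    print(f"TTR: test C-index {c.estimate:.3f} [{c.ci_low:.3f}, {c.ci_high:.3f}]; "
          f"log-rank p (risk groups) = {km['p_value']:.4f}")

    # clinical integration --------------------------------------------------
    clin = out.loc[tr, ["age", "mgmt"]].astype(float)
    joint = combine_clinical(clin, r_tr, out.loc[tr, "ttr_time"],
                             out.loc[tr, "ttr_event"])
    clin_te = out.loc[te, ["age", "mgmt"]].astype(float)
    X_te = pd.DataFrame(index=te)
    for name in joint["predictors"]:
        X_te[name] = r_te if name == "image" else clin_te[name]
    risk_joint = X_te.to_numpy() @ joint["fit"].coef
    c_joint = harrell_c(risk_joint, out.loc[te, "ttr_time"],
                        out.loc[te, "ttr_event"])
    report["ttr_clinical"] = {
        "screened": joint["screened"], "predictors": joint["predictors"],
        "screen_pvalues": joint["screen_pvalues"],
        "test_c_index_joint": c_joint.estimate,
    }
    print(f"clinical screen admitted {joint['screened']}; joint model "
          f"{joint['predictors']}; joint test C-index {c_joint.estimate:.3f}")

    with open(os.path.join(results, "evaluation.json"), "w") as f:
        json.dump(report, f, indent=2, default=float)
    print(f"-> {results}/evaluation.json")
    return report


if __name__ == "__main__":
    main(*(sys.argv[1:2] or ["."]))
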