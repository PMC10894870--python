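"""Consensus radiomics signatures under repeated stratified CV.

Runs the full conventional-modelling chain on a feature-level synthetic
cohort at the default sample sizes (85 training / 47 test subjects, one
planted diagnostic/prognostic feature): clustering of correlated
features, 5x5 stratified CV with per-fold Yeo-Johnson + z transforms and
four selectors (MRMR, MIM, elastic net, univariate regression), the
occurrence-based consensus rule, and final logistic (residual status) and
Cox (recurrence) models refitted on all training data.
"""

import json
import os
import sys
import warnings

import numpy as np

warnings.filterwarnings("ignore")
import pandas as pd
from sklearn.metrics import roc_auc_score

from gbmrad.evalstats import harrell_c
from gbmrad.models import run_cv_pipeline
from gbmrad.signature import (Endpoint, cluster_features, consensus_features,
                              consensus_signature, occurrence_table)
from gbmrad.synthcohort import feature_cohort

SEED = 7


def main(out_root="."):
    results = os.path.join(out_root, "results")
    os.makedirs(results, exist_ok=True)
    fc = feature_cohort(n_train=85, n_test=47, bayes_auc=0.95, seed=SEED)
    tr, te = fc.train_ids, fc.test_ids

    # --- residual-status (binary) signature ---------------------------------
    ep = Endpoint("binary", y=fc.outcomes.loc[tr, "residual_label"])
    reps, members = cluster_features(fc.features.loc[tr], ep)
    print(f"clustering: {fc.features.shape[1]} features -> "
          f"{len(reps)} representatives")
    res = run_cv_pipeline(fc.features.loc[tr][reps], ep,
                          test_features=fc.features.loc[te][reps])
    occ = occurrence_table(res["cv_rankings"])
    occ.to_csv(os.path.join(results, "occurrence_binary.csv"))
    sig = consensus_signature(res["cv_rankings"], fc.features.loc[tr][reps], ep)
    with open(os.path.join(results, "signature_binary.json"), "w") as f:
        f.write(sig.to_json())
    pred_te = sig.predict(fc.features.loc[te])
    auc = roc_auc_score(fc.outcomes.loc[te, "residual_label"], pred_te)
    print(f"binary signature: {sig.features} "
          f"(planted driver: {fc.planted}); test AUC {auc:.3f}")
    res["ensemble"].table.join(res["ensemble"].test_table, how="outer") \
        .to_csv(os.path.join(results, "ensemble_binary.csv"))

    # --- recurrence (survival) signature ------------------------------------
    eps = Endpoint("survival", time=fc.outcomes.loc[tr, "ttr_time"],
                   event=fc.outcomes.loc[tr, "ttr_event"])
    reps_s, _ = cluster_features(fc.features.loc[tr], eps)
    res_s = run_cv_pipeline(fc.features.loc[tr][reps_s], eps,
                            test_features=fc.features.loc[te][reps_s])
    sig_s = consensus_signature(res_s["cv_rankings"],
                                fc.features.loc[tr][reps_s], eps)
    with open(os.path.join(results, "signature_ttr.json"), "w") as f:
        f.write(sig_s.to_json())
    risk_te = sig_s.predict(fc.features.loc[te])
    c = harrell_c(risk_te, fc.outcomes.loc[te, "ttr_time"],
                  fc.outcomes.loc[te, "ttr_event"])
    print(f"TTR signature: {sig_s.features}; test C-index {c.estimate:.3f}")

    summary = {"binary_signature": sig.features, "binary_test_auc": float(auc),
               "ttr_signature": sig_s.features,
               "ttr_test_c_index": float(c.estimate)}
    with open(os.path.join(results, "signature_summary.json"), "w") as f:
        json.dump(summary, f, indent=2)
    return summary


if __name__ == "__main__":
    main(*(sys.argv[1:2] or ["."]))
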