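"""Desk-scale 3-D conv-net ensemble on CTV-centred patches.

Extracts patches around the CTV centre of mass from the phantom PET
volumes, trains the tiny 3-D network within 5x5 stratified CV (25
models) with the tanh-restricted binary head and intensity
augmentation, and writes the train/validation/test ensemble
predictions.  The network is the loss-machinery testbed, not a
full-scale clinical architecture.
"""

import importlib
import os
import sys

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from gbmrad.imgproc import PreprocessConfig, extract_patch
from gbmrad.models import CvScheme
from gbmrad.survloss import AugmentationConfig, NetConfig, train_tiny_ensemble

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
sim = importlib.import_module("01_simulate_cohort")

PATCH_SHAPE = (16, 16, 12)  # desk-scale stand-in for the 60x60x44 patch


def patches_for(records):
    return np.stack([extract_patch(r.pet, r.ctv, PATCH_SHAPE).data
                     for r in records])


def main(out_root="."):
    results = os.path.join(out_root, "results")
    os.makedirs(results, exist_ok=True)
    train, test, _ = sim.main(out_root)
    X_tr = patches_for(train)
    X_te = patches_for(test)
    outcomes = pd.DataFrame({"label": [r.residual_label for r in train]},
                            index=[r.id for r in train])
    cfg = NetConfig(head="binary", n_filters=2, max_epochs=20, patience=5,
                    lr=0.02, seed=0)
    out = train_tiny_ensemble(X_tr, outcomes, CvScheme(master_seed=3), cfg,
                              test_patches=X_te,
                              augment_cfg=AugmentationConfig())
    tab = out["ensemble"].table
    tab.to_csv(os.path.join(results, "dl_ensemble_train.csv"))
    test_tab = out["ensemble"].test_table
    test_tab.index = [r.id for r in test]
    test_tab.to_csv(os.path.join(results, "dl_ensemble_test.csv"))

    y_tr = outcomes["label"]
    y_te = [r.residual_label for r in test]
    auc_val = roc_auc_score(y_tr, tab["valid_ensemble"])
    auc_te = roc_auc_score(y_te, test_tab["test_ensemble"])
    print(f"trained {len(out['models'])} models "
          f"({tab['n_train_models'].iloc[0]} train / "
          f"{tab['n_valid_models'].iloc[0]} held-out per subject)")
    print(f"validation-ensemble AUC {auc_val:.3f}; "
          f"test-ensemble AUC {auc_te:.3f}")
    return out


if __name__ == "__main__":
    main(*(sys.argv[1:2] or ["."]))
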