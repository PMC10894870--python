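"""Preprocess the phantom cohort and extract the radiomics feature table.

PET: SUV truncation to [0, 10] and scaling to [0, 1], isotropic
resampling, LoG (sigma 2 mm) for the filtered first-order features.
MRI: bias correction, soft-tissue masking, z-scoring, resampling, LoG
(sigma 1 mm).  Features are extracted inside the CTV and written as a
wide (subjects x features) and a long (subject, feature, value) CSV.
"""

import importlib
import os
import sys

import pandas as pd

from gbmrad.ibsi import FeatureConfig, extract_all
from gbmrad.imgproc import (PreprocessConfig, bias_correct, log_filter,
                            pet_normalize, resample_mask_nearest,
                            resample_trilinear, soft_tissue_mask,
                            zscore_in_mask)

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
sim = importlib.import_module("01_simulate_cohort")


def preprocess_pet(record, cfg):
    pet = pet_normalize(record.pet, cfg)
    pet = resample_trilinear(pet, cfg.pet_target_spacing_mm)
    ctv = resample_mask_nearest(record.ctv, cfg.pet_target_spacing_mm)
    return pet, ctv


def preprocess_mri(record, cfg):
    mask = soft_tissue_mask(record.mri)
    mri, _ = bias_correct(record.mri, mask)
    mri = zscore_in_mask(mri, mask)
    mri = resample_trilinear(mri, cfg.mri_target_spacing_mm)
    ctv = resample_mask_nearest(record.ctv, cfg.mri_target_spacing_mm)
    return mri, ctv


def extract_cohort(records, cfg=None, fcfg=None):
    cfg = cfg or PreprocessConfig()
    fcfg = fcfg or FeatureConfig()
    rows = {}
    for rec in records:
        pet, pet_ctv = preprocess_pet(rec, cfg)
        feats, _ = extract_all(pet, pet_ctv, fcfg, apply_log=True,
                               log_sigma_mm=cfg.log_sigma_pet_mm)
        rows[rec.id] = feats.add_prefix("pet_")
        mri, mri_ctv = preprocess_mri(rec, cfg)
        mfeats, _ = extract_all(mri, mri_ctv, fcfg, apply_log=True,
                                log_sigma_mm=cfg.log_sigma_mri_mm)
        rows[rec.id] = pd.concat([rows[rec.id], mfeats.add_prefix("mri_")])
    return pd.DataFrame(rows).T.rename_axis("id")


def main(out_root="."):
    results = os.path.join(out_root, "results")
    os.makedirs(results, exist_ok=True)
    train, test, _ = sim.main(out_root)
    table = extract_cohort(train + test)
    table.to_csv(os.path.join(results, "features_wide.csv"))
    long = table.reset_index().melt(id_vars="id", var_name="feature_name",
                                    value_name="value")
    long.to_csv(os.path.join(results, "features_long.csv"), index=False)
    n_deg = int(table.isna().any(axis=0).sum())
    print(f"extracted {table.shape[1]} features for {table.shape[0]} subjects "
          f"({n_deg} with degenerate values in some subject)")
    print(f"-> {results}/features_wide.csv")
    return table


if __name__ == "__main__":
    main(*(sys.argv[1:2] or ["."]))
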