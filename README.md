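# fetrad

Dynamic [¹⁸F]FET-PET radiomics for short-term-survival stratification in
IDH-wildtype glioblastoma: parametric image generation, IBSI-style feature
extraction, and combined clinical–radiomic logistic models — as a reusable,
tested Python pipeline exercised end to end on synthetic dynamic-PET
phantoms with known ground truth.

## Who this is for

Researchers working with dynamic amino-acid brain PET who want a
transparent, scriptable implementation of the common analysis chain:

1. **Parametric imaging.** From a 4D dynamic acquisition (0–40 min p.i.),
   compute the **TBR** map (20–40 min summation image divided by the mean
   activity of a crescent-shaped healthy-hemisphere background VOI) and the
   **TTP** map, which classifies each voxel's time–activity curve (TAC) by
   the frame of peak uptake into six ordinal groups
   (<5, 5–10, 10–15, 15–20, 20–30, 30–40 min). Frames centred before
   2.7 min are excluded (early blood flush), and a voxel whose late TAC
   (15–40 min) still rises is assigned to group 6. Tumor VOIs come from
   thresholding the TBR map at 1.6.
2. **Radiomics.** 107 features (18 first-order, 14 shape, 24 GLCM, 16 GLRLM,
   16 GLSZM, 14 GLDM, 5 NGTDM) after resampling to 2.03 mm isotropic voxels
   and fixed-bin-width discretization (0.13 for TBR images, 5 for TTP maps).
3. **Modelling.** Stratified 70/30 split; training-only standardization;
   Pearson redundancy filter (|r| > 0.99); recursive feature elimination
   under a class-balanced L2 logistic regression with the feature count
   k ∈ 1..15 chosen by mean AUC over 3-repeat 5-fold cross-validation;
   radiomic **signatures** (the fitted model's linear predictor); and seven
   model variants: TBR, TTP, clinical, TBR-TTP, clinical-TBR, clinical-TTP,
   clinical-TBR-TTP.
4. **Evaluation.** AUC (midrank statistic), accuracy, sensitivity,
   specificity, PPV, NPV with 1000-resample percentile-bootstrap 95% CIs;
   integrated discrimination improvement (IDI) between nested models; and
   nested cross-validation (5 outer splits) for stability.

Because patient data of this kind are rarely shareable, the package ships a
first-class **synthetic cohort generator**: gamma-variate voxel kinetics
with analytically known peak times, spherical tumors with intratumoral
kinetic heterogeneity, a crescent background VOI, six clinical covariates
with realistic marginals, and a calibrated logistic label model in which an
aggressive (early-peak) kinetic phenotype raises the risk of short-term
survival. Every stage of the pipeline is validated against this ground
truth and against independent brute-force feature oracles.

## Worked example

```python
import numpy as np
from fetrad.synthetic import generate_cohort
from fetrad.pipeline import cohort_feature_table, run_study

patients = generate_cohort(n=141, seed=8, generate_images=False)
table = cohort_feature_table(patients, kinds=("TBR", "TTP"))
study = run_study(table, seed=8, n_boot=1000)

for variant in ("clinical", "TTP", "clinical-TTP"):
    rep = study.reports[variant]["test"]
    lo, hi = rep.ci_95["auc"]
    print(f"{variant:13s} test AUC {rep.metrics['auc']:.2f} (95% CI {lo:.2f}-{hi:.2f})")
print(f"IDI(clinical -> clinical-TTP) = {study.idi.idi:.4f}, p = {study.idi.p_value:.3f}")
```

Output of this exact snippet (seed 8):

```
clinical      test AUC 0.75 (95% CI 0.59-0.89)
TTP           test AUC 0.77 (95% CI 0.61-0.92)
clinical-TTP  test AUC 0.82 (95% CI 0.65-0.94)
IDI(clinical -> clinical-TTP) = 0.1514, p = 0.056
```

The cohort simulates 141 patients at ~28% short-term-survival prevalence.
`cohort_feature_table` segments each phantom's tumor (TBR ≥ 1.6), builds
its TTP map and extracts 2 × 107 radiomic features; `run_study` splits the
cohort 99/42, selects features and fits all seven model variants on the
training cohort only, then reports held-out metrics. Here the dynamic
(TTP) radiomic signature carries most of the prognostic signal the
generator planted, so the TTP-bearing models outperform the clinical-only
model and the IDI is positive: adding the dynamic-PET signature improves
risk discrimination.

A command-line interface mirrors the stages:

```bash
fetrad simulate --n 20 --seed 1 --out-dir cohort/
fetrad tbr-map --image cohort/patient0000_dynamic.nii \
    --schedule cohort/patient0000_frames.json \
    --background-mask cohort/patient0000_background_mask.nii --out tbr.nii
fetrad ttp-map --image cohort/patient0000_dynamic.nii \
    --schedule cohort/patient0000_frames.json --out ttp.nii
fetrad segment --tbr tbr.nii --out voi.nii
fetrad extract --image ttp.nii --mask voi.nii --bin-width 5 --out features.csv
```

## Layout

- `fetrad.synthetic` — phantom and cohort generator (ground truth).
- `fetrad.parametric` — frame schedules, summation/TBR/TTP images, VOI
  segmentation.
- `fetrad.radiomics` — resampling, discretization and the 107 features.
- `fetrad.modeling` — split, standardization, PCC filter, RFE, logistic
  models, signatures, variants.
- `fetrad.evaluation` — metrics, bootstrap CIs, IDI, nested CV.
- `fetrad.pipeline` — end-to-end study drivers.
- `docs/methods.md` — model assumptions, parameter choices, numerical
  conventions and limitations.
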