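# cscpet

Quantify cancer-stem-cell (CSC) metabolism from a single pretreatment
¹⁸F-FDG PET scan of breast cancer, and use it to predict response to
neoadjuvant chemotherapy (NAC) and disease-free survival (DFS).

Proliferative CSCs are markedly more glycolytic than the differentiated
cancer cells that make up the tumor bulk, so the hottest voxels of a lesion's
SUV histogram act as a proxy for the CSC compartment. `cscpet` implements the
full pipeline for nuclear-medicine and imaging-biomarker researchers:

1. **SUV volumes** — NIfTI I/O and body-weight SUV normalization
   (SUV = activity × weight / dose).
2. **Lesion segmentation** — 26-connected components at a fixed SUV 2.5
   threshold (MTV, TLG) and at 40% of SUVmax (MTV40%, TLG40%); tumors with
   SUVmax < 2.5 are FDG non-avid and excluded.
3. **CSC parameters** — the lesion's voxel SUVs are split into K = 3 clusters
   by k-means (exact 1-D dynamic programming by default, globally
   WCSS-optimal and deterministic; seeded Lloyd as a fidelity mode). The
   most glycolytic cluster defines

   - **MTVcsc** (cm³) = voxel count of the top cluster × voxel volume,
   - **TLGcsc** (SUV·cm³) = summed top-cluster SUVs × voxel volume,
   - **CSC proportion** (%) = 100 · MTVcsc / MTV.

4. **Response prediction** — a patient is predicted to reach pathologic
   complete response (pCR) iff MTVcsc < 1.75 cm³ (the highest pCR-group value
   rounded up to the next 0.05 cm³); confusion tables and accuracies by
   subtype and regimen.
5. **Cohort statistics** — cross-product odds ratios with Woolf CIs, Pearson
   chi-square, exact Fisher enumeration for 2×c tables, and IRLS logistic
   regression (univariable plus the ER + MTVcsc multivariable model).
6. **Survival** — Kaplan–Meier DFS with Greenwood variance and log(−log)
   confidence intervals, compared across MTVcsc cutoff groups by the
   log-rank test.
7. **Synthetic data** — digital phantoms with three metabolic compartments
   (differentiated rim / mixed shell / CSC core) and fully calibrated
   synthetic cohorts, so every stage is testable without patient images.

## Worked example

Simulate a phantom with a 14-voxel CSC core on a 4 mm grid, then run the
lesion pipeline on it:

```bash
cscpet --seed 7 simulate-phantom --out phantom.nii.gz --truth-out truth.json --grid 24
cscpet --seed 7 params --volume phantom.nii.gz --seed-voxel 11,11,11 \
       --label primary --out params.csv
```

`params.csv` contains:

```
patient_id,lesion_label,suv_max,mtv,tlg,mtv40,tlg40,mtv_csc,tlg_csc,csc_proportion
patient,primary,9.15104,7.296,33.7335,3.456,22.307,0.896,8.05198,12.2807
```

The lesion's MTV is 7.296 cm³ (114 voxels × 0.064 cm³) and the recovered
MTVcsc is 0.896 cm³ — exactly the 14 ground-truth CSC voxels, so the K = 3
clustering isolated the hot core perfectly. With MTVcsc < 1.75 cm³ this
lesion would be predicted to achieve pCR.

Cohort-level analysis on a simulated 120-patient study:

```bash
cscpet --seed 3 simulate-cohort --out cohort.csv
cscpet predict  --cohort cohort.csv --out accuracy.csv
cscpet survival --cohort cohort.csv --out-prefix km
```

```
overall accuracy 72% (86/120)
  HER2-positive: 74% (42/57)
  TN: 76% (19/25)
  luminal: 66% (25/38)
low MTVcsc group: 36-month DFS 91% (95% CI 78-97%)
high MTVcsc group: 36-month DFS 73% (95% CI 58-84%)
log-rank chi2 5.91, p 0.015
```

The cutoff predicts response well in HER2-positive/triple-negative disease,
and the low-MTVcsc group enjoys significantly better DFS — the behavior the
generator is calibrated to.

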