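# Methods

## The model

A tumor is treated as a mixture of three metabolic cell populations visible
on FDG-PET through their glucose consumption: differentiated cancer cells
(lowest uptake), a mixed population (intermediate — at 4×4×4 mm resolution
many voxels contain both phenotypes), and proliferative cancer stem cells
(CSCs, highest uptake, the Warburg phenotype at its strongest). Under this
model the SUV histogram of a lesion carries the compartment structure, and a
K = 3 partition of the voxel SUVs assigns each voxel to one population. The
top cluster's volume (MTVcsc), glycolysis (TLGcsc) and share of the total
metabolic volume (CSC proportion) are the quantities of interest: a small
proliferative-CSC burden predicts chemosensitivity (pCR) and fewer relapses.

The approach assumes (a) FDG uptake orders the three populations, (b) the
populations are separated enough in SUV for a 1-D partition to recover them,
and (c) the lesion is resolvable at a fixed SUV 2.5 boundary. Quiescent
CSCs — hypometabolic, prominent in luminal/ER-positive disease — violate
(a), which is why cutoff prediction is expected to work in HER2-positive and
triple-negative subtypes but not luminal ones.

## Pipeline and parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| fixed threshold | 2.5 | SUV | lesion boundary for MTV/TLG and the avidity exclusion (SUVmax < 2.5 excluded); comparisons inclusive (≥) |
| relative fraction | 0.40 | of SUVmax | MTV40%/TLG40% boundary, anchored at the fixed-threshold VOI's hottest voxel |
| K | 3 | clusters | the three-population model |
| clustering method | exact-dp | — | globally WCSS-optimal 1-D dynamic programming; `lloyd` = seeded k-means++ |
| response cutoff | 1.75 | cm³ | strict `<` predicts pCR; derived as the pCR-group max rounded **up** to the next 0.05 cm³ step |
| survival horizon | 36 | months | the DFS timepoint reported per cutoff group |

Segmentation connectivity is 26-neighborhood (standard for blob-like PET
lesions); each lesion is seeded (one voxel per lesion), matching how a
reader encompasses a tumor or node rather than enumerating all components.
Ties for the hottest voxel break to the lowest (z, y, x) index. The
40%-of-SUVmax VOI takes its SUVmax from the fixed-threshold VOI — the
deterministic choice when the two definitions could disagree.

Voxel volume is cm³ = product of mm spacings / 1000, computed once per
volume and carried with every VOI; anisotropic grids are accepted even
though the reference protocol is isotropic 4 mm. TLG is summed SUV × voxel
volume (identically mean SUV × MTV).

### Clustering choices

1-D k-means has an exact polynomial-time optimum: on sorted values every
WCSS-optimal partition is contiguous, so a weighted dynamic program over the
distinct values (O(k·m²), m = distinct SUVs) finds it deterministically.
This is the default because it removes initialization noise from a
biomarker and doubles as a built-in optimality oracle for the Lloyd mode.
Lloyd (k-means++, `n_init=1`, seeded) is retained for fidelity to common
practice; if it yields an empty cluster or coincident centroids it is
re-seeded up to 10 times, then errors. Clusters are always renumbered so
centroids ascend; "most glycolytic" = cluster K−1. Clustering operates on
the raw voxel values by default; a binned mode (default width 0.1 SUV,
cluster bin centers weighted by counts) is provided for sensitivity
analysis. Fewer than K distinct values is a degenerate histogram and an
error. Patient-level MTVcsc is the maximum across the patient's lesions
(primary or nodal), with the contributing lesion logged.

### Statistics

Odds ratios are cross-products with Woolf (log-OR ± 1.96·√Σ1/cell) 95%
intervals; a zero cell requires the Haldane–Anscombe +0.5 correction, which
is applied only on request and flagged. Pearson chi-square is uncorrected
(no Yates). Fisher's exact test enumerates all 2×c tables with the observed
margins (c ≤ 5) and sums multivariate-hypergeometric probabilities ≤ the
observed table's. Logistic regression is IRLS to maximum likelihood
(convergence |Δlog L| < 1e−8, ≤ 100 iterations), Wald intervals and
two-sided p-values, continuous covariates per unit (per 1 cm³ for MTVcsc).
Missing covariates are dropped per analysis (complete-case), so each
univariable row keeps its own denominator. Separation is detected two ways:
diverging coefficients (|β| > 50 during iterations) or convergence onto
perfect prediction (every fitted probability within 1e−6 of its outcome);
either returns the last estimates with `converged=False` and a
`SeparationWarning` rather than an exception — no Firth penalization is
applied. Binary covariate encodings are fixed so ORs point the conventional
direction: T1–2 vs T3–4, stage IIA–IIIA vs IIIB–IIIC, grade 3 vs 1–2,
Ki-67 ≥ 30% vs low, ER-negative vs positive. The multivariable model is
ER status + MTVcsc — documented configuration, not automatic stepwise
selection.

Kaplan–Meier uses the product-limit estimator with Greenwood variance;
confidence intervals use the complementary log-log transform by default
(respects [0, 1]; linear Greenwood available). An event tied with a
censoring at the same time counts the event first. The log-rank statistic is
the usual (O−E)²/V over pooled event times with the hypergeometric variance.
Dates convert to months at 30.4375 days/month.

## The synthetic generators

**Phantoms** place three nested compartments (hot CSC core, mixed shell,
differentiated rim — mimicking the hot-core appearance of real lesions;
random-blob placement is available) on a background of mean 0.8 SUV
(typical breast background, safely below the 2.5 threshold; SD 0.1,
truncated at zero). Defaults: compartment means 3 / 5.5 / 9 SUV, SD 0.2,
counts 60 / 40 / 14 voxels on a 4 mm grid. Ground truth is recomputed from
the **realized** voxel values (voxels at or above 2.5), not the spec
targets, so truth and what segmentation can see always agree. When adjacent
compartment means are within ~6 SD the histogram modes overlap and
cluster-to-compartment correspondence genuinely breaks down; the recovery
report flags such specs as non-separable instead of asserting recovery.

**Cohorts** emulate the reference 120-patient study: 57 HER2-positive,
25 triple-negative, 38 luminal; pCR rates 16/57, 6/25 and 0. MTVcsc is
log-normal per response group, fitted by matching the printed median
(μ = ln median) and mapping the printed min–max range to ±z_n·σ with
z_n = Φ⁻¹(1 − 0.5/n), the expected extreme of n draws (n = 22 pCR, 60
residual): σ ≈ 0.43 (pCR, median 0.9, range 0.3–1.7) and σ ≈ 1.24
(residual, median 2.8, range 0.1–38.0) — log-normal because the residual
group is strongly right-skewed (median 2.8, max 38). Relapse times are
exponential with hazard λ = −ln(S₃ᵧ)/36 per cutoff group (S₃ᵧ = 0.90 below
1.75 cm³, 0.72 above), censored at Uniform(3, 90) months to match the
2.8–89.9-month follow-up range. Remaining covariates (age, histology,
stage, grade, Ki-67, regimen) are drawn to match the study's marginals but
carry no built-in effect on outcome.

What the generators do **not** emulate: scanner point-spread/partial-volume
effects, non-Gaussian reconstruction noise, correlated covariate–outcome
structure beyond subtype and MTVcsc, and irregular lesion shapes. Passing
tests therefore demonstrate the pipeline's correctness and calibration under
the stated three-compartment model — not clinical performance on real
images.

## Problem sizes and numerics

The validation suite uses 24³ phantom grids (114 tumor voxels), 100
replicate phantoms and mixture draws for the rate checks, and n = 10,000
cohorts (same subtype mix) for calibration — sizes at which the checked
quantities are statistically stable while the whole suite runs in seconds.
Exact checks (cluster conservation, KM = empirical survival without
censoring) use float-exact or 1e−12-relative comparisons; cross-library
oracles (statsmodels, lifelines) are compared at 1e−6 to 1e−9.

## Known limitations

* The cutoff rule reproduces the published 1.75 cm³ from an observed pCR
  maximum of 1.7 via the round-up-to-0.05 step; the original derivation of
  that gap is not documented anywhere, so the step is configurable.
* Whether the original analysis clustered raw voxel values or pre-binned
  LIFEx histograms is unknown; both modes exist, raw-voxel is default.
* Separation of contiguous breast and nodal uptake at SUV 2.5 follows the
  seeded-component convention; other readers may split differently.
* Continuous-parameter odds ratios (TLGcsc, SUVmax, …) require patient-level
  data that was never published; they are implemented but can only be
  validated on synthetic cohorts.
* No DICOM SUV chain (decay correction, rescale slopes, lean-body-mass
  variants) — inputs are expected as SUV or activity-concentration NIfTI.
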