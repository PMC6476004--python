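# serumnmr

Serum ¹H-NMR metabolomics analysis for colorectal-cancer screening studies:
a tested, reusable implementation of the standard CPMG-serum workflow —
spectral binning and sum normalization, PCA / PLS-DA / OPLS-DA with
permutation and CV-ANOVA validation, VIP + correlation-loading
identification of differential metabolites, fold-change tables,
Monte-Carlo multivariate ROC biomarker ranking, and metabolite-ratio
diagnostics. A synthetic serum-spectrum generator with known ground truth
drives every stage, so the whole pipeline is testable without access to
patient sera.

## Who this is for

Metabolomics practitioners who run SIMCA/MetaboAnalyst-style analyses of 1D
serum spectra and want a scriptable, reproducible, unit-tested equivalent:
three-group cohorts (healthy controls, a precancerous group, a cancer
group) compared pairwise on binned spectra.

## The methods in brief

- **Preprocessing.** Spectra are referenced to the lactate CH₃ doublet at
  δ1.33, segmented over δ0–9 into 9000 bins of 0.001 ppm (bin value =
  trapezoidal integral / width), the suppressed-water region δ4.6–5.1 is
  masked (500 bins), and each sample is normalized to unit total intensity
  over the 8500 active bins.
- **OPLS-DA.** For each pairwise comparison, orthogonal signal correction
  removes y-uncorrelated X-variation, then a single predictive component
  tp1 carries the class contrast. Q² = 1 − PRESS/SS from stratified 7-fold
  cross-validation; robustness via response permutation testing (R²Y/Q²
  intercepts and an exchangeability-exact empirical p) and CV-ANOVA
  (F-test of cross-validated residuals).
- **Differential metabolites.** A variable is significant when VIP > 1 and
  |r| (Pearson correlation with tp1) exceeds the critical correlation at
  df = min(n₁, n₂) − 1: r_crit = t_c/√(t_c² + df). With cohorts of 38
  controls / 32 polyp / 40 CRC this gives 0.344 and 0.442 (α = 0.05, 0.01)
  for the polyp comparison and 0.316 / 0.408 for the CRC comparison.
  Metabolites are quantified by summing normalized intensity over
  non-overlapping signature windows (±0.01 ppm); fold changes are ratios
  of group means reported ≥ 1 with a direction flag, starred by a
  two-sided Mann-Whitney test.
- **Biomarkers.** Monte-Carlo multivariate ROC: repeated stratified
  2/3 : 1/3 splits, random-forest feature ranking per split, a classifier
  on the top 5 features, held-out probabilities pooled into one ROC/AUC
  plus per-feature selection frequencies. Ratio features
  (acetate/glycerol, lactate/citrate) get single-feature ROC curves with
  Youden-index cutoffs and linear-SVM validation on held-out cohorts.

## Worked example

```python
import numpy as np
from serumnmr import (CohortConfig, load_reference, preprocess_cohort,
                      simulate_cohort, fit_oplsda, quantify_metabolites,
                      differential_table, ratio_feature, roc_curve)
from serumnmr.significance import COMPARISON_GROUPS
from serumnmr.reference import COMPARISONS

ref = load_reference()                                  # 23 serum metabolites
spectra = simulate_cohort(ref, CohortConfig(seed=1))    # 40 CRC / 32 polyp / 38 control
matrix = preprocess_cohort(spectra)                     # 9000 bins, 500 masked, normalized

models = {}
for comp in COMPARISONS:
    sub = matrix.subset(COMPARISON_GROUPS[comp])
    models[comp] = fit_oplsda(sub, sub.groups, n_orth=1)
    m = models[comp]
    print(f"{comp}: R2X={m.r2x:.3f} R2Y={m.r2y:.3f} Q2={m.q2:.3f}")

quant = quantify_metabolites(matrix, ref)
sig = differential_table(quant, models, matrix, ref)
print("significant metabolites (union):", len(sig.significant_union()))
```

prints (exactly, for seed 1):

```
polyp_vs_control: R2X=0.117 R2Y=0.979 Q2=0.892
crc_vs_control: R2X=0.271 R2Y=0.978 Q2=0.917
crc_vs_polyp: R2X=0.226 R2Y=0.973 Q2=0.905
significant metabolites (union): 23
```

so all three pairwise models separate the groups (Q² ≈ 0.9) and all 23
reference metabolites are recovered as significant in at least one
comparison. Selected rows of the polyp-vs-control table (VIP, r, class,
fold change, direction):

```
Lactate     3.26  0.89  very_significant  1.54  up
Acetate     2.12  0.59  very_significant  1.22  up
Glycerol    3.04 -0.82  very_significant  1.29  down
```

— the planted 1.51-fold lactate increase is recovered as 1.54. The
acetate/glycerol ratio then acts as a polyp-specific mark:

```python
ratio = ratio_feature(quant, "Acetate", "Glycerol")
groups = np.asarray(matrix.groups)
for comp in ("polyp_vs_control", "crc_vs_control"):
    case, base = COMPARISON_GROUPS[comp]
    sel = np.isin(groups, (case, base))
    res = roc_curve(ratio[sel], groups[sel])
    print(f"acetate/glycerol {comp}: AUC={res.auc:.3f} cutoff={res.cutoff:.3f}")
```

```
acetate/glycerol polyp_vs_control: AUC=0.951 cutoff=3.651
acetate/glycerol crc_vs_control: AUC=0.791 cutoff=3.348
```

The polyp comparison dominates the CRC one, as expected from the planted
effect directions (acetate up and glycerol down in polyps only).

## Command line

```bash
serumnmr simulate --out cohort/ --seed 1
serumnmr preprocess --manifest cohort/manifest.tsv --out matrix.csv
serumnmr fit --matrix matrix.csv --comparison polyp_vs_control --out model_polyp_vs_control.json
serumnmr run-all --out results/ --seed 1      # the whole pipeline
```

Exit codes: 0 ok, 2 config error, 3 data error, 4 fit error.

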