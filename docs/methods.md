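# Methods

## Scope and model

`serumnmr` implements the standard chemometric workflow for 1D CPMG serum
¹H-NMR cohorts compared pairwise across three groups (control, colorectal
polyp, colorectal cancer). The analysis chain is

1. lactate referencing → 2. binning → 3. water exclusion →
4. total-intensity normalization → 5. OPLS-DA per pairwise comparison →
6. VIP/|r| significance and fold-change tables → 7. ROC-based biomarker
evaluation.

The order of steps 1–4 is recorded in the matrix provenance and enforced
by downstream preconditions (quantification refuses unnormalized
matrices). Water exclusion precedes normalization, so the residual water
signal carries no normalization weight; the alternative order is a
defensible choice, but mixing the two within one study would make samples
incomparable, so the pipeline fixes one.

## Synthetic cohorts

Because patient sera cannot be redistributed, the package ships a
generator whose defaults emulate the cohort the analysis targets: 38
controls, 32 polyp patients, 40 cancer patients.

- **Line shapes.** Metabolite resonances are Lorentzian. Resolved
  multiplets use a 0.002 ppm FWHM; `m`/`bra` envelopes use 0.02 ppm. These
  reproduce realistic CPMG serum line widths while keeping doublets
  resolvable at 0.001-ppm bins. J-splitting is rendered as a fixed
  0.012 ppm line spacing with binomial intensity ratios (1:1, 1:2:1,
  1:3:3:1); splitting constants are not part of the reference table, and a
  single representative spacing suffices for binning-level analysis.
- **Concentrations.** Per sample, each metabolite concentration is drawn
  log-normally (σ = 0.15) around its reference base level times the
  group-effect multiplier, so fold changes act multiplicatively — the
  standard abundance model for metabolite data. Reference base levels are
  plausible relative serum abundances (glucose highest, TCA intermediates
  lowest) on an arbitrary common scale; only ratios matter after
  normalization.
- **Nuisance structure.** A Gaussian residual-water hump (center 4.85 ppm,
  sd 0.08 ppm, integral 20 units) sits inside the excluded window; a
  constant baseline offset (2 units) and additive Gaussian noise
  (sd 0.5) act per point; each sample receives one global ppm jitter
  (sd 0.003 ppm) emulating calibration error, which the lactate
  referencing step must undo. Spectra are evaluated on a grid covering
  [−0.05, 9.05] ppm at 0.00025 ppm so jitter plus re-referencing never
  uncovers the binned 0–9 range.
- **What is not emulated.** Time-domain effects (apodization, phase and
  baseline distortions), peak-position shifts that vary across the
  spectrum (pH-sensitive shifts), macromolecule baseline humps outside the
  water region, and peak-shape deviations from Lorentzian. Consequently,
  passing recovery tests demonstrates the statistical machinery is
  correct, not that the pipeline is robust to all real-spectrum artifacts;
  in particular the global-shift referencing would not fix per-peak
  misalignment, which the generator does not produce.

The reference table also records, per metabolite, the subset of peaks
whose ±0.01 ppm windows overlap no other metabolite's signature
(`quant_peaks`); quantification uses only these. Overlapping signatures
(e.g. the branched-chain amino acids near 0.92–1.05 ppm, glycerol vs
valine at 3.61 ppm) are resolved by assigning each metabolite a window
unique to it. Window sums therefore capture a metabolite-specific,
constant fraction of each metabolite's signal — unbiased for fold changes
(ratios cancel the capture fraction) though not for absolute levels.

## Latent-variable models

- **Scaling.** Mean-centering plus unit variance is the default
  (chemometrics convention for binned NMR); Pareto and centering-only are
  available. Zero-variance variables get unit scale and are flagged where
  relevant rather than producing NaNs.
- **PLS-DA** is NIPALS with X- and y-deflation on a {0, 1}-encoded
  response; for a single response the component weight is the closed form
  w = X'y/‖X'y‖. Predictions agree with scikit-learn's `PLSRegression` to
  machine precision (kept as an independent cross-check in the tests, not
  as the implementation).
- **OPLS-DA** removes `n_orth` orthogonal components (default 1; the
  count is a convention, reported in every output) before fitting one
  predictive component. Orthogonal scores have exactly zero covariance
  with the response by construction; with `n_orth=0` the model reduces
  exactly to one-component PLS-DA. Score orientation is fixed so the
  alphabetically second class has positive mean tp1; PCA signs are fixed
  by making the largest-|loading| element positive.
- **Q²** uses stratified 7-fold cross-validation with a fixed internal
  fold seed, PRESS against the mean-centered encoded response.
- **RPT** refits under label permutations (default 200) with the original
  component count and reports R²Y/Q² intercepts of the regression against
  |corr(y_perm, y)| (the observed model included as the corr = 1 point)
  plus the empirical p-value (1 + #{Q²_perm ≥ Q²_obs})/(n_perm + 1), which
  is exactly uniform under the null by exchangeability (verified at
  0.05 ± binomial error over 200 null runs).
- **CV-ANOVA** computes F = ((SS − PRESS)/df₁)/(PRESS/df₂). Two df
  conventions are defensible for OPLS; this package uses df₁ = number of
  predictive components (only those model the response) and
  df₂ = N − 1 − total fitted components (orthogonal filters still consume
  degrees of freedom), which calibrates near the nominal level
  (≈ 0.025 at α = 0.05 on 40 × 30 null data). Counting orthogonal
  components in df₁ makes the test severely conservative (≈ 0.005).
  Either way the test errs conservative, never anti-conservative: models
  with PRESS ≥ SS report p = 1; a perfect cross-validated fit
  (PRESS = 0) reports p = 0.

### Null behavior of Q²

On effect-free cohorts, cross-validated Q² is centered slightly below
zero. At small cohort sizes (tens of samples) it can come out mildly
positive (up to ≈ +0.1) by chance: the 23 metabolite concentrations form
latent factors spanning many coherent bins, and their sample-level chance
alignment with the labels survives cross-validation. This is a
small-sample property of CV-Q² itself, not an implementation artifact
(white-noise and low-rank nulls behave as classical theory predicts). The
no-spurious-separability test therefore uses 100 samples per group, where
chance alignment is negligible and every null cohort yields Q² ≤ 0; at
study-scale cohorts a mildly positive Q² alone should not be read as
evidence of separation — that is precisely what RPT and CV-ANOVA are for.

## Significance calling

Thresholds on |r| come from the exact closed form
r_crit = t_c/√(t_c² + df), df = min(n₁, n₂) − 1 (validated against
tabulated Pearson critical values, e.g. 0.349 at df = 30, α = 0.05).
A metabolite's VIP and r are those of its maximum-|r| bin inside its
signature windows — one representative pair per metabolite, since
bin-level values within a window are strongly coupled. The univariate
test is Mann-Whitney (robust to the non-normal normalized intensities);
fold changes are ratios of group means, reported ≥ 1 with the direction
flag carrying orientation. Where a signature window borders a strong
neighboring resonance (succinate next to the glutamate envelope), the
max-|r| bin can reflect the neighbor; the fold-change direction, computed
from the window sums, is the more robust direction estimate.

## Biomarker evaluation

ROC curves sweep the observed score values; AUC is trapezoidal (equal to
the concordant-pair fraction with ties at ½); cutoffs maximize the Youden
index; polarity is normalized to AUC ≥ 0.5 and recorded. The
multivariate ROC uses 100 stratified 2/3 : 1/3 splits, 500-tree random
forests (impurity importance) for per-split feature ranking, a fresh
forest on the top 5 features, and per-sample averaged held-out
probabilities pooled into one curve — the convention of metabolomics
biomarker modules. Ties in importance and selection frequency break
alphabetically for determinism. The SVM validator is a linear-kernel SVC
on standardized features and refuses train/test sets sharing sample ids.

## Problem sizes used in the test suite

Unit tests run on toy matrices and 30-sample cohorts. The deeper
statistical checks use: 200 null simulations (40 × 30) for calibration;
60 samples/group for direction recovery; 200/group for fold-change
recovery (low-noise, low-baseline condition, since the quantification
windows then carry negligible baseline mass); 50 cohort seeds at the
default 38/32/40 sizes for the ratio-AUC ordering; 100/group for the
null-separability property. These sizes give each check a comfortable
statistical margin at desk scale.

## Known limitations

- Two-class models only; three-group structure is handled pairwise.
- Global referencing only; no per-peak alignment or baseline correction.
- Metabolite quantification is window integration on normalized spectra —
  relative, not absolute, concentrations; overlapping signatures are
  resolved by window assignment, not deconvolution.
- CV-ANOVA p-values are conservative when variables vastly outnumber
  samples.
- The packaged effect table encodes each group's mean shift relative to
  control; the third (case-vs-case) comparison column is used for
  reporting expectations, not for generation, so simulated case-vs-case
  contrasts follow from the two control-relative effects.
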