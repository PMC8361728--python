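# Methods

## The linear absorption model

Every serum fingerprint is treated as a concentration-weighted sum of
component spectra, IMF(ν̃) = Σᵢ Cᵢ·Sᵢ(ν̃), with Cᵢ in mg/mL and Sᵢ the
component's absorbance at 1 mg/mL on a shared wavenumber grid.  The model
is deliberately intercept-free and interaction-free: within Beer–Lambert,
absorbance adds linearly, and baseline effects are the preprocessing
stage's responsibility, not the model's.  Its forward direction
(`forward_model`) reconstructs spectra from known concentrations and
tracks the mean Euclidean "vector distance" to experiment as components
are added in descending abundance order; its inverse (`inversion`)
recovers concentrations from a spectrum by active-set non-negative least
squares (scipy's NNLS), with the unconstrained normal equations as an
option.  "Vector distance" is read as the plain Euclidean norm of the
pointwise difference over the working range; the residual sum of squares
is carried alongside, and a flag divides both by √N for grid-resolution
invariance when wanted.

## Working grid and spectral I/O

The default working range is 1000–3000 cm⁻¹ sampled at 1 cm⁻¹ (2001
points).  The sampling interval is a package choice — fine enough to
resolve bands 20–50 cm⁻¹ wide without inflating file sizes.  Resampling is
piecewise linear and never extrapolates; FTIR grids are dense relative to
band widths, so linear interpolation errors (bounded by h²·max|f″|/8) are
negligible against measurement noise.  All on-disk formats are plain text
with 17-significant-digit floats, so write→read round-trips bit-exactly.

## Water subtraction

The subtraction scale minimizes the L2 norm of the first derivative of
(sample − a·water) over 1800–2200 cm⁻¹, endpoints inclusive.  The norm is
a choice — "minimal" admits several readings — and L2 gives a convex
problem with the closed-form solution a = ⟨D_s,D_w⟩/⟨D_w,D_w⟩, hence no
optimizer tolerance.  Derivatives are central differences (one-sided,
first-order at the two grid ends), which are exact for affine spectra.
One global scale is fitted per sample, matching the one-reference-per-
sample measurement protocol; a negative optimal scale is returned but
warned about, since it indicates a corrupted reference rather than
physics.  Applying the subtraction to its own output yields a scale of
zero (idempotence), which the tests assert.

## Quantification

LFQ intensities are converted per protein as
C[s,i] = I[s,i]/mean_ref(I[·,i]) × panel[i], with the arithmetic mean over
non-missing reference-cohort intensities.  Missing intensities propagate
as missing concentrations; a protein with no usable reference intensities
is an error, not a silent default.  Coefficients of variation use the n−1
standard deviation (replicate sets are small, n = 8 in the
reproducibility assessment).  Recovery of the generator's ground truth is
summarized by the *through-origin* least-squares slope of recovered vs
true concentration per protein: the rescaling model is proportional by
construction, so an intercept term would only absorb sampling noise, and
with heteroscedastic multiplicative noise the intercept-full slope has
roughly three times the sampling spread (sd ≈ 4% vs ≈ 1.3% at n = 93,
CV 33%, instrument CV 9%), which would make a ±5% acceptance band a coin
flip rather than a check.  For the same reason the recovery checks anchor
the panel to the reference cohort's average true concentration — the
procedure's own definition of the panel ("average reference
concentrations") — not to the population mean, whose 3.4% sampling error
at n = 93 would enter every slope.

Fraction partitioning multiplies concentrations by each protein's share in
a named biochemical fraction (metabolite / HSA-depleted / HSA-enriched).
Shares must be supplied explicitly per protein and lie in [0,1] with sums
≤ 1; a missing share is an error because partition tables are measured
quantities and defaulting them would fabricate data.

## Differential analysis

The differential fingerprint is mean(case) − mean(reference) per
wavenumber with the reference cohort's n−1 standard deviation.
Significance uses the two-sided Welch (unequal-variance) t-test — the
conservative default when the variance structure is unknown — per
wavenumber and per protein, with strict star thresholds (* p<0.05,
** p<0.0005, *** p<10⁻⁶).  No multiple-testing correction is applied by
default (raw per-peak p-values are the reported quantity);
Benjamini–Hochberg is available behind a flag.  Relative differences are
reported against the reference mean; g/dL inputs are converted to mg/mL
(×10).  Because both the model and the mean are linear, the fingerprint
predicted from the mean concentration differences equals the cohort
differential of model-generated spectra up to floating-point summation
order; the tests assert this at machine precision (< 10⁻¹² AU), since two
different IEEE-754 summation orders cannot agree bitwise.

## Classification

Stratified k-fold (class proportions preserved across the 55/93
imbalance), shuffled independently per repeat with seeds derived from one
user seed via `SeedSequence`, so a fixed seed reproduces results bitwise.
Within each training fold, per-feature standardization is fit on training
data only, then a linear-kernel SVM with C = 1 — the most reproducible and
interpretable choice where kernel and hyperparameters are otherwise
unconstrained; RBF is available by argument.  AUC is computed per held-out
fold by midranks (Mann–Whitney U/(n₁n₀)), making it exact under ties and
invariant to monotone score transforms; the reported mean ± std is over
all folds × repeats, and the pooled ROC (concatenated held-out scores) is
kept for plotting only because pooling can bias AUC.  Constant features
are dropped with a warning before cross-validation.

## The synthetic cohort generator

The generator emulates the study design with known ground truth: 93
reference + 55 case samples; a 12-protein panel (the ten most abundant
serum proteins plus ORM1 and SERPINA3) dominated by albumin at 45 mg/mL;
log-normal between-person concentration variability at 33% CV (log-normal
keeps concentrations positive and makes the CV parameterization exact);
LFQ intensities = true concentration × per-protein arbitrary scale ×
log-normal instrument noise at 9% CV, so intensities are relative, never
absolute; measured spectra = component sum + per-sample water scale
(uniform in [0.5, 1.5]) × water reference + additive white Gaussian noise
(2×10⁻⁴ AU, a typical absorbance-noise floor for automated liquid-cell
FTIR); everything reproducible bitwise from (config, seed).

Component spectra are sums of Gaussian bands with the field's standard
assignments: amide I (protein-specific centers 1628–1656 cm⁻¹, reflecting
α-helix vs β-sheet content), amide II (~1534–1552), CH deformations
(1400–1470), amide III / side-chain bands (1200–1400), glycan C–O bands
(1000–1200, dominant for the ~45%-carbohydrate ORM1), lipid ester carbonyl
at 1735 and CH stretches at 2852/2926, and a metabolite pseudo-component
overlapping amide I.  Amplitudes put 45 mg/mL albumin at ~0.4 AU amide I.
Two structural choices matter:

* the 1800–2200 cm⁻¹ window is kept band-free by construction (all bands
  below it sit at ≤ 1735 cm⁻¹ with σ ≤ 42, and the shipped bands are pure
  Gaussians — Lorentzian tails decay only polynomially and would leak into
  the window), so the water-subtraction criterion's signal-quiet
  assumption holds exactly;
* each protein carries enough band fine structure to be spectrally
  identifiable: with generic three-band proteins the immunoglobulins are
  nearly collinear and noisy unmixing of the second-most-abundant
  component degrades several-fold.

Disease effects are multiplicative on case means: albumin ×0.91 (−9%,
−0.4 g/dL — the anchoring clinical observation, which at 33% CV and
n = 93 vs 55 correctly reproduces marginal per-protein significance for
albumin despite its rank-one absolute change), and synthetic acute-phase
responses (HP ×1.8, ORM1 ×1.8, SERPINA3 ×2.0, C3 ×1.35, SERPINA1 ×1.5,
TF ×0.8, APOA1 ×0.8).  The magnitudes sit at the strong end of what is
documented for symptomatic stage II/III disease.  That choice is
deliberate: the generator simulates *only* the 12-protein pattern plus
noise, whereas real serum carries many additional correlated signals, so
mild effects leave a linear SVM on 2001 standardized spectral channels —
half of which are signal-free in this minimal world — unable to express
the pattern that the 12 clean concentration features show, and the
spectra-vs-concentrations concordance that is the pipeline's headline
comparison would hinge on cohort luck.  With the chosen magnitudes both
feature spaces express the pattern clearly and their AUCs agree within
0.1 across cohort realizations.

### What passing tests do and do not show

The synthetic cohort realizes the stated design (cohort sizes, CV levels,
effect directions, band positions) but is more separable than a real
case-control study (AUC ≈ 0.95 vs ≈ 0.85 reported for comparable real
cohorts), because it contains no comorbidities, no batch effects, no
baseline drift, no scattering artifacts, and exactly twelve varying
proteins.  Green tests therefore demonstrate that the *pipeline machinery*
is correct — scales recover, models invert, linearity holds, the CV
protocol is unbiased at chance under permuted labels — not that any
particular clinical performance would be attained on real sera.  Absolute
AUC values from the generator should never be quoted as expected clinical
performance.

## Numerical choices and degenerate inputs

Window endpoints are inclusive everywhere for bit-reproducibility.
The unmixing design matrix is flagged collinear above a Gram condition
number of 10⁸ (immunoglobulin spectra are similar; users get a warning
rather than silently unstable estimates); no regularization by default
(≤ 14 components against 2001 grid points), ridge by argument.  A water
reference whose windowed derivative is identically zero is a hard error
(the scale is undefined).  Ties in AUC scores are midranked, so all-equal
scores give exactly 0.5.  Means in the LFQ rescaling must be strictly
positive; zero-variance features and all-missing proteins are dropped
with warnings where a sensible result remains, and errors where it does
not.

## Known limitations

The generator does not simulate apodization, detector nonlinearity,
water-vapor lines, scattering baselines or batch structure; the
preprocessing module implements only the derivative-minimization water
subtraction (no EMSC or rubber-band correction).  The panel
concentrations, partition shares and non-albumin effect magnitudes are
literature-style synthetic values, intended to be overridden with
measured ones for real studies.  Classification deliberately omits
hyperparameter search, feature selection and calibration; it reports the
protocol's AUC, nothing more.
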