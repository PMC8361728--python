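# imfp — infrared molecular fingerprinting of blood serum

Mid-infrared absorption spectra of liquid blood serum ("infrared molecular
fingerprints", IMFs) are a fast, inexpensive readout of the molecular
composition of a biofluid, and machine learning can link them to disease.
What has been missing is a molecular account of *why* such fingerprints
change in disease.  `imfp` implements a pipeline that supplies that account
for a case-control serum study: it models each sample's fingerprint as a
linear combination of component spectra weighted by proteomics-derived
concentrations, removes the dominating water background, computes
case-vs-reference differential fingerprints with protein-level attributions,
and quantifies classification performance from either feature space.  It is
aimed at spectroscopists and computational biologists who want an
interpretable, testable bridge between an omics table and a vibrational
spectrum.

## The model

Within the Beer–Lambert regime, absorbance is additive in concentration, so
the fingerprint of a serum sample is modeled with no intercept and no
interactions as

    IMF(ν̃) = Σᵢ Cᵢ · Sᵢ(ν̃)

where ν̃ is wavenumber (cm⁻¹), Cᵢ the concentration of component *i* in
mg/mL and Sᵢ(ν̃) its absorption spectrum at 1 mg/mL.  Around this sit four
method pieces:

* **Water subtraction.** Liquid-cell spectra are dominated by water.  A
  scaled water reference is subtracted per sample, the scale *a* chosen so
  that the first derivative of the corrected spectrum is minimal (L2) over
  the signal-quiet 1800–2200 cm⁻¹ window — a scalar least-squares problem
  with the closed form a = ⟨D_s, D_w⟩ / ⟨D_w, D_w⟩ on windowed derivative
  vectors.
* **LFQ rescaling.** Label-free quantification intensities are relative;
  they are converted to mg/mL per protein by normalizing to the reference
  cohort's mean intensity and anchoring to reference concentrations:
  C[s,i] = I[s,i] / mean_ref(I[·,i]) × panel[i].
* **Differential fingerprint.** ΔIMF(ν̃) = mean_case IMF − mean_ref IMF,
  reported with the reference cohort's per-wavenumber spread and two-sided
  Welch t-tests; by linearity the model predicts ΔIMF = Σᵢ ΔC̄ᵢ·Sᵢ(ν̃) from
  the concentration changes alone.  Proteins are ranked by |ΔC̄ᵢ| with
  significance stars (* p<0.05, ** p<0.0005, *** p<10⁻⁶, strict).
* **Classification.** Case vs reference by linear SVM (C = 1) under
  10-times-repeated stratified 10-fold cross-validation, per-fold
  standardization fit on training data only, midrank (Mann–Whitney) AUC per
  held-out fold, mean ± std over all 100 folds.

Because no public data accompany the study design, a first-class synthetic
generator (`imfp.synthetic`) reproduces the study conditions with known
ground truth: 93 reference + 55 case samples, a 12-protein panel dominated
by albumin (45 mg/mL), log-normal between-person variability (33% CV),
multiplicative LFQ instrument noise (9% CV), an albumin −9% disease shift
with acute-phase rises and drops, Gaussian band models for the component
spectra (amide I/II, carbohydrate region, lipid bands at 1735/2852/2926
cm⁻¹) and a strong per-sample-scaled water background.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (seed 7) and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_water_subtraction.py
python analysis/03_quantify_proteins.py
python analysis/04_forward_model.py
python analysis/05_differential_fingerprint.py
python analysis/06_classification.py
```

`03_quantify_proteins.py` prints

```
per-protein recovery slope range: [0.994, 1.007]
mean instrument CV: 9.1% | mean between-person CV: 32.7%
```

i.e. rescaled LFQ values track the true concentrations to within ~1%
per protein, and instrument variability (replicate CV ~9%) is well below
between-person variability (~33%), so cohort differences are measurable.
`05_differential_fingerprint.py` ranks albumin first by absolute change
(−4.0 mg/mL, −9.5%, p = 0.03) followed by haptoglobin (+1.4 mg/mL, ***),
and finds the measured differential fingerprint agrees with the one modeled
from just the 12 mean concentration changes at r = 0.980.
`06_classification.py` prints

```
      features  n_features  mean_auc  std_auc
       spectra        2001     0.967    0.043
concentrations          12     0.991    0.015
 permuted-null          12     0.496    0.137
```

— a single spectral measurement carries essentially the same
disease-relevant information as the 12 separately measured protein
concentrations (ΔAUC 0.024), while permuted labels sit at chance.

The same pipeline is scriptable on your own data through the `imf` command
(`imf simulate`, `imf preprocess`, `imf rescale`, `imf model`, `imf unmix`,
`imf differential`, `imf classify`, `imf run-all`); inputs are plain
delimited text (two-column spectra or wide matrices, intensity tables,
YAML panels).

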