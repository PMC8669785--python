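# Methods

## Overview

`ecgbmi` implements, end to end, an analysis in which a neural network
predicts body mass index (BMI) from resting 10-second 12-lead ECGs and the
*residual* of that prediction — ΔBMI = predicted − measured BMI — is then
used as an adiposity index: regressed against visceral adipose tissue (VAT)
volume controlling for measured BMI, entered into age- and BMI-adjusted
logistic models of cardiometabolic comorbidities, and examined through the
comorbidity profile of misclassified subjects. Because the population
biobank data such an analysis needs is access-controlled, the package ships
a synthetic cohort generator whose construction guarantees the causal
structure the analysis is designed to detect; every stage is tested against
that generator.

## Synthetic cohort model

Phenotypes are drawn per sex: BMI ~ N(26, 5²) kg/m² for males and
N(27, 4²) for females; age ~ N(63, 8²) and N(61, 7²) years, respectively
(clipped to [40, 80]); 52% of subjects are female. VAT is

    vat = s · bmi + ε,  ε ~ N(0, σ_v²),

with slope s = 0.2 L/(kg/m²) and σ_v = 1 L by default, clipped at 0. A
hidden **latent adiposity score** z mixes standardized BMI and the
standardized VAT residual ε with configurable weights (default 0.8 and
0.6, normalized to unit length); setting the second weight to 0 removes
all BMI-independent VAT signal from the ECG. Four comorbidity flags
(hypertension, coronary heart disease, diabetes, dyslipidemia) are
Bernoulli draws with logits `intercept + slope · z`; default intercepts
give prevalences near 29%, 9%, 11% and 24%, and hypertension carries the
steepest slope (0.9 per SD).

ECGs are sums of Gaussian wavelets (P, Q, R, S, T) per lead with fixed
12-lead amplitude templates (aVR inverted, rS pattern in V1–V2, R-wave
progression across the precordium). The latent score acts in the
directions described for obesity:

* global amplitude scale `exp(−k·z)` with k = 0.15 (thoracic-impedance
  attenuation),
* PR = 160 + 8z ms, QRS = 90 + 6z ms, QT = 400 + 10z ms (interval
  prolongation), clipped to physiological ranges.

Heart rate is N(62, 6) bpm clipped to [45, 100], beats equally spaced,
plus band-limited noise (white noise low-passed at 45 Hz, SD 0.02 mV).
Sampling rate defaults to 500 Hz (configurable, ≥ 250 Hz). The effect
sizes are plausibility choices — the source literature reports directions,
not magnitudes — set once so that a small network can learn the signal at
cohort sizes near 2000/sex, and are exposed as parameters.

**What the generator does not emulate:** arrhythmias and conduction
disease, beat-to-beat variability (HRV, respiratory modulation),
electrode-placement and drift artifacts, sex differences in ECG morphology
beyond the phenotype distributions, and any nonlinearity in the
adiposity-morphology mapping. Passing tests therefore demonstrate that the
pipeline's machinery is correct and that its inference recovers a known
generative coupling; they say nothing about effect sizes in real
populations.

## Featurization

Two input forms, both yielding a 100 × N_f × 12 spectral-power tensor over
5–55 Hz:

* **Full trace**: Hann-windowed STFT, 0.5 s window, 0.1 s shift. Windows
  are centered at (k + ½)·shift with zero padding beyond the edges so the
  count is exactly duration/shift = 100. The FFT is zero-padded to 1 s,
  giving a 1 Hz grid; [5, 55) Hz keeps 50 bins.
* **Averaged beat**: R peaks are detected on lead II with a
  Pan–Tompkins-style detector (5–15 Hz bandpass, squared derivative,
  150 ms integration, adaptive threshold, 200 ms refractory); all 12 leads
  are segmented into 1-s windows with the R sample at the center, edge
  beats dropped, and averaged. STFT with 0.2 s window and 0.01 s shift on
  the native 5 Hz grid; [5, 55) keeps 10 bins.

Entries are squared DFT magnitudes (power), so the 36 **band-power
features** (12 leads × 3 overlapping bands, 10–25 / 20–35 / 30–50 Hz,
closed intervals at bin centers) are literally sums of tensor entries over
all windows and the band's bins.

Numerical notes: the zero-padded edge windows spread a small amount of
broadband leakage (≈10⁻³ of the dominant band for a pure tone), which the
tests budget for; band-power additivity for orthogonal tones holds to 1%
of the dominant band.

## Networks

Both architectures share one topology, applied per sex and per task:

1. each STFT window's N_f × 12 image passes through 3×3 convolution
   blocks (ReLU, 2×2 max-pool): one block for model 1 (16 filters), three
   for model 2 (16/32/32);
2. a GRU (hidden width 64 by default) runs over the 100 windows;
3. additive attention (tanh scoring, softmax weights) pools the GRU
   states;
4. the pooled state is concatenated with the 36 band powers — a
   residual-style shortcut past the recurrent stack — and a single fully
   connected layer produces 2 or 3 softmax logits or one linear unit.

Training uses Adam; classification minimizes cross-entropy with class
weights proportional to inverse training-fold frequency, regression
minimizes MSE on targets standardized by training-fold statistics. All
input features are standardized per feature using training-fold statistics
only, after a log1p transform — amplitude scales power multiplicatively,
so the log makes the adiposity signal approximately linear and training
markedly more stable. Initialization is Glorot-uniform from the config
seed; training is deterministic given the seed. There is no early
stopping: epochs are fixed and model choice happens across validation
rotations, not epochs.

The networks run on a small reverse-mode autodiff engine written in numpy
inside the package (`_autograd.py`): broadcasting arithmetic, 2-D matmul,
the pointwise nonlinearities, reductions, concatenation, an im2col 3×3
convolution and a 2×2 max-pool, verified against finite differences for
every parameter tensor. Compute dtype is float32 (memory bandwidth
dominates); gradient-check tests switch to float64. Max-pool ties route
gradient to the first maximal element.

The comparison baseline is logistic regression on the 12 per-lead maximum
absolute amplitudes (standardized), fit with scikit-learn; perfect
separation is flagged and refit with an ordinary L2 penalty.

## Cross-validation protocol

Per sex, subjects are permuted and dealt round-robin into 4 folds (sizes
differ by ≤ 1). For a fixed test fold the other three folds rotate through
the validation role, so three models are trained per setting, each on the
remaining two folds (50%/25%/25% of subjects for train/validation/test).
The model with the highest validation accuracy (lowest validation RMSE for
regression; ties to the lowest validation-fold index, then grid order) is
evaluated once on the untouched test fold. Stage 1 runs this on the
fold-4 setting, optionally over a configuration grid, and freezes the
selected configuration; stage 2 repeats it for test folds 1–3 and pools
their out-of-fold predictions, excluding fold-4 subjects from downstream
statistics. An out-of-bag check evaluates one stage-2 model on a freshly
seeded cohort, with an explicit id-overlap guard. Normalizers and class
weights are recomputed inside every rotation from its own training folds;
training-fold id checksums are recorded in the reports for audit.

## Downstream statistics

All fits run per sex on the pooled out-of-fold table:

* confusion matrices at BMI thresholds 25 (binary) and 25/30 kg/m²
  (3-class); binary decisions at probability 0.5;
* ΔBMI = predicted − measured BMI;
* OLS of VAT on ΔBMI controlling for measured BMI; β per unit with 95%
  Wald CI, β per SD = β · sample SD(ΔBMI), full-model R² (the partial R²
  of ΔBMI is also emitted, since either reading of a single-table R² is
  defensible);
* per-SD odds ratios from logistic models `condition ~ z(index) + age +
  measured BMI`, the index standardized by the within-sex analysis-sample
  SD; Wald CIs; separation flagged and refit with an L2 penalty (no CI);
* χ² (no continuity correction) comparing each comorbidity's frequency
  between TP-vs-FN and TN-vs-FP groups, Benjamini–Hochberg corrected
  across the family of all 8 tests per sex, significance at corrected
  p < .05; tests with any expected cell below 1 are skipped and reported;
* AUC of continuous estimates against binarized truth (BMI at 25 kg/m²;
  VAT at the per-sex sample median, since no conventional VAT obesity
  cutoff exists), via the Mann–Whitney rank statistic with tie averaging;
* RMSE in the task's units.

Wald intervals with normal critical values are used throughout, matching
the large-sample regime the analysis targets.

## Headline experiment and problem sizes

`cli_io.headline_experiment` (also driven by `scripts/acceptance.py`)
runs the package's own headline analyses at sizes chosen for a single CPU:
cohorts of 2000 subjects per sex at 250 Hz, averaged-beat input, model 1
with 8 conv filters, GRU width 24, 5 epochs, batch 50, learning rate
0.005. Out-of-sample predictions come from one train(folds 1–2) /
predict(folds 3–4) split per sex — sufficient for the residual statistics,
which need out-of-sample predictions but not the full 9-training rotation
pool. Three replicate cohort seeds are run for the VAT-coupling contrast
(morphology loading on the VAT residual versus not); binary
classification, VAT estimation, odds ratios, misclassification χ² and the
interval-driven baseline comparison (amplitude effects switched off,
k = 0) run on the first seed. The full two-stage rotational protocol is
exercised end to end by `cli_io.run_pipeline` and its tests at smaller
cohort sizes.

## Known limitations

* The generator's single latent driver makes ΔBMI's VAT signal
  first-order linear; real ECG-adiposity relations are richer.
* The exact convolution/GRU/attention widths of the original architectures
  are not public; the defaults here are reasonable choices exposed in
  `ModelConfig`, and the grid mechanism can search over them.
* Whether the original analysis standardized indices within sex or pooled,
  and the exact BH family, are ambiguous; within-sex standardization and
  the 8-test family per sex are used.
* The hyperparameter grid selects by validation accuracy within the
  fold-4 setting; per-setting test accuracies are deliberately not used
  for selection to keep fold 4 untouched by more than one model.
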