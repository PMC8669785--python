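# ecgbmi

Predicting body mass index (BMI) from resting 12-lead ECGs with
conv/GRU/attention networks, and using the *prediction residual* —
ΔBMI = network-predicted minus measured BMI — as an index of visceral
adiposity and concurrent cardiometabolic ill-health.

Obesity remodels cardiac electrophysiology: amplitudes attenuate with
thoracic impedance, and PR, QRS and QT intervals lengthen. A network that
predicts BMI from the ECG therefore reads adiposity off the heart's
electrical signature rather than off height and weight. When it
*over*-predicts a subject's BMI, the interesting hypothesis is that the
ECG looks "more obese" than the scale says — because of visceral adipose
tissue (VAT) or comorbid cardiometabolic disease. The package implements
that full analysis and, because population biobank ECG data is
access-controlled, ships a synthetic cohort generator whose construction
plants exactly the couplings the analysis is meant to detect, so every
stage is testable end to end.

The pipeline:

1. **Featurization** — short-time Fourier transforms of the full 10-s
   trace (0.5 s window, 0.1 s shift → a 100×50×12 power tensor over
   5–55 Hz) or of the R-centered averaged single beat (0.2 s window,
   0.01 s shift → 100×10×12), plus 36 band-power features (12 leads × 3
   overlapping bands: 10–25, 20–35, 30–50 Hz).
2. **Networks** — per-window conv blocks → GRU over windows → additive
   attention pooling; the pooled state is concatenated with the band
   powers (a residual-style shortcut) before the final fully connected
   layer. Heads: binary (BMI ≥ 25 kg/m²), 3-class (<25 / 25–30 / ≥30),
   or continuous BMI/VAT. Class-weighted cross-entropy or MSE, Adam.
   The networks run on a small numpy reverse-mode autodiff engine
   included in the package and verified against finite differences.
3. **Cross-validation** — per sex, 4 random folds; for each test fold the
   other folds rotate through validation (3 models per setting, best
   validation model tested), so each model trains on 50%, validates on
   25% and tests on 25%. Hyperparameters are chosen on the fold-4
   setting; folds 1–3 then provide pooled out-of-fold predictions.
4. **Inference** — confusion matrices, RMSE, ROC/AUC of binarized
   continuous estimates (BMI at 25 kg/m²; VAT at the per-sex median),
   OLS of VAT on ΔBMI controlling for measured BMI (β per unit and per
   SD), per-SD odds ratios of hypertension, CHD, diabetes and
   dyslipidemia adjusted for age and measured BMI, and χ² comparisons of
   comorbidity frequency between misclassification groups (TP vs FN,
   TN vs FP) with Benjamini–Hochberg correction.

See `docs/methods.md` for the generator's model, all parameter defaults,
numerical choices, and limitations.

## Worked example

```python
from ecgbmi.cli_io import headline_experiment

res = headline_experiment(seed=7, n_per_sex=300, epochs=5,
                          n_regression_seeds=1, with_interval_cohort=False)
for sex, r in res["coupled"][0]["sexes"].items():
    beta = r["vat_regression"]["beta_per_unit"]
    print(f"{sex}: binary accuracy {r['binary_accuracy']:.2f}, "
          f"RMSE {r['rmse_bmi'].estimate:.1f} kg/m2, AUC {r['auc_bmi']:.2f}")
    print(f"  VAT ~ dBMI | BMI: beta {beta.estimate:.3f} "
          f"[{beta.ci_low:.3f}, {beta.ci_high:.3f}] L/(kg/m2), p {beta.p_value:.1e}")
```

prints

```
female: binary accuracy 0.75, RMSE 2.8 kg/m2, AUC 0.85
  VAT ~ dBMI | BMI: beta 0.310 [0.273, 0.347] L/(kg/m2), p 1.9e-35
male: binary accuracy 0.76, RMSE 3.5 kg/m2, AUC 0.88
  VAT ~ dBMI | BMI: beta 0.241 [0.208, 0.273] L/(kg/m2), p 4.5e-30
```

Reading this: on a 300-per-sex synthetic cohort whose ECG morphology is
driven by a mix of BMI and the BMI-independent VAT residual, the network
classifies overweight/obese subjects at ~75% held-out accuracy and
estimates BMI to ~3 kg/m² RMSE; and after controlling for measured BMI,
every extra kg/m² by which the network over-predicts BMI corresponds to
about a quarter litre more VAT — the prediction residual is reading the
visceral adiposity that BMI itself misses. Setting the generator's
VAT-residual coupling to zero makes the same β statistically
indistinguishable from zero.

There is also a CLI for the individual stages:

```
ecgbmi simulate --n 16 --seed 1 --out cohort/      # WFDB records + phenotype CSV
ecgbmi preprocess --cohort cohort/ --out feats.npz
ecgbmi run-all --config config.yaml --out report.json
```

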