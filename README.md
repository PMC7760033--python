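# nmrfinger

Serum ¹H-NMR fingerprinting for predicting response to anti-PD-1
immunotherapy in non-small-cell lung cancer (NSCLC), as a tested, fully
runnable Python pipeline.

Pre-treatment serum spectra are reduced to a *fingerprint* — the vector of
normalized spectral areas over fixed 0.02 ppm chemical-shift bins — and a
supervised OPLS-DA model is asked whether that fingerprint separates patients
who will benefit from checkpoint-inhibitor therapy (responders) from those
who will not. The package is aimed at metabolomics/chemometrics researchers
who want every stage of such an analysis — spectral processing, modelling,
validation, univariate statistics and clinical endpoint derivation — as
importable, seed-reproducible functions, with a synthetic-cohort generator so
the whole pipeline runs and is testable without any patient data.

## What's inside

| module | role |
| --- | --- |
| `nmrfinger.synthetic` | serum-like two-class cohorts: Lorentzian line spectra for six metabolites (glucose, lactate, alanine, pyruvate, citrate, glycine) with planted class effects, plus matching clinical tables and ground truth |
| `nmrfinger.processing` | FID apodization/FT, chemical-shift calibration on the glucose doublet at δ 5.24 ppm, 0.02 ppm binning over 10.00–0.2 ppm, water exclusion (4.50–5.00 ppm) and total-area normalization |
| `nmrfinger.chemometrics` | bespoke PCA and OPLS-DA (orthogonal-signal-corrected PLS) with JSON model serialization |
| `nmrfinger.validation` | leave-one-out and Monte Carlo (90/10 × 500) cross-validation, label-permutation testing, discriminant Q², ROC/AUC, confusion metrics |
| `nmrfinger.univariate` | metabolite levels from ppm integration windows, Wilcoxon–Mann–Whitney tests, Benjamini–Hochberg FDR |
| `nmrfinger.clinical` | iRECIST-based response rules, TTF/OS medians and group comparisons; the published nivolumab (n=34) and pembrolizumab (n=19) cohort tables ship as transcribed CSV fixtures |
| `nmrfinger.cli` | thin `nmrfinger` command with `simulate` / `fingerprint` / `validate` / `univariate` / `clinical` / `transfer` / `report` subcommands |

## The model

For mean-centred, scaled bin matrix **X** (subjects × bins) and class vector
**y** ∈ {−1, +1}ⁿ (responder = +1), each orthogonal component removes
structured variation uncorrelated with class:

    w   = Xᵀy / ‖Xᵀy‖            t  = Xw          p  = Xᵀt / tᵀt
    w_o = p − (wᵀp)w (normalized)  t_o = Xw_o      p_o = Xᵀt_o / t_oᵀt_o
    X  ← X − t_o p_oᵀ

and the predictive part is one-component PLS on the filtered matrix, with
score ŷ = t·q, q = yᵀt/tᵀt, and hard label sign(ŷ). With zero orthogonal
components the model is exactly one-component PLS (tested against an
independent NIPALS implementation to 1e−10).

Model quality is summarised by cross-validated accuracy, ROC AUC and the
discriminant Q²

    DQ² = 1 − Σᵢ eᵢ² / Σᵢ (yᵢ − ȳ)²,   eᵢ = 0 if ŷᵢ overshoots its own label,

and significance by a label-permutation test whose statistic is the full
cross-validated accuracy, p = (1 + #{perm ≥ observed}) / (B + 1).

## Worked example

`examples/` contains one short script per capability. End-to-end
classification on a default synthetic cohort (15 responders with 0.6×
alanine and pyruvate vs 19 non-responders):

```bash
$ python examples/03_classify_validate.py
LOO accuracy: 94%  (2/34 misclassified)
sensitivity 93%, specificity 95%
DQ2 0.66, AUC 0.98
permutation: mean accuracy 51.1%, p = 0.005
```

The model recovers the planted two-metabolite signature far above the
permuted-label baseline (~50%); DQ² > 0 means out-of-fold scores explain
class variance beyond the mean predictor. The clinical stage on the
published nivolumab table:

```bash
$ python examples/05_clinical_endpoints.py
second-assessment rule: 15 responders / 19 non-responders
TTF: responders median 54 wk, non-responders 10 wk, p = 8.3e-07
OS: responders median 75 wk, non-responders 19 wk, p = 2e-05
KM OS medians: 103.0 vs 19.0 weeks
```

The same pipeline is available from the shell:

```bash
nmrfinger simulate --out cohort --seed 1
nmrfinger fingerprint --spectra-dir cohort/spectra --out matrix.csv
nmrfinger validate --matrix matrix.csv --clinical cohort/clinical.csv --out report
```

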