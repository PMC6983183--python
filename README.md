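# apneahrv

Heart-rate-variability (HRV) analysis of overnight beat-to-beat (RR)
interval recordings for the assessment of sleep-apnea severity.

Sleep apnea is diagnosed by polysomnography through the apnea–hypopnea
index (AHI, events per hour of sleep), but polysomnography is expensive and
ill-suited to follow-up. Because apnea events drive cyclic
bradycardia–tachycardia patterns in the heart rhythm, severity information
is recoverable from a single-channel ECG — including wearable
textile-electrode belts, whose higher movement-artifact burden makes RR
pre-filtering an integral part of the analysis. `apneahrv` implements the
full chain for researchers working with such recordings:

1. **RR pre-filter** — excludes intervals outside (300 ms, 1500 ms) and
   intervals deviating more than 20% from the running median of their ten
   preceding and ten following beats.
2. **Whole-night HRV features** — time domain: SDNN, pNN50, rMSSD, IRRR,
   MADRR, HRVi; frequency domain via short-time Fourier spectrograms of the
   4 Hz-resampled tachogram (300 s windows, 10 s displacement): ULF, VLF,
   LF, HF band powers and the LF/HF ratio.
3. **Ordination** — PCA of the standardized feature table; external
   clinical variables (AHI, ODI, ESS) are related to the component plane by
   vector fitting (direction of maximal correlation, R², permutation
   p-value) and linear surface fitting with equally spaced isoclines.
4. **Severity classification** — responses dichotomized at swept quantile
   cut-offs; SVM / LDA / KNN / OPLS-DA classifiers evaluated under repeated
   stratified cross-validation; sensitivity, specificity, accuracy per
   cut-off; ROC curves with Mann–Whitney AUC and DeLong 95% CIs; comparison
   across sensor (belt vs. patch) × filtering conditions.
5. **Synthetic cohort generator** — paired belt/patch overnight RR
   recordings produced by integrate-and-fire over an instantaneous-RR
   trajectory (respiratory sinus arrhythmia, 0.1 Hz oscillation,
   AHI-rate Poisson apnea events, sensor-specific missed/false-beat
   artifacts), with clinical variables calibrated to a referral-cohort
   profile. Every downstream stage is testable without clinical data.

## Worked example

```python
import dataclasses
from apneahrv import (SyntheticConfig, generate_cohort, filter_rr,
                      extract_features, dichotomize, roc_auc,
                      ClassifierSpec)
from apneahrv.hrv_features import cohort_feature_table
from apneahrv.severity_classification import cross_validated_scores

cfg = dataclasses.replace(SyntheticConfig(), n_subjects=50,
                          night_duration_s=14400.0, seed=7)
records, manifest = generate_cohort(cfg)

series = records[0].recordings["belt"]
filtered, report = filter_rr(series)
print(f"removed {report.fraction_removed:.2%} of {report.n_input} beats")

fv = extract_features(filtered)
print(f"SDNN {fv.sdnn:.1f} ms  VLF {fv.vlf:.1f} ms^2  LF/HF {fv.lfhf:.2f}")

feats = cohort_feature_table(records, "belt", filtered=True)
labels = dichotomize(manifest.response("ahi"), 18.0)
scores = cross_validated_scores(feats, labels, ClassifierSpec("svm"),
                                folds=5, repeats=2, seed=0)
r = roc_auc(scores, labels)
print(f"AUC {r.auc:.3f}  [{r.auc_ci_95[0]:.3f}, {r.auc_ci_95[1]:.3f}]")
```

prints (seed 7):

```
removed 1.44% of 14489 beats
SDNN 34.3 ms  VLF 25.3 ms^2  LF/HF 1.86
AUC 0.950  [0.898, 1.000]
```

The filter removes ~1.4% of belt beats (mostly injected sensor artifacts);
the very-low-frequency power reflects this subject's apnea-event burden,
and cross-validated classification of AHI ≥ 18/h from the eleven HRV
features is far above chance on clean synthetic nights.

The same analysis is available from the shell:

```sh
apneahrv simulate --n 20 --seed 1 --out cohort/
apneahrv run --config examples/pipeline.yaml --seed 1
```

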