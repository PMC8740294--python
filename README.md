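# teppipe

Spatiotemporal analysis of TMS-evoked potentials (TEPs) for two-group
comparisons, built for studies that ask whether the EEG response to
single-pulse transcranial magnetic stimulation separates a clinical group
(here: cognitive impairment, CI) from healthy controls (HC).

The package provides, as a tested library plus a thin CLI:

- **`teppipe.synthgen`** — a seeded simulator of two-group TMS-EEG
  cohorts: 62-channel epochs (−1 .. +1 s around the pulse, 1 kHz),
  Gaussian-bump evoked components (N40, P60, N100, P200) with per-subject
  amplitude/latency draws, focal topographies, calibrated local field
  power, and 1/f background noise.
- **`teppipe.prep`** — deterministic preprocessing: baseline correction
  (−500..−50 ms), cubic interpolation of the pulse window (−5..15 ms),
  anti-aliased downsampling to 1 kHz, zero-phase Butterworth band-pass
  (1–80 Hz) and band-stop (48–52 Hz) filtering, common-average reference.
- **`teppipe.features`** — 3-segment trial augmentation, Gaussian
  smoothing (length-20 window), global/local mean field power, and seven
  windowed linear features (LMFP, STD, Latency, Amplitude, AVG, AUC,
  Range) per ROI and component window: 2 windows × 7 ROIs × 7 features =
  98 columns per (subject, segment) row.
- **`teppipe.clf`** — min–max normalisation, optional t-SNE/PCA
  reduction, linear SVM / random forest / k-NN, leave-one-subject-out
  cross-validation with majority voting over the three segment labels,
  confusion metrics, and XGBoost feature importance.
- **`teppipe.permstat`** — cluster-based permutation statistics over
  channels × time (pooled t-maps, spatiotemporal clustering with a
  two-adjacent-channel rule, max-cluster-mass null from subject-label
  permutations, per-tail α = 0.025).

The core quantities, for a window of N samples and an ROI of k channels
with per-sample voltages V_j(i) and ROI mean X(i):

    GMFP(i)  = sqrt( Σ_j (V_j(i) − V̄(i))² / K ),            K = 62
    LMFP     = (1/N) Σ_i sqrt( Σ_j (V_j(i) − V̄(i))² / k )
    STD      = sqrt( (1/N) Σ_i (X(i) − X̄)² )
    AUC      = (1/2f) Σ_i (X(i) + X(i+1))
    Accuracy = (TP+TN)/(TP+TN+FP+FN),  Sensitivity = TP/(TP+FN),
    Specificity = TN/(TN+FP),  F1 = 2TP/(2TP+FP+FN)

See `docs/methods.md` for the full model, parameter tables, and the
numerical choices.

## Worked example

Simulate a small cohort with the default CI/HC group parameters, run the
pipeline, and classify:

```python
from teppipe import clf, features, synthgen, workflow

params = synthgen.GenParams(n_trials=100, seed=7)
cohort = synthgen.simulate_cohort(12, 12, params)        # 12 CI + 12 HC
cohort = workflow.preprocess_cohort(cohort)
table = features.build_feature_table(cohort)             # 72 rows x 98 features
report = clf.loocv_vote(table)
print(table.shape)
print(report.confusion, {k: round(v, 3) for k, v in report.metrics.items()})
```

prints

```
(72, 101)
{'TP': 9, 'FP': 1, 'FN': 3, 'TN': 11} {'accuracy': 0.833, 'sensitivity': 0.75, 'specificity': 0.917, 'f1': 0.818}
```

i.e. 24 subjects × 3 segment rows with the 98 named feature columns (plus
subject/segment/group), and 20 of 24 subjects voted into their true group
by the leave-one-subject-out linear SVM. The exact confusion counts move
with the seed and cohort size; group separation follows the generator's
CI-vs-HC parameter defaults. (The in-memory cohort above needs a few GB;
for larger cohorts use `workflow.run_all`, which streams subjects.)

The same flow from the shell:

```bash
teppipe synth --n-ci 8 --n-hc 8 --trials 100 --seed 7 --out cohort/
teppipe prep --in cohort/ --out clean/
teppipe features --in clean/ --out features.csv
teppipe classify --features features.csv --clf svm --out report.json
teppipe permtest --in clean/ --window N100 --n-perm 5000 --out clusters.json
```

or end-to-end with one config: `teppipe run --config run.yaml`.

## What this is not

Artifact removal for real recordings (ICA, epoch/channel rejection,
channel interpolation) is out of scope; reports list these as bypassed
stages. Published clinical classification numbers depend on clinical
recordings and are not reproducible from simulation; the package's bands
are statements about the pipeline, not about patients.
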