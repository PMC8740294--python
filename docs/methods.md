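# Methods

`teppipe` analyses TMS-evoked potentials (TEPs): the stereotyped voltage
deflections that follow a single transcranial magnetic stimulation pulse,
recorded with multi-channel scalp EEG and obtained by averaging epochs
time-locked to the pulse. The package covers five stages — cohort
simulation, preprocessing, feature extraction, subject-level
classification, and cluster-based group statistics — driven by explicit
seeds so every result is reproducible from a config.

## Signal model of the simulator

A subject's noise-free evoked response is a sum of Gaussian bumps, one per
component c ∈ {N40, P60, N100, P200}:

    s(t) = Σ_c a_c · exp( −(t − τ_c)² / (2 w_c²) ),   s(t) = 0 for t < 0

Amplitudes a_c (µV, signed) and latencies τ_c (s) are drawn once per
subject from group-level normal distributions; w_c is a fixed width.
Channel j records g_{cj} · (component c), plus background noise. Trials
within a subject share the drawn response (per-trial latency jitter is
available but off by default, keeping averaged peaks sharp and recovery
testable).

Group defaults for the N100 and P200 (right-frontal region) are the
published group statistics of a cognitively-impaired (CI) versus
healthy-control (HC) single-pulse DLPFC study:

| parameter | CI | HC |
|---|---|---|
| N100 amplitude (µV) | −2.77 ± 1.68 | −1.10 ± 0.72 |
| N100 latency (s) | 0.120 ± 0.013 | 0.110 ± 0.014 |
| P200 amplitude (µV) | +2.64 ± 1.92 | +1.11 ± 0.64 |
| P200 latency (s) | 0.220 ± 0.031 | 0.220 ± 0.036 |
| N100-window LMFP target (µV) | 0.67 ± 0.40 | 0.37 ± 0.22 |

N40/P60 parameters are free choices for morphological realism only
(−1.5/+1.5 µV at 40/60 ms); nothing downstream asserts them. Component
widths (12/15/20/35 ms) are likewise free parameters: the source study
reports none.

**Topography.** Each component uses a focal spatial gain profile centred
on the right-frontal ROI (Gaussian in planar layout coordinates,
σ = 0.15). The profile has its scalp mean subtracted (a weak negative
far-field lobe) and is scaled so the mean gain across the four ROI
channels is exactly 1. The zero-mean choice is deliberate: scalp
potentials in common-average reference sum to zero by construction, and a
reference-neutral topography is the only way the re-referencing stage can
preserve the ROI-average amplitude the components were calibrated to.
With a nonnegative topography the re-reference would erode the ROI mean
by at least 4/62 ≈ 6.5% — a structural bias, not a modelling feature.

**LMFP calibration.** The local mean field power over a window
(definition below) of a signal g_j·s(t) factorises exactly as
sd_pop(g) · mean_t |s(t)|. `calibrate_gain_spread` therefore returns
within-ROI gains 1 + σu (u an alternating ±1 pattern, zero-mean,
unit population SD) with σ = target / mean_t |s(t)|, making the
noise-free window LMFP of the supplied template equal the drawn target
identically; the identity is verified against a brute-force triple-loop
oracle in the tests. Inside the simulator the template handed to the
calibration is the *measured-space* waveform — the subject's composite
response passed through the default preprocessing filters and trace
smoothing — because the drawn target describes the extracted feature,
and the zero-phase 1 Hz high-pass alone rescales window statistics by
several percent (for weak-N100 subjects the rescaling is large, and
calibrating on the raw waveform was measured to inflate the recovered
group mean by ~0.16 µV). Noise-free, the full pipeline then extracts
the drawn target to ~1e-13. When
the drawn target demands σ > 1, some gains go negative — the component's
polarity inverts across the region, as real scalp fields do near the
zero line of a dipole. Clipping at nonnegativity instead was measured to
bias mean recovered LMFP by −0.09 µV, because infeasibility correlates
with weak-N100 subjects. Negative LMFP-target draws are clipped to zero
(bias on the mean ≈ +0.008 µV for the CI distribution).

**Noise.** Gaussian white noise shaped to a 1/f^α spectrum (α = 1,
flat below 1 Hz, zero DC), independent per trial and channel, scaled to a
per-sample SD of `noise_sd` µV. Default 2 µV: at the default 100-trial
session this keeps the measurement-noise contribution to extracted
feature dispersion minor relative to the between-subject spread above, so
the simulated cohort actually exhibits the group statistics it was
parameterised with (at 5 µV, the field-power noise floor was measured to
inflate the HC LMFP mean by ~75%, which defeats the generator's purpose).
The recovery studies below use 0.2 µV, isolating systematic biases of the
measurement chain from noise.

What the generator does **not** emulate: TMS pulse/decay artifacts,
ocular and muscle artifacts, auditory evoked contamination, channel
drop-outs, volume-conduction-consistent topographies for the N40/P60, or
any spatial correlation structure of the background noise (independent
across channels). Passing tests therefore demonstrate correctness of the
analysis pipeline on data satisfying its assumptions, not robustness of
the pipeline to real-world artifacts — artifact handling (ICA, epoch and
channel rejection) is explicitly outside the pipeline and is recorded as
a bypassed stage in every report.

## Preprocessing

Fixed order, all stages pure and linear:

1. **Baseline correction** — subtract the per-trial, per-channel mean over
   −500..−50 ms.
2. **Pulse interpolation** — replace −5..+15 ms with a single
   least-squares cubic fit jointly to 20 ms flanks on each side. The
   scheme bridges the excised pulse window smoothly and reproduces any
   cubic exactly; real pulse artifacts are not simulated, so the stage's
   role here is fidelity of the numerical contract.
3. **Resampling** — polyphase anti-aliased decimation to 1 kHz (identity
   when already at 1 kHz, the generator default).
4. **Filtering** — Butterworth band-pass 1–80 Hz and band-stop 48–52 Hz,
   order 4 each, applied forward–backward (zero phase). Zero phase
   matters because peak latency is a downstream feature. Two measured
   side effects, both inherent to zero-phase high-passing of a
   net-positive-area waveform: a ~5% deepening of the N100 trough and
   the same ~5% inflation of window-mean |s| (hence of LMFP). Both are
   documented in the recovery bands below. Passband/stopband properties
   (50 Hz ≥ 20 dB down, 10 Hz within 5%) are steady-state statements and
   are tested on a 20-s record; on a 2-s epoch the 1 Hz high-pass
   boundary transient alone reaches ~8% mid-epoch.
5. **Common-average re-reference** — subtract the per-sample channel mean.

## Features

Per subject, trials are split in recorded order into segments 1–30,
31–60, 61–end (boundaries clip to min(30, n−2), min(60, n−1) for short
sessions, keeping all three segments nonempty). Each segment is averaged
into a TEP trace and every channel is smoothed with a unit-sum Gaussian
window of length 20 samples (σ = (L−1)/5 samples, nearest-edge padding so
constants pass through). The even window length shifts the effective
kernel centre by half a sample (+0.5 ms at 1 kHz); on a 20 ms-wide bump
the smoother attenuates the peak by <2%.

For each of 7 ROIs (Fl, Fr, C, Cp, Pl, Pr, O — fixed 10/20 electrode
sets) and 2 windows (N100: 100–160 ms; P200: 180–280 ms, both endpoint-
inclusive), with X(i) the unweighted ROI channel mean and N window
samples:

- **LMFP** = (1/N) Σ_i sqrt( Σ_j (V_j(i) − V̄(i))² / k ) over the k ROI
  channels (V̄ is the ROI mean per sample — a local field power is local,
  so the reference mean is the ROI's, not the whole scalp's);
- **STD** — population SD of X over the window;
- **Latency/Amplitude** — time and signed value of the window extremum
  (minimum in N100, maximum in P200: component polarity is known a
  priori); extrema on window edges are accepted but flagged;
- **AVG** — window mean of X;
- **AUC** = (1/2f) Σ_i (X(i) + X(i+1)), the signed trapezoid area;
- **Range** — max − min of X.

All seven features are computed on the smoothed trace, giving one
internally consistent pipeline. 2 windows × 7 ROIs × 7 features = 98
columns per (subject, segment) row; columns are ordered window-major
("N100.Fr.LMFP"). The global mean field power (GMFP, the same SD over
all 62 channels) is exposed as a diagnostic but is not a classifier
feature.

## Classification

Rows are (subject, segment) pairs; evaluation is leave-one-subject-out:
each fold removes all three rows of one subject, trains on the rest, and
fuses the three predicted segment labels by majority vote (three binary
labels cannot tie). CI is the positive class. Metrics: accuracy,
sensitivity, specificity, F1; zero-denominator cases serialise as null.

Dimensionality reduction precedes min–max normalisation onto [−1, 1].
Modes:

- `joint`: t-SNE embeds all rows before cross-validation
  and normalisation is fit jointly. t-SNE has no out-of-sample transform,
  so this is the only way to put t-SNE coordinates into LOOCV — at the
  price of test-subject leakage. Reports carry an explicit leakage flag.
- `leakage_safe` (default): every data-dependent map is fit on training
  rows only; a train-fit PCA of matching dimension stands in for t-SNE.

Classifiers: linear SVM (C = 1), random forest (7 trees), k-NN (k = 5,
Euclidean on the normalised matrix). No hyperparameter search anywhere.
Feature importance uses XGBoost gain with a fixed seed (50 trees, depth
3, exact splits), on all rows — it is a descriptive ranking, not a
cross-validated quantity. t-SNE perplexity defaults to 10 (must stay
well under the ~129-row table).

## Cluster-based permutation test

Pooled-variance two-sample t per (channel, sample) inside the analysis
window; threshold at the two-sided pointwise p = 0.05 critical value;
group same-sign supra-threshold points into components connected by
temporal contiguity within a channel and spatial adjacency (planar
distance < 0.25 layout units; median ~4 neighbours) across channels;
discard components never showing two adjacent channels co-active at a
sample; score each cluster by its mass (summed t). The null distribution
is the per-permutation maximum cluster mass (per tail), generated by
permuting subject-level group labels — the hypothesis under test is
exchangeability of subjects between groups, so subject-label exchange is
the randomisation that matches it (not within-subject trial shuffling).
p = (1 + #{perm ≥ observed}) / (n_perm + 1), so p ≥ 1/(n_perm+1);
significance at p < 0.025 per tail (two-tailed control). Default 5000
permutations.

## Numerical and testing choices

- Window masks are endpoint-inclusive with a 1 ns tolerance; at 1 kHz the
  N100 window holds 61 samples, P200 101.
- Every field-power and windowed feature is checked against an
  independent brute-force loop implementation at ≤ 1e-12 on full-size
  random traces; shift-invariance and |c|-homogeneity are asserted as
  properties.
- Recovery studies (200 simulated CI subjects, 0.2 µV noise, 90 trials
  per subject): across-subject mean extracted Fr-N100
  latency/amplitude/LMFP recover the generating 0.12 s / −2.77 µV /
  0.67 µV within three standard errors plus the documented chain biases
  (+0.5 ms kernel shift; ~5% trough deepening). 90 trials give balanced
  30/30/30 segments; shorter sessions leave single-trial segments whose
  field-power noise floor (≈ +0.05 µV on the LMFP column at 30 trials)
  would enter the recovered mean. The in-suite fixture runs on the
  compact 26-channel montage — the right-frontal features are identical
  by construction because the topography is reference-neutral on any
  montage — while the acceptance script uses the full 62-channel layout.
- The classification sanity study runs at the study's size (21 CI + 22 HC,
  100 trials) on the compact 26-channel ROI montage (features depend only
  on ROI channels) and requires mean LOOCV voted accuracy > 0.75 over 10
  replicates. This is a sanity band on the synthetic conditions, not a
  reproduction of any published accuracy: published numbers from the
  clinical cohort are not reproducible without the clinical data.
- Type-I error of the permutation test is checked on an exchangeable null
  (both groups drawn from the same distribution; 20+20 subjects, 500
  permutations, 100 replicates, 26-channel montage): the fraction of
  replicates with any significant cluster must stay ≤ 0.08 around the
  nominal two-tailed 0.05.
- The test fixture is a 4-subject, 9-trial, 8-channel micro-cohort whose
  seven ROI names are remapped onto overlapping channel pairs, preserving
  the full 98-column feature surface at negligible cost.

## Known limitations

- The Gaussian-bump/gain model carries no volume conduction; topographies
  are plausibility devices, not forward solutions.
- The within-ROI gain pattern used for LMFP calibration is a fixed
  alternating pattern; only its dispersion is calibrated.
- Latency features inherit a systematic +0.5 ms from the even smoothing
  window, matching the behaviour of a plain length-20 moving Gaussian.
- `joint` mode intentionally reproduces a leakage-prone
  protocol for comparison purposes; its numbers must not be read as
  generalisation estimates.
- Single-trial segments arise for sessions under 62 trials; their feature
  rows are noisier and the voting step then leans on segment 1.
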