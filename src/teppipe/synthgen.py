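"""Synthetic two-group TMS-EEG cohort generator.

The generator emulates the statistical structure that the downstream
analysis assumes: each subject contributes ``n_trials`` single-pulse
epochs on a fixed channel layout; every trial is the subject's evoked
response plus spectrally shaped background noise.  The evoked response
is a sum of Gaussian-bump components (N40, P60, N100, P200) whose
amplitude and latency are drawn once per subject from group-level
normal distributions, so that feature extraction downstream can recover
the generating values.

Group-level defaults for the N100/P200 amplitude and latency follow the
reported right-frontal statistics of a cognitively impaired (CI) versus
healthy control (HC) single-pulse study (see the package methods note);
the spatial pattern is a focal right-frontal gain topography, and the
within-region gain dispersion can be calibrated so the local mean field
power (LMFP) of the noise-free signal hits a prescribed target exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .containers import Cohort, EpochSet, SubjectRecord
from .montage import ROIS, TIME_WINDOWS, ChannelLayout, RoiSpec, TimeWindow, make_default_layout
from . import prep as _prep

__all__ = [
    "ComponentSpec",
    "GenParams",
    "component_template",
    "composite_template",
    "calibrate_gain_spread",
    "default_components",
    "focal_gain_map",
    "simulate_subject",
    "simulate_group",
    "simulate_cohort",
]

_COMPONENT_NAMES = ("N40", "P60", "N100", "P200")


@dataclass(frozen=True)
class ComponentSpec:
    """One evoked component, modelled as a Gaussian bump.

    Amplitudes are in microvolts (signed: N-components negative, P-components
    positive), latencies in seconds, ``width`` is the bump standard deviation
    in seconds.
    """

    name: str
    latency_mean: float
    latency_sd: float
    amp_mean: float
    amp_sd: float
    width: float

    def __post_init__(self) -> None:
        if self.name not in _COMPONENT_NAMES:
            raise ValueError(f"unknown component {self.name!r}")
        if self.width <= 0:
            raise ValueError("component width must be positive")
        if not 0 < self.latency_mean <= 0.5:
            raise ValueError("latency_mean must lie in (0, 0.5] s")
        if self.name.startswith("N") and self.amp_mean > 0:
            raise ValueError(f"{self.name} amp_mean must be <= 0")
        if self.name.startswith("P") and self.amp_mean < 0:
            raise ValueError(f"{self.name} amp_mean must be >= 0")


def default_components() -> dict[str, tuple[ComponentSpec, ...]]:
    """Per-group component parameter defaults.

    N100 and P200 amplitude/latency means and SDs are the reported
    right-frontal group statistics (CI: N100 -2.77 +/- 1.68 uV at
    0.12 +/- 0.013 s, P200 +2.64 +/- 1.92 uV at 0.22 +/- 0.031 s; HC
    correspondingly weaker).  N40/P60 are present for morphological
    realism only; their parameters are free choices.
    """
    return {
        "CI": (
            ComponentSpec("N40", 0.040, 0.005, -1.5, 0.5, 0.012),
            ComponentSpec("P60", 0.060, 0.006, 1.5, 0.5, 0.015),
            ComponentSpec("N100", 0.120, 0.013, -2.77, 1.68, 0.020),
            ComponentSpec("P200", 0.220, 0.031, 2.64, 1.92, 0.035),
        ),
        "HC": (
            ComponentSpec("N40", 0.040, 0.005, -1.2, 0.4, 0.012),
            ComponentSpec("P60", 0.060, 0.006, 1.2, 0.4, 0.015),
            ComponentSpec("N100", 0.110, 0.014, -1.10, 0.72, 0.020),
            ComponentSpec("P200", 0.220, 0.036, 1.11, 0.64, 0.035),
        ),
    }


# Reported right-frontal N100 LMFP group statistics (mean, SD) in uV; used
# to calibrate the within-region gain dispersion per subject.
DEFAULT_LMFP_TARGET: dict[str, tuple[float, float]] = {
    "CI": (0.67, 0.40),
    "HC": (0.37, 0.22),
}


@dataclass(frozen=True)
class GenParams:
    """Cohort-generation parameters.

    Attributes
    ----------
    components
        Per-group ("CI", "HC") component specifications.
    lmfp_target
        Per-group (mean, sd) of the noise-free N100-window LMFP in the
        calibration ROI, or ``None`` to skip gain-spread calibration.
    calibration_roi / calibration_window
        Region and window the gain-spread calibration refers to.
    gain_map
        Optional explicit per-component channel gains (component name ->
        length-``n_channels`` nonnegative array).  When absent, a shared
        focal topography centred on the calibration ROI is used.
    noise_sd
        Per-sample standard deviation of the background noise added to each
        trial and channel, in microvolts (after spectral shaping).  The
        default of 2 uV keeps the measurement-noise contribution to
        feature dispersion minor relative to the between-subject spread at
        the default 100-trial session, so extracted features recover the
        generating group statistics.
    background
        Exponent alpha of the 1/f^alpha noise spectrum.
    per_trial_jitter
        SD (seconds) of additional per-trial latency jitter; 0 disables it,
        keeping latency jitter purely between subjects.
    """

    components: Mapping[str, tuple[ComponentSpec, ...]] = field(
        default_factory=default_components
    )
    lmfp_target: Mapping[str, tuple[float, float]] | None = field(
        default_factory=lambda: dict(DEFAULT_LMFP_TARGET)
    )
    calibration_roi: str = "Fr"
    calibration_window: str = "N100"
    gain_map: Mapping[str, np.ndarray] | None = None
    topo_sigma: float = 0.15
    noise_sd: float = 2.0
    background: float = 1.0
    n_trials: int = 100
    sfreq: float = 1000.0
    epoch_span: tuple[float, float] = (-1.0, 1.0)
    per_trial_jitter: float = 0.0
    seed: int = 0
    layout: ChannelLayout = field(default_factory=make_default_layout)

    def __post_init__(self) -> None:
        if self.n_trials < 3:
            raise ValueError("n_trials must be >= 3 (segmentation needs 3 trials)")
        if not (self.epoch_span[0] <= -1.0 and self.epoch_span[1] >= 1.0):
            raise ValueError("epoch_span must cover [-1, 1] s")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.gain_map is not None:
            for name, g in self.gain_map.items():
                g = np.asarray(g, dtype=float)
                if g.shape != (len(self.layout),):
                    raise ValueError(f"gain map for {name} has wrong length")
                if (g < 0).any():
                    raise ValueError("gain maps must be nonnegative")

    def times(self) -> np.ndarray:
        n = int(round((self.epoch_span[1] - self.epoch_span[0]) * self.sfreq)) + 1
        return self.epoch_span[0] + np.arange(n) / self.sfreq


def component_template(spec: ComponentSpec, times: np.ndarray,
                       amp: float | None = None,
                       latency: float | None = None) -> np.ndarray:
    """Evaluate one component's Gaussian-bump waveform on a time axis.

    The bump support is windowed to t >= 0 (no pre-stimulus response).
    ``amp``/``latency`` override the spec means, e.g. with per-subject draws.
    """
    if spec.width <= 0:
        raise ValueError("component width must be positive")
    t = np.asarray(times, dtype=float)
    a = spec.amp_mean if amp is None else amp
    lat = spec.latency_mean if latency is None else latency
    wave = a * np.exp(-((t - lat) ** 2) / (2.0 * spec.width**2))
    wave[t < 0] = 0.0
    return wave


def composite_template(specs: Sequence[ComponentSpec], times: np.ndarray,
                       amps: Sequence[float] | None = None,
                       latencies: Sequence[float] | None = None) -> np.ndarray:
    """Sum of component templates (a subject's noise-free response shape)."""
    t = np.asarray(times, dtype=float)
    out = np.zeros_like(t)
    for i, spec in enumerate(specs):
        out += component_template(
            spec, t,
            amp=None if amps is None else amps[i],
            latency=None if latencies is None else latencies[i],
        )
    return out


def _spread_pattern(k: int) -> np.ndarray:
    """Zero-mean, unit-population-SD gain pattern with minimal peak value.

    Even k: alternating +/-1.  Odd k: alternating with one zero entry,
    rescaled to unit SD.
    """
    u = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(k)])
    if k % 2 == 1:
        u[-1] = 0.0
    u -= u.mean()
    sd = float(np.sqrt(np.mean(u**2)))
    return u / sd


def calibrate_gain_spread(roi: RoiSpec | int, template: np.ndarray,
                          times: np.ndarray, window: TimeWindow,
                          target_lmfp: float) -> np.ndarray:
    """Per-channel gains whose noise-free LMFP equals ``target_lmfp``.

    With every ROI channel j carrying ``g_j * s(t)``, the across-channel SD
    at sample i is ``sd_pop(g) * |s(i)|``, so the window-averaged LMFP is
    ``sd_pop(g) * mean_i |s(i)|``.  The returned gains have mean exactly 1
    (preserving the ROI-average waveform) and population SD
    ``target_lmfp / mean_i |s(i)|``.  When the required dispersion exceeds
    1, some gains go negative: the component's polarity inverts across the
    region, as it does near the zero line of a dipolar scalp field.

    Parameters
    ----------
    roi
        ROI spec (its channel count is used) or the channel count directly.
    template
        Noise-free ROI-average waveform s(t) on ``times`` (the full
        composite of all components the subject carries).
    window
        Time window over which the LMFP target must hold.
    target_lmfp
        Desired noise-free LMFP in microvolts (>= 0).
    """
    k = roi if isinstance(roi, int) else len(roi.channels)
    if k < 2:
        raise ValueError("gain-spread calibration needs at least 2 ROI channels")
    if target_lmfp < 0:
        raise ValueError("target_lmfp must be nonnegative")
    if target_lmfp == 0:
        return np.ones(k)
    mean_abs = float(np.mean(np.abs(np.asarray(template)[window.mask(times)])))
    if mean_abs == 0:
        raise ValueError("all-zero template in window: LMFP target unreachable")
    u = _spread_pattern(k)
    sigma = target_lmfp / mean_abs
    return 1.0 + sigma * u


def measured_template(template: np.ndarray, times: np.ndarray, sfreq: float,
                      smooth_len: int = 20) -> np.ndarray:
    """A waveform as the default measurement chain would see it.

    Applies baseline correction, pulse-window interpolation, the zero-phase
    band-pass/band-stop filters and the Gaussian trace smoothing to a single
    noise-free waveform.  Re-referencing is omitted: the default topography
    is average-reference-neutral, so the reference leaves ROI means intact.
    Used to express calibration targets in the space where features are
    actually measured (the zero-phase 1 Hz high-pass alone rescales window
    statistics by several percent).
    """
    from scipy import ndimage

    from .features import gaussian_kernel

    layout1 = ChannelLayout(("cal",), np.zeros((1, 2)))
    cfg = _prep.PrepConfig()
    ep = EpochSet(np.asarray(template, dtype=float)[None, None, :],
                  times, sfreq, layout1)
    ep = _prep.baseline_correct(ep, cfg.baseline_window)
    ep = _prep.interpolate_pulse(ep, cfg.pulse_window, cfg.pulse_flank)
    ep = _prep.filter_epochs(ep, cfg.bandpass, cfg.bandstop, cfg.filter_order)
    out = ep.data[0, 0]
    if smooth_len > 1:
        out = ndimage.correlate1d(out, gaussian_kernel(smooth_len),
                                  mode="nearest")
    return out


def focal_gain_map(layout: ChannelLayout, roi: RoiSpec, sigma: float = 0.15,
                   reference_neutral: bool = True) -> np.ndarray:
    """Spatial gain topography focused on ``roi``.

    A Gaussian profile (spatial scale ``sigma`` in layout units) centred on
    the ROI centroid, normalized so the mean gain over the ROI channels is
    exactly 1.  With ``reference_neutral`` (the default) the scalp-mean gain
    is subtracted first, leaving a weak negative far-field lobe: scalp
    potentials in common-average reference sum to zero by construction, so
    a reference-neutral topography keeps average re-referencing from
    eroding the ROI-average amplitude the components were calibrated to.
    """
    idx = layout.indices(roi.channels)
    centre = layout.pos2d[idx].mean(axis=0)
    d2 = np.sum((layout.pos2d - centre) ** 2, axis=1)
    g = np.exp(-d2 / (2.0 * sigma**2))
    if reference_neutral:
        g = g - g.mean()
    return g / g[idx].mean()


def _shaped_noise(rng: np.random.Generator, shape: tuple[int, ...],
                  sfreq: float, alpha: float, noise_sd: float) -> np.ndarray:
    """1/f^alpha-shaped Gaussian noise with per-sample SD ``noise_sd``."""
    n = shape[-1]
    nfft = 1 << max(1, math.ceil(math.log2(n)))
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, n=nfft, axis=-1)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sfreq)
    scale = np.ones_like(freqs)
    nz = freqs >= 1.0
    scale[nz] = freqs[nz] ** (-alpha / 2.0)
    scale[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * scale, n=nfft, axis=-1)[..., :n]
    sd = shaped.std()
    if sd > 0:
        shaped *= noise_sd / sd
    return shaped


def _draw_subject(group: str, params: GenParams, rng: np.random.Generator) -> dict:
    """Draw the per-subject generating parameters (no epochs)."""
    if group not in params.components:
        raise ValueError(f"unknown group label {group!r}")
    specs = params.components[group]
    draws = {
        spec.name: {
            "amp": float(rng.normal(spec.amp_mean, spec.amp_sd)),
            "latency": float(rng.normal(spec.latency_mean, spec.latency_sd)),
        }
        for spec in specs
    }
    truth: dict = {"components": draws}
    if params.lmfp_target is not None:
        mean, sd = params.lmfp_target[group]
        truth["lmfp_target"] = max(0.0, float(rng.normal(mean, sd)))
    return truth


def simulate_subject(group: str, params: GenParams, subject_seed: int,
                     subject_id: str | None = None) -> SubjectRecord:
    """Simulate one subject's epochs.

    Component amplitudes/latencies are drawn once per subject; each trial is
    the resulting multi-channel response plus independent shaped noise.
    With ``noise_sd = 0`` and unit ROI gains the ROI-average of the trial
    mean carries its window extremum exactly at the drawn latency/amplitude.
    """
    rng = np.random.default_rng(subject_seed)
    truth = _draw_subject(group, params, rng)
    specs = params.components[group]
    times = params.times()
    layout = params.layout
    n_ch = len(layout)

    cal_roi = ROIS[params.calibration_roi]
    cal_win = TIME_WINDOWS[params.calibration_window]
    roi_idx = layout.indices(cal_roi.channels)

    amps = [truth["components"][s.name]["amp"] for s in specs]
    lats = [truth["components"][s.name]["latency"] for s in specs]

    # Per-component channel gains: explicit map, or a shared focal topography.
    if params.gain_map is not None:
        gains = {s.name: np.asarray(params.gain_map[s.name], dtype=float)
                 for s in specs}
    else:
        topo = focal_gain_map(layout, cal_roi, params.topo_sigma)
        gains = {s.name: topo.copy() for s in specs}

    # Calibrated within-ROI gain dispersion: shared across components so the
    # ROI signal is exactly (1 + sigma*u_j) * s(t), making the noise-free
    # LMFP separable and equal to the drawn target.  The dispersion is set
    # against the template as the measurement chain sees it, so the target
    # refers to the extracted feature, not to the pre-filter waveform.
    if params.lmfp_target is not None:
        s_roi = composite_template(specs, times, amps=amps, latencies=lats)
        s_meas = measured_template(s_roi, times, params.sfreq)
        g_roi = calibrate_gain_spread(cal_roi, s_meas, times, cal_win,
                                      truth["lmfp_target"])
        truth["gain_sd"] = float(np.sqrt(np.mean((g_roi - 1.0) ** 2)))
        for g in gains.values():
            g[roi_idx] = g_roi

    signal = np.zeros((n_ch, times.size))
    for spec, a, lat in zip(specs, amps, lats):
        signal += np.outer(gains[spec.name],
                           component_template(spec, times, amp=a, latency=lat))

    if params.per_trial_jitter > 0:
        data = np.empty((params.n_trials, n_ch, times.size))
        for tr in range(params.n_trials):
            tr_sig = np.zeros((n_ch, times.size))
            for spec, a, lat in zip(specs, amps, lats):
                jlat = lat + rng.normal(0.0, params.per_trial_jitter)
                tr_sig += np.outer(gains[spec.name],
                                   component_template(spec, times, amp=a, latency=jlat))
            data[tr] = tr_sig
    else:
        data = np.broadcast_to(signal, (params.n_trials, n_ch, times.size)).copy()

    if params.noise_sd > 0:
        data += _shaped_noise(rng, data.shape, params.sfreq,
                              params.background, params.noise_sd)

    epochs = EpochSet(data=data, times=times, sfreq=params.sfreq, layout=layout)
    sid = subject_id if subject_id is not None else f"{group}-{subject_seed}"
    return SubjectRecord(subject_id=sid, group=group, epochs=epochs,
                         seed=subject_seed, truth=truth)


def simulate_group(group: str, n_subjects: int, params: GenParams) -> Cohort:
    """Simulate a single-group cohort (e.g. for parameter-recovery studies)."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    master = np.random.default_rng(params.seed)
    seeds = master.integers(0, 2**31 - 1, size=n_subjects)
    return Cohort([
        simulate_subject(group, params, int(seeds[i]),
                         subject_id=f"{group}{i + 1:03d}")
        for i in range(n_subjects)
    ])


def simulate_cohort(n_ci: int, n_hc: int, params: GenParams) -> Cohort:
    """Simulate a two-group cohort with deterministic per-subject seeds."""
    if n_ci < 1 or n_hc < 1:
        raise ValueError("both groups need at least one subject")
    master = np.random.default_rng(params.seed)
    n = n_ci + n_hc
    seeds = master.integers(0, 2**31 - 1, size=n)
    while len(np.unique(seeds)) < n:  # pragma: no cover - vanishingly rare
        seeds = master.integers(0, 2**31 - 1, size=n)
    subjects = []
    for i in range(n_ci):
        subjects.append(simulate_subject("CI", params, int(seeds[i]),
                                         subject_id=f"CI{i + 1:03d}"))
    for i in range(n_hc):
        subjects.append(simulate_subject("HC", params, int(seeds[n_ci + i]),
                                         subject_id=f"HC{i + 1:03d}"))
    return Cohort(subjects)
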