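"""Deterministic epoch preprocessing.

Fixed stage order: baseline correction, pulse-window cubic interpolation,
downsampling, zero-phase band-pass + band-stop filtering, common-average
re-referencing.  All stages are pure functions of (epochs, config) and
preserve the (trials, channels) shape.

Artifact-removal stages that require operator judgement on real data
(ICA rounds, visual epoch/channel rejection, spherical channel
interpolation) are intentionally not part of this pipeline; the config
carries a provenance note naming them so downstream reports can state
what was bypassed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .containers import EpochSet

__all__ = [
    "PrepConfig",
    "baseline_correct",
    "interpolate_pulse",
    "resample",
    "filter_epochs",
    "rereference_average",
    "preprocess",
]

SKIPPED_STAGES = (
    "ICA artifact removal (both rounds)",
    "visual epoch/channel rejection",
    "spherical interpolation of removed channels",
)


@dataclass(frozen=True)
class PrepConfig:
    """Preprocessing parameters (seconds / Hz)."""

    baseline_window: tuple[float, float] = (-0.500, -0.050)
    pulse_window: tuple[float, float] = (-0.005, 0.015)
    target_sfreq: float = 1000.0
    bandpass: tuple[float, float] = (1.0, 80.0)
    bandstop: tuple[float, float] = (48.0, 52.0)
    reference: str = "common_average"
    pulse_flank: float = 0.020
    filter_order: int = 4
    note: tuple[str, ...] = field(default=SKIPPED_STAGES)

    def __post_init__(self) -> None:
        if not self.baseline_window[1] <= 0:
            raise ValueError("baseline window must be entirely pre-stimulus")
        if not self.pulse_window[0] <= 0 <= self.pulse_window[1]:
            raise ValueError("pulse window must contain the stimulus at t=0")
        if not (self.bandpass[0] < self.bandstop[0]
                and self.bandstop[1] < self.bandpass[1]):
            raise ValueError("bandstop must lie inside the bandpass")
        if self.reference != "common_average":
            raise ValueError("only common_average referencing is supported")


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    eps = 1e-9
    return (times >= window[0] - eps) & (times <= window[1] + eps)


def baseline_correct(epochs: EpochSet,
                     window: tuple[float, float] = (-0.500, -0.050)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    mask = _window_mask(epochs.times, window)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.with_data(epochs.data - base)


def interpolate_pulse(epochs: EpochSet,
                      window: tuple[float, float] = (-0.005, 0.015),
                      flank: float = 0.020) -> EpochSet:
    """Replace samples in the pulse window with a least-squares cubic bridge.

    A single cubic polynomial is fit jointly to ``flank`` seconds of data on
    each side of the removed window and evaluated inside it; samples outside
    the window are untouched.
    """
    t = epochs.times
    inside = _window_mask(t, window)
    if not inside.any():
        return epochs
    left = _window_mask(t, (window[0] - flank, window[0])) & ~inside
    right = _window_mask(t, (window[1], window[1] + flank)) & ~inside
    if left.sum() < 4 or right.sum() < 4:
        raise ValueError("insufficient flank samples for cubic interpolation")
    flank_mask = left | right
    centre = 0.5 * (window[0] + window[1])
    # Centre and scale the abscissa for conditioning.
    tf = (t[flank_mask] - centre) / flank
    ti = (t[inside] - centre) / flank
    A = np.vander(tf, 4)
    Ain = np.vander(ti, 4)
    y = epochs.data[:, :, flank_mask].reshape(-1, flank_mask.sum()).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = (Ain @ coef).T.reshape(epochs.data.shape[0], epochs.data.shape[1], -1)
    out = epochs.data.copy()
    out[:, :, inside] = fitted
    return epochs.with_data(out)


def resample(epochs: EpochSet, target_sfreq: float) -> EpochSet:
    """Polyphase resampling (with anti-alias filtering) to ``target_sfreq``."""
    if target_sfreq > epochs.sfreq:
        raise ValueError("upsampling is not supported")
    if target_sfreq == epochs.sfreq:
        return epochs
    frac = Fraction(target_sfreq / epochs.sfreq).limit_denominator(1000)
    data = sps.resample_poly(epochs.data, frac.numerator, frac.denominator, axis=2)
    times = epochs.times[0] + np.arange(data.shape[2]) / target_sfreq
    return epochs.with_data(data, times=times, sfreq=target_sfreq)


def _design(order: int, band: tuple[float, float], btype: str, sfreq: float):
    nyq = sfreq / 2.0
    if band[1] >= nyq:
        raise ValueError(f"band edge {band[1]} Hz at or above Nyquist {nyq} Hz")
    return sps.butter(order, band, btype=btype, fs=sfreq, output="sos")


def filter_epochs(epochs: EpochSet,
                  bandpass: tuple[float, float] = (1.0, 80.0),
                  bandstop: tuple[float, float] = (48.0, 52.0),
                  order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass then band-stop filtering.

    Both filters are applied forward-backward (``sosfiltfilt``), which
    doubles the effective order and removes group delay -- peak latencies
    are a downstream feature, so phase distortion is not acceptable.
    """
    sos_bp = _design(order, bandpass, "bandpass", epochs.sfreq)
    sos_bs = _design(order, bandstop, "bandstop", epochs.sfreq)
    out = sps.sosfiltfilt(sos_bp, epochs.data, axis=2)
    out = sps.sosfiltfilt(sos_bs, out, axis=2)
    return epochs.with_data(out)


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Re-reference to the common average: per-sample channel mean becomes 0."""
    if epochs.data.shape[1] < 2:
        raise ValueError("average reference needs at least 2 channels")
    mean = epochs.data.mean(axis=1, keepdims=True)
    return epochs.with_data(epochs.data - mean)


def preprocess(epochs: EpochSet, config: PrepConfig | None = None) -> EpochSet:
    """Run the full preprocessing chain in its fixed order."""
    cfg = config or PrepConfig()
    out = baseline_correct(epochs, cfg.baseline_window)
    out = interpolate_pulse(out, cfg.pulse_window, cfg.pulse_flank)
    if out.sfreq != cfg.target_sfreq:
        out = resample(out, cfg.target_sfreq)
    out = filter_epochs(out, cfg.bandpass, cfg.bandstop, cfg.filter_order)
    out = rereference_average(out)
    return out
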