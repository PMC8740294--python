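"""TEP averaging, smoothing, field power, and windowed linear features.

Each subject's trials are split into three fixed segments (a simple
augmentation that triples the rows available to the classifier), each
segment is averaged into a TEP trace and smoothed with a short Gaussian
window, and seven features are computed per (time window, ROI):

``LMFP``      mean over window samples of the across-ROI-channel SD (uV)
``STD``       population SD of the ROI-average signal in the window (uV)
``Latency``   time of the window extremum (s); minimum for N100, maximum
              for P200 (component polarity is known a priori)
``Amplitude`` signed value at that extremum (uV)
``AVG``       window mean of the ROI-average signal (uV)
``AUC``       signed trapezoid area between signal and time axis (uV*s)
``Range``     max - min of the ROI-average signal in the window (uV)

Two windows x seven ROIs x seven features = 98 columns per segment row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import windows as spw

from .containers import Cohort, EpochSet, RoiTrace, TepTrace
from .montage import ROI_ORDER, ROIS, TIME_WINDOWS, WINDOW_ORDER, RoiSpec, TimeWindow

__all__ = [
    "FEATURE_ORDER",
    "PeakResult",
    "segment_trials",
    "average_trials",
    "gaussian_smooth",
    "gmfp",
    "roi_average",
    "feat_latency_amplitude",
    "feat_lmfp",
    "feat_std",
    "feat_auc",
    "feat_avg",
    "feat_range",
    "feature_columns",
    "build_feature_table",
]

FEATURE_ORDER = ("LMFP", "STD", "Latency", "Amplitude", "AVG", "AUC", "Range")


def segment_trials(epochs: EpochSet) -> tuple[EpochSet, EpochSet, EpochSet]:
    """Split trials (in recorded order) into the three fixed segments.

    With >= 61 trials the boundaries are trials 1-30, 31-60, 61-end.  With
    fewer trials the boundaries clip to ``min(30, n-2)`` and ``min(60, n-1)``
    so that all three segments stay nonempty.
    """
    n = epochs.n_trials
    if n < 3:
        raise ValueError(f"segmentation needs at least 3 trials, got {n}")
    b1 = min(30, n - 2)
    b2 = min(60, n - 1)
    return (
        epochs.with_data(epochs.data[:b1]),
        epochs.with_data(epochs.data[b1:b2]),
        epochs.with_data(epochs.data[b2:]),
    )


def average_trials(epochs: EpochSet) -> TepTrace:
    """Time-locked average across trials (the TEP trace)."""
    if epochs.n_trials < 1:
        raise ValueError("cannot average zero trials")
    return TepTrace(
        data=epochs.data.mean(axis=0),
        times=epochs.times,
        sfreq=epochs.sfreq,
        layout=epochs.layout,
        smoothed=False,
    )


def gaussian_kernel(window_len: int = 20) -> np.ndarray:
    """Unit-sum Gaussian smoothing kernel, sigma = (L-1)/5 samples."""
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if window_len == 1:
        return np.ones(1)
    k = spw.gaussian(window_len, std=(window_len - 1) / 5.0)
    return k / k.sum()


def gaussian_smooth(trace: TepTrace, window_len: int = 20) -> TepTrace:
    """Convolve each channel with a unit-sum Gaussian window.

    Edges are handled by nearest-value extension, so constant signals pass
    through unchanged.  An even window length shifts the effective kernel
    centre by half a sample (half a millisecond at 1 kHz).
    """
    if window_len > trace.data.shape[1]:
        raise ValueError("smoothing window longer than the trace")
    k = gaussian_kernel(window_len)
    out = ndimage.correlate1d(trace.data, k, axis=1, mode="nearest")
    return TepTrace(data=out, times=trace.times, sfreq=trace.sfreq,
                    layout=trace.layout, smoothed=True)


def gmfp(trace: TepTrace) -> np.ndarray:
    """Global mean field power: per-sample SD across all channels (uV)."""
    if trace.data.shape[0] < 2:
        raise ValueError("GMFP needs at least 2 channels")
    return trace.data.std(axis=0, ddof=0)


def roi_average(trace: TepTrace, roi: RoiSpec) -> RoiTrace:
    """Unweighted mean of the ROI's channel rows."""
    idx = trace.layout.indices(roi.channels)
    return RoiTrace(x=trace.data[idx].mean(axis=0), times=trace.times,
                    sfreq=trace.sfreq, roi=roi, smoothed=trace.smoothed)


@dataclass(frozen=True)
class PeakResult:
    latency: float
    amplitude: float
    edge_peak: bool


def feat_latency_amplitude(roi_trace: RoiTrace, window: TimeWindow) -> PeakResult:
    """Latency (s) and signed amplitude (uV) of the window extremum.

    The N100 window takes the minimum (negative component), the P200 window
    the maximum.  An extremum falling on a window edge is accepted but
    flagged ``edge_peak``.
    """
    mask = window.mask(roi_trace.times)
    x = roi_trace.x[mask]
    t = roi_trace.times[mask]
    i = int(np.argmin(x)) if window.name == "N100" else int(np.argmax(x))
    return PeakResult(latency=float(t[i]), amplitude=float(x[i]),
                      edge_peak=i in (0, x.size - 1))


def feat_lmfp(trace: TepTrace, roi: RoiSpec, window: TimeWindow) -> float:
    """Local mean field power (uV).

    Per window sample, the population SD of the ROI channels around the
    across-ROI-channel mean; averaged over the window's samples.
    """
    idx = trace.layout.indices(roi.channels)
    if idx.size < 2:
        raise ValueError("LMFP needs at least 2 ROI channels")
    mask = window.mask(trace.times)
    v = trace.data[np.ix_(idx, np.flatnonzero(mask))]
    return float(v.std(axis=0, ddof=0).mean())


def feat_std(roi_trace: RoiTrace, window: TimeWindow) -> float:
    """Population SD of the ROI-average signal over the window (uV)."""
    x = roi_trace.x[window.mask(roi_trace.times)]
    if x.size < 2:
        raise ValueError("STD needs at least 2 window samples")
    return float(x.std(ddof=0))


def feat_auc(roi_trace: RoiTrace, window: TimeWindow,
             f: float | None = None) -> float:
    """Signed trapezoid area between the signal and the time axis (uV*s)."""
    x = roi_trace.x[window.mask(roi_trace.times)]
    if x.size < 2:
        raise ValueError("AUC needs at least 2 window samples")
    sfreq = roi_trace.sfreq if f is None else f
    return float(np.trapezoid(x, dx=1.0 / sfreq))


def feat_avg(roi_trace: RoiTrace, window: TimeWindow) -> float:
    """Window mean of the ROI-average signal (uV)."""
    x = roi_trace.x[window.mask(roi_trace.times)]
    return float(x.mean())


def feat_range(roi_trace: RoiTrace, window: TimeWindow) -> float:
    """Max minus min of the ROI-average signal in the window (uV)."""
    x = roi_trace.x[window.mask(roi_trace.times)]
    return float(x.max() - x.min())


def feature_columns(windows=WINDOW_ORDER, rois=ROI_ORDER) -> list[str]:
    """Deterministic column order: window-major, ROI-second, feature-third."""
    return [f"{w}.{r}.{f}" for w in windows for r in rois for f in FEATURE_ORDER]


def _row_features(trace: TepTrace, windows,
                  roi_map: dict[str, RoiSpec]) -> tuple[dict, list[str]]:
    values: dict[str, float] = {}
    edge_flags: list[str] = []
    for wname in windows:
        win = TIME_WINDOWS[wname] if isinstance(wname, str) else wname
        for roi in roi_map.values():
            rt = roi_average(trace, roi)
            peak = feat_latency_amplitude(rt, win)
            if peak.edge_peak:
                edge_flags.append(f"{win.name}.{roi.name}")
            values[f"{win.name}.{roi.name}.LMFP"] = feat_lmfp(trace, roi, win)
            values[f"{win.name}.{roi.name}.STD"] = feat_std(rt, win)
            values[f"{win.name}.{roi.name}.Latency"] = peak.latency
            values[f"{win.name}.{roi.name}.Amplitude"] = peak.amplitude
            values[f"{win.name}.{roi.name}.AVG"] = feat_avg(rt, win)
            values[f"{win.name}.{roi.name}.AUC"] = feat_auc(rt, win)
            values[f"{win.name}.{roi.name}.Range"] = feat_range(rt, win)
    return values, edge_flags


def build_feature_table(cohort: Cohort, smooth_len: int = 20,
                        windows=WINDOW_ORDER,
                        rois: dict[str, RoiSpec] | None = None) -> pd.DataFrame:
    """Per-(subject, segment) feature table.

    For every subject: segment the (already preprocessed) trials, average
    each segment, smooth, and extract all features for every (window, ROI).
    Returns a DataFrame with ``subject_id``, ``segment``, ``group`` and the
    feature columns in deterministic order; edge-extremum QC flags are kept
    in ``df.attrs["edge_peaks"]``.
    """
    roi_map = ROIS if rois is None else rois
    roi_names = tuple(roi_map)
    cols = [f"{w}.{r}.{f}" for w in windows for r in roi_names
            for f in FEATURE_ORDER]
    rows = []
    edge_log: dict[tuple[str, int], list[str]] = {}
    for subject in cohort:
        try:
            segments = segment_trials(subject.epochs)
            for seg_i, seg in enumerate(segments, start=1):
                trace = gaussian_smooth(average_trials(seg), smooth_len)
                values, flags = _row_features(trace, windows, roi_map)
                if flags:
                    edge_log[(subject.subject_id, seg_i)] = flags
                rows.append({"subject_id": subject.subject_id,
                             "segment": seg_i,
                             "group": subject.group,
                             **values})
        except ValueError as err:
            raise ValueError(
                f"feature extraction failed for subject "
                f"{subject.subject_id}: {err}") from err
    df = pd.DataFrame(rows, columns=["subject_id", "segment", "group"] + cols)
    df.attrs["edge_peaks"] = edge_log
    return df
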