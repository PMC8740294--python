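"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .montage import ChannelLayout, RoiSpec

__all__ = ["EpochSet", "TepTrace", "RoiTrace", "SubjectRecord", "Cohort"]


@dataclass(frozen=True)
class EpochSet:
    """Epoched multi-channel EEG data.

    Attributes
    ----------
    data
        ``(n_trials, n_channels, n_samples)`` array in microvolts.
    times
        Per-sample times in seconds, stimulus at 0; strictly increasing and
        uniformly spaced at ``1/sfreq``.
    sfreq
        Sampling rate in Hz.
    layout
        Channel layout; its size must match the channel axis.
    """

    data: np.ndarray = field(repr=False)
    times: np.ndarray = field(repr=False)
    sfreq: float
    layout: ChannelLayout

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        times = np.asarray(self.times, dtype=float)
        if data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if data.shape[1] != len(self.layout):
            raise ValueError(
                f"{data.shape[1]} channels in data, {len(self.layout)} in layout"
            )
        if data.shape[2] != times.size:
            raise ValueError("times length must match the sample axis")
        dt = np.diff(times)
        if times.size > 1:
            if not (dt > 0).all():
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.sfreq, rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniform at 1/sfreq")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "times", times)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def with_data(self, data: np.ndarray, times: np.ndarray | None = None,
                  sfreq: float | None = None) -> "EpochSet":
        """Copy of this epoch set with replaced data (and optionally time axis)."""
        return replace(
            self,
            data=data,
            times=self.times if times is None else times,
            sfreq=self.sfreq if sfreq is None else sfreq,
        )


@dataclass(frozen=True)
class TepTrace:
    """A trial-averaged TMS-evoked potential: channels x samples."""

    data: np.ndarray = field(repr=False)
    times: np.ndarray = field(repr=False)
    sfreq: float
    layout: ChannelLayout
    smoothed: bool = False

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("trace data must be channels x samples")
        if data.shape[0] != len(self.layout):
            raise ValueError("trace channel count does not match layout")
        if data.shape[1] != np.asarray(self.times).size:
            raise ValueError("times length must match the sample axis")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))


@dataclass(frozen=True)
class RoiTrace:
    """The unweighted channel-mean time course of one region of interest."""

    x: np.ndarray = field(repr=False)
    times: np.ndarray = field(repr=False)
    sfreq: float
    roi: RoiSpec
    smoothed: bool = False

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 1:
            raise ValueError("ROI trace must be a 1-D sample vector")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))


@dataclass
class SubjectRecord:
    """One subject's epochs plus metadata.

    ``truth`` records the generating parameters for simulated subjects
    (per-component amplitude/latency draws, the calibrated gain dispersion);
    it is empty for imported data.
    """

    subject_id: str
    group: str
    epochs: EpochSet
    seed: int | None = None
    truth: dict[str, Any] = field(default_factory=dict)


@dataclass
class Cohort:
    """An ordered collection of subjects with unique ids."""

    subjects: list[SubjectRecord]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def groups(self) -> list[str]:
        return [s.group for s in self.subjects]
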