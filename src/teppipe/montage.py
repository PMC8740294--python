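"""Channel layout, regions of interest, and analysis time windows.

The default montage is a 62-channel recording set from a 64-channel
10/20-extended cap (the reference FCz and ground AFz do not record).
Positions are planar head-circle coordinates (unitless): the anterior-
posterior axis maps electrode rows (Fp ... O, Iz) to y, and the
left-right axis maps electrode numbers to x (odd = left, even = right,
z = midline).  They are adequate for neighbourhood computations, not
for topographic rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelLayout",
    "RoiSpec",
    "TimeWindow",
    "ROIS",
    "ROI_ORDER",
    "TIME_WINDOWS",
    "WINDOW_ORDER",
    "make_default_layout",
    "make_roi_layout",
]


@dataclass(frozen=True)
class ChannelLayout:
    """An ordered set of EEG channels with planar positions.

    Parameters
    ----------
    names
        Unique channel labels on the extended 10/20 system.
    pos2d
        ``(n_channels, 2)`` array of planar coordinates, head-circle
        normalized (unitless).
    """

    names: tuple[str, ...]
    pos2d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        pos = np.asarray(self.pos2d, dtype=float)
        if pos.shape != (len(self.names), 2):
            raise ValueError(
                f"pos2d shape {pos.shape} does not match {len(self.names)} channels"
            )
        object.__setattr__(self, "pos2d", pos)

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in layout") from None

    def indices(self, names) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)

    def subset(self, names) -> "ChannelLayout":
        idx = self.indices(names)
        return ChannelLayout(tuple(names), self.pos2d[idx])


@dataclass(frozen=True)
class RoiSpec:
    """A named region of interest: a fixed set of scalp electrodes."""

    name: str
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.channels) == 0:
            raise ValueError("ROI must contain at least one channel")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("ROI channels must be unique")


@dataclass(frozen=True)
class TimeWindow:
    """A named analysis window (seconds, stimulus at t = 0)."""

    name: str
    span: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.span[1] > self.span[0]:
            raise ValueError("window end must exceed start")

    def mask(self, times: np.ndarray) -> np.ndarray:
        """Boolean sample mask, inclusive of both endpoint samples."""
        t = np.asarray(times)
        eps = 1e-9
        m = (t >= self.span[0] - eps) & (t <= self.span[1] + eps)
        if not m.any():
            raise ValueError(f"window {self.name} contains no samples")
        return m


# Seven regions of interest: left/right frontal, central, centroparietal,
# left/right parietal, occipital.
ROI_ORDER = ("Fl", "Fr", "C", "Cp", "Pl", "Pr", "O")

ROIS: dict[str, RoiSpec] = {
    "Fl": RoiSpec("Fl", ("F1", "F3", "FC3", "FC5")),
    "Fr": RoiSpec("Fr", ("F2", "F4", "FC4", "FC6")),
    "C": RoiSpec("C", ("Cz", "C1", "C2")),
    "Cp": RoiSpec("Cp", ("CPz", "CP1", "CP2", "Pz", "P1", "P2")),
    "Pl": RoiSpec("Pl", ("CP3", "CP5", "P3", "P5")),
    "Pr": RoiSpec("Pr", ("CP4", "CP6", "P4", "P6")),
    "O": RoiSpec("O", ("Oz", "O1", "O2")),
}

# N100: negative component, 100-160 ms; P200: positive component, 180-280 ms.
WINDOW_ORDER = ("N100", "P200")

TIME_WINDOWS: dict[str, TimeWindow] = {
    "N100": TimeWindow("N100", (0.100, 0.160)),
    "P200": TimeWindow("P200", (0.180, 0.280)),
}

# (row label, y, entries).  Entries are (suffix, x).  Midline channels use
# suffix "z" at x = 0; numbers grow laterally in steps of 0.2.
_GRID: list[tuple[str, float, list[tuple[str, float]]]] = [
    ("Fp", 0.8, [("1", -0.2), ("z", 0.0), ("2", 0.2)]),
    ("AF", 0.6, [("7", -0.8), ("3", -0.4), ("4", 0.4), ("8", 0.8)]),
    ("F", 0.4, [("7", -0.8), ("5", -0.6), ("3", -0.4), ("1", -0.2), ("z", 0.0),
                ("2", 0.2), ("4", 0.4), ("6", 0.6), ("8", 0.8)]),
    ("FC", 0.2, [("5", -0.6), ("3", -0.4), ("1", -0.2),
                 ("2", 0.2), ("4", 0.4), ("6", 0.6)]),
    ("C", 0.0, [("5", -0.6), ("3", -0.4), ("1", -0.2), ("z", 0.0),
                ("2", 0.2), ("4", 0.4), ("6", 0.6)]),
    ("CP", -0.2, [("5", -0.6), ("3", -0.4), ("1", -0.2), ("z", 0.0),
                  ("2", 0.2), ("4", 0.4), ("6", 0.6)]),
    ("P", -0.4, [("7", -0.8), ("5", -0.6), ("3", -0.4), ("1", -0.2), ("z", 0.0),
                 ("2", 0.2), ("4", 0.4), ("6", 0.6), ("8", 0.8)]),
    ("PO", -0.6, [("7", -0.8), ("3", -0.4), ("z", 0.0), ("4", 0.4), ("8", 0.8)]),
    ("O", -0.8, [("1", -0.2), ("z", 0.0), ("2", 0.2)]),
]

# Temporal-line channels that sit on the FC/C/CP rows at |x| = 0.8, plus the
# inferior FT9/FT10 pair and inion Iz; completes the 62-channel set.
_EXTRA: list[tuple[str, float, float]] = [
    ("FT7", -0.8, 0.2), ("FT8", 0.8, 0.2),
    ("FT9", -1.0, 0.2), ("FT10", 1.0, 0.2),
    ("T7", -0.8, 0.0), ("T8", 0.8, 0.0),
    ("TP7", -0.8, -0.2), ("TP8", 0.8, -0.2),
    ("Iz", 0.0, -1.0),
]


def make_default_layout() -> ChannelLayout:
    """Build the default 62-channel recording layout.

    Includes every channel used by the seven ROIs plus the stimulation-site
    electrode F3; excludes the cap's reference (FCz) and ground (AFz).
    """
    names: list[str] = []
    pos: list[tuple[float, float]] = []
    for row, y, entries in _GRID:
        for suffix, x in entries:
            names.append(row + suffix)
            pos.append((x, y))
    for name, x, y in _EXTRA:
        names.append(name)
        pos.append((x, y))
    return ChannelLayout(tuple(names), np.array(pos))


def make_roi_layout() -> ChannelLayout:
    """Compact 26-channel layout: the 25 ROI channels plus F3.

    A smaller montage with the same feature surface as the default layout,
    convenient when simulation cost matters more than full-scalp coverage.
    """
    full = make_default_layout()
    wanted = ["F3"]
    for roi in ROI_ORDER:
        for ch in ROIS[roi].channels:
            if ch not in wanted:
                wanted.append(ch)
    return full.subset(wanted)
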