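"""Core container for plantar-pressure recordings.

A recording is a time series of 8x8 pressure grids (kPa) sampled at a fixed
rate, tagged with the subject it came from, the gait class and the
acquisition section (dynamic walking vs. static standing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Grid geometry of the insole sensor array.
GRID_SHAPE = (8, 8)

#: Canonical class order used everywhere (tables, confusion matrices, CLI).
CLASS_ORDER = ("normal", "toe_in", "toe_out", "flat")

SECTIONS = ("dynamic", "static")


@dataclass
class PressureRecording:
    """Timestamped sequence of 8x8 non-negative pressure grids.

    Parameters
    ----------
    frames : ndarray, shape (T, 8, 8)
        Pressure in kPa, non-negative and finite.
    fs : float
        Sampling rate in Hz.
    subject_id : str
        Identifier of the recorded subject.
    label : str
        Gait class, one of ``CLASS_ORDER``.
    section : str
        ``"dynamic"`` (walking) or ``"static"`` (standing).
    t0 : float
        Timestamp of the first frame, seconds.
    meta : dict
        Free-form extra metadata (mass, cadence, foot progression angle...).
    """

    frames: np.ndarray
    fs: float
    subject_id: str
    label: str
    section: str
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != GRID_SHAPE:
            raise ValueError(
                f"frames must have shape (T, 8, 8), got {self.frames.shape}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite pressures")
        if np.any(self.frames < 0):
            raise ValueError("frames contain negative pressures")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.label not in CLASS_ORDER:
            raise ValueError(f"unknown gait label {self.label!r}")
        if self.section not in SECTIONS:
            raise ValueError(f"unknown section {self.section!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames / self.fs

    def times(self) -> np.ndarray:
        """Per-frame timestamps in seconds."""
        return self.t0 + np.arange(self.n_frames) / self.fs
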