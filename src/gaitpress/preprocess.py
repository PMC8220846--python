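"""Filtering and windowing of raw recordings before feature extraction.

The One Euro filter is a first-order adaptive low-pass used for display
smoothing of streaming pressure data: the cutoff rises linearly with the
(filtered) signal speed, giving low jitter on slow signals and low lag on
fast ones.  It is optional in the classification pipeline and off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import PressureRecording


@dataclass(frozen=True)
class OneEuroParams:
    min_cutoff: float = 1.0  # Hz
    beta: float = 0.05  # cutoff increase per unit speed
    d_cutoff: float = 1.0  # Hz, cutoff of the derivative smoother

    def __post_init__(self) -> None:
        if not self.min_cutoff > 0:
            raise ValueError("min_cutoff must be positive")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not self.d_cutoff > 0:
            raise ValueError("d_cutoff must be positive")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding analysis window; 512 frames at 50 Hz spans ~10 gait periods."""

    width: int = 512
    stride: int = 25
    window_fn: str = "hanning"

    def __post_init__(self) -> None:
        if self.width < 2:
            raise ValueError("width must be >= 2")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def _alpha(cutoff: float, fs: float) -> float:
    """Single-pole smoothing coefficient for cutoff (Hz) at rate fs."""
    return 1.0 / (1.0 + fs / (2.0 * np.pi * cutoff))


def one_euro_filter(
    series, fs: float, params: OneEuroParams = OneEuroParams()
) -> np.ndarray:
    """Causal adaptive low-pass of a 1-D series.

    Per sample the derivative estimate is low-passed at ``d_cutoff``, then
    the signal is low-passed with cutoff ``min_cutoff + beta * |dx|``.  The
    first sample passes through unchanged; with ``beta = 0`` this is a
    fixed-cutoff exponential smoother.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("series must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite samples")
    if fs <= 0:
        raise ValueError("fs must be positive")
    out = np.empty_like(x)
    a_d = _alpha(params.d_cutoff, fs)
    prev = x[0]
    dx_hat = 0.0
    out[0] = x[0]
    for i in range(1, x.size):
        dx = (x[i] - prev) * fs
        dx_hat = a_d * dx + (1.0 - a_d) * dx_hat
        cutoff = params.min_cutoff + params.beta * abs(dx_hat)
        a = _alpha(cutoff, fs)
        prev = a * x[i] + (1.0 - a) * prev
        out[i] = prev
    return out


def filter_recording(
    rec: PressureRecording, params: OneEuroParams = OneEuroParams()
) -> PressureRecording:
    """Apply the One Euro filter independently to every cell's time series."""
    frames = rec.frames.reshape(rec.n_frames, -1)
    filtered = np.column_stack(
        [one_euro_filter(frames[:, j], rec.fs, params) for j in range(frames.shape[1])]
    ).reshape(rec.frames.shape)
    return PressureRecording(
        np.clip(filtered, 0.0, None),
        rec.fs,
        rec.subject_id,
        rec.label,
        rec.section,
        rec.t0,
        dict(rec.meta),
    )


def n_windows(length: int, spec: WindowSpec) -> int:
    """Closed-form sliding-window count: floor((L - width)/stride) + 1."""
    if length < spec.width:
        return 0
    return (length - spec.width) // spec.stride + 1


def sliding_windows(series: np.ndarray, spec: WindowSpec = WindowSpec()):
    """Slice aligned windows out of a frame series.

    ``series`` has time on axis 0 (e.g. shape (T, 8, 8)); yields
    ``(start_frame, segment)`` pairs where each segment is a view of
    ``spec.width`` frames.  Raises if the series is shorter than one
    window.
    """
    series = np.asarray(series)
    length = series.shape[0]
    if length < spec.width:
        raise ValueError(
            f"series too short: {length} frames < window width {spec.width}"
        )
    for w in range(n_windows(length, spec)):
        start = w * spec.stride
        yield start, series[start : start + spec.width]


def static_segments(rec: PressureRecording, segment_length: int):
    """Partition a standing recording into non-overlapping segments.

    Yields ``(start_frame, segment)``; a trailing remainder shorter than
    ``segment_length`` is dropped.  An over-long segment length gives an
    empty result, not an error.
    """
    if rec.section != "static":
        raise ValueError("static_segments requires a static recording")
    if segment_length < 1:
        raise ValueError("segment_length must be >= 1")
    for s in range(rec.n_frames // segment_length):
        start = s * segment_length
        yield start, rec.frames[start : start + segment_length]
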