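"""FFT band-energy feature extraction.

Dynamic (walking) samples: each selected sensor's 512-frame window is Hann
tapered and transformed with the DFT
``S(k) = sum_n t(n) W^{kn}``, ``W = exp(-j 2 pi / L)``; the magnitudes of
the one-sided bins are summed over five 2-Hz bands, (0,2], (2,4], (4,6],
(6,8], (8,10] Hz, with the 0 Hz bin excluded.  The 30 sensors' five-element
vectors are concatenated into a 150-element vector and normalized to unit
L2 norm, which cancels the child's bodyweight.

Static (standing) samples keep only the DC component — the time-mean
pressure of each selected sensor — giving a 30-element unit vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import WindowSpec, sliding_windows, static_segments
from .recording import CLASS_ORDER, GRID_SHAPE, PressureRecording

#: Analysis window length (frames) and hence DFT length.
WINDOW_LENGTH = 512


@dataclass(frozen=True)
class SensorMask:
    """Ordered subset of grid cells used for features (row-major order)."""

    cells: tuple

    def __post_init__(self) -> None:
        cells = tuple((int(r), int(c)) for r, c in self.cells)
        if len(set(cells)) != len(cells):
            raise ValueError("mask cells must be unique")
        for r, c in cells:
            if not (0 <= r < GRID_SHAPE[0] and 0 <= c < GRID_SHAPE[1]):
                raise ValueError(f"cell {(r, c)} outside the 8x8 grid")
        object.__setattr__(self, "cells", cells)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def rows(self) -> np.ndarray:
        return np.array([r for r, _ in self.cells])

    @property
    def cols(self) -> np.ndarray:
        return np.array([c for _, c in self.cells])


def default_mask() -> SensorMask:
    """The 30-cell foot-shaped selection: a 3x2 heel block, two midfoot
    rows of 6, and a 4x4 forefoot block minus its corners (row-major)."""
    cells = []
    cells += [(r, c) for r in (0, 1) for c in (2, 3, 4)]          # heel, 6
    cells += [(r, c) for r in (2, 3) for c in range(1, 7)]        # midfoot, 12
    fore = [(r, c) for r in range(4, 8) for c in range(2, 6)]
    for corner in ((4, 2), (4, 5), (7, 2), (7, 5)):
        fore.remove(corner)
    cells += fore                                                  # forefoot, 12
    return SensorMask(tuple(sorted(cells)))


@dataclass(frozen=True)
class BandSpec:
    """Ordered half-open frequency bands (lo, hi] in Hz; DC is never summed."""

    bands: tuple = ((0.0, 2.0), (2.0, 4.0), (4.0, 6.0), (6.0, 8.0), (8.0, 10.0))

    def __post_init__(self) -> None:
        bands = tuple((float(lo), float(hi)) for lo, hi in self.bands)
        prev_hi = None
        for lo, hi in bands:
            if hi <= lo:
                raise ValueError("band hi must exceed lo")
            if prev_hi is not None and lo < prev_hi:
                raise ValueError("bands must be non-overlapping and ascending")
            prev_hi = hi
        if bands[0][0] != 0.0:
            raise ValueError("first band must start at 0 Hz (DC bin excluded)")
        object.__setattr__(self, "bands", bands)

    def __len__(self) -> int:
        return len(self.bands)


@dataclass
class FeatureVector:
    """Unit-L2-norm feature vector with its sample metadata.

    ``all_zero`` flags the degenerate case of an all-zero raw vector (e.g.
    a fully unloaded window), which is returned un-normalized.
    """

    values: np.ndarray
    label: str
    subject_id: str
    section: str
    window_start: int | None = None
    all_zero: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if not self.all_zero and abs(np.linalg.norm(self.values) - 1.0) > 1e-9:
            raise ValueError("feature vector must be unit norm")


def dft_magnitude(window, apply_hann: bool = True) -> np.ndarray:
    """Magnitude spectrum |S(k)|, k = 0..511, of one sensor's window.

    Optionally applies the Hann taper first.  Output length equals the
    window length (both sides of the spectrum).
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or x.size != WINDOW_LENGTH:
        raise ValueError(f"window must be 1-D of length {WINDOW_LENGTH}")
    if apply_hann:
        x = x * np.hanning(WINDOW_LENGTH)
    return np.abs(np.fft.fft(x))


def band_energies(
    frame: np.ndarray, bands: BandSpec = BandSpec(), fs: float = 50.0
) -> np.ndarray:
    """Sum one-sided spectral magnitudes into the configured bands.

    Bin k (k >= 1, up to L/2) at frequency ``k*fs/L`` contributes to the
    band with ``lo < f <= hi``; the DC bin never contributes.
    """
    frame = np.asarray(frame, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    L = frame.size
    if any(hi > fs / 2 for _, hi in bands.bands):
        raise ValueError("band extends above the Nyquist frequency")
    k = np.arange(1, L // 2 + 1)
    f = k * fs / L
    mags = frame[1 : L // 2 + 1]
    out = np.empty(len(bands))
    for b, (lo, hi) in enumerate(bands.bands):
        out[b] = mags[(f > lo) & (f <= hi)].sum()
    return out


def _normalize(raw: np.ndarray, label, subject_id, section, start) -> FeatureVector:
    norm = np.linalg.norm(raw)
    if norm == 0.0:
        return FeatureVector(raw, label, subject_id, section, start, all_zero=True)
    return FeatureVector(raw / norm, label, subject_id, section, start)


def extract_dynamic(
    window: np.ndarray,
    mask: SensorMask = None,
    bands: BandSpec = None,
    fs: float = 50.0,
    apply_hann: bool = True,
    label: str = "normal",
    subject_id: str = "",
    window_start: int | None = None,
) -> FeatureVector:
    """Feature vector of one walking window of shape (512, 8, 8).

    Concatenates each masked sensor's band energies in mask order
    (|mask| x |bands| elements, 150 by default) and L2-normalizes.
    """
    mask = mask or default_mask()
    bands = bands or BandSpec()
    window = np.asarray(window, dtype=float)
    if window.ndim != 3 or window.shape[0] != WINDOW_LENGTH or window.shape[1:] != GRID_SHAPE:
        raise ValueError(f"window must be ({WINDOW_LENGTH}, 8, 8), got {window.shape}")
    x = window[:, mask.rows, mask.cols]  # (L, n_sensors)
    if apply_hann:
        x = x * np.hanning(WINDOW_LENGTH)[:, None]
    spectra = np.abs(np.fft.fft(x, axis=0))
    raw = np.concatenate(
        [band_energies(spectra[:, s], bands, fs) for s in range(len(mask))]
    )
    return _normalize(raw, label, subject_id, "dynamic", window_start)


def extract_static(
    segment: np.ndarray,
    mask: SensorMask = None,
    label: str = "normal",
    subject_id: str = "",
    window_start: int | None = None,
) -> FeatureVector:
    """DC-only feature vector of one standing segment of shape (T, 8, 8):
    per masked sensor the time-mean pressure, L2-normalized (30 elements
    with the default mask)."""
    mask = mask or default_mask()
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 3 or segment.shape[0] < 1 or segment.shape[1:] != GRID_SHAPE:
        raise ValueError("segment must be a non-empty (T, 8, 8) array")
    raw = segment[:, mask.rows, mask.cols].mean(axis=0)
    return _normalize(raw, label, subject_id, "static", window_start)


def extract_features(
    recordings,
    mask: SensorMask = None,
    bands: BandSpec = None,
    window_spec: WindowSpec = None,
    segment_length: int = 100,
    apply_hann: bool = True,
) -> pd.DataFrame:
    """Extract a feature table from a recording collection.

    Dynamic recordings go through sliding windows, static ones through
    non-overlapping segments.  Returns one row per sample with columns
    ``f0..fD-1, label, subject_id, section, window_start``.
    """
    mask = mask or default_mask()
    bands = bands or BandSpec()
    window_spec = window_spec or WindowSpec()
    rows = []
    for rec in recordings:
        limit = rec.meta.get("n_samples")
        if rec.section == "dynamic":
            samples = (
                extract_dynamic(
                    seg, mask, bands, rec.fs, apply_hann,
                    rec.label, rec.subject_id, start,
                )
                for start, seg in sliding_windows(rec.frames, window_spec)
            )
        else:
            samples = (
                extract_static(seg, mask, rec.label, rec.subject_id, start)
                for start, seg in static_segments(rec, segment_length)
            )
        for i, fv in enumerate(samples):
            if limit is not None and i >= limit:
                break
            rows.append(fv)
    if not rows:
        return pd.DataFrame()
    dim = rows[0].values.size
    data = {f"f{j}": [fv.values[j] for fv in rows] for j in range(dim)}
    data["label"] = [fv.label for fv in rows]
    data["subject_id"] = [fv.subject_id for fv in rows]
    data["section"] = [fv.section for fv in rows]
    data["window_start"] = [fv.window_start for fv in rows]
    return pd.DataFrame(data)


def feature_matrix(df: pd.DataFrame):
    """Split a feature table into (X, y, subject_ids)."""
    fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    fcols = sorted(fcols, key=lambda c: int(c[1:]))
    return df[fcols].to_numpy(float), df["label"].to_numpy(), df["subject_id"].to_numpy()
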