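"""Readout-electronics model of the piezoresistive insole array.

The 8x8 sensor mat is a resistive crossbar: each cell is a force-sensing
resistor whose resistance falls inversely with applied pressure,
``R = k_pr / P``.  A non-inverting amplifier converts the selected cell's
resistance to a voltage ``V_out = (R + R_f) / R * V_ref`` which a 10-bit ADC
digitizes against ``V_adc_ref``.  Scanning the mat cell by cell without any
drive scheme lets current sneak through unselected cells (row -> cell ->
column -> cell -> row ... paths), so unloaded cells read above their
baseline; grounding the unselected rows and tying unselected columns to
``V_ref`` (the zero-potential method) cuts every path except the selected
cell's own.

This module simulates both scan modes, including a full nodal-analysis model
of the sneak paths, and provides the per-cell least-squares calibration that
maps ADC counts back to load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .recording import GRID_SHAPE

#: Sentinel resistance (ohms) standing in for an open circuit; keeps the
#: nodal solver well-posed while being many orders above any real path.
R_OPEN = 1e12


@dataclass(frozen=True)
class SensorCharacteristic:
    """Pressure-resistance characteristic of one FSR cell.

    ``k_pr`` is the sensor characteristic constant in ohm*kPa: the cell's
    resistance at pressure P is ``k_pr / P``.  The default maps the full
    0-1000 kPa detection range inside the ADC span (no saturation below
    1000 kPa with the default circuit).
    """

    k_pr: float = 1.0e5

    def __post_init__(self) -> None:
        if not self.k_pr > 0:
            raise ValueError("k_pr must be positive")


@dataclass(frozen=True)
class CircuitConfig:
    """Amplifier + ADC configuration of the scanning circuit.

    v_ref : drive voltage at the amplifier's non-inverting input (V).
    v_adc_ref : ADC full-scale reference (V).
    r_f : feedback resistor (ohm); sets the pressure gain.
    r_0 : charging resistor stabilizing the ADC input (ohm); documented but
        not part of the ideal output equation.
    m : ADC resolution in bits (full scale ``2**m`` counts).
    """

    v_ref: float = 0.5
    v_adc_ref: float = 5.0
    r_f: float = 900.0
    r_0: float = 1000.0
    m: int = 10

    def __post_init__(self) -> None:
        if not self.v_ref > 0:
            raise ValueError("v_ref must be positive")
        if self.v_adc_ref < self.v_ref:
            raise ValueError("v_adc_ref must be >= v_ref")
        if not self.r_f > 0:
            raise ValueError("r_f must be positive")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    @property
    def full_scale(self) -> int:
        return 2 ** self.m


@dataclass(frozen=True)
class CalibrationLine:
    """Least-squares line counts = slope * load + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass
class ArrayState:
    """Load state of the 8x8 mat plus the scan-drive mode.

    ``r_leak`` models the finite zero-load resistance of a real FSR (an
    ideal cell would be open at zero load); it is the parasitic coupling
    strength of the sneak-path network — lower values mean stronger
    crosstalk when the elimination drive is off.
    """

    true_pressure: np.ndarray
    crosstalk_elimination: bool = True
    r_leak: float = 1.0e4

    def __post_init__(self) -> None:
        self.true_pressure = np.asarray(self.true_pressure, dtype=float)
        if self.true_pressure.shape != GRID_SHAPE:
            raise ValueError(
                f"true_pressure must be {GRID_SHAPE}, got {self.true_pressure.shape}"
            )
        if np.any(self.true_pressure < 0):
            raise ValueError("pressures must be non-negative")
        if not self.r_leak > 0:
            raise ValueError("r_leak must be positive")


def resistance_from_pressure(p, char: SensorCharacteristic):
    """Cell resistance (ohm) at pressure ``p`` (kPa): ``k_pr / p``.

    Zero pressure returns ``inf`` (open circuit).  Accepts scalars or
    arrays.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("pressure must be non-negative")
    with np.errstate(divide="ignore"):
        r = np.where(p > 0, char.k_pr / np.where(p > 0, p, 1.0), np.inf)
    return float(r) if r.ndim == 0 else r


def adc_from_resistance(r, char: SensorCharacteristic, cfg: CircuitConfig):
    """ADC counts for a measured resistance via the amplifier equation.

    ``V_out = (R + R_f)/R * V_ref``; counts = floor(2^m V_out / V_adc_ref)
    clipped to [0, 2^m].  ``R = inf`` gives the zero-load baseline
    ``floor(2^m * V_ref / V_adc_ref)``.
    """
    r = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        ratio = np.where(np.isinf(r), 1.0, (r + cfg.r_f) / r)
    d = np.floor(cfg.full_scale * ratio * cfg.v_ref / cfg.v_adc_ref)
    d = np.clip(d, 0, cfg.full_scale).astype(int)
    return int(d) if d.ndim == 0 else d


def adc_output(p, char: SensorCharacteristic, cfg: CircuitConfig):
    """Ideal (crosstalk-free) ADC counts for pressure ``p`` in kPa.

    Implements ``D = 2^m * (k_pr + P*R_f)/k_pr * V_ref/V_adc_ref`` with
    floor quantization and clipping to ``[0, 2^m]``; monotone
    non-decreasing in ``p``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("pressure must be non-negative")
    d = np.floor(
        cfg.full_scale
        * (char.k_pr + p * cfg.r_f)
        / char.k_pr
        * cfg.v_ref
        / cfg.v_adc_ref
    )
    d = np.clip(d, 0, cfg.full_scale).astype(int)
    return int(d) if d.ndim == 0 else d


def _cell_resistances(state: ArrayState, char: SensorCharacteristic) -> np.ndarray:
    """Physical cell resistances: the ideal FSR in parallel with the leak."""
    p = state.true_pressure
    # 1/R = P/k_pr + 1/r_leak  (finite even at zero load)
    g = p / char.k_pr + 1.0 / state.r_leak
    return 1.0 / g


def effective_resistance(resistances: np.ndarray, row: int, col: int) -> float:
    """Two-terminal resistance of a resistive crossbar seen by the scanner.

    Nodes are the row and column lines; each cell ``(i, j)`` is a resistor
    between row node ``i`` and column node ``j``.  The selected row is
    driven, the selected column is held at the amplifier's virtual
    reference, all other lines float — exactly the situation without the
    crosstalk-elimination drive.  Solves the full nodal (Laplacian) system;
    works for any n x m array, which is what the small-array oracle tests
    use.
    """
    resistances = np.asarray(resistances, dtype=float)
    n, m = resistances.shape
    if not (0 <= row < n and 0 <= col < m):
        raise IndexError("selected cell outside the array")
    g = 1.0 / np.clip(resistances, 0.0, R_OPEN)
    nn = n + m  # node count: n row lines then m column lines
    lap = np.zeros((nn, nn))
    for i in range(n):
        for j in range(m):
            gij = g[i, j]
            a, b = i, n + j
            lap[a, a] += gij
            lap[b, b] += gij
            lap[a, b] -= gij
            lap[b, a] -= gij
    src, snk = row, n + col
    free = [k for k in range(nn) if k not in (src, snk)]
    # V[src]=1, V[snk]=0, no injected current at floating nodes.
    if free:
        a_ff = lap[np.ix_(free, free)]
        rhs = -lap[np.ix_(free, [src])].ravel()  # * V_src (=1)
        v_free = np.linalg.solve(a_ff, rhs)
    else:
        v_free = np.zeros(0)
    v = np.zeros(nn)
    v[src] = 1.0
    v[free] = v_free
    current = lap[src] @ v
    if current <= 0:
        return R_OPEN
    return min(1.0 / current, R_OPEN)


def simulate_scan(
    state: ArrayState, char: SensorCharacteristic, cfg: CircuitConfig
) -> np.ndarray:
    """Scan the whole array, returning an 8x8 grid of integer counts.

    With ``crosstalk_elimination`` on, the zero-potential drive isolates
    every cell, so each count equals :func:`adc_output` of that cell's own
    pressure, bit for bit.  With it off, each cell's reading comes from the
    effective resistance of the crossbar with all unselected lines
    floating, so sneak paths through neighboring loaded cells perturb the
    reading; the perturbation shrinks with electrical distance from the
    load.
    """
    if state.crosstalk_elimination:
        return adc_output(state.true_pressure, char, cfg)
    r_cells = _cell_resistances(state, char)
    n, m = r_cells.shape
    counts = np.empty((n, m), dtype=int)
    for i in range(n):
        for j in range(m):
            r_eff = effective_resistance(r_cells, i, j)
            counts[i, j] = adc_from_resistance(r_eff, char, cfg)
    return counts


def calibrate_cell(loads, counts) -> CalibrationLine:
    """Ordinary least-squares calibration of one cell: counts on load (kg).

    Accepts any paired load/count protocol (e.g. two 0 -> 11 -> 0 kg
    sweeps concatenated); requires at least two distinct load values.
    """
    loads = np.asarray(loads, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if loads.shape != counts.shape or loads.ndim != 1:
        raise ValueError("loads and counts must be equal-length 1-D sequences")
    if loads.size < 2:
        raise ValueError("need at least two calibration points")
    if np.ptp(loads) == 0:
        raise ValueError("degenerate calibration: all loads equal")
    res = stats.linregress(loads, counts)
    r2 = float(res.rvalue) ** 2
    # guard tiny numerical overshoot on exact lines
    r2 = min(r2, 1.0)
    return CalibrationLine(float(res.slope), float(res.intercept), r2)
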