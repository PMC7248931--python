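"""Total-pressure tracks for the two sample geometries.

Neither sample geometry carries a pressure gauge: the sealed glass
insert loses its pressure setting during torch-sealing, and the FEP
(fluorinated ethylene propylene) insert leaks slowly by design.  The
pressure is therefore calibrated indirectly:

* the *anchor* pressure ``p0`` comes from the Antoine vapor-pressure
  equation evaluated at the condensation temperature ``T0`` (glass) or
  at the experiment temperature at the moment the liquid has just fully
  evaporated (FEP);
* a sealed glass tube then follows isochoric ideal-gas scaling
  ``p_tot = p0 * T / T0``;
* a leaky FEP insert follows the integral intensity of the methyl NMR
  signal, ``p_tot(t) = (I(t)/I(t0)) * p0 - p_corr``, where ``p_corr``
  absorbs a small spectral-baseline distortion that would otherwise
  leave a spurious pressure floor at long times.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "AntoineCoefficients",
    "VaporDecaySeries",
    "AntoineRangeWarning",
    "acetic_acid_antoine",
    "antoine_pressure",
    "condensation_p0",
    "invert_antoine",
    "glass_pressure_track",
    "fep_pressure_track",
    "smooth_track",
    "detect_t0",
    "read_decay_csv",
    "write_decay_csv",
]

ATM_PER_BAR = 1.0 / 1.01325
ATM_PER_MMHG = 1.0 / 760.0

_UNIT_TO_ATM = {"bar": ATM_PER_BAR, "atm": 1.0, "mmhg": ATM_PER_MMHG, "torr": ATM_PER_MMHG}


class AntoineRangeWarning(UserWarning):
    """Antoine evaluation requested outside the coefficients' validity range."""


@dataclass(frozen=True)
class AntoineCoefficients:
    """Constants of the Antoine relation log10(p_sat) = A - B/(T + C).

    ``pressure_unit`` names the unit the coefficients produce (converted
    to atm on evaluation); temperatures are Kelvin.  Evaluation outside
    [T_min, T_max] warns but proceeds — extrapolation is routine when an
    experiment runs slightly past the tabulated range.
    """

    A: float
    B: float
    C: float
    T_min: float
    T_max: float
    pressure_unit: str = "bar"
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.T_min < self.T_max:
            raise ValueError("require T_min < T_max")
        if self.pressure_unit.lower() not in _UNIT_TO_ATM:
            raise ValueError(f"unsupported pressure unit {self.pressure_unit!r}")


def acetic_acid_antoine() -> AntoineCoefficients:
    """The packaged acetic-acid coefficient set (log10/bar/K dialect)."""
    with resources.files("acdimer.data").joinpath("antoine_acetic_acid.json").open() as fh:
        raw = json.load(fh)
    return AntoineCoefficients(
        A=raw["A"], B=raw["B"], C=raw["C"],
        T_min=raw["T_min_K"], T_max=raw["T_max_K"],
        pressure_unit=raw["pressure_unit"], source=raw["source"],
    )


def antoine_pressure(T, coeffs: AntoineCoefficients):
    """Saturation pressure at temperature T (K), in atm.

    Emits :class:`AntoineRangeWarning` when T falls outside the
    validity range; the value is still returned.
    """
    T_arr = np.asarray(T, dtype=float)
    if np.any(T_arr <= 0):
        raise ValueError("temperature must be positive")
    if np.any(T_arr < coeffs.T_min) or np.any(T_arr > coeffs.T_max):
        warnings.warn(
            f"temperature outside Antoine validity range "
            f"[{coeffs.T_min}, {coeffs.T_max}] K; extrapolating",
            AntoineRangeWarning,
            stacklevel=2,
        )
    p_native = 10.0 ** (coeffs.A - coeffs.B / (T_arr + coeffs.C))
    p_atm = p_native * _UNIT_TO_ATM[coeffs.pressure_unit.lower()]
    return float(p_atm) if np.isscalar(T) else p_atm


def condensation_p0(T0: float, coeffs: AntoineCoefficients) -> float:
    """Anchor pressure p0 from the condensation/evaporation temperature T0.

    When condensation sets in (glass insert) the vapor sits exactly on
    the liquid-vapor coexistence curve, so p0 = p_sat(T0); for a FEP
    experiment T0 is the experiment temperature at the moment the last
    liquid evaporates, where the same identity holds.
    """
    return antoine_pressure(float(T0), coeffs)


def invert_antoine(p_atm: float, coeffs: AntoineCoefficients, tol: float = 1e-4) -> float:
    """Temperature (K) at which p_sat equals ``p_atm``; bisection inverse."""
    if p_atm <= 0:
        raise ValueError("pressure must be positive")
    lo, hi = coeffs.T_min - 50.0, coeffs.T_max + 100.0
    lo = max(lo, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", AntoineRangeWarning)
        f = lambda T: antoine_pressure(T, coeffs) - p_atm
        if f(lo) > 0 or f(hi) < 0:
            raise ValueError("pressure not bracketed by the coefficient range")
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
    return 0.5 * (lo + hi)


def glass_pressure_track(T, p0: float, T0: float):
    """Sealed-tube pressure p_tot = p0 * T / T0 (isochoric ideal gas)."""
    T_arr = np.asarray(T, dtype=float)
    if np.any(T_arr <= 0) or T0 <= 0:
        raise ValueError("temperatures must be positive")
    p = p0 * T_arr / float(T0)
    return float(p) if np.isscalar(T) else p


@dataclass
class VaporDecaySeries:
    """Time track of the methyl-signal integral in a leaky FEP insert.

    After the liquid has fully evaporated (time ``t0``) the vapor leaks
    out and the integral intensity ``I`` decays exponentially; the
    intensity ratio to its value at ``t0`` scales the anchor pressure
    ``p0`` into an absolute pressure track.  ``p_corr`` is the small
    constant baseline-pressure distortion subtracted from the track
    (observed to stay below ~0.005 atm).
    """

    t: np.ndarray
    I: np.ndarray
    t0: float
    p0: float
    p_corr: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.I.shape:
            raise ValueError("t and I must be 1-D arrays of equal length")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("time points must be strictly increasing")
        if not (self.t[0] <= self.t0 <= self.t[-1]):
            raise ValueError("t0 must lie within the sampled time range")
        if self.intensity_at_t0() <= 0:
            raise ValueError("intensity at t0 must be positive")
        if self.p_corr < 0:
            raise ValueError("p_corr must be non-negative")

    def intensity_at_t0(self) -> float:
        return float(np.interp(self.t0, self.t, self.I))

    def after_t0(self) -> np.ndarray:
        """Boolean mask selecting t >= t0 (where the decay model applies)."""
        return self.t >= self.t0


def fep_pressure_track(series: VaporDecaySeries) -> tuple[np.ndarray, np.ndarray]:
    """Pressure track p_tot(t) = (I(t)/I(t0)) p0 - p_corr for t >= t0.

    Returns
    -------
    (t, p_tot) : pair of ndarray
        Times at/after t0 and the corresponding pressures, atm.
        Negative values (the p_corr subtraction can undershoot in
        noise) are clipped to 0 with a warning.
    """
    mask = series.after_t0()
    ratio = series.I[mask] / series.intensity_at_t0()
    p = ratio * series.p0 - series.p_corr
    if np.any(p < 0):
        warnings.warn(
            "baseline correction drove some pressures negative; clipped to 0",
            UserWarning,
            stacklevel=2,
        )
        p = np.clip(p, 0.0, None)
    return series.t[mask], p


def smooth_track(p, window: int = 21, order: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing of a pressure (or intensity-ratio) track.

    The defaults — cubic polynomial, 21-point window — match the
    processing the global fit expects; any polynomial of degree <= order
    passes through unchanged, so the smoother does not bias the
    low-order trend it is protecting.
    """
    p = np.asarray(p, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("polynomial order must be smaller than the window")
    if p.size < window:
        raise ValueError(
            f"series of length {p.size} is shorter than the {window}-point "
            f"window; reduce the window"
        )
    return savgol_filter(p, window_length=window, polyorder=order)


def detect_t0(t, I, run: int = 10, window: int = 21, order: int = 3) -> float:
    """Heuristic decay-onset time: the maximum of the smoothed intensity.

    The intensity is SG-smoothed first (raw argmax is noise-dominated),
    then the candidate must be followed by ``run`` consecutive smoothed
    decreases to count as the start of a monotone decay.
    """
    t = np.asarray(t, dtype=float)
    I = np.asarray(I, dtype=float)
    I_s = smooth_track(I, window=window, order=order) if I.size >= window else I
    i0 = int(np.argmax(I_s))
    tail = I_s[i0:]
    if tail.size > run and not np.all(np.diff(tail[: run + 1]) < 0):
        raise ValueError("no monotone decay detected after the intensity maximum")
    return float(t[i0])


def read_decay_csv(path: str | Path) -> pd.DataFrame:
    """Read a decay-series CSV (columns ``time_s``, ``intensity`` and
    optionally ``delta_OH_ppm``, ``delta_Me_ppm`` or ``dshift_ppm``)."""
    df = pd.read_csv(path)
    required = {"time_s", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"decay CSV {path} missing columns: {sorted(missing)}")
    if {"delta_OH_ppm", "delta_Me_ppm"} <= set(df.columns) and "dshift_ppm" not in df.columns:
        df["dshift_ppm"] = df["delta_OH_ppm"] - df["delta_Me_ppm"]
    return df


def write_decay_csv(path: str | Path, t, intensity, dshift=None) -> None:
    """Write a decay-series CSV in the dialect `read_decay_csv` consumes."""
    data = {"time_s": np.asarray(t, float), "intensity": np.asarray(intensity, float)}
    if dshift is not None:
        data["dshift_ppm"] = np.asarray(dshift, float)
    pd.DataFrame(data).to_csv(path, index=False)
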