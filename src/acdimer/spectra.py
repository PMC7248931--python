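"""Lorentzian lineshape utilities for 1H spectra.

The observable the analysis consumes is the internal chemical-shift
difference delta(OH) - delta(Me): unreferenced gas-phase spectra only
support internal differences, which is also why the difference is
invariant under any global shift of the ppm axis.  This module turns a
spectrum into that observable: polynomial baseline correction, a sum of
Lorentzians fitted by nonlinear least squares, and the difference of
the two fitted peak positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as P
from scipy.optimize import least_squares

__all__ = [
    "Spectrum",
    "PeakFit",
    "PeakFitError",
    "lorentzian_profile",
    "baseline_correct",
    "fit_peaks",
    "shift_difference",
    "read_spectrum_csv",
]


@dataclass
class Spectrum:
    """A 1-D spectrum: ppm axis (strictly monotone) and intensities."""

    axis: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.shape != self.intensity.shape or self.axis.ndim != 1:
            raise ValueError("axis and intensity must be 1-D arrays of equal length")
        d = np.diff(self.axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("axis must be strictly monotone")


@dataclass(frozen=True)
class PeakFit:
    """One fitted Lorentzian: position (ppm), FWHM (ppm), amplitude, area."""

    position: float
    half_width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width (FWHM) must be positive")

    @property
    def area(self) -> float:
        # analytic integral of amplitude * (w/2)^2 / ((x-x0)^2 + (w/2)^2)
        return np.pi * self.amplitude * self.half_width / 2.0


class PeakFitError(RuntimeError):
    """Lineshape fit failed to converge; carries the last residual norm."""

    def __init__(self, message: str, residual_norm: float):
        super().__init__(f"{message} (residual norm {residual_norm:.3g})")
        self.residual_norm = residual_norm


def lorentzian_profile(axis, position: float, half_width: float, amplitude: float) -> np.ndarray:
    """Lorentzian L(x) = amplitude (w/2)^2 / ((x - x0)^2 + (w/2)^2).

    ``half_width`` is the full width at half maximum: the profile equals
    amplitude at x0 and amplitude/2 at x0 +/- half_width/2.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    x = np.asarray(axis, dtype=float)
    hw2 = (0.5 * half_width) ** 2
    return amplitude * hw2 / ((x - position) ** 2 + hw2)


def baseline_correct(spec: Spectrum, order: int = 5, n_iter: int = 5, clip: float = 3.0) -> Spectrum:
    """Subtract a least-squares polynomial baseline of the given order.

    Peak-containing points would drag the polynomial upward, so the fit
    is restricted to baseline regions found by iterative sigma-clipping:
    fit on all points, drop points more than ``clip`` standard
    deviations above the current polynomial, refit, ``n_iter`` times.
    Only upward outliers are clipped (peaks are positive in absorption
    spectra).  A spectrum that IS a polynomial of degree <= order comes
    back identically zero.
    """
    if order < 0:
        raise ValueError("order must be non-negative")
    x, y = spec.axis, spec.intensity
    if x.size <= order + 1:
        raise ValueError("spectrum must be longer than order + 1")
    # center/scale the axis for conditioning
    x0 = (x - x.mean()) / max(np.ptp(x) / 2.0, 1e-300)
    mask = np.ones(x.size, dtype=bool)
    coef = None
    for _ in range(n_iter):
        coef = P.polyfit(x0[mask], y[mask], order)
        resid = y - P.polyval(x0, coef)
        sigma = np.std(resid[mask])
        if sigma == 0:
            break
        new_mask = resid < clip * sigma
        if new_mask.sum() <= order + 1 or np.array_equal(new_mask, mask):
            break
        mask = new_mask
    baseline = P.polyval(x0, coef)
    return Spectrum(x, y - baseline)


def _sum_of_lorentzians(x: np.ndarray, params: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    for pos, hw, amp in params.reshape(-1, 3):
        out += lorentzian_profile(x, pos, hw, amp)
    return out


def fit_peaks(spec: Spectrum, n_peaks: int, initial_positions) -> list[PeakFit]:
    """Fit a sum of ``n_peaks`` Lorentzians by trust-region least squares.

    Initial widths are a small fraction of the axis span and initial
    amplitudes the local intensity at each starting position.  Peaks are
    returned sorted by position descending (high ppm first, the NMR
    convention, so OH precedes Me for this system).
    """
    if n_peaks < 1:
        raise ValueError("need at least one peak")
    init = np.asarray(initial_positions, dtype=float)
    if init.size != n_peaks:
        raise ValueError("need one initial position per peak")
    x, y = spec.axis, spec.intensity
    lo, hi = min(x[0], x[-1]), max(x[0], x[-1])
    if np.any(init < lo) or np.any(init > hi):
        raise ValueError("initial positions must lie within the axis range")

    span = hi - lo
    hw0 = max(span / 200.0, 2.0 * abs(np.median(np.diff(x))))
    theta0 = np.empty(3 * n_peaks)
    for k, pos in enumerate(init):
        amp0 = max(float(np.interp(pos, x[np.argsort(x)], y[np.argsort(x)])), 1e-12)
        theta0[3 * k : 3 * k + 3] = (pos, hw0, amp0)

    lower = np.tile([lo, 1e-9 * span, 0.0], n_peaks)
    upper = np.tile([hi, span, np.inf], n_peaks)
    res = least_squares(
        lambda th: _sum_of_lorentzians(x, th) - y,
        theta0,
        bounds=(lower, upper),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not res.success:
        raise PeakFitError("lineshape fit did not converge", float(np.linalg.norm(res.fun)))
    peaks = [PeakFit(pos, hw, amp) for pos, hw, amp in res.x.reshape(-1, 3)]
    return sorted(peaks, key=lambda p: p.position, reverse=True)


def shift_difference(peaks: list[PeakFit]) -> float:
    """delta(OH) - delta(Me) from exactly two fitted peaks.

    OH is identified as the higher-frequency (higher ppm) peak; for the
    acid the difference is positive.  Translation-invariance of the
    difference is what makes an unreferenced spectrum usable.
    """
    if len(peaks) != 2:
        raise ValueError(f"expected exactly 2 peaks (OH, Me); got {len(peaks)}")
    oh, me = sorted(peaks, key=lambda p: p.position, reverse=True)
    return oh.position - me.position


def read_spectrum_csv(path: str | Path) -> Spectrum:
    """Read a spectrum CSV with columns ``ppm``, ``intensity``."""
    df = pd.read_csv(path)
    if not {"ppm", "intensity"} <= set(df.columns):
        raise ValueError(f"spectrum CSV {path} must have columns ppm, intensity")
    return Spectrum(df["ppm"].to_numpy(), df["intensity"].to_numpy())
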