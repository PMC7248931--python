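"""Two-state monomer/dimer equilibrium of a gas-phase carboxylic acid.

Gaseous acetic acid dimerizes through a pair of O-H...O=C hydrogen bonds,

    2 M <-> D,      K = p_D / p_M**2,

with partial pressures in atm and K made dimensionless by the standard
state p0 = 1 atm.  Under fast exchange the single observed proton signal
is the population-weighted average of the monomer and dimer limiting
shifts; the analysis works throughout with the internal shift difference
delta(OH) - delta(Me), so no external referencing is needed.

Everything here is a pure function of (thermodynamics, temperature,
total pressure); the fitting and synthetic-data layers build on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "R_KCAL",
    "ThermoState",
    "GasComposition",
    "ShiftPair",
    "celsius_to_kelvin",
    "equilibrium_constant",
    "gibbs_energy",
    "monomer_pressure",
    "observed_shift",
    "predict_shift",
]

#: Gas constant in kcal/(mol K).
R_KCAL = 1.9872041e-3


@dataclass(frozen=True)
class ThermoState:
    """Dimerization enthalpy and entropy.

    Parameters
    ----------
    dH : float
        Enthalpy change of dimerization, kcal/mol.
    dS : float
        Entropy change of dimerization, cal/(mol K).  Note the factor
        10**3 between the two units; conversions happen internally.

    For this system both are negative (binding releases heat, two
    molecules become one), but any finite values are accepted: the
    fitting layer must be free to wander.
    """

    dH: float
    dS: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dH) and np.isfinite(self.dS)):
            raise ValueError("dH and dS must be finite")


@dataclass(frozen=True)
class GasComposition:
    """Monomer/dimer partial pressures under Dalton closure (atm)."""

    p_M: float
    p_D: float
    p_tot: float

    def __post_init__(self) -> None:
        if self.p_M < 0 or self.p_D < 0:
            raise ValueError("partial pressures must be non-negative")
        closure = self.p_M + 2.0 * self.p_D
        scale = max(abs(self.p_tot), 1.0)
        if abs(closure - self.p_tot) > 1e-12 * scale:
            raise ValueError(
                f"Dalton closure violated: p_M + 2 p_D = {closure!r} != p_tot = {self.p_tot!r}"
            )


@dataclass(frozen=True)
class ShiftPair:
    """Limiting chemical-shift differences delta(OH) - delta(Me), ppm."""

    delta_M: float
    delta_D: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.delta_M) and np.isfinite(self.delta_D)):
            raise ValueError("limiting shifts must be finite")
        if self.delta_M == self.delta_D:
            raise ValueError(
                "delta_M == delta_D: observed shift carries no composition information"
            )


def celsius_to_kelvin(t_celsius):
    """Convert Celsius to Kelvin (the interfaces accept either scale)."""
    return np.asarray(t_celsius, dtype=float) + 273.15


def _check_temperature(T: float) -> float:
    T = float(T)
    if not T > 0:
        raise ValueError(f"temperature must be positive (got {T} K)")
    return T


def equilibrium_constant(thermo: ThermoState, T: float) -> float:
    """van't Hoff equilibrium constant K(T) = exp(-(dH - T dS)/(R T)).

    Parameters
    ----------
    thermo : ThermoState
    T : float
        Temperature, K.

    Returns
    -------
    float
        Dimensionless K (standard state 1 atm), strictly positive.
    """
    T = _check_temperature(T)
    dG = gibbs_energy(thermo, T)
    return float(np.exp(-dG / (R_KCAL * T)))


def gibbs_energy(thermo: ThermoState, T: float) -> float:
    """Gibbs energy of dimerization dG = dH - T dS, kcal/mol.

    dS is stored in cal/(mol K) and converted here, so
    ``K = exp(-dG/(R T))`` holds identically with `equilibrium_constant`.
    """
    T = _check_temperature(T)
    return thermo.dH - T * thermo.dS * 1e-3


def monomer_pressure(K: float, p_tot: float) -> GasComposition:
    """Solve the dimerization equilibrium at total pressure p_tot.

    Combining K = p_D/p_M**2 with Dalton closure p_M + 2 p_D = p_tot
    gives the quadratic 2 K p_M**2 + p_M - p_tot = 0, whose physical
    root is evaluated in the rationalized form

        p_M = 2 p_tot / (1 + sqrt(1 + 8 K p_tot)),

    which is exact and remains well-conditioned as K -> 0 (the textbook
    form (sqrt(1+8Kp)-1)/(4K) is 0/0 there).

    Returns
    -------
    GasComposition
    """
    K = float(K)
    p_tot = float(p_tot)
    if K < 0:
        raise ValueError("equilibrium constant must be non-negative")
    if p_tot < 0:
        raise ValueError("total pressure must be non-negative")
    if p_tot == 0.0:
        return GasComposition(0.0, 0.0, 0.0)
    p_M = 2.0 * p_tot / (1.0 + np.sqrt(1.0 + 8.0 * K * p_tot))
    # p_D via the mass-action law rather than (p_tot - p_M)/2: identical
    # algebraically, but immune to cancellation when p_M ~ p_tot (K -> 0)
    p_D = K * p_M * p_M
    return GasComposition(p_M, p_D, p_tot)


def observed_shift(comp: GasComposition, shifts: ShiftPair) -> float:
    """Fast-exchange population-averaged shift difference, ppm.

    delta = (p_M/p_tot) (delta_M - delta_D) + delta_D.  Each monomer
    proton counts once and each dimer contains two monomers, so the
    monomer population fraction is p_M/p_tot under Dalton closure.
    """
    if comp.p_tot <= 0:
        raise ValueError("observed shift undefined at zero total pressure")
    x_M = comp.p_M / comp.p_tot
    return x_M * (shifts.delta_M - shifts.delta_D) + shifts.delta_D


def predict_shift(thermo: ThermoState, shifts: ShiftPair, T: float, p_tot) -> np.ndarray | float:
    """Model shift difference at temperature T and total pressure(s) p_tot.

    Vectorized over ``p_tot``; the composition of the van't Hoff
    constant, the equilibrium solution and the fast-exchange average.
    p_tot -> 0 returns delta_M (all monomer); K*p_tot -> inf tends to
    delta_D.

    Parameters
    ----------
    thermo : ThermoState
    shifts : ShiftPair
    T : float
        Temperature, K.
    p_tot : float or array_like
        Total pressure(s), atm; must be non-negative.

    Returns
    -------
    float or ndarray, ppm.
    """
    K = equilibrium_constant(thermo, T)
    p = np.asarray(p_tot, dtype=float)
    if np.any(p < 0):
        raise ValueError("total pressure must be non-negative")
    with np.errstate(invalid="ignore"):
        x_M = np.where(p > 0, 2.0 / (1.0 + np.sqrt(1.0 + 8.0 * K * p)), 1.0)
    delta = x_M * (shifts.delta_M - shifts.delta_D) + shifts.delta_D
    if np.isscalar(p_tot) or (isinstance(p_tot, np.ndarray) and p_tot.ndim == 0):
        return float(delta)
    return delta
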