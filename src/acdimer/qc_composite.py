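"""Composite-thermochemistry post-processing of tabulated energies.

Operates on tables of electronic binding energies by method and
basis-set cardinal number X (Aug-cc-pVXZ, X = 2..5):

* complete-basis-set (CBS) extrapolation of correlation energies with
  the X**-3 form E(X) = E_CBS + A/X**3 (double-zeta rows are excluded
  by default — they sit visibly off the X**-3 trend);
* the CCSD(T)/CBS composite: MP2/CBS plus the CCSD(T)-MP2 difference
  evaluated in a smaller common basis, exploiting the near basis-set
  independence of that difference;
* pasting MP2-level thermal corrections onto electronic energies to
  produce dH, dS and dG0 comparable with experiment;
* the half-counterpoise BSSE treatment: adding only half the
  counterpoise estimate, which empirically lands closer to the CBS
  limit than the full correction (counterpoise overestimates BSSE).

Energies are kcal/mol at every interface; `hartree_to_kcal` converts
raw electronic-structure output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dimer_model import ThermoState, gibbs_energy

__all__ = [
    "HARTREE_TO_KCAL",
    "EnergyRecord",
    "CbsFit",
    "ThermoCorrection",
    "hartree_to_kcal",
    "helgaker_cbs",
    "composite_cbs",
    "apply_thermal",
    "half_counterpoise",
    "read_energy_csv",
    "round_half_even",
]

HARTREE_TO_KCAL = 627.5094740631

_VALID_CARDINALS = {2, 3, 4, 5}


def hartree_to_kcal(e_hartree):
    """Convert hartree to kcal/mol."""
    return np.asarray(e_hartree, dtype=float) * HARTREE_TO_KCAL


@dataclass(frozen=True)
class EnergyRecord:
    """One row of an energy table: method label, basis cardinal, energy.

    ``cardinal`` is the basis-set cardinal number (2-5) or the string
    ``"CBS"``.  ``hf`` and ``corr`` optionally split the energy into
    Hartree-Fock and correlation components (dE = hf + corr when both
    are given), which is what the CBS extrapolation properly consumes.
    """

    method: str
    cardinal: int | str
    dE: float
    hf: float | None = None
    corr: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.cardinal, str):
            if self.cardinal.upper() != "CBS":
                raise ValueError(f"string cardinal must be 'CBS', got {self.cardinal!r}")
        elif self.cardinal not in _VALID_CARDINALS:
            raise ValueError(f"cardinal must be one of {sorted(_VALID_CARDINALS)} or 'CBS'")
        if self.hf is not None and self.corr is not None:
            if abs(self.dE - (self.hf + self.corr)) > 1e-6 * max(1.0, abs(self.dE)):
                raise ValueError("dE must equal hf + corr when both components are present")


@dataclass(frozen=True)
class CbsFit:
    """Result of the X**-3 extrapolation: E_CBS, the amplitude A, cardinals used."""

    e_cbs: float
    a_coef: float
    cardinals_used: tuple[int, ...]

    def predict(self, X) -> np.ndarray:
        return self.e_cbs + self.a_coef / np.asarray(X, dtype=float) ** 3


@dataclass(frozen=True)
class ThermoCorrection:
    """Thermal enthalpy increment and entropy from one thermochemistry run.

    ``dH_thermal`` is dH - dE at the stated level (ZPE + thermal terms),
    kcal/mol; ``dS`` in cal/(mol K); ``level_label`` records provenance
    (e.g. "MP2/Aug-cc-pVTZ").
    """

    dH_thermal: float
    dS: float
    level_label: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dH_thermal) and np.isfinite(self.dS)):
            raise ValueError("thermal correction values must be finite")


def helgaker_cbs(
    records: list[EnergyRecord],
    use_corr: bool = False,
    exclude_double_zeta: bool = True,
) -> CbsFit:
    """Extrapolate E(X) = E_CBS + A/X**3 over the supplied cardinals.

    Parameters
    ----------
    records : list of EnergyRecord
        Rows with integer cardinals.  Cardinal-2 rows are dropped by
        default (they do not follow the X**-3 form reliably); pass
        ``exclude_double_zeta=False`` to keep them.
    use_corr : bool
        Extrapolate the ``corr`` component instead of ``dE``.  The
        proper workflow extrapolates correlation energy only and adds
        the largest-basis HF energy back afterwards.

    With exactly two cardinals (X, Y) the least-squares solution
    reduces to the closed form E_CBS = (X^3 E_X - Y^3 E_Y)/(X^3 - Y^3).
    """
    rows = [r for r in records if isinstance(r.cardinal, int)]
    if exclude_double_zeta:
        rows = [r for r in rows if r.cardinal != 2]
    if len(rows) < 2:
        raise ValueError("need at least 2 records with usable (non-double-zeta) cardinals")
    cards = [r.cardinal for r in rows]
    if len(set(cards)) != len(cards):
        raise ValueError(f"duplicate cardinals in input: {sorted(cards)}")
    if use_corr:
        if any(r.corr is None for r in rows):
            raise ValueError("use_corr=True requires the corr component on every record")
        e = np.array([r.corr for r in rows], dtype=float)
    else:
        e = np.array([r.dE for r in rows], dtype=float)
    X = np.array(cards, dtype=float)
    # linear least squares in (E_CBS, A) with regressor X^-3
    design = np.column_stack([np.ones_like(X), X ** -3])
    (e_cbs, a), *_ = np.linalg.lstsq(design, e, rcond=None)
    return CbsFit(float(e_cbs), float(a), tuple(sorted(cards)))


def composite_cbs(e_mp2_cbs: float, e_high_small: float, e_mp2_small: float) -> float:
    """High-level/CBS composite energy.

    Returns ``e_mp2_cbs + (e_high_small - e_mp2_small)``: the MP2/CBS
    value corrected by the high-level-minus-MP2 difference evaluated in
    a common smaller basis.  The caller guarantees the two small-basis
    energies share a basis set.
    """
    for v in (e_mp2_cbs, e_high_small, e_mp2_small):
        if not np.isfinite(v):
            raise ValueError("composite inputs must be finite")
    return e_mp2_cbs + (e_high_small - e_mp2_small)


def apply_thermal(dE: float, corr: ThermoCorrection, T: float = 298.15) -> dict[str, float]:
    """Electronic energy -> thermodynamic quantities at temperature T.

    dH = dE + dH_thermal; dS comes straight from the thermochemistry
    run; dG0 = dH - T dS (standard state 1 atm).
    """
    dH = dE + corr.dH_thermal
    dS = corr.dS
    dG0 = gibbs_energy(ThermoState(dH, dS), T)
    return {"dH": dH, "dS": dS, "dG0": dG0}


def half_counterpoise(e_uncorrected: float, bsse: float) -> float:
    """Apply half of the counterpoise BSSE estimate.

    Sign convention: binding energies are negative; the counterpoise
    correction weakens binding (adds a positive amount), and taking
    only half of it compensates for the counterpoise method's known
    overestimation.  The result lies midway between the uncorrected and
    fully corrected values.
    """
    if bsse < 0:
        raise ValueError("BSSE estimate must be non-negative")
    return e_uncorrected + 0.5 * bsse


def round_half_even(x: float, decimals: int = 2) -> float:
    """Banker's rounding, matching printed-table presentation."""
    return float(np.round(x, decimals))


def read_energy_csv(path: str | Path) -> list[EnergyRecord]:
    """Read an energy-table CSV.

    Columns: ``method``, ``cardinal`` (int or "CBS"), ``dE_kcal`` and
    optionally ``hf_kcal``, ``corr_kcal``.  A ``basis_label`` column is
    accepted and ignored (provenance only).
    """
    df = pd.read_csv(path)
    required = {"method", "cardinal", "dE_kcal"}
    if not required <= set(df.columns):
        raise ValueError(f"energy CSV {path} missing columns: {sorted(required - set(df.columns))}")
    records = []
    for _, row in df.iterrows():
        card = row["cardinal"]
        if isinstance(card, str) and not card.strip().isdigit():
            card = card.strip().upper()
        else:
            card = int(card)
        records.append(
            EnergyRecord(
                method=str(row["method"]),
                cardinal=card,
                dE=float(row["dE_kcal"]),
                hf=float(row["hf_kcal"]) if "hf_kcal" in df.columns and pd.notna(row.get("hf_kcal")) else None,
                corr=float(row["corr_kcal"]) if "corr_kcal" in df.columns and pd.notna(row.get("corr_kcal")) else None,
            )
        )
    return records
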