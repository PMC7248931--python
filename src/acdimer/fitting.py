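"""Global van't Hoff fitting of fast-exchange shift data.

The experiment measures the internal shift difference dd(t) = d(OH) -
d(Me) of the vapor while its total pressure changes — either over time
in a leaky FEP insert at fixed temperature, or over temperature in a
sealed glass insert.  Fitting the two-state dimerization model to those
curves yields the dimerization enthalpy dH and entropy dS together
with the limiting dimer shift.

The FEP fit is *global*: dH and dS are shared across the datasets
measured at different temperatures, while the dimer limiting shift
delta_D and the baseline pressure correction p_corr are free per
dataset.  The monomer limiting shift delta_M is fixed to the value
obtained by zero-pressure extrapolation of a high-temperature dataset
(3.76 ppm for acetic acid).  Pressure tracks are rebuilt from the
intensity ratio inside the objective, so p_corr acts as a genuine model
parameter rather than a preprocessing step; the intensity-ratio track
is Savitzky-Golay smoothed (cubic, 21 points) once up front — smoothing
commutes with the subsequent linear scaling by p0 and the p_corr shift.

Parameter uncertainties come from Monte Carlo resampling of the anchor
pressures p0, the dominant error source: per iteration one systematic
relative error (default 10%) shared by all datasets and one independent
5% error per dataset are drawn, the anchors rescaled, and the whole
global fit repeated; standard deviations and the dH-dS covariance are
sample statistics over the iterations.  dG0 and its spread are computed
from the (dH, dS) sample directly, so their strong correlation is
honored without linearization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import least_squares

from .dimer_model import (
    R_KCAL,
    ShiftPair,
    ThermoState,
    equilibrium_constant,
    gibbs_energy,
)
from .pressure_calibration import VaporDecaySeries, smooth_track

__all__ = [
    "FepDataset",
    "GlassDataset",
    "GlobalFitResult",
    "FitConvergenceError",
    "IdentifiabilityError",
    "fit_fep_global",
    "fit_glass_dataset",
    "extrapolate_monomer_shift",
    "monte_carlo_uncertainty",
]

#: soft upper bound on the baseline pressure correction (atm); fitted
#: values above it trigger a warning (experimentally it stays below).
P_CORR_SOFT_BOUND = 0.005

_FTOL, _XTOL, _GTOL = 1e-10, 1e-8, 1e-8
_BOUNDS_DH = (-40.0, 0.0)
_BOUNDS_DS = (-80.0, 0.0)
_BOUNDS_PCORR = (0.0, 0.02)
_INIT_DH, _INIT_DS, _INIT_DELTA_D = -15.0, -36.0, 10.5


class FitConvergenceError(RuntimeError):
    """Optimizer failed; carries scipy's status message and residual norm."""


class IdentifiabilityError(ValueError):
    """The requested parameters cannot be determined from the data."""


@dataclass
class FepDataset:
    """One constant-temperature pressure-decay experiment.

    ``decay`` holds the raw intensity track and calibration anchors;
    ``dshift`` the observed d(OH) - d(Me) (ppm) at every time point of
    ``decay.t``.  Only points at or after ``decay.t0`` enter the fit.
    """

    T: float
    decay: VaporDecaySeries
    dshift: np.ndarray

    def __post_init__(self) -> None:
        self.dshift = np.asarray(self.dshift, dtype=float)
        if self.dshift.shape != self.decay.t.shape:
            raise ValueError("dshift must align with the decay time axis")
        if self.T <= 0:
            raise ValueError("temperature must be positive (K)")


@dataclass
class GlassDataset:
    """A sealed-tube temperature series: anchors (p0, T0) plus (T, dd) points."""

    p0: float
    T0: float
    points: list[tuple[float, float]]

    def temperatures(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    def dshifts(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)


@dataclass
class GlobalFitResult:
    """Everything the global FEP fit (and its Monte Carlo stage) reports."""

    thermo: ThermoState
    dG0: float
    delta_M: float
    delta_D_per_dataset: list[float]
    delta_D_mean: float
    p_corr_per_dataset: list[float]
    p0_per_dataset: list[float]
    temperatures: list[float]
    residual_norm: float
    n_fev: int
    sd_dH: float | None = None
    sd_dS: float | None = None
    sd_dG0: float | None = None
    cov_dH_dS: float | None = None
    sd_delta_D: list[float] | None = None
    sd_p_corr: list[float] | None = None
    mc_n_iter: int | None = None
    mc_seed: int | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thermo"] = {"dH": self.thermo.dH, "dS": self.thermo.dS}
        return d


def _prepared_tracks(
    datasets: list[FepDataset], sg_window: int, sg_order: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per dataset: (smoothed intensity ratio for t >= t0, observed dd)."""
    out = []
    for ds in datasets:
        mask = ds.decay.after_t0()
        if mask.sum() < 2:
            raise ValueError("dataset has fewer than 2 points after t0")
        ratio = ds.decay.I / ds.decay.intensity_at_t0()
        if ratio[mask].size >= sg_window:
            ratio_s = smooth_track(ratio[mask], window=sg_window, order=sg_order)
        else:
            ratio_s = ratio[mask]
        out.append((ratio_s, ds.dshift[mask]))
    return out


def _shift_model(dH, dS, delta_M, delta_D, T, p):
    """Vectorized model dd(p) at one temperature; p may contain zeros."""
    K = np.exp(-(dH - T * dS * 1e-3) / (R_KCAL * T))
    x_M = 2.0 / (1.0 + np.sqrt(1.0 + 8.0 * K * p))
    return x_M * (delta_M - delta_D) + delta_D


def fit_fep_global(
    datasets: list[FepDataset],
    delta_M: float,
    p0_per_dataset: list[float],
    sg_window: int = 21,
    sg_order: int = 3,
) -> GlobalFitResult:
    """Global nonlinear least-squares fit of the dimerization model.

    Parameters
    ----------
    datasets : list of FepDataset
        Pressure-decay experiments; at least two distinct temperatures
        are required for dH and dS to separate (at a single T they
        enter only through dG(T)).
    delta_M : float
        Fixed monomer limiting shift difference, ppm.
    p0_per_dataset : list of float
        Anchor pressures at each dataset's t0, atm.

    Returns
    -------
    GlobalFitResult
        Point estimates; standard deviations stay ``None`` until
        :func:`monte_carlo_uncertainty` fills them in.

    Raises
    ------
    IdentifiabilityError
        All datasets share one temperature.
    FitConvergenceError
        The trust-region optimizer reports failure.
    """
    if len(datasets) < 1:
        raise ValueError("need at least one dataset")
    if len(p0_per_dataset) != len(datasets):
        raise ValueError("need one anchor pressure per dataset")
    if not np.isfinite(delta_M):
        raise ValueError("delta_M must be finite")
    temps = [float(ds.T) for ds in datasets]
    if len(set(np.round(temps, 6))) < 2:
        raise IdentifiabilityError(
            "dH and dS are not separately identifiable from a single "
            "temperature: they enter the model only through dG(T). "
            "Degenerate parameters: dH, dS"
        )

    tracks = _prepared_tracks(datasets, sg_window, sg_order)
    n_ds = len(datasets)

    def unpack(theta):
        dH, dS = theta[0], theta[1]
        delta_D = theta[2 : 2 + n_ds]
        p_corr = theta[2 + n_ds :]
        return dH, dS, delta_D, p_corr

    def residuals(theta):
        dH, dS, delta_D, p_corr = unpack(theta)
        res = []
        for k, (ratio_s, dd_obs) in enumerate(tracks):
            p = np.clip(ratio_s * p0_per_dataset[k] - p_corr[k], 0.0, None)
            res.append(_shift_model(dH, dS, delta_M, delta_D[k], temps[k], p) - dd_obs)
        return np.concatenate(res)

    theta0 = np.concatenate(
        [[_INIT_DH, _INIT_DS], np.full(n_ds, _INIT_DELTA_D), np.zeros(n_ds)]
    )
    lower = np.concatenate(
        [[_BOUNDS_DH[0], _BOUNDS_DS[0]], np.full(n_ds, delta_M), np.full(n_ds, _BOUNDS_PCORR[0])]
    )
    upper = np.concatenate(
        [[_BOUNDS_DH[1], _BOUNDS_DS[1]], np.full(n_ds, 20.0), np.full(n_ds, _BOUNDS_PCORR[1])]
    )
    sol = least_squares(
        residuals, theta0, bounds=(lower, upper), ftol=_FTOL, xtol=_XTOL, gtol=_GTOL
    )
    if not sol.success:
        raise FitConvergenceError(
            f"global fit did not converge: {sol.message} "
            f"(residual norm {np.linalg.norm(sol.fun):.3g})"
        )
    dH, dS, delta_D, p_corr = unpack(sol.x)
    if np.any(p_corr > P_CORR_SOFT_BOUND):
        warnings.warn(
            f"fitted p_corr exceeds {P_CORR_SOFT_BOUND} atm for dataset(s) "
            f"{list(np.nonzero(p_corr > P_CORR_SOFT_BOUND)[0])}; check the baseline",
            UserWarning,
            stacklevel=2,
        )
    thermo = ThermoState(float(dH), float(dS))
    return GlobalFitResult(
        thermo=thermo,
        dG0=gibbs_energy(thermo, 298.15),
        delta_M=float(delta_M),
        delta_D_per_dataset=[float(v) for v in delta_D],
        delta_D_mean=float(np.mean(delta_D)),
        p_corr_per_dataset=[float(v) for v in p_corr],
        p0_per_dataset=[float(v) for v in p0_per_dataset],
        temperatures=temps,
        residual_norm=float(np.linalg.norm(sol.fun)),
        n_fev=int(sol.nfev),
    )


def fit_glass_dataset(dataset: GlassDataset) -> dict:
    """Fit one sealed-tube temperature series on its own.

    Four free parameters — dH, dS and *both* limiting shifts — since
    the temperature sweep covers both the dimer-rich and monomer-rich
    regimes.  The pressure at each temperature follows the isochoric
    track ``p0 * T / T0``.

    Returns a dict with keys ``thermo``, ``delta_M``, ``delta_D``,
    ``residual_norm``.
    """
    T = dataset.temperatures()
    dd = dataset.dshifts()
    if T.size < 6:
        raise ValueError("need at least 6 temperature points")
    if np.ptp(T) < 50.0:
        raise ValueError("temperature span must be at least 50 K")
    p = dataset.p0 * T / dataset.T0

    def residuals(theta):
        dH, dS, dM, dD = theta
        return _shift_model(dH, dS, dM, dD, T, p) - dd

    # residuals is vectorized over T because _shift_model broadcasts
    theta0 = np.array([_INIT_DH, _INIT_DS, 3.8, _INIT_DELTA_D])
    lower = np.array([_BOUNDS_DH[0], _BOUNDS_DS[0], 0.0, 0.0])
    upper = np.array([_BOUNDS_DH[1], _BOUNDS_DS[1], 10.0, 20.0])
    sol = least_squares(residuals, theta0, bounds=(lower, upper), ftol=_FTOL, xtol=_XTOL, gtol=_GTOL)
    if not sol.success:
        raise FitConvergenceError(f"glass fit did not converge: {sol.message}")
    dH, dS, dM, dD = sol.x
    return {
        "thermo": ThermoState(float(dH), float(dS)),
        "delta_M": float(dM),
        "delta_D": float(dD),
        "residual_norm": float(np.linalg.norm(sol.fun)),
    }


def extrapolate_monomer_shift(dataset: FepDataset, p0: float) -> float:
    """Zero-pressure limit of dd at one (high) temperature.

    At a single temperature the thermodynamics collapse to one number,
    the equilibrium constant K at that T, so the dd-vs-pressure curve
    is fitted in the (delta_M, delta_D, log10 K) parametrization and
    the p -> 0 intercept delta_M returned.  Run on the hottest dataset
    (150 C for acetic acid), where dimerization is weak and the
    extrapolation shortest.
    """
    mask = dataset.decay.after_t0()
    ratio = dataset.decay.I / dataset.decay.intensity_at_t0()
    ratio_s = smooth_track(ratio[mask]) if ratio[mask].size >= 21 else ratio[mask]
    p = np.clip(ratio_s * p0 - dataset.decay.p_corr, 0.0, None)
    dd = dataset.dshift[mask]
    p_pos = p[p > 0]
    if p_pos.size == 0 or p_pos.min() >= 0.3 * p_pos.max():
        raise ValueError(
            "insufficient pressure span for zero-pressure extrapolation "
            "(need p_min < 0.3 p_max)"
        )

    def residuals(theta):
        dM, dD, log10K = theta
        K = 10.0 ** log10K
        x_M = 2.0 / (1.0 + np.sqrt(1.0 + 8.0 * K * p))
        return x_M * (dM - dD) + dD - dd

    theta0 = np.array([np.max(dd) - 1.0, np.max(dd) + 2.0, 0.0])
    sol = least_squares(
        residuals,
        theta0,
        bounds=(np.array([-5.0, 0.0, -6.0]), np.array([15.0, 25.0, 8.0])),
        ftol=_FTOL, xtol=_XTOL, gtol=_GTOL,
    )
    if not sol.success:
        raise FitConvergenceError(f"extrapolation fit did not converge: {sol.message}")
    return float(sol.x[0])


def monte_carlo_uncertainty(
    datasets: list[FepDataset],
    base_fit: GlobalFitResult,
    n_iter: int = 1000,
    sys_frac: float = 0.10,
    ds_frac: float = 0.05,
    seed: int | None = None,
    max_failure_frac: float = 0.05,
) -> GlobalFitResult:
    """Propagate anchor-pressure uncertainty by Monte Carlo refitting.

    Per iteration one systematic relative error (shared by every
    dataset) and one independent per-dataset error are drawn from
    centered normals with the given fractional widths; each anchor is
    rescaled by (1 + eps_sys + eps_k), redrawing any non-positive
    factor, and the global fit repeated.  Sample standard deviations of
    dH, dS, dG0(298.15 K), per-dataset delta_D and p_corr, and the
    dH-dS covariance are written onto a copy of ``base_fit``.

    Deterministic for a given ``seed``.  Raises if more than
    ``max_failure_frac`` of the refits fail to converge.
    """
    if seed is None:
        raise ValueError("seed is mandatory for the Monte Carlo stage")
    if n_iter < 2:
        raise ValueError("need at least 2 iterations")
    rng = np.random.default_rng(seed)
    p0_base = np.asarray(base_fit.p0_per_dataset, dtype=float)
    n_ds = len(datasets)

    samples = {"dH": [], "dS": [], "dG0": [], "delta_D": [], "p_corr": []}
    failures: list[str] = []
    for _ in range(n_iter):
        while True:
            eps_sys = rng.normal(0.0, sys_frac)
            eps_ds = rng.normal(0.0, ds_frac, size=n_ds)
            factors = 1.0 + eps_sys + eps_ds
            if np.all(factors > 0):
                break
        p0_draw = p0_base * factors
        try:
            fit = fit_fep_global(datasets, base_fit.delta_M, list(p0_draw))
        except (FitConvergenceError, ValueError) as exc:  # pragma: no cover - rare
            failures.append(str(exc))
            continue
        samples["dH"].append(fit.thermo.dH)
        samples["dS"].append(fit.thermo.dS)
        samples["dG0"].append(fit.dG0)
        samples["delta_D"].append(fit.delta_D_per_dataset)
        samples["p_corr"].append(fit.p_corr_per_dataset)

    if len(failures) > max_failure_frac * n_iter:
        raise FitConvergenceError(
            f"{len(failures)}/{n_iter} Monte Carlo refits failed; first: {failures[0]}"
        )

    dH_s = np.array(samples["dH"])
    dS_s = np.array(samples["dS"])
    dG_s = np.array(samples["dG0"])
    dD_s = np.array(samples["delta_D"])
    pc_s = np.array(samples["p_corr"])
    out = GlobalFitResult(**{**base_fit.__dict__})
    out.sd_dH = float(np.std(dH_s, ddof=1))
    out.sd_dS = float(np.std(dS_s, ddof=1))
    out.sd_dG0 = float(np.std(dG_s, ddof=1))
    out.cov_dH_dS = float(np.cov(dH_s, dS_s, ddof=1)[0, 1])
    out.sd_delta_D = [float(v) for v in np.std(dD_s, axis=0, ddof=1)]
    out.sd_p_corr = [float(v) for v in np.std(pc_s, axis=0, ddof=1)]
    out.mc_n_iter = n_iter
    out.mc_seed = seed
    return out
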