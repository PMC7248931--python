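"""Synthetic datasets with the statistical structure the analysis assumes.

The experimental raw data behind this analysis (pressure-decay NMR
series of acetic acid vapor) are not deposited anywhere, so every stage
of the pipeline is exercised on synthetic data generated here.  The
generator's defaults ARE the study conditions:

* thermodynamics dH = -15.4 kcal/mol, dS = -36.6 cal/(mol K) and
  limiting shifts delta_M = 3.76 ppm, delta_D = 10.55 ppm — the
  experimental estimates for acetic acid;
* four FEP datasets at 25, 60, 80 and 100 C, anchor pressures taken
  from the saturation pressure at each temperature (the physical anchor
  of the real calibration), one spectrum per 150 s (2.5 min acquisition),
  800 points per dataset;
* exponential pressure decay (leak) with a decay constant chosen so the
  pressure falls roughly six-fold over the acquisition window, leaking
  faster at higher temperature;
* a small constant baseline-pressure distortion (default 0.002 atm,
  the scale the p_corr nuisance parameter absorbs);
* Gaussian noise: 0.02 ppm on the shift difference and 1% relative on
  intensities, independently seeded channels.

Ground truth is returned beside every dataset so recovery is a
field-wise diff.  Same seed, same data — bit for bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dimer_model import ShiftPair, ThermoState, predict_shift
from .fitting import FepDataset, GlassDataset
from .pressure_calibration import (
    AntoineRangeWarning,
    VaporDecaySeries,
    acetic_acid_antoine,
    antoine_pressure,
    glass_pressure_track,
    write_decay_csv,
)
from .spectra import Spectrum, lorentzian_profile

__all__ = [
    "GeneratorConfig",
    "default_config",
    "simulate_fep_dataset",
    "simulate_fep_ensemble",
    "simulate_glass_dataset",
    "simulate_spectrum_series",
    "write_fep_dataset_csv",
    "write_truth_json",
]

#: Experimental parameter estimates for acetic acid used as generator defaults.
DEFAULT_THERMO = ThermoState(dH=-15.4, dS=-36.6)
DEFAULT_DELTA_M = 3.76
DEFAULT_DELTA_D = 10.55
DEFAULT_TEMPERATURES = (298.15, 333.15, 353.15, 373.15)


@dataclass
class GeneratorConfig:
    """Everything the generators need, with validation.

    ``delta_D`` may be a scalar (shared) or one value per dataset.
    ``seed`` is mandatory; all randomness flows from it through
    independent child streams per dataset and per noise channel.
    """

    thermo: ThermoState
    delta_M: float
    delta_D: list[float]
    temperatures: list[float]
    p0_per_dataset: list[float]
    tau_per_dataset: list[float]
    baseline_offset_per_dataset: list[float]
    n_points: int
    dt: float
    sigma_delta: float
    sigma_I: float
    seed: int

    def __post_init__(self) -> None:
        n = len(self.temperatures)
        if np.isscalar(self.delta_D):
            self.delta_D = [float(self.delta_D)] * n
        for name in ("delta_D", "p0_per_dataset", "tau_per_dataset", "baseline_offset_per_dataset"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per temperature")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.dt <= 0 or any(tau <= 0 for tau in self.tau_per_dataset):
            raise ValueError("time scales must be positive")
        if any(p <= 0 for p in self.p0_per_dataset):
            raise ValueError("anchor pressures must be positive")
        if self.sigma_delta < 0 or self.sigma_I < 0:
            raise ValueError("noise scales must be non-negative")
        if any(b < 0 for b in self.baseline_offset_per_dataset):
            raise ValueError("baseline offsets must be non-negative")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def shifts(self, k: int) -> ShiftPair:
        return ShiftPair(self.delta_M, self.delta_D[k])


def default_config(
    seed: int,
    temperatures=DEFAULT_TEMPERATURES,
    n_points: int = 800,
    dt: float = 150.0,
    sigma_delta: float = 0.02,
    sigma_I: float = 0.01,
    baseline_offset: float | list[float] = 0.002,
    decay_factor: float = 6.0,
) -> GeneratorConfig:
    """Study-condition configuration.

    Anchor pressures are the Antoine saturation pressures at each
    experiment temperature (the state of the vapor the moment the last
    liquid evaporates).  Decay constants give a ``decay_factor``-fold
    pressure drop over the window at the coolest temperature and
    proportionally faster leaks when hotter.
    """
    temperatures = list(temperatures)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", AntoineRangeWarning)
        p0 = [antoine_pressure(T, acetic_acid_antoine()) for T in temperatures]
    window = n_points * dt
    T_ref = min(temperatures)
    tau = [window / np.log(decay_factor) * (T_ref / T) ** 2 for T in temperatures]
    if np.isscalar(baseline_offset):
        baseline_offset = [float(baseline_offset)] * len(temperatures)
    return GeneratorConfig(
        thermo=DEFAULT_THERMO,
        delta_M=DEFAULT_DELTA_M,
        delta_D=[DEFAULT_DELTA_D] * len(temperatures),
        temperatures=temperatures,
        p0_per_dataset=p0,
        tau_per_dataset=tau,
        baseline_offset_per_dataset=list(baseline_offset),
        n_points=n_points,
        dt=dt,
        sigma_delta=sigma_delta,
        sigma_I=sigma_I,
        seed=seed,
    )


def _child_rngs(seed: int, dataset_index: int, n_channels: int = 2):
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(dataset_index,))
    return [np.random.default_rng(c) for c in ss.spawn(n_channels)]


def simulate_fep_dataset(cfg: GeneratorConfig, dataset_index: int) -> tuple[FepDataset, dict]:
    """One leaky-insert experiment at ``cfg.temperatures[dataset_index]``.

    The intensity decays exponentially with multiplicative Gaussian
    noise; the *noiseless* intensity ratio defines the true pressure via
    the same baseline-corrected relation the fit inverts, so fitting the
    true parameters has zero expected residual.  Shift noise is additive
    on the model-evaluated dd.

    Returns the dataset and a ground-truth record (keys mirror the
    fit-result fields so scoring is a field-wise diff).
    """
    k = dataset_index
    T = cfg.temperatures[k]
    p0 = cfg.p0_per_dataset[k]
    tau = cfg.tau_per_dataset[k]
    offset = cfg.baseline_offset_per_dataset[k]
    rng_I, rng_d = _child_rngs(cfg.seed, k)

    t = cfg.dt * np.arange(cfg.n_points)
    I0 = 1000.0
    I_clean = I0 * np.exp(-t / tau)
    I = I_clean * (1.0 + rng_I.normal(0.0, cfg.sigma_I, size=t.size)) if cfg.sigma_I > 0 else I_clean.copy()

    p_true = np.clip((I_clean / I0) * p0 - offset, 0.0, None)
    dd = predict_shift(cfg.thermo, cfg.shifts(k), T, p_true)
    if cfg.sigma_delta > 0:
        dd = dd + rng_d.normal(0.0, cfg.sigma_delta, size=t.size)

    decay = VaporDecaySeries(t=t, I=I, t0=float(t[0]), p0=p0, p_corr=offset)
    dataset = FepDataset(T=T, decay=decay, dshift=dd)
    truth = {
        "thermo": {"dH": cfg.thermo.dH, "dS": cfg.thermo.dS},
        "delta_M": cfg.delta_M,
        "delta_D": cfg.delta_D[k],
        "p_corr": offset,
        "p0": p0,
        "T": T,
        "tau": tau,
        "seed": cfg.seed,
        "dataset_index": k,
    }
    return dataset, truth


def simulate_fep_ensemble(cfg: GeneratorConfig) -> tuple[list[FepDataset], list[dict]]:
    """All datasets of the configuration, with their truth records."""
    pairs = [simulate_fep_dataset(cfg, k) for k in range(len(cfg.temperatures))]
    return [p[0] for p in pairs], [p[1] for p in pairs]


def simulate_glass_dataset(
    cfg: GeneratorConfig,
    p0: float,
    T0: float,
    T_grid,
    bias_amplitude: float = 0.0,
    bias_scale_K: float = 2000.0,
) -> GlassDataset:
    """A sealed-tube temperature series.

    dd(T) follows the dimerization model with the isochoric pressure
    track p0*T/T0 plus Gaussian shift noise.  ``bias_amplitude`` > 0
    injects a temperature-dependent systematic b(T) = b0 *
    exp(-bias_scale_K/T) (ppm) emulating exchange with wall-adsorbed
    molecules — an Arrhenius-like confound that grows with temperature
    and drags the fitted thermodynamics, as surface interaction did in
    glass-tube experiments.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(9001,)))
    p = glass_pressure_track(T_grid, p0, T0)
    dd = np.array(
        [predict_shift(cfg.thermo, ShiftPair(cfg.delta_M, cfg.delta_D[0]), T, pt)
         for T, pt in zip(T_grid, p)]
    )
    if bias_amplitude != 0.0:
        dd = dd + bias_amplitude * np.exp(-bias_scale_K / T_grid)
    if cfg.sigma_delta > 0:
        dd = dd + rng.normal(0.0, cfg.sigma_delta, size=T_grid.size)
    return GlassDataset(p0=p0, T0=T0, points=list(zip(T_grid.tolist(), dd.tolist())))


def simulate_spectrum_series(
    cfg: GeneratorConfig,
    dataset: FepDataset,
    indices=None,
    me_position: float = 2.0,
    axis=None,
    oh_width: float = 0.06,
    me_width: float = 0.03,
    snr: float = 200.0,
    baseline_coefs=(0.5, -0.1, 0.02, 0.0, 0.0, -0.005),
) -> list[Spectrum]:
    """Two-Lorentzian spectra for (a subset of) the dataset's time points.

    The methyl peak sits at ``me_position`` and the OH peak at
    ``me_position + dd(t)``; a polynomial baseline (5th order by
    default) and white noise at the given peak SNR are added.  Running
    baseline correction and peak fitting on the output recovers the
    generating dd within noise.
    """
    if indices is None:
        indices = range(dataset.dshift.size)
    if axis is None:
        axis = np.linspace(-1.0, 16.0, 4096)
    axis = np.asarray(axis, dtype=float)
    x0 = (axis - axis.mean()) / (np.ptp(axis) / 2.0)
    baseline = np.polynomial.polynomial.polyval(x0, np.asarray(baseline_coefs, float))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(7001,)))
    spectra = []
    for i in indices:
        dd = float(dataset.dshift[i])
        y = (
            lorentzian_profile(axis, me_position, me_width, 1.0)
            + lorentzian_profile(axis, me_position + dd, oh_width, 0.6)
            + baseline
        )
        if snr and np.isfinite(snr):
            y = y + rng.normal(0.0, 1.0 / snr, size=axis.size)
        spectra.append(Spectrum(axis.copy(), y))
    return spectra


def write_fep_dataset_csv(dataset: FepDataset, path: str | Path) -> None:
    """Write a dataset in the decay-series CSV dialect the readers consume."""
    write_decay_csv(path, dataset.decay.t, dataset.decay.I, dshift=dataset.dshift)


def write_truth_json(truths: list[dict], path: str | Path) -> None:
    """Ground-truth sidecar for a generated ensemble."""
    Path(path).write_text(json.dumps(truths, indent=2))
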