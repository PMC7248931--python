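#!/usr/bin/env python
"""Global van't Hoff fit of the four-temperature ensemble.

Reads the simulated decay datasets, rebuilds pressure tracks from the
intensity ratios, and fits dH/dS (shared) plus per-dataset dimer shift
and baseline correction, followed by 1000-iteration Monte Carlo
propagation of the 10% systematic + 5% per-dataset anchor-pressure
uncertainty.  Writes results/fit_report.json.
"""

import json
from pathlib import Path

import numpy as np

from acdimer import FepDataset, VaporDecaySeries, fit_fep_global, monte_carlo_uncertainty
from acdimer.pressure_calibration import read_decay_csv

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 2027
DELTA_M = 3.76  # fixed monomer shift from the 150 C extrapolation
TEMPS_C = (25, 60, 80, 100)


def main() -> None:
    sim = ROOT / "simulated"
    config = json.loads((sim / "config.json").read_text())
    datasets = []
    for tc, T_K in zip(TEMPS_C, config["temperatures_K"]):
        df = read_decay_csv(sim / f"fep_{tc}C.csv")
        t = df["time_s"].to_numpy()
        decay = VaporDecaySeries(t=t, I=df["intensity"].to_numpy(), t0=float(t[0]), p0=1.0)
        datasets.append(FepDataset(T=T_K, decay=decay, dshift=df["dshift_ppm"].to_numpy()))

    fit = fit_fep_global(datasets, DELTA_M, config["p0_atm"])
    fit = monte_carlo_uncertainty(datasets, fit, n_iter=1000, seed=SEED)

    truth = json.loads((sim / "truth.json").read_text())[0]
    print("Global dimerization fit (truth in parentheses):")
    print(f"  dH  = {fit.thermo.dH:7.2f} +/- {fit.sd_dH:.2f} kcal/mol   ({truth['thermo']['dH']})")
    print(f"  dS  = {fit.thermo.dS:7.2f} +/- {fit.sd_dS:.2f} cal/mol K  ({truth['thermo']['dS']})")
    print(f"  dG0 = {fit.dG0:7.2f} +/- {fit.sd_dG0:.2f} kcal/mol at 298.15 K")
    print(f"  delta_D mean = {fit.delta_D_mean:.2f} ppm ({truth['delta_D']})")
    print(f"  p_corr (atm) = {[round(v, 4) for v in fit.p_corr_per_dataset]} "
          f"-- all below the 0.005 ceiling: {max(fit.p_corr_per_dataset) < 0.005}")
    print(f"  cov(dH, dS) = {fit.cov_dH_dS:.4f} (positive: errors move together, "
          f"so dG0 is much better determined than dH)")

    out = ROOT / "fit_report.json"
    out.write_text(json.dumps({"seed": SEED, "result": fit.to_dict()}, indent=2))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
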