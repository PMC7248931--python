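#!/usr/bin/env python
"""Generate the synthetic measurement campaign.

Emulates the leaky-insert (FEP) experiments: four pressure-decay
datasets at 25/60/80/100 C plus one at 150 C for the zero-pressure
monomer-shift extrapolation, all at the experimental parameter
estimates for acetic acid (dH = -15.4 kcal/mol, dS = -36.6 cal/mol K,
monomer/dimer shifts 3.76/10.55 ppm, 0.02 ppm shift noise).  Writes
CSVs plus a ground-truth sidecar under results/simulated/.
"""

import json
from pathlib import Path

from acdimer import default_config, simulate_fep_dataset, simulate_fep_ensemble
from acdimer.synthetic_data import write_fep_dataset_csv, write_truth_json

SEED = 2026
OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_config(seed=SEED)
    datasets, truths = simulate_fep_ensemble(cfg)
    for ds in datasets:
        path = OUT / f"fep_{ds.T - 273.15:.0f}C.csv"
        write_fep_dataset_csv(ds, path)
        print(f"wrote {path.name}: {ds.dshift.size} points at {ds.T:.2f} K, "
              f"p0 = {ds.decay.p0:.4f} atm")

    cfg_hot = default_config(seed=SEED + 1, temperatures=[423.15])
    ds_hot, truth_hot = simulate_fep_dataset(cfg_hot, 0)
    write_fep_dataset_csv(ds_hot, OUT / "fep_150C.csv")
    print(f"wrote fep_150C.csv: {ds_hot.dshift.size} points, "
          f"p0 = {ds_hot.decay.p0:.4f} atm (for monomer-shift extrapolation)")

    write_truth_json(truths + [truth_hot], OUT / "truth.json")
    (OUT / "config.json").write_text(json.dumps({
        "seed": SEED, "temperatures_K": cfg.temperatures,
        "p0_atm": cfg.p0_per_dataset, "tau_s": cfg.tau_per_dataset,
        "baseline_offsets_atm": cfg.baseline_offset_per_dataset,
        "n_points": cfg.n_points, "dt_s": cfg.dt,
        "sigma_delta_ppm": cfg.sigma_delta, "sigma_I_rel": cfg.sigma_I,
    }, indent=2, default=float))
    print("wrote truth.json and config.json")


if __name__ == "__main__":
    main()
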