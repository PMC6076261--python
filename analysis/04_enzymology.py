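#!/usr/bin/env python
"""Fit the kinetic models to the simulated assay tables.

Reads results/sim_*.csv (from 01_simulate_data.py); writes fitted IC50,
inhibition-mode call, global Ki and binding KD to results/enzymology.json.
"""

import argparse
from pathlib import Path

import pandas as pd

from punctaflux import enzymology, io
from punctaflux.enzymology import CiConfig
from punctaflux.types import RateTable

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-boot", type=int, default=499)
    args = ap.parse_args()

    results = ROOT / "results"
    ci = CiConfig(method="bootstrap", n_boot=args.n_boot, seed=args.seed)

    doses = pd.read_csv(results / "sim_dose_response.csv").query("~is_truth")
    ic50 = enzymology.fit_ic50(doses.conc_M, doses.response, ci)

    grid = pd.read_csv(results / "sim_inhibition_grid.csv").query("~is_truth")
    table = RateTable(substrate_M=grid.substrate_M.to_numpy(),
                      inhibitor_M=grid.inhibitor_M.to_numpy(),
                      rate_M_per_s=grid.rate_M_per_s.to_numpy(),
                      replicate=grid.replicate.to_numpy())
    mode = enzymology.diagnose_inhibition_mode(
        enzymology.fit_inhibition_grid(table))
    ki = enzymology.fit_uncompetitive_ki(table, ci)

    binding = pd.read_csv(results / "sim_binding_titration.csv") \
        .query("~is_truth")
    kd = enzymology.fit_binding_kd(binding.ligand_M, binding.signal,
                                   p0_M=0.17e-6, ci=ci)

    payload = {"seed": args.seed, "ic50": ic50, "inhibition_mode": mode,
               "uncompetitive_global": ki, "binding": kd}
    io.write_json(payload, results / "enzymology.json")
    print(f"IC50 {ic50.estimates['ic50_M'] / 1e-6:.2f} uM; "
          f"mode {mode}; Ki {ki.estimates['ki_M'] / 1e-6:.2f} uM; "
          f"KD {kd.estimates['kd_M'] / 1e-6:.2f} uM")


if __name__ == "__main__":
    main()
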