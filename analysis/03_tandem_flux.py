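#!/usr/bin/env python
"""Score tandem-reporter autophagic flux on the simulated fields.

Reads scratch/data/tandem_* (from 01_simulate_data.py); writes pooled
red-only:yellow ratios per generated autolysosome fraction to results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from punctaflux import io, tandem
from punctaflux.synthgen import FieldSpec
from punctaflux.tandem import TandemConfig

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    args = ap.parse_args()

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    cfg = TandemConfig(cell_radius_px=FieldSpec().cell_radius_px)

    rows = []
    for frac, sub in ((0.2, "tandem_02"), (0.5, "tandem_05"),
                      (0.8, "tandem_08")):
        data = ROOT / "scratch" / "data" / sub
        total_red = total_yellow = 0
        for tif in sorted(data.glob("field_*.tif")):
            field = io.read_field_tiff(tif)
            gt = json.loads(
                tif.with_name(tif.stem + "_truth.json").read_text())
            summary = tandem.quantify_tandem_field(field, cfg)
            n_red_true = sum(p["color_class"] == "red_only"
                             for p in gt["puncta"])
            n_yellow_true = len(gt["puncta"]) - n_red_true
            for rec in summary.per_cell:
                total_red += rec["n_red_only"]
                total_yellow += rec["n_yellow"]
            rows.append({
                "field_id": f"{sub}/{tif.stem}",
                "red_only_fraction": frac,
                "pooled_ratio": summary.pooled_ratio,
                "true_ratio": (n_red_true / n_yellow_true
                               if n_yellow_true else None),
                "n_cells": summary.n_cells_analyzed,
            })
        print(f"fraction {frac}: pooled ratio "
              f"{total_red / total_yellow:.4f} over {sub}")

    pd.DataFrame(rows).to_csv(results / "tandem_flux.csv", index=False)


if __name__ == "__main__":
    main()
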