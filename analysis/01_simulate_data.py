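#!/usr/bin/env python
"""Generate the synthetic study data: HCS fields, tandem fields, assay tables.

Images (binary TIFF) go to scratch/data/; assay tables (CSV) to results/.
Downstream scripts 02-04 consume these outputs.
"""

import argparse
from pathlib import Path

from punctaflux import io, synthgen

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-fields", type=int, default=8)
    args = ap.parse_args()

    data = ROOT / "scratch" / "data"
    results = ROOT / "results"
    for sub in ("hcs", "tandem_02", "tandem_05", "tandem_08"):
        (data / sub).mkdir(parents=True, exist_ok=True)
    results.mkdir(exist_ok=True)

    for k in range(args.n_fields):
        spec = synthgen.FieldSpec(seed=args.seed + k)
        field, gt = synthgen.gen_hcs_field(spec)
        io.write_field_tiff(field, data / "hcs" / f"field_{k:03d}.tif")
        io.write_ground_truth_json(gt, data / "hcs" / f"field_{k:03d}_truth.json")

    for frac, sub in ((0.2, "tandem_02"), (0.5, "tandem_05"),
                      (0.8, "tandem_08")):
        for k in range(args.n_fields):
            spec = synthgen.FieldSpec(seed=args.seed + 100 + k)
            field, gt = synthgen.gen_tandem_field(spec, red_only_fraction=frac)
            io.write_field_tiff(field, data / sub / f"field_{k:03d}.tif")
            io.write_ground_truth_json(gt,
                                       data / sub / f"field_{k:03d}_truth.json")

    # binding uses additive noise: 5% CV of the ~800-unit baseline would
    # swamp the 200-unit binding amplitude
    for model, name, noise in (
            ("fourPL", "dose_response", {"noise_cv": 0.05}),
            ("michaelis_menten_uncompetitive", "inhibition_grid",
             {"noise_cv": 0.05}),
            ("binding_1to1", "binding_titration", {"noise_sd": 10.0})):
        spec = synthgen.default_assay_spec(model, seed=args.seed, **noise)
        synthgen.gen_assay_table(spec).to_csv(
            results / f"sim_{name}.csv", index=False)

    print(f"wrote images under {data} and assay tables under {results}")


if __name__ == "__main__":
    main()
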