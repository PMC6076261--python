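"""File I/O: multi-page TIFF fields, ground-truth sidecars, assay CSVs.

Images travel as multi-page TIFF with one page per channel and the channel
role recorded in each page's description tag.  Assay tables are CSV with
unit-suffixed columns (``substrate_uM``, ``rate_M_per_s``, ...); values are
converted to molar on read.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthgen import GroundTruth
from .types import LabeledField, RateTable

__all__ = [
    "UNIT_FACTORS",
    "to_molar",
    "write_field_tiff",
    "read_field_tiff",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "write_rate_table_csv",
    "read_rate_table_csv",
    "write_json",
]

UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9}


def to_molar(values, unit: str) -> np.ndarray:
    if unit not in UNIT_FACTORS:
        raise ValueError(f"unknown concentration unit {unit!r}")
    return np.asarray(values, dtype=float) * UNIT_FACTORS[unit]


def write_field_tiff(field: LabeledField, path) -> None:
    """One float32 page per channel; the role goes in the page description."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for role in sorted(field.channels):
            tif.write(field.channels[role].astype(np.float32),
                      description=json.dumps({"channel_role": role}),
                      contiguous=False)


def read_field_tiff(path) -> LabeledField:
    channels = {}
    with tifffile.TiffFile(path) as tif:
        for page in tif.pages:
            desc = page.tags.get("ImageDescription")
            role = None
            if desc is not None:
                try:
                    role = json.loads(desc.value).get("channel_role")
                except (json.JSONDecodeError, AttributeError):
                    role = None
            if role is None:
                role = f"channel_{len(channels)}"
            channels[role] = page.asarray().astype(float)
    return LabeledField(channels=channels, provenance=str(path))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_jsonify(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(
        json.dumps(_jsonify(obj), sort_keys=True, indent=2) + "\n")


def write_ground_truth_json(gt: GroundTruth, path) -> None:
    write_json({"cells": gt.cells, "puncta": gt.puncta,
                "per_cell_counts": gt.per_cell_counts}, path)


def read_ground_truth_json(path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    gt = GroundTruth()
    for c in data["cells"]:
        c = dict(c)
        c["center"] = tuple(c["center"])
        gt.cells.append(c)
    for p in data["puncta"]:
        p = dict(p)
        p["center"] = tuple(p["center"])
        gt.puncta.append(p)
    gt.validate()
    return gt


def write_rate_table_csv(table: RateTable, path) -> None:
    pd.DataFrame({
        "substrate_uM": table.substrate_M / UNIT_FACTORS["uM"],
        "inhibitor_uM": table.inhibitor_M / UNIT_FACTORS["uM"],
        "rate_M_per_s": table.rate_M_per_s,
        "replicate": table.replicate,
    }).to_csv(path, index=False)


def _conc_column(df: pd.DataFrame, stem: str) -> np.ndarray:
    """Read a concentration column by unit suffix, converting to molar."""
    for unit in UNIT_FACTORS:
        col = f"{stem}_{unit}"
        if col in df.columns:
            return to_molar(df[col].to_numpy(), unit)
    raise ValueError(f"no {stem} column with a recognized unit suffix")


def read_rate_table_csv(path) -> RateTable:
    df = pd.read_csv(path)
    if "is_truth" in df.columns:
        df = df[~df["is_truth"]]
    rep = df["replicate"].to_numpy() if "replicate" in df.columns \
        else np.zeros(len(df), dtype=int)
    return RateTable(
        substrate_M=_conc_column(df, "substrate"),
        inhibitor_M=_conc_column(df, "inhibitor"),
        rate_M_per_s=df["rate_M_per_s"].to_numpy(),
        replicate=rep,
    )
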