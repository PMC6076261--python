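"""Seeded synthetic-data generators with full ground truth.

The generators emulate every input the quantification pipeline consumes:

* adherent-cell fluorescence fields (disc-like nuclei, diffuse cytoplasm,
  punctate GFP structures, a viability-stain mask over the dead-cell subset,
  Poisson + Gaussian noise and a background gradient);
* tandem-reporter fields in which each punctum is red-only (autolysosome)
  or yellow (autophagosome, co-located red+green signal);
* assay tables drawn from the closed-form models (4PL dose-response,
  Michaelis-Menten with inhibition terms, 1:1 binding, one-compartment oral
  PK, linear progress curves) with controlled noise.

Everything is driven by one integer seed through an order-stable stream of
sub-seeds, so identical specs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import models
from .types import LabeledField

__all__ = [
    "FieldSpec",
    "GroundTruth",
    "AssaySpec",
    "gen_hcs_field",
    "gen_tandem_field",
    "gen_assay_table",
    "PAPER_SUBSTRATE_GRID_uM",
    "PAPER_INHIBITOR_GRID_uM",
]

# The protease-assay design: substrate 10-124.4 µM, inhibitor 6-54 µM
# (plus the uninhibited baseline).
PAPER_SUBSTRATE_GRID_uM = tuple(
    np.round(np.geomspace(10.0, 124.4, 6), 3)
)  # (10, 16.553, 27.4, 45.35, 75.063, 124.4)
PAPER_INHIBITOR_GRID_uM = (0.0, 6.0, 18.0, 54.0)


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic fluorescence field.

    Defaults emulate a 20x high-content field of adherent cells: ~50 cells
    per 512x512 field, nuclei well inside the cell disc, a handful of
    bright puncta per cell, shot noise plus read noise, and a shallow
    illumination gradient.
    """

    width: int = 512
    height: int = 512
    n_cells: int = 50
    cell_radius_px: float = 18.0
    nucleus_radius_px: float = 6.0
    dead_fraction: float = 0.2
    puncta_per_cell_dist: tuple[str, float] = ("poisson", 4.0)
    punctum_radius_px: float = 2.0
    punctum_peak: float = 800.0
    background_level: float = 100.0
    background_gradient: float = 0.05  # intensity per pixel, along columns
    noise_gaussian_sd: float = 8.0
    noise_poisson: bool = True
    min_cell_separation_px: float = 40.0
    seed: int = 0
    # secondary rendering knobs (kept out of the acceptance-facing surface)
    nucleus_peak: float = 600.0
    cytoplasm_level: float = 60.0
    dead_stain_peak: float = 500.0
    dead_overlap_fraction: float = 0.8
    ambiguous_overlap: bool = False  # draw overlap ~ U(0.4, 0.6) instead
    brightness_lognorm_sd: float = 0.15  # per-cell lognormal brightness factor
    max_puncta_per_cell: int = 8  # Poisson draws are rejected above this cap

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("invalid spec: nonpositive field dimensions")
        if not (0.0 <= self.dead_fraction <= 1.0):
            raise ValueError("invalid spec: dead_fraction outside [0, 1]")
        if self.nucleus_radius_px >= self.cell_radius_px:
            raise ValueError("invalid spec: nucleus radius must be < cell radius")
        if min(self.cell_radius_px, self.nucleus_radius_px, self.punctum_radius_px) <= 0:
            raise ValueError("invalid spec: all radii must be > 0")
        if self.n_cells < 0:
            raise ValueError("invalid spec: negative n_cells")
        name, _ = self.puncta_per_cell_dist
        if name not in ("poisson", "fixed"):
            raise ValueError(f"unknown puncta count distribution {name!r}")


@dataclass
class GroundTruth:
    """What the generator actually placed, for auditing recovery.

    ``cells`` rows: center (row, col), nucleus radius, live flag, painted
    viability-overlap fraction.  ``puncta`` rows: center, radius, owning
    cell index, color class (``green`` for single-reporter fields,
    ``red_only``/``yellow`` for tandem fields).
    """

    cells: list[dict] = field(default_factory=list)
    puncta: list[dict] = field(default_factory=list)

    @property
    def per_cell_counts(self) -> list[int]:
        counts = [0] * len(self.cells)
        for p in self.puncta:
            counts[p["cell_index"]] += 1
        return counts

    def validate(self) -> None:
        n = len(self.cells)
        for p in self.puncta:
            if not (0 <= p["cell_index"] < n):
                raise ValueError("punctum owner index out of range")


def _soft_disc(img: np.ndarray, center: tuple[float, float], radius: float,
               amplitude: float) -> None:
    """Add an anti-aliased disc to ``img`` in place (1-px soft edge)."""
    h, w = img.shape
    r0, c0 = center
    lo_r = max(int(np.floor(r0 - radius - 2)), 0)
    hi_r = min(int(np.ceil(r0 + radius + 2)) + 1, h)
    lo_c = max(int(np.floor(c0 - radius - 2)), 0)
    hi_c = min(int(np.ceil(c0 + radius + 2)) + 1, w)
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    dist = np.hypot(rr - r0, cc - c0)
    img[lo_r:hi_r, lo_c:hi_c] += amplitude * np.clip(radius + 0.5 - dist, 0.0, 1.0)


def _place_centers(rng: np.random.Generator, spec: FieldSpec) -> np.ndarray:
    """Rejection-sample pairwise-separated cell centers, bounded retries."""
    margin = spec.cell_radius_px + 2.0
    if (spec.width - 2 * margin <= 0 or spec.height - 2 * margin <= 0) and spec.n_cells:
        raise ValueError("field overcrowded: no room inside the margin")
    centers: list[tuple[float, float]] = []
    max_attempts = 2000 * max(spec.n_cells, 1)
    attempts = 0
    while len(centers) < spec.n_cells:
        if attempts >= max_attempts:
            raise ValueError("field overcrowded")
        attempts += 1
        r = rng.uniform(margin, spec.height - margin)
        c = rng.uniform(margin, spec.width - margin)
        if all(np.hypot(r - r2, c - c2) >= spec.min_cell_separation_px
               for r2, c2 in centers):
            centers.append((r, c))
    return np.asarray(centers).reshape(-1, 2)


def _place_puncta_in_cell(rng: np.random.Generator, center, spec: FieldSpec,
                          count: int) -> list[tuple[float, float]]:
    """Place ``count`` punctum centers in the cell disc, mutually separated.

    Separation of 2·r_punctum + 3 keeps rendered discs disjoint under
    8-connectivity so detected components map one-to-one to ground truth.
    """
    max_r = spec.cell_radius_px - spec.punctum_radius_px - 1.0
    min_sep = 2.0 * spec.punctum_radius_px + 3.0
    placed: list[tuple[float, float]] = []
    for _ in range(count):
        for _attempt in range(500):
            rad = max_r * np.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * np.pi)
            p = (center[0] + rad * np.sin(theta), center[1] + rad * np.cos(theta))
            if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep for q in placed):
                placed.append(p)
                break
        else:
            raise ValueError("cell overcrowded: cannot place punctum")
    return placed


def _sample_counts(rng: np.random.Generator, spec: FieldSpec, n: int) -> np.ndarray:
    name, param = spec.puncta_per_cell_dist
    if name == "poisson":
        # truncated at max_puncta_per_cell so every sampled count is
        # geometrically placeable at the in-cell separation
        counts = rng.poisson(param, size=n)
        while np.any(counts > spec.max_puncta_per_cell):
            redo = counts > spec.max_puncta_per_cell
            counts[redo] = rng.poisson(param, size=int(redo.sum()))
        return counts
    return np.full(n, int(param))


def _background(spec: FieldSpec) -> np.ndarray:
    cols = np.arange(spec.width, dtype=float)
    ramp = spec.background_level + spec.background_gradient * cols
    return np.broadcast_to(ramp, (spec.height, spec.width)).copy()


def _apply_noise(rng: np.random.Generator, img: np.ndarray,
                 spec: FieldSpec) -> np.ndarray:
    out = img
    if spec.noise_poisson:
        out = rng.poisson(np.maximum(out, 0.0)).astype(float)
    if spec.noise_gaussian_sd > 0:
        out = out + rng.normal(0.0, spec.noise_gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    """Order-stable sub-streams derived from one global seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gen_hcs_field(spec: FieldSpec) -> tuple[LabeledField, GroundTruth]:
    """Generate one high-content-screen field (nuclear / viability / GFP).

    Dead cells carry viability-stain signal over ``dead_overlap_fraction``
    of the cell disc (painted as a concentric disc of matched area), so the
    50%-overlap classification rule is unambiguous by construction.  Puncta
    are placed only inside their owning cell's disc.
    """
    spec.validate()
    rng_place, rng_counts, rng_classes, rng_bright, rng_noise = _streams(spec.seed, 5)

    centers = _place_centers(rng_place, spec)
    counts = _sample_counts(rng_counts, spec, spec.n_cells)
    dead = rng_classes.uniform(size=spec.n_cells) < spec.dead_fraction
    bright = np.exp(rng_bright.normal(0.0, spec.brightness_lognorm_sd,
                                      size=spec.n_cells))

    shape = (spec.height, spec.width)
    nuclear = _background(spec)
    viability = _background(spec)
    gfp = _background(spec)

    gt = GroundTruth()
    for idx in range(spec.n_cells):
        center = tuple(centers[idx])
        _soft_disc(nuclear, center, spec.nucleus_radius_px,
                   spec.nucleus_peak * bright[idx])
        _soft_disc(gfp, center, spec.cell_radius_px,
                   spec.cytoplasm_level * bright[idx])
        overlap = 0.0
        if dead[idx]:
            overlap = (rng_classes.uniform(0.4, 0.6) if spec.ambiguous_overlap
                       else spec.dead_overlap_fraction)
            _soft_disc(viability, center,
                       spec.cell_radius_px * np.sqrt(overlap),
                       spec.dead_stain_peak)
        gt.cells.append({
            "center": center,
            "nucleus_radius": spec.nucleus_radius_px,
            "live": not dead[idx],
            "painted_overlap": overlap,
        })
        for p in _place_puncta_in_cell(rng_place, center, spec, int(counts[idx])):
            _soft_disc(gfp, p, spec.punctum_radius_px,
                       spec.punctum_peak * bright[idx])
            gt.puncta.append({
                "center": p,
                "radius": spec.punctum_radius_px,
                "cell_index": idx,
                "color_class": "green",
            })

    channels = {
        "nuclear": _apply_noise(rng_noise, nuclear, spec),
        "viability": _apply_noise(rng_noise, viability, spec),
        "gfp": _apply_noise(rng_noise, gfp, spec),
    }
    gt.validate()
    field_ = LabeledField(channels=channels, provenance=f"synthgen:hcs:seed={spec.seed}")
    assert field_.shape == shape
    return field_, gt


def gen_tandem_field(spec: FieldSpec,
                     red_only_fraction: float) -> tuple[LabeledField, GroundTruth]:
    """Generate one tandem-reporter field (nuclear / red / green).

    Each punctum is drawn red-only (autolysosome: signal in the red channel
    only) or yellow (autophagosome: co-located signal in both channels) by
    a seeded Bernoulli(red_only_fraction) draw; the class is recorded in
    the ground truth.
    """
    if not (0.0 <= red_only_fraction <= 1.0):
        raise ValueError("red_only_fraction must lie in [0, 1]")
    spec.validate()
    rng_place, rng_counts, rng_classes, rng_bright, rng_noise = _streams(spec.seed, 5)

    centers = _place_centers(rng_place, spec)
    counts = _sample_counts(rng_counts, spec, spec.n_cells)
    bright = np.exp(rng_bright.normal(0.0, spec.brightness_lognorm_sd,
                                      size=spec.n_cells))

    nuclear = _background(spec)
    red = _background(spec)
    green = _background(spec)

    gt = GroundTruth()
    for idx in range(spec.n_cells):
        center = tuple(centers[idx])
        _soft_disc(nuclear, center, spec.nucleus_radius_px,
                   spec.nucleus_peak * bright[idx])
        # faint diffuse cytoplasm in both reporter channels
        _soft_disc(red, center, spec.cell_radius_px, 0.4 * spec.cytoplasm_level)
        _soft_disc(green, center, spec.cell_radius_px, 0.4 * spec.cytoplasm_level)
        gt.cells.append({
            "center": center,
            "nucleus_radius": spec.nucleus_radius_px,
            "live": True,
            "painted_overlap": 0.0,
        })
        for p in _place_puncta_in_cell(rng_place, center, spec, int(counts[idx])):
            is_red_only = bool(rng_classes.uniform() < red_only_fraction)
            _soft_disc(red, p, spec.punctum_radius_px, spec.punctum_peak * bright[idx])
            if not is_red_only:
                _soft_disc(green, p, spec.punctum_radius_px,
                           spec.punctum_peak * bright[idx])
            gt.puncta.append({
                "center": p,
                "radius": spec.punctum_radius_px,
                "cell_index": idx,
                "color_class": "red_only" if is_red_only else "yellow",
            })

    channels = {
        "nuclear": _apply_noise(rng_noise, nuclear, spec),
        "red": _apply_noise(rng_noise, red, spec),
        "green": _apply_noise(rng_noise, green, spec),
    }
    gt.validate()
    field_ = LabeledField(channels=channels,
                          provenance=f"synthgen:tandem:seed={spec.seed}")
    return field_, gt


# ---------------------------------------------------------------------------
# assay tables
# ---------------------------------------------------------------------------

_MODEL_PARAMS = {
    "fourPL": ("ic50_M", "hill", "top", "bottom"),
    "michaelis_menten_uncompetitive": ("vmax_M_per_s", "km_M", "ki_M"),
    "michaelis_menten_competitive": ("vmax_M_per_s", "km_M", "ki_M"),
    "michaelis_menten_noncompetitive": ("vmax_M_per_s", "km_M", "ki_M"),
    "binding_1to1": ("kd_M", "p0_M", "f_free", "delta_f"),
    "one_compartment_oral": ("dose_mg_per_kg", "mw_g_per_mol", "ka_per_h",
                             "ke_per_h", "v_f_L_per_kg"),
    "progress_linear": ("slope_rfu_per_s", "intercept_rfu"),
}


@dataclass(frozen=True)
class AssaySpec:
    """Parameters of one synthetic assay table.

    ``params`` must supply the true parameters the named model needs (see
    module defaults below for the values used throughout this package);
    ``design`` gives the design points (concentrations in M, PK times in h,
    progress-curve times in s).  Noise is either relative (``cv``) or
    additive (``sd``) Gaussian on each of ``n_replicates`` replicates.
    """

    model: str
    params: dict = field(default_factory=dict)
    design: tuple = ()
    n_replicates: int = 3
    noise_cv: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.model not in _MODEL_PARAMS:
            raise ValueError(f"unknown model {self.model!r}")
        missing = [p for p in _MODEL_PARAMS[self.model] if p not in self.params]
        if missing:
            raise ValueError(f"missing parameters for {self.model}: {missing}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_cv < 0 or self.noise_sd < 0:
            raise ValueError("noise SD/CV must be >= 0")
        pts = np.asarray(
            [x for row in np.atleast_2d(np.asarray(self.design, dtype=float))
             for x in np.ravel(row)], dtype=float)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("design points must be finite")


def default_assay_spec(model: str, seed: int = 0, n_replicates: int = 3,
                       noise_cv: float = 0.0, noise_sd: float = 0.0,
                       **overrides) -> AssaySpec:
    """AssaySpec preloaded with the study-scale default truths and designs."""
    uM = 1e-6
    if model == "fourPL":
        params = {"ic50_M": 24.5 * uM, "hill": 1.0, "top": 1.0, "bottom": 0.0}
        design = tuple(np.geomspace(1.0, 600.0, 10) * uM)
    elif model.startswith("michaelis_menten_"):
        params = {"vmax_M_per_s": 1e-8, "km_M": 50.0 * uM, "ki_M": 20.0 * uM}
        design = tuple(
            (s * uM, i * uM)
            for i in PAPER_INHIBITOR_GRID_uM
            for s in PAPER_SUBSTRATE_GRID_uM
        )
    elif model == "binding_1to1":
        # MST titration: 16-point 1:1 serial dilution from 800 µM ligand,
        # 0.17 µM labeled protein
        params = {"kd_M": 16.0 * uM, "p0_M": 0.17 * uM,
                  "f_free": 800.0, "delta_f": 200.0}
        design = tuple(800.0 * uM / 2 ** k for k in range(16))
    elif model == "one_compartment_oral":
        params = {"dose_mg_per_kg": 100.0, "mw_g_per_mol": 400.0,
                  "ka_per_h": 2.0, "ke_per_h": 0.3, "v_f_L_per_kg": 0.85}
        design = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)
    elif model == "progress_linear":
        params = {"slope_rfu_per_s": 100.0, "intercept_rfu": 50.0}
        design = tuple(np.arange(0.0, 7201.0, 900.0))  # every 15 min for 2 h
    else:
        raise ValueError(f"unknown model {model!r}")
    params.update({k: v for k, v in overrides.items() if k in params})
    extra = {k: v for k, v in overrides.items() if k not in params}
    spec = AssaySpec(model=model, params=params, design=design,
                     n_replicates=n_replicates, noise_cv=noise_cv,
                     noise_sd=noise_sd, seed=seed)
    if extra:
        spec = replace(spec, **extra)
    return spec


def _model_values(spec: AssaySpec) -> tuple[pd.DataFrame, np.ndarray]:
    p = spec.params
    if spec.model == "fourPL":
        conc = np.asarray(spec.design, dtype=float)
        y = models.four_pl(conc, p["ic50_M"], p["hill"], p["top"], p["bottom"])
        df = pd.DataFrame({"conc_M": conc})
    elif spec.model.startswith("michaelis_menten_"):
        pts = np.asarray(spec.design, dtype=float).reshape(-1, 2)
        s, i = pts[:, 0], pts[:, 1]
        fn = {"michaelis_menten_uncompetitive": models.mm_uncompetitive,
              "michaelis_menten_competitive": models.mm_competitive,
              "michaelis_menten_noncompetitive": models.mm_noncompetitive}[spec.model]
        y = fn(s, i, p["vmax_M_per_s"], p["km_M"], p["ki_M"])
        df = pd.DataFrame({"substrate_M": s, "inhibitor_M": i})
    elif spec.model == "binding_1to1":
        lig = np.asarray(spec.design, dtype=float)
        fb = models.fraction_bound_1to1(lig, p["kd_M"], p["p0_M"])
        y = p["f_free"] + p["delta_f"] * fb
        df = pd.DataFrame({"ligand_M": lig})
    elif spec.model == "one_compartment_oral":
        t = np.asarray(spec.design, dtype=float)
        dose_umol_per_kg = p["dose_mg_per_kg"] / p["mw_g_per_mol"] * 1e3
        y = models.one_compartment_oral(t, dose_umol_per_kg, p["ka_per_h"],
                                        p["ke_per_h"], p["v_f_L_per_kg"])
        df = pd.DataFrame({"time_h": t})
    elif spec.model == "progress_linear":
        t = np.asarray(spec.design, dtype=float)
        y = p["intercept_rfu"] + p["slope_rfu_per_s"] * t
        df = pd.DataFrame({"time_s": t})
    else:  # pragma: no cover - validate() rejects earlier
        raise ValueError(spec.model)
    return df, np.asarray(y, dtype=float)


_VALUE_COL = {
    "fourPL": "response",
    "michaelis_menten_uncompetitive": "rate_M_per_s",
    "michaelis_menten_competitive": "rate_M_per_s",
    "michaelis_menten_noncompetitive": "rate_M_per_s",
    "binding_1to1": "signal",
    "one_compartment_oral": "conc_plasma_uM",
    "progress_linear": "rfu",
}


def gen_assay_table(spec: AssaySpec) -> pd.DataFrame:
    """Emit design points, noiseless model values and noisy replicates.

    Returns a long-format table: one ``is_truth=True`` row per design point
    holding the exact model value, then ``n_replicates`` noisy rows.  With
    zero noise the replicate rows equal the truth rows exactly.
    """
    spec.validate()
    design_df, truth = _model_values(spec)
    col = _VALUE_COL[spec.model]
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    rows = [design_df.assign(**{col: truth}, replicate=0, is_truth=True)]
    for rep in range(1, spec.n_replicates + 1):
        sd = spec.noise_cv * np.abs(truth) + spec.noise_sd
        noisy = truth + rng.normal(0.0, 1.0, size=truth.shape) * sd
        rows.append(design_df.assign(**{col: noisy}, replicate=rep, is_truth=False))
    return pd.concat(rows, ignore_index=True)
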