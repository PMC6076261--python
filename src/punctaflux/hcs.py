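"""High-content-screen quantification of GFP-LC3 puncta.

Pipeline: segment nuclei from the nuclear stain, define radius-limited cell
regions around each nucleus, classify cells live/dead from viability-stain
overlap (dead when the cell region overlaps the stain mask by at least 50%),
detect GFP-positive puncta of at least 1 pixel with form factor at least
0.4, and summarize the fraction of live cells with at least ``min_puncta``
puncta, optionally normalized to vehicle controls.

The form factor uses the 4-neighbor boundary-edge-count perimeter
convention, under which FF = 4πA/P² is bounded by π/4 (a 3x3 square and a
single pixel both score 4π/16 ≈ 0.785); the 0.4 cutoff then cleanly
separates compact from elongated digital shapes.  Values are convention
dependent, so the convention is part of the contract.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure, segmentation

from .types import CellRecord, FieldSummary, LabeledField, PunctumRecord

__all__ = [
    "HcsConfig",
    "form_factor",
    "edge_count_perimeter",
    "segment_nuclei",
    "define_cell_regions",
    "classify_viability",
    "detect_puncta",
    "summarize_field",
    "quantify_field",
]

FF_MAX = math.pi / 4.0


@dataclass(frozen=True)
class HcsConfig:
    """Tunable parameters of the HCS pipeline (all pixel units).

    ``cell_radius_px`` is the instrument's "radius around the nucleus"; it
    was not reported, so it is a plain config value (default 30).
    Thresholds default to data-driven rules: Otsu for nuclei, a robust
    median + k·MAD rule for the viability mask, and background subtraction
    (median filter) + k·robust-SD for GFP positivity; each has a fixed
    absolute override.
    """

    nuclear_threshold: Optional[float] = None  # None → Otsu
    min_nucleus_area: int = 20
    watershed_split: bool = False
    cell_radius_px: float = 30.0
    dead_overlap_threshold: float = 0.5
    viability_threshold: Optional[float] = None  # None → median + k·MAD
    viability_k: float = 6.0
    gfp_background_window: int = 15
    gfp_k: float = 6.0
    gfp_rel_floor: float = 0.15  # of the residual's 99.8th percentile
    gfp_threshold: Optional[float] = None  # absolute-threshold mode
    min_punctum_area: int = 1
    min_form_factor: float = 0.4
    min_puncta: int = 5


def edge_count_perimeter(mask: np.ndarray) -> int:
    """Perimeter as the count of 4-neighbor region/non-region edges.

    The image border counts as non-region, so an isolated pixel has
    perimeter 4 wherever it sits.
    """
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1, mode="constant", constant_values=False)
    edges = 0
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        shifted = np.roll(np.roll(padded, dr, axis=0), dc, axis=1)
        edges += int(np.sum(padded & ~shifted))
    return edges


def _perimeters_by_label(labels: np.ndarray) -> np.ndarray:
    """Edge-count perimeter for every label at once; index = label."""
    padded = np.pad(labels, 1, mode="constant", constant_values=0)
    n = int(labels.max())
    per = np.zeros(n + 1, dtype=int)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        shifted = np.roll(np.roll(padded, dr, axis=0), dc, axis=1)
        boundary = padded[(padded > 0) & (padded != shifted)]
        per += np.bincount(boundary, minlength=n + 1)
    return per


def form_factor(pixels: np.ndarray) -> float:
    """Circularity 4πA/P² of a pixel set, edge-count perimeter convention."""
    px = np.asarray(pixels, dtype=int).reshape(-1, 2)
    if px.shape[0] == 0:
        raise ValueError("empty pixel set")
    offset = px.min(axis=0)
    local = px - offset
    mask = np.zeros(local.max(axis=0) + 1, dtype=bool)
    mask[local[:, 0], local[:, 1]] = True
    area = px.shape[0]
    perim = edge_count_perimeter(mask)
    return 4.0 * math.pi * area / perim ** 2


def _robust_threshold(img: np.ndarray, k: float) -> float:
    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    return med + k * 1.4826 * mad


def segment_nuclei(field: LabeledField, cfg: HcsConfig = HcsConfig()) -> np.ndarray:
    """Label nuclei from the nuclear-stain channel.

    Otsu (or fixed) threshold, fill holes, drop objects below
    ``min_nucleus_area``, 8-connectivity labeling; optionally a
    distance-transform watershed split for touching nuclei.
    """
    img = field.channel("nuclear")
    if cfg.nuclear_threshold is not None:
        thr = cfg.nuclear_threshold
    else:
        if np.ptp(img) == 0:
            warnings.warn("constant nuclear channel: no nuclei segmented")
            return np.zeros(img.shape, dtype=int)
        thr = filters.threshold_otsu(img)
    mask = img > thr
    mask = ndimage.binary_fill_holes(mask)
    labels = measure.label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())
    small = np.flatnonzero(areas < cfg.min_nucleus_area)
    mask &= ~np.isin(labels, small[small > 0])
    if cfg.watershed_split and mask.any():
        dist = ndimage.distance_transform_edt(mask)
        smoothed = ndimage.gaussian_filter(dist, sigma=2.0)
        peaks = (smoothed == ndimage.maximum_filter(smoothed, size=7)) & mask
        markers, _ = ndimage.label(peaks, structure=np.ones((3, 3)))
        labels = segmentation.watershed(-dist, markers, mask=mask)
    else:
        labels = measure.label(mask, connectivity=2)
    # renumber 1..K in raster order for a stable contract
    return measure.label(labels > 0, connectivity=2) if not cfg.watershed_split \
        else labels


def define_cell_regions(labels: np.ndarray, radius_px: float) -> list[CellRecord]:
    """Voronoi-limited disc regions around nucleus centroids.

    A pixel belongs to a cell iff it lies within ``radius_px`` of that
    nucleus centroid and no other centroid is nearer; regions are therefore
    pairwise disjoint and contain their own nucleus pixels.
    """
    if radius_px <= 0:
        raise ValueError("radius must be > 0")
    props = measure.regionprops(labels)
    records: list[CellRecord] = []
    if not props:
        return records
    h, w = labels.shape
    rr, cc = np.mgrid[0:h, 0:w]
    best_d2 = np.full((h, w), np.inf)
    best_idx = np.full((h, w), -1, dtype=int)
    centroids = [p.centroid for p in props]
    for k, (r0, c0) in enumerate(centroids):
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        best_idx[closer] = k
    within = best_d2 <= radius_px ** 2
    for k, p in enumerate(props):
        region_mask = within & (best_idx == k)
        region = np.argwhere(region_mask)
        records.append(CellRecord(
            nucleus_label=p.label,
            center=tuple(p.centroid),
            nucleus_pixels=p.coords,
            cell_region=region,
        ))
    return records


def classify_viability(cells: Sequence[CellRecord], field: LabeledField,
                       dead_overlap_threshold: float = 0.5,
                       cfg: HcsConfig = HcsConfig()) -> list[CellRecord]:
    """Set live/dead per cell from viability-stain overlap.

    overlap = |cell region ∩ stain mask| / |cell region|; a cell is dead iff
    overlap >= threshold (inclusive, matching the "at least 50%" rule).
    """
    if not (0.0 < dead_overlap_threshold <= 1.0):
        raise ValueError("dead_overlap_threshold must lie in (0, 1]")
    img = field.channel("viability")
    thr = (cfg.viability_threshold if cfg.viability_threshold is not None
           else _robust_threshold(img, cfg.viability_k))
    stain = img > thr
    for cell in cells:
        if cell.cell_region.shape[0] == 0:
            raise ValueError(f"cell {cell.nucleus_label} has an empty region")
        region = cell.cell_region
        overlap = float(np.mean(stain[region[:, 0], region[:, 1]]))
        cell.ethd1_overlap = overlap
        cell.viability = "dead" if overlap >= dead_overlap_threshold else "live"
    return list(cells)


def detect_puncta(field: LabeledField, cells: Sequence[CellRecord],
                  cfg: HcsConfig = HcsConfig(),
                  channel: str = "gfp") -> list[PunctumRecord]:
    """Detect puncta and assign them to cells by centroid membership.

    The GFP-positive mask is (channel − median-filtered background) >
    k·robust-SD, or a fixed absolute threshold when ``gfp_threshold`` is
    set.  8-connected components with area >= ``min_punctum_area`` and form
    factor >= ``min_form_factor`` are retained.  Puncta whose centroid lies
    outside every cell region are returned with ``owner=None`` and excluded
    from per-cell statistics.
    """
    if cfg.min_punctum_area < 1:
        raise ValueError("min_punctum_area must be >= 1")
    if not (0.0 < cfg.min_form_factor <= FF_MAX):
        raise ValueError(f"min_form_factor must lie in (0, {FF_MAX:.4f}]")
    img = field.channel(channel)
    if cfg.gfp_threshold is not None:
        mask = img > cfg.gfp_threshold
    else:
        background = ndimage.median_filter(img, size=cfg.gfp_background_window)
        residual = img - background
        sigma = 1.4826 * float(np.median(np.abs(residual - np.median(residual))))
        # relative floor keeps the rule meaningful on near-noiseless images,
        # where k·sigma collapses to ~0 and punctum skirts would merge
        floor = cfg.gfp_rel_floor * float(np.percentile(residual, 99.8))
        mask = residual > max(cfg.gfp_k * sigma, floor, 1e-12)
    labels = measure.label(mask, connectivity=2)
    perims = _perimeters_by_label(labels)

    # owner lookup grid from the (disjoint) cell regions
    owner = np.full(img.shape, -1, dtype=int)
    for idx, cell in enumerate(cells):
        region = cell.cell_region
        owner[region[:, 0], region[:, 1]] = idx
        cell.puncta = []

    puncta: list[PunctumRecord] = []
    for p in measure.regionprops(labels):
        area = int(p.area)
        if area < cfg.min_punctum_area:
            continue
        perim = int(perims[p.label])
        ff = 4.0 * math.pi * area / perim ** 2
        if ff < cfg.min_form_factor:
            continue
        cr, cc_ = p.centroid
        owner_idx = int(owner[int(round(cr)), int(round(cc_))])
        rec = PunctumRecord(
            pixels=p.coords, area=area, perimeter=perim, form_factor=ff,
            centroid=(cr, cc_),
            owner=cells[owner_idx].nucleus_label if owner_idx >= 0 else None,
        )
        puncta.append(rec)
        if owner_idx >= 0:
            cells[owner_idx].puncta.append(rec)
    return puncta


def summarize_field(cells: Sequence[CellRecord], min_puncta: int = 5,
                    control_summaries: Optional[Sequence[FieldSummary]] = None
                    ) -> FieldSummary:
    """Per-field endpoint: fraction of live cells with >= ``min_puncta`` puncta.

    With zero live cells the fraction is undefined and flagged rather than
    silently reported as zero.  When control summaries are supplied the
    fraction is additionally normalized to the mean control fraction.
    """
    if any(c.viability is None for c in cells):
        raise ValueError("viability must be assigned before summarizing")
    live = [c for c in cells if c.viability == "live"]
    n_dead = sum(c.viability == "dead" for c in cells)
    counts = [c.n_puncta for c in live]
    if not live:
        return FieldSummary(
            n_cells=len(cells), n_live=0, n_dead=n_dead,
            puncta_per_live_cell=[], min_puncta_threshold=min_puncta,
            frac_live_with_min_puncta=None, undefined=True,
        )
    frac = sum(n >= min_puncta for n in counts) / len(live)
    normalized = None
    if control_summaries is not None:
        control_fracs = [s.frac_live_with_min_puncta for s in control_summaries
                         if s.frac_live_with_min_puncta is not None]
        if not control_fracs:
            raise ValueError("no defined control fractions to normalize against")
        normalized = frac / (sum(control_fracs) / len(control_fracs))
    return FieldSummary(
        n_cells=len(cells), n_live=len(live), n_dead=n_dead,
        puncta_per_live_cell=counts, min_puncta_threshold=min_puncta,
        frac_live_with_min_puncta=frac, normalized_value=normalized,
    )


def quantify_field(field: LabeledField, cfg: HcsConfig = HcsConfig(),
                   control_summaries: Optional[Sequence[FieldSummary]] = None
                   ) -> tuple[list[CellRecord], list[PunctumRecord], FieldSummary]:
    """Run the full HCS pipeline on one field."""
    labels = segment_nuclei(field, cfg)
    cells = define_cell_regions(labels, cfg.cell_radius_px)
    classify_viability(cells, field, cfg.dead_overlap_threshold, cfg)
    puncta = detect_puncta(field, cells, cfg)
    summary = summarize_field(cells, cfg.min_puncta, control_summaries)
    return cells, puncta, summary
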