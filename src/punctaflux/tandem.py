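"""Tandem mRFP-eGFP-LC3 flux quantification and Lysotracker metric.

The tandem reporter's GFP moiety quenches in acidic autolysosomes, so
autolysosomes appear as red-only puncta and autophagosomes as yellow
(co-located red+green) puncta.  Flux is scored as the ratio of red-only to
yellow puncta per cell; a drop in that ratio indicates blocked flux.

Each reporter channel is processed independently: Gaussian smoothing, an
adaptive (local-mean) threshold, then connected-component discovery.  A red
punctum is classified yellow when the fraction of its pixels covered by
some green punctum reaches ``yellow_overlap_threshold``.

The Lysotracker (LTR) metric is the per-image mean gray value of the
unadjusted LTR channel minus the mean cell-free background, divided by the
number of stained nuclei, optionally normalized to a vehicle control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .hcs import HcsConfig, define_cell_regions, segment_nuclei
from .types import CellRecord, FluxSummary, LabeledField, LtrResult, TandemPunctum

__all__ = [
    "TandemConfig",
    "preprocess_mask",
    "find_puncta",
    "classify_red_yellow",
    "flux_ratio",
    "ltr_metric",
    "quantify_tandem_field",
]


@dataclass(frozen=True)
class TandemConfig:
    """Adaptive-threshold and classification parameters.

    The mask rule is ``smoothed > local_mean − offset``, so a *negative*
    offset demands pixels that exceed their neighborhood — the regime used
    for punctum detection.  ``adaptive_offset=None`` sets the offset to
    ``−offset_k`` robust SDs of the smoothed channel, adapting the demand
    to the channel's noise floor.
    """

    gaussian_sigma: float = 1.0
    adaptive_block: int = 11
    adaptive_offset: Optional[float] = None
    offset_k: float = 4.0
    min_punctum_area: int = 3
    yellow_overlap_threshold: float = 0.5
    min_cells_analyzed: int = 100
    cell_radius_px: float = 18.0
    ltr_background_erosion_px: int = 2


def _robust_sd(img: np.ndarray) -> float:
    med = float(np.median(img))
    return 1.4826 * float(np.median(np.abs(img - med)))


def preprocess_mask(image: np.ndarray, cfg: TandemConfig = TandemConfig()
                    ) -> np.ndarray:
    """Gaussian filter then adaptive threshold against the local mean.

    mask = smoothed > (local mean over an ``adaptive_block`` window −
    offset).  Subtracting the local mean cancels any constant added to the
    image, so the mask is invariant to uniform offsets.
    """
    if cfg.gaussian_sigma < 0:
        raise ValueError("gaussian_sigma must be >= 0")
    if cfg.adaptive_block < 3 or cfg.adaptive_block % 2 == 0:
        raise ValueError("adaptive_block must be odd and >= 3")
    img = np.asarray(image, dtype=float)
    smoothed = ndimage.gaussian_filter(img, sigma=cfg.gaussian_sigma) \
        if cfg.gaussian_sigma > 0 else img
    offset = (cfg.adaptive_offset if cfg.adaptive_offset is not None
              else -cfg.offset_k * _robust_sd(smoothed))
    local_mean = ndimage.uniform_filter(smoothed, size=cfg.adaptive_block,
                                        mode="reflect")
    return smoothed > (local_mean - offset)


def find_puncta(mask: np.ndarray, cfg: TandemConfig = TandemConfig(),
                channel: str = "red") -> list[TandemPunctum]:
    """8-connected components of a binary mask with area >= min_punctum_area.

    Equivalent to boundary-contour discovery followed by interior fill.
    """
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    out: list[TandemPunctum] = []
    for p in measure.regionprops(labels):
        if p.area < cfg.min_punctum_area:
            continue
        out.append(TandemPunctum(pixels=p.coords, centroid=tuple(p.centroid),
                                 channel=channel))
    return out


def classify_red_yellow(red_puncta: Sequence[TandemPunctum],
                        green_puncta: Sequence[TandemPunctum],
                        yellow_overlap_threshold: float = 0.5,
                        shape: Optional[tuple[int, int]] = None
                        ) -> list[TandemPunctum]:
    """Label each red punctum yellow or red_only by green overlap.

    A red punctum is yellow iff max over green puncta of
    |red ∩ green| / |red| >= threshold.  Class counts are conserved:
    n_red_only + n_yellow equals the number of red puncta.
    """
    if not (0.0 < yellow_overlap_threshold <= 1.0):
        raise ValueError("yellow_overlap_threshold must lie in (0, 1]")
    if shape is None:
        all_px = [p.pixels for p in list(red_puncta) + list(green_puncta)]
        if all_px:
            stacked = np.vstack(all_px)
            shape = (int(stacked[:, 0].max()) + 1, int(stacked[:, 1].max()) + 1)
        else:
            shape = (1, 1)
    green_map = np.zeros(shape, dtype=int)
    for gi, g in enumerate(green_puncta, start=1):
        green_map[g.pixels[:, 0], g.pixels[:, 1]] = gi
    for r in red_puncta:
        hits = green_map[r.pixels[:, 0], r.pixels[:, 1]]
        best = 0.0
        if hits.any():
            counts = np.bincount(hits)[1:]
            best = counts.max() / r.pixels.shape[0]
        r.color_class = ("yellow" if best >= yellow_overlap_threshold
                         else "red_only")
    return list(red_puncta)


def flux_ratio(classified_red: Sequence[TandemPunctum],
               cells: Sequence[CellRecord]) -> FluxSummary:
    """Per-cell and pooled red-only : yellow punctum ratios.

    The per-cell ratio is computed only for cells with at least one yellow
    punctum; zero-yellow cells are excluded from the mean but counted.  The
    pooled ratio Σ red_only / Σ yellow is always computed and flagged
    infinite when no yellow puncta exist at all.
    """
    if not cells:
        raise ValueError("no cells to analyze")
    owner = {}
    shape_cells = [c for c in cells if c.cell_region.shape[0]]
    if shape_cells:
        max_r = max(int(c.cell_region[:, 0].max()) for c in shape_cells) + 1
        max_c = max(int(c.cell_region[:, 1].max()) for c in shape_cells) + 1
        grid = np.full((max_r, max_c), -1, dtype=int)
        for idx, c in enumerate(cells):
            if c.cell_region.shape[0]:
                grid[c.cell_region[:, 0], c.cell_region[:, 1]] = idx
        owner = {"grid": grid}

    n_red = np.zeros(len(cells), dtype=int)
    n_yellow = np.zeros(len(cells), dtype=int)
    for p in classified_red:
        idx = -1
        if owner:
            r, c = int(round(p.centroid[0])), int(round(p.centroid[1]))
            g = owner["grid"]
            if 0 <= r < g.shape[0] and 0 <= c < g.shape[1]:
                idx = int(g[r, c])
        if idx >= 0:
            p.owner = cells[idx].nucleus_label
            if p.color_class == "yellow":
                n_yellow[idx] += 1
            else:
                n_red[idx] += 1

    per_cell = []
    ratios = []
    for idx, c in enumerate(cells):
        ratio = float(n_red[idx] / n_yellow[idx]) if n_yellow[idx] else None
        per_cell.append({"cell": c.nucleus_label, "n_red_only": int(n_red[idx]),
                         "n_yellow": int(n_yellow[idx]), "ratio": ratio})
        if ratio is not None:
            ratios.append(ratio)

    total_red, total_yellow = int(n_red.sum()), int(n_yellow.sum())
    pooled_inf = total_yellow == 0
    pooled = None if pooled_inf else total_red / total_yellow
    mean = sem = None
    undefined = len(ratios) == 0
    if ratios:
        mean = float(np.mean(ratios))
        sem = float(np.std(ratios, ddof=1) / np.sqrt(len(ratios))) \
            if len(ratios) > 1 else 0.0
    return FluxSummary(
        per_cell=per_cell, n_cells_analyzed=len(cells),
        n_cells_with_yellow=int(np.count_nonzero(n_yellow)),
        mean_ratio=mean, sem_ratio=sem, pooled_ratio=pooled,
        pooled_ratio_infinite=pooled_inf, mean_undefined=undefined,
    )


def ltr_metric(ltr: np.ndarray, nuclear: np.ndarray,
               cfg: TandemConfig = TandemConfig(),
               hcs_cfg: HcsConfig = HcsConfig(),
               control_metric: Optional[float] = None) -> LtrResult:
    """Per-image Lysotracker intensity relative to cell count.

    mean_gray is taken over the whole unadjusted LTR image; the background
    mean over the cell-free mask (pixels below the LTR Otsu threshold,
    eroded); nuclei are counted on the nuclear channel.  metric =
    (mean_gray − background_mean) / n_nuclei.
    """
    ltr = np.asarray(ltr, dtype=float)
    mean_gray = float(ltr.mean())
    if np.ptp(ltr) == 0:
        background_mean = mean_gray
    else:
        bg_mask = ltr < filters.threshold_otsu(ltr)
        if cfg.ltr_background_erosion_px > 0:
            bg_mask = ndimage.binary_erosion(
                bg_mask, iterations=cfg.ltr_background_erosion_px)
        background_mean = float(ltr[bg_mask].mean()) if bg_mask.any() else mean_gray

    labels = segment_nuclei(
        LabeledField(channels={"nuclear": np.asarray(nuclear, dtype=float)}),
        hcs_cfg)
    n_nuclei = int(labels.max())
    if n_nuclei == 0:
        return LtrResult(mean_gray=mean_gray, background_mean=background_mean,
                         n_nuclei=0, metric=None, undefined=True)
    metric = (mean_gray - background_mean) / n_nuclei
    normalized = metric / control_metric if control_metric else None
    return LtrResult(mean_gray=mean_gray, background_mean=background_mean,
                     n_nuclei=n_nuclei, metric=metric,
                     normalized_to_control=normalized)


def quantify_tandem_field(field: LabeledField,
                          cfg: TandemConfig = TandemConfig(),
                          hcs_cfg: Optional[HcsConfig] = None) -> FluxSummary:
    """Full tandem pipeline: masks → puncta → color classes → flux ratios."""
    if hcs_cfg is None:
        hcs_cfg = HcsConfig(cell_radius_px=cfg.cell_radius_px)
    red_mask = preprocess_mask(field.channel("red"), cfg)
    green_mask = preprocess_mask(field.channel("green"), cfg)
    red_puncta = find_puncta(red_mask, cfg, channel="red")
    green_puncta = find_puncta(green_mask, cfg, channel="green")
    classify_red_yellow(red_puncta, green_puncta,
                        cfg.yellow_overlap_threshold, shape=field.shape)
    labels = segment_nuclei(field, hcs_cfg)
    cells = define_cell_regions(labels, hcs_cfg.cell_radius_px)
    return flux_ratio(red_puncta, cells)
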