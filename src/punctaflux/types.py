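"""Core containers shared across the quantification pipeline.

Conventions used throughout:

* pixel grids are 0-based ``(row, col)``;
* objects use 8-connectivity, the background complement uses 4-connectivity;
* concentrations are stored in molar internally (CSV I/O converts from
  µM/nM with explicit unit columns);
* the perimeter of a pixel region is the count of 4-neighbor edges between a
  region pixel and a non-region pixel (the image border counts as
  non-region), which bounds the form factor 4πA/P² by π/4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "LabeledField",
    "PunctumRecord",
    "CellRecord",
    "FieldSummary",
    "TandemPunctum",
    "FluxSummary",
    "LtrResult",
    "ProgressCurve",
    "StandardCurve",
    "RateTable",
    "FitResult",
    "MsCleavage",
    "LaneDensity",
    "PkProfile",
    "PkSummary",
]


@dataclass
class LabeledField:
    """A multi-channel fluorescence field with per-channel role tags.

    ``channels`` maps a role name (``nuclear``, ``viability``, ``gfp``,
    ``red``, ``green``, ``ltr``) to a 2-D float array.  All channels must
    share the same shape and hold finite, non-negative intensities.
    """

    channels: dict[str, np.ndarray]
    provenance: str = ""

    def __post_init__(self) -> None:
        shapes = {role: ch.shape for role, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for role, ch in self.channels.items():
            a = np.asarray(ch, dtype=float)
            if not np.all(np.isfinite(a)):
                raise ValueError(f"channel {role!r} contains non-finite values")
            if np.any(a < 0):
                raise ValueError(f"channel {role!r} contains negative intensities")
            self.channels[role] = a

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channels:
            raise KeyError(
                f"channel role {role!r} missing; have {sorted(self.channels)}"
            )
        return self.channels[role]


@dataclass
class PunctumRecord:
    """One detected punctum: its pixels, geometry and owning cell."""

    pixels: np.ndarray  # (N, 2) array of (row, col)
    area: int
    perimeter: int  # 4-neighbor boundary-edge count
    form_factor: float  # 4πA/P², in (0, π/4]
    centroid: tuple[float, float]
    owner: Optional[int] = None  # nucleus label, or None if unassigned

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("punctum area must be >= 1")
        if self.perimeter < 4:
            raise ValueError("edge-count perimeter must be >= 4")


@dataclass
class CellRecord:
    """One segmented cell: nucleus, radius-limited region, viability, puncta."""

    nucleus_label: int
    center: tuple[float, float]
    nucleus_pixels: np.ndarray  # (N, 2)
    cell_region: np.ndarray  # (M, 2), Voronoi-limited disc
    viability: Optional[str] = None  # "live" | "dead"
    ethd1_overlap: Optional[float] = None
    puncta: list[PunctumRecord] = field(default_factory=list)

    @property
    def n_puncta(self) -> int:
        return len(self.puncta)


@dataclass
class FieldSummary:
    """Per-field endpoint for the high-content screen."""

    n_cells: int
    n_live: int
    n_dead: int
    puncta_per_live_cell: list[int]
    min_puncta_threshold: int
    frac_live_with_min_puncta: Optional[float]
    undefined: bool = False  # True when n_live == 0
    normalized_value: Optional[float] = None


@dataclass
class TandemPunctum:
    """A punctum from one tandem-reporter channel.

    ``color_class`` is defined only for red-channel puncta: ``yellow`` when
    the overlap fraction with some green punctum reaches the threshold,
    otherwise ``red_only``.
    """

    pixels: np.ndarray
    centroid: tuple[float, float]
    channel: str  # "red" | "green"
    color_class: Optional[str] = None  # "red_only" | "yellow"
    owner: Optional[int] = None


@dataclass
class FluxSummary:
    """Red:yellow flux statistics for one field or pooled fields."""

    per_cell: list[dict]  # cell label, n_red_only, n_yellow, ratio (or None)
    n_cells_analyzed: int
    n_cells_with_yellow: int
    mean_ratio: Optional[float]
    sem_ratio: Optional[float]
    pooled_ratio: Optional[float]
    pooled_ratio_infinite: bool = False
    mean_undefined: bool = False


@dataclass
class LtrResult:
    """Per-image Lysotracker intensity metric, relative to cell count."""

    mean_gray: float
    background_mean: float
    n_nuclei: int
    metric: Optional[float]
    undefined: bool = False
    normalized_to_control: Optional[float] = None


@dataclass
class ProgressCurve:
    """Time course of fluorescence from one assay well."""

    times_s: np.ndarray
    signal_rfu: np.ndarray
    substrate_M: float = np.nan
    inhibitor_M: float = 0.0
    enzyme_M: float = np.nan

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        self.times_s = t
        self.signal_rfu = np.asarray(self.signal_rfu, dtype=float)
        if self.times_s.shape != self.signal_rfu.shape:
            raise ValueError("times and signal must have equal length")


@dataclass
class StandardCurve:
    """Linear RFU-vs-concentration calibration, signal = m·conc + b."""

    slope_rfu_per_M: float
    intercept_rfu: float
    r_squared: float
    residual_sd: float

    def __post_init__(self) -> None:
        if self.slope_rfu_per_M <= 0:
            raise ValueError("standard-curve slope must be positive")

    def rfu_rate_to_molar_rate(self, rfu_per_s: float) -> float:
        return rfu_per_s / self.slope_rfu_per_M


@dataclass
class RateTable:
    """Initial rates indexed by substrate and inhibitor concentration (M)."""

    substrate_M: np.ndarray
    inhibitor_M: np.ndarray
    rate_M_per_s: np.ndarray
    replicate: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.substrate_M, dtype=float)
        i = np.asarray(self.inhibitor_M, dtype=float)
        v = np.asarray(self.rate_M_per_s, dtype=float)
        r = np.asarray(self.replicate)
        if not (s.shape == i.shape == v.shape == r.shape):
            raise ValueError("rate-table columns must have equal length")
        if np.any(s < 0) or np.any(i < 0):
            raise ValueError("concentrations must be >= 0")
        if not np.all(np.isfinite(v)):
            raise ValueError("rates must be finite")
        self.substrate_M, self.inhibitor_M = s, i
        self.rate_M_per_s, self.replicate = v, r


@dataclass
class FitResult:
    """Parameter estimates with uncertainty for a closed-form assay model."""

    model: str
    estimates: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    converged: bool
    residual_sd: float
    n_points: int
    flags: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


@dataclass
class MsCleavage:
    """One mass-spectrometry timepoint: cleaved (A) vs parent (B) peak heights.

    A is the 27885 Da cleaved species, B the 72904 Da parent substrate; the
    cleavage statistic is A/(A+B).
    """

    time_s: float
    peak_a: float
    peak_b: float

    def __post_init__(self) -> None:
        if self.peak_a < 0 or self.peak_b < 0:
            raise ValueError("peak heights must be >= 0")
        if self.peak_a + self.peak_b <= 0:
            raise ValueError("A + B must be > 0")

    @property
    def fraction(self) -> float:
        return self.peak_a / (self.peak_a + self.peak_b)


@dataclass
class LaneDensity:
    """One western-blot lane: target band and loading-control intensities."""

    lane_id: str
    band: float  # LC3B-II or GABARAP-II density
    loading: float  # actin / vinculin density
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.band <= 0 or self.loading <= 0:
            raise ValueError("band and loading intensities must be > 0")


@dataclass
class PkProfile:
    """Plasma concentration-time profile for one subject and dose."""

    times_h: np.ndarray
    conc_uM: np.ndarray
    dose_mg_per_kg: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.conc_uM, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and concentrations must have equal length")
        if t.size and t[0] != 0:
            raise ValueError("profile must start at t=0")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        self.times_h, self.conc_uM = t, c


@dataclass
class PkSummary:
    """Noncompartmental summaries of one plasma profile."""

    cmax_uM: float
    tmax_h: float
    auc_uM_h: float  # linear trapezoid over the observed interval
    dose_mg_per_kg: float
    cmax_per_dose: float
    auc_per_dose: float
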