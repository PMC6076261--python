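"""Western-blot densitometry, bafilomycin-additivity statistic, PK summaries.

Densitometry starts from numeric band densities (gel-image quantification
is out of scope): relative LC3B-II level = (band / loading control),
normalized to the mean vehicle-control ratio.

The bafilomycin-additivity statistic formalizes the flux-block readout: if
a drug already blocks autophagic flux, adding the lysosomal inhibitor
Baf A1 on top of it produces no further LC3B-II accumulation.  The
statistic is the ratio of the drug-arm Baf increment to the vehicle-arm
Baf increment; R near 0 means blocked flux, near 1 means the drug acts
upstream of the block.  The R <= 0.25 call threshold is an operational
default, not an inference the original analysis performed.

PK summaries are noncompartmental: observed Cmax/Tmax, linear-trapezoid
AUC over the sampled interval, dose-normalized metrics, and the
dose-proportionality ratio between two profiles.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import LaneDensity, PkProfile, PkSummary

__all__ = [
    "normalize_band",
    "baf_additivity",
    "pk_summary",
    "dose_proportionality",
]


def normalize_band(lane: LaneDensity,
                   control_lanes: Sequence[LaneDensity]) -> float:
    """Loading-corrected band level relative to the mean control ratio.

    rel = (band/loading) / mean over control lanes of (band/loading).
    Invariant to rescaling every intensity on the blot by a common factor.
    """
    if not control_lanes:
        raise ValueError("control lanes must be nonempty")
    ratio = lane.band / lane.loading
    control_mean = float(np.mean([c.band / c.loading for c in control_lanes]))
    return ratio / control_mean


def baf_additivity(vehicle: Sequence[float], vehicle_baf: Sequence[float],
                   drug: Sequence[float], drug_baf: Sequence[float],
                   r_threshold: float = 0.25, n_boot: int = 1000,
                   seed: int = 0) -> dict:
    """Additivity ratio R and flux-block call from four condition arms.

    R = mean(drug+Baf − drug) / mean(vehicle+Baf − vehicle).  The call is
    inclusive: flux blocked iff R <= ``r_threshold``.  A bootstrap CI over
    replicates is reported, and the replicate-level comparison of the two
    increments is delegated to a generic Welch t-test.  R is invariant to a
    common affine renormalization of the relative levels.
    """
    veh = np.asarray(vehicle, dtype=float)
    veh_b = np.asarray(vehicle_baf, dtype=float)
    drg = np.asarray(drug, dtype=float)
    drg_b = np.asarray(drug_baf, dtype=float)
    if min(veh.size, veh_b.size, drg.size, drg_b.size) < 1:
        raise ValueError("all four conditions need >= 1 replicate")
    vehicle_increment = float(veh_b.mean() - veh.mean())
    drug_increment = float(drg_b.mean() - drg.mean())
    if vehicle_increment <= 0:
        return {"ratio": None, "flux_blocked": None, "undefined": True,
                "vehicle_increment": vehicle_increment,
                "drug_increment": drug_increment}
    r = drug_increment / vehicle_increment

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        vi = rng.choice(veh_b, veh_b.size).mean() - rng.choice(veh, veh.size).mean()
        di = rng.choice(drg_b, drg_b.size).mean() - rng.choice(drg, drg.size).mean()
        if vi > 0:
            boots.append(di / vi)
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5))) \
        if len(boots) >= 50 else None

    p_value = None
    if min(veh.size, veh_b.size, drg.size, drg_b.size) >= 2:
        inc_v = veh_b - veh.mean()
        inc_d = drg_b - drg.mean()
        p_value = float(stats.ttest_ind(inc_d, inc_v, equal_var=False).pvalue)

    return {
        "ratio": r,
        "flux_blocked": bool(r <= r_threshold),
        "undefined": False,
        "vehicle_increment": vehicle_increment,
        "drug_increment": drug_increment,
        "ci95": ci,
        "p_value_increments": p_value,
        "r_threshold": r_threshold,
    }


def pk_summary(profile: PkProfile) -> PkSummary:
    """Noncompartmental summaries: Cmax, Tmax, linear-trapezoid AUC(0-t)."""
    t, c = profile.times_h, profile.conc_uM
    if t.size < 3:
        raise ValueError("need >= 3 timepoints")
    imax = int(np.argmax(c))
    cmax = float(c[imax])
    tmax = float(t[imax])
    auc = float(np.trapezoid(c, t))
    dose = profile.dose_mg_per_kg
    return PkSummary(
        cmax_uM=cmax, tmax_h=tmax, auc_uM_h=auc, dose_mg_per_kg=dose,
        cmax_per_dose=cmax / dose, auc_per_dose=auc / dose,
    )


def dose_proportionality(low: PkSummary, high: PkSummary) -> float:
    """Dose-normalized AUC ratio (AUC₂/D₂)/(AUC₁/D₁); 1.0 = proportional."""
    return high.auc_per_dose / low.auc_per_dose
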