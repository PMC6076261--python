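"""Protease-assay analytics: rates, IC50, inhibition mode, Ki, KD.

Initial rates are extracted from fluorescence progress curves and converted
from RFU/s to M/s through a linear standard curve.  Dose-response data are
fitted with the four-parameter logistic; substrate-saturation data with the
Michaelis-Menten hyperbola (Hanes-Woolf start values); substrate x
inhibitor grids with the classical single-site inhibition models, globally,
to obtain Ki; and binding titrations with the depletion-corrected 1:1
isotherm to obtain KD.  The inhibition *mode* is diagnosed the way a
kineticist reads the apparent-parameter plots: from the trends of
Vmax_app and KM_app against inhibitor concentration (uncompetitive
inhibition depresses both, competitive raises KM only, noncompetitive
depresses Vmax only).

Confidence intervals default to a seeded nonparametric (case-resampling)
bootstrap with an asymptotic Wald interval as the fast alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from . import models
from .types import FitResult, MsCleavage, ProgressCurve, RateTable, StandardCurve

__all__ = [
    "CiConfig",
    "fit_standard_curve",
    "initial_rate",
    "fit_ic50",
    "fit_michaelis_menten",
    "diagnose_inhibition_mode",
    "fit_uncompetitive_ki",
    "fit_inhibition_grid",
    "ms_cleavage",
    "percent_inhibition",
    "fit_binding_kd",
]


@dataclass(frozen=True)
class CiConfig:
    """How 95% CIs are computed: seeded bootstrap or asymptotic Wald."""

    method: str = "bootstrap"  # "bootstrap" | "wald"
    n_boot: int = 1000
    seed: int = 0


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, R², residual SD of an ordinary least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("singular design: all x values identical")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(len(x) - 2, 1)
    return float(slope), float(intercept), r2, float(np.sqrt(ss_res / dof))


def fit_standard_curve(concs_M: Sequence[float],
                       rfu: Sequence[float]) -> StandardCurve:
    """Linear RFU-vs-concentration calibration with an inverse mapping."""
    concs = np.asarray(concs_M, dtype=float)
    if np.unique(concs).size < 2:
        raise ValueError("need >= 2 distinct concentrations")
    slope, intercept, r2, rsd = _ols(concs, np.asarray(rfu, dtype=float))
    return StandardCurve(slope_rfu_per_M=slope, intercept_rfu=intercept,
                         r_squared=r2, residual_sd=rsd)


def initial_rate(curve: ProgressCurve, std: StandardCurve,
                 max_fraction_consumed: float = 0.1) -> float:
    """Initial velocity in M/s from the early linear window of a progress curve.

    The window keeps points while the estimated product formed stays below
    ``max_fraction_consumed`` of the initial substrate (always at least 3
    points); the RFU/s slope over that window is divided by the
    standard-curve slope.
    """
    t, y = curve.times_s, curve.signal_rfu
    if t.size < 3:
        raise ValueError("need >= 3 points for a rate")
    n = t.size
    if np.isfinite(curve.substrate_M) and curve.substrate_M > 0:
        product_M = (y - y[0]) / std.slope_rfu_per_M
        ok = product_M < max_fraction_consumed * curve.substrate_M
        # keep the longest initial run of in-window points, minimum 3
        n_ok = int(np.argmin(ok)) if not ok.all() else n
        n = max(n_ok, 3)
    slope_rfu_per_s, *_ = _ols(t[:n], y[:n])
    return std.rfu_rate_to_molar_rate(slope_rfu_per_s)


# ---------------------------------------------------------------------------
# generic nonlinear fit machinery
# ---------------------------------------------------------------------------

def _wald_ci(popt, pcov) -> dict:
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return {i: (popt[i] - 1.959964 * se[i], popt[i] + 1.959964 * se[i])
            for i in range(len(popt))}


def _fit_nls(fn, xdata, ydata, p0, names, ci: CiConfig, model_name: str,
             bounds=(-np.inf, np.inf), positive=()) -> FitResult:
    x = np.asarray(xdata, dtype=float)
    y = np.asarray(ydata, dtype=float)
    flags: list[str] = []
    # parameters span many decades (rates ~1e-8 M/s vs Ki ~1e-5 M) and the
    # response can sit near 1e-8; normalize both or the optimizer stalls
    # at the start values
    scale = np.where(np.abs(p0) > 0, np.abs(p0), 1.0)
    y_scale = float(np.max(np.abs(y))) or 1.0

    def fn_scaled(xv, *params):
        return fn(xv, *params) / y_scale

    try:
        popt, pcov = optimize.curve_fit(fn_scaled, x, y / y_scale, p0=p0,
                                        bounds=bounds, x_scale=scale,
                                        maxfev=20000)
        converged = True
    except (RuntimeError, optimize.OptimizeWarning):
        return FitResult(model=model_name, estimates={}, ci95={},
                         converged=False, residual_sd=np.nan,
                         n_points=len(y), flags=["non-convergence"])
    resid = y - fn(x, *popt)
    dof = max(len(y) - len(popt), 1)
    rsd = float(np.sqrt(np.sum(resid ** 2) / dof))

    if ci.method == "bootstrap":
        rng = np.random.default_rng(ci.seed)
        samples = []
        idx_all = np.arange(len(y))
        for _ in range(ci.n_boot):
            idx = rng.choice(idx_all, size=len(y), replace=True)
            xb = x[..., idx] if x.ndim == 1 else x[:, idx]
            try:
                pb, _ = optimize.curve_fit(fn_scaled, xb, y[idx] / y_scale,
                                           p0=popt, bounds=bounds,
                                           x_scale=scale, maxfev=5000)
                samples.append(pb)
            except (RuntimeError, optimize.OptimizeWarning):
                continue
        if len(samples) >= max(50, ci.n_boot // 2):
            arr = np.asarray(samples)
            lo = np.percentile(arr, 2.5, axis=0)
            hi = np.percentile(arr, 97.5, axis=0)
            # a percentile CI can exclude the point estimate on skewed
            # resamples; widen to contain it so the contract holds
            lo = np.minimum(lo, popt)
            hi = np.maximum(hi, popt)
            ci95 = {i: (float(lo[i]), float(hi[i])) for i in range(len(popt))}
        else:
            flags.append("bootstrap unstable; Wald CI reported")
            ci95 = _wald_ci(popt, pcov)
    else:
        ci95 = _wald_ci(popt, pcov)

    for name, val in zip(names, popt):
        if name in positive and val <= 0:
            flags.append(f"nonpositive estimate for {name}")
    return FitResult(
        model=model_name,
        estimates={n: float(v) for n, v in zip(names, popt)},
        ci95={n: tuple(map(float, ci95[i])) for i, n in enumerate(names)},
        converged=converged, residual_sd=rsd, n_points=len(y), flags=flags,
    )


def fit_ic50(doses_M: Sequence[float], responses: Sequence[float],
             ci: CiConfig = CiConfig()) -> FitResult:
    """Four-parameter logistic dose-response fit.

    The direction of the transition (rising or falling with dose) is
    detected from the data; flat data are flagged "no dose effect" and no
    IC50 is emitted.
    """
    doses = np.asarray(doses_M, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if np.unique(doses).size < 4:
        raise ValueError("need >= 4 distinct doses")
    if np.ptp(resp) == 0 or np.ptp(resp) < 1e-9 * max(np.abs(resp).max(), 1.0):
        return FitResult(model="fourPL", estimates={}, ci95={},
                         converged=False, residual_sd=0.0, n_points=len(resp),
                         flags=["no dose effect"])
    order = np.argsort(doses)
    falling = resp[order][-1] < resp[order][0]
    top0 = float(np.max(resp)) if falling else float(np.max(resp))
    bot0 = float(np.min(resp))
    mid = 0.5 * (top0 + bot0)
    # dose whose mean response is nearest the midpoint seeds the IC50
    uniq = np.unique(doses)
    means = np.array([resp[doses == d].mean() for d in uniq])
    ic50_0 = float(uniq[np.argmin(np.abs(means - mid))])
    ic50_0 = ic50_0 if ic50_0 > 0 else float(np.median(uniq[uniq > 0]))
    hill0 = 1.0 if falling else -1.0

    def fn(c, ic50, hill, top, bottom):
        return models.four_pl(c, ic50, hill, top, bottom)

    res = _fit_nls(fn, doses, resp, p0=[ic50_0, hill0, top0, bot0],
                   names=("ic50_M", "hill", "top", "bottom"), ci=ci,
                   model_name="fourPL",
                   bounds=([np.min(uniq[uniq > 0]) / 1e3, -10.0, -np.inf, -np.inf],
                           [np.max(uniq) * 1e3, 10.0, np.inf, np.inf]),
                   positive=("ic50_M",))
    return res


def fit_michaelis_menten(substrate_M: Sequence[float],
                         rates_M_per_s: Sequence[float],
                         ci: CiConfig = CiConfig()) -> FitResult:
    """Michaelis-Menten v = Vmax·S/(KM+S), Hanes-Woolf start values."""
    s = np.asarray(substrate_M, dtype=float)
    v = np.asarray(rates_M_per_s, dtype=float)
    if np.unique(s).size < 3:
        raise ValueError("need >= 3 distinct substrate concentrations")
    # Hanes-Woolf: S/v = S/Vmax + KM/Vmax
    pos = v > 0
    if pos.sum() >= 2 and np.ptp(s[pos]) > 0:
        slope, intercept, *_ = _ols(s[pos], s[pos] / v[pos])
        vmax0 = 1.0 / slope if slope > 0 else float(np.max(v))
        km0 = intercept * vmax0 if intercept > 0 else float(np.median(s))
    else:
        vmax0, km0 = float(np.max(v)), float(np.median(s))
    return _fit_nls(models.michaelis_menten, s, v, p0=[vmax0, km0],
                    names=("vmax_M_per_s", "km_M"), ci=ci,
                    model_name="michaelis_menten",
                    bounds=([0.0, 0.0], [np.inf, np.inf]),
                    positive=("vmax_M_per_s", "km_M"))


def fit_inhibition_grid(table: RateTable, ci: CiConfig = CiConfig()
                        ) -> dict[float, FitResult]:
    """Per-inhibitor-concentration Michaelis-Menten fits of a rate grid."""
    out: dict[float, FitResult] = {}
    fast = CiConfig(method="wald", seed=ci.seed)
    for i_conc in np.unique(table.inhibitor_M):
        sel = table.inhibitor_M == i_conc
        out[float(i_conc)] = fit_michaelis_menten(
            table.substrate_M[sel], table.rate_M_per_s[sel], ci=fast)
    return out


def diagnose_inhibition_mode(per_inhibitor_fits: dict[float, FitResult],
                             rel_tol: float = 0.10) -> str:
    """Classify the inhibition mode from apparent-parameter trends.

    Trends of Vmax_app and KM_app against [I] are fitted by least squares
    (weighted by the apparent-parameter standard errors when available) and
    converted to relative changes over the tested range.  A parameter is
    flat when its relative change is below ``rel_tol`` or its trend is not
    statistically distinguishable from zero (|slope| < 3 SE), which keeps
    noisy but trendless apparent parameters from masquerading as a mode.
    Both decreasing → uncompetitive; KM up with Vmax flat → competitive;
    Vmax down with KM flat → noncompetitive; both flat → none; any other
    combination → mixed.
    """
    i_vals = np.asarray(sorted(per_inhibitor_fits), dtype=float)
    if i_vals.size < 3:
        raise ValueError("need >= 3 inhibitor concentrations")
    if i_vals[0] != 0.0:
        raise ValueError("missing [I]=0 baseline")

    def trend(param: str) -> tuple[float, float]:
        """Relative change over the [I] range and its t statistic."""
        y = np.array([per_inhibitor_fits[i].estimates[param] for i in i_vals])
        se = []
        for i in i_vals:
            lo, hi = per_inhibitor_fits[i].ci95.get(param, (np.nan, np.nan))
            s = (hi - lo) / (2.0 * 1.959964)
            if not np.isfinite(s) or s <= 0:
                s = 1e-6 * max(abs(y[0]), 1e-300)
            se.append(s)
        w = 1.0 / np.square(se)
        xb = np.sum(w * i_vals) / np.sum(w)
        sxx = np.sum(w * (i_vals - xb) ** 2)
        slope = np.sum(w * (i_vals - xb) * y) / sxx
        se_slope = np.sqrt(1.0 / sxx)
        span = i_vals[-1] - i_vals[0]
        return float(slope * span / y[0]), float(slope / se_slope)

    dv, tv = trend("vmax_M_per_s")
    dk, tk = trend("km_M")
    v_flat = abs(dv) < rel_tol or abs(tv) < 3.0
    k_flat = abs(dk) < rel_tol or abs(tk) < 3.0
    v_down = not v_flat and dv < 0
    k_down = not k_flat and dk < 0
    k_up = not k_flat and dk > 0
    if v_down and k_down:
        return "uncompetitive"
    if v_flat and k_up:
        return "competitive"
    if v_down and k_flat:
        return "noncompetitive"
    if v_flat and k_flat:
        return "none"
    return "mixed"


def fit_uncompetitive_ki(table: RateTable, ci: CiConfig = CiConfig()
                         ) -> FitResult:
    """Global uncompetitive fit v = Vmax·S/(KM + S·(1+I/Ki)) over a grid.

    Also reports the apparent-parameter consistency check: under the
    uncompetitive model Vmax_app(I)/Vmax and KM_app(I)/KM both equal
    1/(1+I/Ki).
    """
    s_vals = np.unique(table.substrate_M)
    i_vals = np.unique(table.inhibitor_M)
    if s_vals.size < 3 or i_vals.size < 3:
        raise ValueError("grid too thin: need >= 3 substrate and inhibitor levels")

    def fn(x, vmax, km, ki):
        return models.mm_uncompetitive(x[0], x[1], vmax, km, ki)

    x = np.vstack([table.substrate_M, table.inhibitor_M])
    v = table.rate_M_per_s
    baseline = table.inhibitor_M == 0
    vmax0 = float(np.max(v[baseline])) if baseline.any() else float(np.max(v))
    km0 = float(np.median(s_vals))
    ki0 = float(np.median(i_vals[i_vals > 0]))
    res = _fit_nls(fn, x, v, p0=[vmax0, km0, ki0],
                   names=("vmax_M_per_s", "km_M", "ki_M"), ci=ci,
                   model_name="michaelis_menten_uncompetitive",
                   bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                   positive=("vmax_M_per_s", "km_M", "ki_M"))
    if res.converged:
        per_i = fit_inhibition_grid(table, ci)
        ki = res.estimates["ki_M"]
        check = {
            float(i): {
                "vmax_app_ratio": per_i[i].estimates["vmax_M_per_s"]
                / res.estimates["vmax_M_per_s"],
                "km_app_ratio": per_i[i].estimates["km_M"] / res.estimates["km_M"],
                "predicted_ratio": 1.0 / (1.0 + i / ki),
            }
            for i in per_i
        }
        res.extra["apparent_parameter_check"] = check
    return res


def ms_cleavage(series: Sequence[MsCleavage]) -> dict:
    """Cleavage fraction A/(A+B) per timepoint and its OLS rate.

    A is the cleaved 27885 Da species peak height, B the 72904 Da parent;
    the rate is the slope of fraction vs time over the sampled window.
    """
    if not series:
        raise ValueError("empty cleavage series")
    pts = sorted(series, key=lambda m: m.time_s)
    t = np.array([m.time_s for m in pts])
    frac = np.array([m.fraction for m in pts])
    rate = None
    if t.size >= 2 and np.ptp(t) > 0:
        rate, *_ = _ols(t, frac)
    return {"times_s": t, "fractions": frac, "rate_per_s": rate}


def percent_inhibition(v_inhibited: float, v_control: float) -> dict:
    """100·(1 − v_inhibited/v_control), with a flag when formally negative."""
    if v_control <= 0:
        raise ValueError("control rate must be > 0")
    pct = 100.0 * (1.0 - v_inhibited / v_control)
    return {"percent_inhibition": pct, "negative_flag": pct < 0}


def fit_binding_kd(ligand_M: Sequence[float], signals: Sequence[float],
                   p0_M: float, ci: CiConfig = CiConfig()) -> FitResult:
    """1:1 binding fit with ligand-depletion correction.

    signal = F_free + ΔF·fb(L; KD, P0) with the quadratic fraction bound;
    at P0 ≪ KD this reduces to the hyperbola L/(L+KD).
    """
    lig = np.asarray(ligand_M, dtype=float)
    y = np.asarray(signals, dtype=float)
    if lig.size < 6:
        raise ValueError("need >= 6 titration points")
    if p0_M <= 0:
        raise ValueError("protein concentration must be > 0")

    def fn(l, kd, f_free, delta_f):
        return f_free + delta_f * models.fraction_bound_1to1(l, kd, p0_M)

    kd0 = float(np.median(lig[lig > 0]))
    f0 = float(y[np.argmin(lig)])
    df0 = float(y[np.argmax(lig)] - f0)
    res = _fit_nls(fn, lig, y, p0=[kd0, f0, df0],
                   names=("kd_M", "f_free", "delta_f"), ci=ci,
                   model_name="binding_1to1",
                   bounds=([0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                   positive=("kd_M",))
    if res.converged and res.estimates.get("kd_M", 1.0) <= 0:
        res.flags.append("negative KD")
    return res
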