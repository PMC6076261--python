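"""Closed-form assay models.

These are the response surfaces the bench assays are assumed to follow:
four-parameter logistic dose-response, Michaelis-Menten kinetics with the
three classical single-site inhibition terms, the depletion-corrected 1:1
binding isotherm, and the one-compartment oral absorption PK model.
All concentrations in molar, rates in M/s, PK times in hours.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "four_pl",
    "michaelis_menten",
    "mm_uncompetitive",
    "mm_competitive",
    "mm_noncompetitive",
    "fraction_bound_1to1",
    "one_compartment_oral",
    "one_compartment_tmax",
    "one_compartment_auc_inf",
]


def four_pl(conc, ic50, hill, top, bottom):
    """4PL response: bottom + (top-bottom) / (1 + (C/IC50)^h).

    Decreasing in ``conc`` for positive ``hill``; equals (top+bottom)/2 at
    C = IC50 for any hill slope.
    """
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)


def michaelis_menten(s, vmax, km):
    """v = Vmax·S / (KM + S)."""
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def mm_uncompetitive(s, i, vmax, km, ki):
    """Uncompetitive inhibition: v = Vmax·S / (KM + S·(1 + I/Ki)).

    Both apparent parameters scale as 1/(1 + I/Ki):
    Vmax_app = Vmax/(1+I/Ki), KM_app = KM/(1+I/Ki).
    """
    s = np.asarray(s, dtype=float)
    i = np.asarray(i, dtype=float)
    return vmax * s / (km + s * (1.0 + i / ki))


def mm_competitive(s, i, vmax, km, ki):
    """Competitive inhibition: v = Vmax·S / (KM·(1 + I/Ki) + S)."""
    s = np.asarray(s, dtype=float)
    i = np.asarray(i, dtype=float)
    return vmax * s / (km * (1.0 + i / ki) + s)


def mm_noncompetitive(s, i, vmax, km, ki):
    """Pure noncompetitive inhibition: v = Vmax·S / ((KM + S)·(1 + I/Ki))."""
    s = np.asarray(s, dtype=float)
    i = np.asarray(i, dtype=float)
    return vmax * s / ((km + s) * (1.0 + i / ki))


def fraction_bound_1to1(ligand, kd, p0):
    """Depletion-corrected fraction of protein bound at total ligand L.

    fb = (L + P0 + KD - sqrt((L + P0 + KD)^2 - 4·L·P0)) / (2·P0);
    reduces to the hyperbola L/(L+KD) as P0 → 0.
    """
    ligand = np.asarray(ligand, dtype=float)
    b = ligand + p0 + kd
    disc = b * b - 4.0 * ligand * p0
    return (b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * p0)


def one_compartment_oral(t, dose, ka, ke, v_f, f=1.0):
    """Plasma concentration after a single oral dose.

    C(t) = F·D·ka / (V_F·(ka-ke)) · (e^(-ke·t) - e^(-ka·t)); units follow the
    inputs (dose per kg over apparent volume per kg gives a concentration).
    """
    t = np.asarray(t, dtype=float)
    if np.isclose(ka, ke):
        # degenerate flip-flop limit: C = F·D·ka·t·e^(-ka t)/V_F
        return f * dose * ka * t * np.exp(-ka * t) / v_f
    coef = f * dose * ka / (v_f * (ka - ke))
    return coef * (np.exp(-ke * t) - np.exp(-ka * t))


def one_compartment_tmax(ka, ke):
    """Analytic time of peak concentration: ln(ka/ke)/(ka-ke)."""
    if np.isclose(ka, ke):
        return 1.0 / ka
    return float(np.log(ka / ke) / (ka - ke))


def one_compartment_auc_inf(dose, ke, v_f, f=1.0):
    """Analytic AUC from 0 to infinity: F·D/(V_F·ke)."""
    return f * dose / (v_f * ke)
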