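"""Enzyme-kinetics analytics: rates, IC50, mode, Ki, KD, MS cleavage."""

import numpy as np
import pytest

from punctaflux import enzymology, models, synthgen
from punctaflux.enzymology import CiConfig
from punctaflux.types import MsCleavage, ProgressCurve, RateTable, StandardCurve

WALD = CiConfig(method="wald")
uM = 1e-6


def rate_table_from(df):
    reps = df[~df.is_truth]
    return RateTable(substrate_M=reps.substrate_M.to_numpy(),
                     inhibitor_M=reps.inhibitor_M.to_numpy(),
                     rate_M_per_s=reps.rate_M_per_s.to_numpy(),
                     replicate=reps.replicate.to_numpy())


class TestStandardCurve:
    def test_exact_line_recovered(self):
        concs = np.array([0, 1, 2, 5, 10]) * uM
        rfu = 3e7 * concs + 12.0
        std = enzymology.fit_standard_curve(concs, rfu)
        assert std.slope_rfu_per_M == pytest.approx(3e7)
        assert std.intercept_rfu == pytest.approx(12.0)
        assert std.r_squared == pytest.approx(1.0)
        assert std.rfu_rate_to_molar_rate(3e7) == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            enzymology.fit_standard_curve([1e-6, 1e-6], [10, 20])
        with pytest.raises(ValueError, match="slope"):
            StandardCurve(slope_rfu_per_M=-1.0, intercept_rfu=0.0,
                          r_squared=1.0, residual_sd=0.0)


class TestInitialRate:
    def test_linear_curve_exact_rate(self):
        std = StandardCurve(2e7, 0.0, 1.0, 0.0)
        t = np.arange(0.0, 601.0, 60.0)
        curve = ProgressCurve(times_s=t, signal_rfu=50.0 + 0.4 * t)
        v = enzymology.initial_rate(curve, std)
        assert v == pytest.approx(0.4 / 2e7, rel=1e-12)

    def test_window_excludes_post_consumption_points(self):
        """A curve that is linear until 10% substrate consumption then flat
        must yield the early slope, not the full-trace slope."""
        std = StandardCurve(1e8, 0.0, 1.0, 0.0)
        s0 = 10 * uM
        slope = 100.0  # RFU/s, i.e. 1e-6 M/s against this standard curve
        t = np.arange(0.0, 21.0, 1.0)
        cutoff_rfu = 0.1 * s0 * std.slope_rfu_per_M  # 100 RFU
        y = np.minimum(slope * t, cutoff_rfu * 3)  # plateau well past window
        # product crosses the 10% window at t=1 s; window must still keep >=3 pts
        curve = ProgressCurve(times_s=t, signal_rfu=y, substrate_M=s0)
        v = enzymology.initial_rate(curve, std)
        # oracle: longest initial run with product < 0.1*S0 (min 3 points)
        ok = (y - y[0]) / std.slope_rfu_per_M < 0.1 * s0
        n = max(int(np.argmin(ok)) if not ok.all() else t.size, 3)
        want = np.polyfit(t[:n], y[:n], 1)[0] / std.slope_rfu_per_M
        assert v == pytest.approx(want, rel=1e-12)
        # and it differs from the naive full-trace slope
        naive = np.polyfit(t, y, 1)[0] / std.slope_rfu_per_M
        assert abs(v - naive) > 0.1 * abs(v)

    def test_too_few_points_rejected(self):
        std = StandardCurve(1.0, 0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            enzymology.initial_rate(
                ProgressCurve(times_s=[0.0, 1.0], signal_rfu=[0.0, 1.0]), std)


class TestIc50:
    def test_noiseless_round_trip(self):
        spec = synthgen.default_assay_spec("fourPL", hill=1.3)
        df = synthgen.gen_assay_table(spec)
        reps = df[~df.is_truth]
        res = enzymology.fit_ic50(reps.conc_M, reps.response, ci=WALD)
        assert res.converged
        assert res.estimates["ic50_M"] == pytest.approx(24.5 * uM, rel=1e-6)
        assert res.estimates["hill"] == pytest.approx(1.3, rel=1e-6)

    def test_fitted_curve_passes_through_midpoint(self):
        spec = synthgen.default_assay_spec("fourPL")
        df = synthgen.gen_assay_table(spec)
        reps = df[~df.is_truth]
        res = enzymology.fit_ic50(reps.conc_M, reps.response, ci=WALD)
        e = res.estimates
        at_ic50 = models.four_pl(e["ic50_M"], e["ic50_M"], e["hill"],
                                 e["top"], e["bottom"])
        assert at_ic50 == pytest.approx(0.5 * (e["top"] + e["bottom"]))

    def test_flat_response_flagged_no_dose_effect(self):
        doses = np.geomspace(1, 100, 6) * uM
        res = enzymology.fit_ic50(doses, np.full(6, 0.7), ci=WALD)
        assert not res.converged and "no dose effect" in res.flags

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError):
            enzymology.fit_ic50([1 * uM, 2 * uM, 3 * uM], [1.0, 0.5, 0.1])

    def test_bootstrap_ci_contains_estimate(self):
        spec = synthgen.default_assay_spec("fourPL", seed=5, noise_cv=0.05)
        df = synthgen.gen_assay_table(spec)
        reps = df[~df.is_truth]
        res = enzymology.fit_ic50(reps.conc_M, reps.response,
                                  ci=CiConfig(n_boot=100, seed=1))
        lo, hi = res.ci95["ic50_M"]
        assert lo <= res.estimates["ic50_M"] <= hi


class TestMichaelisMenten:
    def test_noiseless_round_trip(self):
        s = np.array(synthgen.PAPER_SUBSTRATE_GRID_uM) * uM
        v = models.michaelis_menten(s, 1e-8, 50 * uM)
        res = enzymology.fit_michaelis_menten(s, v, ci=WALD)
        assert res.estimates["vmax_M_per_s"] == pytest.approx(1e-8, rel=1e-8)
        assert res.estimates["km_M"] == pytest.approx(50 * uM, rel=1e-8)

    def test_too_few_substrates_rejected(self):
        with pytest.raises(ValueError):
            enzymology.fit_michaelis_menten([1 * uM, 2 * uM], [1e-9, 2e-9])


class TestInhibitionMode:
    @pytest.mark.parametrize("model,want", [
        ("michaelis_menten_uncompetitive", "uncompetitive"),
        ("michaelis_menten_competitive", "competitive"),
        ("michaelis_menten_noncompetitive", "noncompetitive"),
    ])
    def test_noiseless_grid_diagnosed_correctly(self, model, want):
        table = rate_table_from(
            synthgen.gen_assay_table(synthgen.default_assay_spec(model)))
        fits = enzymology.fit_inhibition_grid(table)
        assert enzymology.diagnose_inhibition_mode(fits) == want

    def test_inactive_inhibitor_reads_none(self):
        spec = synthgen.default_assay_spec("michaelis_menten_uncompetitive",
                                           ki_M=1e6)  # effectively no inhibition
        table = rate_table_from(synthgen.gen_assay_table(spec))
        fits = enzymology.fit_inhibition_grid(table)
        assert enzymology.diagnose_inhibition_mode(fits) == "none"

    def test_missing_baseline_rejected(self):
        table = rate_table_from(
            synthgen.gen_assay_table(
                synthgen.default_assay_spec("michaelis_menten_uncompetitive")))
        fits = enzymology.fit_inhibition_grid(table)
        fits.pop(0.0)
        with pytest.raises(ValueError, match="baseline"):
            enzymology.diagnose_inhibition_mode(fits)


class TestUncompetitiveKi:
    def test_noiseless_global_fit_round_trip(self):
        table = rate_table_from(
            synthgen.gen_assay_table(
                synthgen.default_assay_spec("michaelis_menten_uncompetitive")))
        res = enzymology.fit_uncompetitive_ki(table, ci=WALD)
        assert res.estimates["ki_M"] == pytest.approx(20 * uM, rel=1e-6)
        assert res.estimates["vmax_M_per_s"] == pytest.approx(1e-8, rel=1e-6)
        assert res.estimates["km_M"] == pytest.approx(50 * uM, rel=1e-6)

    def test_apparent_parameters_scale_as_one_over_one_plus_i_over_ki(self):
        """Uncompetitive identity: Vmax_app/Vmax = KM_app/KM = 1/(1+I/Ki)."""
        table = rate_table_from(
            synthgen.gen_assay_table(
                synthgen.default_assay_spec("michaelis_menten_uncompetitive")))
        res = enzymology.fit_uncompetitive_ki(table, ci=WALD)
        check = res.extra["apparent_parameter_check"]
        for i_conc, row in check.items():
            assert row["vmax_app_ratio"] == pytest.approx(
                row["predicted_ratio"], rel=1e-4)
            assert row["km_app_ratio"] == pytest.approx(
                row["predicted_ratio"], rel=1e-4)

    def test_thin_grid_rejected(self):
        table = RateTable(substrate_M=np.array([1, 2, 3]) * uM,
                          inhibitor_M=np.zeros(3),
                          rate_M_per_s=np.full(3, 1e-9),
                          replicate=np.ones(3, dtype=int))
        with pytest.raises(ValueError, match="grid too thin"):
            enzymology.fit_uncompetitive_ki(table)


class TestMsCleavage:
    def test_fraction_and_hand_ols_rate(self):
        """Fractions 0.10/0.25/0.40 at 0/15/30 min give exactly the hand OLS
        slope 0.01 per minute."""
        series = [MsCleavage(time_s=0.0, peak_a=10.0, peak_b=90.0),
                  MsCleavage(time_s=900.0, peak_a=25.0, peak_b=75.0),
                  MsCleavage(time_s=1800.0, peak_a=40.0, peak_b=60.0)]
        out = enzymology.ms_cleavage(series)
        np.testing.assert_allclose(out["fractions"], [0.10, 0.25, 0.40])
        assert out["rate_per_s"] == pytest.approx(0.01 / 60.0)

    def test_fraction_uses_both_peaks(self):
        m = MsCleavage(time_s=0.0, peak_a=27885.0, peak_b=72904.0)
        assert m.fraction == pytest.approx(27885.0 / (27885.0 + 72904.0))

    def test_single_point_has_no_rate(self):
        out = enzymology.ms_cleavage([MsCleavage(0.0, 1.0, 1.0)])
        assert out["rate_per_s"] is None

    def test_invalid_series_rejected(self):
        with pytest.raises(ValueError):
            enzymology.ms_cleavage([])
        with pytest.raises(ValueError):
            MsCleavage(time_s=0.0, peak_a=0.0, peak_b=0.0)
        with pytest.raises(ValueError):
            MsCleavage(time_s=0.0, peak_a=-1.0, peak_b=2.0)


class TestPercentInhibition:
    def test_half_rate_is_fifty_percent(self):
        out = enzymology.percent_inhibition(5e-9, 1e-8)
        assert out["percent_inhibition"] == pytest.approx(50.0)
        assert not out["negative_flag"]

    def test_activation_flagged_negative(self):
        out = enzymology.percent_inhibition(1.2e-8, 1e-8)
        assert out["negative_flag"] and out["percent_inhibition"] < 0

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            enzymology.percent_inhibition(1e-9, 0.0)


class TestBindingKd:
    def test_noiseless_round_trip_with_depletion(self):
        spec = synthgen.default_assay_spec("binding_1to1")
        df = synthgen.gen_assay_table(spec)
        reps = df[~df.is_truth]
        res = enzymology.fit_binding_kd(reps.ligand_M, reps.signal,
                                        p0_M=0.17 * uM, ci=WALD)
        assert res.estimates["kd_M"] == pytest.approx(16 * uM, rel=1e-6)
        assert res.estimates["f_free"] == pytest.approx(800.0, rel=1e-6)
        assert res.estimates["delta_f"] == pytest.approx(200.0, rel=1e-6)

    def test_depletion_model_reduces_to_hyperbola_at_low_protein(self):
        lig = np.geomspace(0.1, 1000, 20) * uM
        kd = 16 * uM
        fb = models.fraction_bound_1to1(lig, kd, p0=1e-12)
        np.testing.assert_allclose(fb, lig / (lig + kd), rtol=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            enzymology.fit_binding_kd([1 * uM] * 5, [1.0] * 5, p0_M=0.1 * uM)
        with pytest.raises(ValueError):
            enzymology.fit_binding_kd([1 * uM] * 6, [1.0] * 6, p0_M=0.0)


class TestPkClosedForms:
    def test_tmax_formula_matches_profile_argmax(self):
        t = np.linspace(0.0, 24.0, 20001)
        c = models.one_compartment_oral(t, dose=100.0, ka=2.0, ke=0.3,
                                        v_f=0.85)
        tmax = models.one_compartment_tmax(2.0, 0.3)
        assert tmax == pytest.approx(np.log(2.0 / 0.3) / (2.0 - 0.3))
        assert abs(t[np.argmax(c)] - tmax) <= t[1] - t[0] + 1e-12

    def test_auc_inf_matches_dense_trapezoid(self):
        t = np.linspace(0.0, 400.0, 400001)
        c = models.one_compartment_oral(t, 100.0, 2.0, 0.3, 0.85)
        auc = models.one_compartment_auc_inf(100.0, 0.3, 0.85)
        assert np.trapezoid(c, t) == pytest.approx(auc, rel=1e-4)

    def test_ka_equals_ke_limit_continuous(self):
        t = np.linspace(0.0, 24.0, 97)
        near = models.one_compartment_oral(t, 100.0, 0.3 + 1e-9, 0.3, 0.85)
        at = models.one_compartment_oral(t, 100.0, 0.3, 0.3, 0.85)
        np.testing.assert_allclose(near, at, rtol=1e-5)
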