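"""Capacity estimation: NRH light-curve fits and partitioned A/Ci fits.

Round-trip tests generate curves with the forward model and require the
fitting procedures to return the generating values; a small simulation study
checks bias and interval calibration under measurement noise."""

import numpy as np
import pandas as pd
import pytest

from canophot import fitting, fvcb, synthetic
from canophot.fitting import GasExchangeCurve
from canophot.fvcb import FvCBParams
from canophot.synthetic import GeneratorConfig

NOISELESS = GeneratorConfig(noise_sd=0.0)


class TestLightCurveFit:
    def test_noiseless_round_trip_recovers_all_parameters(self):
        curve, truth = synthetic.gen_light_curve(37.04, phi=0.06, theta=0.75,
                                                 r_d=1.0, config=NOISELESS)
        fit = fitting.fit_light_curve(curve)
        assert fit["a_max"].converged
        assert fit["a_max"].estimate == pytest.approx(37.04, rel=1e-3)
        assert fit["phi"].estimate == pytest.approx(0.06, rel=1e-3)
        assert fit["theta"].estimate == pytest.approx(0.75, rel=1e-2)
        assert fit["r_d"].estimate == pytest.approx(1.0, rel=1e-2)
        assert fit["a_max"].r_squared > 0.999999

    def test_flat_curve_flags_nonconvergence(self):
        pts = pd.DataFrame({"ppfd": np.linspace(50, 1000, 10),
                            "ca_pa": 100.0, "ci_pa": 70.0, "a_net": 5.0})
        curve = GasExchangeCurve(pts, "light_curve")
        fit = fitting.fit_light_curve(curve)
        assert not fit["a_max"].converged
        assert np.isnan(fit["a_max"].estimate)

    def test_too_few_points_is_input_error(self):
        pts = pd.DataFrame({"ppfd": [50, 300, 600, 1000.0], "ca_pa": 100.0,
                            "ci_pa": 70.0, "a_net": [1, 5, 8, 9.0]})
        with pytest.raises(ValueError, match="at least 5"):
            fitting.fit_light_curve(GasExchangeCurve(pts, "light_curve"))

    def test_noisy_amax_median_bias_below_five_percent(self):
        """σ = 0.5 noise on 20-point curves: the Amax estimator's median
        bias stays under 5% across 100 seeded replicates."""
        ests = []
        for seed in range(100):
            curve, _ = synthetic.gen_light_curve(
                37.04, config=GeneratorConfig(noise_sd=0.5, seed=seed))
            fit = fitting.fit_light_curve(curve)
            if fit["a_max"].converged:
                ests.append(fit["a_max"].estimate)
        assert len(ests) >= 95
        med_bias = abs(np.median(ests) - 37.04) / 37.04
        assert med_bias < 0.05


class TestVcmaxFit:
    @pytest.mark.parametrize("vl,jm", [(88.62, 175.42), (20.31, 50.83)])
    def test_noiseless_round_trip(self, vl, jm):
        curve, _ = synthetic.gen_aci_curve(FvCBParams(vl=vl, jm=jm),
                                           NOISELESS)
        fit = fitting.fit_vl(curve)
        assert fit.estimate == pytest.approx(vl, rel=1e-6)
        assert fit.converged and fit.n_points_used >= 3

    def test_window_invariance(self):
        """Points with ci above the Rubisco window never change the fit."""
        curve, _ = synthetic.gen_aci_curve(FvCBParams(vl=60.0, jm=120.0),
                                           NOISELESS)
        base = fitting.fit_vl(curve)
        spiked = curve.points.copy()
        spiked.loc[spiked["ci_pa"] > 30.0, "a_net"] = 999.0
        fit2 = fitting.fit_vl(GasExchangeCurve(spiked, "aci_curve"))
        assert fit2.estimate == base.estimate

    def test_empty_window_is_input_error(self):
        pts = pd.DataFrame({"ppfd": 1000.0, "ca_pa": np.linspace(60, 120, 10),
                            "ci_pa": np.linspace(42, 84, 10), "a_net": 20.0})
        with pytest.raises(ValueError, match="ci <"):
            fitting.fit_vl(GasExchangeCurve(pts, "aci_curve"))

    def test_fixed_respiration_mode(self):
        vl_true, rl = 60.0, 0.6
        ca = np.linspace(0, 120, 20)
        ci = 0.7 * ca
        a = fvcb.rubisco_limited(vl_true, ci) - rl
        pts = pd.DataFrame({"ppfd": 1000.0, "ca_pa": ca, "ci_pa": ci,
                            "a_net": a})
        fit = fitting.fit_vl(GasExchangeCurve(pts, "aci_curve"), fixed_rl=rl)
        assert fit.estimate == pytest.approx(vl_true, rel=1e-9)

    def test_one_se_interval_calibration(self):
        """Under σ = 0.5 noise the ±1 SE interval covers the truth in a
        majority of replicates (normal theory predicts ~68%)."""
        cover = 0
        for seed in range(100):
            curve, _ = synthetic.gen_aci_curve(
                FvCBParams(vl=60.0, jm=150.0),
                GeneratorConfig(noise_sd=0.5, seed=seed))
            fit = fitting.fit_vl(curve)
            if abs(fit.estimate - 60.0) <= fit.standard_error:
                cover += 1
        assert cover >= 55


class TestJmaxFit:
    def test_full_model_curve_recovers_jm_exactly(self):
        curve, _ = synthetic.gen_aci_curve(
            FvCBParams(vl=88.62, jm=175.42), NOISELESS)
        vl = fitting.fit_vl(curve).estimate
        fit = fitting.fit_jm(curve, theta=0.75, vl=vl)
        assert fit.estimate == pytest.approx(175.42, rel=1e-6)
        # per-point inversion is exact, so the spread collapses
        assert fit.standard_error == pytest.approx(0.0, abs=1e-9)

    def test_rubp_limb_curve_recovers_low_jm(self):
        """Bottom-layer Jmax: at Vcmax this low the high-ci window of a full
        min-model curve stays Rubisco-limited, so the RuBP-limb generator is
        the invertible protocol."""
        curve, _ = synthetic.gen_aci_curve(
            FvCBParams(vl=20.31, jm=50.83), NOISELESS, limb="rubp")
        fit = fitting.fit_jm(curve, theta=0.75, vl=20.31)
        assert fit.estimate == pytest.approx(50.83, rel=1e-6)

    def test_no_usable_points_is_failure(self):
        pts = pd.DataFrame({"ppfd": 1000.0, "ca_pa": np.linspace(0, 50, 10),
                            "ci_pa": np.linspace(0, 35, 10), "a_net": 5.0})
        with pytest.raises(ValueError, match="ci > 40"):
            fitting.fit_jm(GasExchangeCurve(pts, "aci_curve"), vl=50.0)

    def test_superphysical_points_dropped_with_warning(self, caplog):
        # A so large that implied J exceeds Ile at low light
        pts = pd.DataFrame({"ppfd": [100.0] * 6,
                            "ca_pa": np.linspace(60, 120, 6),
                            "ci_pa": np.linspace(42, 84, 6),
                            "a_net": [30.0, 30.0, 30.0, 2.0, 2.0, 2.0]})
        curve = GasExchangeCurve(pts, "aci_curve")
        with caplog.at_level("WARNING"):
            fit = fitting.fit_jm(curve, vl=50.0, measurement_ppfd=100.0)
        assert fit.extra["n_dropped"] == 3
        assert fit.n_points_used == 3


class TestLayerProfile:
    def _curves_for_profile(self, vlo_by_layer, n_rep=2, noise=0.0):
        curves = []
        for layer, vl in vlo_by_layer.items():
            for rep in range(n_rep):
                c, _ = synthetic.gen_aci_curve(
                    FvCBParams(vl=vl, jm=2.0 * vl),
                    GeneratorConfig(noise_sd=noise, seed=layer * 10 + rep),
                    layer_index=layer, replicate_id=rep)
                curves.append(c)
        return curves

    def test_identical_layers_zero_slope(self):
        res = fitting.fit_layer_profile(self._curves_for_profile(
            {1: 50.0, 3: 50.0}))
        assert res["trends"]["vlo"]["slope"] == pytest.approx(0.0, abs=1e-9)

    def test_linear_profile_slope_recovered(self):
        truth = {k: 20.0 + 5.0 * k for k in (1, 3, 5, 7)}
        res = fitting.fit_layer_profile(self._curves_for_profile(truth))
        assert res["trends"]["vlo"]["slope"] == pytest.approx(5.0, rel=1e-6)
        assert res["trends"]["vlo"]["r_squared"] == pytest.approx(1.0,
                                                                  abs=1e-9)

    def test_increasing_capacity_gives_positive_trend(self):
        prof = synthetic.capacity_profile()
        truth = dict(zip(prof["layer"], prof["vlo"]))
        res = fitting.fit_layer_profile(self._curves_for_profile(truth,
                                                                 n_rep=1))
        assert res["trends"]["vlo"]["slope"] > 0


class TestCurveIO:
    def test_csv_round_trip(self, tmp_path):
        c1, _ = synthetic.gen_aci_curve(FvCBParams(vl=60, jm=120), NOISELESS,
                                        layer_index=5, replicate_id=1)
        c2, _ = synthetic.gen_light_curve(30.0, config=NOISELESS,
                                          layer_index=5, replicate_id=1)
        df = pd.concat([
            c1.points.assign(layer=5, replicate=1, kind="aci_curve"),
            c2.points.assign(layer=5, replicate=1, kind="light_curve")])
        path = tmp_path / "curves.csv"
        df.to_csv(path, index=False)
        curves = fitting.read_curves_csv(path)
        kinds = sorted(c.curve_kind for c in curves)
        assert kinds == ["aci_curve", "light_curve"]
        assert all(c.layer_index == 5 for c in curves)

    def test_ci_above_ca_rejected(self):
        pts = pd.DataFrame({"ppfd": 1000.0, "ca_pa": [10, 20, 30, 40.0],
                            "ci_pa": [12, 14, 21, 28.0], "a_net": 1.0})
        with pytest.raises(ValueError, match="ci must not exceed"):
            GasExchangeCurve(pts, "aci_curve")
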