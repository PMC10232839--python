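"""Protocol segmentation, % inhibition, and dose-response model fits."""

import numpy as np
import pytest

from meaphen.dose import (
    SteadyStateParams,
    eval_model,
    fit_activation_hill,
    fit_all_models,
    fit_model,
    percent_inhibition,
    segment_steady_state,
)
from meaphen.synth import generate_tevc, standard_etx_protocol
from meaphen.types import DoseFitParams, ProtocolSegment, TEVCTrace

CONCS = np.array([0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0])


def _all_param_sets():
    return [
        ("one_site", DoseFitParams(model="one_site", kd_app=1.0)),
        ("hill", DoseFitParams(model="hill", kd_app=1.0, n_h=0.55)),
        ("two_site", DoseFitParams(model="two_site", c=0.4, kd1_app=0.05, kd2_app=2.0)),
    ]


def _trace(noise_sd=0.0, kd=1.0, seed=0, settle_tau=0.0, sampling=200.0):
    return generate_tevc(
        standard_etx_protocol(),
        girk_max=-4.0,
        leak=-1.0,
        inhibition=DoseFitParams(model="one_site", kd_app=kd),
        noise_sd=noise_sd,
        sampling=sampling,
        seed=seed,
        settle_tau=settle_tau,
    )


class TestSegmentation:
    def test_noiseless_levels_recovered_exactly(self):
        segs = segment_steady_state(_trace())
        by = {(s[0], None if np.isnan(s[1]) else s[1]): s[2] for s in segs}
        assert by[("ND96", None)] == pytest.approx(-1.0)
        assert by[("HK24", None)] == pytest.approx(-5.0)
        assert by[("BA", None)] == pytest.approx(-1.0)
        assert by[("ETX", 1.0)] == pytest.approx(-3.0)

    def test_noisy_levels_within_three_standard_errors(self):
        sd = 0.05
        trace = _trace(noise_sd=sd, seed=4)
        segs = segment_steady_state(trace)
        # 5 s window at 200 Hz -> n = 1000 samples per estimate
        se = sd / np.sqrt(1000)
        hk = next(c for label, _, c in segs if label == "HK24")
        assert abs(hk - -5.0) < 3 * se

    def test_window_longer_than_segment_is_error(self):
        with pytest.raises(ValueError, match="window"):
            segment_steady_state(_trace(), SteadyStateParams(window=40.0))

    def test_guard_respected_on_short_segments(self):
        # the 5 s ND96 segment with a 5 s window must skip the 1 s guard
        trace = _trace(settle_tau=0.3)
        segs = segment_steady_state(trace)
        nd96 = segs[0][2]
        assert nd96 == pytest.approx(-1.0, abs=1e-2)


class TestPercentInhibition:
    def test_halfway_point(self):
        segs = [("HK24", float("nan"), -5.0), ("ETX", 1.0, -3.0), ("BA", float("nan"), -1.0)]
        points = percent_inhibition(segs)
        assert points == [(1.0, pytest.approx(50.0))]

    def test_no_inhibition_and_full_block(self):
        segs = [
            ("HK24", float("nan"), -5.0),
            ("ETX", 0.01, -5.0),
            ("ETX", 30.0, -1.0),
            ("BA", float("nan"), -1.0),
        ]
        points = dict(percent_inhibition(segs))
        assert points[0.01] == pytest.approx(0.0)
        assert points[30.0] == pytest.approx(100.0)

    def test_zero_girk_reference_is_error(self):
        segs = [("HK24", float("nan"), -1.0), ("ETX", 1.0, -1.0), ("BA", float("nan"), -1.0)]
        with pytest.raises(ValueError, match="GIRK"):
            percent_inhibition(segs)

    def test_missing_ba_segment_is_error(self):
        with pytest.raises(ValueError, match="BA"):
            percent_inhibition([("HK24", float("nan"), -5.0), ("ETX", 1.0, -3.0)])


class TestEvalModel:
    def test_one_site_half_saturation(self):
        p = DoseFitParams(model="one_site", kd_app=2.0)
        assert eval_model("one_site", p, 2.0) == pytest.approx(50.0)

    def test_therapeutic_range_point(self):
        p = DoseFitParams(model="one_site", kd_app=1.0)
        assert eval_model("one_site", p, 0.7) == pytest.approx(100 * 0.7 / 1.7)

    def test_hill_with_unit_n_equals_one_site(self):
        x = np.geomspace(0.01, 30, 50)
        one = eval_model("one_site", DoseFitParams(model="one_site", kd_app=1.5), x)
        hill = eval_model("hill", DoseFitParams(model="hill", kd_app=1.5, n_h=1.0), x)
        np.testing.assert_allclose(one, hill, rtol=1e-12)

    def test_hill_worked_value(self):
        p = DoseFitParams(model="hill", kd_app=1.0, n_h=2.0)
        assert eval_model("hill", p, 2.0) == pytest.approx(80.0)

    def test_two_site_reduces_to_one_site_at_c_one(self):
        x = np.geomspace(0.01, 30, 20)
        two = eval_model(
            "two_site",
            DoseFitParams(model="two_site", c=1.0, kd1_app=0.5, kd2_app=10.0),
            x,
        )
        one = eval_model("one_site", DoseFitParams(model="one_site", kd_app=0.5), x)
        np.testing.assert_allclose(two, one, rtol=1e-12)

    def test_zero_and_bounds(self):
        for model, p in _all_param_sets():
            assert eval_model(model, p, 0.0) == 0.0
            x = np.geomspace(1e-4, 1e4, 200)
            y = eval_model(model, p, x)
            assert np.all(np.diff(y) > 0), f"{model} not strictly increasing"
            assert np.all((y >= 0) & (y < 100))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            eval_model("one_site", DoseFitParams(model="one_site", kd_app=1.0), -1.0)


class TestFitModel:
    def test_noiseless_one_site_recovery(self):
        truth = DoseFitParams(model="one_site", kd_app=2.0)
        y = eval_model("one_site", truth, CONCS)
        fit = fit_model(CONCS, y, "one_site")
        assert abs(fit.kd_app - 2.0) / 2.0 < 1e-6

    def test_hill_on_one_site_data_returns_unit_n(self):
        y = eval_model("one_site", DoseFitParams(model="one_site", kd_app=2.0), CONCS)
        fit = fit_model(CONCS, y, "hill")
        assert fit.n_h == pytest.approx(1.0, abs=1e-5)
        assert fit.rss < 1e-10

    def test_two_site_with_c_one_matches_one_site(self):
        y = eval_model("one_site", DoseFitParams(model="one_site", kd_app=2.0), CONCS)
        fit = fit_model(CONCS, y, "two_site")
        # degenerate second site: either c -> 1 with kd1 = 2, or the sites split
        # while the curve stays identical; check the fitted curve instead
        yhat = eval_model("two_site", fit, CONCS)
        np.testing.assert_allclose(yhat, y, atol=1e-5)

    def test_noisy_recovery_median_error_below_ten_percent(self, rng):
        errs = []
        truth = DoseFitParams(model="one_site", kd_app=1.0)
        y0 = eval_model("one_site", truth, CONCS)
        for _ in range(100):
            y = y0 + rng.normal(0, 3.0, size=CONCS.size)
            fit = fit_model(CONCS, y, "one_site")
            errs.append(abs(fit.kd_app - 1.0))
        assert np.median(errs) < 0.10

    def test_low_hill_coefficient_regime_recovered(self, rng):
        """Free-n Hill fits on n=0.55 data stay in [0.45, 0.65] for >=90%."""
        truth = DoseFitParams(model="hill", kd_app=1.0, n_h=0.55)
        y0 = eval_model("hill", truth, CONCS)
        hits = 0
        for _ in range(100):
            y = y0 + rng.normal(0, 3.0, size=CONCS.size)
            fit = fit_model(CONCS, y, "hill")
            hits += 0.45 <= fit.n_h <= 0.65
        assert hits >= 90

    def test_too_few_points_is_error(self):
        with pytest.raises(ValueError, match="points"):
            fit_model(np.array([1.0]), np.array([50.0]), "one_site")

    def test_model_comparison_reports_rss_and_aicc(self):
        y = eval_model("one_site", DoseFitParams(model="one_site", kd_app=1.0), CONCS)
        fits = fit_all_models(CONCS, y)
        assert {f.model for f in fits} == {"one_site", "hill", "two_site"}
        for f in fits:
            assert np.isfinite(f.rss)
            assert f.n_points == CONCS.size


class TestEndToEnd:
    def test_trace_to_fit_recovers_generating_kd(self):
        trace = _trace(noise_sd=0.02, kd=1.0, seed=8)
        segs = segment_steady_state(trace)
        points = percent_inhibition(segs)
        conc = np.array([c for c, _ in points])
        y = np.array([v for _, v in points])
        fit = fit_model(conc, y, "one_site")
        assert fit.kd_app == pytest.approx(1.0, rel=0.05)


class TestActivationHill:
    def test_noiseless_recovery_of_reported_parameters(self):
        g = np.array([20.0, 50.0, 90.0, 118.0, 150.0, 220.0, 400.0])
        truth_imax, truth_kd = 3.4, 118.0
        i = truth_imax * g**4 / (g**4 + truth_kd**4)
        fit = fit_activation_hill(g, i)
        assert abs(fit.imax - truth_imax) / truth_imax < 1e-6
        assert abs(fit.kd - truth_kd) / truth_kd < 1e-6

    def test_half_maximal_current_at_kd(self):
        g = np.array([10.0, 50.0, 118.0, 200.0, 500.0])
        i = 3.4 * g**4 / (g**4 + 118.0**4)
        fit = fit_activation_hill(g, i)
        at_kd = fit.imax * fit.kd**4 / (fit.kd**4 + fit.kd**4)
        assert at_kd == pytest.approx(fit.imax / 2)

    def test_scale_equivariance(self):
        g = np.array([20.0, 60.0, 120.0, 240.0, 480.0])
        i = 2.0 * g**4 / (g**4 + 100.0**4)
        f1 = fit_activation_hill(g, i)
        f2 = fit_activation_hill(2 * g, i)
        assert f2.kd == pytest.approx(2 * f1.kd, rel=1e-6)
        assert f2.imax == pytest.approx(f1.imax, rel=1e-6)

    def test_all_zero_currents_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            fit_activation_hill(np.array([1.0, 2.0, 3.0]), np.zeros(3))
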