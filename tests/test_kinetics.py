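"""Kinetic model linearizations, parameter recovery, selection, extrapolation."""

import numpy as np
import pytest

import franzq as fq
from franzq.errors import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidConfigError,
    NoReleaseError,
)

from conftest import FRANZ_SCHEDULE_H, make_profile


class TestTransforms:
    def test_higuchi_is_sqrt_time(self):
        p = make_profile("zero_order", {"K0": 2.0, "Q0": 0.0}, times=(4, 16, 36))
        ts = fq.transform_profile(p, "higuchi")
        assert ts.x == pytest.approx([2.0, 4.0, 6.0])
        assert ts.y == pytest.approx(p.release_percent)

    def test_first_order_is_log10_release(self):
        p = fq.profile_from_release_percent([1, 2, 3], [10.0, 100.0, 100.0])
        ts = fq.transform_profile(p, "first_order")
        assert ts.y[:2] == pytest.approx([1.0, 2.0])

    def test_zero_order_is_identity(self):
        p = make_profile("zero_order", {"K0": 2.0, "Q0": 5.0})
        ts = fq.transform_profile(p, "zero_order")
        assert ts.x == pytest.approx(p.times_h)
        assert ts.y == pytest.approx(p.release_percent)

    def test_log_transforms_drop_nonpositive_and_report(self):
        p = fq.profile_from_release_percent([1, 2, 3, 4], [-5.0, 10.0, 20.0, 30.0])
        ts = fq.transform_profile(p, "first_order")
        assert ts.n_dropped == 1
        assert len(ts.x) == 3

    def test_weibull_drops_saturated_points(self):
        p = fq.profile_from_release_percent([1, 2, 3, 4], [10.0, 50.0, 90.0, 100.0])
        ts = fq.transform_profile(p, "weibull")
        assert ts.n_dropped == 1

    def test_insufficient_points_raise(self):
        p = fq.profile_from_release_percent([1, 2, 3], [-1.0, -1.0, 10.0])
        with pytest.raises(InsufficientDataError):
            fq.transform_profile(p, "weibull")

    def test_unknown_model_rejected(self):
        p = make_profile("zero_order", {"K0": 2.0})
        with pytest.raises(InvalidConfigError):
            fq.transform_profile(p, "korsmeyer")


class TestExactRecovery:
    """Each model refit to its own noiseless data recovers itself."""

    CASES = [
        ("zero_order", {"K0": 2.0, "Q0": 5.0}),
        ("first_order", {"Q0": 20.0, "K": -0.02}),  # growing release%
        ("higuchi", {"KH": 14.3, "c": 0.0}),
        ("weibull", {"alpha": 0.05, "beta": 1.2}),
    ]

    @pytest.mark.parametrize("model_id,params", CASES)
    def test_r2_is_one_and_params_recover(self, model_id, params):
        profile = make_profile(model_id, params)
        fit = fq.fit_model(profile, model_id)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        for name, truth in params.items():
            assert fit.params[name] == pytest.approx(truth, rel=1e-6, abs=1e-9)

    def test_higuchi_zero_intercept_option(self):
        profile = make_profile("higuchi", {"KH": 14.3, "c": 0.0})
        fit = fq.fit_model(profile, "higuchi", higuchi_intercept="zero")
        assert fit.intercept == 0.0
        assert fit.params["KH"] == pytest.approx(14.3, rel=1e-9)

    def test_first_order_remaining_convention(self):
        # conventional kinetics: remaining% = 100·e^{-Kt}
        times = np.array(FRANZ_SCHEDULE_H)
        pct = 100.0 * (1 - np.exp(-0.05 * times))
        profile = fq.profile_from_release_percent(times, pct)
        fit = fq.fit_model(profile, "first_order", convention="remaining")
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.params["K"] == pytest.approx(0.05, rel=1e-6)
        assert fit.predict(times) == pytest.approx(pct, rel=1e-6)

    def test_r2_invariant_under_affine_y_rescale(self):
        rng = np.random.default_rng(4)
        pct = np.linspace(10, 80, 5) + rng.normal(0, 3, 5)
        p1 = fq.profile_from_release_percent(FRANZ_SCHEDULE_H, pct)
        p2 = fq.profile_from_release_percent(FRANZ_SCHEDULE_H, 2.0 * pct + 0)
        f1 = fq.fit_model(p1, "zero_order")
        # doubling all percentages is an affine map of the y series
        f2 = fq.fit_model(p2, "zero_order")
        assert f2.r2 == pytest.approx(f1.r2, rel=1e-12)

    def test_degenerate_design_raises(self):
        profile = fq.profile_from_release_percent([1, 2, 3], [10.0, 20.0, 30.0])
        profile.times_h = np.array([2.0, 2.0, 2.0])  # forced zero-variance x
        with pytest.raises(DegenerateFitError):
            fq.fit_model(profile, "zero_order")


class TestSelection:
    def test_exact_line_selects_zero_order(self):
        profile = make_profile("zero_order", {"K0": 2.0, "Q0": 5.0})
        fits, best = fq.fit_all_and_select(profile)
        assert best == "zero_order"
        assert next(f for f in fits if f.model_id == "zero_order").r2 == pytest.approx(1.0)

    def test_exact_weibull_selects_weibull(self):
        profile = make_profile("weibull", {"alpha": 0.03, "beta": 1.4})
        _, best = fq.fit_all_and_select(profile)
        assert best == "weibull"

    def test_two_point_profile_fails(self, patch):
        profile = fq.profile_from_release_percent([4, 12], [20.0, 40.0])
        with pytest.raises(fq.AnalysisError):
            fq.fit_all_and_select(profile)

    def test_noisy_higuchi_selected_in_most_runs(self, franz_assay, patch):
        # Monte-Carlo: 2% multiplicative noise on the quantified areas
        from conftest import quantify_series
        wins = 0
        n_runs = 40
        for seed in range(n_runs):
            spectra, truth = fq.simulate_franz_series(
                0.7, FRANZ_SCHEDULE_H, "higuchi", {"KH": 12.0},
                noise=0.02, seed=seed, points=2048)
            profile = fq.build_release_profile(
                truth.initial_mg, quantify_series(spectra, franz_assay), patch)
            _, best = fq.fit_all_and_select(profile)
            wins += best == "higuchi"
        assert wins >= 0.9 * n_runs


class TestRateSummary:
    @pytest.mark.parametrize(
        "kh,c,expected_h",
        [
            (10.0, 0.0, 100.0),
            (14.3, 10.7, ((100 - 10.7) / 14.3) ** 2),  # ≈ 39.0 h
            (12.0, 0.0, (100 / 12.0) ** 2),            # ≈ 69.4 h
        ],
    )
    def test_depletion_time(self, kh, c, expected_h):
        fit = fq.KineticFit("higuchi", kh, c, {"KH": kh, "c": c}, 1.0, 5)
        rs = fq.rate_summary(fit)
        assert rs.higuchi_rate == kh
        assert rs.t_complete_h == pytest.approx(expected_h, rel=1e-9)

    def test_prediction_at_depletion_time_is_hundred(self):
        fit = fq.KineticFit("higuchi", 14.3, 10.7, {"KH": 14.3, "c": 10.7}, 1.0, 5)
        t_c = fq.rate_summary(fit).t_complete_h
        assert fit.predict([t_c])[0] == pytest.approx(100.0, abs=1e-6)

    def test_monotone_in_rate(self):
        ts = [
            fq.rate_summary(
                fq.KineticFit("higuchi", kh, 5.0, {"KH": kh, "c": 5.0}, 1.0, 5)
            ).t_complete_h
            for kh in (10.0, 12.0, 14.0)
        ]
        assert ts[0] > ts[1] > ts[2]

    def test_nonpositive_slope_rejected(self):
        fit = fq.KineticFit("higuchi", -1.0, 0.0, {"KH": -1.0, "c": 0.0}, 0.5, 5)
        with pytest.raises(NoReleaseError):
            fq.rate_summary(fit)

    def test_needs_higuchi_fit(self):
        fit = fq.KineticFit("zero_order", 2.0, 0.0, {"K0": 2.0, "Q0": 0.0}, 1.0, 5)
        with pytest.raises(InvalidConfigError):
            fq.rate_summary(fit)
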