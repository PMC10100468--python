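"""Spectrum container, simulation, Franz-series generation, and CSV I/O."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import franzq as fq
from franzq.errors import InvalidConfigError, SpectrumFormatError


def lorentz_cfg(area=10.0, center=5.0, fwhm=0.01, points=4096,
                ppm_range=(0.0, 10.0), **kw):
    return fq.SimulationConfig(
        resonances=(fq.Resonance(center, fwhm, area),),
        ppm_range=ppm_range, points=points, **kw,
    )


class TestSpectrumContainer:
    def test_ascending_axis_is_resorted_descending(self):
        s = fq.Spectrum([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        assert s.shifts.tolist() == [3.0, 2.0, 1.0]
        assert s.intensities.tolist() == [30.0, 20.0, 10.0]

    @pytest.mark.parametrize(
        "shifts,intens",
        [
            ([1.0], [1.0]),                      # too short
            ([1.0, 2.0], [1.0]),                 # length mismatch
            ([1.0, 1.0, 2.0], [1.0, 2.0, 3.0]),  # not strictly monotone
            ([3.0, 2.0, 1.0], [1.0, np.inf, 2.0]),  # non-finite
        ],
    )
    def test_invariant_violations_rejected(self, shifts, intens):
        with pytest.raises(InvalidConfigError):
            fq.Spectrum(shifts, intens)


class TestSimulateSpectrum:
    def test_baseline_only_is_constant(self):
        cfg = fq.SimulationConfig(resonances=(), baseline=(3.5, 0.0), points=128)
        s = fq.simulate_spectrum(cfg)
        assert np.allclose(s.intensities, 3.5)

    def test_sloped_baseline(self):
        cfg = fq.SimulationConfig(resonances=(), baseline=(1.0, 2.0), points=128)
        s = fq.simulate_spectrum(cfg)
        assert np.allclose(s.intensities, 1.0 + 2.0 * s.shifts)

    def test_determinism_bitwise(self):
        cfg = lorentz_cfg(noise_sd=0.3, seed=42)
        a = fq.simulate_spectrum(cfg)
        b = fq.simulate_spectrum(cfg)
        assert np.array_equal(a.intensities, b.intensities)
        c = fq.simulate_spectrum(lorentz_cfg(noise_sd=0.3, seed=43))
        assert not np.array_equal(a.intensities, c.intensities)

    def test_full_range_integral_matches_closed_form(self):
        # a unit-area Lorentzian carries (2/pi)·arctan(2k) of its mass
        # within ±k·FWHM of the centre
        fwhm = 0.01
        cfg = lorentz_cfg(area=10.0, center=5.0, fwhm=fwhm, points=2**16)
        s = fq.simulate_spectrum(cfg)
        total = np.trapezoid(s.intensities[::-1], s.shifts[::-1])
        k = 5.0 / fwhm  # half-range over FWHM
        expected = 10.0 * (2 / math.pi) * math.atan(2 * k)
        assert total == pytest.approx(expected, rel=5e-4)

    def test_two_peak_area_ratio(self):
        cfg = fq.SimulationConfig(
            resonances=(fq.Resonance(5.57, 0.01, 1.0), fq.Resonance(7.48, 0.01, 4.0)),
            points=2**15,
        )
        s = fq.simulate_spectrum(cfg)
        win = fq.IntegrationWindow.around
        r = fq.integral_ratio(s, win(5.57, 0.1, "none"), win(7.48, 0.1, "none"))
        assert r == pytest.approx(0.25, rel=1e-3)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(scale=st.floats(min_value=0.1, max_value=8.0))
    def test_linearity_in_area(self, scale):
        base = fq.simulate_spectrum(lorentz_cfg(area=2.0, points=512))
        scaled = fq.simulate_spectrum(lorentz_cfg(area=2.0 * scale, points=512))
        assert np.allclose(scaled.intensities, scale * base.intensities)

    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidConfigError):
            fq.SimulationConfig(points=32)
        with pytest.raises(InvalidConfigError):
            fq.SimulationConfig(ppm_range=(10.0, 0.0))
        with pytest.raises(InvalidConfigError):
            fq.SimulationConfig(noise_sd=-1.0)


class TestFranzSeries:
    def test_higuchi_remaining_fractions(self):
        # 10·sqrt(t) percent released at t = 4, 16, 36, 64, 100 h
        _, truth = fq.simulate_franz_series(
            1.0, (4, 16, 36, 64, 100), "higuchi", {"KH": 10.0}, seed=0)
        assert truth.true_remaining_mg == pytest.approx([0.8, 0.6, 0.4, 0.2, 0.0])
        assert not truth.clipped

    def test_zero_order_halfway(self):
        _, truth = fq.simulate_franz_series(
            2.0, (10, 50), "zero_order", {"K0": 1.0, "Q0": 0.0}, seed=0)
        assert truth.true_remaining_mg[-1] == pytest.approx(1.0)

    def test_overshoot_is_clipped_and_flagged(self):
        _, truth = fq.simulate_franz_series(
            1.0, (4, 16, 36, 64, 144), "higuchi", {"KH": 10.0}, seed=0)
        assert truth.clipped
        assert truth.true_remaining_mg[-1] == 0.0

    def test_spectra_carry_time_metadata(self):
        spectra, truth = fq.simulate_franz_series(
            0.7, (4, 12, 24), "higuchi", {"KH": 10.0}, seed=3)
        assert [s.meta["time_h"] for s in spectra] == [4.0, 12.0, 24.0]

    def test_deterministic_under_seed(self):
        a, _ = fq.simulate_franz_series(0.7, (4, 12, 24), "higuchi",
                                        {"KH": 10.0}, noise=0.05, seed=7)
        b, _ = fq.simulate_franz_series(0.7, (4, 12, 24), "higuchi",
                                        {"KH": 10.0}, noise=0.05, seed=7)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.intensities, sb.intensities)

    def test_bad_schedule_rejected(self):
        with pytest.raises(InvalidConfigError):
            fq.simulate_franz_series(1.0, (4.0,), "higuchi", {"KH": 10.0})
        with pytest.raises(InvalidConfigError):
            fq.simulate_franz_series(-1.0, (4, 12), "higuchi", {"KH": 10.0})


class TestSpectrumIO:
    def test_round_trip_preserves_values(self):
        s = fq.simulate_spectrum(lorentz_cfg(points=256, noise_sd=0.1, seed=5))
        text = fq.write_spectrum(s)
        back = fq.read_spectrum(text)
        assert np.allclose(back.shifts, s.shifts, rtol=1e-9, atol=0)
        assert np.allclose(back.intensities, s.intensities, rtol=1e-9)

    def test_ascending_file_reversed(self):
        text = "ppm,intensity\n1.0,10\n2.0,20\n3.0,30\n"
        s = fq.read_spectrum(text)
        assert s.shifts.tolist() == [3.0, 2.0, 1.0]
        assert s.intensities.tolist() == [30.0, 20.0, 10.0]

    def test_comments_ignored(self):
        s = fq.read_spectrum("# a comment\nppm,intensity\n2,1\n# mid\n1,2\n")
        assert len(s) == 2

    @pytest.mark.parametrize(
        "text,fragment",
        [
            ("ppm,intensity\n1.0,2.0\n", "2 data rows"),
            ("ppm,intensity\n1.0,x\n2.0,1\n", "line 2"),
            ("ppm,intensity\n1.0,1\n1.0,2\n", "duplicated"),
            ("wrong,header\n1,2\n2,3\n", "header"),
            ("ppm,intensity\n1.0\n2.0,1\n", "2 columns"),
        ],
    )
    def test_format_errors_name_problem(self, text, fragment):
        with pytest.raises(SpectrumFormatError, match=fragment):
            fq.read_spectrum(text)

    def test_write_to_stream(self):
        s = fq.Spectrum([3.0, 2.0, 1.0], [1.0, 2.0, 3.0])
        buf = io.StringIO()
        fq.write_spectrum(s, buf)
        assert buf.getvalue().startswith("ppm,intensity\n3,")
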