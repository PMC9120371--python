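import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcsleep.cfc import (band_phase_amplitude, kl_mi, mvl, plv, phase_mi,
                         iaaft_surrogates, surrogate_test,
                         surrogate_test_multi, equiquantal_bins,
                         SO_BAND, SPINDLE_BAND)
from tcsleep.synthetic import PacFixtureParams, generate_pac_signal

FS = 100.0


class TestAnalyticSignal:
    def test_sinusoid_amplitude_and_phase_rate(self):
        t = np.arange(0, 60.0, 1 / FS)
        x = 2.0 * np.sin(2 * np.pi * 13.0 * t)
        a = band_phase_amplitude(x, FS, SPINDLE_BAND)
        core = slice(500, -500)
        assert np.allclose(a.amplitude[core], 2.0, rtol=0.02)
        rate = np.diff(np.unwrap(a.phase[core])) * FS / (2 * np.pi)
        assert np.median(rate) == pytest.approx(13.0, rel=0.01)

    def test_phase_convention_at_zero_crossing(self):
        t = np.arange(0, 60.0, 1 / FS)
        x = np.sin(2 * np.pi * 1.0 * t)
        a = band_phase_amplitude(x, FS, SO_BAND)
        k = 3000  # t=30 s: positive-going zero crossing of sin
        assert a.phase[k] == pytest.approx(-np.pi / 2, abs=0.05)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            band_phase_amplitude(np.random.randn(1000), FS, (40.0, 60.0))


class TestKlMi:
    def test_uniform_amplitude_gives_zero(self):
        ph = np.random.default_rng(0).uniform(-np.pi, np.pi, 20000)
        am = np.ones_like(ph)
        assert kl_mi(ph, am) == pytest.approx(0.0, abs=1e-6)

    def test_single_bin_mass_gives_one(self):
        ph = np.full(1000, 0.1)
        am = np.ones(1000)
        assert kl_mi(ph, am) == pytest.approx(1.0)

    def test_modulated_exceeds_unmodulated_every_seed(self):
        for seed in range(20):
            strong = generate_pac_signal(PacFixtureParams(m=0.9, seed=seed,
                                                          duration=60.0))
            none = generate_pac_signal(PacFixtureParams(m=0.0, seed=seed,
                                                        duration=60.0))
            vals = []
            for fx in (strong, none):
                so = band_phase_amplitude(fx["x"], FS, SO_BAND)
                sp = band_phase_amplitude(fx["x"], FS, SPINDLE_BAND)
                vals.append(kl_mi(so.phase, sp.amplitude))
            assert vals[0] > vals[1]

    def test_all_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            kl_mi(np.zeros(100), np.zeros(100))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        ph = rng.uniform(-np.pi, np.pi, 500)
        am = rng.exponential(1.0, 500)
        v = kl_mi(ph, am)
        assert 0.0 <= v <= 1.0


class TestMvlPlv:
    def test_uniform_phase_cancels(self):
        ph = np.linspace(-np.pi, np.pi, 3600, endpoint=False)
        assert abs(mvl(ph, np.ones_like(ph))) < 1e-10

    def test_single_phase_mass_recovers_angle(self):
        ph = np.full(100, 0.6)
        assert np.angle(mvl(ph, np.ones(100))) == pytest.approx(0.6)

    def test_plv_identical_phases(self):
        ph = np.random.default_rng(1).uniform(-np.pi, np.pi, 1000)
        assert abs(plv(ph, ph)) == pytest.approx(1.0)

    def test_plv_constant_offset(self):
        ph = np.random.default_rng(1).uniform(-np.pi, np.pi, 1000)
        v = plv(ph, ph - 0.8)
        assert abs(v) == pytest.approx(1.0)
        assert np.angle(v) == pytest.approx(0.8)

    def test_plv_independent_phases_below_rayleigh_bound(self):
        rng = np.random.default_rng(2)
        n = 12000
        v = abs(plv(rng.uniform(-np.pi, np.pi, n),
                    rng.uniform(-np.pi, np.pi, n)))
        assert v < 1.73 / np.sqrt(n)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            plv(np.array([]), np.array([]))


class TestPhaseMi:
    def test_monotone_bijection_reaches_log_nbins(self):
        # a strictly monotone map gives identical equal-occupancy labels
        ph = np.random.default_rng(3).uniform(-np.pi, np.pi, 16 * 16 * 50)
        v = phase_mi(ph, np.tanh(ph) + 0.1 * ph)
        assert v == pytest.approx(np.log(16), rel=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(-np.pi, np.pi, 5000)
        b = rng.uniform(-np.pi, np.pi, 5000)
        assert phase_mi(a, b) == pytest.approx(phase_mi(b, a), rel=1e-10)

    def test_independent_phases_small_positive_bias(self):
        rng = np.random.default_rng(5)
        n = 16 * 16 * 50
        v = phase_mi(rng.uniform(-np.pi, np.pi, n),
                     rng.uniform(-np.pi, np.pi, n))
        assert 0.0 <= v < 0.05

    def test_short_series_warns(self):
        with pytest.warns(UserWarning):
            phase_mi(np.random.randn(100), np.random.randn(100))

    def test_equiquantal_bins_are_balanced(self):
        x = np.random.default_rng(6).standard_normal(1600)
        counts = np.bincount(equiquantal_bins(x, 16), minlength=16)
        assert counts.min() == counts.max() == 100


@pytest.fixture(scope="module")
def ar2():
    from scipy.signal import lfilter
    return lfilter([1.0], [1.0, -1.2, 0.8],
                   np.random.default_rng(0).standard_normal(12000))


class TestIaaft:
    def test_amplitude_distribution_exact(self, ar2):
        for s in iaaft_surrogates(ar2, 3, seed=1):
            assert np.array_equal(np.sort(s), np.sort(ar2))

    def test_spectrum_match_under_one_percent(self, ar2):
        target = np.abs(np.fft.rfft(ar2))
        for s in iaaft_surrogates(ar2, 3, seed=1):
            err = np.linalg.norm(np.abs(np.fft.rfft(s)) - target)
            assert err / np.linalg.norm(target) < 0.01

    def test_seeded_determinism_and_distinct_surrogates(self, ar2):
        a = iaaft_surrogates(ar2, 4, seed=9)
        b = iaaft_surrogates(ar2, 4, seed=9)
        assert np.array_equal(a, b)
        assert not np.array_equal(a[0], a[1])

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            iaaft_surrogates(np.ones(100), 2, seed=0)


class TestSurrogateTest:
    def test_strong_pac_significant(self):
        fx = generate_pac_signal(PacFixtureParams(m=0.9, duration=60.0,
                                                  seed=7))
        res = surrogate_test("klmi", fx["x"], fx["x"], FS,
                             n_surrogates=99, seed=11)
        assert res.p_value <= 0.02

    def test_no_coupling_not_significant(self):
        fx = generate_pac_signal(PacFixtureParams(m=0.0, duration=60.0,
                                                  seed=8))
        res = surrogate_test("klmi", fx["x"], fx["x"], FS,
                             n_surrogates=99, seed=12)
        assert res.p_value > 0.05

    def test_type_one_error_calibrated(self):
        # uncoupled fixtures: rejection rate at alpha=0.05 stays near alpha
        rejections = 0
        for seed in range(12):
            fx = generate_pac_signal(PacFixtureParams(m=0.0, duration=40.0,
                                                      seed=100 + seed))
            res = surrogate_test("klmi", fx["x"], fx["x"], FS,
                                 n_surrogates=39, seed=seed)
            rejections += res.p_value <= 0.05
        assert rejections <= 3

    def test_p_value_rule_handles_ties(self):
        # p = (1 + #{null >= value}) / (1 + n): with value tied to every
        # surrogate, p = 1; p is never 0 by construction
        fx = generate_pac_signal(PacFixtureParams(m=0.9, duration=40.0,
                                                  seed=3))
        res = surrogate_test("klmi", fx["x"], fx["x"], FS,
                             n_surrogates=24, seed=5)
        assert 0.0 < res.p_value <= 1.0
        assert res.p_value >= 1.0 / 25.0

    def test_shared_surrogates_match_single_runs(self):
        fx = generate_pac_signal(PacFixtureParams(m=0.5, duration=40.0,
                                                  seed=4))
        multi = surrogate_test_multi(["klmi", "mvl"], fx["x"], fx["x"], FS,
                                     n_surrogates=24, seed=6)
        single = surrogate_test("klmi", fx["x"], fx["x"], FS,
                                n_surrogates=24, seed=6)
        assert multi["klmi"].value == single.value
        assert np.array_equal(multi["klmi"].surrogate_values,
                              single.surrogate_values)

    def test_too_few_surrogates_rejected(self):
        with pytest.raises(ValueError):
            surrogate_test("klmi", np.random.randn(1000),
                           np.random.randn(1000), FS, n_surrogates=10)


class TestInvariances:
    def test_statistics_invariant_to_constant_offset(self):
        fx = generate_pac_signal(PacFixtureParams(m=0.7, duration=40.0,
                                                  seed=9))
        x = fx["x"]

        def stats_of(raw):
            so = band_phase_amplitude(raw, FS, SO_BAND)
            sp = band_phase_amplitude(raw, FS, SPINDLE_BAND)
            return (kl_mi(so.phase, sp.amplitude),
                    abs(mvl(so.phase, sp.amplitude)),
                    abs(plv(so.phase, sp.phase)))

        assert np.allclose(stats_of(x), stats_of(x + 57.0), rtol=1e-5,
                           atol=1e-8)
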