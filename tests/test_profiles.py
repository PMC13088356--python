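"""Line-profile sampling, correlograms, first peaks, double labeling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from filamap.detection import FilamentPath, FragmentSpec
from filamap.profiles import (
    Correlogram,
    ProfileFragment,
    autocorrelate,
    cross_correlate,
    first_peak,
    is_double_labeled,
    sample_profile,
    zero_lag_colocalization,
)
from tests.conftest import make_stack


def brute_force_acf(x, kmax):
    """Oracle: O(n²) double-loop biased autocorrelation."""
    x = np.asarray(x, float)
    xbar = x.mean()
    denom = sum((xi - xbar) ** 2 for xi in x)
    out = []
    for k in range(kmax + 1):
        s = 0.0
        for i in range(len(x) - k):
            s += (x[i] - xbar) * (x[i + k] - xbar)
        out.append(s / denom)
    return np.array(out)


def brute_force_ccf(a, b, kmax):
    """Oracle: O(n²) double-loop normalized cross-correlation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    abar, bbar = a.mean(), b.mean()
    denom = np.sqrt(
        sum((x - abar) ** 2 for x in a) * sum((x - bbar) ** 2 for x in b)
    )
    out = []
    for k in range(-kmax, kmax + 1):
        s = 0.0
        for i in range(len(a)):
            j = i + k
            if 0 <= j < len(b):
                s += (a[i] - abar) * (b[j] - bbar)
        out.append(s / denom)
    return np.array(out)


def _straight_path(length=3.0, n=400):
    s = np.linspace(0.0, length, n)
    return FilamentPath(0, np.column_stack([s + 0.5, np.full(n, 1.0)]), s, 0.1)


class TestSampleProfile:
    pixel = 0.032

    def test_uniform_image_gives_constant_profile(self):
        stack = make_stack(np.full((1, 80, 160), 42.0), self.pixel, ["DNA"])
        frag = FragmentSpec(0, 0, 0.0, 1.5)
        prof = sample_profile(stack, _straight_path(), frag, step=0.016, line_width=0.096)
        assert prof is not None
        np.testing.assert_allclose(prof.intensities["DNA"], 42.0)

    def test_zero_linewidth_reduces_to_row_interpolation(self):
        pixels = np.zeros((1, 64, 128))
        pixels[0] = np.arange(128)[None, :]  # intensity = column index
        stack = make_stack(pixels, self.pixel, ["DNA"])
        # path along the row at y = 1.0 µm
        prof = sample_profile(
            stack, _straight_path(), FragmentSpec(0, 0, 0.0, 1.5),
            step=0.016, line_width=0.0,
        )
        s = 0.016 * np.arange(prof.n_samples)
        expected = (s + 0.5) / self.pixel - 0.5  # bilinear on a linear ramp
        np.testing.assert_allclose(prof.intensities["DNA"], expected, atol=1e-9)

    def test_punctum_maximum_at_its_arclength(self):
        # Gaussian spot centered on the path at known arclength
        yy, xx = np.mgrid[:64, :128]
        x_um = (xx + 0.5) * self.pixel
        y_um = (yy + 0.5) * self.pixel
        s_true = 0.7
        spot = np.exp(-(((x_um - (s_true + 0.5)) ** 2 + (y_um - 1.0) ** 2) / (2 * 0.05**2)))
        stack = make_stack(spot[None], self.pixel, ["p"])
        step = 0.016
        prof = sample_profile(
            stack, _straight_path(), FragmentSpec(0, 0, 0.0, 1.5),
            step=step, line_width=0.0,
        )
        s_max = step * np.argmax(prof.intensities["p"])
        assert abs(s_max - s_true) <= step / 2

    def test_out_of_bounds_fragment_rejected(self):
        stack = make_stack(np.ones((1, 10, 200)), self.pixel, ["DNA"])
        path = _straight_path()  # y = 1.0 µm > 10 px * 0.032 µm image height
        out = sample_profile(stack, path, FragmentSpec(0, 0, 0.0, 1.5),
                             step=0.016, line_width=0.0)
        assert out is None

    def test_channels_sampled_at_identical_positions(self):
        pixels = np.stack([np.random.default_rng(0).random((64, 128))] * 2)
        stack = make_stack(pixels, self.pixel, ["a", "b"])
        prof = sample_profile(stack, _straight_path(), FragmentSpec(0, 0, 0.0, 1.5),
                              step=0.016, line_width=0.064)
        np.testing.assert_array_equal(prof.intensities["a"], prof.intensities["b"])


class TestAutocorrelate:
    def _fragment(self, x, step=0.025):
        return ProfileFragment(0, step, {"c": np.asarray(x, float)}, 0.0)

    def test_cosine_first_max_at_period(self):
        x = np.cos(2 * np.pi * np.arange(47) / 10)
        corr = autocorrelate(self._fragment(x), "c", max_lag=0.75)
        vals = corr.values
        # first local maximum after lag 0 sits at lag index 10 (0.25 µm)
        maxima = [k for k in range(1, len(vals) - 1)
                  if vals[k] > vals[k - 1] and vals[k] > vals[k + 1]]
        assert maxima[0] == 10
        assert corr.lags[10] == pytest.approx(0.25)

    def test_constant_profile_excluded(self):
        assert autocorrelate(self._fragment(np.full(60, 3.0)), "c", 0.5) is None

    def test_matches_brute_force_oracle(self, rng):
        x = rng.random(61)
        corr = autocorrelate(self._fragment(x), "c", max_lag=0.75)
        kmax = len(corr.values) - 1
        np.testing.assert_allclose(
            corr.values, brute_force_acf(x, kmax), atol=1e-12
        )

    def test_r0_is_one_and_bounded(self, rng):
        for _ in range(20):
            x = rng.standard_normal(50)
            corr = autocorrelate(self._fragment(x), "c", max_lag=0.6)
            assert corr.values[0] == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.abs(corr.values) <= 1 + 1e-9)

    def test_affine_intensity_invariance(self, rng):
        x = rng.random(55)
        a = autocorrelate(self._fragment(x), "c", 0.6).values
        b = autocorrelate(self._fragment(3.7 * x + 11.0), "c", 0.6).values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_max_lag_must_fit_fragment(self):
        with pytest.raises(ValueError):
            autocorrelate(self._fragment(np.arange(10.0)), "c", max_lag=0.75)


class TestFirstPeak:
    @staticmethod
    def _corr(values, step=0.025):
        values = np.asarray(values, float)
        return Correlogram(step * np.arange(len(values)), values, "auto", 0, ("c",))

    def test_cosine_period_recovered_exactly(self):
        x = np.cos(2 * np.pi * np.arange(47) / 10)
        frag = ProfileFragment(0, 0.025, {"c": x}, 0.0)
        corr = autocorrelate(frag, "c", max_lag=0.75)
        rec = first_peak(corr, min_lag=0.05, min_prominence=0.05)
        assert rec.first_peak_lag == pytest.approx(10 * 0.025)

    def test_monotone_decay_has_no_peak(self):
        rec = first_peak(self._corr(0.9 ** np.arange(30)), 0.05, 0.01)
        assert rec is None

    def test_low_prominence_peak_skipped(self):
        # construct maxima at lags 6 and 12 with known prominences
        values = np.ones(20)
        values[1:6] = [0.6, 0.38, 0.35, 0.36, 0.38]
        values[6] = 0.40          # shallow peak: saddle at 0.35 → prominence 0.05
        values[7:12] = [0.35, 0.1, 0.0, 0.2, 0.5]
        values[12] = 0.55         # prominent peak
        values[13:] = np.linspace(0.15, -0.4, 7)
        corr = self._corr(values)
        # oracle: exhaustive scan with topographic prominence
        from scipy.signal import peak_prominences

        maxima = [k for k in range(1, 19)
                  if values[k] > values[k - 1] and values[k] > values[k + 1]]
        prom = peak_prominences(values, maxima)[0]
        assert maxima == [6, 12]
        assert prom[0] == pytest.approx(0.05, abs=1e-9)
        assert prom[1] >= 0.4
        rec = first_peak(corr, min_lag=0.05, min_prominence=0.1)
        assert rec.first_peak_lag == pytest.approx(12 * 0.025)

    def test_plateau_reports_leftmost_sample(self):
        values = np.concatenate([[1.0], np.linspace(0.8, 0.0, 5),
                                 [0.5, 0.5, 0.5], np.linspace(0.4, -0.2, 5)])
        rec = first_peak(self._corr(values), 0.05, 0.05)
        assert rec.first_peak_lag == pytest.approx(6 * 0.025)

    def test_min_lag_honored(self):
        x = np.cos(2 * np.pi * np.arange(61) / 4)  # period 4 samples = 0.1 µm
        frag = ProfileFragment(0, 0.025, {"c": x}, 0.0)
        corr = autocorrelate(frag, "c", 0.7)
        rec = first_peak(corr, min_lag=0.15, min_prominence=0.05)
        assert rec.first_peak_lag >= 0.15

    def test_min_lag_below_two_steps_rejected(self):
        with pytest.raises(ValueError):
            first_peak(self._corr(np.zeros(10)), min_lag=0.025, min_prominence=0.05)

    @given(st.integers(min_value=3, max_value=15))
    @settings(max_examples=13, deadline=None)
    def test_noiseless_integer_period_recovered_exactly(self, T):
        # ≥ 3 repeats of an exact integer period in the fragment
        n = 4 * T + 3
        x = np.cos(2 * np.pi * np.arange(n) / T)
        frag = ProfileFragment(0, 0.025, {"c": x}, 0.0)
        corr = autocorrelate(frag, "c", max_lag=0.025 * (n - 1) * 0.6)
        rec = first_peak(corr, min_lag=0.05, min_prominence=0.05)
        if T * 0.025 >= 0.05:
            assert rec is not None
            assert rec.first_peak_lag == pytest.approx(T * 0.025, abs=1e-12)


class TestCrossCorrelate:
    @staticmethod
    def _fragment(a, b, step=0.025):
        return ProfileFragment(0, step, {"A": np.asarray(a, float),
                                         "B": np.asarray(b, float)}, 0.0)

    def test_identical_channels_r0_is_one(self, rng):
        x = rng.random(61)
        corr = cross_correlate(self._fragment(x, x), "A", "B", 0.5)
        k0 = len(corr.values) // 2
        assert corr.lags[k0] == 0.0
        assert corr.values[k0] == pytest.approx(1.0, abs=1e-12)

    def test_circular_shift_moves_argmax(self, rng):
        x = rng.random(80)
        m = 7
        corr = cross_correlate(self._fragment(x, np.roll(x, m)), "A", "B", 0.5)
        assert corr.lags[np.argmax(corr.values)] == pytest.approx(m * 0.025)

    def test_matches_brute_force_oracle(self, rng):
        a, b = rng.random(61), rng.random(61)
        corr = cross_correlate(self._fragment(a, b), "A", "B", 0.75)
        kmax = (len(corr.values) - 1) // 2
        np.testing.assert_allclose(
            corr.values, brute_force_ccf(a, b, kmax), atol=1e-12
        )

    def test_symmetry_rab_equals_rba_reversed(self, rng):
        a, b = rng.random(45), rng.random(45)
        ab = cross_correlate(self._fragment(a, b), "A", "B", 0.5).values
        ba = cross_correlate(self._fragment(a, b), "B", "A", 0.5).values
        np.testing.assert_array_equal(ab, ba[::-1])

    def test_white_noise_null_mean_near_zero(self, rng):
        n, reps = 61, 1000
        r0 = np.empty(reps)
        for i in range(reps):
            a, b = rng.standard_normal(n), rng.standard_normal(n)
            rec = zero_lag_colocalization(self._fragment(a, b), ("A", "B"))
            r0[i] = rec.zero_lag_r
        assert abs(r0.mean()) < 3 / np.sqrt(reps * n) * np.sqrt(n)  # CLT on mean of r ~ 1/√n

    def test_zero_variance_excluded(self):
        assert cross_correlate(self._fragment(np.ones(30), np.arange(30)),
                               "A", "B", 0.3) is None


class TestDoubleLabeling:
    step = 0.016

    def _flat_noise(self, rng, n=95, scale=1.0):
        return rng.normal(10, scale, n)

    def _with_punctum(self, rng, n=95, height=10.0):
        x = self._flat_noise(rng, n)
        x[40:46] += height * np.exp(-0.5 * ((np.arange(6) - 2.5) / 1.5) ** 2)
        return x

    def test_flat_noise_not_double_labeled(self, rng):
        f = ProfileFragment(0, self.step,
                            {"a": self._flat_noise(rng), "b": self._flat_noise(rng)}, 0.0)
        assert not is_double_labeled(f, ("a", "b"), snr_min=3.0)

    def test_two_strong_puncta_double_labeled(self, rng):
        f = ProfileFragment(0, self.step,
                            {"a": self._with_punctum(rng), "b": self._with_punctum(rng)}, 0.0)
        assert is_double_labeled(f, ("a", "b"), snr_min=3.0)

    def test_one_labeled_one_flat_is_false(self, rng):
        f = ProfileFragment(0, self.step,
                            {"a": self._with_punctum(rng), "b": self._flat_noise(rng)}, 0.0)
        assert not is_double_labeled(f, ("a", "b"), snr_min=3.0)

    def test_zero_mad_channel_unlabeled(self):
        f = ProfileFragment(0, self.step,
                            {"a": np.full(50, 5.0), "b": np.full(50, 5.0)}, 0.0)
        assert not is_double_labeled(f, ("a", "b"), snr_min=3.0)

    def test_self_colocalization_is_one(self, rng):
        x = rng.random(60)
        f = ProfileFragment(0, self.step, {"a": x, "b": x.copy()}, 0.0)
        rec = zero_lag_colocalization(f, ("a", "b"))
        assert rec.zero_lag_r == pytest.approx(1.0, abs=1e-12)
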