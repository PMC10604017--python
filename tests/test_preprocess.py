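"""Baseline correction, smoothing, normalization, and the per-pixel chain."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ramanmf import (DegenerateSpectrumError, HyperspectralCube,
                     PreprocessParams, RamanPreprocessor, als_baseline,
                     minmax_normalize, preprocess_cube, savgol_smooth)


def dense_asls_oracle(y, lam, p, n_iter):
    """Brute-force AsLS: dense normal equations solved with numpy only."""
    n = len(y)
    D = np.diff(np.eye(n), 2, axis=0)
    P = lam * D.T @ D
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        z = np.linalg.solve(np.diag(w) + P, w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


class TestAlsBaseline:
    def test_constant_signal_is_its_own_baseline(self):
        y = np.full(50, 7.0)
        z = als_baseline(y)
        assert np.max(np.abs(z - 7.0)) < 1e-6 * 7.0

    def test_line_recovered_exactly(self):
        x = np.arange(100, dtype=float)
        y = 3.0 + 0.5 * x
        z = als_baseline(y)
        assert np.max(np.abs(z - y) / np.abs(y)) < 1e-6

    def test_matches_dense_oracle_on_peaks_over_quadratic(self):
        rng = np.random.default_rng(42)
        n = 200
        x = np.linspace(0, 1, n)
        baseline = 5.0 + 2.0 * x - 3.0 * x ** 2
        peaks = sum(
            h * np.exp(-0.5 * ((x - c) / 0.01) ** 2)
            for c, h in [(0.25, 4.0), (0.55, 6.0), (0.8, 3.0)]
        )
        y = baseline + peaks + 0.01 * rng.normal(size=n)
        params = PreprocessParams()
        z = als_baseline(y, params)
        z_oracle = dense_asls_oracle(y, params.als_lambda, params.als_p,
                                     params.als_iterations)
        np.testing.assert_allclose(z, z_oracle, rtol=1e-8, atol=1e-8)
        # corrected signal: background gone, peaks preserved
        corrected = y - z
        assert abs(np.median(corrected)) < 0.05
        assert np.sum(corrected) == pytest.approx(np.sum(peaks), rel=0.05)

    def test_rejects_non_finite(self):
        y = np.ones(10)
        y[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            als_baseline(y)

    def test_rejects_short_input(self):
        with pytest.raises(ValueError):
            als_baseline(np.ones(3))


class TestSavgol:
    def test_reproduces_cubic(self):
        x = np.linspace(-1, 1, 101)
        y = 2.0 - x + 3.0 * x ** 2 - 0.5 * x ** 3
        out = savgol_smooth(y)
        np.testing.assert_allclose(out, y, atol=1e-9)

    def test_constant_preserved(self):
        out = savgol_smooth(np.full(20, 5.0))
        np.testing.assert_allclose(out, 5.0)

    def test_noise_variance_contracted(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=500)
        out = savgol_smooth(y)
        assert out.var() < y.var()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            savgol_smooth(np.ones(50), PreprocessParams(sg_window=10))

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter than window"):
            savgol_smooth(np.ones(7))


class TestMinmax:
    def test_basic(self):
        np.testing.assert_allclose(minmax_normalize([2, 4, 6]), [0, 0.5, 1])

    def test_hand_example(self):
        np.testing.assert_allclose(minmax_normalize([-1, 0, 3]),
                                   [0, 0.25, 1])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=50)
           .filter(lambda v: max(v) > min(v)))
    def test_idempotent(self, vals):
        once = minmax_normalize(vals)
        np.testing.assert_allclose(minmax_normalize(once), once, atol=1e-12)
        assert once.min() == 0.0 and once.max() == 1.0

    def test_constant_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            minmax_normalize([3.0, 3.0, 3.0])


class TestPreprocessCube:
    def _cube(self, intensities):
        n, m = intensities.shape
        return HyperspectralCube(nx=n, ny=1,
                                 axis=np.arange(m, dtype=float) + 1,
                                 intensities=intensities)

    def test_flat_spectra_become_zero(self):
        cube = self._cube(np.full((3, 40), 9.0))
        out = preprocess_cube(cube)
        np.testing.assert_allclose(out.intensities, 0.0, atol=1e-6)

    def test_output_non_negative(self, scene_cube):
        out = preprocess_cube(scene_cube)
        assert np.all(out.intensities >= 0)

    def test_strong_baseline_removed(self):
        """Baseline 10x the peak height: processed pixels must correlate
        with their peak-only truth."""
        rng = np.random.default_rng(3)
        m = 300
        x = np.linspace(0, 1, m)
        peaks = np.exp(-0.5 * ((x - 0.3) / 0.01) ** 2) + \
            0.7 * np.exp(-0.5 * ((x - 0.7) / 0.015) ** 2)
        rows = []
        for _ in range(16):
            c = 10.0 * rng.uniform(0.8, 1.2)
            baseline = c * (1.0 - 0.5 * x + 0.3 * x ** 2)
            rows.append(peaks + baseline + 0.01 * rng.normal(size=m))
        cube = self._cube(np.array(rows))
        out = preprocess_cube(cube)
        for row in out.intensities:
            assert np.corrcoef(row, peaks)[0, 1] >= 0.9

    def test_pixelwise_independence_commutes_with_permutation(self):
        rng = np.random.default_rng(11)
        X = rng.random((6, 60)) + 1.0
        perm = rng.permutation(6)
        pp = RamanPreprocessor()
        np.testing.assert_allclose(pp.transform(X)[perm],
                                   pp.transform(X[perm]))

    def test_error_carries_pixel_coordinates(self):
        bad = np.ones((4, 40))
        bad[3, 5] = np.nan
        cube = HyperspectralCube(nx=2, ny=2, axis=np.arange(40.0) + 1,
                                 intensities=bad)
        with pytest.raises(ValueError, match=r"ix=1, iy=1"):
            preprocess_cube(cube)


class TestPreprocessorEstimator:
    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        pp = RamanPreprocessor(als_lambda=1e4, sg_window=13)
        pp2 = clone(pp)
        assert pp2.get_params()["als_lambda"] == 1e4
        assert pp2.get_params()["sg_window"] == 13

    def test_invalid_params_rejected_at_use(self):
        pp = RamanPreprocessor(als_p=2.0)
        with pytest.raises(ValueError, match="als_p"):
            pp.fit(np.ones((2, 30)))
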