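"""Spectral preprocessing: baseline removal, smoothing, normalization.

The chain applied to every pixel before factorization is

    asymmetric least-squares (AsLS) baseline subtraction
    -> Savitzky-Golay smoothing (window 11, order 3)
    -> clipping of negatives to zero,

which guarantees the non-negative input domain the factorization requires.
Min-max normalization is deliberately NOT part of this chain; it is applied
inside the similarity module immediately before cosine scoring, because
cosine similarity is sensitive to the minimum level and the normalization
belongs with the comparison, not with the decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .io import DegenerateSpectrumError, HyperspectralCube


@dataclass
class PreprocessParams:
    """Parameters of the per-pixel preprocessing chain.

    als_lambda : smoothness weight of the AsLS baseline (dimensionless,
        > 0); larger values give stiffer baselines.  Default 1e5, the
        classic choice for Raman-scale fluorescence backgrounds.
    als_p : asymmetry weight in (0, 1); points above the running baseline
        get weight p, points below get 1 - p.  Default 0.01.
    als_iterations : number of reweighting passes.  Default 10.
    sg_window : odd Savitzky-Golay window length >= 5.  Default 11.
    sg_polyorder : polynomial order < sg_window.  Default 3.
    """

    als_lambda: float = 1e5
    als_p: float = 0.01
    als_iterations: int = 10
    sg_window: int = 11
    sg_polyorder: int = 3

    def __post_init__(self) -> None:
        if self.als_lambda <= 0:
            raise ValueError("als_lambda must be > 0")
        if not 0 < self.als_p < 1:
            raise ValueError("als_p must lie in (0, 1)")
        if self.als_iterations < 1:
            raise ValueError("als_iterations must be >= 1")
        if self.sg_window < 5 or self.sg_window % 2 == 0:
            raise ValueError("sg_window must be an odd integer >= 5")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be < sg_window")


def _second_difference_penalty_bands(n: int, lam: float) -> np.ndarray:
    """Upper banded form (bandwidth 2) of lam * D2.T @ D2 for n points."""
    ab = np.zeros((3, n))
    # main diagonal of D2.T D2: 1, 5, 6, ..., 6, 5, 1
    main = np.full(n, 6.0)
    main[[0, -1]] = 1.0
    if n > 2:
        main[[1, -2]] = 5.0
    if n <= 3:  # tiny systems: fall back to explicit product
        d = np.diff(np.eye(n), 2, axis=0)
        m = d.T @ d
        main = np.diag(m)
    ab[2] = lam * main
    if n > 1:
        off1 = np.full(n - 1, -4.0)
        off1[[0, -1]] = -2.0
        ab[1, 1:] = lam * off1
    if n > 2:
        ab[0, 2:] = lam * 1.0
    return ab


def als_baseline(y, params: PreprocessParams | None = None) -> np.ndarray:
    """Estimate a smooth baseline by asymmetric least squares.

    Minimizes  sum_i w_i (y_i - z_i)^2 + lambda * sum (Delta^2 z)^2  with
    w_i = p where y_i > z_i and 1 - p elsewhere, iterating the weights
    (the Eilers-Boelens scheme).  The pentadiagonal normal equations are
    solved with a banded Cholesky factorization at each pass.
    """
    params = params or PreprocessParams()
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 5:
        raise ValueError("als_baseline needs a 1-D vector of length >= 5")
    if not np.all(np.isfinite(y)):
        raise ValueError("als_baseline requires finite input")
    n = y.size
    penalty = _second_difference_penalty_bands(n, params.als_lambda)
    w = np.ones(n)
    z = y
    for _ in range(params.als_iterations):
        ab = penalty.copy()
        ab[2] += w
        z = solveh_banded(ab, w * y, lower=False)
        w = np.where(y > z, params.als_p, 1.0 - params.als_p)
    return z


def savgol_smooth(y, params: PreprocessParams | None = None) -> np.ndarray:
    """Savitzky-Golay smoothing with the configured window and order."""
    params = params or PreprocessParams()
    y = np.asarray(y, dtype=float)
    if params.sg_window % 2 == 0:
        raise ValueError("sg_window must be odd")
    if y.size < params.sg_window:
        raise ValueError(
            f"input length {y.size} shorter than window {params.sg_window}"
        )
    return savgol_filter(y, params.sg_window, params.sg_polyorder)


def minmax_normalize(y) -> np.ndarray:
    """Scale a vector to [0, 1] by its minimum and maximum.

    Raises :class:`DegenerateSpectrumError` for constant input rather than
    silently returning zeros.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("minmax_normalize needs at least 2 points")
    lo, hi = float(np.min(y)), float(np.max(y))
    if hi == lo:
        raise DegenerateSpectrumError("constant spectrum cannot be normalized")
    return (y - lo) / (hi - lo)


class RamanPreprocessor(TransformerMixin, BaseEstimator):
    """Row-wise baseline-subtract / smooth / clip transformer.

    Operates on a 2-D array of spectra (one pixel per row).  Stateless:
    ``fit`` only validates, so the transformer drops into sklearn pipelines
    ahead of the factorization step.
    """

    def __init__(self, als_lambda=1e5, als_p=0.01, als_iterations=10,
                 sg_window=11, sg_polyorder=3):
        self.als_lambda = als_lambda
        self.als_p = als_p
        self.als_iterations = als_iterations
        self.sg_window = sg_window
        self.sg_polyorder = sg_polyorder

    def _params(self) -> PreprocessParams:
        return PreprocessParams(
            als_lambda=self.als_lambda, als_p=self.als_p,
            als_iterations=self.als_iterations,
            sg_window=self.sg_window, sg_polyorder=self.sg_polyorder,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D array of spectra")
        self._params()  # validate
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        params = self._params()
        out = np.empty_like(X)
        for i, row in enumerate(X):
            corrected = row - als_baseline(row, params)
            out[i] = savgol_smooth(corrected, params)
        np.clip(out, 0.0, None, out=out)
        return out


def preprocess_spectrum(y, params: PreprocessParams | None = None) -> np.ndarray:
    """Apply the full chain (baseline -> smooth -> clip) to one vector."""
    params = params or PreprocessParams()
    corrected = np.asarray(y, dtype=float) - als_baseline(y, params)
    return np.clip(savgol_smooth(corrected, params), 0.0, None)


def preprocess_cube(cube: HyperspectralCube,
                    params: PreprocessParams | None = None) -> HyperspectralCube:
    """Preprocess every pixel of a cube; returns a new cube.

    Failures are re-raised with the offending pixel's grid coordinates.
    """
    params = params or PreprocessParams()
    out = np.empty_like(cube.intensities)
    for row in range(cube.n_pixels):
        try:
            out[row] = preprocess_spectrum(cube.intensities[row], params)
        except Exception as exc:
            ix, iy = cube.pixel_coords(row)
            raise type(exc)(f"pixel (ix={ix}, iy={iy}): {exc}") from exc
    return HyperspectralCube(
        nx=cube.nx, ny=cube.ny, axis=cube.axis.copy(), intensities=out,
        step_x=cube.step_x, step_y=cube.step_y,
        excitation_nm=cube.excitation_nm,
    )
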