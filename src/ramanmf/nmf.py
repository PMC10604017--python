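"""Non-negative matrix factorization by multiplicative updates.

The data matrix A (pixels x wavenumbers) is approximated as W @ S with
W >= 0 (per-pixel concentrations, pixels x k) and S >= 0 (component
spectra, k x wavenumbers), minimizing the Frobenius norm of the residual.
The classical Lee-Seung multiplicative updates are used, which keep both
factors non-negative and never increase the objective.  Model quality is
summarized by the relative reconstruction error

    RRE = ||A - W S||_F / ||A||_F,

which is 0 for a perfect fit and 1 for the trivial W = 0 model.

Initialization is non-negative double SVD (NNDSVD, "a" variant: zeros
filled with the matrix mean) so that every fit is deterministic; random
initialization with an explicit seed is also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

_EPS = np.finfo(float).eps


@dataclass
class NMFModel:
    """One fitted factorization A ~ W @ S.

    Components are stored in canonical gauge (max of each spectral row of S
    equals 1, the scale moved into W) and ordered by descending total
    concentration sum(W[:, c]), so "component 1" is the most abundant.
    """

    k: int
    W: np.ndarray
    S: np.ndarray
    rre: float
    objective: float
    n_iter: int
    converged: bool
    seed: int | None = None
    axis: np.ndarray | None = None
    objective_history: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_pixels(self) -> int:
        return self.W.shape[0]


def _nndsvd(A: np.ndarray, k: int, variant: str = "a") -> tuple[np.ndarray, np.ndarray]:
    """Boutsidis-Gallopoulos non-negative double SVD initialization."""
    U, sig, Vt = np.linalg.svd(A, full_matrices=False)
    n, m = A.shape
    W = np.zeros((n, k))
    H = np.zeros((k, m))
    W[:, 0] = np.sqrt(sig[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(sig[0]) * np.abs(Vt[0, :])
    for j in range(1, k):
        u, v = U[:, j], Vt[j, :]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        nup, nun = np.linalg.norm(up), np.linalg.norm(un)
        nvp, nvn = np.linalg.norm(vp), np.linalg.norm(vn)
        if nup * nvp >= nun * nvn:
            scale = np.sqrt(sig[j] * nup * nvp)
            if nup > 0 and nvp > 0:
                W[:, j] = scale * up / nup
                H[j, :] = scale * vp / nvp
        else:
            scale = np.sqrt(sig[j] * nun * nvn)
            if nun > 0 and nvn > 0:
                W[:, j] = scale * un / nun
                H[j, :] = scale * vn / nvn
    if variant == "a":
        mean = A.mean()
        W[W == 0] = mean
        H[H == 0] = mean
    return W, H


def _frobenius(A, W, H, normA2, WtA=None) -> float:
    """||A - W H||_F via the expanded quadratic form (no big residual)."""
    if WtA is None:
        WtA = W.T @ A
    cross = float(np.einsum("ij,ij->", WtA, H))
    gram = float(np.einsum("ij,ij->", W.T @ W, H @ H.T))
    return float(np.sqrt(max(normA2 - 2.0 * cross + gram, 0.0)))


def nmf_fit(A, k: int, *, init: str = "nndsvda", seed: int | None = 0,
            tol: float = 1e-6, max_iter: int = 4000,
            track_objective: bool = False, axis=None) -> NMFModel:
    """Fit a k-component non-negative factorization of A.

    Parameters
    ----------
    A : array (n_pixels, n_wavenumbers)
        Non-negative data matrix (preprocessed cube intensities).
    k : int
        Number of components, 1 <= k <= min(A.shape).
    init : {"nndsvda", "random"}
        Deterministic SVD-based init (default) or seeded random init.
    seed : int
        Seed for the random init; recorded on the model either way.
    tol : float
        Relative change of the Frobenius objective below which iteration
        stops.
    max_iter : int
        Iteration cap.
    track_objective : bool
        If True, store the per-iteration objective on the model (used by the
        monotonicity checks).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ValueError("A must be 2-D")
    if np.any(A < 0):
        raise ValueError("A must be elementwise non-negative")
    if not 1 <= k <= min(A.shape):
        raise ValueError(f"k={k} outside 1..{min(A.shape)}")

    if init == "nndsvda":
        W, H = _nndsvd(A, k, variant="a")
    elif init == "random":
        rng = np.random.default_rng(seed)
        scale = np.sqrt(A.mean() / max(k, 1))
        W = scale * rng.random((A.shape[0], k))
        H = scale * rng.random((k, A.shape[1]))
    else:
        raise ValueError(f"unknown init {init!r}")
    W = np.maximum(W, _EPS)
    H = np.maximum(H, _EPS)

    normA2 = float(np.einsum("ij,ij->", A, A))
    prev = _frobenius(A, W, H, normA2)
    history = [prev] if track_objective else None
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # Lee-Seung multiplicative updates for the Frobenius loss
        WtA = W.T @ A
        H *= WtA / (W.T @ W @ H + _EPS)
        AHt = A @ H.T
        W *= AHt / (W @ (H @ H.T) + _EPS)
        obj = _frobenius(A, W, H, normA2)
        if history is not None:
            # exact residual norm for the debug trace (the fast expanded
            # form can wobble at machine precision)
            obj = float(np.linalg.norm(A - W @ H))
            history.append(obj)
        if prev > 0 and (prev - obj) / prev < tol:
            converged = True
            prev = obj
            break
        prev = obj

    # canonical gauge: max of each spectral row = 1, scale moved into W
    peak = H.max(axis=1)
    peak[peak == 0] = 1.0
    H = H / peak[:, None]
    W = W * peak[None, :]
    # order components by descending total concentration
    order = np.argsort(-W.sum(axis=0), kind="stable")
    W, H = W[:, order], H[order, :]

    objective = prev
    normA = np.sqrt(normA2)
    model = NMFModel(
        k=k, W=W, S=H,
        rre=float(objective / normA) if normA > 0 else 0.0,
        objective=float(objective), n_iter=n_iter, converged=converged,
        seed=seed, axis=None if axis is None else np.asarray(axis, float),
        objective_history=None if history is None else np.asarray(history),
    )
    return model


def reconstruct(model: NMFModel) -> np.ndarray:
    """Return the model's reconstruction W @ S."""
    return model.W @ model.S


def rre(A, model: NMFModel) -> float:
    """Relative reconstruction error ||A - W S||_F / ||A||_F."""
    A = np.asarray(A, dtype=float)
    R = reconstruct(model)
    if A.shape != R.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {R.shape}")
    denom = np.linalg.norm(A)
    if denom == 0:
        raise ValueError("RRE undefined for an all-zero data matrix")
    return float(np.linalg.norm(A - R) / denom)


def fit_ladder(A, k_range=range(1, 11), *, init: str = "nndsvda",
               seed: int | None = 0, tol: float = 1e-6, max_iter: int = 4000,
               axis=None) -> list[NMFModel]:
    """Fit one independent model per component count in ``k_range``.

    Each model gets its own deterministic initialization (NNDSVD by
    default; with random init the seed is offset by k so the models stay
    independent).  Models are returned in ascending k with their RREs, the
    data behind reconstruction-error-versus-k diagnostics.
    """
    ks = sorted(set(int(k) for k in k_range))
    models = []
    for k in ks:
        try:
            models.append(
                nmf_fit(A, k, init=init,
                        seed=None if seed is None else seed + k,
                        tol=tol, max_iter=max_iter, axis=axis)
            )
        except ValueError as exc:
            raise ValueError(f"k={k}: {exc}") from exc
    return models


class MultiplicativeNMF(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper around :func:`nmf_fit`.

    ``fit(X)`` factorizes X; ``components_`` holds the spectral matrix S and
    ``transform`` returns fresh concentrations for new rows by non-negative
    least squares against the fitted spectra.
    """

    def __init__(self, n_components=2, init="nndsvda", tol=1e-6,
                 max_iter=4000, random_state=0):
        self.n_components = n_components
        self.init = init
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        self.model_ = nmf_fit(
            X, self.n_components, init=self.init, seed=self.random_state,
            tol=self.tol, max_iter=self.max_iter,
        )
        self.components_ = self.model_.S
        self.reconstruction_err_ = self.model_.objective
        self.rre_ = self.model_.rre
        self.n_iter_ = self.model_.n_iter
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.model_.W

    def transform(self, X):
        from scipy.optimize import nnls

        X = np.atleast_2d(np.asarray(X, dtype=float))
        S = self.components_
        W = np.empty((X.shape[0], S.shape[0]))
        for i, row in enumerate(X):
            W[i], _ = nnls(S.T, row)
        return W

    def inverse_transform(self, W):
        return np.asarray(W) @ self.components_
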