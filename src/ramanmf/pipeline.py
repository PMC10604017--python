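"""End-to-end orchestration: estimator, run configuration, pipeline runner.

:class:`RamanUnmixer` is the one-stop estimator: ``fit(X)`` preprocesses
(optionally), fits the model ladder, scores it against the reference
library, and selects the optimal component count; ``transform(X)`` returns
the selected model's concentrations.  :func:`run_pipeline` is the file-level
driver behind the command line: it reads a map and references, runs the
estimator, and writes images, plots and the report JSON.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .imaging import concentration_image, render_summary
from .io import HyperspectralCube, ReferenceLibrary, read_library, read_map_text
from .nmf import fit_ladder
from .preprocess import PreprocessParams, preprocess_cube, preprocess_spectrum
from .similarity import (SelectionParams, SelectionReport, score_ladder,
                         select_optimal)

logger = logging.getLogger("ramanmf")


class RamanUnmixer(TransformerMixin, BaseEstimator):
    """Ladder-of-models unmixer with reference-guided order selection.

    Parameters
    ----------
    library : ReferenceLibrary
        Labeled reference spectra on the data's wavenumber axis.
    k_max : int
        Largest component count in the ladder (models 1..k_max).
    tau, epsilon, delta : float
        Selection thresholds (resolution threshold, parsimony tolerance,
        argmax margin).
    preprocess : bool
        Apply the baseline/smooth/clip chain to rows of X before fitting.
    preprocess_references : bool
        Pass the references through the same chain before scoring, so both
        sides of every comparison saw identical treatment.

    Attributes (after ``fit``)
    --------------------------
    models_ : list of NMFModel, ks 1..k_max
    grid_ : SimilarityGrid over (k, component, reference)
    report_ : SelectionReport with assignments, first resolution, k_star
    k_star_ : selected component count (None if no model resolves all)
    best_model_ : the NMFModel at k_star_
    """

    def __init__(self, library: ReferenceLibrary, k_max: int = 10,
                 tau: float = 0.5, epsilon: float = 0.05, delta: float = 0.0,
                 preprocess: bool = True, preprocess_references: bool = True,
                 preprocess_params: PreprocessParams | None = None,
                 init: str = "nndsvda", seed: int = 0, tol: float = 1e-6,
                 max_iter: int = 4000):
        self.library = library
        self.k_max = k_max
        self.tau = tau
        self.epsilon = epsilon
        self.delta = delta
        self.preprocess = preprocess
        self.preprocess_references = preprocess_references
        self.preprocess_params = preprocess_params
        self.init = init
        self.seed = seed
        self.tol = tol
        self.max_iter = max_iter

    def _selection_params(self) -> SelectionParams:
        return SelectionParams(tau=self.tau, epsilon=self.epsilon,
                               delta=self.delta)

    def _scoring_library(self) -> ReferenceLibrary:
        if not self.preprocess_references:
            return self.library
        pp = self.preprocess_params or PreprocessParams()
        from .io import Spectrum

        return ReferenceLibrary([
            Spectrum(s.axis.copy(), preprocess_spectrum(s.intensities, pp),
                     label=s.label)
            for s in self.library.spectra
        ])

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (pixels x wavenumbers)")
        if X.shape[1] != len(self.library.axis):
            raise ValueError(
                f"X has {X.shape[1]} wavenumbers, library has "
                f"{len(self.library.axis)}"
            )
        if self.preprocess:
            pp = self.preprocess_params or PreprocessParams()
            work = np.array([preprocess_spectrum(row, pp) for row in X])
        else:
            work = np.clip(X, 0.0, None)
        self.processed_ = work
        self.models_ = fit_ladder(
            work, range(1, self.k_max + 1), init=self.init, seed=self.seed,
            tol=self.tol, max_iter=self.max_iter, axis=self.library.axis,
        )
        lib = self._scoring_library()
        self.grid_ = score_ladder(self.models_, lib)
        rre_per_k = {m.k: m.rre for m in self.models_}
        self.report_ = select_optimal(self.grid_, rre_per_k,
                                      self._selection_params())
        self.k_star_ = self.report_.k_star
        self.best_model_ = (
            None if self.k_star_ is None
            else next(m for m in self.models_ if m.k == self.k_star_)
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X=None):
        """Concentrations of the selected model's components.

        With X=None (the usual case for a map that was just fitted) the
        fitted W is returned directly.
        """
        if self.best_model_ is None:
            raise RuntimeError("no model resolves all species")
        if X is None:
            return self.best_model_.W
        from .nmf import MultiplicativeNMF

        proxy = MultiplicativeNMF(n_components=self.k_star_)
        proxy.components_ = self.best_model_.S
        return proxy.transform(np.asarray(X, dtype=float))

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(None)


@dataclass
class RunConfig:
    """File paths plus every stage's parameters for one pipeline run."""

    map_path: str
    reference_paths: dict  # label -> path
    out_dir: str
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    preprocess_references: bool = True
    selection: SelectionParams = field(default_factory=SelectionParams)
    k_max: int = 10
    seed: int = 0
    tol: float = 1e-6
    max_iter: int = 4000
    init: str = "nndsvda"
    dataset: str = "run"
    optical_image: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        pp = raw.get("preprocess", {})
        nmf = raw.get("nmf", {})
        sel = raw.get("selection", {})
        return cls(
            map_path=raw["map"],
            reference_paths=dict(raw["references"]),
            out_dir=raw.get("out", "out"),
            preprocess=PreprocessParams(
                als_lambda=pp.get("als_lambda", 1e5),
                als_p=pp.get("als_p", 0.01),
                als_iterations=pp.get("als_iterations", 10),
                sg_window=pp.get("sg_window", 11),
                sg_polyorder=pp.get("sg_polyorder", 3),
            ),
            preprocess_references=raw.get("preprocess_references", True),
            selection=SelectionParams(
                tau=sel.get("tau", 0.5),
                epsilon=sel.get("epsilon", 0.05),
                delta=sel.get("delta", 0.0),
            ),
            k_max=nmf.get("k_max", 10),
            seed=nmf.get("seed", 0),
            tol=nmf.get("tol", 1e-6),
            max_iter=nmf.get("max_iter", 4000),
            init=nmf.get("init", "nndsvda"),
            dataset=raw.get("dataset", "run"),
            optical_image=raw.get("optical_image"),
        )


NO_MODEL_RESOLVES_ALL = 3  # distinct exit code for the structured failure


def run_pipeline(config: RunConfig) -> SelectionReport:
    """Read -> preprocess -> fit ladder -> score -> select -> render.

    Returns the selection report; all artifacts (images, plots, tables,
    report JSON) land in ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("reading map %s", config.map_path)
    cube = read_map_text(config.map_path)
    logger.info("map: %dx%d pixels, %d wavenumbers",
                cube.nx, cube.ny, cube.axis.size)
    library = read_library(config.reference_paths, target_axis=cube.axis)
    if library.axis.size != cube.axis.size:
        # references only overlap part of the cube axis: crop the cube
        keep = (cube.axis >= library.axis[0]) & (cube.axis <= library.axis[-1])
        cube = HyperspectralCube(
            nx=cube.nx, ny=cube.ny, axis=cube.axis[keep],
            intensities=cube.intensities[:, keep],
            step_x=cube.step_x, step_y=cube.step_y,
            excitation_nm=cube.excitation_nm,
        )

    unmixer = RamanUnmixer(
        library=library, k_max=config.k_max,
        tau=config.selection.tau, epsilon=config.selection.epsilon,
        delta=config.selection.delta,
        preprocess=True, preprocess_references=config.preprocess_references,
        preprocess_params=config.preprocess,
        init=config.init, seed=config.seed, tol=config.tol,
        max_iter=config.max_iter,
    )
    logger.info("fitting ladder k=1..%d (seed=%d, tol=%g)",
                config.k_max, config.seed, config.tol)
    unmixer.fit(cube.intensities)
    report = unmixer.report_
    for m in unmixer.models_:
        logger.info("k=%d rre=%.4f iter=%d", m.k, m.rre, m.n_iter)
    logger.info("k_star=%s status=%s", report.k_star, report.status)

    from .similarity import write_similarity_table

    write_similarity_table(unmixer.grid_, out / f"{config.dataset}_grid.csv")
    images = {}
    if report.k_star is not None:
        best = unmixer.best_model_
        for ref, (comp, _score) in report.assignments[report.k_star].items():
            images[ref] = concentration_image(best, cube, comp, species=ref)
    render_summary(report, images, unmixer.models_, library, unmixer.grid_,
                   out, dataset=config.dataset,
                   optical_image=config.optical_image)
    return report
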