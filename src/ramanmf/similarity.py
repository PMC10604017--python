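"""Cosine scoring of resolved spectra and data-driven model selection.

Each component spectrum of every model in the ladder is compared with each
reference spectrum by cosine similarity of the min-max normalized vectors,

    sim(a, b) = (a . b) / (||a|| ||b||),

which for non-negative spectra lies in [0, 1] and equals 1 for identical
band shapes.  The scores form a grid over (model k, component, reference) —
the machine-readable form of a published similarity table.

Model selection formalizes two quantitative criteria:

1. *Resolution*: a model is a candidate only if every reference can be
   assigned its own component.  A component's candidate reference is its
   best-scoring one; the pair is eligible if the score clears the
   resolution threshold tau (and an optional argmax margin delta), and
   references are claimed greedily by descending score so the assignment
   is injective.
2. *Similarity with parsimony*: among candidates, the model score m(k) is
   the worst assigned similarity; the selected model is the smallest k
   whose m(k) comes within epsilon of the best m over all candidates.

A third criterion — agreement of the resolved spatial maps with the
optical image — is inherently visual; the report carries the images for
side-by-side human review and never computes a score for it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AxisMismatchError, DegenerateSpectrumError, ReferenceLibrary
from .nmf import NMFModel
from .preprocess import minmax_normalize


def cosine_similarity(a, b) -> float:
    """Cosine similarity of two spectra after min-max normalization.

    Both inputs are normalized to [0, 1] internally, so the score is
    invariant to the scale and offset of either spectrum; for non-negative
    spectra it lies in [0, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    # constant non-zero vectors are left as-is (min-max would be undefined);
    # only a zero-norm vector is truly degenerate here
    if a.max() > a.min():
        a = minmax_normalize(a)
    if b.max() > b.min():
        b = minmax_normalize(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateSpectrumError("zero-norm spectrum in cosine similarity")
    return float(np.dot(a, b) / (na * nb))


@dataclass
class SimilarityGrid:
    """Scores indexed by (model k, component 1..k, reference label).

    Backed by a tidy DataFrame with columns ``model_k``, ``component`` and
    one column per reference label.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"model_k", "component"}
        if not need <= set(self.frame.columns):
            raise ValueError("grid frame needs model_k and component columns")
        if len(self.frame) == 0:
            raise ValueError("empty similarity grid")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def references(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("model_k", "component")]

    @property
    def ks(self) -> list[int]:
        return sorted(int(k) for k in self.frame["model_k"].unique())

    @property
    def n_scores(self) -> int:
        return len(self.frame) * len(self.references)

    def model(self, k: int) -> pd.DataFrame:
        sub = self.frame[self.frame["model_k"] == k]
        if len(sub) == 0:
            raise KeyError(f"no model with k={k} in grid")
        return sub.sort_values("component").reset_index(drop=True)

    def score(self, k: int, component: int, reference: str) -> float:
        sub = self.model(k)
        row = sub[sub["component"] == component]
        if len(row) != 1:
            raise KeyError(f"component {component} of model {k} not in grid")
        return float(row.iloc[0][reference])

    @classmethod
    def from_records(cls, records: list[dict]) -> "SimilarityGrid":
        return cls(pd.DataFrame.from_records(records))

    @classmethod
    def read_csv(cls, path) -> "SimilarityGrid":
        return cls(pd.read_csv(path))


def write_similarity_table(grid: SimilarityGrid, path) -> None:
    """Write the grid as CSV, scores rounded to 2 decimals for display,
    plus an unrounded machine copy alongside (suffix ``.full.csv``)."""
    path = str(path)
    refs = grid.references
    rounded = grid.frame.copy()
    rounded[refs] = rounded[refs].round(2)
    rounded.to_csv(path, index=False)
    full = path[:-4] + ".full.csv" if path.endswith(".csv") else path + ".full.csv"
    grid.frame.to_csv(full, index=False)


def score_ladder(models: list[NMFModel],
                 library: ReferenceLibrary) -> SimilarityGrid:
    """Score every component of every model against every reference."""
    n_wn = len(library.axis)
    records = []
    for model in models:
        if model.S.shape[1] != n_wn:
            raise AxisMismatchError(
                f"model k={model.k} has {model.S.shape[1]} wavenumbers, "
                f"library has {n_wn}"
            )
        if model.axis is not None and not np.allclose(model.axis, library.axis):
            raise AxisMismatchError(
                f"model k={model.k} axis differs from library axis"
            )
        for c in range(model.k):
            rec = {"model_k": model.k, "component": c + 1}
            for ref in library.spectra:
                rec[ref.label] = cosine_similarity(model.S[c], ref.intensities)
            records.append(rec)
    return SimilarityGrid.from_records(records)


@dataclass
class SelectionParams:
    """Thresholds of the selection rule.

    tau : resolution threshold on the assigned similarity (default 0.5).
    epsilon : parsimony tolerance — a smaller model within epsilon of the
        best worst-case similarity is preferred (default 0.05).
    delta : optional margin the best reference must hold over the runner-up
        for a component to be assignable (default 0).
    """

    tau: float = 0.5
    epsilon: float = 0.05
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must lie in [0, 1)")
        if not 0 <= self.delta < 1:
            raise ValueError("delta must lie in [0, 1)")


def assign_components(grid: SimilarityGrid, k: int,
                      params: SelectionParams | None = None) -> dict:
    """Assign references to components of model k.

    Each component's candidate reference is its argmax over references; the
    pair is eligible iff the score is >= tau and leads the component's
    second-best reference by >= delta.  References are then claimed
    greedily by descending eligible score, at most one component per
    reference.  Returns {reference: (component, score)}.
    """
    params = params or SelectionParams()
    sub = grid.model(k)
    refs = grid.references
    candidates = []  # (score, component, reference)
    for _, row in sub.iterrows():
        scores = np.array([float(row[r]) for r in refs])
        order = np.argsort(-scores, kind="stable")
        best, second = scores[order[0]], (scores[order[1]] if len(refs) > 1 else -np.inf)
        if best >= params.tau and best - second >= params.delta:
            candidates.append((best, int(row["component"]), refs[order[0]]))
    assignment: dict = {}
    claimed_components: set[int] = set()
    for score, comp, ref in sorted(candidates, key=lambda t: (-t[0], t[1])):
        if ref in assignment or comp in claimed_components:
            continue
        assignment[ref] = (comp, float(score))
        claimed_components.add(comp)
    return assignment


def first_resolution(grid: SimilarityGrid,
                     params: SelectionParams | None = None) -> dict:
    """Smallest k whose assignment includes each reference (None if never)."""
    params = params or SelectionParams()
    out = {ref: None for ref in grid.references}
    for k in grid.ks:
        assigned = assign_components(grid, k, params)
        for ref in assigned:
            if out[ref] is None:
                out[ref] = k
    return out


def stability_profile(grid: SimilarityGrid, reference: str,
                      params: SelectionParams | None = None) -> dict:
    """Assigned scores for a reference across models at/after its first
    resolution, with their mean and standard deviation.

    An unresolved reference yields an empty profile.
    """
    params = params or SelectionParams()
    if reference not in grid.references:
        raise KeyError(reference)
    first = first_resolution(grid, params)[reference]
    scores: dict[int, float] = {}
    if first is not None:
        for k in grid.ks:
            if k < first:
                continue
            assigned = assign_components(grid, k, params)
            if reference in assigned:
                scores[k] = assigned[reference][1]
    vals = np.array(list(scores.values()))
    return {
        "scores": scores,
        "mean": float(vals.mean()) if vals.size else None,
        "sd": float(vals.std(ddof=0)) if vals.size else None,
    }


@dataclass
class SelectionReport:
    """Full outcome of the ladder evaluation.

    ``k_star`` is None when no model resolves every reference, with
    ``status`` set to ``"no model resolves all species"`` — a structured
    outcome advising a larger ladder, not an exception.
    """

    assignments: dict            # k -> {reference: (component, score)}
    resolved: dict               # k -> sorted list of resolved references
    first_resolution: dict       # reference -> smallest k or None
    candidates: list             # ks resolving every reference
    m_per_k: dict                # candidate k -> min assigned similarity
    k_star: int | None
    stability: dict              # reference -> {scores, mean, sd}
    rre_per_k: dict | None = None
    params: SelectionParams = field(default_factory=SelectionParams)
    status: str = "ok"

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "k_star": self.k_star,
            "assignments": {
                str(k): {r: [c, s] for r, (c, s) in a.items()}
                for k, a in self.assignments.items()
            },
            "resolved": {str(k): v for k, v in self.resolved.items()},
            "first_resolution": self.first_resolution,
            "candidates": self.candidates,
            "m_per_k": {str(k): v for k, v in self.m_per_k.items()},
            "rre_per_k": None if self.rre_per_k is None
            else {str(k): v for k, v in self.rre_per_k.items()},
            "stability": {
                r: {"scores": {str(k): v for k, v in p["scores"].items()},
                    "mean": p["mean"], "sd": p["sd"]}
                for r, p in self.stability.items()
            },
            "params": {"tau": self.params.tau, "epsilon": self.params.epsilon,
                       "delta": self.params.delta},
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def select_optimal(grid: SimilarityGrid, rre_per_k: dict | None = None,
                   params: SelectionParams | None = None) -> SelectionReport:
    """Select the optimal model from a scored ladder.

    Candidates are the models assigning every reference; the model score
    m(k) is the minimum assigned similarity; the selected k* is the
    smallest candidate within epsilon of the best m(k).  The RRE sequence,
    when supplied, is carried through so the traditional
    reconstruction-error elbow can be displayed alongside.
    """
    params = params or SelectionParams()
    refs = grid.references
    assignments = {k: assign_components(grid, k, params) for k in grid.ks}
    resolved = {k: sorted(a.keys()) for k, a in assignments.items()}
    first = {ref: None for ref in refs}
    for k in grid.ks:
        for ref in assignments[k]:
            if first[ref] is None:
                first[ref] = k
    candidates = [k for k in grid.ks if set(resolved[k]) == set(refs)]
    m_per_k = {
        k: float(min(s for _, s in assignments[k].values()))
        for k in candidates
    }
    if candidates:
        best = max(m_per_k.values())
        k_star = min(k for k in candidates if m_per_k[k] >= best - params.epsilon)
        status = "ok"
    else:
        k_star = None
        status = "no model resolves all species"
    stability = {ref: stability_profile(grid, ref, params) for ref in refs}
    return SelectionReport(
        assignments=assignments, resolved=resolved, first_resolution=first,
        candidates=candidates, m_per_k=m_per_k, k_star=k_star,
        stability=stability, rre_per_k=rre_per_k, params=params,
        status=status,
    )
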