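"""Cosine scoring, assignment, first resolution, and model selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ramanmf import (DegenerateSpectrumError, ReferenceLibrary,
                     SelectionParams, SimilarityGrid, Spectrum,
                     assign_components, cosine_similarity, first_resolution,
                     score_ladder, select_optimal, stability_profile)
from ramanmf.nmf import NMFModel


class TestCosine:
    def test_self_similarity_is_one(self):
        a = np.array([0.1, 0.9, 0.3, 0.0])
        assert cosine_similarity(a, a) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert cosine_similarity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_forty_five_degrees(self):
        assert cosine_similarity([1.0, 0.0], [1.0, 1.0]) == pytest.approx(
            1 / np.sqrt(2), abs=1e-4)

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])

    def test_scale_and_offset_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.random(50)
        b = rng.random(50)
        base = cosine_similarity(a, b)
        assert cosine_similarity(3.5 * a + 2.0, b) == pytest.approx(base)

    @given(st.integers(0, 1000))
    def test_non_negative_pairs_score_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random(30), rng.random(30)
        assert 0.0 <= cosine_similarity(a, b) <= 1.0 + 1e-12


def _toy_models_and_library(n_refs=4, k_max=10, n_wn=24, seed=0):
    rng = np.random.default_rng(seed)
    axis = np.arange(n_wn, dtype=float) + 400
    refs = [Spectrum(axis, rng.random(n_wn) + 0.01, label=f"ref{i}")
            for i in range(n_refs)]
    library = ReferenceLibrary(refs)
    models = []
    for k in range(1, k_max + 1):
        S = rng.random((k, n_wn)) + 0.01
        models.append(NMFModel(k=k, W=rng.random((5, k)), S=S, rre=0.1,
                               objective=1.0, n_iter=1, converged=True,
                               axis=axis))
    return models, library


class TestScoreLadder:
    def test_full_ladder_score_count(self):
        models, library = _toy_models_and_library()
        grid = score_ladder(models, library)
        assert grid.n_scores == 220

    def test_single_model_single_reference(self):
        models, library = _toy_models_and_library(n_refs=1, k_max=1)
        grid = score_ladder(models, library)
        assert grid.n_scores == 1

    def test_own_spectrum_scores_one(self):
        models, library = _toy_models_and_library(k_max=2)
        # plant a component equal to a reference
        models[1].S[0] = library["ref2"].intensities.copy()
        grid = score_ladder(models, library)
        assert grid.score(2, 1, "ref2") == pytest.approx(1.0)

    def test_axis_mismatch_rejected(self):
        from ramanmf import AxisMismatchError

        models, library = _toy_models_and_library(n_wn=24)
        _, other = _toy_models_and_library(n_wn=30, seed=1)
        with pytest.raises(AxisMismatchError):
            score_ladder(models, other)

    def test_all_scores_in_unit_interval(self, fitted_unmixer):
        refs = fitted_unmixer.grid_.references
        vals = fitted_unmixer.grid_.frame[refs].to_numpy()
        assert np.all(vals >= 0) and np.all(vals <= 1 + 1e-12)


class TestAssignment:
    def test_published_model8(self, published_grid):
        out = assign_components(published_grid, 8)
        assert out == {
            "Acrylamide Resin": (1, 0.98), "Glass": (2, 0.97),
            "Bis-Tris": (3, 0.84), "PanK": (7, 0.77),
        }

    def test_published_model2_partial(self, published_grid):
        out = assign_components(published_grid, 2)
        assert out == {"Acrylamide Resin": (1, 0.99), "Glass": (2, 0.96)}
        assert "PanK" not in out and "Bis-Tris" not in out

    def test_below_threshold_unassigned(self):
        frame = pd.DataFrame([
            {"model_k": 1, "component": 1, "a": 0.4, "b": 0.4},
        ])
        out = assign_components(SimilarityGrid(frame), 1)
        assert out == {}

    def test_injective_within_model(self, published_grid):
        for k in published_grid.ks:
            out = assign_components(published_grid, k)
            comps = [c for c, _ in out.values()]
            assert len(comps) == len(set(comps))


class TestFirstResolution:
    def test_published_ordering(self, published_grid):
        first = first_resolution(published_grid)
        assert first["Acrylamide Resin"] == 1
        assert first["Glass"] == 2
        assert first["Bis-Tris"] == 3

    def test_never_resolved_maps_to_none(self):
        frame = pd.DataFrame([
            {"model_k": k, "component": c, "a": 0.2, "b": 0.1}
            for k in (1, 2) for c in range(1, k + 1)
        ])
        first = first_resolution(SimilarityGrid(frame))
        assert first == {"a": None, "b": None}


class TestSelectOptimal:
    def test_published_grid_selects_eight(self, published_grid):
        report = select_optimal(published_grid)
        assert report.k_star == 8
        assert report.assignments[8]["PanK"] == (7, 0.77)
        assert set(report.candidates) <= set(range(6, 11))
        assert report.m_per_k[8] == pytest.approx(0.77)

    def test_parsimony_within_epsilon(self):
        rows = []
        # k=2 resolves both refs at 0.9; k=3 slightly better (0.92)
        rows.append({"model_k": 1, "component": 1, "a": 0.95, "b": 0.2})
        rows += [{"model_k": 2, "component": 1, "a": 0.95, "b": 0.1},
                 {"model_k": 2, "component": 2, "a": 0.2, "b": 0.90}]
        rows += [{"model_k": 3, "component": 1, "a": 0.95, "b": 0.1},
                 {"model_k": 3, "component": 2, "a": 0.2, "b": 0.92},
                 {"model_k": 3, "component": 3, "a": 0.3, "b": 0.2}]
        report = select_optimal(SimilarityGrid(pd.DataFrame(rows)))
        assert report.k_star == 2

    def test_single_model_single_reference(self):
        frame = pd.DataFrame([{"model_k": 1, "component": 1, "only": 0.99}])
        report = select_optimal(SimilarityGrid(frame))
        assert report.k_star == 1

    def test_unresolved_is_structured_not_raised(self):
        frame = pd.DataFrame([{"model_k": 1, "component": 1,
                               "a": 0.9, "b": 0.2}])
        report = select_optimal(SimilarityGrid(frame))
        assert report.k_star is None
        assert report.status == "no model resolves all species"

    def test_invariant_to_reference_column_order(self, published_grid):
        base = select_optimal(published_grid)
        cols = ["model_k", "component"] + published_grid.references[::-1]
        flipped = SimilarityGrid(published_grid.frame[cols])
        rep = select_optimal(flipped)
        assert rep.k_star == base.k_star
        assert rep.assignments[8] == base.assignments[8]

    def test_invariant_to_component_relabeling(self, published_grid):
        rng = np.random.default_rng(13)
        frame = published_grid.frame.copy()
        pieces = []
        for k, sub in frame.groupby("model_k"):
            sub = sub.sample(frac=1.0, random_state=int(k)).copy()
            sub["component"] = rng.permutation(sub["component"].to_numpy())
            pieces.append(sub)
        shuffled = SimilarityGrid(pd.concat(pieces))
        rep = select_optimal(shuffled)
        base = select_optimal(published_grid)
        assert rep.k_star == base.k_star
        # same references resolved with the same scores (labels permuted)
        for k in published_grid.ks:
            got = {r: s for r, (_c, s) in rep.assignments[k].items()}
            want = {r: s for r, (_c, s) in base.assignments[k].items()}
            assert got == want

    def test_report_json_round_trip(self, tmp_path, published_grid):
        import json

        report = select_optimal(published_grid, rre_per_k={1: 0.3, 2: 0.2})
        p = tmp_path / "report.json"
        report.to_json(p)
        payload = json.loads(p.read_text())
        assert payload["k_star"] == 8
        assert payload["first_resolution"]["Bis-Tris"] == 3
        assert payload["rre_per_k"]["2"] == 0.2


class TestStability:
    def test_resin_high_and_flat(self, published_grid):
        prof = stability_profile(published_grid, "Acrylamide Resin")
        assert all(v >= 0.98 for v in prof["scores"].values())
        assert prof["sd"] < 0.01

    def test_bistris_floor(self, published_grid):
        prof = stability_profile(published_grid, "Bis-Tris")
        assert all(v >= 0.81 for v in prof["scores"].values())

    def test_unresolved_reference_empty(self):
        frame = pd.DataFrame([{"model_k": 1, "component": 1,
                               "a": 0.9, "b": 0.2}])
        prof = stability_profile(SimilarityGrid(frame), "b")
        assert prof["scores"] == {} and prof["mean"] is None


class TestSelectionParams:
    @pytest.mark.parametrize("kwargs", [
        {"tau": 0.0}, {"tau": 1.0}, {"epsilon": -0.1}, {"delta": 1.0},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SelectionParams(**kwargs)
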