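# ramanmf

Reference-guided NMF unmixing of Raman hyperspectral images.

## The scientific problem

Raman microscopy of heterogeneous samples — for example an enzyme
immobilized on porous resin beads sitting on a glass slide — produces a
*hyperspectral map*: a grid of pixels, each with a full Raman spectrum.
Every pixel spectrum is a mixture: carrier, support, analyte, and residue
signals superimpose, on top of a fluorescence baseline and noise. Two
questions matter in practice: **which chemical species are present and
where**, and — harder — **how many factorization components are needed to
separate them**, since the right number is rarely the number of species
(baseline residue and substrate variation soak up extra components).

`ramanmf` implements a complete pipeline for this problem:

1. **Preprocessing** per pixel: asymmetric-least-squares (AsLS) baseline
   subtraction, Savitzky-Golay smoothing, and clipping of residual
   negatives.
2. **Non-negative matrix factorization** (NMF) by multiplicative updates
   minimizing the Frobenius norm, with deterministic NNDSVD-a
   initialization, fitted for every component count `k = 1..k_max`.
3. **Model-order selection** guided by a library of reference spectra:
   every component of every model is scored against every reference by
   cosine similarity of min-max normalized spectra; the selected model is
   the most parsimonious one that resolves *all* references nearly as
   well as the best model in the ladder.
4. **Chemical imaging**: the selected model's concentration columns,
   reshaped onto the pixel grid, give one abundance map per species.

A ground-truthed synthetic-scene generator (enzyme + resin + glass + wash
residue) makes the whole pipeline testable end to end without measured
data. See `docs/methods.md` for the precise model, selection rule, and
limitations.

The model is `A ~ W S`, where `A` (pixels x wavenumbers) is the map, `W`
holds per-pixel concentrations and `S` the component spectra, both
non-negative. Fit quality is the relative reconstruction error
`RRE = ||A - W S||_F / ||A||_F`.

## Worked example 1: selecting the model order from a published table

The package ships a similarity table from a published enzyme-immobilization
study (785 nm, pantothenate kinase "PanK" on acrylamide resin): cosine
scores of every component of models `k = 1..10` against four references.
Running the default selection rule on it:

```python
from ramanmf import published_similarity_grid, select_optimal

grid = published_similarity_grid()
report = select_optimal(grid)
print("k_star:", report.k_star)
print("candidates:", report.candidates)
print("m(k):", {k: round(v, 2) for k, v in report.m_per_k.items()})
for ref, (comp, score) in sorted(report.assignments[report.k_star].items()):
    print(f"  {ref}: component {comp}, similarity {score:.2f}")
```

prints exactly:

```
k_star: 8
candidates: [6, 7, 8, 9, 10]
m(k): {6: 0.73, 7: 0.71, 8: 0.77, 9: 0.8, 10: 0.78}
  Acrylamide Resin: component 1, similarity 0.98
  Bis-Tris: component 3, similarity 0.84
  Glass: component 2, similarity 0.97
  PanK: component 7, similarity 0.77
```

Reading it: models with 6 or more components resolve all four references
(the candidates); `m(k)` is each candidate's worst assigned score. The
best worst-case is 0.80 at `k = 9`, and the smallest candidate within the
parsimony tolerance (0.05) of that is `k = 8` — the selected model, where
PanK scores 0.77. The report also shows that resin is resolved from the
1-component model onward (stability mean 0.982, sd 0.004), glass from 2,
the Bis-Tris buffer from 3, and the enzyme only from 6 — the
component-hungry species is what drives the model order.

## Worked example 2: recovering a known synthetic scene

```python
import numpy as np
from ramanmf import (RamanUnmixer, ReferenceLibrary, default_scene,
                     reference_spectra, render_cube)

truth = default_scene(32, 32, seed=0)           # 4 species, known maps
cube = render_cube(truth)                        # + baseline + noise
library = ReferenceLibrary(list(reference_spectra(truth).values()))
unmixer = RamanUnmixer(library=library, k_max=10, seed=0)
unmixer.fit(cube.intensities)

report = unmixer.report_
print("k_star:", report.k_star)
for ref, (comp, score) in sorted(report.assignments[report.k_star].items()):
    pearson = np.corrcoef(unmixer.best_model_.W[:, comp - 1],
                          truth.abundances[ref].ravel())[0, 1]
    print(f"  {ref}: component {comp}, similarity {score:.2f}, "
          f"abundance Pearson {pearson:.2f}")
```

prints (deterministically, about half a minute on one CPU):

```
k_star: 5
  enzyme: component 3, similarity 0.95, abundance Pearson 0.99
  glass: component 1, similarity 0.97, abundance Pearson 1.00
  resin: component 2, similarity 0.95, abundance Pearson 0.98
  wash: component 4, similarity 0.97, abundance Pearson 0.98
```

All four species are recovered with spectra matching their references at
0.95+ and abundance maps correlating with ground truth at 0.98+; the
fifth component absorbs baseline residue, illustrating why the selected
order exceeds the species count.

`RamanUnmixer` follows the scikit-learn estimator convention: parameters
in `__init__`, fitted state in trailing-underscore attributes
(`models_`, `grid_`, `report_`, `k_star_`, `best_model_`),
`transform(None)` returning the selected concentrations, and
compatibility with `sklearn.base.clone`. Every stage is also available as
a plain function (`als_baseline`, `nmf_fit`, `score_ladder`,
`select_optimal`, ...).

## Command line

Each stage is independently invocable:

```
ramanmf simulate --nx 32 --ny 32 --seed 0 --out scene/
ramanmf preprocess --map scene/map.txt --out processed.txt
ramanmf fit --map scene/map.txt --references scene/ --k-max 10 --out run/
ramanmf select --grid run/grid.full.csv --rre run/rre.csv --out report.json
ramanmf report --run-dir run/ --map scene/map.txt --references scene/
ramanmf run --config config.yaml          # everything, from YAML
```

`run` writes per-species abundance images (16-bit PNG + raw CSV, named
`<dataset>_<species>_k<k>_c<comp>`), the RRE-versus-k and
similarity-versus-k plots, spectral overlays, the similarity table, and a
report JSON. Exit code 3 signals the structured outcome "no model
resolves all species".

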