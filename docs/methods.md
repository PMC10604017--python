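# Methods note

This note records the exact model, the algorithmic and numerical choices
made in `ramanmf`, the scope of the synthetic-scene generator, and the
known limitations. It is the reference for anyone auditing results
produced with the package.

## Problem setting

A Raman hyperspectral map is a grid of pixels, each carrying a full
spectrum. With `n` pixels and `m` wavenumber channels the data form a
non-negative matrix `A` (`n x m`). The physical premise is linear mixing:
every pixel spectrum is approximately a non-negative combination of a
small number of pure-species spectra. The tasks are (1) recover those
pure spectra and their per-pixel abundances without knowing how many
species are present, and (2) decide the number of components by comparing
the recovered spectra against a library of measured reference spectra.

## Preprocessing

Each pixel spectrum is processed independently, in this order:

1. **Baseline subtraction** by asymmetric least squares (AsLS). The
   baseline `z` minimizes `sum_i w_i (y_i - z_i)^2 + lambda * sum_i
   (Delta^2 z_i)^2` with asymmetric weights `w_i = p` where `y_i > z_i`
   and `1 - p` otherwise, iterated to a fixed point. Defaults:
   `lambda = 1e5`, `p = 0.01`, 10 iterations. The pentadiagonal normal
   equations are solved with `scipy.linalg.solveh_banded`; a dense
   normal-equations oracle in the test suite pins the solution to
   `rtol = 1e-8`.
2. **Savitzky-Golay smoothing**, window 11, polynomial order 3
   (`scipy.signal.savgol_filter`). This filter reproduces cubics exactly,
   which the tests check to `1e-9`.
3. **Clipping** of residual negative values to zero, so the matrix handed
   to the factorizer is non-negative.

Min-max normalization to `[0, 1]` is deliberately *not* part of this
chain: it is applied only inside the similarity scoring, to both sides of
each comparison, so factorization sees intensities on their native scale
while scoring is scale- and offset-free.

When reference spectra are supplied for scoring they are passed through
the same baseline/smooth/clip chain by default
(`preprocess_references=True`), so both sides of every cosine comparison
received identical treatment.

## Factorization

`A ~ W S` with `W` (`n x k`) the concentration (abundance) matrix and `S`
(`k x m`) the spectral matrix, both non-negative. The factorization
minimizes the Frobenius norm `||A - W S||_F` by Lee-Seung multiplicative
updates. Choices:

- **Initialization**: NNDSVD-a (non-negative double SVD, zeros filled
  with the matrix mean). This makes every fit deterministic with no seed
  sensitivity; `init="random"` with an explicit seed is available for
  robustness checks.
- **Convergence**: relative change of the objective between sweeps below
  `tol`, default `tol = 1e-6` with `max_iter = 4000`. The loose setting
  `1e-4`-`1e-5` that is common elsewhere was found to leave visibly mixed
  components on realistic scenes: component spectra still carried
  off-species bands that depressed cosine scores and destabilized model
  selection. Tightening the tolerance removed this without any other
  change.
- **Gauge fixing**: the scaling freedom `(W D)(D^-1 S)` is fixed by
  rescaling each row of `S` to maximum 1, with the inverse factor
  absorbed into `W`. Components are then ordered by descending total
  concentration (column sums of `W`). Reported quantities are invariant
  to this gauge.
- **Fit quality**: relative reconstruction error
  `RRE = ||A - W S||_F / ||A||_F`, which lies in `[0, 1]` for the fits
  produced here and decreases (weakly) in `k` along a ladder.

The independent check: on random matrices the final objective agrees with
scikit-learn's multiplicative-update NMF (same init family, same
tolerance) to within 1%. scikit-learn's solver is used only as a test
oracle, never in the library code path.

## Model-order selection

Models are fitted for every `k = 1..k_max` (default 10). Every component
of every model is scored against every reference by cosine similarity of
the min-max normalized spectra; for non-negative inputs the score lies in
`[0, 1]`.

Within one model, references are assigned to components as follows: each
component's best-matching reference must reach the resolution threshold
`tau` (default 0.5) and exceed the runner-up by at least the margin
`delta` (default 0); assignments are then claimed greedily in order of
descending score, so no component is assigned twice. A model is a
*candidate* if every reference in the library is assigned. For each
candidate `k`, `m(k)` is the minimum assigned score — the quality of the
worst-resolved species. The selected order `k*` is the **smallest**
candidate with `m(k) >= max_k m(k) - epsilon` (default `epsilon = 0.05`):
the most parsimonious model whose worst species is within tolerance of
the best achievable. If no candidate exists the outcome is the structured
status "no model resolves all species" (CLI exit code 3), not an
exception.

Two diagnostics accompany the choice: the *first resolution* order per
reference (smallest `k` at which it is assigned) and a *stability
profile* (the assigned scores across all models at or after first
resolution, with mean and standard deviation). Agreement between resolved
abundance maps and an optical image, when one exists, is a visual check
for the analyst; it is recorded in the report but never scored.

## Synthetic scenes

Because the method must be testable end to end without measured data, the
generator builds ground-truthed scenes with four species emulating an
enzyme-on-carrier system:

- **resin**: hemispherical bead profiles placed by rejection sampling
  (non-overlapping), with sharp bands at 852/1112/1454/1662 cm^-1;
- **glass**: the complement of the bead support, one broad band near
  1400 cm^-1 plus a weaker one near 1090 cm^-1;
- **enzyme**: a surface coating (shell profile) on a subset of beads,
  with bands at 1003/1244/1454/1605/1662 cm^-1, modulated by a smooth
  random coverage field;
- **wash** residue: the same shell geometry on the *other* beads, so
  enzyme and wash abundances are negatively correlated across the map.

Two geometric details are structural requirements, not tuning. First,
coatings live on shells whose footprint protrudes slightly (12%) beyond
the bead outline: if the coating support were strictly inside the bead
support, the factorization could shift any multiple of the carrier
spectrum into the coating component and the problem would be genuinely
non-identifiable. The protruding rim provides pixels containing coating
but no carrier, which anchors the spectra. Second, coverage varies
smoothly and independently of bead size, so no species' abundance is a
scalar multiple of another's — the mixing matrix has full column rank.

The forward model is exactly the mixing model the factorization assumes:
`intensities = abundances x pure spectra + per-pixel quadratic baseline +
Gaussian noise` whose standard deviation has a signal-proportional term
(`sd = noise_sd + shot_scale * sqrt(clean)`). Defaults give a
signal-to-noise ratio around 20 and a baseline large enough that raw
cubes fail the similarity threshold while preprocessed cubes pass.
Everything is deterministic per seed.

Not modeled: physical Raman cross sections, fluorescence photophysics,
cosmic-ray spikes, detector nonlinearity, excitation-wavelength physics.

## Numerical and format choices

- Maps are long-format delimited text (x, y, wavenumber, intensity);
  delimiter and optional header are auto-detected. Values are parsed with
  a round-trip-exact float parser so write-read cycles are bit-identical.
- Pixels are linearized row-major with x varying fastest and origin at
  the top-left; `pixel_index`/`pixel_coords` are exact inverses, and
  chemical images are `W` columns reshaped with the same convention.
- Wavenumber axes are sorted ascending on ingestion. References are
  resampled onto the map axis by linear interpolation; extrapolation is
  refused, and a map is cropped to the overlap of its references' axes.
- Similarity tables are written twice: rounded to two decimals for
  human-facing output and at full precision alongside (`*.full.csv`) for
  downstream computation.

## Limitations

- Multiplicative updates converge to a local optimum; NNDSVD-a makes the
  result reproducible but not provably global. Robustness can be probed
  with `init="random"` over seeds.
- The selection rule resolves ties and near-ties with fixed defaults
  (`tau = 0.5`, `delta = 0`, `epsilon = 0.05`); datasets whose best and
  runner-up scores differ by less than measurement noise can flip between
  adjacent `k` values. The report's candidate list and stability profiles
  are provided so such flips are visible rather than silent.
- Cosine similarity on normalized spectra is insensitive to band-height
  ratios between distant bands; chemically distinct species with
  coincident band positions can score high against each other.
- AsLS with fixed `lambda` under-fits baselines whose curvature varies
  strongly across the spectrum; `lambda` is exposed for such cases.
- The generator's band presets are role-named stand-ins, not measured
  reference intensities; recovery results on synthetic scenes bound what
  the pipeline can do under its own assumptions, not instrument reality.
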