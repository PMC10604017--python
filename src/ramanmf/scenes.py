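"""Ground-truthed synthetic scenes of immobilized-enzyme samples.

The generator emulates a Raman map of enzyme-loaded resin beads on a glass
slide: disk-shaped beads of a carrier resin, glass substrate everywhere the
beads are not, enzyme bound to a subset of the beads, and residue of the
final wash buffer concentrated in the remaining beads (so enzyme and wash
abundances anti-correlate, as a washing step leaves residue where less
enzyme is bound).  Pure spectra are sums of Gaussian/Lorentzian bands at
positions characteristic of the real species: the enzyme carries the
1003 cm^-1 phenylalanine band plus C-H deformation (1454) and amide I
(1662) bands it shares with the resin; glass contributes one broad band
near 1400 cm^-1 (785 nm excitation); the wash buffer has bands in the
800-900, 1000-1100 and 1400-1500 cm^-1 regions.  The rendered cube is

    intensity = sum_species abundance * pure  +  smooth baseline  +  noise,

exactly the bilinear mixing model the factorization assumes, so parameter
recovery is well posed; the baseline and heteroscedastic (shot-like plus
read) noise supply the nuisance structure the preprocessing chain exists
to remove.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import HyperspectralCube, Spectrum

DEFAULT_AXIS = np.arange(600.0, 1801.0, 2.0)

#: default band presets per role: (center cm^-1, FWHM cm^-1, height, shape)
SPECIES_BANDS: dict[str, list[tuple]] = {
    "enzyme": [
        (1003.0, 12.0, 1.00, "gaussian"),   # phenylalanine ring breathing
        (1244.0, 25.0, 0.45, "gaussian"),   # amide III
        (1605.0, 16.0, 0.40, "gaussian"),   # aromatic ring modes
        (1454.0, 20.0, 0.30, "gaussian"),   # C-H deformation (shared)
        (1662.0, 28.0, 0.35, "gaussian"),   # amide I (shared with resin)
    ],
    "resin": [
        (852.0, 18.0, 0.40, "gaussian"),
        (1112.0, 22.0, 0.45, "gaussian"),
        (1454.0, 20.0, 1.00, "gaussian"),   # C-H deformation (shared)
        (1662.0, 26.0, 0.70, "gaussian"),   # carbonyl/amide (shared)
    ],
    "glass": [
        (1400.0, 140.0, 1.00, "gaussian"),  # broad silicate band, 785 nm
        (1090.0, 90.0, 0.35, "gaussian"),
    ],
    "wash": [
        (838.0, 16.0, 0.60, "gaussian"),
        (876.0, 16.0, 0.45, "gaussian"),
        (1032.0, 16.0, 0.80, "gaussian"),
        (1068.0, 18.0, 0.65, "gaussian"),
        (1462.0, 22.0, 1.00, "gaussian"),
    ],
}


@dataclass
class BandSpec:
    """One vibrational band: center, full width at half maximum, height."""

    center: float
    fwhm: float
    height: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.height < 0:
            raise ValueError("height must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")


def make_pure_spectrum(bands: list[BandSpec], axis, label: str = "") -> Spectrum:
    """Evaluate a sum of band profiles on the axis.

    Bands centered outside the axis range are skipped with a warning.
    """
    axis = np.asarray(axis, dtype=float)
    if not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be strictly increasing")
    y = np.zeros_like(axis)
    for b in bands:
        if not axis[0] <= b.center <= axis[-1]:
            warnings.warn(
                f"band at {b.center} cm^-1 outside axis "
                f"[{axis[0]}, {axis[-1]}]; skipped", stacklevel=2,
            )
            continue
        if b.shape == "gaussian":
            y += b.height * np.exp(
                -4.0 * np.log(2.0) * (axis - b.center) ** 2 / b.fwhm ** 2
            )
        else:  # lorentzian
            hw = b.fwhm / 2.0
            y += b.height * hw ** 2 / ((axis - b.center) ** 2 + hw ** 2)
    return Spectrum(axis=axis, intensities=y, label=label)


@dataclass
class SceneTruth:
    """Everything needed to render a cube and to grade recovery against it."""

    axis: np.ndarray
    pure: dict[str, Spectrum]            # species -> pure spectrum
    abundances: dict[str, np.ndarray]    # species -> (ny, nx) map, >= 0
    nx: int
    ny: int
    baseline_amplitude: float
    noise_sd: float
    shot_scale: float
    seed: int
    bead_masks: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = np.zeros((self.ny, self.nx))
        for name, m in self.abundances.items():
            if m.shape != (self.ny, self.nx):
                raise ValueError(f"abundance map {name!r} has wrong shape")
            if np.any(m < 0):
                raise ValueError(f"abundance map {name!r} has negatives")
            total += m
        if np.any(total <= 0):
            raise ValueError("some pixel has no species present")

    @property
    def species(self) -> list[str]:
        return list(self.pure.keys())

    def to_json(self, path) -> None:
        payload = {
            "nx": self.nx, "ny": self.ny, "seed": self.seed,
            "baseline_amplitude": self.baseline_amplitude,
            "noise_sd": self.noise_sd, "shot_scale": self.shot_scale,
            "axis": self.axis.tolist(),
            "pure": {k: s.intensities.tolist() for k, s in self.pure.items()},
            "abundances": {k: m.tolist() for k, m in self.abundances.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)
            fh.write("\n")


def _disk_profile(nx: int, ny: int, cx: float, cy: float, r: float) -> np.ndarray:
    """Hemispherical bead profile: thickness of a sphere of radius r seen
    from above, peaking at the center."""
    yy, xx = np.mgrid[0:ny, 0:nx]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    return np.sqrt(np.clip(1.0 - d2 / r ** 2, 0.0, None))


def _shell_profile(nx: int, ny: int, cx: float, cy: float, r: float,
                   inner: float = 0.55, overhang: float = 1.12) -> np.ndarray:
    """Projected thickness of the outer shell of a coated sphere,
    normalized to peak 1: where a diffusion-limited coating sits.

    The coating adds to the bead radius, so the shell's footprint extends
    ``overhang`` times the bare-bead radius — past the bead outline.  That
    small protruding rim is structurally important: it gives the coating
    pixels where the bead itself contributes nothing, which anchors the
    factorization (otherwise coat and bead are only jointly identifiable).
    """
    yy, xx = np.mgrid[0:ny, 0:nx]
    rr = overhang * r
    d2 = ((xx - cx) ** 2 + (yy - cy) ** 2) / rr ** 2
    outer = np.sqrt(np.clip(1.0 - d2, 0.0, None))
    core = np.sqrt(np.clip(inner ** 2 - d2, 0.0, None))
    shell = outer - core
    peak = shell.max()
    return shell / peak if peak > 0 else shell


def _smooth_field(nx: int, ny: int, rng, lo: float = 0.3,
                  hi: float = 1.0) -> np.ndarray:
    """Smooth positive random field in [lo, hi] (coverage variation)."""
    from scipy.ndimage import gaussian_filter

    raw = gaussian_filter(rng.normal(size=(ny, nx)),
                          sigma=max(2.0, min(nx, ny) / 10.0))
    span = raw.max() - raw.min()
    if span == 0:
        return np.full((ny, nx), hi)
    return lo + (hi - lo) * (raw - raw.min()) / span


def default_scene(nx: int = 32, ny: int = 32, seed: int = 0, *,
                  noise_sd: float = 0.05, shot_scale: float = 0.01,
                  baseline_amplitude: float = 5.0,
                  axis=None) -> SceneTruth:
    """Build the default 4-species scene (resin beads on glass, enzyme in
    half of the beads, wash residue in the other half).

    Deterministic per seed.  ``noise_sd`` defaults to 1/20 of the unit peak
    height (signal-to-noise around 20); ``baseline_amplitude`` is the scale
    of the smooth per-pixel background relative to that same unit peak and
    defaults high enough that unpreprocessed cubes are dominated by it.
    """
    if nx < 16 or ny < 16:
        raise ValueError("grid must be at least 16 x 16")
    axis = DEFAULT_AXIS if axis is None else np.asarray(axis, dtype=float)
    rng = np.random.default_rng(seed)

    pure = {
        name: make_pure_spectrum([BandSpec(*b) for b in bands], axis, label=name)
        for name, bands in SPECIES_BANDS.items()
    }

    # place non-overlapping beads by rejection sampling
    n_beads = max(4, (nx * ny) // 250)
    r_base = min(nx, ny) / 6.5
    beads: list[tuple[float, float, float]] = []
    tries = 0
    while len(beads) < n_beads and tries < 400:
        tries += 1
        r = r_base * rng.uniform(0.75, 1.15)
        cx = rng.uniform(r * 0.6, nx - 1 - r * 0.6)
        cy = rng.uniform(r * 0.6, ny - 1 - r * 0.6)
        if all((cx - x) ** 2 + (cy - y) ** 2 > (0.95 * (r + rr)) ** 2
               for x, y, rr in beads):
            beads.append((cx, cy, r))

    profiles = [_disk_profile(nx, ny, cx, cy, r) for cx, cy, r in beads]
    shells = [_shell_profile(nx, ny, cx, cy, r) for cx, cy, r in beads]
    bead_masks = [p > 0 for p in profiles]
    resin = np.clip(sum(profiles), 0.0, None)
    support = resin > 0

    # Enzyme binds to alternate beads only; wash residue stays in the
    # remaining beads.  Binding is diffusion-limited, so both concentrate
    # in an outer shell of each bead and are further modulated by a smooth
    # random coverage field.  The shell weighting matters structurally: it
    # decorrelates the enzyme and wash maps from the bead-thickness resin
    # map, so the scene has as many independent abundance patterns as
    # species — without it the mixture would collapse to fewer effective
    # components than species.
    loads = rng.permutation([1.0 if i % 2 == 0 else 0.0
                             for i in range(len(beads))])
    field_e = _smooth_field(nx, ny, rng, lo=0.2)
    field_w = _smooth_field(nx, ny, rng, lo=0.2)
    enzyme = np.zeros((ny, nx))
    wash = np.zeros((ny, nx))
    for shell, load in zip(shells, loads):
        enzyme += load * 1.3 * shell * field_e
        wash += (1.0 - load) * 0.9 * shell * field_w

    glass = np.where(support, 0.0, 1.0) * rng.uniform(0.9, 1.0)

    return SceneTruth(
        axis=axis, pure=pure,
        abundances={"enzyme": enzyme, "resin": resin,
                    "glass": glass, "wash": wash},
        nx=nx, ny=ny,
        baseline_amplitude=baseline_amplitude,
        noise_sd=noise_sd, shot_scale=shot_scale, seed=seed,
        bead_masks=bead_masks,
    )


def render_cube(truth: SceneTruth) -> HyperspectralCube:
    """Render the forward model: mixing + smooth baseline + noise."""
    rng = np.random.default_rng(truth.seed + 1_000_003)
    n_pix = truth.nx * truth.ny
    n_wn = truth.axis.size
    clean = np.zeros((n_pix, n_wn))
    for name, m in truth.abundances.items():
        clean += m.reshape(-1, 1) * truth.pure[name].intensities[None, :]

    signal = clean.copy()
    if truth.baseline_amplitude > 0:
        # per-pixel smooth background: decreasing quadratic with jittered
        # coefficients, always positive (fluorescence-like)
        t = (truth.axis - truth.axis[0]) / (truth.axis[-1] - truth.axis[0])
        c0 = truth.baseline_amplitude * rng.uniform(0.8, 1.2, size=(n_pix, 1))
        c1 = -0.5 * truth.baseline_amplitude * rng.uniform(0.6, 1.0, size=(n_pix, 1))
        c2 = 0.25 * truth.baseline_amplitude * rng.uniform(0.2, 0.8, size=(n_pix, 1))
        signal = signal + c0 + c1 * t[None, :] + c2 * t[None, :] ** 2

    if truth.noise_sd > 0 or truth.shot_scale > 0:
        sd = truth.noise_sd + truth.shot_scale * np.sqrt(np.clip(signal, 0, None))
        signal = signal + rng.normal(0.0, 1.0, size=signal.shape) * sd

    return HyperspectralCube(
        nx=truth.nx, ny=truth.ny, axis=truth.axis.copy(),
        intensities=signal, excitation_nm=785.0,
    )


def reference_spectra(truth: SceneTruth) -> dict[str, Spectrum]:
    """Pure spectra of the scene, usable as the reference library."""
    return {
        name: Spectrum(truth.axis.copy(), s.intensities.copy(), label=name)
        for name, s in truth.pure.items()
    }
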