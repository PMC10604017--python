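import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_cube():
    """2x2 grid, 3 wavenumbers, known values."""
    from ramanmf import HyperspectralCube

    intens = np.arange(12, dtype=float).reshape(4, 3)
    return HyperspectralCube(nx=2, ny=2, axis=[100.0, 200.0, 300.0],
                             intensities=intens)


@pytest.fixture(scope="session")
def scene_truth():
    """Default 32x32 synthetic scene, seed 0."""
    from ramanmf import default_scene

    return default_scene(32, 32, seed=0)


@pytest.fixture(scope="session")
def scene_cube(scene_truth):
    from ramanmf import render_cube

    return render_cube(scene_truth)


@pytest.fixture(scope="session")
def scene_library(scene_truth):
    from ramanmf import ReferenceLibrary, reference_spectra

    return ReferenceLibrary(list(reference_spectra(scene_truth).values()))


@pytest.fixture(scope="session")
def published_grid():
    from ramanmf import published_similarity_grid

    return published_similarity_grid()


@pytest.fixture(scope="session")
def fitted_unmixer(scene_cube, scene_library):
    """One full end-to-end fit on the default scene, shared across tests."""
    from ramanmf import RamanUnmixer

    return RamanUnmixer(library=scene_library, k_max=10, seed=0).fit(
        scene_cube.intensities
    )


def write_long_map(path, nx, ny, axis, values=None, delimiter="\t",
                   header=True, drop_pixel=None, shuffle_rows=False,
                   seed=0):
    """Write a long-format map file for tests; returns expected intensities
    in canonical row-major order."""
    rng = np.random.default_rng(seed)
    if values is None:
        values = rng.random((ny * nx, len(axis)))
    lines = []
    for iy in range(ny):
        for ix in range(nx):
            if drop_pixel == (ix, iy):
                continue
            for iw, w in enumerate(axis):
                lines.append(
                    delimiter.join(
                        [str(float(ix)), str(float(iy)), str(float(w)),
                         repr(float(values[iy * nx + ix, iw]))]
                    )
                )
    if shuffle_rows:
        rng.shuffle(lines)
    text = ""
    if header:
        text = delimiter.join(["X", "Y", "Wavenumber", "Intensity"]) + "\n"
    text += "\n".join(lines) + "\n"
    path.write_text(text)
    return np.asarray(values)
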