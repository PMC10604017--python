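"""Text-dialect readers and writers for Raman mapping data.

Hyperspectral maps arrive as long-format delimited text (one line per
(x, y, wavenumber) triple), the dialect exported by mapping Raman
spectrometers.  Reference spectra are two-column text files.  Everything is
normalized on read to one canonical in-memory layout: row-major pixel order
(x fastest, origin top-left) and a strictly ascending wavenumber axis, so
that reshaping an NMF concentration column into an image is unambiguous.
"""

from __future__ import annotations

import csv
import io as _stdio
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class MapStructureError(ValueError):
    """The long-format file does not describe a complete rectangular grid."""


class AxisMismatchError(ValueError):
    """Two spectra that must share a wavenumber axis do not."""


class SpectrumParseError(ValueError):
    """A reference-spectrum file contains a malformed cell or too few rows."""


class DegenerateSpectrumError(ValueError):
    """A spectrum is constant or zero where a non-trivial one is required."""


@dataclass
class Spectrum:
    """One wavenumber axis plus an intensity vector.

    Parameters
    ----------
    axis : ndarray
        Wavenumbers in cm^-1, strictly increasing.
    intensities : ndarray
        Intensities in arbitrary counts, same length as ``axis``.
    label : str
        Species name, or empty for anonymous spectra.
    """

    axis: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.axis.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("axis and intensities must be 1-D")
        if self.axis.size != self.intensities.size:
            raise ValueError(
                f"axis ({self.axis.size}) and intensities "
                f"({self.intensities.size}) differ in length"
            )
        if self.axis.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.axis) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")

    def __len__(self) -> int:
        return self.axis.size


@dataclass
class HyperspectralCube:
    """A gridded set of spectra: the experimental data matrix A.

    ``intensities`` has one row per pixel in row-major order (x fastest,
    origin top-left) and one column per wavenumber.
    """

    nx: int
    ny: int
    axis: np.ndarray
    intensities: np.ndarray
    step_x: float = 1.0
    step_y: float = 1.0
    excitation_nm: float | None = None

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.intensities.shape != (self.nx * self.ny, self.axis.size):
            raise ValueError(
                f"intensities shape {self.intensities.shape} does not match "
                f"{self.nx}x{self.ny} grid with {self.axis.size} wavenumbers"
            )
        if not np.all(np.diff(self.axis) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    def pixel_index(self, ix: int, iy: int) -> int:
        """Row index of pixel (ix, iy); x fastest, origin top-left."""
        if not (0 <= ix < self.nx and 0 <= iy < self.ny):
            raise IndexError(f"pixel ({ix}, {iy}) outside {self.nx}x{self.ny} grid")
        return iy * self.nx + ix

    def pixel_coords(self, row: int) -> tuple[int, int]:
        """Inverse of :meth:`pixel_index`."""
        if not 0 <= row < self.n_pixels:
            raise IndexError(f"row {row} outside 0..{self.n_pixels - 1}")
        return row % self.nx, row // self.nx

    def spectrum_at(self, ix: int, iy: int) -> Spectrum:
        return Spectrum(self.axis, self.intensities[self.pixel_index(ix, iy)])


@dataclass
class ReferenceLibrary:
    """Labeled reference spectra on one common wavenumber axis."""

    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("a reference library needs at least one spectrum")
        labels = [s.label for s in self.spectra]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate labels in library: {labels}")
        axis = self.spectra[0].axis
        for s in self.spectra[1:]:
            if s.axis.size != axis.size or not np.allclose(s.axis, axis):
                raise AxisMismatchError(
                    f"reference {s.label!r} is not on the common axis"
                )

    @property
    def axis(self) -> np.ndarray:
        return self.spectra[0].axis

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.spectra]

    def __len__(self) -> int:
        return len(self.spectra)

    def __getitem__(self, label: str) -> Spectrum:
        for s in self.spectra:
            if s.label == label:
                return s
        raise KeyError(label)

    def resampled_to(self, axis: np.ndarray) -> "ReferenceLibrary":
        """Resample every reference onto ``axis`` (restricted to overlap).

        The target axis is clipped to each spectrum's support before
        interpolation, per the convention that the cube axis wins and
        references follow it on the overlapping range.
        """
        axis = np.asarray(axis, dtype=float)
        lo = max(float(s.axis[0]) for s in self.spectra)
        hi = min(float(s.axis[-1]) for s in self.spectra)
        common = axis[(axis >= lo) & (axis <= hi)]
        if common.size < 2:
            raise AxisMismatchError(
                "cube axis and reference axes share fewer than 2 wavenumbers"
            )
        return ReferenceLibrary(
            [resample_to_axis(s, common) for s in self.spectra]
        )


# ---------------------------------------------------------------------------
# parsing helpers

_DIALECT_DEFAULT = {"x": 0, "y": 1, "wavenumber": 2, "intensity": 3}


def _sniff_and_load(path, n_columns_min: int) -> pd.DataFrame:
    """Load a delimited numeric text file, auto-detecting tab/comma/space
    and an optional single header line."""
    with open(path, "r", encoding="utf-8") as fh:
        sample = fh.read(4096)
        if not sample.strip():
            raise SpectrumParseError(f"{path}: empty file")
    try:
        delim = csv.Sniffer().sniff(sample, delimiters=",\t; ").delimiter
    except csv.Error:
        delim = None  # fall back to whitespace
    kwargs = dict(header=None, comment="#", float_precision="round_trip")
    if delim in (None, " "):
        kwargs["sep"] = r"\s+"  # python engine; low_memory unsupported
    else:
        kwargs["sep"] = delim
        kwargs["low_memory"] = False
    df = pd.read_csv(path, **kwargs)
    # optional header: first row non-numeric
    first = df.iloc[0]
    if any(isinstance(v, str) for v in first):
        try:
            first.astype(float)
        except (ValueError, TypeError):
            df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] < n_columns_min:
        raise SpectrumParseError(
            f"{path}: expected at least {n_columns_min} columns, "
            f"found {df.shape[1]}"
        )
    return df


def read_map_text(path, dialect: dict | None = None) -> HyperspectralCube:
    """Read a long-format hyperspectral map into a cube.

    Parameters
    ----------
    path : path-like
        Delimited text with columns X(um), Y(um), Wavenumber(cm^-1),
        Intensity; header optional; tab/comma/whitespace auto-detected.
    dialect : dict, optional
        Column mapping, keys ``x, y, wavenumber, intensity`` to 0-based
        column indices.  Defaults to the 4-column export order.

    Raises
    ------
    MapStructureError
        If any (x, y) grid position is missing, naming the coordinate.
    AxisMismatchError
        If pixels disagree on the wavenumber list.
    """
    cols = dict(_DIALECT_DEFAULT, **(dialect or {}))
    df = _sniff_and_load(path, n_columns_min=max(cols.values()) + 1)
    data = pd.DataFrame(
        {
            # astype(float) parses via Python's round-trip-exact float()
            "x": df.iloc[:, cols["x"]].astype(float),
            "y": df.iloc[:, cols["y"]].astype(float),
            "w": df.iloc[:, cols["wavenumber"]].astype(float),
            "i": df.iloc[:, cols["intensity"]].astype(float),
        }
    )
    xs = np.sort(data["x"].unique())
    ys = np.sort(data["y"].unique())
    nx, ny = xs.size, ys.size

    # canonical ascending axis, taken from the first pixel encountered
    first_key = (data["y"].iloc[0], data["x"].iloc[0])
    axis = np.sort(
        data.loc[(data["y"] == first_key[0]) & (data["x"] == first_key[1]), "w"]
        .to_numpy()
    )
    if axis.size < 1 or np.unique(axis).size != axis.size:
        raise AxisMismatchError(f"{path}: duplicate wavenumbers within a pixel")

    ix = np.searchsorted(xs, data["x"].to_numpy())
    iy = np.searchsorted(ys, data["y"].to_numpy())
    iw = np.searchsorted(axis, data["w"].to_numpy())
    if np.any(iw >= axis.size) or np.any(axis[np.clip(iw, 0, axis.size - 1)] != data["w"].to_numpy()):
        bad = data["w"].to_numpy()[axis[np.clip(iw, 0, axis.size - 1)] != data["w"].to_numpy()][0]
        raise AxisMismatchError(
            f"{path}: wavenumber {bad} not shared by all pixels"
        )

    intens = np.full((ny * nx, axis.size), np.nan)
    intens[(iy * nx + ix), iw] = data["i"].to_numpy()
    if np.isnan(intens).any():
        row = int(np.argwhere(np.isnan(intens).any(axis=1))[0, 0])
        raise MapStructureError(
            f"{path}: incomplete grid — missing data at "
            f"(x={xs[row % nx]}, y={ys[row // nx]})"
        )

    step_x = float(np.median(np.diff(xs))) if nx > 1 else 1.0
    step_y = float(np.median(np.diff(ys))) if ny > 1 else 1.0
    return HyperspectralCube(
        nx=nx, ny=ny, axis=axis, intensities=intens,
        step_x=step_x, step_y=step_y,
    )


def write_map_text(cube: HyperspectralCube, path, delimiter: str = "\t") -> None:
    """Write a cube back to long-format text (round-trip inverse of
    :func:`read_map_text` for well-formed files)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(["X", "Y", "Wavenumber", "Intensity"]) + "\n")
        for iy in range(cube.ny):
            for ix in range(cube.nx):
                row = cube.intensities[cube.pixel_index(ix, iy)]
                x = ix * cube.step_x
                y = iy * cube.step_y
                for w, v in zip(cube.axis, row):
                    fh.write(
                        delimiter.join(
                            [repr(float(x)), repr(float(y)), repr(float(w)),
                             repr(float(v))]
                        )
                        + "\n"
                    )


def read_reference(path, label: str = "") -> Spectrum:
    """Read a two-column (wavenumber, intensity) reference spectrum.

    A descending axis is reordered ascending; duplicate wavenumbers are
    rejected; a non-numeric cell raises :class:`SpectrumParseError` with the
    offending line number.
    """
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").replace(";", " ").split()]
            if lineno == 1 and parts:
                # allow one header line, recognized by a non-numeric first cell
                try:
                    float(parts[0])
                except ValueError:
                    continue
            if len(parts) < 2:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected 2 columns"
                )
            try:
                w, v = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-numeric cell ({exc})"
                ) from None
            rows.append((w, v))
    if len(rows) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data rows")
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0])
    arr = arr[order]
    if np.any(np.diff(arr[:, 0]) == 0):
        dup = arr[:-1, 0][np.diff(arr[:, 0]) == 0][0]
        raise SpectrumParseError(f"{path}: duplicate wavenumber {dup}")
    return Spectrum(axis=arr[:, 0], intensities=arr[:, 1], label=label)


def read_library(paths_by_label: dict, target_axis=None) -> ReferenceLibrary:
    """Read several reference files and put them on one axis.

    If ``target_axis`` is given the references are resampled onto it
    (restricted to the overlapping range); otherwise all files must already
    share an axis.
    """
    spectra = [read_reference(p, label=lab) for lab, p in paths_by_label.items()]
    lib_axis_ok = all(
        s.axis.size == spectra[0].axis.size and np.allclose(s.axis, spectra[0].axis)
        for s in spectra
    )
    if target_axis is None and not lib_axis_ok:
        raise AxisMismatchError(
            "reference files are on different axes; pass target_axis"
        )
    lib = ReferenceLibrary(spectra) if lib_axis_ok else None
    if target_axis is not None:
        if lib is None:
            # build pairwise-resampled library on the target
            tmp = ReferenceLibrary.__new__(ReferenceLibrary)
            tmp.spectra = spectra
            return ReferenceLibrary.resampled_to(tmp, target_axis)
        return lib.resampled_to(target_axis)
    return lib


def resample_to_axis(s: Spectrum, axis) -> Spectrum:
    """Linearly interpolate a spectrum onto a target axis.

    The target must lie inside the spectrum's support; extrapolation raises.
    """
    axis = np.atleast_1d(np.asarray(axis, dtype=float))
    if axis.size and (axis[0] < s.axis[0] or axis[-1] > s.axis[-1]):
        raise ValueError(
            f"target axis [{axis[0]}, {axis[-1]}] extends beyond spectrum "
            f"support [{s.axis[0]}, {s.axis[-1]}]"
        )
    vals = np.interp(axis, s.axis, s.intensities)
    if axis.size == 1:
        # Spectrum requires >= 2 points; single-point queries return the value
        return SpectrumPoint(axis=axis, intensities=vals, label=s.label)
    return Spectrum(axis=axis, intensities=vals, label=s.label)


@dataclass
class SpectrumPoint:
    """Degenerate single-point result of resampling onto one wavenumber."""

    axis: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __len__(self) -> int:
        return 1
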