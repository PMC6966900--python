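"""Core data model and I/O for Raman spectra, hyperspectral maps, and reference sets.

A map scan is stored spatially unfolded: the cube is an ``(x*y, L)`` matrix of
per-pixel spectra over a shared wavenumber axis (Raman shift, cm^-1), together
with a per-pixel foreground mask.  Reference sets hold the pure-component
spectra (the endmembers) used for spectral unmixing, one row per component on
the same axis.

Band lookup is always by wavenumber, never by index: ``axis.index_of(1089.0)``
returns the nearest axis point, with ties resolved toward the lower
wavenumber.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "SpectralMap",
    "ReferenceSet",
    "read_spectrum_table",
    "write_map_container",
    "read_map_container",
    "read_reference_csv",
    "write_reference_csv",
    "read_labeled_spectra_csv",
    "write_labeled_spectra_csv",
    "resample_to_axis",
]

CONTAINER_FORMAT_VERSION = 1

DEFAULT_RANGE = (580.0, 3062.0)


class AxisError(ValueError):
    """Raised when a wavenumber axis violates its invariants."""


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing Raman-shift axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise AxisError("axis must be a 1-D array with at least one point")
        if not np.all(np.isfinite(v)):
            raise AxisError("axis contains non-finite values")
        d = np.diff(v)
        if np.any(d <= 0):
            bad = int(np.argmax(d <= 0))
            raise AxisError(
                f"axis not strictly increasing at position {bad}: "
                f"{v[bad]:g} followed by {v[bad + 1]:g} cm^-1"
            )
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with ndarray field
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))

    def index_of(self, wavenumber: float) -> int:
        """Nearest axis index; ties go to the lower wavenumber."""
        v = self.values
        if wavenumber < v[0] or wavenumber > v[-1]:
            raise AxisError(
                f"wavenumber {wavenumber:g} cm^-1 outside axis range "
                f"[{v[0]:g}, {v[-1]:g}]"
            )
        d = np.abs(v - wavenumber)
        # argmin returns the first (lower-wavenumber) index on exact ties
        return int(np.argmin(d))

    def close_to(self, other: "WavenumberAxis", tol: float = 1e-9) -> bool:
        return len(self) == len(other) and bool(
            np.allclose(self.values, other.values, atol=tol, rtol=0.0)
        )

    @classmethod
    def linspace(
        cls, start: float = DEFAULT_RANGE[0], stop: float = DEFAULT_RANGE[1], num: int = 1015
    ) -> "WavenumberAxis":
        return cls(np.linspace(start, stop, num))


@dataclass
class Spectrum:
    """A single Raman spectrum: intensities (arbitrary counts) on an axis."""

    axis: WavenumberAxis
    intensity: np.ndarray
    label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        y = np.asarray(self.intensity, dtype=float)
        if y.ndim != 1 or y.size != len(self.axis):
            raise ValueError(
                f"intensity length {y.size} does not match axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("intensity contains non-finite values")
        self.intensity = y

    def replace(self, intensity: np.ndarray, **meta_updates) -> "Spectrum":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(self.axis, intensity, label=self.label, meta=meta)


@dataclass
class SpectralMap:
    """Spatially unfolded hyperspectral map: ``cube[(row*width + col), band]``.

    Pixel order is row-major with origin at the top-left; ``width`` counts
    columns (x) and ``height`` rows (y).  ``mask`` is True for foreground
    (sample) pixels.
    """

    axis: WavenumberAxis
    width: int
    height: int
    cube: np.ndarray
    mask: np.ndarray | None = None
    spacing_um: float = 2.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cube = np.asarray(self.cube, dtype=float)
        n = self.width * self.height
        if cube.shape != (n, len(self.axis)):
            raise ValueError(
                f"cube shape {cube.shape} does not match "
                f"(width*height={n}, L={len(self.axis)})"
            )
        self.cube = cube
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        else:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != (n,):
                raise ValueError(f"mask length {m.size} != pixel count {n}")
            self.mask = m

    @property
    def n_pixels(self) -> int:
        return self.width * self.height

    def pixel(self, i: int) -> Spectrum:
        return Spectrum(self.axis, self.cube[i], meta={"pixel": i})

    def grid(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Fold a per-pixel vector back into a (height, width) image."""
        out = np.asarray(values, dtype=float).reshape(self.height, self.width).copy()
        if self.mask is not None:
            out[~self.mask.reshape(self.height, self.width)] = fill
        return out

    def replace(self, cube: np.ndarray | None = None, mask: np.ndarray | None = None,
                **meta_updates) -> "SpectralMap":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return SpectralMap(
            self.axis,
            self.width,
            self.height,
            self.cube if cube is None else cube,
            self.mask if mask is None else mask,
            self.spacing_um,
            meta,
        )


@dataclass
class ReferenceSet:
    """k pure-component spectra (rows) on a shared axis."""

    axis: WavenumberAxis
    names: list[str]
    spectra: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.spectra, dtype=float)
        if len(self.names) < 1:
            raise ValueError("reference set needs at least one component")
        if s.shape != (len(self.names), len(self.axis)):
            raise ValueError(
                f"spectra shape {s.shape} != (k={len(self.names)}, L={len(self.axis)})"
            )
        self.spectra = s
        self.names = list(self.names)

    @property
    def k(self) -> int:
        return len(self.names)

    def component(self, name: str) -> Spectrum:
        try:
            i = self.names.index(name)
        except ValueError:
            raise KeyError(f"no component named {name!r}; have {self.names}") from None
        return Spectrum(self.axis, self.spectra[i], label=name)

    def replace(self, spectra: np.ndarray) -> "ReferenceSet":
        return ReferenceSet(self.axis, self.names, spectra, dict(self.meta))


# ---------------------------------------------------------------------------
# Text table I/O


def _read_delimited(path: str | Path) -> pd.DataFrame:
    # sep=None lets pandas sniff comma vs tab vs whitespace
    try:
        return pd.read_csv(path, sep=None, engine="python")
    except pd.errors.ParserError as e:
        raise ValueError(f"ragged or malformed table {path}: {e}") from e


def _validated_axis_from(values: Sequence[float], origin: str) -> tuple[WavenumberAxis, np.ndarray]:
    v = np.asarray(values, dtype=float)
    uniq, counts = np.unique(v, return_counts=True)
    dup = uniq[counts > 1]
    if dup.size:
        raise AxisError(
            f"{origin}: duplicated wavenumber(s) {', '.join(f'{d:g}' for d in dup[:5])}"
        )
    order = np.argsort(v)
    return WavenumberAxis(v[order]), order


def read_spectrum_table(path: str | Path, dialect: str = "long") -> Spectrum | SpectralMap:
    """Read a delimited-text spectrum table.

    ``long`` dialect: columns ``wavenumber, intensity[, x, y]`` — one row per
    (band, pixel); with x/y columns a :class:`SpectralMap` is returned.
    ``wide`` dialect: header row of wavenumbers, then one intensity row per
    pixel; a single row yields a :class:`Spectrum`.
    """
    path = Path(path)
    df = _read_delimited(path)
    if dialect == "long":
        if df.shape[1] < 2:
            raise ValueError(f"{path}: long table needs >= 2 columns")
        cols = list(df.columns)
        wn = df[cols[0]].to_numpy(dtype=float)
        inten = df[cols[1]].to_numpy(dtype=float)
        if df.shape[1] >= 4:
            xs = df[cols[2]].to_numpy(dtype=int)
            ys = df[cols[3]].to_numpy(dtype=int)
            width, height = int(xs.max()) + 1, int(ys.max()) + 1
            uniq_wn = np.unique(wn)
            axis, _ = _validated_axis_from(uniq_wn, str(path))
            cube = np.full((width * height, len(axis)), np.nan)
            band_idx = np.searchsorted(axis.values, wn)
            pix_idx = ys * width + xs
            cube[pix_idx, band_idx] = inten
            if np.isnan(cube).any():
                raise ValueError(f"{path}: incomplete long map table (missing bands)")
            return SpectralMap(axis, width, height, cube)
        axis, order = _validated_axis_from(wn, str(path))
        return Spectrum(axis, inten[order], meta={"source": str(path)})
    if dialect == "wide":
        # pandas mangles duplicate header names, so parse the header row raw
        raw = pd.read_csv(path, sep=None, engine="python", header=None)
        try:
            wns = [float(c) for c in raw.iloc[0]]
        except (TypeError, ValueError) as e:
            raise ValueError(f"{path}: wide header must be numeric wavenumbers: {e}") from e
        axis, order = _validated_axis_from(wns, str(path))
        vals = raw.iloc[1:].to_numpy(dtype=float)[:, order]
        if vals.shape[0] == 1:
            return Spectrum(axis, vals[0], meta={"source": str(path)})
        return SpectralMap(axis, width=vals.shape[0], height=1, cube=vals,
                           meta={"source": str(path)})
    raise ValueError(f"unknown dialect {dialect!r}; use 'long' or 'wide'")


def read_reference_csv(path: str | Path) -> ReferenceSet:
    """Read a reference set: first column component name, wavenumber headers."""
    df = _read_delimited(path)
    names = df.iloc[:, 0].astype(str).tolist()
    wns = [float(c) for c in df.columns[1:]]
    axis, order = _validated_axis_from(wns, str(path))
    spectra = df.iloc[:, 1:].to_numpy(dtype=float)[:, order]
    return ReferenceSet(axis, names, spectra)


def write_reference_csv(refs: ReferenceSet, path: str | Path) -> None:
    df = pd.DataFrame(refs.spectra, columns=[f"{w:g}" for w in refs.axis.values])
    df.insert(0, "component", refs.names)
    df.to_csv(path, index=False)


def read_labeled_spectra_csv(path: str | Path) -> list[Spectrum]:
    """Read labeled spot-scan spectra: first column class label, wavenumber headers."""
    df = _read_delimited(path)
    wns = [float(c) for c in df.columns[1:]]
    axis, order = _validated_axis_from(wns, str(path))
    vals = df.iloc[:, 1:].to_numpy(dtype=float)[:, order]
    labels = df.iloc[:, 0].astype(str).tolist()
    return [Spectrum(axis, v, label=lab) for v, lab in zip(vals, labels)]


def write_labeled_spectra_csv(spectra: Sequence[Spectrum], path: str | Path) -> None:
    axis = spectra[0].axis
    df = pd.DataFrame(
        np.stack([s.intensity for s in spectra]),
        columns=[f"{w:g}" for w in axis.values],
    )
    df.insert(0, "label", [s.label for s in spectra])
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Binary map container (HDF5)


def write_map_container(smap: SpectralMap, path: str | Path) -> None:
    """Write a map to a single-file HDF5 container (axis/cube/mask + attrs)."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = CONTAINER_FORMAT_VERSION
        f.attrs["width"] = smap.width
        f.attrs["height"] = smap.height
        f.attrs["spacing_um"] = smap.spacing_um
        f.attrs["meta_json"] = json.dumps(smap.meta, default=str)
        f.create_dataset("axis", data=smap.axis.values)
        f.create_dataset("cube", data=smap.cube)
        f.create_dataset("mask", data=smap.mask)


def read_map_container(path: str | Path) -> SpectralMap:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("format_version", -1))
            if version != CONTAINER_FORMAT_VERSION:
                raise ValueError(
                    f"{path}: container format version {version} not supported "
                    f"(expected {CONTAINER_FORMAT_VERSION})"
                )
            axis = WavenumberAxis(f["axis"][()])
            return SpectralMap(
                axis=axis,
                width=int(f.attrs["width"]),
                height=int(f.attrs["height"]),
                cube=f["cube"][()],
                mask=f["mask"][()].astype(bool),
                spacing_um=float(f.attrs["spacing_um"]),
                meta=json.loads(f.attrs["meta_json"]),
            )
    except OSError as e:
        raise ValueError(f"{path}: not a readable map container (corrupt/truncated?): {e}") from e


# ---------------------------------------------------------------------------
# Resampling


def resample_to_axis(obj: Spectrum | ReferenceSet, axis: WavenumberAxis):
    """Linearly interpolate a spectrum or reference set onto a target axis.

    Out-of-range target bands are filled with the edge value and their count
    recorded under ``meta['extrapolated_bands']``.  Disjoint axes are an error.
    """
    src = obj.axis.values
    tgt = axis.values
    if tgt[-1] < src[0] or tgt[0] > src[-1]:
        raise AxisError(
            f"target axis [{tgt[0]:g}, {tgt[-1]:g}] disjoint from source "
            f"[{src[0]:g}, {src[-1]:g}]"
        )
    n_extrap = int(np.sum((tgt < src[0]) | (tgt > src[-1])))
    if isinstance(obj, Spectrum):
        y = np.interp(tgt, src, obj.intensity)
        meta = dict(obj.meta)
        meta["extrapolated_bands"] = n_extrap
        return Spectrum(axis, y, label=obj.label, meta=meta)
    if isinstance(obj, ReferenceSet):
        rows = np.stack([np.interp(tgt, src, row) for row in obj.spectra])
        meta = dict(obj.meta)
        meta["extrapolated_bands"] = n_extrap
        return ReferenceSet(axis, obj.names, rows, meta)
    raise TypeError(f"cannot resample object of type {type(obj).__name__}")
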