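"""Synthetic lignocellulose Raman data with known ground truth.

Real map scans of plant tissue are rarely redistributable, so this module
builds scenes from first principles: each pixel is a linear mixture of
pure-component reference spectra (cellulose, hemicellulose, lignin) on the
probability simplex, plus the nuisance signals that plague real tissue
Raman — a broad fluorescence background that rises with wavenumber, Gaussian
shot-like noise, and isolated cosmic-ray spikes.  The ground-truth abundance
map and cell-type layout are returned alongside the rendered cube, so
preprocessing and unmixing can be scored against truth.

Component peak positions follow standard lignocellulose band assignments:
1089 cm^-1 (C-O-C / C-C ring, polysaccharides), 1508 and 1620 cm^-1 (lignin
aromatic ring modes), 1739 cm^-1 (hemicellulose C=O stretch), and the
2800-3000 cm^-1 C-H stretch region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ReferenceSet, Spectrum, SpectralMap, WavenumberAxis

__all__ = [
    "ComponentModel",
    "NoiseSpec",
    "SyntheticScene",
    "default_axis",
    "default_components",
    "nuisance_fluorescence_shape",
    "render_scene",
    "make_spot_dataset",
    "CELL_TYPE_ABUNDANCE",
    "TABLE_UNTREATED_COMPOSITION",
    "TABLE_TREATED_COMPOSITION",
    "DEFAULT_TREATMENT_EFFECT",
]

COMPONENT_NAMES = ("cellulose", "hemicellulose", "lignin")

# Dry-base wet-chemistry composition (%): cellulose, hemicellulose, lignin.
TABLE_UNTREATED_COMPOSITION = {"cellulose": 39.5, "hemicellulose": 33.2, "lignin": 4.5}
TABLE_TREATED_COMPOSITION = {"cellulose": 34.4, "hemicellulose": 15.6, "lignin": 3.4}

# Per-component retention after alkali treatment (treated/untreated content).
DEFAULT_TREATMENT_EFFECT = (0.87, 0.47, 0.75)

# Nominal abundance (cellulose, hemicellulose, lignin) per tissue region;
# background is embedding resin with no lignocellulose signal.
CELL_TYPE_ABUNDANCE: dict[str, tuple[float, float, float]] = {
    "epidermis": (0.25, 0.15, 0.60),
    "parenchyma": (0.35, 0.50, 0.15),
    "sclerenchyma": (0.45, 0.15, 0.40),
    "xylem": (0.55, 0.10, 0.35),
    "vascular bundle": (0.45, 0.30, 0.25),
}
BACKGROUND_LABEL = "background"


def default_axis(n: int = 1015) -> WavenumberAxis:
    """Default acquisition axis: 580-3062 cm^-1, ~2.45 cm^-1 steps."""
    return WavenumberAxis.linspace(580.0, 3062.0, n)


@dataclass
class ComponentModel:
    """Parametric pure-component spectrum: Gaussian peaks over a smooth
    fluorescence background that increases with wavenumber."""

    name: str
    peaks: list[tuple[float, float, float]]  # (center cm^-1, width cm^-1, height)
    fluorescence: tuple[float, float] = (0.0, 2.0)  # (amplitude, curvature)

    def __post_init__(self) -> None:
        for c, w, h in self.peaks:
            if w <= 0:
                raise ValueError(f"{self.name}: peak width must be > 0 (got {w})")
            if h < 0:
                raise ValueError(f"{self.name}: peak height must be >= 0 (got {h})")

    def peak_signal(self, axis: WavenumberAxis) -> np.ndarray:
        v = axis.values
        lo, hi = v[0], v[-1]
        y = np.zeros_like(v)
        for c, w, h in self.peaks:
            if not (lo <= c <= hi):
                raise ValueError(
                    f"{self.name}: peak center {c} cm^-1 outside axis [{lo}, {hi}]"
                )
            y += h * np.exp(-0.5 * ((v - c) / w) ** 2)
        return y

    def baseline(self, axis: WavenumberAxis) -> np.ndarray:
        amp, curvature = self.fluorescence
        v = axis.values
        u = (v - v[0]) / (v[-1] - v[0])
        return amp * u**curvature

    def spectrum(self, axis: WavenumberAxis) -> np.ndarray:
        return self.peak_signal(axis) + self.baseline(axis)


def default_components(axis: WavenumberAxis | None = None):
    """Three-component lignocellulose model and its reference set.

    Cellulose: sharp peaks (1089 cm^-1 among them) with negligible
    fluorescence.  Lignin: aromatic-ring peaks at 1508/1620 cm^-1 over a
    moderate background.  Hemicellulose: weak 1089/1739 cm^-1 features nearly
    buried under a strong fluorescence background.

    Returns ``(refs, models)`` where each reference row is max-normalized to
    [0, 1].
    """
    if axis is None:
        axis = default_axis()
    models = [
        ComponentModel(
            "cellulose",
            peaks=[
                (1089.0, 9.0, 1.00),
                (1121.0, 9.0, 0.70),
                (1376.0, 11.0, 0.45),
                (2895.0, 18.0, 0.90),
            ],
            fluorescence=(0.05, 2.0),
        ),
        ComponentModel(
            "hemicellulose",
            peaks=[
                (1089.0, 13.0, 0.12),
                (1739.0, 13.0, 0.15),
                (2930.0, 22.0, 0.20),
            ],
            fluorescence=(1.00, 1.8),
        ),
        ComponentModel(
            "lignin",
            peaks=[
                (1508.0, 12.0, 0.50),
                (1620.0, 11.0, 1.00),
                (1660.0, 12.0, 0.35),
                (2940.0, 20.0, 0.50),
            ],
            fluorescence=(0.45, 2.0),
        ),
    ]
    rows = np.stack([m.spectrum(axis) for m in models])
    rows = rows / rows.max(axis=1, keepdims=True)
    refs = ReferenceSet(axis, [m.name for m in models], rows, meta={"synthetic": True})
    return refs, models


def nuisance_fluorescence_shape(
    axis: WavenumberAxis, center: float = 0.45, width: float = 0.22
) -> np.ndarray:
    """Unit-max smooth background rising with wavenumber (tissue chromophores).

    A logistic ramp over the normalized axis coordinate; ``center`` and
    ``width`` set where and how fast the background climbs.
    """
    v = axis.values
    u = (v - v[0]) / (v[-1] - v[0])
    y = 1.0 / (1.0 + np.exp(-(u - center) / width))
    return y / y.max()


@dataclass
class NoiseSpec:
    """Nuisance amplitudes for scene rendering (units of the normalized
    reference scale, whose peak maxima are 1)."""

    gaussian_sd: float = 0.01
    spike_rate: float = 0.02  # expected cosmic-ray events per pixel
    spike_magnitude: float = 10.0  # multiples of local signal
    baseline_scale: float = 1.0  # per-pixel fluorescence amplitude

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ValueError(f"gaussian_sd must be >= 0 (got {self.gaussian_sd})")
        if self.spike_rate < 0 or self.spike_magnitude < 0 or self.baseline_scale < 0:
            raise ValueError("noise amplitudes must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass
class SyntheticScene:
    """Rendered map plus the ground truth used to render it."""

    map: SpectralMap
    truth_abundance: np.ndarray  # (n_pixels, k); background rows are 0
    truth_labels: np.ndarray  # (n_pixels,) cell-type tags
    references: ReferenceSet
    noise_spec: NoiseSpec
    seed: int

    def __post_init__(self) -> None:
        fg = self.truth_labels != BACKGROUND_LABEL
        rows = self.truth_abundance[fg]
        if rows.size and (np.any(rows < -1e-12) or
                          np.any(np.abs(rows.sum(axis=1) - 1.0) > 1e-9)):
            raise ValueError("foreground truth rows must lie on the simplex")


def _tile_layout(shape, rng):
    """Checkerboard of tissue tiles: pure-component tiles, mixed cell-type
    tiles, and resin background tiles."""
    width, height = shape
    cycle = [
        "cellulose",
        BACKGROUND_LABEL,
        "hemicellulose",
        "lignin",
        "epidermis",
        BACKGROUND_LABEL,
        "parenchyma",
        "sclerenchyma",
        "xylem",
        "vascular bundle",
    ]
    tile = max(4, min(width, height) // 5)
    labels = np.empty((height, width), dtype=object)
    idx = 0
    for r0 in range(0, height, tile):
        for c0 in range(0, width, tile):
            labels[r0:r0 + tile, c0:c0 + tile] = cycle[idx % len(cycle)]
            idx += 1
    return labels.reshape(-1)


def _cells_layout(shape, rng):
    """Idealized tissue transection: resin border, lignin-rich epidermis ring,
    parenchyma ground tissue, and round vascular bundles with xylem cores."""
    width, height = shape
    labels = np.full((height, width), "parenchyma", dtype=object)
    border = max(1, min(width, height) // 10)
    labels[:border, :] = BACKGROUND_LABEL
    labels[-border:, :] = BACKGROUND_LABEL
    labels[:, :border] = BACKGROUND_LABEL
    labels[:, -border:] = BACKGROUND_LABEL
    epi = border + max(1, min(width, height) // 16)
    ring = np.zeros((height, width), bool)
    ring[border:epi, border:-border] = True
    ring[-epi:-border, border:-border] = True
    ring[border:-border, border:epi] = True
    ring[border:-border, -epi:-border] = True
    labels[ring] = "epidermis"
    yy, xx = np.mgrid[0:height, 0:width]
    n_bundles = max(1, (width * height) // 600)
    for _ in range(n_bundles):
        cy = rng.integers(epi + 2, max(epi + 3, height - epi - 2))
        cx = rng.integers(epi + 2, max(epi + 3, width - epi - 2))
        r = rng.integers(2, max(3, min(width, height) // 8))
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        inside = (d2 <= r**2) & (labels == "parenchyma")
        labels[inside & (d2 > (0.6 * r) ** 2)] = "vascular bundle"
        labels[inside & (d2 <= (0.6 * r) ** 2) & (d2 > (0.3 * r) ** 2)] = "sclerenchyma"
        labels[inside & (d2 <= (0.3 * r) ** 2)] = "xylem"
    return labels.reshape(-1)


def _abundance_for_labels(labels: np.ndarray, k: int, names, rng,
                          jitter_conc: float = 300.0) -> np.ndarray:
    n = labels.size
    A = np.zeros((n, k))
    for lab in np.unique(labels):
        sel = labels == lab
        if lab == BACKGROUND_LABEL:
            continue
        if lab in names:  # pure-component tile
            A[sel, list(names).index(lab)] = 1.0
            continue
        prior = np.asarray(CELL_TYPE_ABUNDANCE[lab])
        A[sel] = rng.dirichlet(prior * jitter_conc, size=int(sel.sum()))
    return A


def render_scene(
    layout: str = "cells",
    shape: tuple[int, int] = (40, 50),
    components=None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    spacing_um: float = 2.5,
    effect: tuple[float, float, float] | None = None,
) -> SyntheticScene:
    """Render a hyperspectral scene ``cube = abundance @ references + nuisance``.

    Parameters
    ----------
    layout
        ``tiles`` (block pattern incl. pure-component tiles), ``cells``
        (idealized tissue transection), or ``random-simplex`` (Dirichlet
        abundances, all foreground).
    shape
        (width, height) in pixels.
    noise
        Nuisance amplitudes; ``NoiseSpec.zero()`` gives an exact noiseless
        forward model.
    effect
        Optional per-component retention factors emulating a chemical
        treatment: abundance rows are reweighted by these factors and
        renormalized (e.g. ``DEFAULT_TREATMENT_EFFECT`` for the
        alkali-treated state).
    """
    rng = np.random.default_rng(seed)
    if components is None:
        refs, _ = default_components()
    else:
        refs = components
    if noise is None:
        noise = NoiseSpec()
    width, height = shape
    if width < 1 or height < 1:
        raise ValueError(f"shape must be >= 1x1 (got {shape})")
    n = width * height
    if layout == "tiles":
        labels = _tile_layout(shape, rng)
    elif layout == "cells":
        labels = _cells_layout(shape, rng)
    elif layout == "random-simplex":
        labels = np.full(n, "random mixture", dtype=object)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if layout == "random-simplex":
        A = rng.dirichlet(np.ones(refs.k), size=n)
    else:
        A = _abundance_for_labels(labels, refs.k, refs.names, rng)
    fg = labels != BACKGROUND_LABEL
    if effect is not None:
        if len(effect) != refs.k or any(e <= 0 for e in effect):
            raise ValueError(f"effect must be {refs.k} positive factors (got {effect})")
        A = A * np.asarray(effect)
        rowsum = A.sum(axis=1, keepdims=True)
        A = np.divide(A, rowsum, out=np.zeros_like(A), where=rowsum > 0)

    cube = A @ refs.spectra
    # resin background: flat, weak
    cube[~fg] = 0.02

    # per-pixel tissue fluorescence, amplitude randomized +/-20%
    if noise.baseline_scale > 0:
        shape_fn = nuisance_fluorescence_shape(refs.axis)
        amp = noise.baseline_scale * rng.uniform(0.8, 1.2, size=n)
        amp[~fg] = 0.0
        cube = cube + amp[:, None] * shape_fn[None, :]

    if noise.gaussian_sd > 0:
        cube = cube + rng.normal(0.0, noise.gaussian_sd, size=cube.shape)

    if noise.spike_rate > 0:
        L = len(refs.axis)
        n_spikes = rng.poisson(noise.spike_rate, size=n)
        for i in np.nonzero(n_spikes)[0]:
            for _ in range(n_spikes[i]):
                j = rng.integers(0, L - 1)
                w = rng.integers(1, 3)  # 1-2 bands
                local = max(abs(float(cube[i, j])), 0.05)
                mag = rng.uniform(0.5, 2.0) * noise.spike_magnitude * local
                cube[i, j:j + w] += mag

    smap = SpectralMap(
        refs.axis, width, height, cube, mask=fg.astype(bool),
        spacing_um=spacing_um,
        meta={"synthetic": True, "layout": layout, "seed": int(seed)},
    )
    return SyntheticScene(smap, A, np.asarray(labels), refs, noise, int(seed))


def make_spot_dataset(
    n_untreated: int = 235,
    n_treated: int = 339,
    effect: tuple[float, float, float] = DEFAULT_TREATMENT_EFFECT,
    seed: int = 0,
    noise: NoiseSpec | None = None,
    composition_jitter: float = 0.045,
    fluorescence_sigma: float = 0.5,
) -> list[Spectrum]:
    """Labeled spot-scan spectra for untreated vs alkali-treated tissue.

    Untreated composition follows the dry-base wet-chemistry ratios of rice
    straw (cellulose:hemicellulose:lignin = 39.5:33.2:4.5); the treated class
    multiplies the component weights by per-component retention factors
    (default 0.87/0.47/0.75, the measured content ratios after alkali
    treatment) before renormalizing.

    Within-class composition jitter is multiplicative log-normal with sd
    ``composition_jitter`` (default 4.5%, the mean relative standard
    deviation of the wet-chemistry contents; each spot sample averages many
    raw spectra, so spot-to-spot compositional spread is small).

    Spot scans sample many tissue types (epidermis, parenchyma, sclerenchyma,
    xylem, ...) whose chromophore content differs strongly, so each spot
    carries its own fluorescence background: amplitude log-normal with
    ``fluorescence_sigma`` and a randomly shifted/steepened ramp shape, on
    top of per-band Gaussian noise.  This spot-to-spot background
    heterogeneity is what degrades classifiers fed the raw spectra.
    """
    if any(e <= 0 for e in effect):
        raise ValueError(f"effect scale factors must be > 0 (got {effect})")
    rng = np.random.default_rng(seed)
    refs, _ = default_components()
    if noise is None:
        noise = NoiseSpec(gaussian_sd=0.01, spike_rate=0.0, baseline_scale=1.0)
    base = np.array([TABLE_UNTREATED_COMPOSITION[n] for n in COMPONENT_NAMES])
    base = base / base.sum()
    treated = base * np.asarray(effect)
    treated = treated / treated.sum()
    out: list[Spectrum] = []
    for label, mean_w, count in (
        ("untreated", base, n_untreated),
        ("alkali-treated", treated, n_treated),
    ):
        for _ in range(count):
            w = mean_w * np.exp(rng.normal(0.0, composition_jitter, size=3))
            w = w / w.sum()
            y = w @ refs.spectra
            if noise.baseline_scale > 0:
                amp = noise.baseline_scale * rng.lognormal(0.0, fluorescence_sigma)
                shape_fn = nuisance_fluorescence_shape(
                    refs.axis,
                    center=rng.uniform(0.35, 0.55),
                    width=rng.uniform(0.18, 0.28),
                )
                y = y + amp * shape_fn
            if noise.gaussian_sd > 0:
                y = y + rng.normal(0.0, noise.gaussian_sd, size=y.shape)
            out.append(Spectrum(refs.axis, y, label=label,
                                meta={"true_weights": w.tolist()}))
    return out
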