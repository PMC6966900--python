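"""Fully constrained least-squares (FCLS) spectral unmixing and chemical imaging.

The linear mixing model treats the unfolded map ``D`` ((x*y) x L) as
``D = C P^T + R`` with ``P^T`` the k x L matrix of pure-component reference
spectra, ``C`` the per-pixel abundances, and ``R`` the residual.  FCLS
estimates each abundance row as the least-squares solution under the two
physical constraints: abundances sum to one and are non-negative.  Abundance
fractions are converted to concentrations (% dry base) by multiplying with
the laboratory-measured total content W of the k components.

The solver is the active-set scheme of the classic FCLS estimator: start from
the sum-to-one constrained least-squares solution (one Lagrange multiplier),
then iteratively clamp negative abundances to zero and re-solve on the free
set, releasing clamped components whose KKT multiplier turns negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ReferenceSet, Spectrum, SpectralMap

__all__ = [
    "AbundanceResult",
    "ChemicalImage",
    "fcls",
    "fcls_pixel",
    "unmix_map",
    "calibrate",
    "abundance_images",
    "single_band_image",
    "concentration_histogram",
    "composition_report",
    "W_UNTREATED",
    "W_TREATED",
]

# Default calibration totals (% d.b.): sum of cellulose + hemicellulose +
# lignin contents from wet-chemistry analysis of rice straw.
W_UNTREATED = 77.2
W_TREATED = 53.4


@dataclass
class AbundanceResult:
    """Per-pixel abundance fractions with optional calibration.

    ``abundance`` rows for foreground pixels lie on the probability simplex;
    background rows are NaN.  ``calibrated`` is ``abundance * W`` when a
    calibration total has been applied.
    """

    names: list[str]
    abundance: np.ndarray  # (n_pixels, k)
    residual: np.ndarray  # (n_pixels,) L2 norm of pixel residual
    mask: np.ndarray  # foreground flags
    width: int
    height: int
    W: float | None = None
    calibrated: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.names)

    def foreground_abundance(self) -> np.ndarray:
        return self.abundance[self.mask]

    def flagged_pixels(self, residual_quantile: float = 0.99) -> np.ndarray:
        """Indices of foreground pixels whose residual norm exceeds the given
        quantile — likely unmixing failures, flagged but never dropped."""
        fg = np.nonzero(self.mask)[0]
        if fg.size == 0:
            return fg
        tau = np.quantile(self.residual[fg], residual_quantile)
        return fg[self.residual[fg] > tau]


@dataclass
class ChemicalImage:
    component: str
    grid: np.ndarray  # (height, width); NaN where masked
    units: str  # "fraction" or "% d.b."
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# FCLS solver


def _sum_to_one_ls(G: np.ndarray, b: np.ndarray):
    """Least squares under the equality constraint sum(c) = 1 via the KKT
    system; returns (c, mu) with mu the constraint multiplier."""
    k = G.shape[0]
    K = np.zeros((k + 1, k + 1))
    K[:k, :k] = G
    K[:k, k] = 1.0
    K[k, :k] = 1.0
    rhs = np.concatenate([b, [1.0]])
    try:
        sol = np.linalg.solve(K, rhs)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
    return sol[:k], sol[k]


def fcls(d: np.ndarray, P: np.ndarray, tol: float = 1e-10, max_iter: int = 200):
    """Solve min ||d - P^T c||^2 subject to sum(c) = 1, c >= 0.

    ``P`` holds the k reference spectra as rows (k x L).  Returns
    ``(c, residual_norm)``.  The solution is unique when P has full row rank;
    rank deficiency falls back to a minimum-norm solve with a warning.
    """
    d = np.asarray(d, dtype=float)
    P = np.asarray(P, dtype=float)
    k, L = P.shape
    if k > L:
        raise ValueError(f"more components (k={k}) than bands (L={L})")
    if k == 1:
        c = np.array([1.0])
        return c, float(np.linalg.norm(d - P[0]))
    G = P @ P.T
    b = P @ d
    if np.linalg.matrix_rank(G, tol=1e-10 * np.trace(G) / k) < k:
        warnings.warn("rank-deficient reference set; abundance solution is "
                      "a minimum-norm compromise", stacklevel=2)
    free = np.ones(k, dtype=bool)
    c = np.zeros(k)
    for _ in range(max_iter):
        idx = np.nonzero(free)[0]
        c_free, mu = _sum_to_one_ls(G[np.ix_(idx, idx)], b[idx])
        if np.min(c_free) < -tol:
            # clamp the most negative abundance to zero
            free[idx[np.argmin(c_free)]] = False
            if not free.any():  # numerically pathological; restore last
                free[idx[np.argmax(c_free)]] = True
                c = np.zeros(k)
                c[idx[np.argmax(c_free)]] = 1.0
                break
            continue
        c = np.zeros(k)
        c[idx] = np.clip(c_free, 0.0, None)
        # KKT check for clamped components: gradient + mu must be >= 0
        clamped = np.nonzero(~free)[0]
        if clamped.size:
            g = G[clamped] @ c - b[clamped] + mu
            worst = np.argmin(g)
            if g[worst] < -tol * max(1.0, np.abs(b).max()):
                free[clamped[worst]] = True
                continue
        break
    c = np.clip(c, 0.0, None)
    s = c.sum()
    if s > 0:
        c = c / s
    resid = float(np.linalg.norm(d - P.T @ c))
    return c, resid


def fcls_pixel(d: Spectrum, P: ReferenceSet):
    """FCLS abundance row and residual norm for one pixel spectrum."""
    if not d.axis.close_to(P.axis):
        raise ValueError("spectrum and reference set are on different axes; "
                         "resample before unmixing")
    return fcls(d.intensity, P.spectra)


def _scale_to_unit(M: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale a matrix into [0, 1] by its global maximum if it exceeds 1.

    A single shared scalar keeps the linear mixing relation between pixels
    and references intact; per-row scaling would break the sum-to-one
    constraint for mixed pixels.
    """
    m = float(M.max())
    if m > 1.0:
        return M / m, m
    return M, 1.0


def unmix_map(
    smap: SpectralMap,
    refs: ReferenceSet,
    normalize: str = "auto",
) -> AbundanceResult:
    """FCLS unmixing of every foreground pixel against the reference set.

    ``normalize='auto'`` adjusts the cube and the reference matrix into
    [0, 1] by their global maxima (matrices already within [0, 1] pass
    through unchanged); ``'none'`` uses the data as given.  Background
    pixels carry NaN abundance.
    """
    if not smap.axis.close_to(refs.axis):
        raise ValueError(
            "map and reference set are on different axes; resample the "
            "references with resample_to_axis() first"
        )
    cube = smap.cube
    P = refs.spectra
    if normalize == "auto":
        # scale from foreground pixels only: masked background may hold
        # unprocessed artifacts (e.g. cosmic spikes) that would skew it
        fg_max = float(cube[smap.mask].max()) if smap.mask.any() else float(cube.max())
        cube_scale = fg_max if fg_max > 1.0 else 1.0
        cube = cube / cube_scale
        P, ref_scale = _scale_to_unit(P)
    elif normalize == "none":
        cube_scale = ref_scale = 1.0
    else:
        raise ValueError(f"unknown normalize mode {normalize!r}")
    n, k = smap.n_pixels, refs.k
    A = np.full((n, k), np.nan)
    R = np.full(n, np.nan)
    for i in np.nonzero(smap.mask)[0]:
        A[i], R[i] = fcls(cube[i], P)
    return AbundanceResult(
        names=list(refs.names),
        abundance=A,
        residual=R,
        mask=smap.mask.copy(),
        width=smap.width,
        height=smap.height,
        meta={
            "normalize": normalize,
            "cube_scale": cube_scale,
            "ref_scale": ref_scale,
            "map_meta": dict(smap.meta),
        },
    )


def calibrate(result: AbundanceResult, W: float) -> AbundanceResult:
    """Convert abundance fractions to concentrations: calibrated = C * W,
    with W the laboratory-measured total content (% d.b.) of the k
    components.  The abundance matrix itself is unchanged."""
    if W <= 0:
        raise ValueError(f"calibration total W must be > 0 (got {W})")
    result.W = float(W)
    result.calibrated = result.abundance * W
    return result


def abundance_images(result: AbundanceResult, calibrated: bool | None = None
                     ) -> list[ChemicalImage]:
    """One chemical image per component, NaN outside the foreground."""
    if calibrated is None:
        calibrated = result.calibrated is not None
    values = result.calibrated if calibrated else result.abundance
    if values is None:
        raise ValueError("no calibrated concentrations; call calibrate() first")
    units = "% d.b." if calibrated else "fraction"
    mask2d = result.mask.reshape(result.height, result.width)
    images = []
    for j, name in enumerate(result.names):
        grid = values[:, j].reshape(result.height, result.width).copy()
        grid[~mask2d] = np.nan
        images.append(ChemicalImage(name, grid, units,
                                    provenance={"W": result.W, **result.meta}))
    return images


def single_band_image(smap: SpectralMap, wavenumber: float) -> ChemicalImage:
    """Raw per-pixel intensity at the nearest axis point — the traditional
    single-band imaging method, kept for comparison with FCLS images."""
    j = smap.axis.index_of(wavenumber)
    grid = smap.grid(smap.cube[:, j])
    return ChemicalImage(
        component=f"{smap.axis.values[j]:g} cm^-1",
        grid=grid,
        units="intensity",
        provenance={"wavenumber": float(smap.axis.values[j])},
    )


def concentration_histogram(
    images: list[ChemicalImage], bins: int | np.ndarray = 20
) -> pd.DataFrame:
    """Pixel counts per concentration bin per component.

    Returns a tidy frame with columns (component, bin_left, bin_right,
    count); counts per component sum to that image's foreground pixel count.
    """
    if isinstance(bins, int) and bins < 1:
        raise ValueError("need at least one histogram bin")
    rows = []
    for img in images:
        vals = img.grid[np.isfinite(img.grid)].ravel()
        if vals.size == 0:
            raise ValueError(f"image {img.component!r} has no foreground pixels")
        counts, edges = np.histogram(vals, bins=bins)
        for c, lo, hi in zip(counts, edges[:-1], edges[1:]):
            rows.append({"component": img.component, "bin_left": lo,
                         "bin_right": hi, "count": int(c)})
    return pd.DataFrame(rows)


def composition_report(
    before: dict[str, float],
    after: dict[str, float],
    gas: tuple[float, float] | None = None,
) -> dict:
    """Relative composition changes between two measured states.

    Per-component relative reduction = (before - after) / before * 100,
    reported both raw and rounded to the nearest integer percent.  Totals
    are the sums over the shared components.  With ``gas=(yield_before,
    yield_after)``, the relative yield change is reported to one decimal.
    """
    missing = set(before) ^ set(after)
    if missing:
        raise ValueError(f"component(s) {sorted(missing)} missing from one state")
    if any(v <= 0 for v in before.values()) or any(v <= 0 for v in after.values()):
        raise ValueError("component contents must be > 0")
    components = {}
    for name in before:
        raw = (before[name] - after[name]) / before[name] * 100.0
        components[name] = {
            "before": before[name],
            "after": after[name],
            "reduction_pct_raw": raw,
            "reduction_pct": int(round(raw)),
        }
    report = {
        "components": components,
        "total_before": float(sum(before.values())),
        "total_after": float(sum(after.values())),
    }
    report["total_reduction"] = report["total_before"] - report["total_after"]
    if gas is not None:
        y0, y1 = gas
        if y0 <= 0:
            raise ValueError("baseline gas yield must be > 0")
        report["gas_yield_change_pct"] = round((y1 - y0) / y0 * 100.0, 1)
    return report
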