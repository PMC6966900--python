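"""Noise-reduction chain for Raman maps and spot spectra.

Stages, in pipeline order: background segmentation (threshold on a per-pixel
intensity score), cosmic-ray despiking (running-median modified z-score),
airPLS baseline correction (adaptive iteratively reweighted penalized least
squares on a Whittaker smoother), PCA denoising (reconstruction from the
leading principal components), and two normalizations — per-spectrum area
normalization (each band divided by the band sum) and max normalization to
[0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.ndimage import median_filter
from scipy.sparse.linalg import spsolve
from sklearn.decomposition import PCA

from .core import ReferenceSet, Spectrum, SpectralMap

__all__ = [
    "BaselineFit",
    "DenoiseReport",
    "segment_background",
    "despike",
    "airpls",
    "airpls_array",
    "preprocess_references",
    "pca_denoise",
    "area_normalize",
    "max_normalize",
    "preprocess_map",
]


@dataclass
class BaselineFit:
    """Result of an airPLS baseline estimate; ``corrected + baseline == input``."""

    baseline: np.ndarray
    corrected: np.ndarray
    iterations: int
    converged: bool
    lam: float
    ratio: float


@dataclass
class DenoiseReport:
    n_components: int
    explained_variance: float
    residual_energy: float


# ---------------------------------------------------------------------------
# Background segmentation


def _otsu_threshold(scores: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold maximizing between-class variance of the score
    histogram."""
    hist, edges = np.histogram(scores, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = hist.astype(float)
    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    m = np.cumsum(hist * centers)
    mu0 = np.divide(m, w0, out=np.zeros_like(m), where=w0 > 0)
    mu1 = np.divide(m[-1] - m, w1, out=np.zeros_like(m), where=w1 > 0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    return float(centers[np.argmax(between)])


def segment_background(
    smap: SpectralMap,
    strategy: str = "otsu",
    threshold: float | None = None,
    band_window: tuple[float, float] | None = None,
    quantile: float = 0.25,
) -> np.ndarray:
    """Foreground mask from a per-pixel scalar score (mean intensity over a
    band window, default the full axis).

    ``otsu`` picks the threshold maximizing between-class score variance;
    ``quantile`` masks out the lowest-scoring fraction; ``manual`` uses the
    given ``threshold``.  If every pixel lands on one side, a warning is
    raised and the all-foreground mask is returned.
    """
    if smap.n_pixels < 2:
        raise ValueError("segmentation needs a map with >= 2 pixels")
    if band_window is None:
        scores = smap.cube.mean(axis=1)
    else:
        i0 = smap.axis.index_of(band_window[0])
        i1 = smap.axis.index_of(band_window[1])
        scores = smap.cube[:, min(i0, i1): max(i0, i1) + 1].mean(axis=1)
    if strategy == "manual":
        if threshold is None:
            raise ValueError("manual segmentation requires a threshold")
        tau = float(threshold)
    elif strategy == "quantile":
        tau = float(np.quantile(scores, quantile))
    elif strategy == "otsu":
        tau = _otsu_threshold(scores)
    else:
        raise ValueError(f"unknown segmentation strategy {strategy!r}")
    mask = scores > tau
    if mask.all() or not mask.any():
        warnings.warn(
            f"segmentation threshold {tau:g} puts all pixels on one side; "
            "returning all-foreground mask",
            stacklevel=2,
        )
        return np.ones(smap.n_pixels, dtype=bool)
    return mask


# ---------------------------------------------------------------------------
# Despiking


def despike(s: Spectrum, window: int = 7, z: float = 8.0,
            min_ratio: float = 0.5) -> Spectrum:
    """Replace cosmic-ray spikes by the local running median.

    A band is a spike when its modified z-score against the running median
    (0.6745 * residual / MAD of the residuals) exceeds ``z`` in absolute
    value AND the residual rises above ``min_ratio`` times the local median
    level.  The second guard keeps noiseless smooth peaks — whose curvature
    towers over a near-zero global MAD — from being flagged; genuine cosmic
    rays are several-fold brighter than their surroundings and always pass
    it.  All other bands are returned unchanged.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3 (got {window})")
    y = s.intensity
    if window >= y.size:
        raise ValueError(f"window {window} must be smaller than spectrum length {y.size}")
    med = median_filter(y, size=window, mode="nearest")
    resid = y - med
    mad = np.median(np.abs(resid))
    scale = max(mad, 1e-12 * max(np.ptp(y), 1.0), 1e-300)
    zscore = 0.6745 * resid / scale
    spikes = (np.abs(zscore) > z) & (np.abs(resid) > min_ratio * np.abs(med))
    out = y.copy()
    out[spikes] = med[spikes]
    return s.replace(out, despiked=int(spikes.sum()))


def _despike_array(Y: np.ndarray, window: int, z: float, axis_obj) -> np.ndarray:
    out = np.empty_like(Y)
    for i, row in enumerate(Y):
        out[i] = despike(Spectrum(axis_obj, row), window=window, z=z).intensity
    return out


# ---------------------------------------------------------------------------
# airPLS baseline correction


def _whittaker_system(L: int, lam: float) -> sparse.csc_matrix:
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(L - 2, L))
    return (lam * (D.T @ D)).tocsc()


def airpls(
    s: Spectrum | np.ndarray,
    lam: float = 1e5,
    max_iter: int = 15,
    ratio: float = 1e-3,
) -> BaselineFit:
    """Adaptive iteratively reweighted penalized least-squares baseline.

    Each iteration solves the weighted Whittaker system

        z = argmin  sum_i w_i (y_i - z_i)^2 + lam * sum (d2 z)^2

    then re-estimates the weights: w_i = 0 where y_i >= z_i (peak region),
    otherwise exp(t * |d_i| / |d|) with d the negative part of the residual
    and t the iteration index.  Iteration stops when |d|_1 < ratio * |y|_1.
    Non-convergence returns the best iterate with ``converged=False``.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be > 0 (got {lam})")
    y = s.intensity if isinstance(s, Spectrum) else np.asarray(s, dtype=float)
    L = y.size
    if L < 3:
        raise ValueError("airPLS needs at least 3 bands")
    P = _whittaker_system(L, lam)
    w = np.ones(L)
    z = y.copy()
    converged = False
    abs_y = np.abs(y).sum()
    it = 0
    for it in range(1, max_iter + 1):
        W = sparse.diags(w)
        z = spsolve((W + P).tocsc(), w * y)
        d = y - z
        neg = d < 0
        dssn = np.abs(d[neg]).sum()
        if dssn < ratio * abs_y or abs_y == 0.0:
            converged = True
            break
        w[~neg] = 0.0
        w[neg] = np.exp(it * np.abs(d[neg]) / dssn)
        # anchor the endpoints so the baseline cannot drift free
        w[0] = np.exp(it * np.abs(d[neg]).max() / dssn) if neg.any() else 1.0
        w[-1] = w[0]
    return BaselineFit(
        baseline=z,
        corrected=y - z,
        iterations=it,
        converged=converged,
        lam=float(lam),
        ratio=float(ratio),
    )


def airpls_array(Y: np.ndarray, lam: float = 1e5, max_iter: int = 15,
                 ratio: float = 1e-3) -> np.ndarray:
    """Baseline-corrected copy of a stack of spectra (rows)."""
    out = np.empty_like(Y, dtype=float)
    for i, row in enumerate(Y):
        out[i] = airpls(row, lam=lam, max_iter=max_iter, ratio=ratio).corrected
    return out


def preprocess_references(refs: ReferenceSet, lam: float = 1e5) -> ReferenceSet:
    """Baseline-corrected copy of a reference set.

    When a map is unmixed after airPLS correction, the references must go
    through the same correction so pixel and reference spectra stay on the
    same (fluorescence-free) footing.
    """
    out = refs.replace(airpls_array(refs.spectra, lam=lam))
    out.meta["baseline_corrected"] = True
    return out


# ---------------------------------------------------------------------------
# PCA denoising


def pca_denoise(
    data: list[Spectrum] | SpectralMap | np.ndarray,
    target_variance: float = 0.9999,
    max_components: int = 3,
):
    """Reconstruct spectra from their leading principal components.

    Keeps the smaller of (number of components reaching ``target_variance``
    cumulative explained variance, ``max_components``).  Returns the denoised
    data in its original container plus a :class:`DenoiseReport`.
    """
    if isinstance(data, SpectralMap):
        X = data.cube
    elif isinstance(data, np.ndarray):
        X = data
    else:
        X = np.stack([s.intensity for s in data])
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA denoising needs at least 2 spectra")
    n_max = min(max_components, n - 1, X.shape[1])
    pca = PCA(n_components=n_max, svd_solver="full")
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    reached = np.searchsorted(cum, target_variance - 1e-15) + 1
    n_keep = int(min(reached, n_max))
    recon = scores[:, :n_keep] @ pca.components_[:n_keep] + pca.mean_
    total_ss = np.sum((X - X.mean(axis=0)) ** 2)
    resid_ss = np.sum((X - recon) ** 2)
    if total_ss > 0:
        residual = resid_ss / total_ss
        explained = 1.0 - residual
    else:
        residual, explained = 0.0, 1.0
    report = DenoiseReport(n_keep, float(explained), float(residual))
    if isinstance(data, SpectralMap):
        return data.replace(cube=recon, pca_denoised=n_keep), report
    if isinstance(data, np.ndarray):
        return recon, report
    out = [s.replace(recon[i]) for i, s in enumerate(data)]
    return out, report


# ---------------------------------------------------------------------------
# Normalizations


def area_normalize(s: Spectrum) -> Spectrum:
    """Divide each band by the band sum so the spectrum integrates to one.

    Negative intensities (possible after baseline subtraction) are clipped to
    zero before summing so the intensity mass stays non-negative.
    """
    y = np.clip(s.intensity, 0.0, None)
    total = y.sum()
    if total <= 0:
        pixel = s.meta.get("pixel", s.label or "<unnamed>")
        raise ValueError(f"cannot area-normalize all-zero spectrum ({pixel})")
    return s.replace(y / total, area_normalized=True)


def max_normalize(obj: Spectrum | ReferenceSet | SpectralMap):
    """Divide every spectrum (row) by its own maximum, mapping it into [0, 1]."""
    if isinstance(obj, Spectrum):
        m = obj.intensity.max()
        if m <= 0:
            raise ValueError("cannot max-normalize spectrum with non-positive maximum")
        return obj.replace(obj.intensity / m)
    if isinstance(obj, ReferenceSet):
        m = obj.spectra.max(axis=1, keepdims=True)
        if np.any(m <= 0):
            bad = obj.names[int(np.argmax(obj.spectra.max(axis=1) <= 0))]
            raise ValueError(f"component {bad!r} has non-positive maximum")
        return obj.replace(obj.spectra / m)
    if isinstance(obj, SpectralMap):
        m = obj.cube.max(axis=1, keepdims=True)
        if np.any(m <= 0):
            bad = int(np.argmax(obj.cube.max(axis=1) <= 0))
            raise ValueError(f"pixel {bad} has non-positive maximum")
        return obj.replace(cube=obj.cube / m)
    raise TypeError(f"cannot max-normalize {type(obj).__name__}")


# ---------------------------------------------------------------------------
# Full chain


def preprocess_map(
    smap: SpectralMap,
    segment: str | None = "otsu",
    run_despike: bool = True,
    despike_window: int = 7,
    despike_z: float = 8.0,
    baseline_lam: float | None = 1e5,
    denoise: bool = True,
    target_variance: float = 0.9999,
    max_components: int = 3,
) -> SpectralMap:
    """Noise-reduction chain for a map: segmentation -> despike ->
    PCA denoise -> airPLS.

    Impulsive artifacts (cosmic spikes) are removed first; PCA denoising then
    collapses the foreground pixels onto their low-rank signal manifold
    before baseline estimation.  The order matters: airPLS weights out
    positive residuals, so on noisy spectra its baseline hugs the noise floor
    from below and leaves a broadband positive offset in the corrected
    signal; denoising first makes the baseline estimate essentially exact.

    Normalization is left to the consumer: classification uses per-spectrum
    area normalization, unmixing uses max normalization of the cube and the
    reference matrix.  Only foreground pixels are processed.
    """
    mask = smap.mask.copy()
    if segment is not None:
        mask &= segment_background(smap, strategy=segment)
    cube = smap.cube.copy()
    fg = np.nonzero(mask)[0]
    meta_updates: dict = {"preprocessed": True}
    if run_despike and fg.size:
        cube[fg] = _despike_array(cube[fg], despike_window, despike_z, smap.axis)
    if denoise and fg.size >= 2:
        sub, report = pca_denoise(cube[fg], target_variance=target_variance,
                                  max_components=max_components)
        cube[fg] = sub
        meta_updates["pca_components"] = report.n_components
    if baseline_lam is not None and fg.size:
        cube[fg] = airpls_array(cube[fg], lam=baseline_lam)
        meta_updates["baseline_corrected"] = True
        meta_updates["baseline_lam"] = float(baseline_lam)
    return smap.replace(cube=cube, mask=mask, **meta_updates)
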