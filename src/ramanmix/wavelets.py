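"""Discrete-wavelet single-branch reconstruction features.

A spectrum is decomposed to level 8 (nine coefficient sets: one approximation
A8 and details D8..D1).  Reconstructing from one coefficient set with all
others zeroed isolates one frequency band of the signal; the branches sum
back to the input exactly.  Mid-level detail branches (D5-D7 on a ~1000-band
axis) straddle the width of Raman peaks, so they retain chemical peaks while
rejecting both high-frequency noise (D1-D2) and the broad fluorescence
background (A8/D8).  D6 is the default feature signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .core import Spectrum, SpectralMap

__all__ = ["WaveletBranches", "branch_names", "decompose_branches",
           "extract_branch", "branch_band_image"]

DEFAULT_FAMILY = "db4"
DEFAULT_LEVEL = 8


def branch_names(level: int = DEFAULT_LEVEL) -> list[str]:
    return [f"A{level}"] + [f"D{i}" for i in range(level, 0, -1)]


@dataclass
class WaveletBranches:
    """Additive single-branch decomposition of one spectrum set."""

    length: int
    family: str
    level: int
    branches: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.branches[name]
        except KeyError:
            raise KeyError(
                f"unknown branch {name!r}; available: {sorted(self.branches)}"
            ) from None

    def reconstruction(self) -> np.ndarray:
        return sum(self.branches.values())


def _check_level(L: int, level: int) -> None:
    if L < 2**level:
        feasible = int(np.floor(np.log2(max(L, 1))))
        raise ValueError(
            f"spectrum length {L} < 2^{level}; maximum feasible level is {feasible}"
        )


def _branch_signals(Y: np.ndarray, family: str, level: int) -> dict[str, np.ndarray]:
    """Single-branch reconstructions along the last axis of ``Y``."""
    wavelet = pywt.Wavelet(family)
    L = Y.shape[-1]
    with warnings.catch_warnings():
        # level 8 on a ~1000-band axis exceeds pywt's conservative
        # boundary-effect heuristic; single-branch reconstruction is still
        # exact (the branches sum back to the input)
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(Y, wavelet, level=level, mode="symmetric", axis=-1)
    names = branch_names(level)
    out: dict[str, np.ndarray] = {}
    for i, name in enumerate(names):
        only = [c if j == i else np.zeros_like(c) for j, c in enumerate(coeffs)]
        rec = pywt.waverec(only, wavelet, mode="symmetric", axis=-1)
        out[name] = rec[..., :L]
    return out


def decompose_branches(
    s: Spectrum, family: str = DEFAULT_FAMILY, level: int = DEFAULT_LEVEL
) -> WaveletBranches:
    """Decompose one spectrum into level+1 single-branch reconstructions."""
    L = len(s.axis)
    _check_level(L, level)
    wavelet = pywt.Wavelet(family)
    if wavelet.rec_lo is None or len(wavelet.rec_lo) == 0:
        raise ValueError(f"wavelet family {family!r} has no reconstruction filters")
    return WaveletBranches(L, family, level, _branch_signals(s.intensity, family, level))


def extract_branch(
    data: list[Spectrum] | SpectralMap | np.ndarray,
    branch: str = "D6",
    family: str = DEFAULT_FAMILY,
    level: int = DEFAULT_LEVEL,
):
    """Replace every spectrum by one named wavelet branch (same container)."""
    if branch not in branch_names(level):
        raise ValueError(
            f"unknown branch {branch!r} for level {level}; "
            f"choose from {branch_names(level)}"
        )
    if isinstance(data, SpectralMap):
        _check_level(len(data.axis), level)
        sig = _branch_signals(data.cube, family, level)[branch]
        return data.replace(cube=sig, wavelet_branch=branch, wavelet_family=family)
    if isinstance(data, np.ndarray):
        _check_level(data.shape[-1], level)
        return _branch_signals(data, family, level)[branch]
    _check_level(len(data[0].axis), level)
    X = np.stack([s.intensity for s in data])
    sig = _branch_signals(X, family, level)[branch]
    return [s.replace(sig[i], wavelet_branch=branch) for i, s in enumerate(data)]


def branch_band_image(
    smap: SpectralMap,
    branch: str,
    wavenumber: float,
    family: str = DEFAULT_FAMILY,
    level: int = DEFAULT_LEVEL,
) -> np.ndarray:
    """Per-pixel branch intensity at the axis point nearest ``wavenumber``,
    folded into a (height, width) image; masked pixels are NaN."""
    j = smap.axis.index_of(wavenumber)
    bm = extract_branch(smap, branch, family=family, level=level)
    return smap.grid(bm.cube[:, j])
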