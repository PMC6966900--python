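"""Chemometric analysis of labeled spot-scan spectra.

Unsupervised: mean-centered PCA of the spectra with loading-weight band
analysis (bands whose |loading| exceeds a threshold on PC1/PC2 point to the
chemistry driving the separation).  Supervised: LDA and KNN classifiers over
a feature grid of input signals (raw spectra or one wavelet branch A8/D1..D8)
crossed with band sets (full range or a short fingerprint list such as
1620 + 1089 cm^-1), using a single stratified 3:1 train/prediction split.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from .core import Spectrum, WavenumberAxis
from .preprocess import area_normalize
from .wavelets import DEFAULT_FAMILY, DEFAULT_LEVEL, branch_names, extract_branch

__all__ = [
    "PcaResult",
    "ClassifierReport",
    "pca_fit",
    "select_loading_bands",
    "split_train_test",
    "fit_predict_lda",
    "fit_predict_knn",
    "run_feature_grid",
    "grid_to_frame",
]


@dataclass
class PcaResult:
    axis: WavenumberAxis
    scores: np.ndarray  # (n, n_pc)
    loadings: np.ndarray  # (n_pc, L), unit-norm rows
    explained: np.ndarray  # variance fractions
    cumulative: np.ndarray


@dataclass
class ClassifierReport:
    algorithm: str  # LDA | KNN
    signal: str  # raw | A8 | D1..D8
    bands: str  # "full" or comma-joined wavenumbers
    split_ratio: str
    seed: int
    train_accuracy: float  # percent
    test_accuracy: float  # percent
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierReport":
        return cls(**d)


def _matrix(spectra: list[Spectrum]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.intensity for s in spectra])
    y = np.asarray([s.label for s in spectra])
    return X, y


def pca_fit(spectra: list[Spectrum], n_pc: int = 2) -> PcaResult:
    """Mean-centered PCA; deterministic up to sign, which is fixed by making
    the largest-magnitude loading of each component positive."""
    X, _ = _matrix(spectra)
    n, L = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 spectra")
    if n_pc > min(n, L):
        raise ValueError(f"n_pc={n_pc} exceeds min(n={n}, L={L})")
    Xc = X - X.mean(axis=0)
    total_var = np.sum(Xc**2)
    if total_var <= 1e-300:
        warnings.warn("spectra have zero variance; PCA scores are all zero",
                      stacklevel=2)
        axis = spectra[0].axis
        return PcaResult(axis, np.zeros((n, n_pc)),
                         np.zeros((n_pc, L)), np.zeros(n_pc), np.zeros(n_pc))
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[:n_pc]
    scores = U[:, :n_pc] * S[:n_pc]
    # sign convention
    for i in range(n_pc):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    explained = (S[:n_pc] ** 2) / total_var
    return PcaResult(spectra[0].axis, scores, loadings, explained,
                     np.cumsum(explained))


def select_loading_bands(
    pca: PcaResult, threshold: float = 0.025, pcs: tuple[int, ...] = (1, 2)
) -> list[float]:
    """Wavenumbers of loading-weight peaks: axis points where |loading|
    exceeds ``threshold`` on any selected PC, merged into contiguous runs
    reported by their apex (largest |loading|)."""
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0 (got {threshold})")
    idx = [p - 1 for p in pcs]
    for i in idx:
        if i < 0 or i >= pca.loadings.shape[0]:
            raise ValueError(f"PC {i + 1} not available (have {pca.loadings.shape[0]})")
    mag = np.abs(pca.loadings[idx]).max(axis=0)
    above = mag > threshold
    apexes: list[float] = []
    v = pca.axis.values
    j = 0
    L = above.size
    while j < L:
        if above[j]:
            j0 = j
            while j < L and above[j]:
                j += 1
            run = slice(j0, j)
            apex = j0 + int(np.argmax(mag[run]))
            apexes.append(float(v[apex]))
        else:
            j += 1
    return apexes


def split_train_test(
    spectra: list[Spectrum], test_fraction: float = 0.25, seed: int = 0
) -> tuple[list[Spectrum], list[Spectrum]]:
    """Stratified random split (default 3:1 train:prediction)."""
    labels = [s.label for s in spectra]
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("split requires at least two classes")
    if counts.min() < 2:
        small = classes[np.argmin(counts)]
        raise ValueError(f"class {small!r} has fewer than 2 members")
    idx = np.arange(len(spectra))
    tr, te = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=labels
    )
    return [spectra[i] for i in sorted(tr)], [spectra[i] for i in sorted(te)]


def _band_columns(axis: WavenumberAxis, bands) -> list[int] | None:
    if bands is None or bands == "full":
        return None
    return [axis.index_of(w) for w in bands]


def _features(X: np.ndarray, cols: list[int] | None) -> np.ndarray:
    return X if cols is None else X[:, cols]


def _report(algorithm, signal, bands, seed, model, Xtr, ytr, Xte, yte) -> ClassifierReport:
    train_acc = 100.0 * float(np.mean(model.predict(Xtr) == ytr))
    test_acc = 100.0 * float(np.mean(model.predict(Xte) == yte))
    band_str = "full" if bands is None or bands == "full" else "+".join(
        f"{b:g}" for b in bands
    )
    return ClassifierReport(
        algorithm=algorithm,
        signal=signal,
        bands=band_str,
        split_ratio="3:1",
        seed=int(seed),
        train_accuracy=train_acc,
        test_accuracy=test_acc,
        n_train=len(ytr),
        n_test=len(yte),
    )


def fit_predict_lda(
    train: list[Spectrum],
    test: list[Spectrum],
    bands=None,
    signal: str = "raw",
    seed: int = 0,
) -> ClassifierReport:
    """Fisher linear discriminant with Ledoit-Wolf shrinkage of the
    within-class scatter (full-range spectra are strongly collinear)."""
    Xtr, ytr = _matrix(train)
    Xte, yte = _matrix(test)
    if np.unique(ytr).size < 2:
        raise ValueError("LDA needs at least 2 classes in the training set")
    cols = _band_columns(train[0].axis, bands)
    model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinearity warnings are expected
        model.fit(_features(Xtr, cols), ytr)
    return _report("LDA", signal, bands, seed, model,
                   _features(Xtr, cols), ytr, _features(Xte, cols), yte)


def fit_predict_knn(
    train: list[Spectrum],
    test: list[Spectrum],
    bands=None,
    k: int = 5,
    signal: str = "raw",
    seed: int = 0,
) -> ClassifierReport:
    """K-nearest-neighbor vote on Euclidean distance over the selected bands.

    Default k=5: an odd k cannot tie in a two-class vote.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1 (got {k})")
    if k > len(train):
        raise ValueError(f"k={k} exceeds training-set size {len(train)}")
    Xtr, ytr = _matrix(train)
    Xte, yte = _matrix(test)
    cols = _band_columns(train[0].axis, bands)
    model = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
    model.fit(_features(Xtr, cols), ytr)
    return _report("KNN", signal, bands, seed, model,
                   _features(Xtr, cols), ytr, _features(Xte, cols), yte)


DEFAULT_SIGNALS = ("raw",) + tuple(branch_names(DEFAULT_LEVEL)[:1]) + tuple(
    f"D{i}" for i in range(1, DEFAULT_LEVEL + 1)
)
DEFAULT_BAND_SETS = ("full", (1620.0, 1089.0))


def run_feature_grid(
    dataset: list[Spectrum],
    algorithms: tuple[str, ...] = ("LDA", "KNN"),
    signals: tuple[str, ...] = DEFAULT_SIGNALS,
    band_sets=DEFAULT_BAND_SETS,
    seed: int = 0,
    k: int = 5,
    normalize: bool = False,
    family: str = DEFAULT_FAMILY,
    level: int = DEFAULT_LEVEL,
) -> list[ClassifierReport]:
    """One classifier report per (algorithm x input signal x band set).

    Input signals are the spectra as given or one single-branch wavelet
    reconstruction of them.  With ``normalize=True`` each spectrum is
    area-normalized first; the default leaves the acquisition scale intact,
    because dividing fluorescence-dominated spectra by their total area
    injects the (uninformative, highly variable) background magnitude into
    every band.  The same stratified 3:1 split is reused across the whole
    grid so rows are comparable.
    """
    if not any(s.label for s in dataset):
        raise ValueError("feature grid needs labeled spectra")
    base = [area_normalize(s) for s in dataset] if normalize else list(dataset)
    train, test = split_train_test(base, seed=seed)
    reports: list[ClassifierReport] = []
    for signal in signals:
        if signal == "raw":
            tr, te = train, test
        else:
            tr = extract_branch(train, signal, family=family, level=level)
            te = extract_branch(test, signal, family=family, level=level)
        for bands in band_sets:
            b = None if (bands is None or bands == "full") else bands
            for algo in algorithms:
                if algo == "LDA":
                    reports.append(fit_predict_lda(tr, te, b, signal=signal, seed=seed))
                elif algo == "KNN":
                    reports.append(
                        fit_predict_knn(tr, te, b, k=k, signal=signal, seed=seed)
                    )
                else:
                    raise ValueError(f"unknown algorithm {algo!r}")
    return reports


def grid_to_frame(reports: list[ClassifierReport], which: str = "test") -> pd.DataFrame:
    """Pivot a report list into the accuracy-grid layout: one row per
    (algorithm, band set), one column per input signal."""
    col = f"{which}_accuracy"
    rows = [r.to_dict() for r in reports]
    df = pd.DataFrame(rows)
    return df.pivot_table(index=["algorithm", "bands"], columns="signal",
                          values=col).round(2)
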