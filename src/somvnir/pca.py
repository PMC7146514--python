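"""PCA spectral feature extraction ("1DV" variables).

Spectra are column-centered (no unit-variance scaling — all bands share
units) and decomposed into principal components.  The number of retained
components is the smallest k whose cumulative explained-variance ratio
exceeds 95%, with a floor of five components when available, since five
PC scores are carried forward as the one-dimensional modeling variables.

To avoid leakage, the PCA used for modeling features is fitted on the
calibration set only and validation spectra are projected onto it;
fitting on the entire dataset is also supported for eigenvector
inspection plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .datatypes import SpectraSet

__all__ = ["PCAResult", "fit_pca", "project", "correlate_scores", "select_n_components"]


@dataclass
class PCAResult:
    loadings: np.ndarray         # (n_components, n_bands), unit-norm rows
    explained_ratio: np.ndarray  # fractions, non-increasing
    scores: np.ndarray           # (n_samples, n_components) of the fit data
    center: np.ndarray           # mean spectrum of the fit data
    wavelengths: np.ndarray      # grid the fit used


def select_n_components(explained_ratio: np.ndarray, threshold: float = 0.95, floor: int = 5) -> int:
    """Smallest k with cumulative ratio > threshold, floored at ``floor``."""
    ratios = np.asarray(explained_ratio, dtype=float)
    cum = np.cumsum(ratios)
    above = np.nonzero(cum > threshold)[0]
    k = int(above[0]) + 1 if above.size else ratios.size
    return min(max(k, floor), ratios.size)


def fit_pca(spectra: SpectraSet, threshold: float = 0.95, floor: int = 5) -> PCAResult:
    """Fit a centered PCA and retain components by the cumulative-ratio rule.

    Loadings are sign-fixed so each component's largest-magnitude element
    is positive, making repeated fits bit-stable.
    """
    X = spectra.reflectance
    if spectra.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if np.allclose(X, X[0:1, :], rtol=0, atol=1e-15):
        raise ValueError("PCA undefined for a constant matrix (no variance)")
    full = PCA(n_components=min(spectra.n_samples - 1, spectra.n_bands), svd_solver="full")
    scores = full.fit_transform(X)
    k = select_n_components(full.explained_variance_ratio_, threshold=threshold, floor=floor)
    loadings = full.components_[:k].copy()
    scores = scores[:, :k].copy()
    # sign convention: largest-|element| of each loading vector is positive
    flip = np.sign(loadings[np.arange(k), np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    loadings *= flip[:, None]
    scores *= flip[None, :]
    return PCAResult(
        loadings=loadings,
        explained_ratio=full.explained_variance_ratio_[:k].copy(),
        scores=scores,
        center=full.mean_.copy(),
        wavelengths=spectra.wavelengths.copy(),
    )


def project(result: PCAResult, spectra: SpectraSet) -> np.ndarray:
    """Project spectra onto a fitted PCA: ``(X - center) @ loadings.T``."""
    if spectra.wavelengths.size != result.wavelengths.size or not np.allclose(
        spectra.wavelengths, result.wavelengths, rtol=0, atol=1e-9
    ):
        raise ValueError("wavelength grid does not match the PCA fit")
    return (spectra.reflectance - result.center[None, :]) @ result.loadings.T


def correlate_scores(scores: np.ndarray, som: np.ndarray) -> np.ndarray:
    """Pearson r between each score column and SOM; NaN for constant columns."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    som = np.asarray(som, dtype=float).ravel()
    if scores.shape[0] != som.size:
        raise ValueError("scores and som lengths differ")
    if som.size < 3:
        raise ValueError("need at least 3 samples for a correlation")
    yc = som - som.mean()
    sy = np.sqrt((yc**2).sum())
    out = np.empty(scores.shape[1])
    for j in range(scores.shape[1]):
        xc = scores[:, j] - scores[:, j].mean()
        sx = np.sqrt((xc**2).sum())
        out[j] = np.nan if sx == 0 or sy == 0 else float((xc @ yc) / (sx * sy))
    return out
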