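"""Spectral preprocessing chain.

Order of operations for a raw 350-2500 nm, 1 nm spectrum:

1. :func:`trim_wavelengths` — drop the noisy instrument fringes, keeping
   the closed interval [400, 2400] nm (2001 bands at 1 nm).
2. :func:`gaussian_downsample` — resample to a 5 nm grid with a Gaussian
   kernel (2001 -> 401 bands), simultaneously smoothing and decimating.
3. :func:`savgol_smooth` — Savitzky-Golay filter, order 2, window 11.
4. :func:`continuum_remove` — divide each spectrum by its upper convex
   hull to isolate absorption features (optional; used where continuum
   removed (CR) spectra are requested, e.g. for PCA).

Every stage preserves sample count and order.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .datatypes import SpectraSet

__all__ = [
    "trim_wavelengths",
    "gaussian_downsample",
    "savgol_smooth",
    "continuum_remove",
    "subsample_bands",
    "preprocess_pipeline",
]


def trim_wavelengths(spectra: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Keep only wavelengths w with lo <= w <= hi (closed interval)."""
    if not lo < hi:
        raise ValueError(f"invalid trim interval [{lo}, {hi}]: lo must be < hi")
    mask = (spectra.wavelengths >= lo) & (spectra.wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"trim interval [{lo}, {hi}] contains no grid wavelengths")
    return SpectraSet(
        wavelengths=spectra.wavelengths[mask],
        reflectance=spectra.reflectance[:, mask],
        sample_ids=list(spectra.sample_ids),
    )


def gaussian_downsample(
    spectra: SpectraSet, step: float, sigma: float | None = None
) -> SpectraSet:
    """Resample to a coarser uniform grid with a Gaussian kernel.

    Output nodes run from the first to the last input wavelength at
    ``step`` nm.  Each output value is a Gaussian-weighted average of the
    input values, kernel centered on the node, truncated at +/-3 sigma and
    renormalized at the edges, so outputs are convex combinations of
    inputs (bounded by the per-spectrum min/max).

    ``sigma`` defaults to ``step / 2.355``, i.e. a kernel whose FWHM
    equals the output spacing.
    """
    wl = spectra.wavelengths
    dif = np.diff(wl)
    if not np.allclose(dif, dif[0], rtol=0, atol=1e-9):
        raise ValueError("gaussian_downsample requires a uniform input grid")
    span = wl[-1] - wl[0]
    if step <= 0:
        raise ValueError("step must be positive")
    if step > span:
        raise ValueError(f"step {step} nm exceeds the grid span {span} nm")
    if sigma is None:
        sigma = step / 2.355
    if sigma <= 0:
        raise ValueError("sigma must be positive")

    n_out = int(round(span / step)) + 1
    nodes = wl[0] + step * np.arange(n_out)
    # weight matrix (n_out, n_in); truncated at 3 sigma, rows renormalized
    d = nodes[:, None] - wl[None, :]
    w = np.exp(-0.5 * (d / sigma) ** 2)
    w[np.abs(d) > 3.0 * sigma] = 0.0
    w /= w.sum(axis=1, keepdims=True)
    return SpectraSet(
        wavelengths=nodes,
        reflectance=spectra.reflectance @ w.T,
        sample_ids=list(spectra.sample_ids),
    )


def savgol_smooth(spectra: SpectraSet, window: int = 11, polyorder: int = 2) -> SpectraSet:
    """Savitzky-Golay smoothing along the wavelength axis.

    Boundary bands are handled by fitting the window polynomial
    one-sidedly (``mode='interp'``), so the grid length is unchanged and
    a spectrum that is exactly a degree <= ``polyorder`` polynomial of
    wavelength passes through unchanged.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window > spectra.n_bands:
        raise ValueError("window exceeds the number of bands")
    smoothed = savgol_filter(
        spectra.reflectance, window_length=window, polyorder=polyorder, axis=1, mode="interp"
    )
    # polynomial fits can undershoot near clipped dark bands; reflectance
    # is physically positive, so floor at a tiny epsilon
    smoothed = np.maximum(smoothed, 1e-6)
    return SpectraSet(
        wavelengths=spectra.wavelengths.copy(),
        reflectance=smoothed,
        sample_ids=list(spectra.sample_ids),
    )


def _upper_hull_indices(x: np.ndarray, y: np.ndarray) -> list:
    """Indices of the upper convex hull of (x, y), left to right.

    Monotone-chain scan; collinear points are kept so hull-touching bands
    divide to exactly 1.
    """
    hull = []
    for i in range(x.size):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # cross product; pop i2 if it lies strictly below chord i1->i
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (y[i2] - y[i1]) * (x[i] - x[i1])
            if cross > 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def continuum_remove(spectra: SpectraSet) -> SpectraSet:
    """Divide each spectrum by its upper convex hull (continuum removal).

    The continuum is the piecewise-linear upper convex hull of the points
    (wavelength, reflectance); dividing by it rescales every band into
    (0, 1], with hull-touching bands (always including the first and last)
    exactly 1.  Isolates absorption troughs from the broad albedo trend.
    """
    if spectra.n_bands < 2:
        raise ValueError("continuum removal needs at least 2 bands")
    if np.any(spectra.reflectance <= 0):
        raise ValueError("continuum removal requires strictly positive reflectance")
    wl = spectra.wavelengths
    out = np.empty_like(spectra.reflectance)
    for row in range(spectra.n_samples):
        y = spectra.reflectance[row]
        hull = _upper_hull_indices(wl, y)
        continuum = np.interp(wl, wl[hull], y[hull])
        cr = y / continuum
        cr[hull] = 1.0  # exact at hull-touching bands
        out[row] = np.minimum(cr, 1.0)
    return SpectraSet(wavelengths=wl.copy(), reflectance=out, sample_ids=list(spectra.sample_ids))


def subsample_bands(spectra: SpectraSet, step: float) -> SpectraSet:
    """Keep every band whose offset from the first wavelength is a multiple
    of ``step`` nm.  Used to thin an already-preprocessed grid for coarse
    exhaustive scans; unlike resampling it leaves the kept values untouched.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    offs = spectra.wavelengths - spectra.wavelengths[0]
    keep = np.isclose(np.mod(offs + step / 2, step), step / 2, rtol=0, atol=1e-6)
    if not keep.any():
        raise ValueError("subsampling step keeps no bands")
    return SpectraSet(
        wavelengths=spectra.wavelengths[keep],
        reflectance=spectra.reflectance[:, keep],
        sample_ids=list(spectra.sample_ids),
    )


def preprocess_pipeline(
    spectra: SpectraSet,
    trim_lo: float = 400.0,
    trim_hi: float = 2400.0,
    step: float = 5.0,
    sigma: float | None = None,
    sg_window: int = 11,
    sg_polyorder: int = 2,
    continuum: bool = False,
) -> SpectraSet:
    """Full chain: trim -> Gaussian downsample -> Savitzky-Golay [-> CR]."""
    out = trim_wavelengths(spectra, trim_lo, trim_hi)
    out = gaussian_downsample(out, step=step, sigma=sigma)
    out = savgol_smooth(out, window=sg_window, polyorder=sg_polyorder)
    if continuum:
        out = continuum_remove(out)
    return out
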