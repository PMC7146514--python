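"""Exhaustive optimal band-combination search.

The central feature-extraction idea: given calibration spectra and SOM
values, evaluate a spectral index form (sum, difference, product, ratio,
normalized difference for two bands; five analogous three-band forms) at
*every* ordered combination of distinct wavelengths, correlate each
candidate index with SOM (Pearson r), keep the top 1% of combinations by
|r|, and pick the combination whose correlation is most stable between
the calibration and validation sets (minimum |r_cal - r_val|).

Index forms
-----------
Two-band (``Ri``, ``Rj`` reflectance at bands i, j):

====  =========================
SI    Ri + Rj
DI    Ri - Rj
PI    Ri * Rj
RI    Ri / Rj
NDI   (Ri - Rj) / (Ri + Rj)
====  =========================

Three-band (adds ``Rk``):

=====  ==============================
TBI1   Ri / (Rj + Rk)
TBI2   (Ri + Rj) / Rk
TBI3   (Ri - Rj) / (Rj - Rk)
TBI4   (Ri - Rj) / (Ri + Rj - 2 Rk)
TBI5   Ri + Rj - 2 Rk
=====  ==============================

Combinations with repeated wavelengths, any near-zero denominator
(|den| < eps for any sample) or near-zero index variance are flagged
invalid and excluded from ranking.  The scan is chunked along the first
band axis so peak working memory stays below a configurable cap; chunked
and unchunked scans are bit-identical because each cell's reduction is
always computed whole.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datatypes import SpectraSet

__all__ = [
    "IndexForm",
    "FORMS",
    "TWO_BAND_FORMS",
    "THREE_BAND_FORMS",
    "CorrelationMap",
    "Candidate",
    "SelectedIndex",
    "SliceViews",
    "index_values",
    "scan",
    "top_candidates",
    "select_optimal",
    "select_best_index",
    "slice_views",
]

_EPS = 1e-12


@dataclass(frozen=True)
class IndexForm:
    """A spectral index form: name, arity, numerator/denominator callables."""

    name: str
    arity: int
    numerator: callable
    denominator: callable | None = None  # None -> no division

    def evaluate(self, *bands):
        """Raw value and a boolean "bad denominator" mask (elementwise)."""
        num = self.numerator(*bands)
        if self.denominator is None:
            return num, np.zeros(np.shape(num), dtype=bool)
        den = self.denominator(*bands)
        bad = np.abs(den) < _EPS
        with np.errstate(divide="ignore", invalid="ignore"):
            val = num / den
        return val, bad


FORMS = {
    "SI": IndexForm("SI", 2, lambda ri, rj: ri + rj),
    "DI": IndexForm("DI", 2, lambda ri, rj: ri - rj),
    "PI": IndexForm("PI", 2, lambda ri, rj: ri * rj),
    "RI": IndexForm("RI", 2, lambda ri, rj: ri + 0 * rj, lambda ri, rj: rj + 0 * ri),
    "NDI": IndexForm("NDI", 2, lambda ri, rj: ri - rj, lambda ri, rj: ri + rj),
    "TBI1": IndexForm("TBI1", 3, lambda ri, rj, rk: ri + 0 * rj, lambda ri, rj, rk: rj + rk),
    "TBI2": IndexForm("TBI2", 3, lambda ri, rj, rk: ri + rj, lambda ri, rj, rk: rk + 0 * ri),
    "TBI3": IndexForm("TBI3", 3, lambda ri, rj, rk: ri - rj, lambda ri, rj, rk: rj - rk),
    "TBI4": IndexForm("TBI4", 3, lambda ri, rj, rk: ri - rj, lambda ri, rj, rk: ri + rj - 2 * rk),
    "TBI5": IndexForm("TBI5", 3, lambda ri, rj, rk: ri + rj - 2 * rk),
}
TWO_BAND_FORMS = ("SI", "DI", "PI", "RI", "NDI")
THREE_BAND_FORMS = ("TBI1", "TBI2", "TBI3", "TBI4", "TBI5")


@dataclass
class CorrelationMap:
    """Dense Pearson-r array over all ordered band combinations of a form."""

    form: IndexForm
    wavelengths: np.ndarray
    r: np.ndarray       # shape (B,)*arity; NaN where invalid
    valid: np.ndarray   # same shape, boolean

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass(frozen=True)
class Candidate:
    form_name: str
    bands: tuple      # wavelengths in nm
    r_cal: float


@dataclass(frozen=True)
class SelectedIndex:
    form_name: str
    bands: tuple
    r_cal: float
    r_val: float

    @property
    def err(self) -> float:
        return abs(self.r_cal - self.r_val)


def _resolve_form(form) -> IndexForm:
    if isinstance(form, IndexForm):
        return form
    try:
        return FORMS[form]
    except KeyError:
        raise ValueError(f"unknown index form {form!r}") from None


def index_values(form, spectra: SpectraSet, bands) -> np.ndarray:
    """Per-sample index values at a wavelength tuple; NaN where undefined.

    Samples whose denominator magnitude falls below 1e-12 are flagged NaN
    rather than silently producing huge values.
    """
    form = _resolve_form(form)
    bands = tuple(bands)
    if len(bands) != form.arity:
        raise ValueError(f"{form.name} takes {form.arity} wavelengths, got {len(bands)}")
    if len(set(bands)) != len(bands):
        raise ValueError("wavelengths must be distinct")
    cols = [spectra.reflectance[:, spectra.band_index(w)] for w in bands]
    val, bad = form.evaluate(*cols)
    val = np.asarray(val, dtype=float).copy()
    val[bad | ~np.isfinite(val)] = np.nan
    return val


def _chunk_size(arity: int, n_samples: int, n_bands: int, chunk_mb: float) -> int:
    per_i = n_samples * n_bands ** (arity - 1) * 8  # bytes of one V slab slice
    budget = max(chunk_mb, 1) * 2**20
    return max(1, int(budget // (3 * per_i)))


def scan(
    form,
    spectra: SpectraSet,
    som: np.ndarray,
    eps: float = _EPS,
    chunk_mb: float = 64.0,
) -> CorrelationMap:
    """Pearson correlation of an index form with SOM over all band combinations.

    Returns a dense ``(B,)*arity`` map of r values with a validity mask.
    Cells with repeated wavelengths, any bad denominator, non-finite index
    values or index variance < eps are invalid (r = NaN).
    """
    form = _resolve_form(form)
    R = spectra.reflectance
    y = np.asarray(som, dtype=float).ravel()
    n, B = R.shape
    if y.size != n:
        raise ValueError("som length must match number of spectra")
    if n < 3:
        raise ValueError("need at least 3 samples to scan")
    yc = y - y.mean()
    ynorm = math.sqrt(float(yc @ yc))
    if ynorm < eps:
        raise ValueError("SOM variance is zero; correlations undefined")
    yc = yc / ynorm

    shape = (B,) * form.arity
    r_map = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)

    ci = _chunk_size(form.arity, n, B, chunk_mb)
    for start in range(0, B, ci):
        stop = min(start + ci, B)
        if form.arity == 2:
            ri = R[:, start:stop, None]
            rj = R[:, None, :]
            V, bad = form.evaluate(ri, rj)
        else:
            ri = R[:, start:stop, None, None]
            rj = R[:, None, :, None]
            rk = R[:, None, None, :]
            V, bad = form.evaluate(ri, rj, rk)
        bad_cell = bad.any(axis=0) | ~np.isfinite(V).all(axis=0)
        V = np.where(np.isfinite(V), V, 0.0)
        mean = V.mean(axis=0)
        Vc = V - mean[None]
        ss = np.einsum("s...,s...->...", Vc, Vc)
        num = np.einsum("s,s...->...", yc, Vc)
        ok = ~bad_cell & (ss >= eps)
        with np.errstate(divide="ignore", invalid="ignore"):
            r_chunk = num / np.sqrt(ss)
        r_chunk[~ok] = np.nan
        r_map[start:stop] = r_chunk
        valid[start:stop] = ok

    # repeated-wavelength cells are outside the search space
    idx = np.arange(B)
    if form.arity == 2:
        valid[idx, idx] = False
        r_map[idx, idx] = np.nan
    else:
        valid[idx, idx, :] = False
        valid[idx, :, idx] = False
        valid[:, idx, idx] = False
        r_map[idx, idx, :] = np.nan
        r_map[idx, :, idx] = np.nan
        r_map[:, idx, idx] = np.nan
    return CorrelationMap(form=form, wavelengths=spectra.wavelengths.copy(), r=r_map, valid=valid)


def top_candidates(cmap: CorrelationMap, fraction: float = 0.01) -> list:
    """The ceil(fraction * n_valid) combinations with largest |r|.

    Ties in |r| break toward lexicographically smallest band indices, so
    the candidate list is fully deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    flat_valid = np.nonzero(cmap.valid.ravel())[0]
    if flat_valid.size == 0:
        raise ValueError("no valid cells in the correlation map")
    absr = np.abs(cmap.r.ravel()[flat_valid])
    k = math.ceil(fraction * flat_valid.size)
    order = np.lexsort((flat_valid, -absr))[:k]
    chosen = flat_valid[order]
    wl = cmap.wavelengths
    shape = cmap.r.shape
    out = []
    for flat in chosen:
        idx = np.unravel_index(flat, shape)
        out.append(
            Candidate(
                form_name=cmap.form.name,
                bands=tuple(float(wl[i]) for i in idx),
                r_cal=float(cmap.r.ravel()[flat]),
            )
        )
    return out


def _pearson(x: np.ndarray, y: np.ndarray, eps: float = _EPS) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx < eps or sy < eps:
        return math.nan
    return float(xc @ yc) / (sx * sy)


def select_optimal(
    candidates,
    val_spectra: SpectraSet,
    val_som: np.ndarray,
    err_resolution: float = 0.01,
) -> SelectedIndex:
    """Pick the candidate with minimum |r_cal - r_val| on the validation set.

    The stability error is compared at ``err_resolution`` (default 0.01,
    the precision at which correlation coefficients are conventionally
    reported); candidates tying within one resolution bin are separated
    by larger |r_cal|, then lexicographically smallest wavelengths.
    Comparing at finite resolution matters: with tens of thousands of
    retained combinations, some mediocre candidate almost surely shows a
    freakishly small raw error, and an exact-minimum rule would degrade
    into a lottery among stable-but-weak indices.  Candidates whose index
    is undefined for any validation sample (or has no variance there) are
    dropped.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidates to select from")
    val_som = np.asarray(val_som, dtype=float).ravel()
    if val_som.size < 3:
        raise ValueError("validation set needs at least 3 samples")

    form = _resolve_form(candidates[0].form_name)
    if any(c.form_name != form.name for c in candidates):
        raise ValueError("all candidates must share one index form")
    # gather reflectance columns for all candidates at once: (n_val, n_cand)
    band_idx = np.array(
        [[val_spectra.band_index(w) for w in c.bands] for c in candidates], dtype=int
    )
    cols = [val_spectra.reflectance[:, band_idx[:, a]] for a in range(form.arity)]
    vals, bad = form.evaluate(*cols)
    vals = np.asarray(vals, dtype=float)
    defined = np.isfinite(vals).all(axis=0) & ~bad.any(axis=0)

    yc = val_som - val_som.mean()
    sy = math.sqrt(float(yc @ yc))
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        vc = vals - vals.mean(axis=0, keepdims=True)
        sx = np.sqrt(np.einsum("sc,sc->c", vc, vc))
        r_val = (yc @ vc) / (sx * sy)
    defined &= np.isfinite(r_val) & (sx >= _EPS)

    best = None
    best_key = None
    for c, ok, rv in zip(candidates, defined, r_val):
        if not ok:
            continue
        sel = SelectedIndex(c.form_name, c.bands, c.r_cal, float(rv))
        err_bin = int(round(sel.err / err_resolution))
        key = (err_bin, -abs(sel.r_cal), sel.bands)
        if best_key is None or key < best_key:
            best, best_key = sel, key
    if best is None:
        raise ValueError("all candidates were undefined on the validation set")
    return best


def select_best_index(
    form,
    cal_spectra: SpectraSet,
    cal_som: np.ndarray,
    val_spectra: SpectraSet,
    val_som: np.ndarray,
    fraction: float = 0.01,
    chunk_mb: float = 64.0,
) -> SelectedIndex:
    """Full three-step selection for one form: scan, top 1%, stability pick."""
    cmap = scan(form, cal_spectra, cal_som, chunk_mb=chunk_mb)
    cands = top_candidates(cmap, fraction=fraction)
    return select_optimal(cands, val_spectra, val_som)


@dataclass
class SliceViews:
    """Raw arrays behind the contour / slice visualizations of a map."""

    planes: dict        # axis name -> 2-D array through the optimum
    optimum_indices: tuple


def slice_views(cmap: CorrelationMap, best: SelectedIndex) -> SliceViews:
    """Orthogonal 2-D sections of a correlation map through the optimum.

    For a three-band cube, returns the x/y/z planes through the selected
    combination; for a two-band map, the map itself under key "xy".
    """
    idx = tuple(int(np.searchsorted(cmap.wavelengths, w)) for w in best.bands)
    for d, w in zip(idx, best.bands):
        if d >= cmap.wavelengths.size or not np.isclose(cmap.wavelengths[d], w):
            raise ValueError(f"selected wavelength {w} nm is not on the map grid")
    if cmap.form.arity == 2:
        return SliceViews(planes={"xy": cmap.r.copy()}, optimum_indices=idx)
    i, j, k = idx
    return SliceViews(
        planes={
            "x": cmap.r[i, :, :].copy(),
            "y": cmap.r[:, j, :].copy(),
            "z": cmap.r[:, :, k].copy(),
        },
        optimum_indices=idx,
    )
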