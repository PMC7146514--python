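"""Exhaustive index scan: oracle equivalence, symmetries, selection logic."""

import itertools

import numpy as np
import pytest

from somvnir.band_search import (
    FORMS,
    THREE_BAND_FORMS,
    TWO_BAND_FORMS,
    Candidate,
    index_values,
    scan,
    select_optimal,
    slice_views,
    top_candidates,
)
from somvnir.datatypes import SpectraSet


def _toy(n_samples=30, n_bands=6, seed=0):
    rng = np.random.default_rng(seed)
    wl = 400.0 + 50.0 * np.arange(n_bands)
    refl = rng.uniform(0.05, 0.95, size=(n_samples, n_bands))
    som = rng.uniform(0.5, 45.0, size=n_samples)
    return SpectraSet(wavelengths=wl, reflectance=refl), som


def _formula(name, cols):
    """Direct elementwise formula evaluation, independent of the package."""
    if name == "SI":
        return cols[0] + cols[1]
    if name == "DI":
        return cols[0] - cols[1]
    if name == "PI":
        return cols[0] * cols[1]
    if name == "RI":
        return cols[0] / cols[1]
    if name == "NDI":
        return (cols[0] - cols[1]) / (cols[0] + cols[1])
    if name == "TBI1":
        return cols[0] / (cols[1] + cols[2])
    if name == "TBI2":
        return (cols[0] + cols[1]) / cols[2]
    if name == "TBI3":
        return (cols[0] - cols[1]) / (cols[1] - cols[2])
    if name == "TBI4":
        return (cols[0] - cols[1]) / (cols[0] + cols[1] - 2 * cols[2])
    if name == "TBI5":
        return cols[0] + cols[1] - 2 * cols[2]
    raise KeyError(name)


def _oracle_map(name, spectra, som, eps=1e-12):
    """Naive nested-loop Pearson map; NaN where invalid."""
    arity = FORMS[name].arity
    B = spectra.n_bands
    out = np.full((B,) * arity, np.nan)
    for combo in itertools.product(range(B), repeat=arity):
        if len(set(combo)) != arity:
            continue
        cols = [spectra.reflectance[:, b] for b in combo]
        with np.errstate(divide="ignore", invalid="ignore"):
            v = _formula(name, cols)
        den_ok = True
        if name == "RI":
            den_ok = np.all(np.abs(cols[1]) >= eps)
        elif name == "NDI":
            den_ok = np.all(np.abs(cols[0] + cols[1]) >= eps)
        elif name == "TBI1":
            den_ok = np.all(np.abs(cols[1] + cols[2]) >= eps)
        elif name == "TBI2":
            den_ok = np.all(np.abs(cols[2]) >= eps)
        elif name == "TBI3":
            den_ok = np.all(np.abs(cols[1] - cols[2]) >= eps)
        elif name == "TBI4":
            den_ok = np.all(np.abs(cols[0] + cols[1] - 2 * cols[2]) >= eps)
        if not den_ok or not np.all(np.isfinite(v)):
            continue
        vc = v - v.mean()
        yc = som - som.mean()
        ss = vc @ vc
        if ss < eps:
            continue
        out[combo] = (vc @ yc) / np.sqrt(ss * (yc @ yc))
    return out


class TestIndexValues:
    def test_si_direct_formula(self):
        sp = SpectraSet(
            wavelengths=np.array([500.0, 600.0]), reflectance=np.array([[0.2, 0.3]])
        )
        np.testing.assert_allclose(index_values("SI", sp, (500.0, 600.0)), [0.5])

    def test_tbi5_algebraic_identity(self):
        rng = np.random.default_rng(2)
        ri, rj = rng.uniform(0.1, 0.9, 4), rng.uniform(0.1, 0.9, 4)
        rk = (ri + rj) / 2
        sp = SpectraSet(
            wavelengths=np.array([500.0, 600.0, 700.0]),
            reflectance=np.column_stack([ri, rj, rk]),
        )
        np.testing.assert_allclose(
            index_values("TBI5", sp, (500.0, 600.0, 700.0)), 0.0, atol=1e-15
        )

    def test_zero_denominator_flagged_nan(self):
        refl = np.array([[0.5, 0.3, 0.3], [0.5, 0.4, 0.2]])
        sp = SpectraSet(wavelengths=np.array([500.0, 600.0, 700.0]), reflectance=refl)
        vals = index_values("TBI3", sp, (500.0, 600.0, 700.0))
        assert np.isnan(vals[0]) and np.isfinite(vals[1])

    def test_repeated_wavelengths_rejected(self, toy_spectra):
        with pytest.raises(ValueError):
            index_values("DI", toy_spectra, (500.0, 500.0))

    def test_off_grid_wavelength_rejected(self, toy_spectra):
        with pytest.raises(ValueError):
            index_values("DI", toy_spectra, (500.0, 555.0))


class TestScanOracle:
    @pytest.mark.parametrize("name", TWO_BAND_FORMS + THREE_BAND_FORMS)
    def test_matches_naive_loop(self, name):
        sp, som = _toy(n_samples=30, n_bands=6, seed=3)
        got = scan(name, sp, som)
        want = _oracle_map(name, sp, som)
        np.testing.assert_array_equal(np.isnan(got.r), np.isnan(want))
        ok = ~np.isnan(want)
        np.testing.assert_allclose(got.r[ok], want[ok], rtol=0, atol=1e-12)
        assert got.valid.sum() == ok.sum()

    @pytest.mark.parametrize("name,sign", [("DI", -1), ("NDI", -1), ("SI", 1), ("PI", 1)])
    def test_symmetry(self, name, sign):
        sp, som = _toy(seed=4)
        r = scan(name, sp, som).r
        both = ~np.isnan(r) & ~np.isnan(r.T)
        np.testing.assert_allclose(r[both], sign * r.T[both], atol=1e-12)

    def test_chunked_equals_unchunked_bitwise(self):
        sp, som = _toy(n_samples=40, n_bands=12, seed=5)
        for name in ("DI", "TBI3"):
            big = scan(name, sp, som, chunk_mb=1024.0)
            tiny = scan(name, sp, som, chunk_mb=0.001)
            np.testing.assert_array_equal(big.r, tiny.r)
            np.testing.assert_array_equal(big.valid, tiny.valid)

    def test_som_scale_invariance(self):
        sp, som = _toy(seed=6)
        a = scan("NDI", sp, som).r
        b = scan("NDI", sp, 3.7 * som).r
        ok = ~np.isnan(a)
        np.testing.assert_allclose(a[ok], b[ok], atol=1e-12)

    def test_constant_som_rejected(self):
        sp, som = _toy()
        with pytest.raises(ValueError):
            scan("DI", sp, np.full(som.size, 5.0))


class TestTopCandidates:
    def test_one_percent_of_hundred_is_argmax(self):
        sp, som = _toy(n_samples=25, n_bands=11, seed=7)  # 110 valid DI cells
        cmap = scan("DI", sp, som)
        assert cmap.n_valid == 110
        cands = top_candidates(cmap, fraction=0.01)
        assert len(cands) == 2  # ceil(1.10)
        best_flat = np.nanargmax(np.abs(cmap.r))
        i, j = np.unravel_index(best_flat, cmap.r.shape)
        assert cands[0].bands == (cmap.wavelengths[i], cmap.wavelengths[j])

    def test_fraction_one_returns_all_valid(self):
        sp, som = _toy(seed=8)
        cmap = scan("NDI", sp, som)
        assert len(top_candidates(cmap, fraction=1.0)) == cmap.n_valid

    def test_matches_independent_sort(self):
        sp, som = _toy(n_samples=30, n_bands=8, seed=9)
        cmap = scan("PI", sp, som)
        cands = top_candidates(cmap, fraction=0.25)
        flat = [(abs(r), tuple(b)) for r, b in
                ((cmap.r[i, j], (cmap.wavelengths[i], cmap.wavelengths[j]))
                 for i in range(8) for j in range(8) if not np.isnan(cmap.r[i, j]))]
        flat.sort(key=lambda t: (-t[0], t[1]))
        want = [b for _, b in flat[: len(cands)]]
        assert [c.bands for c in cands] == want

    def test_bad_fraction_rejected(self):
        sp, som = _toy()
        cmap = scan("DI", sp, som)
        with pytest.raises(ValueError):
            top_candidates(cmap, fraction=0.0)


class TestSelectOptimal:
    def test_singleton_returned(self):
        sp, som = _toy(seed=10)
        cand = Candidate("DI", (450.0, 500.0), r_cal=0.5)
        sel = select_optimal([cand], sp, som)
        assert sel.bands == cand.bands and sel.r_cal == 0.5

    def test_minimum_error_wins(self):
        """Construct validation data where one candidate's r_val matches its
        r_cal almost exactly."""
        sp, som = _toy(n_samples=40, n_bands=6, seed=11)
        cmap = scan("DI", sp, som)
        cands = top_candidates(cmap, fraction=1.0)
        sel = select_optimal(cands, sp, som)  # validation = calibration
        assert sel.err <= min(
            abs(c.r_cal - c.r_cal) + 1e-12 for c in cands
        )  # err == 0 when val == cal
        assert sel.err <= 1e-12

    def test_minimality_over_retained_candidates(self):
        """The winner's stability error is minimal at the comparison
        resolution (0.01): no retained candidate beats it by a full bin."""
        cal_sp, cal_som = _toy(n_samples=40, n_bands=6, seed=12)
        val_sp, val_som = _toy(n_samples=20, n_bands=6, seed=13)
        cmap = scan("NDI", cal_sp, cal_som)
        cands = top_candidates(cmap, fraction=0.5)
        sel = select_optimal(cands, val_sp, val_som)
        for c in cands:
            v = index_values("NDI", val_sp, c.bands)
            if not np.all(np.isfinite(v)):
                continue
            r_val = np.corrcoef(v, val_som)[0, 1]
            assert round(sel.err / 0.01) <= round(abs(c.r_cal - r_val) / 0.01)

    def test_stability_tie_prefers_stronger_calibration_correlation(self):
        """Within one stability bin, larger |r_cal| wins: a freakishly
        stable weak index cannot displace a strong one."""
        sp, som = _toy(n_samples=40, n_bands=6, seed=16)
        cmap = scan("DI", sp, som)
        cands = top_candidates(cmap, fraction=1.0)
        sel = select_optimal(cands, sp, som)  # all errs ~0 -> one bin
        best_r = max(abs(c.r_cal) for c in cands)
        assert abs(sel.r_cal) == pytest.approx(best_r, abs=1e-12)

    def test_undefined_candidates_dropped(self):
        refl = np.array([[0.5, 0.3, 0.3], [0.6, 0.4, 0.2], [0.7, 0.5, 0.1], [0.4, 0.2, 0.35]])
        sp = SpectraSet(wavelengths=np.array([500.0, 600.0, 700.0]), reflectance=refl)
        som = np.array([1.0, 2.0, 3.0, 4.0])
        bad = Candidate("TBI3", (500.0, 600.0, 700.0), r_cal=0.9)  # Rj == Rk sample 0
        good = Candidate("TBI5", (500.0, 600.0, 700.0), r_cal=0.2)
        with pytest.raises(ValueError):
            select_optimal([bad], sp, som)


class TestSliceViews:
    def test_cube_slices_contain_optimum(self):
        sp, som = _toy(n_samples=30, n_bands=6, seed=14)
        cmap = scan("TBI5", sp, som)
        cands = top_candidates(cmap, fraction=0.01)
        sel = select_optimal(cands, sp, som)
        views = slice_views(cmap, sel)
        i, j, k = views.optimum_indices
        np.testing.assert_array_equal(views.planes["z"], cmap.r[:, :, k])
        best_val = cmap.r[i, j, k]
        assert any(np.nanmax(np.abs(p)) >= abs(best_val) for p in views.planes.values())
        for plane in views.planes.values():
            assert plane.shape == (6, 6)

    def test_two_band_view_is_the_map(self):
        sp, som = _toy(seed=15)
        cmap = scan("DI", sp, som)
        cands = top_candidates(cmap, fraction=0.01)
        sel = select_optimal(cands, sp, som)
        views = slice_views(cmap, sel)
        np.testing.assert_array_equal(views.planes["xy"], cmap.r)
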