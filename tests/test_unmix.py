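"""FCLS unmixing: oracle equivalence, constraint satisfaction, map recovery,
calibration arithmetic, imaging, histograms, and composition reporting."""

import numpy as np
import pytest
from scipy.optimize import minimize

from ramanmix.core import ReferenceSet, Spectrum, SpectralMap, WavenumberAxis
from ramanmix.preprocess import preprocess_map, preprocess_references
from ramanmix.synth import DEFAULT_TREATMENT_EFFECT, NoiseSpec, render_scene
from ramanmix.unmix import (
    abundance_images,
    calibrate,
    composition_report,
    concentration_histogram,
    fcls,
    fcls_pixel,
    single_band_image,
    unmix_map,
)


def qp_oracle(d, P):
    """Independent constrained solve via SLSQP on the quadratic objective."""
    k = P.shape[0]
    res = minimize(
        lambda c: np.sum((d - P.T @ c) ** 2),
        np.full(k, 1.0 / k),
        jac=lambda c: 2.0 * (P @ P.T @ c - P @ d),
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda c: c.sum() - 1.0}],
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-14},
    )
    return res.x


def simplex_grid_oracle(d, P, step=0.001):
    """Brute-force minimizer over a dense grid on the 3-simplex."""
    G = P @ P.T
    b = P @ d
    n = int(round(1.0 / step))
    c1 = np.repeat(np.arange(n + 1), np.arange(n + 1, 0, -1)) * step
    c2 = np.concatenate([np.arange(n + 1 - i) for i in range(n + 1)]) * step
    C = np.stack([c1, c2, 1.0 - c1 - c2], axis=1)
    obj = np.einsum("ij,jk,ik->i", C, G, C) - 2.0 * C @ b
    return C[np.argmin(obj)]


class TestFclsPixel:
    def test_pure_pixel_gives_one_hot(self, refs):
        for j, name in enumerate(refs.names):
            c, r = fcls(refs.spectra[j], refs.spectra)
            expected = np.zeros(refs.k)
            expected[j] = 1.0
            np.testing.assert_allclose(c, expected, atol=1e-9)
            assert r == pytest.approx(0.0, abs=1e-9)

    def test_single_component_forced_to_one(self, refs):
        P = ReferenceSet(refs.axis, ["cellulose"], refs.spectra[:1])
        s = Spectrum(refs.axis, np.zeros(len(refs.axis)))
        c, _ = fcls_pixel(s, P)
        np.testing.assert_array_equal(c, [1.0])

    def test_noiseless_mix_matches_both_oracles(self, refs):
        d = np.array([0.3, 0.5, 0.2]) @ refs.spectra
        c, r = fcls(d, refs.spectra)
        np.testing.assert_allclose(c, [0.3, 0.5, 0.2], atol=1e-10)
        grid = simplex_grid_oracle(d, refs.spectra)
        assert np.max(np.abs(c - grid)) <= 2e-3
        qp = qp_oracle(d, refs.spectra)
        assert np.max(np.abs(c - qp)) <= 1e-6

    def test_matches_qp_oracle_on_random_instances(self, rng):
        """FCLS vs an independent QP solve on random (d, P) pairs with
        active non-negativity constraints."""
        L = 60
        worst = 0.0
        for _ in range(60):
            k = int(rng.integers(2, 5))
            P = rng.random((k, L))
            d = rng.random(L)
            c, _ = fcls(d, P)
            assert c.min() >= -1e-12
            assert c.sum() == pytest.approx(1.0, abs=1e-9)
            worst = max(worst, float(np.max(np.abs(c - qp_oracle(d, P)))))
        assert worst <= 1e-6

    def test_objective_dominates_simplex_vertices(self, rng):
        """The FCLS objective can never exceed the best pure-component fit."""
        L = 80
        for _ in range(20):
            k = int(rng.integers(2, 5))
            P = rng.random((k, L))
            d = rng.random(L)
            c, r = fcls(d, P)
            vertex_best = min(np.linalg.norm(d - P[j]) for j in range(k))
            assert r <= vertex_best + 1e-12

    def test_more_components_than_bands_rejected(self):
        with pytest.raises(ValueError, match="more components"):
            fcls(np.ones(2), np.ones((3, 2)))

    def test_rank_deficient_references_warn(self):
        P = np.vstack([np.linspace(0, 1, 50), np.linspace(0, 1, 50)])
        with pytest.warns(UserWarning, match="rank-deficient"):
            c, _ = fcls(np.linspace(0, 1, 50), P)
        assert c.sum() == pytest.approx(1.0)

    def test_axis_mismatch_rejected(self, refs):
        other = WavenumberAxis(np.linspace(600, 3000, 500))
        s = Spectrum(other, np.ones(500))
        with pytest.raises(ValueError, match="different axes"):
            fcls_pixel(s, refs)


class TestUnmixMap:
    def test_zero_nuisance_scene_recovered_exactly(self, clean_tile_scene, refs):
        res = unmix_map(clean_tile_scene.map, refs)
        fg = clean_tile_scene.map.mask
        err = np.abs(res.abundance[fg] - clean_tile_scene.truth_abundance[fg])
        assert err.mean() <= 1e-8

    def test_abundance_rows_satisfy_constraints(self, clean_tile_scene, refs):
        res = unmix_map(clean_tile_scene.map, refs)
        fg = res.mask
        assert np.all(res.abundance[fg] >= -1e-12)
        np.testing.assert_allclose(res.abundance[fg].sum(axis=1), 1.0, atol=1e-9)
        assert np.isnan(res.abundance[~fg]).all()

    def test_noisy_scene_recovered_after_preprocessing(self, noisy_cells_scene, refs):
        scene = noisy_cells_scene
        pp = preprocess_map(scene.map)
        res = unmix_map(pp, preprocess_references(refs))
        sel = res.mask & scene.map.mask
        err = np.abs(res.abundance[sel] - scene.truth_abundance[sel])
        assert err.mean() <= 0.05

    def test_recovery_error_decreases_with_noise(self, refs):
        """Abundance error shrinks monotonically (to small slack) as the
        Gaussian noise level drops."""
        errors = []
        for sd in (0.05, 0.02, 0.01, 0.0):
            scene = render_scene("cells", (20, 20),
                                 noise=NoiseSpec(sd, 0.0, 0.0, 1.0), seed=17)
            pp = preprocess_map(scene.map)
            res = unmix_map(pp, preprocess_references(refs))
            sel = res.mask & scene.map.mask
            errors.append(
                float(np.mean(np.abs(res.abundance[sel] - scene.truth_abundance[sel])))
            )
        assert all(errors[i] >= errors[i + 1] - 5e-3 for i in range(3))

    def test_all_background_map_is_vacuous(self, refs):
        ax = refs.axis
        m = SpectralMap(ax, 3, 2, np.full((6, len(ax)), 0.02),
                        mask=np.zeros(6, dtype=bool))
        res = unmix_map(m, refs)
        assert np.isnan(res.abundance).all()
        assert res.foreground_abundance().shape == (0, 3)

    def test_axis_mismatch_requires_resampling(self, refs, clean_tile_scene):
        sub = WavenumberAxis(refs.axis.values[::2])
        refs_sub = ReferenceSet(sub, refs.names, refs.spectra[:, ::2])
        with pytest.raises(ValueError, match="resample"):
            unmix_map(clean_tile_scene.map, refs_sub)

    def test_residual_flagging_keeps_pixels(self, noisy_cells_scene, refs):
        res = unmix_map(noisy_cells_scene.map, refs)
        flagged = res.flagged_pixels(0.99)
        assert flagged.size <= int(res.mask.sum() * 0.02) + 1
        assert np.isfinite(res.abundance[flagged]).all()


class TestCalibration:
    def test_unit_total_is_identity(self, clean_tile_scene, refs):
        res = calibrate(unmix_map(clean_tile_scene.map, refs), 1.0)
        np.testing.assert_array_equal(res.calibrated, res.abundance)

    def test_concentration_arithmetic(self):
        res_row = np.array([[0.5, 0.3, 0.2]])
        from ramanmix.unmix import AbundanceResult

        res = AbundanceResult(["c", "h", "l"], res_row, np.zeros(1),
                              np.ones(1, bool), 1, 1)
        out = calibrate(res, 77.2)
        np.testing.assert_allclose(out.calibrated, [[38.6, 23.16, 15.44]])

    def test_calibrated_rows_sum_to_total(self, clean_tile_scene, refs):
        res = calibrate(unmix_map(clean_tile_scene.map, refs), 77.2)
        fg = res.mask
        np.testing.assert_allclose(res.calibrated[fg].sum(axis=1), 77.2, atol=1e-6)

    def test_nonpositive_total_rejected(self, clean_tile_scene, refs):
        res = unmix_map(clean_tile_scene.map, refs)
        with pytest.raises(ValueError, match="W"):
            calibrate(res, 0.0)


class TestImaging:
    def test_constant_map_gives_constant_image(self, refs):
        ax = refs.axis
        m = SpectralMap(ax, 4, 3, np.full((12, len(ax)), 1.5))
        img = single_band_image(m, 1089.0)
        np.testing.assert_allclose(img.grid, 1.5)

    def test_masked_pixels_absent(self, refs):
        ax = refs.axis
        mask = np.array([True, False, True, True])
        m = SpectralMap(ax, 2, 2, np.ones((4, len(ax))), mask=mask)
        img = single_band_image(m, 1089.0)
        assert np.isnan(img.grid.reshape(-1)[1])
        assert np.isfinite(np.delete(img.grid.reshape(-1), 1)).all()

    def test_out_of_axis_band_rejected(self, clean_tile_scene):
        with pytest.raises(Exception, match="outside axis"):
            single_band_image(clean_tile_scene.map, 100.0)

    def test_shared_fluorescence_artifact_reproduced(self, refs):
        """Strong shared fluorescence makes the 1089/1620 single-band images
        spuriously similar, while FCLS images recover the true (anti-)
        correlation of cellulose and lignin."""
        scene = render_scene("cells", (40, 50),
                             noise=NoiseSpec(0.02, 0.02, 10.0, 3.0), seed=5)

        def corr(a, b):
            m = np.isfinite(a) & np.isfinite(b)
            return np.corrcoef(a[m], b[m])[0, 1]

        sb = corr(single_band_image(scene.map, 1089.0).grid,
                  single_band_image(scene.map, 1620.0).grid)
        pp = preprocess_map(scene.map)
        res = unmix_map(pp, preprocess_references(refs))
        imgs = {i.component: i.grid for i in abundance_images(res, calibrated=False)}
        fc = corr(imgs["cellulose"], imgs["lignin"])
        assert sb > fc

    def test_histogram_conserves_pixel_counts(self, clean_tile_scene, refs):
        res = calibrate(unmix_map(clean_tile_scene.map, refs), 77.2)
        images = abundance_images(res)
        hist = concentration_histogram(images, bins=15)
        n_fg = int(res.mask.sum())
        for name in res.names:
            assert hist.loc[hist.component == name, "count"].sum() == n_fg

    def test_single_pixel_histogram(self, refs):
        from ramanmix.unmix import ChemicalImage

        img = ChemicalImage("cellulose", np.array([[0.7]]), "fraction")
        hist = concentration_histogram([img], bins=5)
        assert hist["count"].sum() == 1
        row = hist[hist["count"] == 1].iloc[0]
        assert row.bin_left <= 0.7 <= row.bin_right

    def test_treated_scene_histograms_shift_left(self, refs):
        """Calibrated concentration distributions move to lower values for
        every component after the treatment effect + lower total content."""
        kw = dict(layout="cells", shape=(30, 30),
                  noise=NoiseSpec(0.01, 0.0, 0.0, 1.0), seed=19)
        untreated = render_scene(**kw)
        treated = render_scene(**kw, effect=DEFAULT_TREATMENT_EFFECT)
        means = {}
        for tag, scene, W in (("u", untreated, 77.2), ("t", treated, 53.4)):
            pp = preprocess_map(scene.map)
            res = calibrate(unmix_map(pp, preprocess_references(refs)), W)
            for img in abundance_images(res):
                means[(tag, img.component)] = np.nanmean(img.grid)
        for comp in refs.names:
            assert means[("t", comp)] < means[("u", comp)]


class TestCompositionReport:
    def test_no_change_gives_zero_reductions(self):
        state = {"cellulose": 39.5, "hemicellulose": 33.2, "lignin": 4.5}
        rep = composition_report(state, dict(state))
        for comp in rep["components"].values():
            assert comp["reduction_pct"] == 0

    def test_measured_composition_reductions(self):
        """Dry-base wet-chemistry contents: hemicellulose falls 53%,
        cellulose 13%; lignin's raw reduction is 24.4% (prints as 24 under
        nearest-integer rounding)."""
        rep = composition_report(
            {"cellulose": 39.5, "hemicellulose": 33.2, "lignin": 4.5},
            {"cellulose": 34.4, "hemicellulose": 15.6, "lignin": 3.4},
        )
        assert rep["components"]["hemicellulose"]["reduction_pct"] == 53
        assert rep["components"]["cellulose"]["reduction_pct"] == 13
        assert rep["components"]["lignin"]["reduction_pct_raw"] == pytest.approx(
            24.444, abs=0.01
        )
        assert rep["total_before"] == pytest.approx(77.2)
        assert rep["total_after"] == pytest.approx(53.4)

    def test_gas_yield_change(self):
        rep = composition_report({"x": 1.0}, {"x": 1.0}, gas=(126.30, 236.35))
        assert rep["gas_yield_change_pct"] == 87.1

    def test_mismatched_components_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            composition_report({"a": 1.0}, {"b": 1.0})
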