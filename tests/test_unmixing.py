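import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.linalg import lstsq

from hsikit.cubes import AttenuationCube, ROISpec, SpectralGrid
from hsikit.unmixing import (
    ExtinctionLibrary,
    MBLLUnmixer,
    UnmixingConfig,
    delta_attenuation,
    derived_maps,
    fov_summary,
    unmix_cube,
    unmix_pixel,
)


def _forward(lib, c_by_name, offset=0.0):
    """Noiseless ΔA = E c + offset on the library's full grid."""
    spectrum = np.full(len(lib.grid), float(offset))
    for name, c in c_by_name.items():
        spectrum = spectrum + lib.epsilon[name] * c
    return spectrum


def _oracle(lib, cfg, y):
    """Independent unconstrained normal-equations solve on the window."""
    mask = lib.grid.window_slice(*cfg.window)
    E = lib.design_matrix(mask, cfg.include_offset)
    coef = np.linalg.solve(E.T @ E, E.T @ y[mask])
    return coef


class TestDeltaAttenuation:
    def test_own_spectrum_reference_gives_zero(self, tissue_case):
        att = tissue_case["att"]
        ref = att.values[3, 4, :]
        da = delta_attenuation(att, ref)
        np.testing.assert_allclose(da.values[3, 4, :], 0.0, atol=1e-12)

    def test_zero_reference_is_identity(self, tissue_case):
        att = tissue_case["att"]
        da = delta_attenuation(att, np.zeros(len(att.grid)))
        np.testing.assert_array_equal(da.values, att.values)

    def test_single_band_perturbation(self, library):
        grid = library.grid
        ref = np.full(len(grid), 0.5)
        values = np.broadcast_to(ref, (2, 2, len(grid))).copy()
        values[:, :, 40] += 0.3
        da = delta_attenuation(AttenuationCube(values.copy(), grid), ref)
        np.testing.assert_allclose(da.values[:, :, 40], 0.3)
        other = np.delete(da.values, 40, axis=2)
        np.testing.assert_allclose(other, 0.0, atol=1e-12)

    def test_grid_mismatch_raises(self, tissue_case):
        with pytest.raises(ValueError):
            delta_attenuation(tissue_case["att"], np.zeros(5))


class TestUnmixPixel:
    def test_zero_spectrum_gives_zero_everything(self, library):
        dc, offset, resid = unmix_pixel(np.zeros(len(library.grid)), library)
        np.testing.assert_allclose(dc, 0.0, atol=1e-12)
        assert offset == pytest.approx(0.0, abs=1e-12)
        assert resid == pytest.approx(0.0, abs=1e-12)

    def test_forward_construction_recovers_truth(self, library):
        c_true = {"HbO2": 1.5, "HHb": -0.7, "oxCCO": 0.4, "redCCO": 0.9,
                  "oxCyt_b": -0.2, "redCyt_b": 0.3, "oxCyt_c": 0.6,
                  "redCyt_c": -0.5, "water": 0.8, "lipid": 0.1}
        y = _forward(library, c_true, offset=0.05)
        dc, offset, resid = unmix_pixel(y, library)
        expected = np.array([c_true[n] for n in library.chromophores])
        np.testing.assert_allclose(dc, expected, atol=1e-8)
        assert offset == pytest.approx(0.05, abs=1e-8)
        assert resid < 1e-10
        # agree with the independent normal-equations oracle
        oracle = _oracle(library, UnmixingConfig(), y)
        np.testing.assert_allclose(dc, oracle[:-1], atol=1e-8)

    def test_single_chromophore_scalar_least_squares(self, library):
        solo = library.subset(["HbO2"])
        y = solo.epsilon["HbO2"] * 2.0
        dc, offset, _ = unmix_pixel(y, solo, UnmixingConfig(include_offset=False))
        assert dc[0] == pytest.approx(2.0, abs=1e-10)

    @settings(max_examples=20, derandomize=True)
    @given(alpha=st.floats(-5.0, 5.0))
    def test_linearity_when_bounds_inactive(self, alpha, library):
        c_true = {"HbO2": 0.8, "HHb": 0.3, "water": 0.5}
        sub = library.subset(list(c_true))
        y = _forward(sub, c_true)
        dc1, _, _ = unmix_pixel(y, sub)
        dc2, _, _ = unmix_pixel(alpha * y, sub)
        np.testing.assert_allclose(dc2, alpha * dc1, atol=1e-8)

    def test_active_box_bounds_are_respected(self, library):
        sub = library.subset(["HbO2"])
        y = sub.epsilon["HbO2"] * 5.0
        cfg = UnmixingConfig(include_offset=False, bounds={"HbO2": (0.0, 2.0)})
        dc, _, resid = unmix_pixel(y, sub, cfg)
        assert dc[0] == pytest.approx(2.0, abs=1e-8)
        assert resid > 0

    def test_collinear_design_matrix_raises(self, library):
        grid = library.grid
        eps = library.epsilon["HbO2"]
        twin = ExtinctionLibrary(grid, {"a": eps, "b": 2.0 * eps})
        with pytest.raises(ValueError, match="rank-deficient"):
            unmix_pixel(np.zeros(len(grid)), twin)

    def test_too_few_bands_raises(self, library):
        cfg = UnmixingConfig(window=(500.0, 530.0))
        with pytest.raises(ValueError, match="fewer bands"):
            unmix_pixel(np.zeros(len(library.grid)), library, cfg)


class TestUnmixCube:
    def test_homogeneous_cube_self_reference_gives_zero(self, library):
        grid = library.grid
        att = AttenuationCube(np.full((8, 8, len(grid)), 0.7), grid)
        res = unmix_cube(att, library)
        for cmap in res.delta_c.values():
            np.testing.assert_allclose(cmap, 0.0, atol=1e-10)

    def test_two_region_scene_recovers_contrast(self, library):
        names = ("HbO2", "HHb")
        sub = library.subset(names)
        grid = sub.grid
        base = np.full(len(grid), 0.3)
        values = np.broadcast_to(base, (6, 6, len(grid))).copy()
        # right half carries extra chromophore load
        values[:, 3:, :] += 1.2 * sub.epsilon["HbO2"] + 0.5 * sub.epsilon["HHb"]
        att = AttenuationCube(values, grid)
        res = unmix_cube(att, sub, reference=base)
        assert res.delta_c["HbO2"][:, 3:].mean() == pytest.approx(1.2, abs=1e-8)
        assert res.delta_c["HbO2"][:, :3].mean() == pytest.approx(0.0, abs=1e-8)
        assert res.delta_c["HHb"][:, 3:].mean() == pytest.approx(0.5, abs=1e-8)

    def test_matches_per_pixel_oracle_on_random_pixels(self, tissue_case):
        att, lib = tissue_case["att"], tissue_case["lib"]
        cfg = UnmixingConfig()
        ref = tissue_case["background"]
        res = unmix_cube(att, lib, cfg, reference=ref)
        rng = np.random.default_rng(19)
        rows, cols, _ = att.shape
        for _ in range(10):
            r, c = rng.integers(rows), rng.integers(cols)
            y = att.values[r, c, :] - ref
            oracle = _oracle(lib, cfg, y)
            got = np.array([res.delta_c[n][r, c] for n in lib.chromophores])
            np.testing.assert_allclose(got, oracle[:-1], atol=1e-6)

    def test_noiseless_tissue_recovery(self, tissue_case):
        res = unmix_cube(tissue_case["att"], tissue_case["lib"],
                         reference=tissue_case["background"])
        for name, truth in tissue_case["fields"].items():
            err = np.abs(res.delta_c[name] - truth).max()
            assert err <= 1e-6 * np.linalg.norm(truth)

    def test_restricting_library_never_hurts_residual(self, library):
        """On noiseless input from 2 chromophores, adding extra columns
        cannot beat the generating subset's (zero) residual."""
        gen = library.subset(["HbO2", "water"])
        y = _forward(gen, {"HbO2": 1.0, "water": 0.4})
        grid = library.grid
        att = AttenuationCube(np.broadcast_to(y, (2, 2, len(grid))).copy(), grid)
        res_gen = unmix_cube(att, gen, reference=np.zeros(len(grid)))
        res_all = unmix_cube(att, library.subset(["HbO2", "water", "oxCCO", "lipid"]),
                             reference=np.zeros(len(grid)))
        assert res_gen.residual_map.max() <= res_all.residual_map.max() + 1e-12


class TestNoisyRecovery:
    def test_unbiased_and_rmse_shrinks_with_window(self, library):
        """1% Gaussian spectral noise: near-zero per-chromophore bias over
        200 seeded repeats, and wider fit windows give lower RMSE."""
        names = ("HbO2", "HHb", "oxCCO", "redCCO")
        sub = library.subset(names)
        c_true = np.array([1.0, 0.6, 0.4, 0.8])
        y0 = sum(sub.epsilon[n] * c for n, c in zip(names, c_true))
        sigma = 0.01 * np.abs(y0).max()
        rng = np.random.default_rng(23)
        windows = [(550.0, 850.0), (525.0, 875.0), (500.0, 900.0)]
        errors = {w: [] for w in windows}
        for _ in range(200):
            y = y0 + rng.normal(0.0, sigma, y0.shape)
            for w in windows:
                dc, _, _ = unmix_pixel(y, sub, UnmixingConfig(window=w))
                errors[w].append(dc - c_true)
        rmse = []
        for w in windows:
            e = np.asarray(errors[w])
            bias = e.mean(axis=0)
            mc_err = e.std(axis=0) / np.sqrt(len(e))
            assert np.all(np.abs(bias) < 4 * mc_err + 1e-3)
            rmse.append(float(np.sqrt((e**2).mean())))
        assert rmse[0] > rmse[1] > rmse[2]


class TestDerivedAndSummary:
    def test_hbt_sum(self, tissue_case):
        res = unmix_cube(tissue_case["att"], tissue_case["lib"],
                         reference=tissue_case["background"])
        maps = derived_maps(res)
        np.testing.assert_allclose(maps["HbT"],
                                   res.delta_c["HbO2"] + res.delta_c["HHb"])
        np.testing.assert_allclose(maps["DiffCCO"],
                                   res.delta_c["oxCCO"] - res.delta_c["redCCO"])
        # and against the simulated fields in closed form
        f = tissue_case["fields"]
        np.testing.assert_allclose(maps["HbT"], f["HbO2"] + f["HHb"], atol=1e-6)

    def test_equal_cco_forms_cancel(self, library):
        names = ("HbO2", "HHb", "oxCCO", "redCCO")
        sub = library.subset(names)
        grid = sub.grid
        y = _forward(sub, {"oxCCO": 0.7, "redCCO": 0.7})
        att = AttenuationCube(np.broadcast_to(y, (2, 2, len(grid))).copy(), grid)
        res = unmix_cube(att, sub, reference=np.zeros(len(grid)))
        np.testing.assert_allclose(derived_maps(res)["DiffCCO"], 0.0, atol=1e-8)

    def test_missing_chromophore_raises(self, library):
        sub = library.subset(["HbO2", "HHb"])
        grid = sub.grid
        att = AttenuationCube(np.zeros((2, 2, len(grid))), grid)
        res = unmix_cube(att, sub, reference=np.zeros(len(grid)))
        with pytest.raises(KeyError):
            derived_maps(res)

    def test_summary_means_and_order_invariance(self, tissue_case):
        res = unmix_cube(tissue_case["att"], tissue_case["lib"],
                         reference=tissue_case["background"])
        rec = fov_summary(res, "s1", "fov0")
        assert rec["sample_id"] == "s1" and rec["fov_id"] == "fov0"
        assert rec["HbO2"] == pytest.approx(res.delta_c["HbO2"].mean(), abs=1e-10)
        # permuting pixels jointly leaves every mean unchanged
        rng = np.random.default_rng(2)
        perm = rng.permutation(res.flag_map.size)
        import copy

        res2 = copy.deepcopy(res)
        for name in res2.delta_c:
            flat = res2.delta_c[name].ravel()[perm]
            res2.delta_c[name] = flat.reshape(res.delta_c[name].shape)
        res2.flag_map = res2.flag_map.ravel()[perm].reshape(res2.flag_map.shape)
        res2.residual_map = res2.residual_map.ravel()[perm].reshape(res2.residual_map.shape)
        rec2 = fov_summary(res2, "s1", "fov0")
        for name in tissue_case["lib"].chromophores:
            assert rec2[name] == pytest.approx(rec[name], abs=1e-12)

    def test_flagged_pixels_excluded(self, library):
        sub = library.subset(["HbO2"])
        grid = sub.grid
        att = AttenuationCube(np.zeros((2, 2, len(grid))), grid)
        res = unmix_cube(att, sub, reference=np.zeros(len(grid)))
        res.delta_c["HbO2"][0, 0] = 99.0
        res.flag_map[0, 0] = True
        rec = fov_summary(res, "s", "f")
        assert rec["HbO2"] == pytest.approx(0.0, abs=1e-10)
        assert rec["n_pixels"] == 3

    def test_all_flagged_raises(self, library):
        sub = library.subset(["HbO2"])
        grid = sub.grid
        att = AttenuationCube(np.zeros((2, 2, len(grid))), grid)
        res = unmix_cube(att, sub, reference=np.zeros(len(grid)))
        res.flag_map[:] = True
        with pytest.raises(ValueError):
            fov_summary(res, "s", "f")

    def test_two_fovs_share_sample_id(self, tissue_case):
        res = unmix_cube(tissue_case["att"], tissue_case["lib"],
                         reference=tissue_case["background"])
        recs = [fov_summary(res, "sampleA", f"fov{i}") for i in range(2)]
        assert {r["sample_id"] for r in recs} == {"sampleA"}
        assert recs[0]["fov_id"] != recs[1]["fov_id"]


class TestEstimator:
    def test_fit_freezes_reference_across_fovs(self, tissue_case):
        att, lib = tissue_case["att"], tissue_case["lib"]
        est = MBLLUnmixer(library=lib).fit(att, reference=tissue_case["background"])
        res = est.transform(att)
        direct = unmix_cube(att, lib, reference=tissue_case["background"])
        for name in lib.chromophores:
            np.testing.assert_array_equal(res.delta_c[name], direct.delta_c[name])

    def test_default_reference_is_central_roi(self, tissue_case):
        att, lib = tissue_case["att"], tissue_case["lib"]
        est = MBLLUnmixer(library=lib).fit(att)
        from hsikit.cubes import roi_mean_spectrum

        expected = roi_mean_spectrum(att, ROISpec.centered(att.shape))
        np.testing.assert_allclose(est.reference_spectrum_, expected)

    def test_sklearn_param_interface(self, library):
        est = MBLLUnmixer(library=library, window=(520.0, 880.0))
        assert est.get_params()["window"] == (520.0, 880.0)
        est.set_params(include_offset=False)
        assert est._config().include_offset is False
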