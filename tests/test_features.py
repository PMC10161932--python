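"""Vegetation indices, GLCM texture statistics, scenario assembly."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from peafuse.errors import BandError, ContractError
from peafuse.features import (
    COMMON_VIS,
    GLCMParams,
    VI_REGISTRY,
    available_vis,
    build_scenario,
    compute_vi,
    glcm_features,
    plot_spectral_features,
    plot_texture_features,
)
from peafuse.raster import Band, PlotMap, PlotRecord, Scene
from peafuse.segment import VegetationMask
from peafuse.simulate import SATELLITE_BANDS, UAS_BANDS


def _uniform_scene(band_values: dict, shape=(4, 4)):
    bands = []
    planes = []
    wavelengths = {"blue": 475, "green": 560, "yellow": 605, "red": 668,
                   "red_edge": 717, "nir": 842, "nir2": 950}
    for name, val in band_values.items():
        bands.append(Band(name, wavelengths[name]))
        planes.append(np.full(shape, float(val)))
    return Scene(np.stack(planes, axis=2), tuple(bands), 1.0)


class TestRegistry:
    def test_registry_holds_the_eleven_indices(self):
        assert set(VI_REGISTRY) == {
            "NDVI", "GNDVI", "NDREI", "SAVI", "ARVI", "TVI",
            "IPVI", "RDVI", "EVI2", "NDRE2", "NDVI2",
        }

    def test_common_count_per_sensor(self):
        uas = _uniform_scene({b.name: 0.3 for b in UAS_BANDS})
        sat = _uniform_scene({b.name: 0.3 for b in SATELLITE_BANDS})
        assert available_vis(uas) == list(COMMON_VIS)
        assert len(available_vis(uas)) == 9
        assert len(available_vis(sat)) == 11


class TestVIFormulas:
    def test_symmetry_identities(self):
        scene = _uniform_scene({"nir": 0.4, "red": 0.4})
        np.testing.assert_allclose(compute_vi(scene, "NDVI"), 0.0, atol=1e-15)
        np.testing.assert_allclose(compute_vi(scene, "IPVI"), 0.5, rtol=1e-12)

    def test_hand_arithmetic(self):
        scene = _uniform_scene({"nir": 0.5, "red": 0.1, "blue": 0.08,
                                "green": 0.2, "red_edge": 0.3})
        np.testing.assert_allclose(compute_vi(scene, "NDVI"), 0.4 / 0.6, rtol=1e-12)
        np.testing.assert_allclose(
            compute_vi(scene, "EVI2"), 2.5 * 0.4 / (0.5 + 2.4 * 0.1 + 1.0), rtol=1e-12
        )
        np.testing.assert_allclose(
            compute_vi(scene, "SAVI"), 1.5 * 0.4 / 1.1, rtol=1e-12
        )
        np.testing.assert_allclose(
            compute_vi(scene, "TVI"), np.sqrt(0.5 + 0.4 / 0.6), rtol=1e-12
        )
        rb = 2 * 0.1 - 0.08
        np.testing.assert_allclose(
            compute_vi(scene, "ARVI"), (0.5 - rb) / (0.5 + rb), rtol=1e-12
        )
        np.testing.assert_allclose(
            compute_vi(scene, "RDVI"), 0.4 / np.sqrt(0.6), rtol=1e-12
        )

    def test_satellite_only_indices(self):
        scene = _uniform_scene({"nir": 0.5, "yellow": 0.2, "nir2": 0.45, "red": 0.1})
        np.testing.assert_allclose(compute_vi(scene, "NDRE2"), 0.3 / 0.7, rtol=1e-12)
        np.testing.assert_allclose(compute_vi(scene, "NDVI2"), 0.35 / 0.55, rtol=1e-12)
        with pytest.raises(BandError):
            compute_vi(_uniform_scene({b.name: 0.3 for b in UAS_BANDS}), "NDRE2")

    def test_zero_denominator_gives_nan(self):
        scene = _uniform_scene({"nir": 0.0, "red": 0.0})
        assert np.isnan(compute_vi(scene, "NDVI")).all()

    def test_normalized_difference_range(self, rng):
        planes = rng.uniform(0.0, 1.0, size=(16, 16, 5))
        scene = Scene(planes, UAS_BANDS, 1.0)
        for name in ("NDVI", "GNDVI", "NDREI"):
            vi = compute_vi(scene, name)
            assert np.nanmin(vi) >= -1.0 and np.nanmax(vi) <= 1.0
        ipvi = compute_vi(scene, "IPVI")
        assert np.nanmin(ipvi) >= 0.0 and np.nanmax(ipvi) <= 1.0


class TestPlotMedians:
    def _setup(self, pixel_values):
        n = len(pixel_values)
        values = np.zeros((1, n, 2))
        values[0, :, 0] = 0.1  # red
        nir = 0.1 * (1 + np.asarray(pixel_values)) / (1 - np.asarray(pixel_values))
        values[0, :, 1] = nir  # chosen so NDVI equals pixel_values
        scene = Scene(values, (Band("red", 668.0), Band("nir", 842.0)), 1.0)
        plots = PlotMap([PlotRecord("P1", "E1", 1, box(0, 0, n, 1), 1.0)])
        return scene, plots

    def test_odd_median(self):
        scene, plots = self._setup([0.1, 0.2, 0.3])
        out = plot_spectral_features(scene, plots, vis=["NDVI"], source="UAS", timepoint="TP1")
        assert out.loc["P1", "NDVI_UAS_TP1"] == pytest.approx(0.2)

    def test_even_median_mid_mean(self):
        scene, plots = self._setup([0.1, 0.2, 0.3, 0.4])
        out = plot_spectral_features(scene, plots, vis=["NDVI"], source="UAS", timepoint="TP1")
        assert out.loc["P1", "NDVI_UAS_TP1"] == pytest.approx(0.25)

    def test_against_sort_oracle(self, fine_scene, small_plots):
        from peafuse.raster import extract_plot_pixels

        out = plot_spectral_features(fine_scene, small_plots, vis=["NDVI"], source="UAS", timepoint="TP2")
        ndvi = compute_vi(fine_scene, "NDVI")
        px = extract_plot_pixels(fine_scene, small_plots)
        for rec in small_plots:
            vals = np.sort(ndvi[px[rec.plot_id].rows, px[rec.plot_id].cols])
            n = vals.size
            oracle = vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
            assert out.loc[rec.plot_id, "NDVI_UAS_TP2"] == pytest.approx(oracle)

    def test_empty_mask_gives_nan(self):
        scene, _ = self._setup([0.1, 0.2, 0.3])
        plots = PlotMap([
            PlotRecord("P1", "E1", 1, box(0, 0, 1, 1), 1.0),   # masked out
            PlotRecord("P2", "E2", 1, box(1, 0, 3, 1), 1.0),
        ])
        mask = np.array([[False, True, True]])
        out = plot_spectral_features(scene, plots, mask, vis=["NDVI"], source="UAS", timepoint="TP1")
        assert np.isnan(out.loc["P1", "NDVI_UAS_TP1"])
        assert np.isfinite(out.loc["P2", "NDVI_UAS_TP1"])

    def test_all_plots_empty_is_pipeline_error(self):
        from peafuse.errors import PipelineError

        scene, plots = self._setup([0.1, 0.2, 0.3])
        mask = VegetationMask(np.zeros((1, 3), dtype=bool), rule="value", threshold=9.9)
        with pytest.raises(PipelineError):
            plot_spectral_features(scene, plots, mask, vis=["NDVI"])


class TestGLCM:
    def test_constant_window_degenerate(self):
        out = glcm_features(np.full((4, 4), 0.7))
        assert out == {"CO": 0.0, "HO": 1.0, "CR": 0.0, "EN": 1.0}

    def test_checkerboard_horizontal(self):
        # 2×2 checkerboard, distance 1, angle 0°, symmetric: both horizontal
        # pairs discordant -> CO = 1, HO = 0.5, EN = Σp² = 0.5
        window = np.array([[0.0, 1.0], [1.0, 0.0]])
        params = GLCMParams(levels=2, angles_deg=(0.0,))
        out = glcm_features(window, params)
        assert out["CO"] == pytest.approx(1.0)
        assert out["HO"] == pytest.approx(0.5)
        assert out["EN"] == pytest.approx(0.5)

    def test_brute_force_cooccurrence_oracle(self, rng):
        window = rng.uniform(size=(4, 4))
        levels = 4
        q = np.clip(np.floor((window - window.min()) / (window.max() - window.min()) * levels),
                    0, levels - 1).astype(int)
        # brute-force symmetric normalized co-occurrence at distance 1, 0°
        P = np.zeros((levels, levels))
        for i in range(4):
            for j in range(3):
                a, b = q[i, j], q[i, j + 1]
                P[a, b] += 1
                P[b, a] += 1
        P /= P.sum()
        ii, jj = np.meshgrid(range(levels), range(levels), indexing="ij")
        co = float((P * (ii - jj) ** 2).sum())
        ho = float((P / (1 + (ii - jj) ** 2)).sum())
        en = float((P**2).sum())
        mu_i = float((P * ii).sum())
        mu_j = float((P * jj).sum())
        sd_i = np.sqrt(float((P * (ii - mu_i) ** 2).sum()))
        sd_j = np.sqrt(float((P * (jj - mu_j) ** 2).sum()))
        cr = float((P * (ii - mu_i) * (jj - mu_j)).sum()) / (sd_i * sd_j)
        out = glcm_features(window, GLCMParams(levels=levels, angles_deg=(0.0,)))
        assert out["CO"] == pytest.approx(co, rel=1e-10)
        assert out["HO"] == pytest.approx(ho, rel=1e-10)
        assert out["EN"] == pytest.approx(en, rel=1e-10)
        assert out["CR"] == pytest.approx(cr, rel=1e-10)

    def test_affine_rescaling_invariance(self, rng):
        window = rng.uniform(size=(6, 6))
        a = glcm_features(window)
        b = glcm_features(3.7 * window + 0.2)
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-10)

    def test_window_too_small_rejected(self):
        with pytest.raises(ContractError):
            glcm_features(np.ones((1, 5)))


class TestScenarios:
    def _table(self, plot_ids, cols, fill=0.5):
        return pd.DataFrame(
            fill, index=pd.Index(plot_ids, name="plot_id"), columns=cols
        )

    def test_fusion_scenario_column_counts(self):
        plots = [f"P{i}" for i in range(10)]
        uas_tp1 = self._table(plots, [f"{v}_UAS_TP1" for v in COMMON_VIS])
        sat_tp2 = self._table(plots, [f"{v}_SAT_TP2" for v in COMMON_VIS])
        assert build_scenario([uas_tp1, sat_tp2]).shape[1] == 18
        uas_tp2 = self._table(plots, [f"{v}_UAS_TP2" for v in COMMON_VIS])
        sat_tp1 = self._table(plots, [f"{v}_SAT_TP1" for v in COMMON_VIS])
        both = build_scenario([uas_tp1, uas_tp2, sat_tp1, sat_tp2])
        assert both.shape[1] == 36

    def test_self_concatenation_rejected(self):
        t = self._table(["P1", "P2"], ["NDVI_UAS_TP1"])
        with pytest.raises(ContractError):
            build_scenario([t, t])

    def test_plot_set_mismatch_rejected(self):
        a = self._table(["P1", "P2"], ["NDVI_UAS_TP1"])
        b = self._table(["P1", "P3"], ["NDVI_SAT_TP2"])
        with pytest.raises(ContractError):
            build_scenario([a, b])

    def test_texture_column_count(self, fine_scene, small_plots):
        tex = plot_texture_features(fine_scene, small_plots, source="UAS", timepoint="TP1")
        assert tex.shape[1] == 5 * 4  # 5 bands × 4 statistics
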