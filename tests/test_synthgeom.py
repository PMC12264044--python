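"""Generator checks against analytic geometry and planted ground truth."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spleenniche import synthgeom as sg


class TestGeometry:
    def test_ellipse_mask_area_matches_analytic(self, steady_tissue):
        params = steady_tissue.params
        analytic = math.pi * params.a * params.b / 1e6
        raster = steady_tissue.area_mm2("cross_section")
        assert raster == pytest.approx(analytic, rel=0.02)

    def test_capsule_annulus_area_matches_analytic(self):
        params = sg.GeometryParams(shape="disk", a=500.0, b=500.0,
                                   capsule_width=20.0, pixel_size=5.0,
                                   n_trabeculae=0, n_wp_discs=0,
                                   vessel_density_rp=0.0, vessel_density_wp=0.0,
                                   lymph_density_rp=0.0, seed=1)
        tissue = sg.make_tissue(params)
        analytic = math.pi * (500.0**2 - 480.0**2) / 1e6  # 0.0616 mm²
        assert tissue.area_mm2("capsule") == pytest.approx(analytic, rel=0.02)

    def test_bare_geometry_red_pulp_is_core(self, bare_disk):
        core = bare_disk.masks["cross_section"] & ~bare_disk.masks["capsule"]
        assert np.array_equal(bare_disk.red_pulp, core)

    def test_mask_set_identities(self, steady_tissue):
        m = steady_tissue.masks
        cs = m["cross_section"]
        assert not (m["capsule"] & ~cs).any()           # capsule ⊆ CS
        assert not (m["wp"] & m["capsule"]).any()       # WP ∩ capsule = ∅
        assert not (m["wp"] & m["marginal_zone"]).any()
        recon = (cs & ~m["wp"] & ~m["marginal_zone"] & ~m["capsule"]
                 & ~m["trabeculae"] & ~m["blood_vessels"] & ~m["lymph_vessels"])
        assert np.array_equal(steady_tissue.red_pulp, recon)
        shapes = {mask.shape for mask in m.values()}
        assert len(shapes) == 1

    def test_same_seed_reproduces_masks_and_cells(self):
        geom, place, _ = sg.scenario("steady_female")
        small = sg.PlacementSpec(**{**place.__dict__, "n_cells": 50})
        t1, t2 = sg.make_tissue(geom), sg.make_tissue(geom)
        for name in t1.masks:
            assert np.array_equal(t1.masks[name], t2.masks[name])
        c1 = sg.plant_cells(t1, small, seed=7)
        c2 = sg.plant_cells(t2, small, seed=7)
        pd.testing.assert_frame_equal(c1, c2)

    def test_parameter_validation(self):
        with pytest.raises(sg.ParameterError):
            sg.GeometryParams(a=100.0, b=200.0).validate()  # a < b
        with pytest.raises(sg.ResolutionError):
            sg.GeometryParams(capsule_width=2.0, pixel_size=5.0).validate()
        with pytest.raises(sg.ParameterError):
            sg.GeometryParams(vessel_density_rp=1.5).validate()


class TestPlacement:
    def test_zone_constraint_binds(self, steady_tissue):
        spec = sg.PlacementSpec(n_cells=300, zone_max=200.0)
        cells = sg.plant_cells(steady_tissue, spec, seed=3)
        assert len(cells) == 300
        assert (cells["true_distance_um"] <= 200.0 + steady_tissue.pixel_size).all()

    def test_uniform_disk_mean_distance_is_r_over_3(self, bare_disk):
        spec = sg.PlacementSpec(n_cells=50_000, distance_law=sg.UniformArea(),
                                zone_max=1e9, restrict_to="whole_cs")
        cells = sg.plant_cells(bare_disk, spec, seed=11)
        # E[R - r] = R/3 for uniform positions in a disk of radius R = 500
        assert cells["true_distance_um"].mean() == pytest.approx(500 / 3, abs=2.0)

    def test_uniform_disk_distances_follow_annulus_law(self, bare_disk):
        spec = sg.PlacementSpec(n_cells=50_000, distance_law=sg.UniformArea(),
                                zone_max=1e9, restrict_to="whole_cs")
        d = sg.plant_cells(bare_disk, spec, seed=13)["true_distance_um"]
        R = 500.0
        ks = stats.kstest(d, lambda x: 1 - ((R - x) / R) ** 2)
        assert ks.statistic < 0.02

    def test_ki67_positive_cells_sit_deeper(self, steady_tissue):
        spec = sg.PlacementSpec(n_cells=5000, ki67_slope=0.009)
        cells = sg.plant_cells(steady_tissue, spec, seed=21)
        mean_pos = cells.loc[cells["Ki67"], "true_distance_um"].mean()
        mean_neg = cells.loc[~cells["Ki67"], "true_distance_um"].mean()
        assert mean_pos > mean_neg

    def test_red_pulp_restriction_avoids_white_pulp(self, steady_tissue):
        cells = sg.plant_cells(steady_tissue, sg.PlacementSpec(n_cells=400),
                               seed=5)
        wp = steady_tissue.region_mask("white_pulp")
        px = steady_tissue.pixel_size
        ix = np.round(cells["x_um"] / px).astype(int)
        iy = np.round(cells["y_um"] / px).astype(int)
        assert not wp[iy, ix].any()

    def test_law_beyond_geometry_reach_raises(self, bare_disk):
        # support beyond the deepest reachable point → parameter error
        law = sg.Piecewise(edges=(600.0, 650.0), weights=(1.0,))
        spec = sg.PlacementSpec(n_cells=5, distance_law=law, zone_max=700.0,
                                restrict_to="whole_cs")
        with pytest.raises(sg.ParameterError):
            sg.plant_cells(bare_disk, spec, seed=1)

    def test_vanishing_target_band_exhausts_rejections(self, bare_disk):
        # targets pinned to the single deepest point: the admissible band is
        # a few pixels, so the bounded rejection budget runs out
        law = sg.Piecewise(edges=(499.9, 500.0), weights=(1.0,))
        spec = sg.PlacementSpec(n_cells=5, distance_law=law, zone_max=500.0,
                                restrict_to="whole_cs")
        with pytest.raises(sg.PlacementError):
            sg.plant_cells(bare_disk, spec, seed=1)


class TestDistanceLaws:
    def test_trunc_exponential_mean_matches_sample(self, rng):
        law = sg.TruncExponential(60.0)
        d = law.sample(100_000, 200.0, rng)
        assert d.max() <= 200.0
        assert d.mean() == pytest.approx(law.mean(200.0), abs=0.5)

    def test_piecewise_sampling_respects_weights(self, rng):
        law = sg.Piecewise(edges=(0.0, 50.0, 100.0), weights=(0.25, 0.75))
        d = law.sample(40_000, 100.0, rng)
        assert np.mean(d < 50.0) == pytest.approx(0.25, abs=0.01)

    def test_piecewise_validation(self):
        with pytest.raises(sg.ParameterError):
            sg.Piecewise(edges=(0.0, 10.0), weights=(0.5, 0.5))
        with pytest.raises(sg.ParameterError):
            sg.Piecewise(edges=(0.0, 10.0, 20.0), weights=(0.4, 0.4))


class TestScenarios:
    def test_fu5_zone_expands_to_400um(self):
        _, place, _ = sg.scenario("fu5")
        assert place.zone_max == 400.0

    def test_gcsf_reduces_intensity_within_unchanged_zone(self):
        _, place, intensity = sg.scenario("gcsf")
        assert intensity.scale_factor < 1.0
        assert place.zone_max == 200.0

    def test_male_law_mean_exceeds_female(self):
        _, female, _ = sg.scenario("steady_female")
        _, male, _ = sg.scenario("steady_male")
        assert (male.distance_law.mean(male.zone_max)
                > female.distance_law.mean(female.zone_max))

    def test_steady_law_concentrates_mass_near_capsule(self, rng):
        _, place, _ = sg.scenario("steady_female")
        d = place.distance_law.sample(50_000, place.zone_max, rng)
        assert np.mean(d <= 60.0) > 0.5

    def test_unknown_scenario_raises(self):
        with pytest.raises(KeyError):
            sg.scenario("zombie")


class TestIntensity:
    def test_noiseless_capsule_mean_is_exact(self, bare_disk):
        spec = sg.IntensitySpec(capsule_level=100.0, stromal_cell_level=40.0,
                                noise_sd=0.0, scale_factor=1.0)
        img = sg.render_channel(bare_disk, spec, seed=1)
        assert img.values[bare_disk.masks["capsule"]].mean() == 100.0

    def test_scale_factor_is_linear(self, bare_disk):
        spec = sg.IntensitySpec(capsule_level=100.0, noise_sd=0.0,
                                scale_factor=0.4)
        img = sg.render_channel(bare_disk, spec, seed=1)
        assert img.values[bare_disk.masks["capsule"]].mean() == pytest.approx(40.0)

    def test_noisy_capsule_mean_within_standard_error(self):
        params = sg.GeometryParams(shape="disk", a=500.0, b=500.0,
                                   capsule_width=30.0, pixel_size=2.0,
                                   n_trabeculae=0, n_wp_discs=0,
                                   vessel_density_rp=0.0,
                                   vessel_density_wp=0.0,
                                   lymph_density_rp=0.0, seed=2)
        tissue = sg.make_tissue(params)
        spec = sg.IntensitySpec(capsule_level=100.0, noise_sd=5.0)
        img = sg.render_channel(tissue, spec, seed=2)
        cap = tissue.masks["capsule"]
        assert cap.sum() > 10_000
        assert img.values[cap].mean() == pytest.approx(100.0, abs=0.5)

    def test_src_pixels_carry_stromal_level(self, bare_disk):
        spec = sg.IntensitySpec(stromal_cell_level=60.0, noise_sd=0.0)
        img = sg.render_channel(bare_disk, spec, seed=3)
        assert img.src_mask.any()
        assert (img.values[img.src_mask] == 60.0).all()


class TestAbundanceSimulator:
    def test_planted_log2fc_recovered_on_linear_scale(self):
        eff = pd.DataFrame({"CTM": [2.0] * 50},
                           index=[f"P{i:05d}" for i in range(50)])
        m = sg.simulate_abundance(500, {"CTM": 6, "STC": 6}, effects=eff,
                                  missing_rate=0.0, seed=4)
        log2 = np.log2(m.values)
        ctm = log2[m.columns_for("CTM")].mean(axis=1)
        stc = log2[m.columns_for("STC")].mean(axis=1)
        planted = (ctm - stc).iloc[:50].mean()
        assert planted == pytest.approx(2.0, abs=0.15)  # ratio 4x

    def test_missingness_rate_matches_expectation(self):
        m = sg.simulate_abundance(2431, {"A": 3, "B": 3}, missing_rate=0.1,
                                  seed=5, n_tech=1)
        n_missing = int(m.values.isna().sum().sum())
        expected = 0.1 * 2431 * 6  # = 1458.6
        sd = math.sqrt(expected * 0.9)
        assert abs(n_missing - expected) < 4 * sd

    def test_null_simulation_has_no_mean_effect(self):
        m = sg.simulate_abundance(1000, {"A": 6, "B": 6}, missing_rate=0.0,
                                  seed=6)
        log2 = np.log2(m.values)
        diff = (log2[m.columns_for("A")].mean(axis=1)
                - log2[m.columns_for("B")].mean(axis=1))
        se = diff.std(ddof=1) / math.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se

    def test_degenerate_design_raises(self):
        with pytest.raises(sg.DesignError):
            sg.simulate_abundance(10, {"A": 1, "B": 6})
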