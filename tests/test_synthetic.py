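"""Ground-truth structure and determinism of the synthetic generator."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fibdamage.bfactor import fit_group
from fibdamage.fsc import fsc_curve, resolution_at_threshold
from fibdamage.surface_geometry import interpolate_surface
from fibdamage.synthetic import (
    SyntheticConfig,
    bfactor_at_depth,
    build_fixture_bundle,
    simulate_geometry,
    simulate_half_maps,
    simulate_particles,
    simulate_resolution_series,
)


def flat_config(**kw):
    base = dict(
        n_tomograms=3,
        particles_per_tomogram=300,
        tomo_shape=(200, 200, 386),
        tilt_max_deg=0.0,
        roughness_amp_nm=0.0,
        thickness_sd_nm=0.0,
        seed=0,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestGeometry:
    def test_flat_config_gives_parallel_planes(self):
        cfg = flat_config()
        sheets, _ = simulate_geometry(cfg, np.random.default_rng(0))
        for front, back in sheets.values():
            assert np.ptp(front.heights) == pytest.approx(0.0)
            sep_nm = (back.heights - front.heights) * cfg.pixel_size_A / 10
            np.testing.assert_allclose(sep_nm, 200.0)

    def test_thickness_sampling_consistency(self):
        cfg = SyntheticConfig(
            n_tomograms=50, particles_per_tomogram=1, tomo_shape=(100, 100, 386), seed=0
        )
        sheets, _ = simulate_geometry(cfg, np.random.default_rng(12))
        vox = 10 / cfg.pixel_size_A
        thick = np.array(
            [np.mean(b.heights - f.heights) / vox for f, b in sheets.values()]
        )
        se = 30.0 / np.sqrt(50)
        assert abs(thick.mean() - 200.0) < 3 * se

    def test_annotations_reproduce_true_sheets_within_roughness(self):
        cfg = flat_config(n_tomograms=1, tilt_max_deg=3.0, roughness_amp_nm=2.0)
        rng = np.random.default_rng(5)
        sheets, ann = simulate_geometry(cfg, rng)
        tomo = next(iter(sheets))
        front_true, _ = sheets[tomo]
        rebuilt = interpolate_surface(ann.sheet(tomo, "front"), cfg.grid_step_vox, "front")
        u = np.linspace(5, 190, 40)
        v = np.linspace(5, 190, 40)
        uu, vv = np.meshgrid(u, v, indexing="ij")
        err_vox = np.abs(
            rebuilt.height_at(uu.ravel(), vv.ravel())
            - front_true.height_at(uu.ravel(), vv.ravel())
        )
        # blending between annotated slices can miss at most ~2x the
        # roughness amplitude; tilt and in-slice structure interpolate exactly
        assert err_vox.max() * cfg.pixel_size_A / 10 <= 2 * cfg.roughness_amp_nm + 1e-6


class TestParticles:
    def test_planar_true_depth_closed_form(self):
        cfg = flat_config()
        rng = np.random.default_rng(1)
        sheets, _ = simulate_geometry(cfg, rng)
        table = simulate_particles(cfg, sheets, rng)
        front, back = sheets[table.df["tomogram_id"].iloc[0]]
        vox = 10 / cfg.pixel_size_A
        sub = table.df[table.df["tomogram_id"] == table.df["tomogram_id"].iloc[0]]
        z0 = front.heights[0, 0]
        z1 = back.heights[0, 0]
        expected = np.minimum(sub["z"] - z0, z1 - sub["z"]) / vox
        np.testing.assert_allclose(sub["true_depth_nm"], expected, atol=1e-9)

    def test_depth_uniformity_not_rejected(self):
        # uniform placement: depth / (thickness/2) should be U(0, 1)
        cfg = flat_config(n_tomograms=1, particles_per_tomogram=400)
        rejections = 0
        n_trials = 60
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            sheets, _ = simulate_geometry(cfg, rng)
            table = simulate_particles(cfg, sheets, rng)
            u = table.df["true_depth_nm"] / (table.df["true_thickness_nm"] / 2)
            if stats.kstest(u, "uniform").pvalue < 0.01:
                rejections += 1
        assert rejections <= 0.05 * n_trials + 2

    def test_full_margin_leaves_no_volume(self):
        cfg = flat_config(n_tomograms=1)
        rng = np.random.default_rng(0)
        sheets, _ = simulate_geometry(cfg, rng)
        with pytest.raises(ValueError, match="no interior volume"):
            simulate_particles(cfg, sheets, rng, margin_nm=100.0)

    def test_zero_density_rejected(self):
        cfg = flat_config()
        cfg.particles_per_tomogram = 0
        rng = np.random.default_rng(0)
        sheets, _ = simulate_geometry(cfg, rng)
        with pytest.raises(ValueError, match="density"):
            simulate_particles(cfg, sheets, rng)


class TestDamageModel:
    def test_bfactor_at_depth_closed_form(self):
        cfg = flat_config(b_bulk_A2=300.0, delta_b_A2=1100.0, decay_length_nm=5.4)
        assert bfactor_at_depth(7.5, cfg) == pytest.approx(
            300 * (1 + (1100 / 300) * np.exp(-7.5 / 5.4)), rel=1e-12
        )
        assert bfactor_at_depth(7.5, cfg) == pytest.approx(574, abs=1.0)
        assert bfactor_at_depth(1e6, cfg) == pytest.approx(300.0)

    def test_noiseless_series_inverts_to_generating_B(self):
        cfg = flat_config(resolution_noise_sd=0.0)
        series = simulate_resolution_series(
            12.0, [8000, 4000, 2000, 1000], cfg, np.random.default_rng(0), group="g"
        )
        B_true = float(bfactor_at_depth(12.0, cfg))
        assert fit_group(series).B == pytest.approx(B_true, rel=1e-9)

    def test_noisy_series_recovers_B_within_ci(self):
        cfg = flat_config()
        series = simulate_resolution_series(
            7.5, [8000, 4000, 2000, 1000, 500], cfg, np.random.default_rng(3), group="g"
        )
        result = fit_group(series)
        B_true = float(bfactor_at_depth(7.5, cfg))
        assert abs(result.B - B_true) < 4 * result.sigma_B


class TestHalfMaps:
    def test_noiseless_pair_identical(self):
        a, b = simulate_half_maps(0.1, 48, 1.9, seed=0, noise=False)
        np.testing.assert_array_equal(a.data, b.data)
        curve = fsc_curve(a, b)
        np.testing.assert_allclose(curve.fsc, 1.0, atol=1e-9)
        assert resolution_at_threshold(curve) == pytest.approx(3.8)

    def test_seed_determinism(self):
        a1, b1 = simulate_half_maps(0.08, 32, 1.9, seed=4)
        a2, b2 = simulate_half_maps(0.08, 32, 1.9, seed=4)
        np.testing.assert_array_equal(a1.data, a2.data)
        np.testing.assert_array_equal(b1.data, b2.data)

    def test_crossover_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_half_maps(0.5, 32, 1.9, seed=0)


class TestBundle:
    def test_ground_truth_matches_config(self, small_bundle, small_config):
        with open(small_bundle / "truth" / "ground_truth.json") as fh:
            truth = json.load(fh)
        assert truth["decay_length_nm"] == small_config.decay_length_nm
        assert truth["seed"] == small_config.seed

    def test_bundle_determinism(self, tmp_path, small_config, small_bundle):
        out2 = tmp_path / "again"
        build_fixture_bundle(small_config, out2)
        for name in ("particles.star", "annotations.csv", "tomograms.csv"):
            assert (out2 / name).read_bytes() == (small_bundle / name).read_bytes()

    def test_different_seed_differs(self, tmp_path, small_config, small_bundle):
        import dataclasses

        cfg = dataclasses.replace(small_config, seed=small_config.seed + 1)
        out2 = tmp_path / "other"
        build_fixture_bundle(cfg, out2)
        assert (out2 / "particles.star").read_bytes() != (
            small_bundle / "particles.star"
        ).read_bytes()

    def test_truth_depths_match_pipeline_geometry_on_flat_bundle(self, tmp_path):
        cfg = flat_config(n_tomograms=2)
        out = tmp_path / "flat"
        build_fixture_bundle(cfg, out)
        truth = pd.read_csv(out / "truth" / "particles_truth.csv")
        assert (truth["true_depth_nm"] <= truth["true_thickness_nm"] / 2 + 1e-9).all()
        assert (truth["true_depth_nm"] >= 0).all()
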