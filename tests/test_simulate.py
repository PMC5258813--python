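"""Generator contracts: determinism, geometry, mixtures, instrument ranges."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from colonycyto import (
    CHANNELS,
    PackingError,
    SimConfig,
    fractions_from_marginals,
    generate_colony_field,
    generate_ground_truth,
    simulate_flow_readings,
)
from colonycyto.simulate import GroundTruth, PHENOTYPES, POSITIVE_ON


class TestConfig:
    def test_camera_levels_default_bit_depth(self):
        cfg = SimConfig()
        assert cfg.camera_bit_depth == 12
        assert cfg.camera_ceiling + 1 == 4096  # 4096 levels at 12 bit

    def test_flow_ceiling_default_decades(self):
        assert SimConfig().flow_ceiling == 10_000.0

    def test_invalid_fractions_rejected(self):
        cfg = SimConfig(phenotype_fractions={p: 0.3 for p in PHENOTYPES})
        with pytest.raises(ValueError, match="sum"):
            cfg.validate()

    def test_zero_area_field_rejected(self):
        with pytest.raises(ValueError, match="zero-area"):
            SimConfig(field_shape=(0, 100)).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(seed=42, edge_bias=1.5)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert SimConfig.from_yaml(tmp_path / "cfg.yaml") == cfg


@given(
    px=st.floats(0.0, 1.0),
    py=st.floats(0.0, 1.0),
    assoc=st.floats(-1.0, 1.0),
)
def test_fractions_from_marginals_preserve_marginals(px, py, assoc):
    fr = fractions_from_marginals(px, py, assoc)
    vals = np.array([fr[p] for p in PHENOTYPES])
    assert (vals >= -1e-12).all()
    assert vals.sum() == pytest.approx(1.0, abs=1e-9)
    assert fr["double_pos"] + fr["x_single_pos"] == pytest.approx(px, abs=1e-9)
    assert fr["double_pos"] + fr["y_single_pos"] == pytest.approx(py, abs=1e-9)


class TestGenerate:
    def test_same_seed_bit_identical(self, small_config):
        img1, truth_a = generate_colony_field(small_config)
        img2, truth_b = generate_colony_field(small_config)
        for ch in CHANNELS:
            np.testing.assert_array_equal(img1.channel(ch), img2.channel(ch))
        pd.testing.assert_frame_equal(truth_a.cells, truth_b.cells)

    def test_truth_only_matches_rendered_truth(self, small_config):
        _, rendered = generate_colony_field(small_config)
        truth = generate_ground_truth(small_config)
        pd.testing.assert_frame_equal(rendered.cells, truth.cells)

    def test_empty_field_is_background_only(self):
        cfg = SimConfig(field_shape=(128, 128), n_colonies=0, n_delaminated=0)
        image, truth = generate_colony_field(cfg)
        assert truth.n_cells == 0
        nuc = image.channel("nuclear").astype(float)
        assert abs(nuc.mean() - cfg.background_level) < 3 * cfg.background_noise_sd

    def test_pixel_range_and_dtype(self, default_field, default_config):
        image, _ = default_field
        for ch in CHANNELS:
            arr = image.channel(ch)
            assert arr.dtype == np.uint16
            assert arr.max() <= default_config.camera_ceiling

    def test_cell_ids_dense(self, default_field):
        _, truth = default_field
        np.testing.assert_array_equal(
            truth.cells["cell_id"].to_numpy(), np.arange(1, truth.n_cells + 1)
        )

    def test_in_colony_centroids_inside_footprint(self, default_field):
        _, truth = default_field
        in_colony = truth.cells[truth.cells["colony_id"] > 0]
        assert (in_colony["boundary_dist_norm"] > 0).all()

    def test_minimum_spacing_between_in_colony_nuclei(self, default_field, default_config):
        _, truth = default_field
        sub = truth.cells[truth.cells["colony_id"] > 0]
        rc = sub[["row", "col"]].to_numpy()
        radii = sub["radius"].to_numpy()
        from scipy.spatial import cKDTree

        pairs = cKDTree(rc).query_pairs(
            2 * default_config.packing_min_spacing * radii.max(), output_type="ndarray"
        )
        d = np.hypot(*(rc[pairs[:, 0]] - rc[pairs[:, 1]]).T)
        min_allowed = default_config.packing_min_spacing * (
            radii[pairs[:, 0]] + radii[pairs[:, 1]]
        )
        assert (d >= min_allowed - 1e-9).all()

    def test_marginals_converge_to_phenotype_fractions(self):
        # pool several fields to n >= 2000 and compare against a binomial CI
        cells = []
        for seed in range(5):
            cells.append(generate_ground_truth(SimConfig(seed=seed)).cells)
        pooled = pd.concat(cells, ignore_index=True)
        n = len(pooled)
        assert n >= 2000
        cfg = SimConfig()
        for ch in ("marker_x", "marker_y"):
            p_true = sum(cfg.phenotype_fractions[p] for p in POSITIVE_ON[ch])
            p_obs = pooled["phenotype"].isin(POSITIVE_ON[ch]).mean()
            assert abs(p_obs - p_true) < 4 * math.sqrt(p_true * (1 - p_true) / n)

    def test_edge_bias_concentrates_differentiated_class_at_boundary(self):
        cells = pd.concat(
            [generate_ground_truth(SimConfig(seed=s)).cells for s in range(2)],
            ignore_index=True,
        )
        in_colony = cells[cells["colony_id"] > 0]
        assert len(in_colony) >= 500
        diff = in_colony[in_colony["phenotype"] == "y_single_pos"]
        other = in_colony[in_colony["phenotype"] != "y_single_pos"]
        assert diff["boundary_dist_norm"].mean() < other["boundary_dist_norm"].mean()

    def test_no_edge_bias_within_permutation_null(self):
        """With edge_bias = 0 the differentiated class is exchangeable, so
        its boundary-distance contrast must sit inside the permutation null."""
        cfg = replace(SimConfig(seed=5), edge_bias=0.0)
        cells = generate_ground_truth(cfg).cells
        in_colony = cells[cells["colony_id"] > 0].reset_index(drop=True)
        is_ph = (in_colony["phenotype"] == "y_single_pos").to_numpy()
        d = in_colony["boundary_dist_norm"].to_numpy()
        obs = d[is_ph].mean() - d.mean()
        rng = np.random.default_rng(0)
        perms = np.array(
            [d[rng.permutation(is_ph)].mean() - d.mean() for _ in range(999)]
        )
        assert abs(obs) <= np.quantile(np.abs(perms), 0.995)

    def test_infeasible_packing_raises(self):
        cfg = SimConfig(
            field_shape=(380, 380),
            n_colonies=1,
            colony_radius_range=(50.0, 50.0),
            cells_per_colony=5000,
        )
        with pytest.raises(PackingError, match="minimum spacing"):
            generate_colony_field(cfg)


class TestFlow:
    def test_zero_cv_reads_truth_exactly(self, small_config):
        truth = generate_ground_truth(small_config)
        cfg = replace(small_config, flow_cv=0.0)
        sample = simulate_flow_readings(truth, cfg)
        merged = sample.readings.merge(
            truth.cells[["cell_id", "expr_marker_x", "expr_marker_y"]], on="cell_id"
        )
        np.testing.assert_allclose(merged["marker_x"], merged["expr_marker_x"])
        np.testing.assert_allclose(merged["marker_y"], merged["expr_marker_y"])

    def test_saturated_expression_clips_at_ten_thousand(self, small_config):
        truth = generate_ground_truth(small_config)
        cells = truth.cells.copy()
        cells["expr_marker_x"] = 1e6
        cells["expr_marker_y"] = 2e5
        sat = GroundTruth(cells=cells, colonies=truth.colonies)
        sample = simulate_flow_readings(sat, replace(small_config, flow_cv=0.05))
        assert (sample.readings["marker_x"] == 10_000.0).all()
        assert (sample.readings["marker_y"] == 10_000.0).all()

    def test_readings_within_flow_range(self, small_config):
        truth = generate_ground_truth(small_config)
        sample = simulate_flow_readings(truth, small_config)
        for ch in ("marker_x", "marker_y"):
            assert sample.readings[ch].between(0, small_config.flow_ceiling).all()

    def test_empty_truth_rejected(self, small_config):
        empty = GroundTruth(
            cells=pd.DataFrame(columns=["cell_id", "expr_marker_x", "expr_marker_y"]),
            colonies=pd.DataFrame(),
        )
        with pytest.raises(ValueError, match="empty"):
            simulate_flow_readings(empty, small_config)

    def test_negative_expression_rejected(self, small_config):
        truth = generate_ground_truth(small_config)
        cells = truth.cells.copy()
        cells.loc[0, "expr_marker_y"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            simulate_flow_readings(
                GroundTruth(cells=cells, colonies=truth.colonies), small_config
            )

    def test_positive_fraction_matches_lognormal_mixture_cdf(self):
        """Measured = lognormal expression x mean-1 lognormal noise is again
        lognormal, so the expected positive fraction at a threshold has a
        closed form; the Monte-Carlo estimate must agree within sampling
        error at n = 10,000."""
        n = 10_000
        rng = np.random.default_rng(123)
        frac_pos = 0.3
        mu_pos, sig_pos = math.log(400.0), 0.7
        mu_neg, sig_neg = math.log(8.0), 0.6
        cv = 0.25
        is_pos = rng.random(n) < frac_pos
        expr = np.where(
            is_pos,
            rng.lognormal(mu_pos, sig_pos, n),
            rng.lognormal(mu_neg, sig_neg, n),
        )
        cells = pd.DataFrame(
            {
                "cell_id": np.arange(1, n + 1),
                "expr_marker_x": expr,
                "expr_marker_y": expr,
            }
        )
        truth = GroundTruth(cells=cells, colonies=pd.DataFrame())
        cfg = SimConfig(flow_cv=cv)
        sample = simulate_flow_readings(truth, cfg, seed=5)
        t = 60.0
        observed = (sample.readings["marker_x"] > t).mean()
        s2 = math.log(1 + cv**2)

        def tail(mu, sig):
            # ln(measured) ~ N(mu - s2/2, sig^2 + s2)
            return 1 - norm.cdf(
                (math.log(t) - (mu - s2 / 2)) / math.sqrt(sig**2 + s2)
            )

        expected = frac_pos * tail(mu_pos, sig_pos) + (1 - frac_pos) * tail(
            mu_neg, sig_neg
        )
        assert abs(observed - expected) < 4 * math.sqrt(expected * (1 - expected) / n)
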