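"""Spatial analysis: colony grouping, edge metrics, enrichment, backtracking."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from colonycyto import (
    assign_colonies,
    backtrack,
    classify_quadrants,
    edge_scores,
    phenotype_edge_enrichment,
)
from colonycyto.spatial import ColonyAssignment


def cell_table(points, areas=None):
    points = np.asarray(points, dtype=float)
    df = pd.DataFrame({"row": points[:, 0], "col": points[:, 1]})
    df.insert(0, "cell_id", np.arange(1, len(df) + 1))
    df["area"] = 113 if areas is None else areas
    return df


class TestAssignColonies:
    def test_single_tight_cluster(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(40, 60, (12, 2))
        asg = assign_colonies(cell_table(pts), linkage_distance=30.0,
                              min_colony_size=3, field_shape=(100, 100))
        assert (asg.cell_colony == 1).all()
        assert asg.colonies.iloc[0]["n_cells"] == 12

    def test_two_distant_clusters(self):
        pts = np.vstack([
            np.random.default_rng(1).uniform(20, 40, (8, 2)),
            np.random.default_rng(2).uniform(160, 180, (8, 2)),
        ])
        asg = assign_colonies(cell_table(pts), linkage_distance=30.0,
                              min_colony_size=3, field_shape=(220, 220))
        assert set(asg.cell_colony) == {1, 2}

    def test_small_components_stay_unassigned(self):
        pts = [[10, 10], [12, 12], [100, 100], [102, 100], [104, 102],
               [106, 100], [108, 102]]
        asg = assign_colonies(cell_table(pts), linkage_distance=5.0,
                              min_colony_size=5, field_shape=(140, 140))
        assert (asg.cell_colony[:2] == 0).all()
        assert (asg.cell_colony[2:] == 1).all()

    def test_matches_brute_force_union_find_oracle(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 120, (50, 2))
        link = 14.0
        asg = assign_colonies(cell_table(pts), linkage_distance=link,
                              min_colony_size=1, field_shape=(160, 160))

        parent = list(range(50))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i, j):
            parent[find(i)] = find(j)

        for i in range(50):
            for j in range(i + 1, 50):
                if np.hypot(*(pts[i] - pts[j])) <= link:
                    union(i, j)
        roots = [find(i) for i in range(50)]
        # same partition
        for i in range(50):
            for j in range(50):
                assert (roots[i] == roots[j]) == (
                    asg.cell_colony[i] == asg.cell_colony[j]
                )

    def test_non_positive_linkage_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            assign_colonies(cell_table([[1, 1]]), linkage_distance=0.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            assign_colonies(cell_table(np.empty((0, 2))).iloc[:0], 5.0)

    def test_footprint_covers_members(self, default_cells, default_labels):
        asg = assign_colonies(default_cells, linkage_distance=36.0,
                              labels=default_labels,
                              field_shape=default_labels.shape)
        assigned = default_cells[asg.cell_colony > 0]
        fp = asg.footprints
        for _, cell in assigned.head(50).iterrows():
            assert fp[int(round(cell["row"])), int(round(cell["col"]))] > 0


def disc_assignment(R=30, center=(40, 40), shape=(80, 80), members=2):
    mask = np.zeros(shape, dtype=np.int32)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    mask[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= R**2] = 1
    return ColonyAssignment(
        cell_colony=np.ones(members, dtype=int),
        colonies=pd.DataFrame({"colony_id": [1], "n_cells": [members]}),
        footprints=mask,
    )


class TestEdgeScores:
    def test_disc_center_scores_full_depth(self):
        R = 30
        asg = disc_assignment(R=R)
        cells = cell_table([[40, 40], [40, 62]])
        scores = edge_scores(asg, cells, edge_band=10.0)
        center = scores.iloc[0]
        assert center["boundary_distance"] == pytest.approx(R, abs=1.0)
        assert center["normalized_score"] == pytest.approx(1.0, abs=0.05)
        assert not center["edge_flag"]
        edge = scores.iloc[1]
        assert edge["boundary_distance"] < 10.0
        assert edge["edge_flag"]

    def test_scores_decrease_along_ray_to_boundary(self):
        asg = disc_assignment(R=30, members=5)
        cols = [40, 45, 52, 60, 67]
        scores = edge_scores(asg, cell_table([[40, c] for c in cols]))
        bd = scores["boundary_distance"].to_numpy()
        assert all(a >= b for a, b in zip(bd, bd[1:]))

    def test_single_cell_colony_scores_zero_by_convention(self):
        asg = disc_assignment(members=1)
        scores = edge_scores(asg, cell_table([[40, 40]]))
        assert scores.iloc[0]["normalized_score"] == 0.0

    def test_cell_outside_footprint_clamped_with_warning(self):
        asg = disc_assignment(members=2)
        cells = cell_table([[40, 40], [5, 5]])  # second is outside the disc
        with pytest.warns(UserWarning, match="clamped"):
            scores = edge_scores(asg, cells)
        assert scores.iloc[1]["boundary_distance"] == 0.0

    def test_delaminated_cells_carry_no_score(self):
        asg = disc_assignment(members=2)
        asg.cell_colony = np.array([1, 0])
        scores = edge_scores(asg, cell_table([[40, 40], [70, 70]]))
        assert np.isnan(scores.iloc[1]["boundary_distance"])
        assert not scores.iloc[1]["edge_flag"]


def toy_enrichment_table(n=40, n_edge=10, phenotype_on_edge=True):
    df = cell_table(np.random.default_rng(0).uniform(0, 50, (n, 2)))
    df["colony_id"] = 1
    df["edge_flag"] = [i < n_edge for i in range(n)]
    if phenotype_on_edge:
        df["quadrant"] = ["y_single_pos" if i < n_edge else "double_pos"
                          for i in range(n)]
    else:
        df["quadrant"] = "double_pos"
    return df


class TestEnrichment:
    def test_uniform_phenotype_gives_zero_statistic(self):
        df = toy_enrichment_table(phenotype_on_edge=False)
        res = phenotype_edge_enrichment(df, "double_pos", n_permutations=99, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_perfect_edge_phenotype_matches_enumeration(self):
        # 10 edge cells are exactly the phenotype; overall edge fraction 10/40
        df = toy_enrichment_table(n=40, n_edge=10)
        res = phenotype_edge_enrichment(df, "y_single_pos", n_permutations=999, seed=1)
        assert res.statistic == pytest.approx(1.0 - 0.25)
        assert res.p_value < 0.05

    def test_fixed_seed_reproduces_p_exactly(self):
        df = toy_enrichment_table()
        r1 = phenotype_edge_enrichment(df, "y_single_pos", seed=7)
        r2 = phenotype_edge_enrichment(df, "y_single_pos", seed=7)
        assert r1.p_value == r2.p_value
        assert r1.statistic == r2.statistic

    def test_add_one_correction_bounds_p(self):
        df = toy_enrichment_table()
        res = phenotype_edge_enrichment(df, "y_single_pos", n_permutations=199, seed=3)
        assert res.p_value >= 1 / 200

    def test_absent_phenotype_rejected(self):
        df = toy_enrichment_table(phenotype_on_edge=False)
        with pytest.raises(ValueError, match="absent"):
            phenotype_edge_enrichment(df, "y_single_pos")

    def test_too_few_cells_rejected(self):
        df = toy_enrichment_table(n=5, n_edge=2)
        with pytest.raises(ValueError, match=">= 10"):
            phenotype_edge_enrichment(df, "y_single_pos")


class TestBacktrack:
    @pytest.fixture(scope="class")
    def gated_cells(self, default_cells, control_gates):
        gx, gy, _ = control_gates
        _, gated = classify_quadrants(default_cells, gx, gy)
        return gated, gx, gy

    def test_crop_contains_centroid_and_matches_bbox_at_zero_pad(
        self, gated_cells, default_field, default_labels
    ):
        gated, _, _ = gated_cells
        image, _ = default_field
        ids = gated["cell_id"].iloc[[0, 10, 50]].tolist()
        for crop in backtrack(ids, gated, image, default_labels, pad=0):
            r0, c0, r1, c1 = crop.bbox
            cell = gated.set_index("cell_id").loc[crop.cell_id]
            assert (r0, c0, r1, c1) == (
                cell["bbox_r0"], cell["bbox_c0"], cell["bbox_r1"], cell["bbox_c1"]
            )
            assert r0 <= crop.centroid[0] <= r1
            assert c0 <= crop.centroid[1] <= c1
            assert crop.nucleus_mask.any()

    def test_unknown_ids_listed_in_error(self, gated_cells, default_field, default_labels):
        gated, _, _ = gated_cells
        image, _ = default_field
        with pytest.raises(KeyError, match="999999"):
            backtrack([gated["cell_id"].iloc[0], 999999], gated, image, default_labels)

    def test_round_trip_quadrant_recomputed_from_crop(
        self, gated_cells, default_field, default_labels
    ):
        """The quadrant class recomputed from the crop's masked mean
        intensities equals the class stored in the table."""
        gated, gx, gy = gated_cells
        image, _ = default_field
        ids = gated["cell_id"].iloc[::37].tolist()
        for crop in backtrack(ids, gated, image, default_labels, pad=6):
            mx = float(crop.crops["marker_x"][crop.nucleus_mask].mean())
            my = float(crop.crops["marker_y"][crop.nucleus_mask].mean())
            x_pos, y_pos = mx > gx.threshold, my > gy.threshold
            expected = (
                "double_pos" if x_pos and y_pos
                else "x_single_pos" if x_pos
                else "y_single_pos" if y_pos
                else "double_neg"
            )
            stored = gated.set_index("cell_id").loc[crop.cell_id, "quadrant"]
            assert stored == expected
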