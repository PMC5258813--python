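"""Shared fixtures: one default simulated field and its processed products,
built once per session, plus a fast small-field variant."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

from colonycyto import (
    SegmentationParams,
    SimConfig,
    fit_threshold,
    generate_colony_field,
    measure_cells,
    segment_nuclei,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def default_field(default_config):
    """(image, truth) for the default generator configuration."""
    return generate_colony_field(default_config)


@pytest.fixture(scope="session")
def default_labels(default_field):
    image, _ = default_field
    return segment_nuclei(image.channel("nuclear"), SegmentationParams())


@pytest.fixture(scope="session")
def default_cells(default_labels, default_field):
    image, _ = default_field
    return measure_cells(default_labels, image)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast ~200-cell configuration for tests that re-generate fields."""
    return SimConfig(
        field_shape=(380, 380),
        n_colonies=2,
        colony_radius_range=(60.0, 80.0),
        n_delaminated=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def control_gates(default_config):
    """Negative-control-derived gates matched to the default field."""
    ctrl_cfg = replace(default_config, seed=997).negative_control(0)
    image, _ = generate_colony_field(ctrl_cfg)
    cells = measure_cells(segment_nuclei(image.channel("nuclear")), image)
    return (
        fit_threshold(cells, "marker_x"),
        fit_threshold(cells, "marker_y"),
        cells,
    )


def greedy_centroid_f1(truth_rc: np.ndarray, found_rc: np.ndarray, radius: float):
    """Greedy nearest-centroid matching; returns (precision, recall, f1)."""
    from scipy.spatial import cKDTree

    if len(found_rc) == 0 or len(truth_rc) == 0:
        return 0.0, 0.0, 0.0
    d, idx = cKDTree(truth_rc).query(found_rc)
    matched = set()
    tp = 0
    for di, ti in sorted(zip(d, idx)):
        if di <= radius and ti not in matched:
            matched.add(ti)
            tp += 1
    precision = tp / len(found_rc)
    recall = tp / len(truth_rc)
    f1 = 0.0 if tp == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1
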