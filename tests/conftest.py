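"""Shared fixtures: small analytic trees and synthetic tube clouds."""

from __future__ import annotations

import numpy as np
import pytest

from phytoskel.synthetic import (
    PlantSpec,
    generate_ground_truth,
    perturb_skeleton,
    sample_tube_cloud,
)
from phytoskel.tree import (
    CurveTree,
    QuotientTree,
    SkeletonTree,
    build_curve_tree,
    decompose_axes,
)


@pytest.fixture
def y_skeleton() -> SkeletonTree:
    """A Y: straight trunk continuing upward, one 45-degree side branch."""
    nodes = np.array(
        [
            [0, 0, 0], [0, 0, 1], [0, 0, 2],          # trunk below junction
            [0, 0, 3], [0, 0, 4], [0, 0, 5],          # straight continuation
            [0.7, 0, 2.7], [1.4, 0, 3.4], [2.1, 0, 4.1],  # 45-deg branch
        ],
        dtype=float,
    )
    parent = np.array([-1, 0, 1, 2, 3, 4, 2, 6, 7])
    return SkeletonTree(nodes, parent, root=0)


def straight_tube_case(radius: float, seed: int, length: float = 50.0,
                       zigzag: float = 0.5):
    """Cloud + zigzag-perturbed skeleton + its curve tree for a straight tube.

    The centerline is the z-axis; sampling density is scaled so the cloud
    holds ~5000 points at every radius; radial noise is 2% of the radius.
    """
    n_ctrl = int(length) + 1
    axis = np.linspace([0, 0, 0], [0, 0, length], n_ctrl)
    center = CurveTree(QuotientTree([-1], [[]]), [axis.copy()], [None])
    spec = PlantSpec(
        n_axes=1, depth=0, radius=radius, curvature=0.0,
        points_per_mm2=16.0 / radius, noise_sd=0.02 * radius, seed=seed,
    )
    cloud = sample_tube_cloud(center, spec, seed=seed)
    pert = perturb_skeleton(center, zigzag_amp=zigzag, drift_amp=0.0, seed=seed)
    ct = build_curve_tree(decompose_axes(pert))
    return cloud, pert, ct


def trident_case(seed: int, zigzag: float = 0.5, drift: float = 0.0):
    """Synthetic 3-axis / 2-junction plant with ground truth and a degraded
    initial skeleton."""
    spec = PlantSpec(
        n_axes=3, depth=2, seed=seed, curvature=0.01, radius=1.0,
        points_per_mm2=8.0, noise_sd=0.02,
    )
    gt, center = generate_ground_truth(spec)
    cloud = sample_tube_cloud(center, spec, seed=seed)
    pert = perturb_skeleton(center, zigzag_amp=zigzag, drift_amp=drift, seed=seed + 1)
    ct = build_curve_tree(decompose_axes(pert))
    return gt, center, cloud, pert, ct


def rmse_to_z_axis(points: np.ndarray) -> float:
    """Root-mean-square perpendicular distance to the z-axis."""
    return float(np.sqrt(np.mean(points[:, 0] ** 2 + points[:, 1] ** 2)))
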