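"""Junction-location and branch-segment-length error metrics."""

import numpy as np
import pytest

from phytoskel.metrics import (
    GroundTruth,
    branch_segment_error,
    evaluate_skeleton,
    extract_junctions,
    junction_location_error,
    match_junctions,
    summary_stats,
)
from phytoskel.refine import GMMParams, refine
from phytoskel.tree import SkeletonTree

from conftest import trident_case


class TestExtractJunctions:
    def test_path_has_none(self):
        sk = SkeletonTree(
            np.column_stack([np.zeros(5), np.zeros(5), np.arange(5.0)]),
            np.arange(5) - 1,
        )
        assert extract_junctions(sk).shape == (0, 3)

    def test_y_has_one(self, y_skeleton):
        J = extract_junctions(y_skeleton)
        assert J.shape == (1, 3)
        np.testing.assert_array_equal(J[0], [0, 0, 2])

    def test_three_branchings_counted(self):
        # full binary tree with 3 internal branchings
        nodes = np.array(
            [[0, 0, 0], [0, 0, 1], [-1, 0, 2], [1, 0, 2],
             [-2, 0, 3], [-1, 1, 3], [2, 0, 3], [1, 1, 3.0]]
        )
        parent = np.array([-1, 0, 1, 1, 2, 2, 3, 3])
        assert extract_junctions(SkeletonTree(nodes, parent)).shape[0] == 3


class TestMatchJunctions:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(0, 10, (6, 3))
        matches = match_junctions(pts, pts)
        assert matches == [(i, i) for i in range(6)]

    def test_uniform_offset(self):
        pts = np.random.default_rng(1).normal(0, 10, (5, 3))
        delta = np.array([0.3, -0.2, 0.1])
        matches = match_junctions(pts, pts + delta)
        assert matches == [(i, i) for i in range(5)]

    def test_two_gt_one_pred(self):
        gt = np.array([[0, 0, 0], [10, 0, 0.0]])
        pred = np.array([[0.4, 0, 0.0]])
        matches = match_junctions(gt, pred)
        assert matches == [(0, 0)]

    def test_cutoff_discards_far_pairs(self):
        gt = np.array([[0, 0, 0], [1, 0, 0.0]])
        pred = np.array([[0.1, 0, 0], [500.0, 0, 0]])
        matches = match_junctions(gt, pred)
        assert matches == [(0, 0)]


class TestJunctionError:
    def test_perfect_skeleton_zero_error(self):
        pts = np.random.default_rng(2).normal(0, 5, (4, 3))
        err = junction_location_error(pts, pts, avg_branch_length=10.0)
        assert err.junction_errors == pytest.approx([0, 0, 0, 0], abs=1e-15)

    def test_one_mm_over_ten_mm(self):
        gt = np.array([[0, 0, 0.0]])
        pred = np.array([[1.0, 0, 0]])
        err = junction_location_error(gt, pred, avg_branch_length=10.0)
        assert err.junction_errors == [pytest.approx(0.1)]
        assert err.junction_errors_mm == [pytest.approx(1.0)]

    def test_rigid_invariance(self):
        rng = np.random.default_rng(3)
        gt = rng.normal(0, 5, (5, 3))
        pred = gt + rng.normal(0, 0.5, (5, 3))
        ang = 1.1
        R = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]]
        )
        b = np.array([1.0, 2.0, 3.0])
        e1 = junction_location_error(gt, pred, 8.0)
        e2 = junction_location_error(gt @ R.T + b, pred @ R.T + b, 8.0)
        np.testing.assert_allclose(e1.junction_errors, e2.junction_errors, rtol=1e-9)

    def test_bad_normalizer(self):
        with pytest.raises(ValueError):
            junction_location_error(np.zeros((1, 3)), np.zeros((1, 3)), 0.0)


class TestSegmentError:
    def _straight_gt(self):
        # stem 0..20 with one junction at z=10; two segments of 10 mm
        junctions = np.array([[0, 0, 10.0]])
        segments = [
            (np.array([0, 0, 0.0]), np.array([0, 0, 10.0]), 10.0),
            (np.array([0, 0, 10.0]), np.array([0, 0, 20.0]), 10.0),
        ]
        return GroundTruth(junctions, segments)

    def test_perfect_skeleton_zero_error(self):
        gt = self._straight_gt()
        z = np.linspace(0, 20, 21)
        nodes = np.column_stack([np.zeros(21), np.zeros(21), z])
        nodes = np.vstack([nodes, [[1.0, 0, 11.0]]])  # branch to make z=10...
        parent = np.concatenate([np.arange(21) - 1, [10]])
        sk = SkeletonTree(nodes, parent)
        err = branch_segment_error(gt, sk)
        assert err.segment_errors == pytest.approx([0.0, 0.0], abs=1e-9)

    def test_twenty_vs_twentytwo(self):
        gt = GroundTruth(
            np.array([[0, 0, 0.0]]),
            [(np.array([0, 0, 0.0]), np.array([0, 0, 20.0]), 20.0)],
            avg_branch_length=10.0,
        )
        # predicted polyline measures 22 mm between the matched endpoints
        z = np.linspace(0, 22, 23)
        nodes = np.column_stack([np.zeros(23), np.zeros(23), z])
        nodes = np.vstack([nodes, [[1.0, 0, 1.0]]])
        parent = np.concatenate([np.arange(23) - 1, [0]])
        sk = SkeletonTree(nodes, parent)
        err = branch_segment_error(gt, sk)
        assert err.segment_errors == [pytest.approx(0.2)]

    def test_scale_invariance(self):
        gt = self._straight_gt()
        z = np.linspace(0, 20, 21)
        nodes = np.column_stack([np.full(21, 0.2), np.zeros(21), z])
        nodes = np.vstack([nodes, [[1.0, 0, 11.0]]])
        parent = np.concatenate([np.arange(21) - 1, [10]])
        e1 = branch_segment_error(gt, SkeletonTree(nodes, parent))
        gt3 = GroundTruth(
            3 * gt.junctions,
            [(3 * a, 3 * b, 3 * l) for a, b, l in gt.segments],
        )
        e2 = branch_segment_error(gt3, SkeletonTree(3 * nodes, parent))
        np.testing.assert_allclose(e1.segment_errors, e2.segment_errors, rtol=1e-9)


class TestEndToEndImprovement:
    def test_refined_beats_zigzag_on_trident(self):
        gt, center, cloud, pert, ct = trident_case(seed=3)
        refined, _ = refine(cloud, ct, GMMParams())
        e_pert = evaluate_skeleton(gt, pert)
        e_ref = evaluate_skeleton(gt, refined)
        assert np.mean(e_ref.segment_errors) < np.mean(e_pert.segment_errors)
        assert np.mean(e_pert.junction_errors) > 0


class TestSummaryStats:
    def test_box_plot_conventions(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 100.0]
        s = summary_stats(vals)
        assert s["n"] == 9
        assert s["median"] == pytest.approx(5.0)
        assert s["q25"] == pytest.approx(np.percentile(vals, 25))
        assert s["q75"] == pytest.approx(np.percentile(vals, 75))
        assert s["outliers"] == [100.0]

    def test_empty(self):
        assert summary_stats([]) == {"n": 0}
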