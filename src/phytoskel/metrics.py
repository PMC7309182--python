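"""Skeleton quality metrics against a known ground truth.

Two measures quantify how well a computed skeleton captures the branching
structure: (i) the deviation of each junction point (where two or more
branches meet) from its true location, and (ii) the error in branch-segment
length, a segment being the skeleton arc between consecutive junction
points (or a junction and a branch tip).  Both are reported relative to the
average ground-truth branch-segment length, which makes them dimensionless
and comparable across plants of different size; the raw mm deviations are
kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .tree import CurveTree, SkeletonTree

__all__ = [
    "GroundTruth",
    "SkeletonErrors",
    "extract_junctions",
    "match_junctions",
    "junction_location_error",
    "branch_segment_error",
    "evaluate_skeleton",
    "summary_stats",
]


@dataclass
class GroundTruth:
    """True junction positions and branch-segment lengths (mm).

    ``segments`` is a list of (endpoint_a, endpoint_b, length) where the
    endpoints are 3-vectors — junctions, the root, or branch tips — and the
    length is the true arc length between them.  ``avg_branch_length``
    defaults to the mean segment length.
    """

    junctions: np.ndarray
    segments: list[tuple[np.ndarray, np.ndarray, float]]
    avg_branch_length: float = 0.0

    def __post_init__(self) -> None:
        self.junctions = np.asarray(self.junctions, dtype=float).reshape(-1, 3)
        if self.avg_branch_length <= 0:
            if not self.segments:
                raise ValueError("need segments or an explicit avg_branch_length")
            self.avg_branch_length = float(np.mean([s[2] for s in self.segments]))


@dataclass
class SkeletonErrors:
    """Per-item relative errors plus unmatched counts."""

    junction_errors: list[float] = field(default_factory=list)
    junction_errors_mm: list[float] = field(default_factory=list)
    segment_errors: list[float] = field(default_factory=list)
    unmatched_gt: int = 0
    unmatched_pred: int = 0


def extract_junctions(tree: SkeletonTree | CurveTree) -> np.ndarray:
    """Positions of nodes where two or more branches meet."""
    if isinstance(tree, CurveTree):
        return tree.junctions()
    ch = tree.children()
    out = [tree.nodes[i] for i in range(tree.n_nodes) if len(ch[i]) >= 2]
    return np.array(out) if out else np.empty((0, 3))


def match_junctions(
    gt: np.ndarray, pred: np.ndarray, cutoff: float | None = None
) -> list[tuple[int, int]]:
    """Optimal one-to-one assignment of predicted to true junctions.

    Minimizes the total Euclidean distance (Hungarian algorithm); pairs
    farther apart than ``cutoff`` (default 5x the average nearest-neighbour
    spacing of the true junctions) are discarded.
    """
    gt = np.asarray(gt, dtype=float).reshape(-1, 3)
    pred = np.asarray(pred, dtype=float).reshape(-1, 3)
    if gt.shape[0] == 0 or pred.shape[0] == 0:
        return []
    D = cdist(gt, pred)
    if cutoff is None:
        if gt.shape[0] > 1:
            DG = cdist(gt, gt)
            np.fill_diagonal(DG, np.inf)
            cutoff = 5.0 * float(DG.min(axis=1).mean())
        else:
            cutoff = np.inf
    rows, cols = linear_sum_assignment(D)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if D[r, c] <= cutoff]


def junction_location_error(
    gt: np.ndarray,
    pred: np.ndarray,
    avg_branch_length: float,
    matches: list[tuple[int, int]] | None = None,
) -> SkeletonErrors:
    """Relative junction deviations ||pred - gt|| / avg_branch_length."""
    if avg_branch_length <= 0:
        raise ValueError("avg_branch_length must be positive")
    gt = np.asarray(gt, dtype=float).reshape(-1, 3)
    pred = np.asarray(pred, dtype=float).reshape(-1, 3)
    if matches is None:
        matches = match_junctions(gt, pred)
    err = SkeletonErrors()
    for r, c in matches:
        d = float(np.linalg.norm(pred[c] - gt[r]))
        err.junction_errors_mm.append(d)
        err.junction_errors.append(d / avg_branch_length)
    err.unmatched_gt = gt.shape[0] - len(matches)
    err.unmatched_pred = pred.shape[0] - len(matches)
    return err


def _skeleton_graph(tree: SkeletonTree) -> nx.Graph:
    g = nx.Graph()
    for i in range(tree.n_nodes):
        p = int(tree.parent[i])
        if p >= 0:
            g.add_edge(i, p, weight=float(np.linalg.norm(tree.nodes[i] - tree.nodes[p])))
    g.add_nodes_from(range(tree.n_nodes))
    return g


def _nearest_node(tree: SkeletonTree, pos: np.ndarray, candidates: np.ndarray) -> int:
    d = np.linalg.norm(tree.nodes[candidates] - pos, axis=1)
    return int(candidates[np.argmin(d)])


def branch_segment_error(
    gt: GroundTruth,
    pred_tree: SkeletonTree | CurveTree,
    matches: list[tuple[int, int]] | None = None,
) -> SkeletonErrors:
    """Relative branch-segment length errors |len_gt - len_pred| / avg length.

    Predicted length is the arc length along the skeleton polyline between
    the two nodes corresponding to the segment endpoints: matched junction
    nodes for junction endpoints, nearest tip/root node otherwise.  Segments
    with an unmatched junction endpoint are excluded and counted.
    """
    tree = pred_tree.to_skeleton() if isinstance(pred_tree, CurveTree) else pred_tree
    pred_j = extract_junctions(pred_tree)
    if matches is None:
        matches = match_junctions(gt.junctions, pred_j)
    # node index of each predicted junction position
    ch = tree.children()
    junction_nodes = np.array(
        [i for i in range(tree.n_nodes) if len(ch[i]) >= 2], dtype=int
    )
    tip_nodes = np.array(
        [i for i in range(tree.n_nodes) if len(ch[i]) == 0 or int(tree.parent[i]) < 0],
        dtype=int,
    )
    match_of_gt: dict[int, int] = {}
    for r, c in matches:
        match_of_gt[r] = _nearest_node(tree, pred_j[c], junction_nodes)

    g = _skeleton_graph(tree)
    err = SkeletonErrors()

    def node_for(pos: np.ndarray) -> int | None:
        if gt.junctions.shape[0]:
            dj = np.linalg.norm(gt.junctions - pos, axis=1)
            j = int(np.argmin(dj))
            if dj[j] < 1e-6:  # this endpoint IS a ground-truth junction
                return match_of_gt.get(j)
        if tip_nodes.size == 0:
            return None
        return _nearest_node(tree, pos, tip_nodes)

    for a, b, length in gt.segments:
        na, nb = node_for(np.asarray(a, float)), node_for(np.asarray(b, float))
        if na is None or nb is None:
            err.unmatched_gt += 1
            continue
        pred_len = nx.shortest_path_length(g, na, nb, weight="weight")
        err.segment_errors.append(abs(length - pred_len) / gt.avg_branch_length)
    return err


def evaluate_skeleton(
    gt: GroundTruth, pred_tree: SkeletonTree | CurveTree
) -> SkeletonErrors:
    """Both metrics under one shared junction matching."""
    pred_j = extract_junctions(pred_tree)
    matches = match_junctions(gt.junctions, pred_j)
    jerr = junction_location_error(gt.junctions, pred_j, gt.avg_branch_length, matches)
    serr = branch_segment_error(gt, pred_tree, matches)
    jerr.segment_errors = serr.segment_errors
    jerr.unmatched_gt += serr.unmatched_gt
    return jerr


def summary_stats(values: list[float]) -> dict:
    """Box-plot style summary: mean, median, quartiles, 1.5*IQR outliers."""
    if not values:
        return {"n": 0}
    v = np.asarray(values, dtype=float)
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    iqr = q75 - q25
    lo, hi = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
        "outliers": [float(x) for x in v[(v < lo) | (v > hi)]],
    }
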