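"""Ground-truthed synthetic plants: tube clouds around known curve trees.

The generator grows a leafless branching structure as a tree of smoothly
bent polyline axes (a bounded-curvature random walk per axis, children
attached at random arc-length positions at controlled branching angles),
samples a surface point cloud on generalized cylinders of known radius
around it, and can degrade the true centerline into a "coarse-skeleton"
style initialization (zigzag offsets plus drift toward the bifurcating
branch near junctions).  Because the centerline, junction positions and
segment lengths are known exactly, every pipeline stage can be scored
without external scan data.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import GroundTruth
from .tree import Attachment, CurveTree, QuotientTree

__all__ = [
    "PlantSpec",
    "generate_ground_truth",
    "sample_tube_cloud",
    "perturb_skeleton",
    "perturb_curve_tree",
]


@dataclass
class PlantSpec:
    """Parameters of the synthetic plant.

    Lengths in mm, angles in degrees, curvature in rad/mm, sampling density
    in points per mm^2 of tube surface, radial noise SD in mm.
    """

    n_axes: int = 3
    depth: int = 2
    branch_length_range: tuple[float, float] = (20.0, 40.0)
    branching_angle_range: tuple[float, float] = (30.0, 60.0)
    curvature: float = 0.01
    radius: float = 1.0
    taper: float = 1.0  # radius multiplier per branching depth
    points_per_mm2: float = 20.0
    noise_sd: float = 0.02
    seed: int = 0
    step: float = 1.0  # centerline polyline step, mm

    def validate(self) -> None:
        if self.n_axes < 1 or self.depth < 0:
            raise ValueError("need n_axes >= 1 and depth >= 0")
        for lo, hi in (self.branch_length_range, self.branching_angle_range):
            if not (0 < lo <= hi):
                raise ValueError("ranges must be positive and ordered")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.curvature < 0 or self.noise_sd < 0 or self.points_per_mm2 <= 0:
            raise ValueError("curvature/noise_sd must be >= 0, density > 0")


def _perp_basis(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Any orthonormal pair spanning the plane perpendicular to t."""
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, t)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(t, a)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(t, e1)


def _grow_axis(
    start: np.ndarray, direction: np.ndarray, length: float, spec: PlantSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bounded-curvature random-walk polyline of the given arc length."""
    n_steps = max(2, int(round(length / spec.step)))
    pts = [start]
    d = direction / np.linalg.norm(direction)
    for _ in range(n_steps):
        if spec.curvature > 0:
            e1, e2 = _perp_basis(d)
            ang = rng.uniform(-spec.curvature, spec.curvature) * spec.step
            phi = rng.uniform(0, 2 * np.pi)
            axis = np.cos(phi) * e1 + np.sin(phi) * e2
            d = d * np.cos(ang) + np.cross(axis, d) * np.sin(ang)
            d /= np.linalg.norm(d)
        pts.append(pts[-1] + d * spec.step)
    return np.array(pts)


def _branch_direction(
    tangent: np.ndarray, angle_deg: float, rng: np.random.Generator
) -> np.ndarray:
    e1, e2 = _perp_basis(tangent)
    phi = rng.uniform(0, 2 * np.pi)
    lat = np.cos(phi) * e1 + np.sin(phi) * e2
    ang = np.radians(angle_deg)
    d = np.cos(ang) * tangent + np.sin(ang) * lat
    return d / np.linalg.norm(d)


def _arc_lengths(poly: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(poly, axis=0), axis=1))])


def generate_ground_truth(spec: PlantSpec) -> tuple[GroundTruth, CurveTree]:
    """Grow the plant; return exact ground truth and its centerline curve tree.

    Axes beyond the first are attached, breadth-first over depth, to a
    randomly chosen existing axis whose depth is below the limit, at a
    uniformly random interior arc position, at a branching angle drawn from
    the configured range.  Segments are the arcs between consecutive branch
    points along each axis (axis ends included); junctions are the exact
    attachment points.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    polys: list[np.ndarray] = []
    parent_axis: list[int] = []
    parent_point: list[int] = []
    depth_of: list[int] = []

    L0 = rng.uniform(*spec.branch_length_range)
    polys.append(_grow_axis(np.zeros(3), np.array([0.0, 0.0, 1.0]), L0, spec, rng))
    parent_axis.append(-1)
    parent_point.append(-1)
    depth_of.append(0)

    while len(polys) < spec.n_axes:
        eligible = [a for a in range(len(polys)) if depth_of[a] < spec.depth]
        if not eligible:
            raise ValueError(
                f"cannot place {spec.n_axes} axes within depth {spec.depth}"
            )
        pa = int(rng.choice(eligible))
        poly = polys[pa]
        j = int(rng.integers(1, poly.shape[0] - 1))  # interior attachment
        tangent = poly[min(j + 1, poly.shape[0] - 1)] - poly[j - 1]
        tangent /= np.linalg.norm(tangent)
        ang = rng.uniform(*spec.branching_angle_range)
        d = _branch_direction(tangent, ang, rng)
        L = rng.uniform(*spec.branch_length_range)
        child = _grow_axis(poly[j], d, L, spec, rng)
        polys.append(child)
        parent_axis.append(pa)
        parent_point.append(j)
        depth_of.append(depth_of[pa] + 1)

    # curve tree bookkeeping
    children: list[list[int]] = [[] for _ in polys]
    for a, pa in enumerate(parent_axis):
        if pa >= 0:
            children[pa].append(a)
    for pa in range(len(polys)):
        children[pa].sort(key=lambda a: (parent_point[a], a))
    attachments: list[Attachment | None] = [None] * len(polys)
    for a in range(1, len(polys)):
        arc = _arc_lengths(polys[parent_axis[a]])
        attachments[a] = Attachment(
            parent_axis[a], parent_point[a], float(arc[parent_point[a]] / arc[-1])
        )
    qt = QuotientTree(parent_axis, children)
    ct = CurveTree(qt, [p.copy() for p in polys], attachments)

    # ground truth: junctions = attachment points; segments split each axis
    junctions = ct.junctions()
    segments: list[tuple[np.ndarray, np.ndarray, float]] = []
    for a, poly in enumerate(polys):
        arc = _arc_lengths(poly)
        cuts = sorted({0, poly.shape[0] - 1} | {
            attachments[c].parent_point for c in children[a]
        })
        for i0, i1 in zip(cuts, cuts[1:]):
            segments.append((poly[i0].copy(), poly[i1].copy(), float(arc[i1] - arc[i0])))
    gt = GroundTruth(junctions, segments)
    return gt, ct


def sample_tube_cloud(
    centerline: CurveTree, spec: PlantSpec, seed: int | None = None
) -> np.ndarray:
    """Sample points on generalized cylinders around every axis.

    Area-uniform over each polyline segment's lateral surface, uniform in
    angle, radius perturbed by N(0, noise_sd); junction overlap regions are
    double-sampled on purpose (real scans pile up density there).  Expected
    count = surface area x points_per_mm2.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    pts: list[np.ndarray] = []
    depth_of = _axis_depths(centerline.quotient.parent_axis)
    for a, poly in enumerate(centerline.curves):
        r = spec.radius * spec.taper ** depth_of[a]
        seg = np.diff(poly, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        for i in range(seg.shape[0]):
            if seg_len[i] <= 0:
                continue
            area = 2.0 * np.pi * r * seg_len[i]
            n_i = rng.poisson(area * spec.points_per_mm2)
            if n_i == 0:
                continue
            t = seg[i] / seg_len[i]
            e1, e2 = _perp_basis(t)
            u = rng.uniform(0, 1, n_i)[:, None]
            theta = rng.uniform(0, 2 * np.pi, n_i)
            rad = r + rng.normal(0, spec.noise_sd, n_i)
            base = poly[i] + u * seg[i]
            offs = rad[:, None] * (np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2)
            pts.append(base + offs)
    if not pts:
        raise ValueError("no points sampled; check radius/density")
    return np.concatenate(pts, axis=0)


def _axis_depths(parent_axis: list[int]) -> list[int]:
    depth = [0] * len(parent_axis)
    for a, pa in enumerate(parent_axis):
        if pa >= 0:
            depth[a] = depth[pa] + 1
    return depth


def perturb_skeleton(
    centerline: CurveTree,
    zigzag_amp: float = 0.5,
    drift_amp: float = 0.0,
    seed: int = 0,
):
    """Degrade the true centerline into a coarse-skeleton-like SkeletonTree.

    Same perturbation as :func:`perturb_curve_tree`, flattened to a rooted
    skeleton tree — the natural input for the axial-decomposition +
    spline-resampling + refinement pipeline.
    """
    return perturb_curve_tree(centerline, zigzag_amp, drift_amp, seed).to_skeleton()


def perturb_curve_tree(
    centerline: CurveTree,
    zigzag_amp: float = 0.5,
    drift_amp: float = 0.0,
    seed: int = 0,
) -> CurveTree:
    """Degrade the true centerline into a coarse-skeleton-like initialization.

    Interior points of each axis (including points bearing a child) receive
    alternating lateral offsets of magnitude ``zigzag_amp`` perpendicular to
    the local tangent; each junction point and its two parent-axis
    neighbours additionally drift by ``drift_amp`` toward the bifurcating
    branch (the cluster centre at a bifurcation shifts toward the branch in
    centroid-based coarse skeletons).  Topology and attachments are
    unchanged.
    """
    if zigzag_amp < 0 or drift_amp < 0:
        raise ValueError("amplitudes must be >= 0")
    rng = np.random.default_rng(seed)
    curves = [c.copy() for c in centerline.curves]
    for a, poly in enumerate(curves):
        if zigzag_amp > 0 and poly.shape[0] > 2:
            tangents = np.gradient(poly, axis=0)
            phi = rng.uniform(0, 2 * np.pi)
            for i in range(1, poly.shape[0] - 1):
                t = tangents[i] / max(np.linalg.norm(tangents[i]), 1e-12)
                e1, e2 = _perp_basis(t)
                lat = np.cos(phi) * e1 + np.sin(phi) * e2
                poly[i] = poly[i] + ((-1) ** i) * zigzag_amp * lat
    if drift_amp > 0:
        for a, att in enumerate(centerline.attachments):
            if att is None:
                continue
            child = centerline.curves[a]
            if child.shape[0] < 2:
                continue
            d = child[1] - child[0]
            nd = np.linalg.norm(d)
            if nd <= 0:
                continue
            d = d / nd
            parent = curves[att.parent_axis]
            for j in (att.parent_point - 1, att.parent_point, att.parent_point + 1):
                if 0 < j < parent.shape[0] - 1:
                    parent[j] = parent[j] + drift_amp * d
    out = CurveTree(centerline.quotient, curves, centerline.attachments, centerline.axial)
    out.resync_attachments()
    return out
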