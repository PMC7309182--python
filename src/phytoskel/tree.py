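"""Rooted skeleton trees, axial decomposition, quotient graphs and curve trees.

A plant skeleton is a rooted tree of 3D points.  Decorating the tree with a
*successor* function (each vertex nominates at most one child that continues
its botanical axis) decomposes the vertex set into *axes* — maximal successor
paths that play the role of stem and branches.  Collapsing each axis to a
single node yields the *quotient tree*, whose edges record which axis bears
which; the *bearing vertex* of an axis is the parent (on the parent axis) of
its first vertex.

A *curve tree* attaches one resampled beta-spline curve to every axis.  Two
attachment conditions tie the curves together:

* a child curve starts ON its parent curve, at parameter ``u0`` (the
  normalized arc length of the parent polyline point it snaps to);
* siblings borne lower on the parent axis attach at smaller ``u0``.

Both are enforced structurally here and can be re-checked with
:func:`validate_curve_tree`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spline import BetaSplineParams, resample_axis

__all__ = [
    "SkeletonTree",
    "AxialTree",
    "QuotientTree",
    "Attachment",
    "CurveTree",
    "decompose_axes",
    "build_quotient",
    "build_curve_tree",
    "validate_curve_tree",
]


class TreeStructureError(ValueError):
    """The node/parent data do not describe a single rooted tree."""


@dataclass
class SkeletonTree:
    """Rooted tree of 3D skeleton points.

    ``nodes`` is an (N, 3) array in mm; ``parent[i]`` is the parent index of
    node i, with -1 for the root.
    """

    nodes: np.ndarray
    parent: np.ndarray
    root: int = 0

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)
        self.validate()

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def validate(self) -> None:
        n = self.nodes.shape[0]
        if n == 0:
            raise TreeStructureError("empty skeleton tree")
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise TreeStructureError("nodes must be (N, 3)")
        if not np.all(np.isfinite(self.nodes)):
            raise TreeStructureError("non-finite node coordinates")
        if self.parent.shape != (n,):
            raise TreeStructureError("parent array shape mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeStructureError(
                f"expected exactly one root, found {len(roots)} parentless nodes"
            )
        if self.root != roots[0]:
            raise TreeStructureError("declared root is not the parentless node")
        # walk to the root from every node; cycle or stray parent -> error
        for i in range(n):
            seen = set()
            j = i
            while j >= 0:
                if j in seen:
                    raise TreeStructureError("cycle detected in parent chain")
                seen.add(j)
                j = int(self.parent[j])
        # connectivity is implied: every chain terminated at the unique root


@dataclass
class AxialTree:
    """Skeleton tree plus its successor decomposition into axes.

    ``axes`` lists vertex-index paths in depth-first order; ``succ[v]`` is
    the continuing child of v (or -1); ``bearing[a]`` is the parent vertex
    of axis a's first vertex (-1 for the root axis).
    """

    skeleton: SkeletonTree
    succ: np.ndarray
    axes: list[list[int]]
    bearing: list[int]

    @property
    def n_axes(self) -> int:
        return len(self.axes)

    def axis_of_vertex(self) -> np.ndarray:
        out = np.full(self.skeleton.n_nodes, -1, dtype=int)
        for a, ax in enumerate(self.axes):
            out[ax] = a
        return out


@dataclass
class QuotientTree:
    """One node per axis; edges follow the bearing relation."""

    parent_axis: list[int]                 # -1 for the root axis
    children_axes: list[list[int]]         # sibling order = bearing order


@dataclass
class Attachment:
    """Where a child axis hooks onto its parent curve.

    The attachment point is ``(1 - frac) * parent[k] + frac * parent[k + 1]``
    with ``k = parent_point`` — i.e. a point of the continuous parent
    polyline, not necessarily one of its samples.  ``u0`` is its normalized
    arc-length parameter on the parent curve.
    """

    parent_axis: int
    parent_point: int     # segment index into the parent's resampled polyline
    u0: float             # normalized curve parameter of the attachment point
    frac: float = 0.0     # interpolation fraction within that segment


@dataclass
class CurveTree:
    """Axial tree with one uniformly resampled spline polyline per axis.

    ``curves[a]`` is the (N_a, 3) resampled polyline of axis a.  The first
    point of every non-root curve is an exact copy of the parent polyline
    point recorded in ``attachments[a]``.  ``all_points`` concatenates the
    curves into the moving set S with ``point_axis``/``point_index``
    bookkeeping, and ``offsets[a]`` locates curve a inside it.
    """

    quotient: QuotientTree
    curves: list[np.ndarray]
    attachments: list[Attachment | None]
    axial: AxialTree | None = None
    offsets: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        counts = [c.shape[0] for c in self.curves]
        self.offsets = np.concatenate([[0], np.cumsum(counts)])

    @property
    def n_axes(self) -> int:
        return len(self.curves)

    @property
    def all_points(self) -> np.ndarray:
        return np.concatenate(self.curves, axis=0)

    @property
    def point_axis(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_axes), [c.shape[0] for c in self.curves])

    @property
    def point_index(self) -> np.ndarray:
        return np.concatenate([np.arange(c.shape[0]) for c in self.curves])

    def with_points(self, points: np.ndarray) -> "CurveTree":
        """Rebuild the curve tree with displaced coordinates, re-synchronising
        child attachment points onto their (displaced) parent points."""
        points = np.asarray(points, dtype=float)
        if points.shape != (self.offsets[-1], 3):
            raise ValueError("point array shape mismatch")
        curves = [
            points[self.offsets[a]: self.offsets[a + 1]].copy()
            for a in range(self.n_axes)
        ]
        ct = CurveTree(self.quotient, curves, self.attachments, self.axial)
        ct.resync_attachments()
        return ct

    def attachment_point(self, axis: int) -> np.ndarray:
        """The point on the parent polyline where this axis attaches."""
        att = self.attachments[axis]
        pc = self.curves[att.parent_axis]
        k = att.parent_point
        if att.frac <= 0.0 or k + 1 >= pc.shape[0]:
            return pc[k].copy()
        return (1.0 - att.frac) * pc[k] + att.frac * pc[k + 1]

    def resync_attachments(self) -> None:
        """Set each child's first point to its attachment point on the
        (possibly displaced) parent polyline; parents are processed before
        children since axes are in DFS order."""
        for a in range(self.n_axes):
            if self.attachments[a] is not None:
                self.curves[a][0] = self.attachment_point(a)

    def junctions(self) -> np.ndarray:
        """Positions of points where two or more branches meet (attachment
        points on parent curves)."""
        seen: dict[tuple[int, int, float], np.ndarray] = {}
        for a, att in enumerate(self.attachments):
            if att is not None:
                seen[(att.parent_axis, att.parent_point, round(att.frac, 9))] = (
                    self.attachment_point(a)
                )
        if not seen:
            return np.empty((0, 3))
        return np.array(list(seen.values()))

    def to_skeleton(self) -> SkeletonTree:
        """Flatten to a SkeletonTree: chains along each curve, child curves
        parented at the parent-axis node nearest their attachment point
        (an exactly coincident first point is merged with it)."""
        nodes: list[np.ndarray] = []
        parent: list[int] = []
        id_of: list[np.ndarray] = []  # per axis, node id of each curve point
        for a in range(self.n_axes):
            c = self.curves[a]
            ids = np.empty(c.shape[0], dtype=int)
            att = self.attachments[a]
            start = 0
            if att is None:
                prev = -1
            else:
                k = att.parent_point + (1 if att.frac > 0.5 else 0)
                k = min(k, self.curves[att.parent_axis].shape[0] - 1)
                anchor = int(id_of[att.parent_axis][k])
                if np.array_equal(c[0], nodes[anchor]):
                    ids[0] = anchor
                    start = 1
                prev = anchor
            for i in range(start, c.shape[0]):
                nodes.append(c[i])
                parent.append(prev)
                ids[i] = len(nodes) - 1
                prev = ids[i]
            id_of.append(ids)
        return SkeletonTree(np.array(nodes), np.array(parent), root=0)


# ---------------------------------------------------------------------------
# operations


def _path_lengths_to_leaf(sk: SkeletonTree) -> np.ndarray:
    """For each vertex, the largest Euclidean path length down to a leaf."""
    ch = sk.children()
    order = _topo_order(sk)
    out = np.zeros(sk.n_nodes)
    for v in reversed(order):
        best = 0.0
        for c in ch[v]:
            best = max(best, out[c] + float(np.linalg.norm(sk.nodes[c] - sk.nodes[v])))
        out[v] = best
    return out


def _topo_order(sk: SkeletonTree) -> list[int]:
    ch = sk.children()
    order, stack = [], [sk.root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(ch[v]))
    return order


def decompose_axes(skeleton: SkeletonTree) -> AxialTree:
    """Choose a successor at every vertex and split the tree into axes.

    At a branching vertex the successor is the child that bends least, i.e.
    minimizes the angle between (v - parent(v)) and (child - v); at the root
    (which has no incoming direction) it is the child with the longest
    Euclidean path to a leaf.  Ties break on the smallest child index.
    """
    sk = skeleton
    ch = sk.children()
    succ = np.full(sk.n_nodes, -1, dtype=int)
    downlen = _path_lengths_to_leaf(sk)
    for v in range(sk.n_nodes):
        kids = ch[v]
        if not kids:
            continue
        if len(kids) == 1:
            succ[v] = kids[0]
        elif v == sk.root:
            best = max(kids, key=lambda c: (downlen[c], -c))
            succ[v] = best
        else:
            d = sk.nodes[v] - sk.nodes[sk.parent[v]]
            nd = np.linalg.norm(d)
            d = d / nd if nd > 0 else d

            def cosang(c: int) -> float:
                e = sk.nodes[c] - sk.nodes[v]
                ne = np.linalg.norm(e)
                if ne == 0 or nd == 0:
                    return -2.0
                return float(np.dot(d, e) / ne)

            succ[v] = max(kids, key=lambda c: (round(cosang(c), 12), -c))
    # build axes in depth-first order: an axis starts at the root or at any
    # non-successor child
    axes: list[list[int]] = []
    bearing: list[int] = []
    is_start = np.ones(sk.n_nodes, dtype=bool)
    for v in range(sk.n_nodes):
        if succ[v] >= 0:
            is_start[succ[v]] = False
    for v in _topo_order(sk):
        if not is_start[v]:
            continue
        axis = [v]
        w = succ[v]
        while w >= 0:
            axis.append(w)
            w = succ[w]
        axes.append(axis)
        bearing.append(int(sk.parent[v]))
    return AxialTree(sk, succ, axes, bearing)


def build_quotient(at: AxialTree) -> QuotientTree:
    """Collapse each axis to a node; edges follow bearing vertices.

    Sibling edges are ordered by the position of their bearing vertices along
    the parent axis (lower first).
    """
    axis_of = at.axis_of_vertex()
    pos_in_axis = np.full(at.skeleton.n_nodes, -1, dtype=int)
    for ax in at.axes:
        for i, v in enumerate(ax):
            pos_in_axis[v] = i
    parent_axis: list[int] = []
    for a, w in enumerate(at.bearing):
        if w < 0:
            parent_axis.append(-1)
        else:
            pa = int(axis_of[w])
            if pa < 0:
                raise TreeStructureError(f"bearing vertex {w} belongs to no axis")
            parent_axis.append(pa)
    children: list[list[int]] = [[] for _ in range(at.n_axes)]
    for a, pa in enumerate(parent_axis):
        if pa >= 0:
            children[pa].append(a)
    for pa, kids in enumerate(children):
        kids.sort(key=lambda a: (pos_in_axis[at.bearing[a]], a))
    return QuotientTree(parent_axis, children)


def build_curve_tree(
    at: AxialTree, spline_params: BetaSplineParams | None = None
) -> CurveTree:
    """Resample every axis and attach child curves onto their parents.

    Each axis's skeleton vertices act as spline control points; child axes
    borrow their bearing vertex as leading control point so every child
    curve starts at the branch point.  A child attaches to the parent curve
    at the bearing vertex's parametric position along the parent axis
    (u0 = control index / (parent control count - 1)), realized as an
    interpolated point of the parent's resampled polyline.  Bearing
    vertices are ordered along the parent axis, so sibling attachments are
    ordered by construction.
    """
    if spline_params is None:
        spline_params = BetaSplineParams()
    qt = build_quotient(at)
    sk = at.skeleton
    curves: list[np.ndarray | None] = [None] * at.n_axes
    attachments: list[Attachment | None] = [None] * at.n_axes
    for a in range(at.n_axes):  # DFS order: parents precede children
        ctrl = sk.nodes[at.axes[a]]
        if at.bearing[a] >= 0:
            # child curves must start at the junction: lead with the bearing
            # vertex so C_child(0) approximates the branch point
            ctrl = np.vstack([sk.nodes[at.bearing[a]], ctrl])
        try:
            curves[a] = resample_axis(ctrl, spline_params)
        except ValueError as exc:
            raise ValueError(f"spline resampling failed on axis {a}: {exc}") from exc
    # attach children at their bearing vertex's parametric position on the
    # parent; bearing order along the axis makes sibling u0 monotone
    pos_in_axis = np.full(sk.n_nodes, -1, dtype=int)
    for ax in at.axes:
        for i, v in enumerate(ax):
            pos_in_axis[v] = i
    for pa in range(at.n_axes):
        pc = curves[pa]
        n_samp = pc.shape[0]
        # control index of a parent-axis vertex within the parent's control
        # polygon (which is led by the parent's own bearing vertex)
        lead = 1 if at.bearing[pa] >= 0 else 0
        n_ctrl = len(at.axes[pa]) + lead
        for a in qt.children_axes[pa]:
            w = at.bearing[a]
            u0 = (pos_in_axis[w] + lead) / max(n_ctrl - 1, 1)
            x = u0 * (n_samp - 1)
            k = min(int(np.floor(x)), n_samp - 2)
            attachments[a] = Attachment(pa, k, float(u0), float(x - k))
    ct = CurveTree(qt, [np.asarray(c) for c in curves], attachments, at)
    ct.resync_attachments()
    return ct


def validate_curve_tree(ct: CurveTree, atol: float = 1e-9) -> None:
    """Assert both attachment conditions; raise AssertionError on violation."""
    for a, att in enumerate(ct.attachments):
        if att is None:
            continue
        gap = np.linalg.norm(ct.curves[a][0] - ct.attachment_point(a))
        assert gap <= atol, f"axis {a} detached from parent by {gap}"
    for pa, kids in enumerate(ct.quotient.children_axes):
        u0s = [ct.attachments[a].u0 for a in kids]
        assert all(x <= y for x, y in zip(u0s, u0s[1:])), (
            f"sibling attachment order violated on axis {pa}: {u0s}"
        )
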