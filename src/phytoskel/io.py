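"""Readers and writers for point clouds (XYZ, PLY) and skeletons (JSON, SWC).

Coordinates are millimetres throughout; no unit conversion is performed.
PLY parsing/serialisation is delegated to :mod:`trimesh` after a small
header check that gives format errors the caller can act on (missing x/y/z
vertex properties, big-endian binaries).  SWC is the neuron-morphology
7-column format, emitted topologically sorted with a constant radius of
0.5 mm since no radii are estimated here.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import trimesh

from .tree import CurveTree, SkeletonTree, TreeStructureError

__all__ = [
    "PointCloudFormatError",
    "read_point_cloud",
    "write_point_cloud",
    "read_skeleton",
    "write_skeleton",
]


class PointCloudFormatError(ValueError):
    """File content does not match the declared point-cloud format."""


def _infer_format(path: str | os.PathLike, fmt: str | None, kinds: tuple[str, ...]) -> str:
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in kinds:
        raise ValueError(f"unsupported format {fmt!r}; expected one of {kinds}")
    return fmt


def _read_xyz(path: str | os.PathLike) -> np.ndarray:
    pts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            tok = body.split()
            if len(tok) != 3:
                raise PointCloudFormatError(
                    f"{path}: line {lineno}: expected 3 numeric tokens, got {len(tok)}"
                )
            try:
                xyz = [float(t) for t in tok]
            except ValueError:
                raise PointCloudFormatError(
                    f"{path}: line {lineno}: non-numeric coordinate in {body!r}"
                ) from None
            pts.append(xyz)
    if not pts:
        raise PointCloudFormatError(f"{path}: no valid points")
    return np.array(pts, dtype=float)


def _check_ply_header(path: str | os.PathLike) -> None:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise PointCloudFormatError(f"{path}: not a PLY file")
        props: list[bytes] = []
        in_vertex = False
        saw_vertex = False
        for raw in fh:
            line = raw.strip()
            if line.startswith(b"format"):
                if b"big_endian" in line:
                    raise PointCloudFormatError(
                        f"{path}: binary_big_endian PLY is not supported"
                    )
            elif line.startswith(b"element"):
                in_vertex = line.split()[1] == b"vertex"
                saw_vertex = saw_vertex or in_vertex
            elif line.startswith(b"property") and in_vertex:
                props.append(line.split()[-1])
            elif line == b"end_header":
                break
        if not saw_vertex:
            raise PointCloudFormatError(f"{path}: no 'vertex' element in header")
        for need in (b"x", b"y", b"z"):
            if need not in props:
                raise PointCloudFormatError(
                    f"{path}: vertex element lacks property {need.decode()!r}"
                )


def _read_ply(path: str | os.PathLike) -> np.ndarray:
    _check_ply_header(path)
    obj = trimesh.load(str(path), process=False)
    verts = np.asarray(obj.vertices, dtype=float)
    if verts.size == 0:
        raise PointCloudFormatError(f"{path}: zero vertices")
    return verts


def read_point_cloud(path: str | os.PathLike, fmt: str | None = None) -> np.ndarray:
    """Read a point cloud as an (n, 3) float array in file order.

    ``fmt`` is 'xyz' or 'ply'; inferred from the suffix when omitted.  Only
    finite vertices are kept; an empty result is an error.
    """
    fmt = _infer_format(path, fmt, ("xyz", "ply"))
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    pts = _read_xyz(path) if fmt == "xyz" else _read_ply(path)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if pts.shape[0] == 0:
        raise PointCloudFormatError(f"{path}: no finite points")
    return pts


def write_point_cloud(
    cloud: np.ndarray, path: str | os.PathLike, fmt: str | None = None
) -> None:
    """Write an (n, 3) cloud as ASCII XYZ (>= 9 significant digits) or PLY."""
    fmt = _infer_format(path, fmt, ("xyz", "ply"))
    pts = np.asarray(cloud, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] == 0:
        raise ValueError("point cloud must be a non-empty (n, 3) array")
    if fmt == "xyz":
        with open(path, "w") as fh:
            for p in pts:
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
    else:
        trimesh.PointCloud(pts).export(str(path), file_type="ply")


def _tree_nodes_parents(tree: SkeletonTree | CurveTree) -> tuple[np.ndarray, np.ndarray, list[list[int]] | None]:
    if isinstance(tree, CurveTree):
        sk = tree.to_skeleton()
        # recover which flat node ids make up each axis (same walk as to_skeleton)
        axes: list[list[int]] = []
        id_of: list[list[int]] = []
        count = 0
        for a in range(tree.n_axes):
            c = tree.curves[a]
            ids = []
            att = tree.attachments[a]
            start = 0
            if att is not None:
                ids.append(id_of[att.parent_axis][att.parent_point])
                start = 1
            for _ in range(start, c.shape[0]):
                ids.append(count)
                count += 1
            id_of.append(ids)
            axes.append(ids)
        return sk.nodes, sk.parent, axes
    return tree.nodes, tree.parent, None


def write_skeleton(
    tree: SkeletonTree | CurveTree, path: str | os.PathLike, fmt: str | None = None
) -> None:
    """Write a skeleton tree as JSON (nodes + parent ids + optional axes) or SWC.

    JSON: ``{"nodes": [{"id", "x", "y", "z", "parent_id"}, ...], "axes": [...]}``
    with the root's parent_id = -1.  SWC: 7 columns, ids 1-based, type 0,
    radius 0.5, parent of root = -1, parents always precede children.
    """
    fmt = _infer_format(path, fmt, ("json", "swc"))
    nodes, parent, axes = _tree_nodes_parents(tree)
    if fmt == "json":
        doc = {
            "nodes": [
                {
                    "id": int(i),
                    "x": float(nodes[i, 0]),
                    "y": float(nodes[i, 1]),
                    "z": float(nodes[i, 2]),
                    "parent_id": int(parent[i]),
                }
                for i in range(nodes.shape[0])
            ]
        }
        if axes is not None:
            doc["axes"] = [[int(i) for i in ax] for ax in axes]
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    else:
        # topological order guarantees parent id < child id in the output
        order = _swc_order(parent)
        new_id = {v: i + 1 for i, v in enumerate(order)}
        with open(path, "w") as fh:
            for v in order:
                p = int(parent[v])
                pid = -1 if p < 0 else new_id[p]
                fh.write(
                    f"{new_id[v]} 0 {nodes[v,0]:.9g} {nodes[v,1]:.9g} {nodes[v,2]:.9g} 0.5 {pid}\n"
                )


def _swc_order(parent: np.ndarray) -> list[int]:
    n = len(parent)
    kids: list[list[int]] = [[] for _ in range(n)]
    roots = [i for i in range(n) if parent[i] < 0]
    if len(roots) != 1:
        raise TreeStructureError(f"expected one root, found {len(roots)}")
    for i, p in enumerate(parent):
        if p >= 0:
            kids[p].append(i)
    order, stack = [], [roots[0]]
    seen = 0
    while stack:
        v = stack.pop()
        order.append(v)
        seen += 1
        stack.extend(reversed(kids[v]))
    if seen != n:
        raise TreeStructureError("cyclic or disconnected skeleton")
    return order


def read_skeleton(path: str | os.PathLike) -> SkeletonTree:
    """Read a skeleton from the JSON dialect written by :func:`write_skeleton`."""
    with open(path) as fh:
        doc = json.load(fh)
    recs = sorted(doc["nodes"], key=lambda r: r["id"])
    ids = [r["id"] for r in recs]
    if ids != list(range(len(recs))):
        remap = {old: new for new, old in enumerate(ids)}
    else:
        remap = None
    nodes = np.array([[r["x"], r["y"], r["z"]] for r in recs])
    parent = np.array(
        [
            -1 if r["parent_id"] < 0 else (remap[r["parent_id"]] if remap else r["parent_id"])
            for r in recs
        ],
        dtype=int,
    )
    root = int(np.flatnonzero(parent < 0)[0]) if np.any(parent < 0) else 0
    return SkeletonTree(nodes, parent, root=root)
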