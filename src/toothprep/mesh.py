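"""Triangle-mesh core: I/O, cleaning, adjacency, BVH closest-point queries and
rigid (ICP) registration.

Units are millimetres throughout.  STL files carry no unit information; scans
exported by intraoral scanners are conventionally in mm and this package
assumes that convention.

The in-memory container is :class:`trimesh.Trimesh` (non-processed, so vertex
order and face order stay deterministic after our own cleaning pass).  The
closest-point machinery is implemented here: an axis-aligned bounding volume
hierarchy traversed with a priority queue for single queries, and an exact
kd-tree candidate-pruning routine for large batches.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, MeshFormatError, RegistrationWarning

_MERGE_TOL = 1e-6  # mm; STL duplicates vertices per facet


# ---------------------------------------------------------------------------
# I/O and cleaning
# ---------------------------------------------------------------------------

def clean_mesh(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Merge duplicate vertices (1e-6 mm) and drop zero-area faces.

    Returns a new non-processed Trimesh with deterministic vertex/face order.
    """
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=np.int64)
    if len(v) == 0 or len(f) == 0:
        raise DegenerateInputError("mesh has no vertices or faces")
    # quantize to the merge tolerance, keep first occurrence
    key = np.round(v / _MERGE_TOL).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    v2 = v[np.sort(first)]
    f2 = rank[inverse][f]
    # drop degenerate faces (repeated vertex or zero area)
    nondegen = (
        (f2[:, 0] != f2[:, 1]) & (f2[:, 1] != f2[:, 2]) & (f2[:, 0] != f2[:, 2])
    )
    f2 = f2[nondegen]
    if len(f2):
        tri = v2[f2]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        f2 = f2[areas > 1e-14]
    if len(f2) == 0:
        raise DegenerateInputError("mesh empty after cleaning")
    # drop unreferenced vertices
    used = np.zeros(len(v2), dtype=bool)
    used[f2.ravel()] = True
    remap = np.cumsum(used) - 1
    return trimesh.Trimesh(vertices=v2[used], faces=remap[f2], process=False)


def load_mesh(path, fmt: str = "auto") -> trimesh.Trimesh:
    """Load an STL (binary or ASCII) or PLY file and clean it.

    Parameters
    ----------
    path : str or Path
        File to read.
    fmt : {"auto", "stl", "ply"}
        Forced format; "auto" derives it from the file extension.
    """
    ftype = None if fmt == "auto" else fmt
    try:
        raw = trimesh.load(str(path), file_type=ftype, process=False, force="mesh")
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise MeshFormatError(f"could not parse {path!s}: {exc}") from exc
    if not isinstance(raw, trimesh.Trimesh) or len(raw.faces) == 0:
        raise MeshFormatError(f"{path!s} contains no triangle geometry")
    return clean_mesh(raw)


def save_mesh(mesh: trimesh.Trimesh, path, fmt: str = "auto",
              binary: bool = True) -> None:
    """Write STL (binary or ASCII) or PLY; PLY keeps vertex colors if set."""
    path = str(path)
    if fmt == "auto":
        fmt = "ply" if path.lower().endswith(".ply") else "stl"
    if fmt == "stl":
        data = mesh.export(file_type="stl" if binary else "stl_ascii")
    elif fmt == "ply":
        data = mesh.export(file_type="ply", encoding="binary" if binary else "ascii")
    else:
        raise MeshFormatError(f"unsupported format {fmt!r}")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


# ---------------------------------------------------------------------------
# Adjacency helpers
# ---------------------------------------------------------------------------

def vertex_adjacency(mesh: trimesh.Trimesh):
    """Neighbour lists per vertex as (indptr, indices) CSR arrays."""
    e = mesh.edges_unique
    n = len(mesh.vertices)
    both = np.concatenate([e, e[:, ::-1]])
    order = np.lexsort((both[:, 1], both[:, 0]))
    both = both[order]
    indptr = np.searchsorted(both[:, 0], np.arange(n + 1))
    return indptr, both[:, 1].copy()


def neighbours(indptr, indices, v: int):
    return indices[indptr[v]:indptr[v + 1]]


# ---------------------------------------------------------------------------
# Closest-point queries
# ---------------------------------------------------------------------------

@dataclass
class ClosestHit:
    """Result of a closest-point query.

    ``point`` lies on face ``face_index``; ``distance == |query - point|``.
    """

    distance: float
    point: np.ndarray
    face_index: int
    barycentric: np.ndarray


def _closest_on_triangles(triangles: np.ndarray, point: np.ndarray) -> np.ndarray:
    """Closest point to ``point`` on each triangle of (n,3,3) array."""
    pts = np.broadcast_to(point, (len(triangles), 3))
    return trimesh.triangles.closest_point(triangles, pts)


class BVH:
    """Axis-aligned bounding volume hierarchy over mesh faces.

    Top-down median split on the longest axis of face-centroid bounds, leaf
    size 4.  ``closest_point`` traverses with a priority queue ordered by the
    lower-bound distance to each box, pruning boxes whose bound exceeds the
    best hit so far.  Construction and traversal are fully deterministic.
    """

    leaf_size = 4

    def __init__(self, mesh: trimesh.Trimesh):
        if len(mesh.faces) == 0:
            raise DegenerateInputError("cannot index an empty mesh")
        self.mesh = mesh
        self.triangles = np.asarray(mesh.triangles, dtype=float)
        centroids = self.triangles.mean(axis=1)
        n = len(self.triangles)
        # flat arrays describing the tree
        self._lo, self._hi = [], []      # box bounds per node
        self._left, self._right = [], []  # child node ids (-1 for leaf)
        self._leaf_faces = []             # face-index array per node (leaves)
        order = np.arange(n)
        self._build(order, centroids)
        self._lo = np.array(self._lo)
        self._hi = np.array(self._hi)
        self._left = np.array(self._left)
        self._right = np.array(self._right)
        # batch-query support
        self._centroid_tree = cKDTree(centroids)
        rel = self.triangles - centroids[:, None, :]
        self._face_radius = np.linalg.norm(rel, axis=2).max(axis=1)

    # -- construction -----------------------------------------------------
    def _build(self, faces: np.ndarray, centroids: np.ndarray) -> int:
        tri = self.triangles[faces]
        lo = tri.min(axis=(0, 1))
        hi = tri.max(axis=(0, 1))
        node = len(self._lo)
        self._lo.append(lo)
        self._hi.append(hi)
        self._left.append(-1)
        self._right.append(-1)
        self._leaf_faces.append(None)
        if len(faces) <= self.leaf_size:
            self._leaf_faces[node] = faces
            return node
        c = centroids[faces]
        axis = int(np.argmax(c.max(axis=0) - c.min(axis=0)))
        order = faces[np.argsort(c[:, axis], kind="stable")]
        mid = len(order) // 2
        self._left[node] = self._build(order[:mid], centroids)
        self._right[node] = self._build(order[mid:], centroids)
        return node

    # -- queries ----------------------------------------------------------
    def _box_dist2(self, node: int, q: np.ndarray) -> float:
        d = np.maximum(self._lo[node] - q, 0) + np.maximum(q - self._hi[node], 0)
        return float(d @ d)

    def closest_point(self, query) -> ClosestHit:
        """Globally nearest point on the mesh surface to ``query``."""
        q = np.asarray(query, dtype=float)
        best_d2 = np.inf
        best_face = -1
        best_pt = None
        heap = [(self._box_dist2(0, q), 0)]
        while heap:
            bound, node = heapq.heappop(heap)
            if bound >= best_d2:
                break  # every remaining box is at least this far
            faces = self._leaf_faces[node]
            if faces is None:
                for child in (self._left[node], self._right[node]):
                    b = self._box_dist2(child, q)
                    if b < best_d2:
                        heapq.heappush(heap, (b, child))
            else:
                pts = _closest_on_triangles(self.triangles[faces], q)
                d2 = ((pts - q) ** 2).sum(axis=1)
                i = int(np.argmin(d2))
                if d2[i] < best_d2:
                    best_d2 = float(d2[i])
                    best_face = int(faces[i])
                    best_pt = pts[i]
        bary = trimesh.triangles.points_to_barycentric(
            self.triangles[best_face][None], best_pt[None]
        )[0]
        return ClosestHit(
            distance=float(np.sqrt(best_d2)),
            point=best_pt,
            face_index=best_face,
            barycentric=bary,
        )

    def closest_points(self, queries: np.ndarray):
        """Exact batch closest points: (points, distances, face indices).

        Upper-bounds each query by its nearest-centroid triangle, then tests
        every triangle whose centroid ball can beat that bound.
        """
        q = np.asarray(queries, dtype=float).reshape(-1, 3)
        _, near = self._centroid_tree.query(q)
        ub_pts = trimesh.triangles.closest_point(self.triangles[near], q)
        ub = np.linalg.norm(ub_pts - q, axis=1)
        best_pts, best_face, best_dist = ub_pts.copy(), near.copy(), ub.copy()
        radius = ub + self._face_radius.max() + 1e-12
        groups = self._centroid_tree.query_ball_point(q, radius)
        # flatten candidate lists for one vectorized triangle test
        counts = np.fromiter((len(g) for g in groups), int, len(groups))
        if counts.sum():
            cand = np.concatenate([np.asarray(g, dtype=int) for g in groups])
            qrep = np.repeat(q, counts, axis=0)
            pts = trimesh.triangles.closest_point(self.triangles[cand], qrep)
            d = np.linalg.norm(pts - qrep, axis=1)
            owner = np.repeat(np.arange(len(q)), counts)
            order = np.lexsort((d, owner))
            owner_s, d_s = owner[order], d[order]
            firsts = np.searchsorted(owner_s, np.arange(len(q)))
            has = counts > 0
            sel = order[firsts[has]]
            upd = d[sel] < best_dist[has]
            idx = np.flatnonzero(has)[upd]
            best_pts[idx] = pts[sel[upd]]
            best_face[idx] = cand[sel[upd]]
            best_dist[idx] = d[sel[upd]]
        return best_pts, best_dist, best_face


def build_bvh(mesh: trimesh.Trimesh) -> BVH:
    """Build the closest-point index used throughout the pipeline."""
    return BVH(mesh)


def brute_force_closest(mesh: trimesh.Trimesh, query) -> ClosestHit:
    """Reference closest point by scanning every face (test oracle)."""
    q = np.asarray(query, dtype=float)
    pts = _closest_on_triangles(np.asarray(mesh.triangles), q)
    d2 = ((pts - q) ** 2).sum(axis=1)
    i = int(np.argmin(d2))
    bary = trimesh.triangles.points_to_barycentric(
        np.asarray(mesh.triangles)[i][None], pts[i][None]
    )[0]
    return ClosestHit(float(np.sqrt(d2[i])), pts[i], i, bary)


# ---------------------------------------------------------------------------
# Rigid registration
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Rotation + translation with the RMS point-to-surface residual (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rms: float = np.nan

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
            rms=self.rms,
        )

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit src -> dst (proper rotation via SVD)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rotation=r, translation=cd - r @ cs)


def register_icp(
    source: trimesh.Trimesh,
    target: trimesh.Trimesh,
    init: RigidTransform | None = None,
    max_iterations: int = 100,
    tol: float = 1e-6,
    warn_rms: float = 0.5,
    trim_fraction: float = 0.0,
) -> RigidTransform:
    """Iterative closest point: rigid transform taking ``source`` onto
    ``target`` by minimizing point-to-surface RMS.

    Uses every source vertex, no sampling — fully deterministic.  By default
    no correspondences are trimmed; ``trim_fraction`` > 0 drops that fraction
    of the worst correspondences each iteration (robust variant for pairs
    that only share part of their surface, e.g. an intact tooth registered
    onto its prepared counterpart via the unchanged cervical region).
    Stops when the RMS improves by less than ``tol`` mm or after
    ``max_iterations``.  If the final RMS exceeds ``warn_rms`` mm a
    :class:`RegistrationWarning` is emitted (non-overlapping inputs), never a
    silent failure.
    """
    current = init if init is not None else RigidTransform()
    bvh = build_bvh(target)
    pts = np.asarray(source.vertices, dtype=float)
    prev_rms = np.inf
    rms = np.inf
    for _ in range(max_iterations):
        moved = current.apply(pts)
        feet, dist, _ = bvh.closest_points(moved)
        keep = slice(None)
        if trim_fraction > 0:
            cutoff = np.quantile(dist, 1.0 - trim_fraction)
            keep = dist <= cutoff
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        if prev_rms - rms < tol:
            break
        prev_rms = rms
        step = _kabsch(moved[keep], feet[keep])
        current = step.compose(current)
    current.rms = rms
    if rms > warn_rms:
        warnings.warn(
            f"ICP residual {rms:.3f} mm exceeds {warn_rms} mm; "
            "inputs may not overlap",
            RegistrationWarning,
            stacklevel=2,
        )
    return current
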