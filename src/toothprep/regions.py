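"""Partition of the prepared surface into evaluation regions.

Regions, from cervical to occlusal:

* **margin band** — between the detected margin loop and the lower axial
  boundary (the projected band whose mean width is reported);
* **axial band** — between the lower and upper axial boundaries, split into
  mesial / buccal / distal / lingual quadrants for taper measurement;
* **occlusal area** — the cap enclosed by connecting the surface feet of the
  seven standard occlusal landmarks (five cusp tips, two marginal ridges).

Boundary loops are built by mapping guide points onto the prepared surface
(closest point), snapping to mesh vertices and joining consecutive vertices
with geodesic (Euclidean-weight) shortest paths.  Face sets are then
extracted by flood fill over face adjacency with the loops acting as cuts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import RegionError
from .margin import (
    MarginLoop,
    azimuths,
    edge_graph,
    shortest_path,
)
from .mesh import BVH

QUADRANTS = ("M", "B", "D", "L")  # centred at 0°, 90°, 180°, 270° from mesial


@dataclass
class StandardPoints:
    """The seven labelled landmarks on the *anatomical* occlusal surface.

    Labels: "MB", "DB", "ML", "DL" (graded cusps), "D5" (distal cusp),
    "MR", "DR" (mesial / distal marginal ridges).
    """

    points: dict  # label -> (3,) array

    CUSPS = ("MB", "DB", "ML", "DL")
    ALL = ("MB", "DB", "D5", "DL", "ML", "MR", "DR")

    def __post_init__(self):
        labels = list(self.points)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate landmark labels")
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}

    def array(self, labels=None) -> np.ndarray:
        labels = labels if labels is not None else list(self.points)
        return np.array([self.points[k] for k in labels])


@dataclass
class RegionPartition:
    """Face sets and boundary loops of one prepared tooth."""

    margin: MarginLoop
    lower_boundary: MarginLoop
    upper_boundary: MarginLoop
    occlusal_boundary: MarginLoop
    band_faces: np.ndarray
    axial_faces: np.ndarray
    quadrant_faces: dict          # "M"/"B"/"D"/"L" -> face index array
    occlusal_faces: np.ndarray
    occlusal_feet: dict = field(default_factory=dict)  # landmark -> foot point


# ---------------------------------------------------------------------------
# Loop construction helpers
# ---------------------------------------------------------------------------

def _snap_loop(prepared: trimesh.Trimesh, feet: np.ndarray, graph) -> MarginLoop:
    """Snap an ordered ring of surface points to vertices and connect them
    into a closed edge path."""
    _, vids = prepared.kdtree.query(feet)
    vids = np.asarray(vids, dtype=int)
    # drop consecutive duplicates (and a duplicated closing vertex)
    keep = np.ones(len(vids), dtype=bool)
    keep[1:] = vids[1:] != vids[:-1]
    vids = vids[keep]
    if len(vids) > 1 and vids[0] == vids[-1]:
        vids = vids[:-1]
    uniq = []
    seen = set()
    for x in vids:
        if int(x) not in seen:
            uniq.append(int(x))
            seen.add(int(x))
    vids = np.asarray(uniq)
    if len(vids) < 3:
        raise RegionError("boundary collapsed onto fewer than 3 vertices")
    v = np.asarray(prepared.vertices)
    loop: list[int] = []
    for a, b in zip(vids, np.roll(vids, -1)):
        seg = shortest_path(graph, int(a), int(b))
        loop.extend(int(x) for x in seg[:-1])
    # remove any repeated visits so the cycle stays simple
    loop = list(dict.fromkeys(loop))
    arr = np.asarray(loop)
    pts = v[arr]
    length = float(np.linalg.norm(pts - np.roll(pts, -1, axis=0), axis=1).sum())
    return MarginLoop(vertices=arr, length=length, anchors=vids)


def euclidean_graph(mesh: trimesh.Trimesh):
    """Edge graph weighted by plain Euclidean edge length."""
    e = np.asarray(mesh.edges_unique)
    v = np.asarray(mesh.vertices)
    w = np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1)
    return edge_graph(len(v), e, w)


# ---------------------------------------------------------------------------
# Boundaries
# ---------------------------------------------------------------------------

def axial_lower_boundary(
    prepared: trimesh.Trimesh,
    index: BVH,
    margin: MarginLoop,
    p=(0.0, 0.0, 1.0),
    offset: float = 0.8,
    graph=None,
) -> MarginLoop:
    """Lower boundary of the axial band: the margin translated by ``offset``
    along the insertion axis and mapped back onto the prepared surface.

    ``offset`` should span the finish-line (chamfer) band; with offset 0 the
    margin itself is returned.
    """
    if offset == 0.0:
        return MarginLoop(
            vertices=margin.vertices.copy(),
            length=margin.length,
            anchors=margin.anchors.copy(),
        )
    p = np.asarray(p, dtype=float)
    p = p / np.linalg.norm(p)
    pts = margin.points(prepared) + offset * p
    feet, dist, _ = index.closest_points(pts)
    proj = np.asarray(prepared.vertices) @ p
    top = proj.max()
    if np.mean(feet @ p > top - 1e-6) > 0.5:
        raise RegionError(
            f"offset {offset} mm pushes the lower boundary past the mesh top"
        )
    graph = graph if graph is not None else euclidean_graph(prepared)
    return _snap_loop(prepared, feet, graph)


def axial_upper_boundary(
    prepared: trimesh.Trimesh,
    index: BVH,
    lower: MarginLoop,
    p=(0.0, 0.0, 1.0),
    t: float = 0.5,
    occlusal_height: float | None = None,
    graph=None,
) -> MarginLoop:
    """Upper boundary of the axial band.

    Each lower-boundary vertex is moved toward its vertical projection on the
    occlusal-side plane (the plane ⟂ p at the highest prepared vertex, unless
    ``occlusal_height`` overrides it), dividing the segment in ratio
    ``t : (1 − t)``; the displaced ring is mapped back onto the surface.
    Where the occlusal anatomy sits higher, the axial band is taller.
    """
    if not 0.0 < t < 1.0:
        raise RegionError("interior-division ratio t must be in (0, 1)")
    p = np.asarray(p, dtype=float)
    p = p / np.linalg.norm(p)
    v = np.asarray(prepared.vertices)
    h = float((v @ p).max()) if occlusal_height is None else float(occlusal_height)
    pts = lower.points(prepared)
    gap = h - pts @ p
    if np.any(gap <= 0):
        raise RegionError("lower boundary lies above the occlusal plane")
    targets = pts + (t * gap)[:, None] * p
    feet, _, _ = index.closest_points(targets)
    graph = graph if graph is not None else euclidean_graph(prepared)
    loop = _snap_loop(prepared, feet, graph)
    if len(np.unique(loop.vertices)) < 3:
        raise RegionError("upper boundary collapsed")
    return loop


# ---------------------------------------------------------------------------
# Face-set extraction
# ---------------------------------------------------------------------------

def _loop_edge_set(loop: MarginLoop):
    vs = loop.vertices
    pairs = np.column_stack([vs, np.roll(vs, -1)])
    return {tuple(sorted((int(a), int(b)))) for a, b in pairs}


def _components_with_cuts(mesh: trimesh.Trimesh, loops) -> np.ndarray:
    """Connected components of face adjacency after cutting the loop edges."""
    cut = set()
    for lp in loops:
        cut |= _loop_edge_set(lp)
    fa = mesh.face_adjacency
    fae = np.sort(mesh.face_adjacency_edges, axis=1)
    keep = np.array(
        [tuple(e) not in cut for e in map(tuple, fae)], dtype=bool
    )
    fa = fa[keep]
    n = len(mesh.faces)
    g = coo_matrix(
        (np.ones(len(fa)), (fa[:, 0], fa[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(g, directed=False)
    return labels


def _touches(mesh: trimesh.Trimesh, labels: np.ndarray, loop: MarginLoop):
    """Component labels having a face incident to any loop vertex."""
    mask = np.zeros(len(mesh.vertices), dtype=bool)
    mask[loop.vertices] = True
    inc = mask[np.asarray(mesh.faces)].any(axis=1)
    return set(labels[inc].tolist())


def faces_between(mesh: trimesh.Trimesh, labels: np.ndarray,
                  loop_a: MarginLoop, loop_b: MarginLoop,
                  exclude: MarginLoop | None = None) -> np.ndarray:
    """Faces of the component(s) touching both loops (optionally required not
    to touch ``exclude``)."""
    cand = _touches(mesh, labels, loop_a) & _touches(mesh, labels, loop_b)
    if exclude is not None:
        cand -= _touches(mesh, labels, exclude)
    if not cand:
        raise RegionError("no face component lies between the two boundaries")
    return np.flatnonzero(np.isin(labels, list(cand)))


# ---------------------------------------------------------------------------
# Quadrants
# ---------------------------------------------------------------------------

def split_quadrants(
    prepared: trimesh.Trimesh,
    axial_faces: np.ndarray,
    p=(0.0, 0.0, 1.0),
    mesial_dir=(1.0, 0.0, 0.0),
    origin=None,
) -> dict:
    """Assign each axial face to M/B/D/L by the azimuth of its centroid.

    Sectors (right-handed about p, mesial at 0°): M = [−45°, 45°),
    B = [45°, 135°), D = [135°, 225°), L = [225°, 315°).  ``origin`` fixes
    the azimuth centre (default: mean face centroid; the pipeline passes the
    margin-loop centre, which sits on the insertion axis even when the walls
    are asymmetric).
    """
    centroids = np.asarray(mesh_centroids(prepared))[axial_faces]
    if origin is None:
        origin = centroids.mean(axis=0)
    az = np.degrees(azimuths(centroids, p, origin, mesial_dir))
    sector = ((az + 45.0) % 360.0) // 90.0
    out = {}
    for i, name in enumerate(QUADRANTS):
        out[name] = axial_faces[sector == i]
        if len(out[name]) == 0:
            warnings.warn(
                f"quadrant {name} is empty; its taper is undefined",
                stacklevel=2,
            )
    return out


def mesh_centroids(mesh: trimesh.Trimesh) -> np.ndarray:
    return np.asarray(mesh.triangles).mean(axis=1)


# ---------------------------------------------------------------------------
# Occlusal area
# ---------------------------------------------------------------------------

def occlusal_area(
    anatomical: trimesh.Trimesh,
    index: BVH,
    prepared: trimesh.Trimesh,
    pts: StandardPoints,
    p=(0.0, 0.0, 1.0),
    graph=None,
):
    """Occlusal reduction area: feet of the seven standard points on the
    prepared surface, joined in cyclic azimuthal order by geodesic paths.

    Returns ``(boundary_loop, feet_dict)``; the enclosed face set is
    extracted later together with the other regions.
    """
    labels = [k for k in StandardPoints.ALL if k in pts.points]
    query = pts.array(labels)
    feet, _, _ = index.closest_points(query)
    feet_dict = {k: feet[i] for i, k in enumerate(labels)}
    origin = feet.mean(axis=0)
    az = azimuths(feet, p, origin)
    if len(np.unique(np.round(az, 6))) < 3:
        raise RegionError("standard-point feet are collinear in projection")
    order = np.argsort(az, kind="stable")
    graph = graph if graph is not None else euclidean_graph(prepared)
    loop = _snap_loop(prepared, feet[order], graph)
    return loop, feet_dict


def occlusal_faces_from_loop(
    prepared: trimesh.Trimesh,
    labels: np.ndarray,
    loop: MarginLoop,
    upper: MarginLoop,
) -> np.ndarray:
    """The cap component enclosed by the occlusal boundary (touches the
    occlusal loop but not the axial upper boundary)."""
    cand = _touches(prepared, labels, loop) - _touches(prepared, labels, upper)
    if not cand:
        raise RegionError("occlusal cap not found inside the boundary")
    return np.flatnonzero(np.isin(labels, list(cand)))


# ---------------------------------------------------------------------------
# Full partition
# ---------------------------------------------------------------------------

def build_partition(
    anatomical: trimesh.Trimesh,
    prepared: trimesh.Trimesh,
    index: BVH,
    margin_loop: MarginLoop,
    pts: StandardPoints,
    p=(0.0, 0.0, 1.0),
    mesial_dir=(1.0, 0.0, 0.0),
    band_offset: float = 0.8,
    t: float = 0.5,
) -> RegionPartition:
    """Compose all region boundaries and face sets for one specimen."""
    graph = euclidean_graph(prepared)
    lower = axial_lower_boundary(prepared, index, margin_loop, p, band_offset, graph)
    upper = axial_upper_boundary(prepared, index, lower, p, t, graph=graph)
    occ_loop, feet = occlusal_area(anatomical, index, prepared, pts, p, graph)
    labels = _components_with_cuts(prepared, [margin_loop, lower, upper, occ_loop])
    band = faces_between(prepared, labels, margin_loop, lower)
    axial = faces_between(prepared, labels, lower, upper, exclude=margin_loop)
    occl = occlusal_faces_from_loop(prepared, labels, occ_loop, upper)
    quads = split_quadrants(prepared, axial, p, mesial_dir,
                            origin=margin_loop.points(prepared).mean(axis=0))
    return RegionPartition(
        margin=margin_loop,
        lower_boundary=lower,
        upper_boundary=upper,
        occlusal_boundary=occ_loop,
        band_faces=band,
        axial_faces=axial,
        quadrant_faces=quads,
        occlusal_faces=occl,
        occlusal_feet=feet,
    )
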