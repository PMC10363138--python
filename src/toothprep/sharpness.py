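"""Discrete sharpness fields on a triangle mesh.

Two complementary notions of sharpness drive margin detection:

* **Vertex sharpness** — the magnitude of the cotangent-weighted Laplacian of
  the vertex coordinates,

      (Δf)_i = (1/Ω_i) Σ_{(i,j)}  (cot α_ij + cot β_ij)/2 · (v_i − v_j),

  where α_ij, β_ij are the angles opposite edge (i, j) in its two incident
  triangles and Ω_i is the vertex cell area.  This is the discrete
  mean-curvature normal: ‖(Δf)_i‖ ≈ 2·H at vertex i, so it is large exactly on
  creases such as a chamfer finish line.

* **Edge sharpness** — each edge length is rescaled by how far its two
  incident face normals disagree,

      e'_ij = (n_ijk · n_jil + 1) / 2 · e_ij,

  so a perfectly flat edge keeps its length (factor 1), a right-angle crease
  is halved, and a fold-back edge collapses to 0.  Shortest paths under e'
  therefore prefer running *along* sharp feature lines.

Boundary edges (one incident face) keep their original length; vertices with
no incident face are excluded (with a warning) from the Laplacian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.sparse import coo_matrix

COT_CLAMP = 100.0  # survive near-degenerate (sliver) triangles


@dataclass
class SharpnessFields:
    """Per-vertex Laplacian data and per-edge adjusted lengths."""

    laplacian: np.ndarray        # (n, 3) mean-curvature normal, mm^-1 scale
    magnitude: np.ndarray        # (n,) ‖(Δf)_i‖
    cell_area: np.ndarray        # (n,) Ω_i, mm²
    edges: np.ndarray            # (m, 2) unique vertex pairs
    edge_length: np.ndarray      # (m,) e_ij, mm
    adjusted_length: np.ndarray  # (m,) e'_ij, mm


def _cotangents(mesh: trimesh.Trimesh) -> np.ndarray:
    """Cotangent of each face angle, clamped; shape (n_faces, 3) where column
    k is the angle at face vertex k (opposite edge (k+1, k+2))."""
    tri = np.asarray(mesh.triangles, dtype=float)
    cots = np.empty((len(tri), 3))
    for k in range(3):
        a = tri[:, (k + 1) % 3] - tri[:, k]
        b = tri[:, (k + 2) % 3] - tri[:, k]
        cross = np.linalg.norm(np.cross(a, b), axis=1)
        cross = np.maximum(cross, 1e-300)
        cots[:, k] = (a * b).sum(axis=1) / cross
    return np.clip(cots, -COT_CLAMP, COT_CLAMP)


def cotangent_laplacian(mesh: trimesh.Trimesh, cell: str = "barycentric"):
    """Per-vertex mean-curvature normals and their magnitudes.

    ``cell`` selects the vertex-area convention: "barycentric" (one third of
    the incident triangle areas; robust to obtuse triangles, the default) or
    "mixed" (Voronoi-style mixed areas).

    Returns ``(laplacian (n,3), magnitude (n,), cell_area (n,))``.
    """
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces)
    n = len(v)
    cots = _cotangents(mesh)
    areas = np.asarray(mesh.area_faces)

    rows, cols, vals = [], [], []
    for k in range(3):
        i, j = f[:, (k + 1) % 3], f[:, (k + 2) % 3]
        w = 0.5 * cots[:, k]  # this face's half-cotangent for edge (i, j)
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([w, w])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    w = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    deg = np.asarray(w.sum(axis=1)).ravel()

    if cell == "mixed":
        omega = _mixed_cell_areas(v, f, cots, areas)
    else:
        omega = np.zeros(n)
        np.add.at(omega, f.ravel(), np.repeat(areas / 3.0, 3))

    isolated = omega <= 0
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} vertices have no incident face; "
            "their sharpness is set to 0",
            stacklevel=2,
        )
        omega[isolated] = 1.0

    lap = (deg[:, None] * v - w @ v) / omega[:, None]
    lap[isolated] = 0.0
    mag = np.linalg.norm(lap, axis=1)
    return lap, mag, omega


def _mixed_cell_areas(v, f, cots, areas) -> np.ndarray:
    """Mixed Voronoi cell areas (Meyer et al. convention)."""
    n = len(v)
    omega = np.zeros(n)
    obtuse = (cots < 0).any(axis=1)
    # non-obtuse: Voronoi area  1/8 * (|e1|² cot α1 + |e2|² cot α2) per corner
    tri = v[f]
    for k in range(3):
        i = f[:, k]
        e1 = tri[:, (k + 1) % 3] - tri[:, k]
        e2 = tri[:, (k + 2) % 3] - tri[:, k]
        # cot of angles opposite those edges, i.e. at vertices k+2 / k+1
        voro = ((e1**2).sum(1) * cots[:, (k + 2) % 3]
                + (e2**2).sum(1) * cots[:, (k + 1) % 3]) / 8.0
        # obtuse fallback: half the face area at the obtuse corner, quarter else
        at_corner = np.where(cots[:, k] < 0, areas / 2.0, areas / 4.0)
        contrib = np.where(obtuse, at_corner, voro)
        np.add.at(omega, i, contrib)
    return omega


def adjusted_edge_lengths(mesh: trimesh.Trimesh):
    """Sharpness-adjusted edge lengths.

    Returns ``(edges (m,2), length (m,), adjusted (m,))`` over the unique
    edges of the mesh.  Interior edges are scaled by ``(n1·n2 + 1)/2`` using
    their two incident unit face normals; boundary edges are left unchanged.
    """
    edges = np.asarray(mesh.edges_unique)
    v = np.asarray(mesh.vertices, dtype=float)
    length = np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1)
    factor = np.ones(len(edges))
    fa = mesh.face_adjacency            # (k, 2) adjacent face pairs
    fae = mesh.face_adjacency_edges     # (k, 2) shared vertex pairs
    if len(fa):
        normals = np.asarray(mesh.face_normals)
        dots = (normals[fa[:, 0]] * normals[fa[:, 1]]).sum(axis=1)
        fac = np.clip((dots + 1.0) / 2.0, 0.0, 1.0)
        # map shared-edge vertex pairs onto unique-edge rows
        key = np.sort(edges, axis=1)
        lut = {(int(a), int(b)): i for i, (a, b) in enumerate(key)}
        idx = np.fromiter(
            (lut[(int(a), int(b))] for a, b in np.sort(fae, axis=1)),
            dtype=int,
            count=len(fae),
        )
        factor[idx] = fac
    return edges, length, factor * length


def compute_sharpness(mesh: trimesh.Trimesh, cell: str = "barycentric") -> SharpnessFields:
    """Convenience wrapper computing both vertex and edge sharpness."""
    lap, mag, omega = cotangent_laplacian(mesh, cell=cell)
    edges, length, adjusted = adjusted_edge_lengths(mesh)
    return SharpnessFields(
        laplacian=lap,
        magnitude=mag,
        cell_area=omega,
        edges=edges,
        edge_length=length,
        adjusted_length=adjusted,
    )


def export_sharpness_ply(mesh: trimesh.Trimesh, fields: SharpnessFields, path) -> None:
    """Debug export: sharpness magnitude as a grayscale vertex color ramp."""
    m = mesh.copy()
    mag = fields.magnitude
    hi = np.percentile(mag, 99) or 1.0
    shade = np.clip(mag / hi, 0, 1)
    rgba = np.empty((len(mag), 4), dtype=np.uint8)
    rgba[:, :3] = (shade[:, None] * 255).astype(np.uint8)
    rgba[:, 3] = 255
    m.visual.vertex_colors = rgba
    data = m.export(file_type="ply", encoding="ascii")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(str(path), mode) as fh:
        fh.write(data)
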