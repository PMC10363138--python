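"""The seven evaluation numbers of one prepared tooth.

* Four cusp reductions (MB, DB, ML, DL): the shortest distance from each
  anatomical cusp tip to the prepared surface (mm).
* Two total occlusal convergence values: the taper of a face f against the
  path of insertion p is ``90° − angle(p, n_f)``; the per-wall taper T is the
  area-weighted mean over the wall's quadrant,

      T = 90° − (1/A) Σ_f a_f · arccos(p·n_f),   A = Σ_f a_f,

  and TOC sums opposing walls: TOC_MD = T_M + T_D, TOC_BL = T_B + T_L.
  Positive taper = convergent wall, negative = undercut.
* Margin width: projected band area over mean perimeter (see
  :mod:`toothprep.margin`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from shapely.geometry import Point, Polygon

from .errors import GeometryError, TaperUndefinedError
from .margin import (
    MarginSearchConfig,
    connect_margin,
    margin_band_width,
    project_loop,
    refine_on_prepared,
    seed_vertices,
    trace_to_margin,
)
from .mesh import BVH, build_bvh, register_icp, vertex_adjacency
from .regions import RegionPartition, StandardPoints, build_partition
from .sharpness import compute_sharpness


# ---------------------------------------------------------------------------
# Taper
# ---------------------------------------------------------------------------

def face_taper(normal, p) -> float:
    """Taper of a single face in degrees: 0 for a wall parallel to the axis,
    positive when converging occlusally, negative for an undercut."""
    n = np.asarray(normal, dtype=float)
    p = np.asarray(p, dtype=float)
    nn, pp = np.linalg.norm(n), np.linalg.norm(p)
    if nn < 1e-12 or pp < 1e-12:
        raise GeometryError("zero-length normal or axis")
    cosang = np.clip((n @ p) / (nn * pp), -1.0, 1.0)
    return 90.0 - float(np.degrees(np.arccos(cosang)))


def average_taper(mesh: trimesh.Trimesh, faces, p) -> tuple[float, float]:
    """Area-weighted mean taper (degrees) and total area (mm²) of a face set."""
    faces = np.asarray(faces)
    if len(faces) == 0:
        raise TaperUndefinedError("empty face set")
    p = np.asarray(p, dtype=float)
    p = p / np.linalg.norm(p)
    normals = np.asarray(mesh.face_normals)[faces]
    areas = np.asarray(mesh.area_faces)[faces]
    cosang = np.clip(normals @ p, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    a = float(areas.sum())
    t = 90.0 - float((areas * ang).sum() / a)
    return t, a


@dataclass
class TaperResult:
    """Per-wall tapers, quadrant areas and the two TOC values (degrees)."""

    tapers: dict       # "M"/"B"/"D"/"L" -> degrees
    areas: dict        # mm² per quadrant
    toc_md: float
    toc_bl: float


def total_occlusal_convergence(
    mesh: trimesh.Trimesh, partition: RegionPartition, p
) -> TaperResult:
    """TOC in both planes from the quadrant face sets."""
    tapers, areas = {}, {}
    for name, faces in partition.quadrant_faces.items():
        if len(faces) == 0:
            raise TaperUndefinedError(f"quadrant {name} has no faces")
        tapers[name], areas[name] = average_taper(mesh, faces, p)
    return TaperResult(
        tapers=tapers,
        areas=areas,
        toc_md=tapers["M"] + tapers["D"],
        toc_bl=tapers["B"] + tapers["L"],
    )


# ---------------------------------------------------------------------------
# Cusp reduction
# ---------------------------------------------------------------------------

def cusp_reduction(standard_point, prepared_index: BVH) -> float:
    """Shortest distance (mm) from an anatomical cusp tip to the prepared
    surface (BVH closest-point query)."""
    return prepared_index.closest_point(standard_point).distance


def min_occlusal_reduction(
    anatomical: trimesh.Trimesh,
    prepared_index: BVH,
    partition: RegionPartition,
    prepared: trimesh.Trimesh,
    p=(0.0, 0.0, 1.0),
) -> float:
    """Experimental: the minimum reduction anywhere over the occlusal area.

    Scans anatomical vertices whose projection falls inside the projected
    occlusal boundary and takes the smallest closest-point distance to the
    prepared surface.  Proposed as a future evaluation criterion; reported in
    the provenance log only, never graded.
    """
    ring = project_loop(
        np.asarray(prepared.vertices)[partition.occlusal_boundary.vertices], p
    )
    poly = Polygon(ring)
    if not poly.is_valid:
        poly = poly.buffer(0)
    v = np.asarray(anatomical.vertices)
    flat = project_loop(v, p)
    proj = v @ np.asarray(p, dtype=float)
    top_half = proj > np.median(proj)  # only the crown side can be occlusal
    inside = np.array(
        [top_half[i] and poly.contains(Point(*flat[i])) for i in range(len(v))]
    )
    if not inside.any():
        raise GeometryError("no anatomical vertices over the occlusal area")
    _, dist, _ = prepared_index.closest_points(v[inside])
    return float(dist.min())


# ---------------------------------------------------------------------------
# Full specimen evaluation
# ---------------------------------------------------------------------------

@dataclass
class MeasurementSet:
    """The seven reported numbers for one specimen (one table row)."""

    specimen: str
    reduction_mb: float
    reduction_db: float
    reduction_ml: float
    reduction_dl: float
    toc_md: float
    toc_bl: float
    margin_width: float

    FIELDS = (
        "reduction_mb", "reduction_db", "reduction_ml", "reduction_dl",
        "toc_md", "toc_bl", "margin_width",
    )

    def to_dict(self) -> dict:
        d = {"specimen": self.specimen}
        d.update({f: float(getattr(self, f)) for f in self.FIELDS})
        return d


@dataclass
class EvalConfig:
    """End-to-end pipeline configuration.

    axis / mesial_dir
        Path of insertion p and the mesial direction (defaults +z / +x);
        buccal is 90° counter-clockwise from mesial about p.
    epsilon, seed_count, seed_height_frac
        Margin-search parameters (see :class:`MarginSearchConfig`).
    band_offset
        Height (mm) of the lower axial boundary above the margin; should
        span the chamfer band (default 0.8 mm ≈ twice a 0.4 mm chamfer).
    t
        Interior-division ratio placing the upper axial boundary (default 0.5).
    register
        Run ICP to align anatomical onto prepared first (default False:
        inputs are assumed pre-registered, as scanner software exports them).
    """

    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    mesial_dir: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    epsilon: float = 0.15
    seed_count: int = 12
    seed_height_frac: float = 0.25
    band_offset: float = 0.8
    t: float = 0.5
    register: bool = False
    experimental_min_reduction: bool = False

    def margin_config(self) -> MarginSearchConfig:
        return MarginSearchConfig(
            epsilon=self.epsilon,
            seed_count=self.seed_count,
            axis=np.asarray(self.axis, dtype=float),
            seed_height_frac=self.seed_height_frac,
        )


@dataclass
class SpecimenEvaluation:
    """Everything the pipeline produced for one specimen."""

    measurement: MeasurementSet
    taper: TaperResult
    partition: RegionPartition
    prepared: trimesh.Trimesh
    anatomical: trimesh.Trimesh
    provenance: dict


def detect_margin(anatomical, prepared, index, fields, cfg: MarginSearchConfig,
                  reference=None):
    """Seed → trace → refine → connect; returns the margin loop."""
    adjacency_a = vertex_adjacency(anatomical)
    adjacency_p = vertex_adjacency(prepared)
    seeds = seed_vertices(anatomical, cfg, reference)
    av = np.asarray(anatomical.vertices)
    anchors = []
    for s in seeds:
        cand = trace_to_margin(anatomical, index, int(s), cfg, adjacency_a)
        anchors.append(
            refine_on_prepared(prepared, fields, av[cand], adjacency_p,
                               search_radius=1.5 * cfg.epsilon)
        )
    return connect_margin(prepared, fields, anchors, cfg.axis, reference), seeds


def evaluate_specimen(
    anatomical: trimesh.Trimesh,
    prepared: trimesh.Trimesh,
    pts: StandardPoints,
    cfg: EvalConfig | None = None,
    specimen: str = "specimen",
) -> SpecimenEvaluation:
    """Run the complete margin → regions → metrics pipeline."""
    cfg = cfg if cfg is not None else EvalConfig()
    if cfg.register:
        # the two scans only coincide below the margin; trim the crown-side
        # correspondences so the shared cervical/root region drives the fit
        xf = register_icp(anatomical, prepared, trim_fraction=0.5)
        anatomical = anatomical.copy()
        anatomical.vertices = xf.apply(np.asarray(anatomical.vertices))
        pts = StandardPoints({k: xf.apply(v[None])[0] for k, v in pts.points.items()})

    index = build_bvh(prepared)
    fields = compute_sharpness(prepared)
    mcfg = cfg.margin_config()
    loop, seeds = detect_margin(
        anatomical, prepared, index, fields, mcfg, cfg.mesial_dir
    )
    partition = build_partition(
        anatomical, prepared, index, loop, pts,
        p=cfg.axis, mesial_dir=cfg.mesial_dir,
        band_offset=cfg.band_offset, t=cfg.t,
    )
    band = margin_band_width(
        prepared, loop, partition.lower_boundary, cfg.axis,
        faces=partition.band_faces,
    )
    taper = total_occlusal_convergence(prepared, partition, cfg.axis)
    reductions = {
        k: cusp_reduction(pts.points[k], index)
        for k in pts.points
    }
    measurement = MeasurementSet(
        specimen=specimen,
        reduction_mb=reductions["MB"],
        reduction_db=reductions["DB"],
        reduction_ml=reductions["ML"],
        reduction_dl=reductions["DL"],
        toc_md=taper.toc_md,
        toc_bl=taper.toc_bl,
        margin_width=band.width,
    )
    provenance = {
        "epsilon_mm": cfg.epsilon,
        "seed_count": cfg.seed_count,
        "band_offset_mm": cfg.band_offset,
        "t_ratio": cfg.t,
        "anchors": [int(a) for a in loop.anchors],
        "seeds": [int(s) for s in seeds],
        "quadrant_areas_mm2": {k: float(v) for k, v in taper.areas.items()},
        "band_area_mm2": band.area,
        "band_perimeters_mm": [band.outer_perimeter, band.inner_perimeter],
        "ridge_reductions_mm": {
            k: float(reductions[k]) for k in reductions
            if k not in StandardPoints.CUSPS
        },
    }
    if cfg.experimental_min_reduction:
        provenance["min_occlusal_reduction_mm_experimental"] = (
            min_occlusal_reduction(anatomical, index, partition, prepared, cfg.axis)
        )
    return SpecimenEvaluation(
        measurement=measurement,
        taper=taper,
        partition=partition,
        prepared=prepared,
        anatomical=anatomical,
        provenance=provenance,
    )
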