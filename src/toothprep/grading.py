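"""Rubric-based grading of the measurements and color-coded mesh output.

Each of the six graded criteria (four cusp reductions and the two TOC
planes) maps a measured value to grade A (acceptable, 2 points, green),
B (marginally acceptable, 1 point, yellow) or C (unacceptable, 0 points,
red).  The default rubric for a mandibular first molar anatomic-contour
crown:

    MB / DB cusp reduction   A: 1.5–2.0 mm   B: 1.0–1.5 or 2.0–2.5 mm
    ML / DL cusp reduction   A: 1.0–1.5 mm   B: 0.5–1.0 or 1.5–2.0 mm
    TOC (MD and BL planes)   A: 6°–20°       B: 0°–6° or 20°–30°
                             C otherwise (undercut TOC < 0° is always C)

Boundary convention: a value exactly on an acceptable/marginal boundary
takes the better grade; exactly on a marginal/unacceptable boundary it stays
marginal (intervals are checked best-first as closed intervals).  Margin
width is reported but carries no grade.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .errors import IncompleteMeasurementError, RubricError
from .metrics import MeasurementSet
from .regions import RegionPartition, StandardPoints

GRADE_POINTS = {"A": 2, "B": 1, "C": 0}
GRADE_COLORS = {
    "A": (0, 170, 0),
    "B": (255, 200, 0),
    "C": (220, 30, 30),
}
NEUTRAL_COLOR = (160, 160, 160)

CRITERIA = (
    "reduction_mb", "reduction_db", "reduction_ml", "reduction_dl",
    "toc_md", "toc_bl",
)


@dataclass
class CriterionRubric:
    """Closed acceptable interval plus closed marginal intervals."""

    acceptable: tuple            # (lo, hi)
    marginal: tuple              # ((lo1, hi1), (lo2, hi2))

    def grade(self, value: float) -> str:
        lo, hi = self.acceptable
        if lo <= value <= hi:
            return "A"
        for mlo, mhi in self.marginal:
            if mlo <= value <= mhi:
                return "B"
        return "C"


def default_rubric() -> dict:
    buccal = CriterionRubric((1.5, 2.0), ((1.0, 1.5), (2.0, 2.5)))
    lingual = CriterionRubric((1.0, 1.5), ((0.5, 1.0), (1.5, 2.0)))
    toc = CriterionRubric((6.0, 20.0), ((0.0, 6.0), (20.0, 30.0)))
    return {
        "reduction_mb": buccal,
        "reduction_db": buccal,
        "reduction_ml": lingual,
        "reduction_dl": lingual,
        "toc_md": toc,
        "toc_bl": toc,
    }


def load_rubric(path) -> dict:
    """Rubric override from JSON: {criterion: {"acceptable": [lo, hi],
    "marginal": [[lo, hi], [lo, hi]]}}."""
    with open(str(path)) as fh:
        raw = json.load(fh)
    rub = default_rubric()
    for key, spec in raw.items():
        if key not in rub:
            raise RubricError(f"unknown criterion {key!r}")
        rub[key] = CriterionRubric(
            acceptable=tuple(spec["acceptable"]),
            marginal=tuple(tuple(m) for m in spec["marginal"]),
        )
    return rub


def grade_value(criterion: str, value: float, rubric: dict | None = None):
    """Grade one measured value; returns (grade, points)."""
    rubric = rubric if rubric is not None else default_rubric()
    if criterion not in rubric:
        raise RubricError(f"unknown criterion {criterion!r}")
    g = rubric[criterion].grade(float(value))
    return g, GRADE_POINTS[g]


@dataclass
class GradeReport:
    """Six grades, their points and the 0–12 total for one specimen."""

    specimen: str
    grades: dict                 # criterion -> "A"/"B"/"C"
    points: dict                 # criterion -> 0/1/2
    values: dict                 # criterion -> measured value
    margin_width: float
    total: int = field(init=False)

    def __post_init__(self):
        self.total = int(sum(self.points.values()))

    def to_dict(self) -> dict:
        return {
            "specimen": self.specimen,
            "criteria": {
                c: {
                    "value": float(self.values[c]),
                    "grade": self.grades[c],
                    "points": self.points[c],
                    "color": GRADE_COLORS[self.grades[c]],
                }
                for c in CRITERIA
            },
            "margin_width_mm": float(self.margin_width),
            "total_points": self.total,
        }


def score_specimen(m: MeasurementSet, rubric: dict | None = None) -> GradeReport:
    """Grade all six criteria of one measurement set."""
    rubric = rubric if rubric is not None else default_rubric()
    grades, points, values = {}, {}, {}
    for c in CRITERIA:
        v = getattr(m, c, None)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise IncompleteMeasurementError(f"measurement {c} missing")
        g, p = grade_value(c, v, rubric)
        grades[c], points[c], values[c] = g, p, float(v)
    return GradeReport(
        specimen=m.specimen,
        grades=grades,
        points=points,
        values=values,
        margin_width=m.margin_width,
    )


def score_table(measurements, rubric: dict | None = None) -> pd.DataFrame:
    """Mean ± sample SD of the 0/1/2 points per criterion over specimens.

    ``measurements`` is a list of :class:`MeasurementSet` or a DataFrame with
    the measurement columns.  With a single specimen the SD is reported as 0
    and flagged in the ``sd_defined`` column.
    """
    if isinstance(measurements, pd.DataFrame):
        rows = [
            MeasurementSet(
                specimen=str(r.get("specimen", i)),
                **{f: float(r[f]) for f in MeasurementSet.FIELDS},
            )
            for i, r in measurements.iterrows()
        ]
    else:
        rows = list(measurements)
    if not rows:
        raise IncompleteMeasurementError("no specimens to score")
    reports = [score_specimen(m, rubric) for m in rows]
    data = {c: [r.points[c] for r in reports] for c in CRITERIA}
    df = pd.DataFrame(data)
    single = len(df) < 2
    out = pd.DataFrame(
        {
            "mean_points": df.mean(),
            "sd_points": 0.0 if single else df.std(ddof=1),
            "sd_defined": not single,
        }
    )
    out.index.name = "criterion"
    return out


# ---------------------------------------------------------------------------
# Color-coded output
# ---------------------------------------------------------------------------

_QUADRANT_TO_TOC = {"M": "toc_md", "D": "toc_md", "B": "toc_bl", "L": "toc_bl"}
_CUSP_TO_CRIT = {
    "MB": "reduction_mb", "DB": "reduction_db",
    "ML": "reduction_ml", "DL": "reduction_dl",
}


def colorize(
    prepared: trimesh.Trimesh,
    partition: RegionPartition,
    report: GradeReport,
) -> trimesh.Trimesh:
    """Copy of the prepared mesh with grade colors painted per region.

    Axial quadrants take their TOC-plane grade color; the occlusal area is
    split by nearest graded-cusp foot and takes the cusp grade colors; the
    ungraded margin band and everything else stay neutral grey.
    """
    mesh = prepared.copy()
    n = len(mesh.faces)
    colors = np.tile(np.array(NEUTRAL_COLOR + (255,), dtype=np.uint8), (n, 1))
    for quad, crit in _QUADRANT_TO_TOC.items():
        faces = partition.quadrant_faces.get(quad, np.empty(0, dtype=int))
        colors[faces, :3] = GRADE_COLORS[report.grades[crit]]
    occ = partition.occlusal_faces
    if len(occ):
        feet_labels = [k for k in StandardPoints.CUSPS
                       if k in partition.occlusal_feet]
        feet = np.array([partition.occlusal_feet[k] for k in feet_labels])
        centroids = np.asarray(mesh.triangles[occ]).mean(axis=1)
        nearest = np.argmin(
            np.linalg.norm(centroids[:, None, :] - feet[None], axis=2), axis=1
        )
        for i, lab in enumerate(feet_labels):
            colors[occ[nearest == i], :3] = GRADE_COLORS[
                report.grades[_CUSP_TO_CRIT[lab]]
            ]
    mesh.visual.face_colors = colors
    return mesh


def export_colored_ply(mesh: trimesh.Trimesh, path) -> None:
    from .mesh import save_mesh

    save_mesh(mesh, path, fmt="ply", binary=False)
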