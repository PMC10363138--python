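"""Synthetic abutment phantoms with analytically known ground truth, plus the
packaged 35-specimen measurement table.

The phantom pair emulates a scanned mandibular first molar before and after
crown preparation:

* **prepared** — root cylinder up to the margin height, a 45° chamfer band
  ending in a sharp crease at the margin circle, four axial wall sectors
  with per-wall taper (smoothly blended over a few degrees at the sector
  boundaries), and a flat occlusal table;
* **anatomical** — identical root below the margin (so the ε-walk of margin
  detection works), a cylindrical crown continuing at the margin radius, and
  an occlusal cap carrying cone-shaped cusps and marginal-ridge bumps whose
  apex heights above the prepared table are exactly the nominal reductions.

Meshes are structured rings (azimuth × graded height rows), refined near the
creases; optional Gaussian noise is applied along vertex normals with a
fixed seed to mimic scanner precision.  Every target quantity is recorded in
a :class:`PhantomTruth` before noise is applied.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import trimesh

from .errors import GenerationError
from .metrics import MeasurementSet
from .regions import StandardPoints

_FIXTURE_NAME = "table1_sae.csv"
_FIXTURE_SHA256 = "d5e1962e935838bc861e47ab2bf697a6b784e8d39129614b57c966fb7a941e91"

# landmark azimuths (degrees from mesial = +x, counter-clockwise via buccal = +y)
LANDMARK_AZIMUTH = {
    "MR": 0.0, "MB": 45.0, "DB": 135.0, "D5": 157.5,
    "DR": 180.0, "DL": 225.0, "ML": 315.0,
}


# ---------------------------------------------------------------------------
# Specification and truth record
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry and noise parameters of one phantom pair (mm / degrees)."""

    margin_radius: float = 4.6
    margin_height: float = 3.0
    chamfer_width: float = 0.4          # horizontal depth of the chamfer band
    chamfer_rise: float | None = None   # vertical rise; default = width (45°)
    taper_m: float = 6.0
    taper_b: float = 6.0
    taper_d: float = 6.0
    taper_l: float = 6.0
    wall_height: float = 4.0
    reduction_mb: float = 1.5
    reduction_db: float = 1.5
    reduction_ml: float = 1.5
    reduction_dl: float = 1.5
    reduction_d5: float = 1.5
    ridge_reduction: float = 1.0
    cusp_ring_frac: float = 0.39        # cusp-tip ring radius / margin radius
    ridge_ring_frac: float = 0.55
    bump_width: float = 0.65            # cone support radius of each feature
    n_azimuth: int = 96                 # must be a multiple of 16
    fine_res: float = 0.08              # row spacing near creases
    coarse_res: float = 0.35
    blend_deg: float = 3.0              # taper transition half-width
    noise_sigma: float = 0.01           # mm along vertex normals (10 µm)
    seed: int = 0

    def __post_init__(self):
        if self.chamfer_rise is None:
            self.chamfer_rise = self.chamfer_width
        if not self.margin_radius > self.chamfer_width > 0:
            raise GenerationError("need margin radius > chamfer width > 0")
        if self.fine_res >= self.chamfer_width / 2:
            raise GenerationError(
                "resolution too coarse: the chamfer crease is not resolvable"
            )
        if self.noise_sigma >= 0.05:
            raise GenerationError("noise sigma must stay below epsilon/3")
        if self.n_azimuth % 16:
            raise GenerationError("n_azimuth must be a multiple of 16")
        for t in (self.taper_m, self.taper_b, self.taper_d, self.taper_l):
            r_top = (self.margin_radius - self.chamfer_width
                     - self.wall_height * np.tan(np.radians(t)))
            if r_top < 0.8 * self.margin_radius * self.cusp_ring_frac + 0.3:
                raise GenerationError(
                    f"taper {t}° collapses the occlusal table"
                )

    @property
    def tapers(self) -> dict:
        return {"M": self.taper_m, "B": self.taper_b,
                "D": self.taper_d, "L": self.taper_l}

    @property
    def wall_base_radius(self) -> float:
        return self.margin_radius - self.chamfer_width

    @property
    def wall_base_z(self) -> float:
        return self.margin_height + self.chamfer_rise

    @property
    def top_z(self) -> float:
        return self.wall_base_z + self.wall_height


@dataclass
class PhantomTruth:
    """Analytic ground truth recorded at construction time."""

    tapers: dict
    toc_md: float
    toc_bl: float
    reductions: dict             # MB/DB/ML/DL/D5
    ridge_reductions: dict       # MR/DR
    margin_radius: float
    margin_z: float
    spec: PhantomSpec

    def band_width(self, offset: float) -> float:
        """Expected projected band width for a lower boundary built by
        translating the margin by ``offset`` along the axis and projecting it
        back onto the ideal profile (averaged over the four walls)."""
        inner = [
            _profile_foot_radius(self.spec, t, offset)
            for t in self.tapers.values()
        ]
        return self.margin_radius - float(np.mean(inner))

    def margin_rms(self, points: np.ndarray) -> float:
        """RMS distance of loop points from the true margin circle."""
        pts = np.asarray(points, dtype=float)
        rho = np.linalg.norm(pts[:, :2], axis=1)
        d2 = (rho - self.margin_radius) ** 2 + (pts[:, 2] - self.margin_z) ** 2
        return float(np.sqrt(d2.mean()))


def _profile_foot_radius(spec: PhantomSpec, taper_deg: float, offset: float) -> float:
    """Radial coordinate of the closest point on the ideal (ρ, z) profile to
    the margin point raised by ``offset``."""
    r, h = spec.margin_radius, spec.margin_height
    r1, z1 = spec.wall_base_radius, spec.wall_base_z
    t = np.radians(taper_deg)
    r2 = r1 - spec.wall_height * np.tan(t)
    segs = [
        ((r, 0.0), (r, h)),                    # root wall
        ((r, h), (r1, z1)),                    # chamfer
        ((r1, z1), (r2, spec.top_z)),          # axial wall
    ]
    q = np.array([r, h + offset])
    best, best_d = None, np.inf
    for (a, b) in segs:
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        ab = b - a
        s = np.clip((q - a) @ ab / (ab @ ab), 0.0, 1.0)
        foot = a + s * ab
        d = np.linalg.norm(q - foot)
        if d < best_d:
            best, best_d = foot, d
    return float(best[0])


# ---------------------------------------------------------------------------
# Mesh assembly helpers
# ---------------------------------------------------------------------------

def _graded_levels(a: float, b: float, fine_a: float, fine_b: float,
                   coarse: float, growth: float = 1.6) -> np.ndarray:
    """Monotone levels from a to b, spacing ``fine`` at the ends growing
    geometrically toward ``coarse`` in the interior."""
    mid = 0.5 * (a + b)
    left, s = [a], fine_a
    while left[-1] + s < mid and s < coarse:
        left.append(left[-1] + s)
        s *= growth
    right, s = [b], fine_b
    while right[-1] - s > mid and s < coarse:
        right.append(right[-1] - s)
        s *= growth
    lo, hi = left[-1], right[-1]
    n_mid = max(1, int(np.ceil((hi - lo) / coarse)))
    interior = np.linspace(lo, hi, n_mid + 1)
    levels = np.unique(np.concatenate([left, interior, right[::-1]]))
    return levels


def _strip(faces: list, row_a: int, row_b: int, n: int) -> None:
    """Triangulated quad strip between two vertex rows of length n."""
    for k in range(n):
        a0 = row_a + k
        a1 = row_a + (k + 1) % n
        b0 = row_b + k
        b1 = row_b + (k + 1) % n
        faces.append((a0, a1, b1))
        faces.append((a0, b1, b0))


def _taper_at(phi_deg: np.ndarray, tapers: dict, blend: float) -> np.ndarray:
    """Per-azimuth taper (degrees): piecewise constant per quadrant with a
    cosine blend of half-width ``blend`` at the 45°+k·90° boundaries."""
    values = np.array([tapers["M"], tapers["B"], tapers["D"], tapers["L"]])
    phi = np.mod(np.asarray(phi_deg, dtype=float), 360.0)
    sector = (((phi + 45.0) % 360.0) // 90.0).astype(int)
    local = (phi + 45.0) % 90.0  # 0 at the lower boundary of the sector
    out = values[sector]
    if blend > 0:
        prev = values[(sector - 1) % 4]
        nxt = values[(sector + 1) % 4]
        near_lo = local < blend
        u = local[near_lo] / blend
        w = 0.5 * (1.0 + np.sin(0.5 * np.pi * u))
        out[near_lo] = w * out[near_lo] + (1 - w) * prev[near_lo]
        near_hi = (90.0 - local) < blend
        u = (90.0 - local[near_hi]) / blend
        w = 0.5 * (1.0 + np.sin(0.5 * np.pi * u))
        out[near_hi] = w * out[near_hi] + (1 - w) * nxt[near_hi]
    return out


class _Builder:
    """Accumulates rows of ring vertices and tracks row offsets."""

    def __init__(self):
        self.vertices: list[np.ndarray] = []
        self.faces: list[tuple] = []
        self.offset = 0
        self.last_row: int | None = None
        self.row_len = 0

    def add_ring(self, xyz: np.ndarray, connect: bool = True) -> int:
        start = self.offset
        self.vertices.append(xyz)
        self.offset += len(xyz)
        if connect and self.last_row is not None:
            _strip(self.faces, self.last_row, start, len(xyz))
        self.last_row = start
        self.row_len = len(xyz)
        return start

    def add_center(self, point: np.ndarray) -> int:
        start = self.offset
        self.vertices.append(point[None])
        self.offset += 1
        ring = self.last_row
        n = self.row_len
        for k in range(n):
            self.faces.append((ring + k, ring + (k + 1) % n, start))
        return start

    def mesh(self) -> trimesh.Trimesh:
        v = np.vstack(self.vertices)
        f = np.asarray(self.faces, dtype=np.int64)
        return trimesh.Trimesh(vertices=v, faces=f, process=False)


def _ring(radii, phi, z) -> np.ndarray:
    return np.column_stack([
        radii * np.cos(phi), radii * np.sin(phi),
        np.broadcast_to(z, phi.shape).copy(),
    ])


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

def _build_prepared(spec: PhantomSpec) -> trimesh.Trimesh:
    n = spec.n_azimuth
    phi = 2 * np.pi * np.arange(n) / n
    phi_deg = np.degrees(phi)
    taper = np.radians(_taper_at(phi_deg, spec.tapers, spec.blend_deg))
    b = _Builder()
    # root cylinder, refined toward the margin crease
    for z in _graded_levels(0.0, spec.margin_height, 2 * spec.fine_res,
                            spec.fine_res, spec.coarse_res):
        b.add_ring(_ring(np.full(n, spec.margin_radius), phi, z))
    # chamfer band (45°-style ramp), refined throughout
    slope = np.hypot(spec.chamfer_width, spec.chamfer_rise)
    n_ch = max(3, int(np.ceil(slope / spec.fine_res)))
    for s in np.linspace(0.0, 1.0, n_ch + 1)[1:]:
        rr = spec.margin_radius - s * spec.chamfer_width
        zz = spec.margin_height + s * spec.chamfer_rise
        b.add_ring(_ring(np.full(n, rr), phi, zz))
    # tapered axial walls
    for z in _graded_levels(spec.wall_base_z, spec.top_z, spec.fine_res,
                            spec.fine_res, spec.coarse_res)[1:]:
        rr = spec.wall_base_radius - (z - spec.wall_base_z) * np.tan(taper)
        b.add_ring(_ring(rr, phi, z))
    # flat occlusal table
    r_top = spec.wall_base_radius - spec.wall_height * np.tan(taper)
    for frac in (0.85, 0.7, 0.55, 0.4, 0.25, 0.12):
        b.add_ring(_ring(r_top * frac, phi, spec.top_z))
    b.add_center(np.array([0.0, 0.0, spec.top_z]))
    return b.mesh()


def _bump_height(xy: np.ndarray, features: dict, width: float) -> np.ndarray:
    """max-of-cones height field over 2D points; ``features`` maps label ->
    ((x, y), height)."""
    h = np.zeros(len(xy))
    for (fx, fy), height in features.values():
        d = np.hypot(xy[:, 0] - fx, xy[:, 1] - fy)
        h = np.maximum(h, height * np.clip(1.0 - d / width, 0.0, None))
    return h


def _build_anatomical(spec: PhantomSpec):
    n = spec.n_azimuth
    phi = 2 * np.pi * np.arange(n) / n
    R = spec.margin_radius
    b = _Builder()
    # root: identical levels to the prepared mesh -> exact coincidence
    for z in _graded_levels(0.0, spec.margin_height, 2 * spec.fine_res,
                            spec.fine_res, spec.coarse_res):
        b.add_ring(_ring(np.full(n, R), phi, z))
    # crown cylinder up to the occlusal base, refined near the margin
    for z in _graded_levels(spec.margin_height, spec.top_z, spec.fine_res,
                            spec.fine_res, spec.coarse_res)[1:]:
        b.add_ring(_ring(np.full(n, R), phi, z))
    # occlusal cap with cusp / ridge bumps
    tip_r = spec.cusp_ring_frac * R
    ridge_r = spec.ridge_ring_frac * R
    features = {}
    heights = {
        "MB": spec.reduction_mb, "DB": spec.reduction_db,
        "ML": spec.reduction_ml, "DL": spec.reduction_dl,
        "D5": spec.reduction_d5,
        "MR": spec.ridge_reduction, "DR": spec.ridge_reduction,
    }
    for name, az in LANDMARK_AZIMUTH.items():
        rr = ridge_r if name in ("MR", "DR") else tip_r
        a = np.radians(az)
        features[name] = ((rr * np.cos(a), rr * np.sin(a)), heights[name])
    ring_radii = sorted(
        {0.87 * R, 0.74 * R, 0.61 * R, ridge_r, 0.47 * R, tip_r,
         0.30 * R, 0.20 * R, 0.10 * R},
        reverse=True,
    )
    landmark_idx = {}
    for rr in ring_radii:
        xy = np.column_stack([rr * np.cos(phi), rr * np.sin(phi)])
        z = spec.top_z + _bump_height(xy, features, spec.bump_width)
        start = b.add_ring(np.column_stack([xy, z]))
        for name, az in LANDMARK_AZIMUTH.items():
            target_r = ridge_r if name in ("MR", "DR") else tip_r
            if abs(rr - target_r) < 1e-9:
                k = int(round(az / 360.0 * n)) % n
                landmark_idx[name] = start + k
    center_h = _bump_height(np.zeros((1, 2)), features, spec.bump_width)[0]
    b.add_center(np.array([0.0, 0.0, spec.top_z + center_h]))
    return b.mesh(), landmark_idx


def _apply_noise(mesh: trimesh.Trimesh, sigma: float, rng) -> trimesh.Trimesh:
    if sigma <= 0:
        return mesh
    normals = np.asarray(mesh.vertex_normals)
    disp = rng.normal(0.0, sigma, size=len(mesh.vertices))
    v = np.asarray(mesh.vertices) + disp[:, None] * normals
    return trimesh.Trimesh(vertices=v, faces=mesh.faces.copy(), process=False)


def make_phantom_pair(spec: PhantomSpec | None = None):
    """Build (anatomical, prepared, truth, standard_points).

    The returned :class:`StandardPoints` are taken from the (noisy)
    anatomical mesh vertices, as a user would click them on a scan.
    """
    spec = spec if spec is not None else PhantomSpec()
    prepared = _build_prepared(spec)
    anatomical, landmark_idx = _build_anatomical(spec)
    ss = np.random.SeedSequence(spec.seed)
    rng_a, rng_p = [np.random.default_rng(s) for s in ss.spawn(2)]
    anatomical = _apply_noise(anatomical, spec.noise_sigma, rng_a)
    prepared = _apply_noise(prepared, spec.noise_sigma, rng_p)
    av = np.asarray(anatomical.vertices)
    pts = StandardPoints({k: av[i].copy() for k, i in landmark_idx.items()})
    truth = PhantomTruth(
        tapers=dict(spec.tapers),
        toc_md=spec.taper_m + spec.taper_d,
        toc_bl=spec.taper_b + spec.taper_l,
        reductions={
            "MB": spec.reduction_mb, "DB": spec.reduction_db,
            "ML": spec.reduction_ml, "DL": spec.reduction_dl,
            "D5": spec.reduction_d5,
        },
        ridge_reductions={"MR": spec.ridge_reduction, "DR": spec.ridge_reduction},
        margin_radius=spec.margin_radius,
        margin_z=spec.margin_height,
        spec=spec,
    )
    return anatomical, prepared, truth, pts


def phantom_eval_config(spec: PhantomSpec, **overrides):
    """Pipeline configuration matched to a phantom's finish-line scale.

    The error bound ε must sit below the largest anatomical/prepared
    deviation inside the chamfer band (c/√2 for a 45° chamfer) or the walk
    overshoots the margin, and above the noise level; ε = min(0.15, 0.4 c)
    satisfies both for every supported phantom and keeps the crease-capture
    ball (1.5 ε) away from the chamfer's inner crease.  The lower axial
    boundary offset spans the chamfer band (twice its width).
    """
    from .metrics import EvalConfig

    params = dict(
        epsilon=min(0.15, 0.4 * spec.chamfer_width),
        band_offset=2.0 * spec.chamfer_width,
    )
    params.update(overrides)
    return EvalConfig(**params)


# ---------------------------------------------------------------------------
# Packaged measurement table
# ---------------------------------------------------------------------------

def table1_fixture() -> pd.DataFrame:
    """The packaged 35-specimen measurement table (one row per prepared
    tooth: four cusp reductions in mm, two TOC values in degrees, margin
    width in mm), integrity-checked by SHA-256."""
    data = (resources.files("toothprep") / "data" / _FIXTURE_NAME).read_bytes()
    if hashlib.sha256(data).hexdigest() != _FIXTURE_SHA256:
        raise RuntimeError("measurement-table fixture is corrupted")
    from io import BytesIO

    df = pd.read_csv(BytesIO(data))
    if len(df) != 35:
        raise RuntimeError("fixture must contain exactly 35 specimens")
    return df


def fixture_measurements() -> list[MeasurementSet]:
    """Fixture rows as :class:`MeasurementSet` objects."""
    df = table1_fixture()
    return [
        MeasurementSet(
            specimen=str(int(r["specimen"])),
            **{f: float(r[f]) for f in MeasurementSet.FIELDS},
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Simulated repeat ratings
# ---------------------------------------------------------------------------

def make_ratings(
    fixture: pd.DataFrame | None = None,
    rubric=None,
    rounds: int = 3,
    flip_prob: float = 0.0,
    seed: int = 0,
) -> dict:
    """Simulated repeat scorings for agreement statistics.

    Round 0 holds the deterministic automated grades; each later round flips
    each grade one step up or down with probability ``flip_prob`` (clamped to
    the 0–2 scale), emulating an imperfect human re-scoring.  Returns
    {criterion: (n_specimens, rounds) int array}.
    """
    from .grading import CRITERIA, score_specimen

    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip_prob must be in [0, 1]")
    measurements = (
        fixture_measurements() if fixture is None
        else [
            MeasurementSet(
                specimen=str(i),
                **{f: float(r[f]) for f in MeasurementSet.FIELDS},
            )
            for i, r in fixture.iterrows()
        ]
    )
    reports = [score_specimen(m, rubric) for m in measurements]
    rng = np.random.default_rng(seed)
    out = {}
    for crit in CRITERIA:
        base = np.array([r.points[crit] for r in reports], dtype=int)
        cols = [base]
        for _ in range(1, rounds):
            flips = rng.random(len(base)) < flip_prob
            step = rng.choice([-1, 1], size=len(base))
            col = np.clip(base + np.where(flips, step, 0), 0, 2)
            cols.append(col)
        out[crit] = np.column_stack(cols)
    return out
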