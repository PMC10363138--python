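# toothprep

Automated geometric evaluation of single-crown abutment tooth preparations
from 3D scans.

When a tooth is prepared for a full-coverage crown, three things decide
whether the crown will fit, retain and survive: enough **occlusal
reduction** at the cusp tips (room for crown material), a **total occlusal
convergence (TOC)** of the axial walls in the recommended range (taper
controls retention; undercuts prevent seating), and a well-defined
**finish line (margin)** of adequate width.  In dental schools these are
graded by faculty from visual or software-assisted inspection, with the
usual problems of inter- and intra-rater disagreement.  `toothprep`
replaces the human measurement step entirely: given a registered pair of
triangle meshes — the intact anatomical tooth scanned *before* preparation
and the prepared abutment scanned *after* — it detects the preparation
margin, partitions the prepared surface into regions, measures the seven
standard quantities, and grades them against an explicit rubric with
color-coded mesh output.  Repeat runs on the same input are bit-identical,
so intra-rater reliability is perfect by construction.

Intended users: dental-education researchers, prosthodontics instructors
building objective grading workflows, and developers of scan-analysis
tooling.

## Method

All lengths are millimetres; the path of insertion **p** (default +z) and
the mesial direction (default +x) are configuration.

1. **Margin detection.**  Sharpness is measured two ways: per vertex as the
   magnitude of the cotangent-weighted Laplacian of the coordinates
   (the discrete mean-curvature normal)

   $$(\Delta f)_i = \frac{1}{\Omega_i}\sum_{(i,j)\in E}
     \frac{\cot\alpha_{ij}+\cot\beta_{ij}}{2}\,(v_i - v_j),$$

   and per edge by rescaling each edge length with the agreement of its two
   face normals, $e'_{ij} = \tfrac{1}{2}(n_1\!\cdot\!n_2 + 1)\,e_{ij}$, so
   sharp creases become artificially "short".  Twelve seed vertices in the
   root area walk crown-ward while the anatomical surface stays within an
   error bound ε of the prepared surface (below the margin the two scans
   coincide); where they diverge, each candidate snaps to the sharpest
   nearby prepared-mesh vertex, and the twelve anchors are joined by
   shortest paths under $e'$ — the closed loop hugs the finish line.
2. **Regions.**  The margin translated by a configurable offset along p and
   projected back onto the surface gives the lower axial boundary; interior
   division (ratio t, default 0.5) toward the occlusal plane gives the upper
   boundary; the band between them is split into mesial / buccal / distal /
   lingual quadrants by centroid azimuth.  The feet of seven standard
   occlusal landmarks (five cusp tips, two marginal ridges) enclose the
   occlusal area.
3. **Measurements.**  Cusp reduction is the shortest distance from each
   anatomical cusp tip to the prepared surface (BVH + priority-queue
   closest-point query).  Per-wall taper is the area-weighted mean of
   $90° - \angle(p, n_f)$ over the quadrant, and
   $TOC_{MD} = T_M + T_D$, $TOC_{BL} = T_B + T_L$ (negative taper =
   undercut).  Margin width is the projected band area divided by the mean
   of its two projected perimeters (exactly $r_2 - r_1$ for an annulus).
4. **Grading.**  Each criterion maps to A (2 points, green), B (1, yellow)
   or C (0, red); e.g. buccal cusp reduction is acceptable in 1.5–2.0 mm,
   marginal in 1.0–1.5 or 2.0–2.5 mm, unacceptable outside; TOC is
   acceptable in 6°–20°, unacceptable above 30° or undercut.  The
   unweighted total is 0–12 points.
5. **Agreement statistics.**  Cronbach's α over repeated scoring rounds and
   linearly weighted Cohen's κ between raters, with the standard
   interpretation bands.

A synthetic phantom generator (`toothprep.synthetic`) builds
anatomical/prepared mesh pairs — root cylinder, 45° chamfer with a sharp
margin crease, per-wall tapered axial sectors, flat occlusal table versus a
cusped anatomical crown — with every target quantity known analytically,
plus optional Gaussian scan noise.  The packaged 35-specimen measurement
table ships as a CSV fixture.

## Worked example

Generate a phantom pair with known ground truth (12° TOC in both planes,
1.7 mm buccal / 1.2 mm lingual cusp reductions, 0.4 mm chamfer) and
evaluate it:

```
$ toothprep phantom --out-prefix demo --seed 42
wrote demo_anatomical.stl, demo_prepared.stl, demo_truth.json

$ toothprep evaluate demo_anatomical.stl demo_prepared.stl \
      --points demo_points.json --out demo_out
```

(`demo_points.json` maps the seven landmark labels to coordinates on the
anatomical mesh; for a phantom they are the `standard_points` entry of
`demo_truth.json`.)

`demo_out/report.json` then contains (abridged):

```json
"measurements": {
  "reduction_mb": 1.6817, "reduction_db": 1.6881,
  "reduction_ml": 1.2031, "reduction_dl": 1.2045,
  "toc_md": 12.1815, "toc_bl": 12.0636,
  "margin_width": 0.4028
},
"grades": { ... "total_points": 12 }
```

Every measurement sits within scan-noise distance of the constructed truth
(1.7 / 1.2 mm reductions, 12° TOC, ≈0.4 mm margin width), every criterion
grades A, and the total is 12/12.  `demo_out/graded.ply` holds the
color-coded mesh and `demo_out/margin.csv` the detected margin polyline.

Grading a measurement table reproduces per-criterion score means:

```
$ toothprep grade-table table1.csv
              mean_points  sd_points
reduction_mb         1.20       0.58
reduction_db         1.26       0.66
reduction_ml         0.74       0.74
reduction_dl         1.23       0.60
toc_md               0.86       0.69
toc_bl               1.37       0.73
```

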