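# Methods

## Problem and scope

Given a watertight-enough triangle mesh of a standing human in A-pose
(millimetres, +Y up), derive the body values used for obesity and
body-shape monitoring: stature, seven circumferences (chest, waist, hip,
both upper arms, both thighs), chest volume, and limb/torso lengths. The
package also provides the capture-side machinery used to validate
reconstructed bodies: perspective depth-map rendering, silhouette
landmarking, camera-placement selection from ratio-error grids, and
per-part accuracy aggregation.

## Camera model and depth maps

The camera is a symmetric perspective frustum parameterised by the vertical
field of view `fovy`, aspect ratio, and clip range `[n, f]` (mm). With
`c = cot(fovy/2)` the projection matrix has `m[0][0] = c/aspect`,
`m[1][1] = c`, bottom row `(0, 0, −1, 0)`; the canonical projection plane
sits at `z = −c`. The physical placement is a camera at height `h` m above
the floor and horizontal distance `d` m from the subject's vertical axis,
looking horizontally; the defaults (1 m, 3 m) are the placement that
minimised both ratio errors on the bundled capture grid (see Evaluation).

Rendering is a CPU z-buffer over per-triangle bounding boxes with
perspective-correct depth (1/depth interpolated linearly in screen space).
Depth maps are 8-bit, near-bright: camera distance maps linearly from
`[n, f]` onto `[255, 1]`, background is 0, and the unquantised depth is
kept per pixel so any silhouette pixel can be cast back to a world point.
No antialiasing is applied, deliberately — the landmark rules operate on
crisp binary silhouettes. `fovy` defaults to 40°, which frames a 1.9 m
subject with margin at 3 m; it is exposed as a flag.

## Landmark rules

Eleven seed points are detected on the frontal depth map from the per-row
width profile (total nonzero pixels per row and the list of maximal column
intervals). A 5-row moving average of the width and of the side contours
suppresses rasterisation jitter for the extremum/inflection rules; the raw
interval lists are used for the gap rules. In rule order:

1. **head top** — topmost silhouette row, centroid column;
2. **neck** — thinnest smoothed row within the top 30 % of silhouette
   rows. The search starts below the first local maximum of the smoothed
   width going down from the head top (the widest head row): on any rounded
   head the apex rows are arbitrarily thin and would otherwise always win.
   A silhouette whose width is monotone from the top (e.g. an hourglass)
   has its "head peak" at the very first row, so the rule reduces to the
   plain minimum there. Ties break to the topmost row;
3. **shoulders** — per side, the first sign change of the second difference
   of the smoothed side contour below the neck; curvature below 0.5 px is
   treated as zero (rasterisation noise), and the first three rows are
   skipped because the moving average is edge-padded there;
4. **armpits** — per side, the first row below the shoulder where the
   interval count rises above its running minimum (a gap opens between arm
   and torso), required to persist for 3 consecutive rows so a single-row
   sliver at the shoulder cap cannot fire the rule early; the landmark sits
   at the torso-side gap boundary;
5. **fingertips** — a range search over the columns outside the central
   body span (the armpit-row torso interval widened by the bottom-row leg
   span, so leg pixels can never shadow the search): with the arms abducted
   downward, the arm end is the bottommost such pixel on each side;
6. **toes** — bottommost silhouette row, centre of each leg interval;
7. **crotch** — scanning upward from the toes along their columns, the
   lowest row at which the two leg intervals are one and the same.

Each rule raises a detection error naming its landmark when it cannot fire
(arms touching the torso, legs joined, no silhouette). Detection is
deterministic and frontal-only; side views are rendered but not
landmarked. The 11-point roster (head, neck and crotch single; shoulders,
armpits, fingertips and toes paired) follows bilateral anatomy.

Segmentation assigns head (rows above the neck), neck (neck row to
shoulder row), arms (pixels below the armpit rows outside the torso
interval), legs (below the crotch, split at the midline) and torso (the
rest); the labels exactly partition the silhouette.

## Measurements

**Cross-sections.** Every triangle is intersected with the horizontal plane
`y = const` (vectorised via trimesh's plane intersection); the resulting
segments are chained into closed loops by endpoint matching at 1e-6 mm.
Open chains (non-watertight patches) are discarded with a warning rather
than aborting the section. Perimeters are polygon edge sums; areas use the
shoelace formula.

**Tape modes.** Torso girths use the convex-hull perimeter of the section
loop (`convex`), emulating a tape measure spanning concavities (hull
perimeter ≤ raw perimeter, never greater); limb girths use the raw
perimeter. Both modes are exposed.

**Measurement planes.** Rather than hard-coding height fractions, the
chest/waist/hip planes are located by searching for girth extrema of the
largest-area (torso) loop between landmark levels: chest = widest section
between the waist-search floor (crotch + 40 % of the crotch-to-armpit
span) and the armpit; waist = narrowest section in the same window; hip =
widest section between crotch and waist. Searches sample 48 planes per
window and prefer interior local extrema, so an extreme hip girth at the
window edge cannot masquerade as the chest; a window with no interior
maximum (e.g. a cone-shaped torso) falls back to its upper bound with a
warning. The thigh plane sits 5 % of body height below the crotch and the
upper-arm plane 25 % of the shoulder-to-fingertip span below the armpit;
these fixed offsets are a documented surrogate for survey-style anatomical
definitions, which the mesh alone cannot identify.

**Volumes.** Slab volume integrates section area over `n+1` uniform planes
with the trapezoid rule (default 64 slices). The end planes are evaluated a
relative 1e-9 inside the slab: a plane exactly tangent to a cap has an
empty line intersection, but the slab integrand there is the solid's
limiting interior section. Chest volume integrates the largest loop per
slice (torso only) between the located waist and chest planes.

**Vertex normals** are the unweighted normalised mean of incident-face unit
normals (classical smooth-shading normals); degenerate faces are skipped
with a warning. Full Phong shading (ambient/diffuse/specular) is
visualisation, not measurement, and is out of scope.

**Lengths** are landmark distances: Euclidean shoulder-to-fingertip for
arms, vertical armpit-to-toe for legs, vertical neck-to-crotch for the
torso. **BMI** = kg/m² and **WHtR** = waist/height round out the report.

## Preprocessing

Decimation is iterative shortest-edge collapse with midpoint placement,
chosen for simplicity and girth preservation; a quadric-error variant could
be swapped in behind the same contract. The stepwise reducer removes a
fixed number of vertices per step (default 10,000) and stops before
crossing a vertex floor (default 60,000 — the scale at which body
dimensions on full-resolution scans begin to degrade) or before a step
whose information loss exceeds the budget. Information loss is the worst
relative change of total section perimeter over probe planes at 10/30/45/
55/72 % of the reference height — a dimensional, not visual, criterion; it
is asymmetric in its arguments (the second argument normalises).
`resize_to_height` scales uniformly about the floor point, so girths scale
linearly and volumes cubically, exactly.

## Synthetic bodies and ground truth

The generator emulates a standing scan subject in A-pose:

* **torso** — elliptical cross-sections (width/depth ratio 1.45) lofted
  between control levels at fixed height fractions (pelvis bottom 0.48,
  hip 0.54, waist 0.62, chest 0.72, shoulder 0.82). Semi-axes are PCHIP
  interpolants through the control values; monotone interpolation keeps
  girth extrema exactly at the control levels, which the plane search must
  rediscover. Control girths are exact 256-gon perimeters: the polygon is
  scaled so its perimeter equals the requested girth, making ground truth
  a polygon sum rather than an elliptic integral. Pelvis-bottom and
  shoulder girths are 0.92× hip and chest;
* **head and neck** — an ellipsoid (vertical semi-axis 6 % of height,
  centre at 94 %) on a 48-gon neck cylinder; the head bottom at 88 % of
  height is the construction neck level;
* **arms** — 48-gon tapered cones abducted 25° from sockets at 80 % of
  height, with a hemispherical shoulder cap so the upper arm overlaps the
  torso silhouette down to the armpit. The ground-truth armpit height
  solves (arm inner silhouette edge) = (torso edge) with a bracketing root
  find on the construction functions — independent of rendering;
* **legs** — 48-gon cylinders separated by a stance gap; the gap closes at
  the pelvis bottom, which is therefore the construction crotch level.

Parts are concatenated, not CSG-unioned; overlap regions (neck/head,
arm/torso sockets, leg/pelvis) can yield nested or intersecting section
loops, which the largest-area/side-loop selection rules tolerate. The
ground-truth chest volume is an adaptive quadrature of the exact
polygon-area function of the torso profile between the waist and chest
levels.

Population sampling draws heights uniformly on 1500–1900 mm and chest/
waist/hip girths on 80–115 / 60–105 / 80–115 cm, rejecting draws that
violate the body plan (waist below chest and hip) or leave no armpit gap;
limb and head dimensions vary over plausible adult ranges. All randomness
flows through one seeded generator; the same seed reproduces identical
meshes bit for bit.

What the generator does **not** emulate: soft-tissue asymmetry, clothing,
pose variation away from the ideal A-pose, scanner noise and holes, and
realistic skin topology. Passing recovery tests therefore demonstrates the
correctness of the geometry-to-measurement chain, not robustness to
real-world scan artefacts.

## Evaluation metrics

The ratio-error pair compares a measured report with a reference:
`A = |r_m − r_ref| / r_ref` with `r = chest/waist`, and `B` likewise with
`r = left arm/left thigh`. Ratios are scale-free, so the metric isolates
shape distortion from overall size error; an absolute-difference mode is
also provided. Camera placement is selected by minimising `A + B` per
generation model over a placement grid; the bundled grid (SMPL and PIFuHD
columns over heights 0.5/1/1.5 m and distances 1.5–4 m, with the PIFuHD
4 m column marked broken) yields (1 m, 3 m) for both models, which
validates the `A + B` operationalisation on the only available data point.
If models were to disagree, the cell minimising the summed error is
returned with a warning.

Accuracy aggregation: per-part percent error `100·|actual − generated| /
actual`, averaged over parts; accuracy = 100 − mean. Applied to the
per-part error column 7.5/6.2/8.2/5.4 % this gives 6.825 % mean error and
93.175 % accuracy.

## Problem sizes and numerical choices

The default humanoid has ≈ 11 k vertices / 23 k faces; depth maps are
512×512; plane searches sample 48 planes per window; slab volumes use 64
slices; the recovery suite uses 20 random bodies. These sizes keep the
full test suite and the acceptance script comfortably reproducible on a
single CPU while leaving every rule exercised at realistic resolution.
Chain tolerance is 1e-6 mm; weld tolerance 1e-6 mm; ties in extremum
searches break to the topmost row / first sample.

## Known limitations

* Landmark rules assume a frontal A-pose with visible armpit and crotch
  gaps; clothed or arms-down subjects fail with named detection errors
  rather than degrading silently.
* Measurement planes are extremum-based surrogates for survey anatomical
  definitions; on bodies whose girth profile has no interior extremum the
  chest falls back to the armpit plane.
* The slab-volume and cross-section machinery assumes sections of the
  relevant part are closed; badly holed scans will shed loops (with
  warnings) and under-report volume.
* STL/OBJ carry no units; inputs are assumed millimetres unless a unit
  flag says otherwise.
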