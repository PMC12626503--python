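# Methods

This note records how the measurement protocol is defined computationally,
what the synthetic generators do and do not emulate, and the numerical and
design choices made where the protocol was genuinely open.

## Geometric protocol

**Planes and frames.** All anatomy is derived from named landmarks; no
global axis convention is assumed. The Frankfort horizontal (FH) is fitted
exactly through the left and right porion and one orbitale point (a single
orbitale is the schema's convention; when a file carries `orbitale_l` and
`orbitale_r` they are averaged). The plane-fit normal is oriented by a
caller-supplied superior reference point; the pipeline uses the crista
galli. The osteotomy plane C is parallel to FH through the sigmoid-notch
point *s* of the measured side. The condylar frame takes `u_si` = plane-C
normal, `u_ml` = the in-plane projection of the inter-porion axis (signed
to point laterally for the declared side), and `u_ap` = the in-plane,
re-orthogonalized projection of the porion-midpoint→orbitale direction.

**Block cutting.** The mandible mesh must be watertight (validated; the
error reports the open-edge count). Vertices within 1e-6 mm of C are
snapped onto it to avoid sliver triangles. The mesh is sliced at C
(trimesh), duplicate vertices along the cut are merged, and when several
connected components lie above C the one with the most posterior centroid
along `u_ap` is kept — plane C through the sigmoid notch separates condyle
(posterior) from coronoid (anterior). The open cut loops are closed by
ear-clipping triangulation in plane-C coordinates, with cap normals along
−`u_si`; volume is the divergence-theorem signed volume of the capped mesh
(auto-reoriented and logged if negative).

**Seven landmarks.** *i*/*o* are the mediolateral extreme vertices of the
block excluding on-plane (cap) vertices, ties broken by greater height,
then vertex index. The section planes M, N, N1, N2 follow the ±45°
construction exactly (orthogonality is algebraic, not fitted). Contour
searches run on plane–mesh section polylines resampled at 0.1 mm
arc-length spacing. Closed contours are first rotated to a canonical start
(highest raw vertex; ties toward the positive in-plane horizontal axis,
which is frame-covariant): without this, the resampling phase depends on
the mesh library's arbitrary section start and landmark heights drift by
up to ~0.07 mm under rigid motion of the scene; with it, all heights are
rigid-invariant to machine precision.

**"Lowest edge of a slope."** The protocol's source imagery never defines
this point computationally, and a literal lowest point would sit on the
cut plane at height 0. It is operationalized as the head–neck
concave-curvature inflection: the section contour is split at its apex,
the branch on the negative/positive `u_ap` side is the posterior/anterior
slope, and walking from the apex downward the first local maximum of
concave turning rate is returned. Discrete curvature is estimated over an
arc-length window of three mean mesh edge lengths; the convex sign is
calibrated from the apex region. Points below `cap_exclusion` = 0.5 mm are
never candidates; if no concave inflection exists the lowest non-excluded
branch point is returned with a logged warning. On the synthetic condyle
the detected heights match the analytically placed waist within one mesh
edge length.

**Cephalometrics.** ANB is measured after projecting A, nasion and B onto
the facial-midline plane, reproducing the 2D lateral-cephalogram
convention from 3D input; its sign is positive when A is anterior to B
(anterior = in-FH, in-midsagittal component of crista galli→nasion). ME
and PN are unsigned by default with a `signed=` flag exposing the
deviation direction, since published tables do not state a sign
convention.

## Synthetic data

**Condyle geometry.** A solid of revolution with elliptical cross-sections:
an ellipsoidal head joined C1-continuously to a hyperbolic neck
`r(z) = A·sqrt(1 + ((z − h*)/w)²)` whose curvature is maximal exactly at
the waist height `h*` — the analytic ground truth for the slope-landmark
search — continued by a sub-notch stub below the cut plane. The join
height is solved so the waist radius equals the `neck_radius` parameter.
Setting `neck_length = 0` produces a head-only ellipsoid centered on the
cut plane (the analytic half-ellipsoid volume limit). The true block
volume is computed by 1D quadrature of the profile,
`V = π (a_ml/a_ap) ∫ r(z)² dz`. Default semi-axes (8.0 × 4.8 × 4.8 mm,
waist at 5.0 mm) give a per-condyle block of ≈1320 mm³, i.e. summed
bilateral volumes of ≈2640 mm³ — the scale reported for adolescent TMJ
cohorts. Landmarks are emitted in a fixed world frame (FH exactly z = 0,
midline exactly x = 0) with the A/N/B rays constructed so prescribed
ANB/PN/ME values are recovered exactly.

**Remodeling fields.** Region membership uses 45° spherical-direction
sectors about the head centroid (superior, anterior, posterior, medial,
lateral, posteromedial, posterolateral — mirroring the ±45° N1/N2
construction), blended by a Gaussian of angular scale `smoothness_mm`
divided by the head radius, and tapered to zero toward the cut plane. A
field has two components:

* **normal apposition/resorption** (`amplitudes`, mm along outward vertex
  normals): changes volume by the surface integral of the amplitude
  (verified to first order within 5%);
* **vertical growth** (`growth`, mm along `u_si`): emulates condylar
  vertical growth (neck elongation / superior apposition) and is what
  raises landmark heights.

The split is deliberate. Outward normals at the head–neck waist are nearly
horizontal, so normal apposition cannot lift the detected inflection — in
fact a +1.5 mm posterolateral normal bump *sharpens* the crease below
itself and moves the detected slope point ~1.2 mm down. Vertical growth
moves the contour (and with it the curvature maximum) up by the field's
vertical displacement at the landmark, which is exactly the
field-evaluation oracle the tests assert against.

**Cohorts.** The measurement-level generator samples per-patient summed
T0 values and T1−T0 changes from shifted (reflected where left-skewed)
log-logistic distributions fitted to (median, Q25, Q75) triples — the
published scale of two-arm disc-displacement trials (volume-change medians
≈30 vs ≈280 mm³, height changes ≈ −2 to +3.5 mm) — then splits them into
left/right sides with a per-patient fraction ≈ N(0.5, 0.03). Group mix
defaults: 90% female, 65% aged 10–18, 34:26 unilateral:bilateral, and a
23:18:45 anteromedial:anterolateral:pure-anterior displacement mix among
affected joints. Every draw is ledgered for recovery tests. The
mesh-level generator builds paired T0/T1 meshes per patient (jittered head
proportions; group-specific fields: posterolateral/lateral/superior growth
≈0.65/0.45/0.45 mm plus ≈0.25 mm posterior/lateral apposition in the
repositioned arm, near-zero in the displaced arm), calibrated once at
design time so the measured group change medians land near the published
≈30 / ≈280 mm³.

What the generators do **not** emulate: real segmentation noise and mesh
topology defects, cortical/trabecular distinction, osteophytes or erosive
lesions, true disc mechanics, and correlated bilateral remodeling. Passing
tests therefore demonstrate correctness of the geometry and statistics
under clean, watertight surfaces with known ground truth — not robustness
to clinical segmentation artifacts.

## Statistics

* **Quartiles** use the weighted-average h = (n+1)p percentile rule (the
  default of the major commercial statistics packages), so summaries are
  directly comparable with published clinical tables.
* **Mann–Whitney U** is exact by full enumeration of label assignments for
  n₁+n₂ ≤ 12 (midranks under ties; two-sided p = share of assignments at
  least as far from n₁n₂/2), otherwise a tie-corrected normal
  approximation without continuity correction. Exact and asymptotic p
  agree within ≈0.05 at 8 vs 8; the gap is a property of the normal
  approximation at that size, with or without continuity correction.
* **t tests** accept raw data or (n, mean, sd) tuples, with identical
  results on both paths; pooled-variance Student is the default for the
  directional baseline contrast, Welch behind a flag. From the published
  direction-group summaries (n 23 vs 18, means −0.151 vs −1.068, SDs
  1.197 vs 1.333) both forms give t ≈ 2.32, p ≈ 0.026–0.028; the smaller
  p printed alongside those summaries in the source table is not
  reproducible from them, and this package reports what the formulas give.
* **ICC** is the two-way random-effects, absolute-agreement,
  single-measure form (A,1), with the F-based confidence interval using
  Satterthwaite degrees of freedom; it matches an independent
  implementation to 1e-9 and recovers the variance-components value 16/17
  under simulation.
* **Sample size** scans equal per-group n upward using the noncentral-t
  power of the two-sided unequal-variance test, inflates by 1/(1 −
  dropout) with ceiling rounding, and doubles (1:1 allocation, total
  forced even). The exact scan carries a small-sample offset relative to
  the normal-approximation formula, so n ∝ σ² holds as a ratio law rather
  than to ±1.
* **No multiple-testing correction** is applied anywhere: each result
  table's tests are marginal, matching common clinical reporting. Users
  comparing many endpoints should adjust downstream.

## Problem sizes and determinism

Synthetic meshes default to subdivision level 2 (≈1,400 vertices, mean
edge ≈1.0 mm), where block volume is within 0.7% of the analytic truth
and a full one-condyle measurement takes ≈50 ms; convergence is verified
over levels 1–3. Simulation-based checks use fixed seeds throughout:
2,000 replicates for null calibration of the two-sample tests, 500 seeds
for regression CI coverage, 200 for ICC recovery, and 10 replicate
mesh-level cohorts of 20 patients per arm for end-to-end power. All
generators are pure functions of (parameters, seed).

## Known limitations

* The curvature-inflection rule for "lowest edge of the slope" is this
  package's operationalization; other software may use manual or
  different automatic definitions, so absolute slope-point heights are
  comparable only within a fixed protocol.
* Ear-clipping caps assume simple (non-self-intersecting) cut polygons;
  pathological cut sections fall back to a fan with a logged warning.
* Landmark heights are contour-resampled at 0.1 mm; differences below
  that scale are not meaningful.
* The cohort generator draws each measure independently given the group;
  real measurements are correlated across points and sides beyond the
  shared per-patient draw it models.
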