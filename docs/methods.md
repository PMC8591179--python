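# Methods

This note records the models behind `osteomargin`, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical choices a maintainer would want spelled out.

## Phantoms

The physical study used artificial skulls with moldable tumor masses of
higher x-ray attenuation than the bone substitute; those objects were
never dimensioned, so the digital phantoms keep only the properties the
analysis consumes: a closed tumor surface, attenuation contrast, and
rigid fiducials.

* Geometry: a hemispherical bone shell (outer radius 55 mm, thickness
  4 mm) and one tumor per phantom built as the union of 1–3 overlapping
  ellipsoids with semiaxes of 7–16 mm.  Four fixed ellipsoid sets stand
  in for the four tumor models.  **All tumor sizes are invented**; they
  were chosen once as plausible for locally advanced sinonasal masses
  (roughly 20–30 mm across) and are config-exposed.
* Attenuation: background 0, bone 700, tumor 1200, additive Gaussian
  noise sd 30 (arbitrary HU-like units, well separated so the midpoint
  threshold 950 is insensitive to noise).  Default grid 256³ at 0.5 mm
  isotropic — cone-beam-CT-like resolution at desktop memory; tests and
  the acceptance script run a 96³ / 1.5 mm scale-down, which changes only
  discretization error, not the model.
* Fiducials: 6 points on the outer shell with ≥ 20 mm pairwise spacing
  (the study reports "predrilled divots" without a count; 6 is typical
  for paired-point craniofacial registration).  World positions are the
  image positions mapped through a seeded random rigid transform; the
  tracker measurement noise (isotropic Gaussian, sd 0.15 mm, a typical
  optical-tracker jitter) is added at registration time.
* Osteotomy sites: the five corridors (Pa, FMJ, LIOR, Zy, PMJ) are unit
  directions from the tumor centroid, invented to be anatomically
  plausible.  The nominal cut plane of a site is found by sliding the
  plane along its normal until the minimum distance of the scored region
  to the tumor surface equals the margin target (brentq on the sampled
  minimum, xtol 1e-4 mm) — "tangent to the tumor dilated by the margin".

## Segmentation and the distance field

Contouring mirrors the semiautomatic protocol: global threshold
(default: midpoint of bone/tumor levels) then a deterministic refinement
standing in for interactive smoothing — binary closing (1-voxel ball),
hole filling, and removal of components under 100 voxels.  The manual
edits of the original workflow have no specification, so a reproducible
morphological pipeline replaces them.

The tumor surface is the marching-cubes isosurface of the binary label at
level 0.5.  The signed distance field composes inside/outside Euclidean
distance transforms; because each transform measures to the nearest voxel
*center* of the opposite phase, both sides are shifted half a voxel so the
zero level set coincides with the marching-cubes surface.  Distance
queries are trilinear (order-1 `map_coordinates`) with no extrapolation —
a point outside the grid is an error.  Accuracy budget: one voxel
diagonal (0.87 mm at 0.5 mm spacing), verified against exact brute-force
point-to-triangle distance (`meshdist.py`, which exists precisely to be
the independent oracle and the ray caster).  One consequence worth
knowing: the field has a cone apex at the center of a sphere, which
trilinear interpolation clips if the center falls between voxel centers;
oracle tests therefore digitize spheres with the center on a voxel.

## Cut placement and noise calibration

A simulated cut perturbs the ideal (margin-target) plane by

1. a normal offset ~ N(0, σ_offset),
2. a tilt of N(0, σ_tilt) degrees about a uniformly random in-plane axis,
3. an in-plane shift of N(0, σ_inplane) along each in-plane axis.

This is an explicit stand-in for human performance, not a model of
vision or hand tremor.  For offset-only noise against a sphere the
intratumoral probability is Φ(−m/σ), inverted by the calibrator to hit
each condition's observed rate (20.7 / 9.4 / 1.2 / 0 %): σ = 12.24, 7.60
and 4.43 mm for unguided, AR and IN.  A zero rate has no finite σ; the
AR+IN condition uses a configured 1 mm sd, giving Φ(−10) ≈ 0.  Defaults
set tilt and in-plane sds to zero so the calibration is exact; the
closed form neglects planes that overshoot *through* the entire tumor,
which is why the calibration-validation sphere is large (radius 25 mm)
— for the 12.24 mm unguided σ the pass-through probability is then
Φ(−70/12.24) ≈ 5×10⁻⁹.  On the ellipsoid phantoms, whose curvature and
site geometry differ from the calibration sphere, realized rates are
approximate by design.

## Margin scoring

For each cut, a 4 cm × 2 cm region (2 cm on both ends along the blade's
longitudinal axis, 1 cm on both sides across it), centered at the
recorded osteotome origin, is sampled at 0.5 mm (81 × 41 = 3,321 points)
and each point's signed distance is binned: intratumoral d ≤ 0, close
0 < d ≤ 5, adequate 5 < d ≤ 15, excessive > 15 mm (upper bounds
inclusive).  A cut is flagged intratumoral when **any** grid point has
d ≤ 0 — the only aggregation consistent with "a margin violation
occurred"; with this choice the per-point and per-cut definitions
coincide.  Bin percentages always sum to 100 (a partition; floating
residue is folded into the last bin at the 1e-13 level).  The rendering
uses a fixed diverging colormap anchored at the 0 / 5 / 15 mm bin edges
so images are comparable across cuts; PNG bytes are deterministic.

In the full pipeline, a rare far-outlying unguided draw can push the
region outside the distance-field grid; such cuts are scored by the exact
mesh distance instead (same sign convention), so no draw is dropped or
clamped.

## Registration and the AR chain

Paired-point registration is closed-form orthogonal Procrustes (SVD with
a reflection guard that flips the smallest singular direction when the
unconstrained optimum is improper).  FRE is the RMS residual; the
protocol gate accepts FRE ≤ 1 mm, and the pipeline redraws the simulated
digitization (fresh noise, logged attempt count, max 10) on failure —
mirroring re-registration in the operating room.  Pivot calibration of
the tracked osteotome solves the stacked linear system R_i x + p_i = c
and requires ≥ 10 poses with ≥ 30° orientation spread.

The projector is a pinhole with known intrinsics (the physical device was
pre-calibrated; self-calibration is out of scope).  Pose estimation
minimizes reprojection error with Levenberg–Marquardt started from a
deterministic bank of 24 orientation seeds — slower than a linear DLT
initializer but uniform across coplanar and non-coplanar landmark sets.
Two residuals are exposed, RMS reprojection (px) and RMS ray-to-landmark
distance (mm); the < 1 mm acceptance gate applies to the latter, since
the study states its AR "registration error < 1 mm" without defining the
metric.

**Landing points and repositioning.**  A landing point is the first
positive-depth intersection of the ray through a projected vertex with
the skull surface.  For a vertex *on* the surface the landing point is
the vertex itself in the skull frame, for any projector pose — so the
projected tumor outline is invariant under rigid repositioning of skull
or projector once the tracked chain is updated.  That invariance (1e-6
mm in the tests) is the package's operationalization of "repositioning
without compromising projection accuracy".  For vertices *inside* the
skull the landing point genuinely shifts with projector pose (parallax),
and the oblique-projection footprint of a square stretches by 1/cos θ on
a surface tilted by θ — both measurable with `landing_points`, matching
the distortions the study discusses qualitatively.

## Gaze, workload, durations

Gaze is an alternating-renewal process with exponential dwells whose
means are scaled so the expected screen fraction equals the condition
parameter (0.555 / 0 / 0.785 / 0.618); the AR zero is structural (a
single field event), not a sampled value.  The metric is pooled screen
time over total time; per-session percentages are also reported since the
two differ when durations vary.  NASA-TLX responses are clipped-normal
draws around condition means — the means' *ordering* (unguided ≈ AR high
on mental demand, effort, frustration; the combination lowest) follows
the study's qualitative findings, but the magnitudes are invented, so TLX
analyses exercise the pipeline rather than reproduce numbers.  Durations
are clipped-normal around the reported 215 / 117 / 134 / 120 s.  Raw
(unweighted) TLX is used throughout; the pairwise-weighting stage is
omitted because the study never mentions it.

## Statistics

* **Exact test**: Freeman–Halton by full enumeration of tables with the
  observed margins; the two-sided p sums multivariate-hypergeometric
  probabilities of tables no more probable than observed (log-space,
  with a 1e-7 relative tie tolerance).  Verified exhaustively against
  the closed-form hypergeometric on every 2×2 table with N ≤ 30.
* **Odds ratios**: Haldane–Anscombe 0.5 added to *all* cells in every
  univariate OR — the only convention that reproduces all three
  published point estimates (2.44, 0.16, 0.05) simultaneously, including
  the zero-cell arm.  The CI is Woolf on the corrected table and is an
  approximation; the study's printed intervals match neither Woolf nor
  simple exact bounds (likely profile or exact-conditional, method
  unstated), so intervals are reported with that caveat and are not
  reproduction targets.
* **Multivariable model**: logistic regression of the intratumoral flag
  on condition + tumor + surgeon (dummy-coded, AR reference).  Because
  one condition has zero events, plain MLE diverges; Firth's Jeffreys-
  prior penalty is engaged automatically when any predictor level is
  event-free, guaranteeing finite estimates (verified against a
  brute-force penalized-likelihood grid on a 2-parameter toy).
* **Rank tests**: tie-corrected Kruskal–Wallis (scipy) with the
  Steel–Dwass–Critchlow–Fligner all-pairs post hoc: pairwise rank-sum
  statistics scaled by √2 and referred to the studentized range with k
  groups and ∞ df.  Family-wise type-I error calibrates to ≈ 0.05 in
  simulation (4 groups of 20).
* Two-sided tests throughout, α = 0.05.

## Scales used in tests and the acceptance script

Monte Carlo sizes were fixed in advance at the points where the checked
quantities stabilize: 1,000 registration trials, 5,000 cuts per condition
for the calibration round trip (binomial SE 0.57 points on the unguided
rate), 2,000 replicates for post-hoc error calibration, n = 4,000 for
logistic parameter recovery, 60 gaze streams of 300 s per condition.
End-to-end study runs use 96³ phantoms at 1.5 mm; the coarser grid only
widens discretization tolerances already budgeted at one voxel diagonal.

## Known limitations

* The surgeon-error model is a stationary Gaussian; no learning over the
  fixed Pa→FMJ→LIOR→Zy→PMJ order, no per-surgeon skill differences, no
  AR-projection-angle effect on human error.
* The study's 335 recorded cuts (of 400 planned) are unexplained; a
  neutral per-cut drop probability (default 0) stands in.
* Phantom anatomy is schematic; results transfer to real anatomy only
  through the distance-field abstraction.
* Gaze streams carry no blink/lost-tracking states; any such gaps in
  external input are counted as field time, consistent with a
  total-study-time denominator.
* Printed confidence intervals, multivariate ORs (2.54 / 0.16 / 0.06)
  and the duration/TLX findings of the study are not reproducible from
  published data (no raw per-cut records); the corresponding code paths
  are validated on synthetic data with planted parameters instead.
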