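# Methods

## Coordinate and mask conventions

All geometry is computed in physical millimetres; anisotropic voxel spacing
(in-plane 0.38–0.89 mm, slice 0.6–1.25 mm for the CT sources this emulates)
makes voxel-index geometry meaningless. Voxel `(i, j, k)` (0-based) has its
*center* at `origin + (i·sx, j·sy, k·sz)`. Masks are strictly binary; float
inputs are re-thresholded at 0.5. Masks are consumed in stored axis order —
no reorientation to anatomical axes is attempted, because the anatomical
information the pipeline needs (which end of the aorta leaves the heart) is
supplied explicitly as an anchor hint point. On phantoms the truth provides
it; on real data the caller must pass the aortic-root / pulmonic-valve end.
This is the single entry point for anatomical knowledge.

## Centerline extraction

1. **Isotropic resampling.** The mask is linearly resampled to an isotropic
   lattice at the finest spacing component and re-thresholded at 0.5.
   Topological thinning operates on the lattice and is badly biased by
   anisotropy (a wide, short tube looks disk-like to it); resampling keeps
   the thinning geometry-aware at negligible cost.
2. **Thinning and graph.** 3D topological thinning produces a voxel
   skeleton, converted to a 26-connected graph with physical edge lengths.
   Diagonal edges that also exist as a strictly shorter two-edge detour are
   removed ("triangle reduction"); without this, lattice adjacency inflates
   node degrees around corners and junction voxels, breaking endpoint and
   branch-node counts.
3. **Pruning.** A terminal branch is spurious when its geodesic length plus
   the interior-EDT radius at its tip is below `2 ×` the EDT radius at its
   junction. The tip radius is credited because thinning retracts every
   tube end by roughly one local radius: a true daughter vessel's skeleton
   arm is shorter than the vessel it represents by about its own radius,
   while a voxel-scale spur has a tip radius near one voxel. The factor 2
   is configurable.
4. **Main path.** The centerline is the maximal-physical-length
   endpoint-to-endpoint geodesic. Raw paths shorter than 1 mm are rejected
   ("no admissible path"), which is how degenerate skeletons (e.g. of a
   sphere) surface.
5. **End correction.** Thinning either retracts a tube end or overshoots
   into a rounded stump, wandering off-axis where the object is blob-like.
   Both are corrected symmetrically: the path is first cut back to the last
   point still on the EDT plateau (local EDT within one voxel of the tube
   radius near that end); a straight ray is then cast along the terminal
   path direction to where it exits the mask, and the endpoint is placed
   one tube radius short of the exit. For a rounded stump the medial curve
   ends exactly one radius inside the surface, so this reproduces the
   analytic endpoint to sub-voxel accuracy. The ray is straight; the
   correction therefore assumes mild curvature over the final radius of arc
   length, and on a tapered vessel it uses the largest nearby radius, which
   can misplace the endpoint by a few millimetres (a second-order effect on
   windowed means).
6. **Smoothing and resampling.** A 5-point centered moving average
   suppresses voxel staircase (which otherwise inflates arc length and
   corrupts tangents), followed by resampling at 0.2 mm arc steps and
   central-difference tangents. Both parameters are configurable.

**Bifurcation localization.** The candidate junction is the branch node
whose three deepest incident subtrees have the largest summed geodesic
depths — a criterion that spurs cannot win. The skeleton junction of a
thick Y, however, sits distal to the geometric branch point by an
appreciable fraction of the trunk radius, so the point is refined: a
straight line is fitted (PCA) to each of the three arms over a window one
junction-radius clear of the junction, and the least-squares mutual
intersection of the three lines is returned. On bifurcation phantoms this
lands well within one voxel of the analytic branch point.

## Diametry

The diameter at a centerline position is the *equivalent-area diameter*
`D = 2·√(A/π)` of the cross-section perpendicular to the local tangent: the
plane is sampled on a 0.2 mm grid over a ±60 mm extent, the mask is
trilinearly interpolated, thresholded at 0.5, and `A` is the area of the
in-plane connected component containing the center (which isolates the
vessel from any other structure the plane happens to cut). Equivalent-area
is rotation-stable, robust to tangent noise (the area of an oblique section
grows only with `1/cos θ`), and reduces to the caliper diameter for
circular sections. A position whose interpolated mask value falls below 0.5
raises "centerline exited lumen" rather than measuring a neighbouring
structure.

Windows follow the clinical protocol: aorta 0.5–2.5 cm of arc length from
the heart-exit anchor, sampled at 0.09-cm intervals (23 positions); main PA
0.5–1.5 cm proximal to the branching point, measured back toward the
trunk-origin anchor at 0.04-cm intervals (26 positions). Window ends are
inclusive (with a 1e-6 cm tolerance so evenly dividing windows keep their
final sample), the vessel mean is the arithmetic mean of the profile, and
the enlargement threshold `PA/Ao ≥ 1` is inclusive. The source protocol's
methods text and its figure captions disagree on which vessel gets which
interval; the defaults here follow the methods text and both intervals are
plain config fields.

The 2D single-slice emulation selects the axial slice at the branching
point's z, takes each vessel's in-plane component nearest its centroid, and
reports the diameter of the largest inscribed circle (2 × max in-plane
EDT). An inscribed circle was chosen because the manual caliper placement
convention is unknowable and the PA's axial footprint is an oblique
ellipse; the inscribed circle is the stable lower envelope of manual
measurements.

## Synthetic phantoms

A phantom voxel is foreground iff its center lies within the local tube
radius of an analytically sampled centerline curve (0.1 mm sampling), which
makes the solid's medial curve equal the analytic curve and its ends
rounded like vessel stumps. Kinds: constant-radius cylinder, linearly
tapered cylinder, circular-arc tube (aorta stand-in), and a straight trunk
splitting into two equal daughters (PA stand-in; default 60° between
daughters, daughter radius 0.7 × trunk — the opening angle and daughter
calibre are package choices, as no geometry for them is published).
Optional segmentation noise flips surface-adjacent voxels independently
with a configurable probability; no spatially correlated error model is
attempted. Truth records the exact centerline, per-position radius, anchor
and branch point. The default "vessel pair" uses radii 17.4/13.9 mm so the
truth ratio is the cohort-scale mean of 0.8.

Phantoms are resolvable only when the tube radius is at least 3× the
coarsest spacing; generation is refused otherwise. What phantoms do *not*
emulate: real lumen ellipticity, wall irregularity, touching adjacent
structures, and the error structure of a learned segmentation — passing
phantom tests therefore validates the measurement geometry, not
segmentation robustness on clinical CT.

## Synthetic cohort

Each patient draws independent Bernoulli indicators for PA enlargement
(prevalence 0.0757), tumor > 3 cm (0.144), uniportal VATS (0.292) and
female sex (0.632); age is normal (61.0 ± 9.7 y, shifted −6.6 y in the
enlarged group) and the Charlson index a rounded, zero-clipped normal
(2.3 ± 1.7, shifted −0.6). The shifts give the enlarged group genuine
confounding for the matching stage to remove; only group marginals are
published, so the additive joint structure is a package assumption. The
complication outcome is logistic with exactly the two significant terms:

    P(complication) = expit(b0 + ln(3.084)·enlarged + ln(3.173)·large_tumor)

with intercept 0 by default — odds-ratio recovery is intercept-invariant,
and no outcome-prevalence calibration target is assumed. A PA/Ao ratio
column consistent with the enlargement label (truncated normal below 1,
mean 0.8 ± 0.09; 1 + |N(0, 0.05)| above) and a noisy 2D companion are
generated for correlation-style analyses. Clavien–Dindo grades are
assigned to complication cases with a fixed mix (35 % grade 1, 48 % grade
2, 14.8 % 3a, 2.2 % 3b) consistent with the published severity fractions.
All generators are bit-reproducible under a fixed seed.

## Statistics

* **Categorical tests:** Pearson chi-square without continuity correction
  unless any expected cell count is strictly below 5, then Fisher's exact
  test (hypergeometric for 2×2; full conditional enumeration, written here,
  for 2×K). The uncorrected chi-square matches the common SPSS reporting
  default; the correction is a flag away in scipy if wanted.
* **Continuous tests:** Shapiro–Wilk on both samples at α = 0.05 gates a
  pooled-variance t test versus Mann–Whitney U (exact for tie-free samples
  of ≤ 20, otherwise the tie-corrected normal approximation). Degenerate
  zero-variance samples are reported as untestable rather than given a p
  value.
* **Logistic regression:** maximum likelihood via statsmodels, Wald 95 %
  intervals `exp(β ± 1.96·SE)`. Separation or non-convergence is flagged on
  the result and logged, never silently returned.
* **Propensity matching:** the score is the logit of the fitted probability
  of enlarged-group membership given age, CCI and uniportal VATS. Greedy
  nearest-neighbour matching without replacement processes cases in
  descending score order, takes up to 4 in-caliper controls each (caliper =
  0.1 × SD of all pre-match logit scores), breaks ties by smallest control
  id, and retains cases with 1–4 controls. Order, tie-break and variable-k
  retention are package choices made for determinism; incomplete 1:4
  matching is deliberately kept, matching the published 29-case / 105-control
  pattern. Balance is reported as standardized mean differences
  `(m₁ − m₀)/√((v₁ + v₀)/2)` before and after matching.
* **Formatting:** summary tables render counts as `n (p%)` with half-up
  rounding (one decimal by default), continuous variables as mean ± SD, and
  empty groups as a dash with a logged warning.

## Problem sizes and numerical choices

The test suite validates diameter recovery on cylinders of radius 10–18 mm
at both extremes of the printed spacing ranges (|error| ≤ max(1 mm, 3 %)),
2D/3D concordance on 50 shared-grid vessel pairs (the PA radius sweeps
9–21 mm in 0.24 mm steps, large enough that both measurements order
strictly), and odds-ratio recovery at n = 200,000 (Monte-Carlo SE ≈ 2 % on
the enlargement OR, comfortably inside the 5 % check). The acceptance
script uses the same n = 200,000 refit. Plane sampling at 0.2 mm bounds the
area quantization error of a 25–35 mm vessel well below 0.1 mm of
equivalent diameter; the 1e-6 cm window tolerance, the 0.5 interpolation
threshold and the inclusive ratio threshold are the remaining numerical
conventions.

## Known limitations

* Vessels with more than one bifurcation generation are out of scope; only
  the first split is located.
* The end-correction ray is straight and uses the largest nearby radius;
  strongly curved or strongly tapered vessel stumps are placed a few
  millimetres off (second-order for windowed means).
* The 2D emulation fixes one caliper convention (inscribed circle); it
  tracks manual measurements in rank but not necessarily in level.
* The cohort generator reproduces published marginals and the two
  significant outcome effects only; all other covariates carry zero
  generative effect, so it cannot be used to study their adjustment.
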