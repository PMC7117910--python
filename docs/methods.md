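# Methods

`spindlemech` quantifies how a mammalian metaphase spindle responds when a
microneedle pulls laterally on one of its kinetochore-fibers (k-fibers),
and provides a ground-truthed synthetic generator of such experiments so
that every analysis stage can be validated without microscope data.  This
note records the models, the parameters that matter, the numerical
choices, and the limits of what the synthetic experiments can show.

## Curvature profiling

Fibers are traced as ordered 2D polylines (plus-end / chromosome end
first, coordinates in µm) and resampled to 100 equally spaced coordinates.
Local curvature at arc position `s` is the inverse radius of the circle
circumscribing the three points that span the measurement window `w`
(default 1 µm): the points at `s − w/2`, `s`, `s + w/2`.  The triplet-span
reading of the window is the one consistent with the geometric bound
|κ| ≤ 2/w (the outer chord of the triplet is at most `w`, so the
circumradius is at least `w/2`) and keeps the estimator's discretization
bias small: on `y = 0.5·sin x` (peak curvature 0.5 µm⁻¹) the maximum
deviation from the analytic plane-curve curvature is ≈ 2% of the peak.
Had the three points been placed a full window apart (span `2w`), the
low-pass bias at that curve's crests would be ≈ 12%.  No smoothing is
applied beyond the window itself; the window *is* the length scale on
which curvature is defined.  Profiles are trimmed to `s ∈ [w, L − w]`.

The sign convention is fixed once per manipulation: curvature is positive
where the fiber bows toward the reference normal, which is taken as the
direction the fiber is displaced at the needle (the perpendicular
deviation of the needle-proximal point from the end-to-end chord, or the
needle's net displacement direction when a time series is available).
This pins the bend at the needle to positive and the chromosome-proximal
reverse bend to negative.

A reverse bend counts as detectable when κ_min < −0.1 µm⁻¹ (the
`negative_threshold`).  Troughs are classified by position:
chromosome-proximal when `s_min ≤ proximal_fraction · L` (default
fraction 0.4), pole-proximal when within the same fraction of the pole
end, unclassified otherwise.  The fraction is configurable, and the
classification flips for a trough at 0.35·L between fractions 0.3 and
0.5, so sensitivity to this choice should be (and in the test suite is)
reported.

## Strain maps and the spatial decay of deformation

Deformation between an undeformed and a deformed frame is quantified by
connecting coordinate *i* of every structure in one frame to coordinate
*i* in the other, after both frames are brought into register by a
least-squares rigid transform (cross-covariance/SVD solution, reflection
forbidden).  Registration anchors are the pole centroids plus every
matched point farther than 5 µm from the needle tip in *both* frames —
the deformation is local, so distal structure approximates a rigid
reference, and the symmetric exclusion rule makes the frame-swapped map
the exact inverse.  Displacement magnitude `D` and distance-from-needle
`d` are then summarized in 1 µm bins (mean ± SEM), restricted to the
manipulated (needle-side) half-spindle — the opposite half responds
through sister coupling and whole-spindle geometry, not through the local
crosslink network that the decay is meant to probe — and fitted with the
two-parameter model `D = A·exp(−λ·d)` (nonlinear least squares, both
parameters bounded below by zero, no offset: deformations vanish far from
the needle).  Binned-mean fitting is the default; per-point fitting is
available through the same function.

## Reinforcement lifetime

In a manipulate-and-hold experiment the needle ramps for 60 s and then
stays.  The tracking window is fixed from the last strictly-pre-hold
profile: the position of its most negative chromosome-proximal curvature,
padded by ±1.5 µm.  The lifetime is the first time since hold start at
which the windowed minimum rises to or above the −0.1 µm⁻¹ threshold and
stays there for every later frame; single-frame dips back below the
threshold are ignored as tracing noise, and a trough that never clears
the threshold is censored at the last frame.

## Comparing experimental groups

Needle positions differ between groups, and trough detection depends on
where the fiber was pulled, so before comparing conditions both groups
are minimally down-sampled to the intersection of their normalized
needle-position ranges; the residual difference is checked with a
two-sided Mann-Whitney U test (exact null for combined n ≤ 16 without
ties, tie-corrected normal approximation otherwise).  Paired differences
use the Wilcoxon signed-rank test (exact for n ≤ 12 untied nonzero
differences).  Spearman p-values are exact (full permutation) for n ≤ 8.
No multiple-testing correction is applied; raw p-values are reported with
group sizes.

## The synthetic spindle

### Mechanics of the manipulated fiber

The manipulated k-fiber is a discrete elastic rod of n = 51 nodes
(spacing ≤ 0.2 µm) with energy

    E = Σ (B/Δs)(1 − cos(θᵢ − θᵢ⁰))                bending vs. intrinsic shape
      + Σ k_s/(2Δsᵢ) (|eᵢ| − Δsᵢ)²                  inextensibility penalty
      + Σ kc(sᵢ)/2 [ (nᵢ·uᵢ)² + α (tᵢ·uᵢ)² ]        anchorage to the network
      + k_kt/2 |x₊ − x_kt|²                          kinetochore tether

where `uᵢ = xᵢ − xᵢ⁰` is the displacement from rest and `nᵢ, tᵢ` the rest
normal and tangent.  Three modelling choices matter and were made for
physical rather than numerical convenience, though they also make the
problem well posed:

- **Anisotropic anchorage.**  Crosslinks to the background
  non-kinetochore-microtubule network resist lateral separation at
  density `kc` but axial sliding only at a fraction α = 0.5 of that
  (crosslinker friction).  A fully isotropic anchorage together with an
  inextensible rod makes micron-scale lateral pulls geometrically
  infeasible (the rod cannot recruit the arc length the bump requires
  without >30% stretch); zero axial resistance instead allows the rod to
  slide bodily along its own axis at no cost.
- **The needle is a frictionless peg of finite width.**  The ~1 µm of
  fiber nearest the needle's arc position is driven, by a stiff penalty,
  to its rest position plus the pull displacement *along the pull
  direction only*; the fiber slides freely across the tip, as it does
  across a real glass needle, and the finite contact width reproduces the
  tip's ~1.1 µm diameter rather than a point clamp.
- **Boundary conditions.**  The pole end is hinged — held laterally, free
  to pivot — and mounted on an axial spring (600 pN/µm in scenes), so the
  chord shortening of the bowed fiber draws the pole inward and the
  spindle shortens.  The plus-end is tethered to the kinetochore by a
  50 pN/µm spring; removing sister coupling (the PRC1-depleted condition)
  softens this tether ten-fold, letting the chromosome stretch.

The two anchorage hypotheses are realized in the crosslink profile:
uniform density along the fiber (model 1, default 75 pN/µm²), or a weak
background (18 pN/µm²) plus a chromosome-proximal enhancement of
300 pN/µm² over the first 3 µm from the plus-end (model 2).  Holding the
needle lets the enhancement decay as `k_enh(t) = k_enh(0)·e^(−t/τ)` with
turnover lifetime τ (default 20 s); the background is untouched, so the
rod tends to model 1.

Equilibria are found by a short L-BFGS-B leg on the free nodes with the
analytic gradient, finished by damped Newton: the Hessian couples each
node only to its two neighbors on either side, so the exact (banded)
Hessian is assembled from eleven colored forward differences of the
analytic gradient and factorized densely, with Levenberg damping and
backtracking guarding early steps — first-order methods alone crawl on
this stiff, penalty-dominated energy.  Convergence requires ‖∇E‖∞ < 10⁻⁴ pN on
the free nodes; segment strains stay below ~0.5% in scene use.  Shape
accuracy is validated against the Euler–Bernoulli three-point-bending
closed form (pinned ends, no anchorage): maximum deviation < 0.5% of the
imposed deflection, comfortably within the 2% the pipeline tolerates.

### Calibration

Absolute forces are uncalibrated (no force-calibrated needles exist in
this assay); only shape-level quantities are meaningful.  The bending
stiffness B = 500 pN·µm² sets the needle-peak curvature of a 2.5 µm pull
to ≈ 0.5–0.9 µm⁻¹ and the reverse bend to ≈ −0.2 µm⁻¹, the scale the
experiments show, and together with the model-2 background anchorage
gives a transverse response envelope decaying over ℓ = (4B/kc)^¼ ≈ 3 µm.
Neighbor k-fibers respond as anchored, coupling-dominated elements: each
successive neighbor receives the previous fiber's displacement field
(matched by normalized arc position) attenuated by
`f = k_nb·c / (k_nb·c + k_anchor)` with k_nb = 88 and k_anchor = 75
pN/µm², chosen so that the simulated deformation-versus-distance decay
matches the observed spatial scale (λ ≈ 0.44 µm⁻¹ for the 12 s pulls,
deformation undetectable beyond ~5 µm).  The rigor-crosslinked condition
multiplies the inter-fiber coupling by c = 2, raising transmission and
flattening the decay (λ ≈ 0.25–0.35 µm⁻¹); bending of neighbor fibers is
neglected.  The coupled sister follows the manipulated plus-end as a
rigid junction — translation plus co-rotation with the plus-end region,
preserving the inter-sister angle — with the response decaying over 2 µm
of the sister's own length.

### Scene, protocols, noise

The default scene is a 16 µm bipolar spindle with four sister pairs per
half, the manipulated fiber the outermost (plus-end 3.5 µm off-axis,
length ≈ 8 µm, shallow 0.4 µm sagitta), resting inter-kinetochore
distance 2.35 µm (1.86 µm in the depleted condition).  Needle protocols
mirror the experimental ramps: 1.8 µm over 12 s, 2.5 µm over 60 s, or
ramp-and-hold; the stepper program generator emits 0.0625 µm steps with
uniform dwells.  Whole-spindle rigid jitter (rotation σ = 0.5°,
translation σ = 0.2 µm about the spindle center, independent per frame)
emulates stage and cell drift and is what the rigid registration must
remove.  Tracing noise is *smooth*: a Gaussian process along each fiber
with amplitude σ = 75 nm and correlation length 3 µm, applied per frame,
emulating the semi-automatic tracing of a continuous bright fiber.
White per-point noise of the same amplitude would be unrealistic for
traced curves and would swamp 1 µm-window curvature (second-difference
noise ≈ 0.18 µm⁻¹, above the detection threshold); the correlated model
keeps curvature noise near 0.01–0.04 µm⁻¹, which matches how smooth the
published profiles are.  All randomness flows from one recorded seed;
reruns are bit-identical.

### What the generator does and does not emulate

It emulates: local lateral pulls with controlled position/duration, the
two anchorage geometries and their distinguishing trough behavior,
crosslink turnover during holds, transmission of deformation to
neighbors, sister coupling and its loss, rigid drift, and smooth tracing
error.  It does not emulate: 3D (out-of-plane bending, z-tracking loss),
microtubule polymerization dynamics or length changes, viscoelastic
transients (each frame is quasi-static equilibrium — defensible because
pulls are slow, ≤ 9.3 µm/min), poleward flux, chromosome arms, or
active force generators.  Passing the suite therefore shows the
*analysis* is correct on data with known truth and realistic nuisance
structure; it does not by itself validate the biological conclusions on
real images.

## Numerical choices and degenerate inputs

- Exactly collinear curvature triplets return 0; coincident points are an
  error.  Ties among curvature extrema resolve toward the plus-end,
  deterministically.
- Resampling preserves endpoints bit-exactly; unit conversion (pixels →
  µm) happens once at input and is idempotent.
- Image-convention input (y down) is flipped to mathematical convention
  at the I/O boundary only.
- The exponential fit refuses all-zero deformation ("degenerate") and
  reports amplitude, rate, residual norm and n; a constant profile fits
  λ → 0.
- Rigid alignment needs ≥ 2 non-coincident anchors; when the exclusion
  radius would leave fewer, all matched points are used instead.
- Reports carry a JSON manifest with the full effective configuration,
  seed and library versions, and no timestamp, so rerunning a seeded
  pipeline regenerates reports bit-identically.

## Known limitations

- The sister-angle *sign* is not reproduced: in the experiments the
  sister k-fiber's plus-end region reorients toward the pole-pole axis,
  while the generator's junction coupling yields a small away-from-axis
  or near-zero tilt depending on the axial-friction setting.  Magnitudes
  are in the observed few-degree range and the condition ordering
  (coupled ≫ uncoupled) is reproduced; the discrepancy points at
  spindle-scale reorganization the single-rod-plus-junction model does
  not capture.  Angle changes are therefore reported as magnitudes.
- The pole-pole shortening of 60 s pulls runs larger than observed
  (≈ −1.5 µm vs ≈ −0.5 µm for short pulls), as the quasi-static model
  has no time-dependent remodeling to relieve axial load.
- Neighbor fibers do not bend and their sisters are static.
- Two-dimensional throughout, matching the in-plane imaging of the
  assay.
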