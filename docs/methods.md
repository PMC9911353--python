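# Methods

## Coordinate conventions and projection geometry

All positions are in micrometres in a right-handed frame: `x` along the
stage tilt axis, `y` in-plane perpendicular to it, `z` along the sample
normal toward the light objective. Arrays are indexed `[z, y, x]`
(`[row, col]` for images), with pixel/voxel centers at integer indices.
Angles are degrees at every API surface.

The ion beam meets the sample plane at the milling angle β (default 18°;
the 17° stage tilt is carried as metadata only, since the tilt→β offset is
instrument specific and both are quoted independently). For beam azimuth 0
the beam direction is `v = (0, cos β, −sin β)` and the projection plane is
spanned by `u1 = (1, 0, 0)` and `u2 = (0, sin β, cos β)`; a point `p`
projects to `(p·u1, p·u2)`. {u1, u2, v} is orthonormal for every azimuth
(azimuth rotates all three about z), which makes the inverse lift onto any
plane of known z exact. β = 90° is allowed as the regular top-down limit,
where the projection reduces to the conventional axial view. Surface
distances along u2 foreshorten by exactly sin β — the property that makes
the projected light image and the ion-beam image directly comparable.

## Oblique projection and virtual lamellae

Confocal stacks are anisotropic (axial step ≫ lateral pixel), so reslicing
first resamples to cubic voxels at the finest input pitch. Interpolation
is a prefiltered cubic B-spline (an interpolating cubic; `order=1` gives
trilinear), the pragmatic stand-in for the tricubic kernel conventionally
used for this reslicing, whose exact "sharp" variant is not published;
the kernel order is config-exposed and recorded in image provenance.

Projections sample the volume on an *absolute* cubic grid — sample
positions are integer multiples of the pitch along each of the projection
axes, independent of the view — and reduce along the projection axis with
`max` (default, the right choice for point targets), `sum`, or `mean`.
Samples outside the volume contribute zero, so projections dim near the
edges rather than hallucinate signal. Consequences of the absolute grid:

* the β = 90° maximum projection equals the axial MIP bit-for-bit
  (samples coincide with voxel centers);
* sum-mode projection conserves total intensity to the interpolation
  tolerance (measured ≲ 1e−5 relative on smooth scenes, against the 1%
  requirement);
* virtual-lamella slabs use half-open membership `d − t/2 < p·u2 ≤ d + t/2`
  on the shared sample grid, so contiguous slabs partition the volume and
  their sum projections rebuild the full projection to ~1e−7 relative
  error (float accumulation only).

Virtual lamellae render either face-on (along u2; image axes u1 and the
in-lamella beam direction) or top-down (along z, for comparison with a
top-down image of the milled lamella); at β = 18° the two differ only by a
cos β ≈ 0.95 scale along one axis. An empty slab raises with the valid
range of plane offsets.

## Synthetic scenes

A scene is a flat vitrified sample: the surface at `surface_z_um`, a
protective coat above it, point emitters with a separable Gaussian PSF
(lateral σ 150 nm, axial σ 450 nm by default — conventional values for an
NA-0.9 dry objective, config-exposed), diffuse organelle-like Gaussian
blobs, and a cross-shaped reference pattern (RP) etched into the surface.
The confocal render carries the fluorescence channels plus a reflected-
light bright-field channel: an axially PSF-thick surface sheet with the RP
as an intensity deficit. The ion-beam render shows only the surface —
foreshortened by sin β, with the RP deficit, the coat cross-section, and
surface-level emitters as small bright spots; buried emitters are
invisible, which is precisely why the confocal stack is needed. Cross
edges are drawn with a one-sample linear coverage ramp; sampling the sharp
footprint would alias the edges and bias subpixel center estimates by a
few tenths of a pixel. Noise is optional Poisson followed by additive
Gaussian; one scene seed fixes every rendered array bit-exactly through
named RNG substreams.

Drift is modeled as pure translation at constant rate along a configurable
direction (default: the milling direction, the dominant axis in practice);
no rotation or creep.

What the generator does *not* emulate: optical aberrations and depth-
dependent PSF changes, bleaching, ice contamination, curtaining and
sputtering physics, surface topography beyond the flat plane, and real
detector noise statistics. Passing tests therefore demonstrate the
correctness of the geometry, registration and planning logic under
idealized imaging, not robustness to every instrumental artifact.

## Reference-pattern detection and calibration

The RP center is found by normalized cross-correlation against a rendered
template, refined to subpixel by 1D quadratic fits of the correlation
peak; scores below 0.5 raise a detection error carrying the best
candidate. Templates are modality-faithful. A surface view uses the sharp
foreshortened cross. An LM-via-FIB projection sees the cross through an
axially thick surface sheet max-projected along the oblique beam: each ray
samples the surface over a y-range of ~σ_axial·cot β, so the deficit
survives only where the cross covers that range. The template reproduces
this by maximizing `exp(−δ²/2σ²)·(1 − c·cross)` over depth offsets δ,
with σ defaulting to the 450 nm axial PSF. Templates are kept vertically
compact so their constant border does not overlap the projected volume
boundary, which would bias the peak. A practical consequence of the smear:
at grazing angles a small cross washes out, so benchmarks should be etched
with arms of several µm and placed a few µm clear of the imaged-volume
edge (the synthetic validation scenes enforce ~5 µm arms and matching
margins).

Pixel sizes come from FOV / pixel-count metadata (84 µm at 1536 px gives
the nominal 54 nm pixel, truncated to integer nm as conventionally
quoted). The calibration cross-check measures the apparent RP arm lengths
in the two images when both are surface views (warning beyond 2%
disagreement); the projected cross carries no sharp scale information, so
against an LM-via-FIB image the metadata is trusted — the projection's
pixel size is derived from the stack voxel size by construction.

Target transfer needs no image superposition: physical offsets are pixel
offsets times the calibrated pixel size, and
`fib_pos = rp_center_fib + (dx, dy) / fib_pixel`. Localization precision
is budgeted from the manual pick errors either as worst case
(max error × pixel: 4 px at 54 nm → 216 nm ≈ 200 nm, the default, matching
how the headline figure is quoted) or in quadrature over the independent
picks; whether the quoted 2–4 px refers to each pick or the combined
measurement is ambiguous, so both interpretations are provided as modes.
Spot refinement fits a 2D elliptical Gaussian (per-axis 1D fits of
marginal profiles in 3D), falling back to an intensity-weighted centroid,
and raises when no maximum stands 4 robust σ above background.

## Two-step milling plan and Monte-Carlo verification

The coarse prelamella thickness is
`t_final + 2σ_loc + drift_rate·t_coarse + margin`; drift is counted once
because it is directional, and the default 150 nm margin closes the
arithmetic to the ~1.3 µm regime at the default budget (precisely 1332 nm
with σ_loc = 216 nm). The planner centers the symmetric part
(`t_final + 2σ_loc + margin`) on the mapped target and allocates the full
drift allowance on the drift side, because the pattern is fixed in the
beam frame while the sample drifts: the drift-side face is eroded by the
realized displacement. Box rectangles are axis-aligned in ion-image
pixels; beam currents come from a configurable schedule (500 pA etch/
coarse, 150/50 pA fine, 10 pA polish). Relief-cut rectangles may be
attached to a plan but are externally specified, not computed.

The fine step detects the prelamella's two faces as half-maximum crossings
of the band's row profile (subpixel by linear interpolation), measures the
target's distance to each, and emits asymmetric trims leaving the final
thickness centered on the target; trims never cross the target by
construction, and a target outside the detected band raises (the coarse
step failed).

`simulate_success` draws, per run and along the milling direction (errors
transverse to it cannot move the target out of a slab):

* coarse localization error: magnitude uniform in (σ_loc/2, σ_loc) with
  random sign — at σ_loc = 216 nm and 54 nm pixels this is exactly a
  uniform 2–4 px pick, and tying the draw to σ_loc makes success monotone
  in the budget at fixed plan thickness;
* drift displacement: the budgeted rate × duration scaled by
  1 ± 20% uniformly (a realistic stability spread around the typical
  rate), eroding the drift-side face;
* fine boundary-relative measurement error: magnitude uniform in 0–54 nm
  (≤1 px) with random sign. Measuring a distance to an edge within a
  single image is a relative, sub-pixel operation, unlike the absolute
  RP-based picks; fine-step drift is neglected by default (short, low-
  current polishing) and can be enabled via the budget's fine duration.

A run succeeds if the target lies inside the eroded prelamella and inside
the final lamella. Under the default budget the procedure succeeds in
every simulated run, consistent with (and stronger than) the ≥95%
empirical regime it emulates; the simulator also reproduces the designed
failure modes (a prelamella thinner than the error budget fails on the
coarse step).

## LM–TEM rigid correlation

Both images are first brought to a common pixel size (the finer image
downsampled with anti-aliasing by default). The estimator correlates edge
maps (Gaussian-smoothed Sobel magnitude — the lamella outline dominates
both modalities): a coarse rotation sweep scored by phase correlation,
parabolic refinement of the angle, then a 1/100-pixel phase-correlation
translation. The transform is rigid by construction (rotation about the
image center + translation; the linear part is orthogonal with unit
determinant), honoring the constraint that no nonrigid deformation be
introduced. A manual mode accepts an operator-supplied transform and only
attaches its score, replicating the by-hand procedure the automated
estimator replaces. Measured recovery on synthetic lamellae: ~0.06°
rotation and ~0.05 px translation error, against the 0.2° / 0.5 px
requirement. Featureless inputs return a low-confidence warning rather
than failing, since the score threshold (default 0.1 NCC) is heuristic.
Navigation boxes are centered on fluorescence maxima mapped into the TEM
frame and ranked by integrated intensity.

## Problem sizes and numerical choices

Validation scenes are 16 × 16 × 5 µm sampled at 0.1 µm laterally / 0.3 µm
axially, projected at a 0.1 µm cubic pitch, with matched 160 px ion-beam
views — small enough that the full synthetic benchmark suite (21
registration scenes, 8-emitter projection oracles at five angles, 200
Monte-Carlo localization trials, 20 rigid round trips, 1000 plan
simulations) runs in about a minute on one core, while every tolerance is
assessed in pixels of equal physical size in both modalities, as in the
workflow being modeled. Degenerate inputs fail loudly: milling angles
outside (0°, 90°], empty slabs, targets outside the prelamella, flat
images in spot search, undetectable benchmarks and missing voxel metadata
all raise with actionable messages. Ties in correlation maxima resolve to
the first (row-major) maximum; quadratic subpixel refinement is skipped at
image borders and at non-concave peaks.

## Known limitations

* The beam is an ideal orthographic direction: no convergence, dose or
  sputter-rate modeling, and no vendor pattern-file export.
* Calibration against the projected cross is trust-the-metadata; an
  independent physical scale check needs two surface views.
* The fine-trim boundary detector assumes a single bright band in the row
  profile; heavily structured prelamella images would need the manual-pick
  path.
* LM↔tomogram (3D) correlation is out of scope; correlation is 2D at the
  lamella plane.
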