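# Methods

This note documents the models behind `tbiplan`: what is simulated, the
simplifications chosen, the tunable parameters and their defaults, and
what the package's passing tests do and do not establish about real
patients.

## Coordinate conventions

World coordinates are patient coordinates in millimetres with the origin
at the pelvis reference mark; x toward the patient's left, y anterior,
z superior. Arrays are indexed `[ix, iy, iz]` with the voxel-centre world
position `origin + index * spacing`. A feet-first (FFS) volume stores the
scanner's view of the patient rotated 180° about the vertical axis: its
stored x and z axes run opposite to the patient axes, and conversion is an
exact axis flip. Sub-target z-intervals are half-open,
superior-exclusive, which makes tiling arithmetic unambiguous.

## Synthetic phantom

The phantom is a stack of analytic solids: paired overlapping leg
cylinders (adducted legs that touch at the midline, so the isocenter line
passes through tissue), an elliptic-cylinder trunk, a neck cylinder and a
cranial ellipsoid ending exactly at the prescribed height. Lungs and
kidneys are paired ellipsoids. Proportions default to standard
anthropometric ratios of height (pelvis mark at 52% of height above the
soles, trunk width 0.25 h, AP thickness 0.12 h clamped to the 14.3–33 cm
clinical span, leg width 0.10 h, lungs centred at 0.205 h with length
0.12 h, kidneys at 0.075 h with length 0.06 h, head–neck length
min(24 cm, 0.16 h)); every value is a `PhantomSpec` field and can be
overridden. HU values are three-level (soft tissue 0, lung −700, air
−1000): the dose engine only distinguishes water-equivalent and lung
density, so bone is omitted. Three small 800 HU spheres near the pelvis
mark emulate the marked reference point and bony detail; without them a
smooth trunk leaves the two-scan registration unidentifiable along z.
The default grid is 2.5 × 2.5 × 5 mm (5 mm slices); the test-suite and
acceptance runs use 5 mm isotropic CTs to keep the full pipeline fast —
all geometric rules operate in continuous millimetres and are unaffected
by the raster resolution beyond voxel rounding.

What the phantom does **not** emulate: CT texture and noise (a `noise_hu`
field exists, default 0), arms, bone heterogeneity, body-contour
variation along the trunk, and separated legs. Tests passing on this
phantom demonstrate the correctness of the workflow's *rules and
transforms*, not dosimetric accuracy in real anatomy.

## Two-scan simulation and stitching

`split_scans` cuts the whole phantom at ±overlap/2 around the pelvis mark
(default overlap 10 cm — the scan protocol does not fix it) and resamples
the feet-first scan with a known rigid offset (≤ 20 mm/axis) emulating the
setup change between acquisitions; the offset is returned as registration
ground truth. Registration minimizes the mean squared intensity
difference (the scans are same-modality by construction) over a pelvis
z-interval, translation-only by default with optional small (≤ 10°)
rotations, using a deterministic coarse grid search (±12 mm, 3 mm steps)
followed by Powell refinement. The SFF voxels serve as the fixed samples
and the SHF scan is the image interpolated during optimization; because
the synthetic SFF scan is itself an interpolated image, this orientation
avoids double interpolation and recovers the applied offset essentially
exactly. Stitching resamples the aligned SFF scan onto the extended SHF
grid with a hard transition at the mid-overlap plane (SHF precedence
above it): deterministic and testable, where feathered intensity blending
would be cosmetic.

## PTV and sub-target division

PTV = body eroded 3 mm isotropically (Euclidean distance transform
threshold), minus lungs and kidneys. The division rules:

1. head sub-target `[neck_bottom, PTV top)`; its optimization length
   (+2.5 cm inferior OFZ) must not exceed the 28 cm optimization cap;
2. fixed-length VMAT blocks (23 cm default, derived from the machine
   constants) stack inferiorly; by default the last block *crosses* the
   top of the legs so that AP/PA fields only ever cover legs and feet
   (≤ 35 cm wide). A flag restores the stricter "end at or above
   legs-top" behaviour, which can push a >35 cm-wide pelvis slab into the
   AP/PA region;
3. the AP/PA look-up: the remaining length plus the ≥5 cm feet margin is
   covered by equal-length sub-targets from {25, 30, 35} cm, minimizing
   the isocenter count first and the length second (verified against
   exhaustive search);
4. isocenters at sub-target z-centres; junction points at the centres of
   the 5 cm opt-interval overlaps; all points share the lateral/vertical
   coordinates of the pelvis-level PTV centroid, rounded to 1 mm.

Because the equal-length AP/PA stack must overshoot the feet, the
sub-target intervals cover (rather than exactly equal) the PTV z-extent;
the partition tests assert contiguity, disjointness, coverage, and the
feet margin.

**Pediatric adjustment.** Boundaries can only move superiorly when
sub-target lengths shrink (the stack is anchored at the neck), so the
adjuster picks the boundary requiring the smallest total shortening to
land its 5 cm junction overlap inside the lung–kidney gap (error if the
gap is under 5 cm) and distributes that shortening evenly over the VMAT
sub-targets between the neck and that boundary; everything below shifts
up, and the AP/PA stack is rebuilt. **Large-patient adjustment.** When
the lateral extent exceeds a 40 cm threshold, trunk VMAT lengths are
reduced by 1–2 cm and the stack re-tiled.

## Dose engine

A primary-only exponential engine keeps every junction property
analytically checkable:

    D = MU · 0.01 Gy/MU · w_segment · (SAD/d_src)² · A(WED) · T_block

with `A` a linear build-up to d_max followed by `exp(−μ_eff (WED−d_max))`,
and WED the parallel-ray line integral of relative density along the beam
axis (2.5 mm steps; divergence is kept in the inverse-square factor and
the aperture projection but neglected in depth). Densities: air 0, lung
0.3, soft tissue 1. Defaults (engineering values, configurable in
`PhysicsConstants`): μ_eff 0.049 / 0.044 cm⁻¹ and d_max 1.5 / 2.5 cm at
6 / 10 MV; cerrobend 0.49 / 0.43 cm⁻¹; Lucite density 1.18. Apertures
are rectangles at the isocenter plane; voxels outside all apertures get
exactly zero (no penumbra or scatter). Dose is evaluated on a 5 mm grid
whose centres lie on the CT lattice (this keeps nearest-neighbour
resampling stable under the exact frame flip used by the delivery-plan
equivalence check) and only at voxels with non-zero density. All dose
arithmetic is float64 so that the SHF/SFF equivalence check passes at
1 μGy rather than float32 rounding (~2 μGy at 13 Gy).

## Junction dosimetry

**Feathered AP/PA.** Each AP/PA sub-target gets a 6 MV AP/PA pair,
collimator 90°, three nested rectangular segments whose longitudinal
edges step in 2.5 cm decrements across each junction-facing 5 cm zone
(the exact step sizes are not dictated by the machine constraints; half
the feathering-zone width per step reproduces a three-level staircase).
The most inferior pair's inferior edge is fixed at the 20 cm maximum
opening to cover beyond the feet. Segment weights are optimized jointly
by non-negative least squares to the prescription over the AP/PA-region
PTV plus, across the VMAT-facing junction, the descending linear ramp
spanning the junction plus one feathering step — that target makes the
fitted staircase levels 1, 2/3, 1/3, 0 (equal steps, the least
shift-sensitive three-level ramp). Weak intra-beam smoothness rows break
active-set ties that would otherwise collapse the staircase to fewer
steps. The optimizer naturally runs the leg interior slightly hot
because the surface build-up region cannot reach the prescription with
unmodulated open fields — the same behaviour as clinical AP/PA dosimetry.

**Step wedge.** Nine equally weighted beams, gantry 0°–320° in 40° steps
(0° start assumed), each with five equal-weight nested segments advancing
in 1 cm steps, produce a five-level staircase fluence spanning the 5 cm
junction, monotone toward the chosen side. These beams assist planning
only and are not part of the delivery plan.

**VMAT surrogate.** The commercial arc optimizer is out of scope; each
VMAT sub-target is represented by the idealized dose it is forced toward:
prescription inside the optimization interval (body voxels only, half-
voxel roll-off at non-junction edges), minus the junction base dose,
clipped at zero. At VMAT–VMAT junctions the base is the *linear* ramp
that the staircase wedge idealizes (the staircase bin midpoints are
collinear); this makes complementary ramps sum exactly to the
prescription and gives the closed-form shift-error law
`deviation = δ / 50 mm × rx`. At the VMAT/AP-PA junction the base is the
actually delivered AP/PA column profile along the isocenter line, frozen
into the surrogate beam's metadata so a delivery plan recomputes
identically on its own. Junction-closure guarantees are therefore stated
along the isocenter line; off-axis, AP/PA depth dose varies with anatomy
as it would clinically. The lung-isocenter surrogate scales lung-voxel
dose to the organ goal (10 Gy adult / 8 Gy pediatric over the course),
standing in for the optimizer's sparing objectives; kidney sparing is not
modelled in the surrogate (kidney dose is only reduced in the classic
comparator, via blocks). Surrogate monitor units are the per-fraction
prescription in cGy times a modulation factor (default 10, an engineering
estimate for heavily modulated arcs); the lung isocenter runs at
200 MU/min, everything else at 600 MU/min, and the lung dose rate is the
per-fraction lung dose from the lung-isocenter beams divided by their
beam-on time.

## Classic extended-SSD comparator

Opposed 10 MV beams at SAD 400 cm, 40 × 40 cm field collimated at 45° (so
the diagonal covers the body axis), single isocenter at the body
centroid; a 1 cm Lucite spoiler adds 11.8 mm water-equivalent build-up.
MU is set so the open pair delivers the prescription at mid-separation of
the thickest section. The lung block is the beam's-eye-view lung shadow
contracted 5 mm, with thickness solved in closed form
(`t = ln(D_open/D_target)/μ_cerrobend`) for 10 Gy (adult) or 8 Gy
(pediatric) at mid-lung — the phantom has no heart, so the lung outline
stands in for the lung–heart outline; kidney blocks take the kidney
shadow at a fixed 4 cm. The comparator is used for directional
plan-quality comparisons only (coverage up, hotspot down for the
multi-isocenter technique); no printed clinical DVH value is a
reproduction target.

## Delivery-plan conversion

Beams with isocenters superior to the pelvis origin are delivered
head-first; inferior beams are inverted to the feet-first frame:
`gantry → (360 − g) mod 360`, `collimator → (c + 180) mod 360`, isocenter
x and z negated about the origin point. The mirrored gantry flips both
beam's-eye-view basis vectors and the half-turn collimator rotation flips
them back, so unchanged segment apertures cover the same tissue — the
inversion is an involution and the recomputed delivery dose matches the
whole-body dose to ≈1e-14 Gy. An isocenter exactly at the origin z is an
error rather than a silent assignment (silent choice risks double
delivery). Table shifts exported with each delivery plan are the planned
isocenter spacings.

## Robustness model

Setup errors are rigid translations of each isocenter's dose contribution
(dose-cloud shift, linear interpolation), not a recomputation through
shifted anatomy: this isolates the junction-matching mechanism and keeps
the ramp closed forms exact. The correction policy corrects
lateral/vertical errors (perfectly by default; a residual fraction is
available) and leaves longitudinal errors untouched, mirroring
image-guided delivery with locked longitudinal table moves. Junction
error is the signed worst deviation from the nominal composite, as a
percentage of prescription, along the isocenter line in each 5 cm
junction slab. The scenario generator draws independent per-axis
Gaussians whose sigmas are calibrated so the probability of an any-axis
shift above 5 mm matches observed clinical frequencies per isocenter role
(head 38%, lung 62%, abdomen 39%, pelvis 33%; the pelvis value is reused
for leg/feet isocenters) — a calibration target for the generator, not a
reproduction of the clinical distributions. Under this model the VMAT
junctions (linear ramps) show mean absolute deviations of a few percent,
while the AP/PA staircase junctions quantize at one-third of the
prescription per step and are accordingly less robust — the expected
behaviour of three-segment feathering relative to optimizer-shaped ramps.

## Problem sizes

The shipped tests and the acceptance script run adult phantoms of
120–200 cm at 5 mm (partition property sweeps at 7.5 mm lateral) with
5 mm dose grids: large enough that every rule (counts, overlaps, margins,
junction laws) is exercised at clinical dimensions, small enough that the
whole suite completes in a few minutes.

## Known limitations

- Primary-beam dosimetry only: no scatter, penumbra, or heterogeneity
  corrections beyond the lung density override; absolute doses are
  internally consistent, not clinically calibrated.
- The VMAT surrogate asserts what a converged optimizer is forced toward;
  it cannot detect optimizer failures, MLC sequencing limits, or
  deliverability issues.
- Kidney sparing and arm anatomy are not modelled in the surrogate plans.
- Registration is validated on noise-free phantoms with fiducial-like
  features; real CT–CT registration robustness (noise, bowel gas,
  truncation) is out of scope.
- Clinical outcome statistics (patient DVH populations, observed shift
  distributions, treatment times) cannot be reproduced at desk scale and
  are used only to set calibration targets or comparison directions.
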