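# Methods

`nestmech` quantifies how a wall-anchored, single-material half-cup nest —
the architecture the edible-nest swiftlet (*Aerodramus fuciphagus*) builds
from threaded saliva — carries the loads of the birds and eggs it exists to
hold.  The pipeline mirrors a μCT-based structural workflow: volumetric
imaging, segmentation and closed-pore morphometrics, tensile
characterization of the material, and a linear-elastic finite-element (FE)
simulation whose failure criterion is the maximum principal stress, as
appropriate for a brittle material.  Because real nest scans are large and
not redistributable, every stage is exercised end-to-end on a synthetic
phantom whose architecture follows the published description of the real
nests; the phantom's ground-truth masks double as the oracle for
segmentation-recovery tests.

## Axis and unit conventions

Array axis 0 is U-D (up-down; gravity acts toward −axis 0), axis 1 is B-F
(back-front; the vertical wall the nest is glued to is the axis-1 = 0 grid
face), axis 2 is R-L (right-left).  Voxel (i, j, k) has its physical center
at ((i+0.5), (j+0.5), (k+0.5))·spacing.  All lengths are carried in mm, and
the FE stage works in the consistent mm–N–MPa–tonne/mm³ system with
g = 9806.65 mm/s², so an elastic modulus in MPa combines with forces in N
without conversion factors.

## Synthetic nest phantom

**Geometry.**  The shell is the region between two concentric
half-ellipsoids clipped at the horizontal rim plane and at the wall plane.
The outer envelope spans 77.5 mm (R-L) × 39.8 mm (U-D), the dimensions
reported for real nests (which agree across specimens to within ~10%); the
nest depth and the wall thicknesses are *not* reported anywhere, so the
defaults — depth 38 mm, wall thickness graded linearly from 6 mm at the
anchor to 4.5 mm at the rim, plus a quadratic inward flare of the anchor
pad onto the wall — are package assumptions chosen to reproduce the
qualitative gradients (cross-section decreasing, porosity increasing from
anchor to rim).  The target mass defaults to the reported 5.93 g.

**Strand texture.**  Real walls are built from ~0.25 mm horizontal saliva
threads whose inter-strand gaps leave closed pores elongated along the R-L
axis.  The phantom emulates the *pores* directly: material is removed on a
quasi-periodic, jittered lattice of ellipsoidal voids elongated along R-L
(transverse pitch from `fiber_pitch`, clamped to ≥ 6 voxels so voids stay
resolvable at desk spacings; the clamp is inactive at the full 34.04 μm
scan-class resolution).  Each candidate void is accepted with probability
proportional to a linear porosity ramp (defaults 3% at the anchor to 9% at
the rim, normalized by the lattice's maximum achievable porosity), and only
at sites where the void plus a two-voxel material margin fits inside the
shell.  Any carved air that still reaches the exterior (or the open cup) is
filled back, so every ground-truth pore is closed by construction.  The
two-voxel margin is what lets the pores survive the one-voxel boundary
erosion of Gaussian smoothing during segmentation.

**Imaging model.**  Grayscale is painted from per-region means that fall
from anchor (90) to rim (60) — mirroring the denser anchor material — over
a background of 10, with additive zero-mean Gaussian noise (SD 8) clipped
to [0, 255].  The means are chosen so the default threshold of 40 sits near
the blurred edge midpoint, keeping the segmented surface unbiased.  Beam
hardening, ring artifacts, detector physics and partial-volume blur are not
modelled; consequently, passing recovery tests demonstrates that the
pipeline is correct and well-calibrated on clean, known-truth geometry, not
that it is robust to every real-scanner artifact.

**Desk preset.**  The default voxel spacing is 0.35 mm (grid ≈ 118 × 111 ×
226, ~3M voxels, generated in ~1 s) and the FE stage runs on the factor-2
downsample (0.7 mm elements, ~68k elements).  This is a deliberate
scaled-down preset: it preserves the architecture (graded shell, closed
elongated pores, ~180 pores per nest) at a size a laptop solves in about a
minute.  Full 34.04 μm generation is supported but gated behind a voxel
budget (`max_voxels`) so a desk machine is never asked for a 3·10⁹-voxel
array by accident.

**Determinism.**  One `numpy` Generator seeded from `PhantomParams.seed`
drives jitter, acceptance and noise; identical parameters give bit-identical
bundles.

## Segmentation

The recipe follows the published scan-processing protocol, in a fixed,
logged order: Gaussian smoothing (σ = 1 voxel, discrete kernel truncated at
4σ, re-quantized round-half-even) → inclusive window threshold (40…255) →
largest 26-connected component (flood-fill artifact removal, ties broken by
raster order) → linear-interpolation downsampling (factor 2; 34.04 μm →
68.08 μm, i.e. the "68.1 μm" class) → closed-pore classification.  The
background is labelled with 6-connectivity; components touching any volume
border are exterior, the rest are closed pores; pores smaller than 125
voxels are added back into the material mask (the published rule, defined
at scan-class voxel sizes), and survivors are labelled 1..N.  Material
foreground uses 26-connectivity and pores 6-connectivity — complementary
connectivities avoid corner-leak paradoxes; the original software's choice
is unpublished, so both are parameters.  "Recursive Gaussian" in the source
protocol names the filter family, not coefficients; an equivalent discrete
Gaussian is used and asserted against an explicit convolution oracle at
8-bit precision.  Downsampling before pore extraction is the default
(matching the protocol); the reverse order is available
(`resample_before_pores=False`) with nearest-neighbour label resampling.

*Recovery harness.*  Segmentation-recovery tests run at generation
resolution (`resample_factor=1`) with `min_pore_voxels=2`: the 125-voxel
rule is a physical-volume rule (~5·10⁻³ mm³ at 34–68 μm voxels); applied
verbatim at 0.35 mm desk voxels it would fill every pore (125 desk voxels
≈ 5.4 mm³).  Across seeds 1–5 at default noise the material Dice is ≈ 0.986
and the closed-pore count is recovered exactly.

## Morphometrics

Material volume is voxel count × voxel volume.  Surface area counts exposed
voxel faces; for smooth bodies this estimator converges to 1.5× the true
area (staircase bias — asserted on digitized balls), so it is used only
comparatively, e.g. the anchor-to-rim surface-area profile.  Slice profiles
report, per slice along any axis, the material area, the face-count surface
contribution, and the closed-pore percentage with denominator
material + pore voxels (exterior air excluded, so padding cannot change the
number; empty slices report 0).  Pore shape comes from the second-moment
tensor of voxel centers, augmented by each voxel's own uniform moment
(s²/12 per axis — voxels are cubes, not points, and without this term
few-voxel-thick pores read systematically thin).  Principal lengths use the
uniform-ellipsoid identity L = 2√(5λ), which recovers digitized analytic
ellipsoids within the stated tolerances; angles to the anatomical axes are
folded to [0°, 90°] because pore orientation is sign-free.  Single-voxel
pores are flagged degenerate (elongation 1, angles undefined); elongation
< 1.1 sets a near-isotropic flag since the major axis of a near-ball is
noise.

## Tensile reduction

Engineering stress and strain throughout: σ = F/A₀, ε = ΔL/L₀, no
smoothing.  The elastic modulus is the OLS slope of σ on ε over
ε ∈ [0.002, ε at 0.5·σ_peak] restricted to the pre-peak branch — the lower
bound skips the seating toe, the upper bound stays clear of the softening
branch; with fewer than 5 samples in that window the fit falls back to the
first half of the pre-peak range, and the window actually used is recorded.
Fracture stress is the global peak; strain to fracture is the strain at the
first post-peak sample below 10% of the peak (flagged if never reached);
post-peak drops exceeding 5% of the peak between consecutive samples are
reported as fiber-failure events.  The 0.002 / 0.5 / 0.1 / 0.05 brackets
are conventions exposed as parameters — the source protocol describes the
linear regime and the stress drops only qualitatively.  Cohorts aggregate
with unweighted mean and sample SD (ddof = 1; a single specimen reports
SD 0 by convention), both overall and per cut orientation (0°/45°/90°),
since how the original horizontal-specimen average was weighted is
unstated.  A seeded synthetic-specimen generator (linear rise, parabolic
cap, discrete post-peak drops, cliff at the fracture strain) supports tests
and demos; it is a test articulation, not a measurement model.

## Voxel finite elements

Each material voxel becomes an 8-node trilinear hexahedron with shared
nodes — the micro-FE convention for CT-derived structures, and this
package's one deliberate methodological substitution for the original
tetrahedral free meshing (deterministic, library-free, and exactly testable
against patch states).  All elements are identical cubes, so one 24×24
stiffness matrix (isotropic Hooke, full 2×2×2 Gauss quadrature) is
assembled over the mesh into a CSR system.  The material is isotropic at
the element level (E = 155 MPa, ν = 0.3 by default, from the tensile
characterization of the real material); structural anisotropy arises from
geometry only.  Element densities are proportional to mean voxel grayscale
and rescaled so the summed mass equals the measured nest mass (5.93 g
default) — the grayscale-to-density map of the original workflow is
unpublished, so a linear rescale to total mass is the declared choice.
Gravity enters as equal 1/8 nodal shares of ρgV per element (the consistent
load for constant body force on a trilinear brick); external loads are
split equally over their ROI node sets.  Wall-face material nodes are fully
pinned.

The solver is Jacobi-preconditioned conjugate gradients with fixed
ordering, relative residual ≤ 10⁻⁸, max 50,000 iterations; non-convergence
raises.  Stresses are recovered once per element at the centroid (no Gauss
extrapolation) and the maximum principal stress is the largest eigenvalue
of the symmetric centroid tensor, tension positive.  Verified oracles:
constant-stress patch states exact at any resolution; bar end displacement
FL/AE; slender-cantilever tip deflection within 10% of PL³/3EI; reaction
equilibrium to 10⁻⁶ relative; exact linearity in the loads.

## Loading scenarios

Loads: each bird 16 g and each egg 1.2 g, converted at standard gravity
with 4-decimal truncation to 0.1569 N and 0.0117 N, acting along −U-D.
`worst_case` places two bird cuboid footprints (default 5 × 5 mm) on the
outermost rim band at ±20° from the front midline and two egg elliptic
patches (default 10 × 6 mm) on the cup floor at ±8 mm from the floor low
point; `eggs_only` and `birds_only` isolate the load groups; `damaged`
re-runs the worst case after spherical damage sites are carved out.  The
±20° default follows the loading intent of the worst case — the bending
moment on the wall fixation is the applied force times its B-F distance
from the wall, maximal at the front midline — while keeping two distinct,
symmetric footprints; wider angles shorten the moment arm.  ROI shapes
follow the original study's figures; their sizes and exact placement are
unpublished, so all are configuration with the defaults above.

ROI forces resolve onto exterior material nodes with an upward-exposed
face inside the plan footprint, restricted to within 1.5 mm of the highest
such node (`surface_band`): a standing bird or resting egg contacts the
top surface only, never ledges or damage-crater floors further down the
same plan column.  Each load is split equally over its node set.

Reports carry the global maximum principal stress with its location,
per-region statistics (rim band = top 10% of the occupied U-D extent; anchor
band = the 10% of the B-F extent nearest the wall; egg region = elements
inside the egg patches dilated 1.5×) and the safety factor
σ_fracture / σ_max against the measured mean fracture strength (2.75 MPa
default).  Region definitions and the fracture strength are reporting
conventions only — they never enter the solve.  On the desk phantom the
worst case peaks near 0.01 MPa at the top corner of the wall fixation —
the peel-off point under the birds' bending moment — more than two orders
of magnitude below the fracture strength: the same overdesign verdict the
original full-resolution models reach (their finer, strand-resolved
geometry concentrates stress to ~0.56 MPa where the birds stand — still
five-fold below strength).  A coarse smooth-walled phantom cannot and
should not reproduce that strand-scale peak value, which is why the
package's acceptance checks compare against the fracture-strength bound
rather than the peak itself.

## Problem sizes and tolerances

Defaults were chosen so the full chain is desk-sized: phantom generation
~1 s; segmentation at native resolution ~4 s; the worst-case FE model
(~68k elements, ~260k DOF) solves in ~1500 CG iterations / ~1 min.
Numerical tie-breaks are all deterministic (raster order for component
ties, fixed solver ordering).  Degenerate inputs raise explicit errors:
empty masks, free-floating models, ROIs that touch no material, spacing
never defaulted silently.

## Known limitations

- The phantom's pores sit on a jittered lattice; real inter-strand pore
  networks are irregular, and strand-scale stress concentrations are absent
  at desk resolution.
- The face-count surface estimator is comparative, not absolute (1.5× bias).
- Linear elasticity with small strains only; no contact, fracture
  propagation, or material nonlinearity — adequate for the load scale
  studied, where peak stresses stay far below strength.
- Single-point centroid stress recovery slightly smooths extrema relative
  to Gauss-point extrapolation.
- The grayscale-to-density map is a linear rescale to total mass; real
  attenuation-to-density calibration would require scanner calibration
  phantoms.
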