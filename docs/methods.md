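# Methods

This note documents the models, conventions, numerical choices and
known limitations of the `osteomech` pipeline. It is the package's own
account of its science; every number quoted here is computed by the
test suite or by `scripts/acceptance.py`.

## Synthetic specimens

All inputs are synthetic, generated by `osteomech.phantoms` with
recorded ground truth. The generators define the study conditions; the
analyses never see the truth they are checked against.

**Femur phantom.** A stylized distal femur on an isotropic voxel grid
(default 10 μm; the test suite and acceptance script use 20 μm to keep
volumes at ~10⁷ voxels): a piecewise-linearly tapered cortical tube
(metaphysis outer radius 0.9 mm narrowing to a 0.55 mm diaphysis, wall
0.2 mm) whose medullary canal carries a trabecular lattice in the
metaphysis (3.2 mm below the growth-plate plane, which is stored as
metadata, not a label) and marrow elsewhere. Labels: 0 background,
1 cortical, 2 trabecular, 3 marrow.

The trabecular compartment is a *regular plate/rod lattice with seeded
jitter*, chosen over a stochastic Gaussian field because its volume
fraction, strut thickness and pore size have closed forms. For square
rods of thickness t at cubic spacing s (a = t/s), inclusion–exclusion
over the three rod families gives BV/TV = 3a² − 2a³, which is inverted
(Brent's method) to pick the spacing for a requested BV/TV. An optional
plate component — horizontal plate tiles of one lattice cell, selected
per level by area-weighted quota sampling so the realized plate volume
tracks its budget within one tile — takes a configurable share
(`plate_fraction`) of the solid budget. Rod positions are jittered by
±5% of the spacing (seeded); all randomness flows through one
`numpy.random.Generator`.

**WT/KO presets.** The presets encode the knockout contrasts as
*measured* ratios, i.e. they are calibrated so the morphometry pipeline
reports the designed directions (the spec for absolute murine anatomy
is not the target):

| parameter | WT | KO |
|---|---|---|
| trabecular BV/TV target | 0.12 | 0.03 (0.25×) |
| architecture | plates + rods (plate_fraction 0.5) | rods only |
| strut thickness | 50 μm | 66 μm |
| diaphysis outer radius | 0.55 mm | 0.44 mm |
| cortical thickness | 0.2 mm | 0.2 mm (unchanged) |
| cortical / trabecular El | 10 / 6 GPa | 7 / 4.5 GPa (0.70× / 0.75×) |

The plate-to-rod conversion is the load-bearing modeling choice: on a
pure rod lattice the maximal-sphere thickness is dominated by the
junction spheres (diameter ≈ √2·t), which inflates measured Tb.Th by a
factor that almost exactly cancels a +10% strut-thickness contrast.
With plates in the WT (thickness measured at face value) and rods only
in the KO, both Tb.Th↑ and SMI↑ express robustly across seeds, as they
do in osteoporotic bone for the same structural reason.

**Curves and tables.** Indentation records are exact forward-Hertz
curves on a uniform depth grid (200 points, 50 nm default cap, optional
contact offset and additive Gaussian force noise). Bending records
compose a quadratic toe, a linear elastic ramp, slope-continuous
quadratic hardening to the peak, a shallow post-peak decline and a
terminal >50% force drop at fracture; the recorded ground-truth yield is
the 0.2%-offset construction evaluated on the noise-free curve (the
`yield_load` input is the proportional limit, a different quantity).
Calcein tables draw interlabel distances about MAR×interval and split
the mineralizing surface 60/40 between double and single labels so that
(dL + ½sL)/BS equals the target.

What the generators do **not** emulate: real trabecular architecture
statistics (connectivity, anisotropy), CT reconstruction artifacts and
partial-volume gray levels, AFM adhesion/creep, post-yield damage
mechanics, or biological variance structure. Passing tests therefore
demonstrate correctness of the *computations*, not robustness to every
artifact of real data.

## Micro-CT morphometry

The VOI is the axial window [gp + 1 mm, gp + 3 mm) (half-open, by voxel
center); the reference total volume for BV/TV and BS/TV is the
endosteal region (trabecular bone + marrow). Conventions, all recorded
in the report's `conventions` field so alternates can be swapped in:

* **Surface (BS/TV):** marching cubes at level 0.5 on the binary phase
  Gaussian-smoothed with σ = 1 voxel. Raw binary marching cubes reads a
  digital sphere's area ~9% high (faceting); smoothing brings it to
  +0.25%. Boundary mode is `reflect`, so surfaces are open at the VOI
  faces (open-VOI-face convention; an all-foreground block has BS = 0).
* **Tb.Th / Tb.Sp:** model-independent maximal-inscribed-sphere local
  thickness (Hildebrand–Rüegsegger), computed by scanning
  distance-transform radii in descending half-voxel bins and painting
  each sphere class's coverage; volume-weighted mean over the phase
  (marrow phase inside the VOI for Tb.Sp). Ideal plates and rods are
  recovered within one voxel. Phases touching the array boundary are
  effectively mirrored there by the distance transform.
* **Tb.N:** the 3D direct convention 1/(Tb.Th + Tb.Sp).
* **SMI = 6·V·S′/S²:** S′ is the surface-area derivative under unit
  surface dilation, estimated by central difference with the
  triangulated surface's vertices displaced ±½ voxel along their
  outward normals (mesh dilation). Offsetting a voxel signed-distance
  field instead was tested and carries an irreducible quantization
  drift (ideal cylinder/sphere read 2.6/3.4 or 3.3/4.4 depending on the
  boundary convention); mesh dilation reads 3.03/3.99 against the
  closed-form 3/4, and 0.0 for a plate.
* Undefined metrics raise (`UndefinedMetricError`) rather than return
  0, because 0 is a legal SMI value. Foreground connectivity is 26,
  background 6, where connectivity matters.

## Section geometry

Each voxel is a solid unit square contributing its own h⁴/12 plus the
parallel-axis term about the section centroid (point-mass voxels would
bias thin walls). Principal moments come from the eigen-decomposition
of the 2×2 second-moment tensor [[Ixx, −Ixy], [−Ixy, Iyy]], whose
eigenvectors are the axis directions; θ is the Imax-axis angle in
(−π/2, π/2], with θ = 0 on ties. C1/C2 are the farthest voxel-center
perpendicular distances from the Imax/Imin axes, so Imax/C1 and Imin/C2
are the section moduli about the two principal bending axes. The
profile runs over cortical+trabecular labels by default; flexural
rigidity is E·Imin when a modulus is supplied. Verified: trace
invariance to machine precision, exact agreement with a brute-force
per-voxel oracle, closed forms for circle/square/ellipse within 1% at
≥200 voxels/diameter, and rotation/translation invariance.

## Nanoindentation

The Hertz fit is linear least squares of F on δ^{3/2} through the
origin over the post-contact window capped at 50 nm (hard filter,
configurable) — closed form, no initialization; E = slope·(3/4)(1−ν²)/√R,
with nm/nN units giving GPa directly. Contact detection thresholds the
force at baseline mean + 5 SD and refines the offset as the x-intercept
of the (exactly linear) F^{2/3}-vs-δ relation, clamped to the record
start. Default ν = 0.3 when curve metadata omits it. The log-frequency
law E(f) = a + b·ln f is plain least squares on (ln f, E); b > 0 is the
rate-stiffening signature of viscoelastic bone. Round trip: noise-free
curves refit to <0.1%; 50 replicates at 2% multiplicative force noise
recover the mean within 0.2% with no directional bias.

## Three-point bending

Stiffness is the maximum moving-window least-squares slope inside the
elastic window. The window is found by (1) excluding the toe — leading
windows whose slope is below half the running maximum and below 90% of
a robust reference slope (90th percentile of window slopes, which
resists single noisy spikes); (2) ending at the first sustained
(3-sample) drop of the *curve* below the anchored elastic line by
max(3σ, 1.5% of peak force) — testing the curve rather than windowed
slopes proved far less noise-sensitive. Slope windows default to 25% of
the elastic window: at the generator's sampling density and noise,
narrower windows make the max-slope statistic a maximum over many noisy
estimates and bias stiffness upward by ~9%. Yield is the intersection
with the elastic line offset by 0.2% of the span (the reproducible
standard when no definition is given); fracture is the first
inter-sample force drop exceeding 50% of peak; ultimate load and
displacement are taken just before it (flagged, not fatal, if absent);
work is the trapezoidal integral to fracture. The span is an explicit
parameter (default 7 mm; the physical support distance is ambiguous in
such protocols). Stiffness is a whole-bone structural property in N/mm
and is never converted to a tissue modulus here.

## Finite elements

Voxel-aligned 8-node hexahedra; because all elements are congruent
cubes, the element stiffness is cached once as two 24×24 kernels
(λ- and μ-parts, K_e = h·(λK_λ + μK_μ)) built with 2×2×2 Gauss
integration and B-bar (mean-dilatation) volumetric treatment — required
because marrow at ν = 0.499 would otherwise lock. Materials map per
label (the phantom's HU proxy is monotone affine per tissue, so HU
binning reduces to label mapping); marrow default E = 20 MPa, ν = 0.499;
bone ν = 0.3 with El means from nanoindentation. The mesh must be a
single face-connected component (anything else is a mechanism and is
rejected naming the component sizes).

Three-point bending: vertical displacement fixed on two transverse
bottom node lines a span apart; one pin (x, z) at one support's center
node and one (x) at the other remove the remaining rigid modes without
restraining axial fiber strain; the 5 N load is spread over the
midspan top node line (a line, not a node, to avoid a singular point
load). Nodes are numbered z-major so the matrix is banded; direct
sparse factorization is used up to 60k free DOFs and
Jacobi-preconditioned CG (rtol 1e-10) above. Stresses/strains are
evaluated per element at the center with the B-bar operator; the
midspan deflection is read on the bottom fiber (the loaded top line
carries a local indentation). Energy is ½fᵀu; vertical support
reactions balance the load to ~1e-11 relative.

Validation against Euler–Bernoulli uses a hollow tube at
span/diameter ≈ 14 with I and c taken from `section_geometry` on the
as-meshed section: at slenderness 10, Timoshenko shear deflection alone
is 8–11% of FL³/48EI, so no correct 3D solver can match the closed form
to 5% there; at ≈14 shear is ~3% and the solver lands within 2.1%
(50 μm voxels) / 0.4% (40 μm). Outer-fiber von Mises is compared at the
tension-side outermost element rows (voxel stair-step surface elements
are locally under-stressed — a standard voxel-FE caveat) and agrees
with (FL/4)·c/I within 5–7%.

## Histomorphometry and statistics

MAR = mean interlabel distance / label interval (7 days default); no
obliquity correction is applied to interlabel distances (none is
standard without section-angle data). MS/BS = (dL + ½sL)/BS;
BFR/BS = MAR × MS/BS in μm³/μm²/day. TRAP-positive cells need ≥ 3
nuclei to count as osteoclasts; densities are per bone perimeter.

t-tests are pooled-variance Student by default (Welch by flag), ANOVA
is the classical fixed-effects F, ΔΔCt uses the mean calibrator ΔCt and
reports 2^(−ΔΔCt) per sample, ratio metrics bootstrap their CI with
2000 seeded resamples, and no multiple-testing correction is applied by
default (optional Holm flag would be the natural extension). Degenerate
zero-variance inputs return flagged p ∈ {0, 1} rather than NaN.

## Problem sizes

The shipped tests and the acceptance script use: 20 μm femur phantoms
(~4×10⁶ labeled voxels), a 50 μm FE tube of ~17.6k elements (~80k
DOFs), cohorts of n = 5 (tests) or n = 3 (acceptance morphometry), 50
Monte-Carlo indentation replicates, and 200–400-point curves. These
sizes were chosen so the full suite runs in a couple of minutes while
every oracle band (1–10%) stays comfortably discriminating; all are
parameters, and the defaults of the library itself (10 μm voxels, 200
curve points) match the emulated instrumentation instead.

## Known limitations

* Phantom trabecular statistics are lattice-regular; only contrast
  *directions* and designed ratios are meaningful, not absolute murine
  index values.
* Maximal-sphere thickness on lattice phantoms is junction-dominated;
  the presets account for this (see above), but Tb.Th on arbitrary
  custom lattices will read above the strut thickness.
* The FE model is small-strain, isotropic, linear; no contact at the
  supports, no fracture, no orthotropy.
* Surface-element stresses in voxel FE are boundary-layer quantities;
  field summaries (p95) are the robust comparison statistic.
* ΔΔCt assumes equal amplification efficiency of target and reference.
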