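# Methods

`mc3fe` implements a subject-specific "virtual mechanical testing" pipeline
for the distal third metacarpal (MC3) of the horse: a calibrated CT volume
in, a surface-strain summary for the parasagittal groove (PSG) out, plus
the inverse machinery to tune the material model against measured strains.
This note documents the model, its assumptions, the tunable parameters and
the numerical choices, and what the synthetic phantoms do and do not show.

## Material mapping

CT numbers are converted to radiological (hydroxyapatite-equivalent)
density through an affine calibration fitted by ordinary least squares to
phantom plugs of known density (200, 800, 1250, 1750 mgHA cm⁻³):

    rho_CT = (HU − intercept) / slope

with default constants intercept = 93.0710 HU, slope = 1.0123 HU/(mgHA cm⁻³).
Radiological density (g cm⁻³) is converted to ash density

    rho_ash = 0.8772 · rho_CT + 0.07895          [g cm⁻³]

and ash density to an isotropic Young's modulus by the power law

    E = 3378 · rho_ash^1.52                      [MPa]

Unit convention throughout: mm / N / MPa; densities internally in g cm⁻³,
with an explicit ÷1000 conversion from the mgHA cm⁻³ scale of the
calibration stage. Ash density is floored at 0.01 g cm⁻³ before the power
law so that low-attenuation voxels inside the mesh receive a small positive
modulus (≈3.1 MPa) instead of zero or a negative value; the floor only
matters for voxels far below any physiologic bone density.

Two regions get a modified law. Trabecular voxels above HU 1500
(≈1390 mgHA cm⁻³) are *sclerotic* (SCL) — densely adapted subchondral
bone whose microdamage is invisible at clinical CT resolution — and are
assigned E_SCL = (1 − a_scl) · E. Isolated sub-threshold pockets inside
the PSG search region are *lytic* (LYS), resorptive fatigue damage, and
get E_LYS = (1 − d_lys) · E. The adaptive factor a_scl ∈ [−1.00, 0.50]
may stiffen or soften; the damage factor d_lys ∈ [0, 0.95] only softens.
`RegionFactors(0, 0)` is the non-tuned model.

The tuned adaptive factor follows a linear law in the normalized sclerotic
volume V_SCL = V_sclerosis / V_condyle:

    a_scl = 994.23 · V_SCL − 184.55   (clamped to [−1.00, 0.50])

These printed coefficients make the output traverse the whole admissible
range over ΔV_SCL ≈ 0.0015, so the clamp is mandatory and both
coefficients are configurable; the law is implemented exactly as stated
rather than rescaled, and most realistic V_SCL values land on one of the
clamps. The pooled damage factor default is 0.65, the mean of the two
per-specimen optima (0.80, 0.50) that the tuning procedure produces.

## Segmentation

Label maps distinguish OUTSIDE / CORTEX / TRABECULAR / SCL / LYS. The
cortex–trabecular split is an input (phantoms emit it; for real data it
comes from upstream segmentation). SCL is a simple threshold (HU > 1500 on
trabecular voxels). LYS components are found by 26-connected labelling of
sub-threshold voxels inside the declared PSG search region; a component
qualifies only if it has ≥ 8 voxels (noise-speckle guard) and its
26-neighbour outer boundary touches only dense bone (SCL or cortex), which
operationalizes "isolated focal defect" and prevents diffuse low-density
trabecular bone from being mislabelled. Connectivity, minimum size and the
search region are configurable because no canonical definitions exist.

The anatomical frame replaces a cylinder fit with the principal axis of
the bone voxel cloud (for elongated, near-cylindrical masks the two agree
to well under 1°); the dorsal direction is supplied as a landmark hint and
orthogonalized. A near-isotropic cloud (principal extent ratio < 1.5) is
rejected as ambiguous. Distal isolation keeps everything within 63.5 mm of
the distal-most bone voxel along the long axis.

## Meshing

The mesh is structured and voxel-based: bone voxels are grouped into cubic
cells — fine cells inside a margin-expanded bounding box of SCL ∪ LYS and
wherever a coarse cell is partially filled, coarse cells elsewhere — and
every cell is split into tetrahedra by the Kuhn (Freudenthal) 6-tet
decomposition. A one-cell transition layer of "fan" cells (cell centre
connected to a globally-determined triangulation of the cell boundary)
makes the two resolutions conform exactly; the mesh is conforming by
construction at every interface, which the tests verify by counting facet
incidences. Cell edges must be integer multiples of the (isotropic) voxel
spacing. Partial fine cells at the bone boundary are dropped, so with
fine edge = voxel spacing (the phantom default, 0.5 mm) the tet volumes
sum *exactly* to the bone-mask volume.

Element ash density is the mean of the constituent voxels' per-voxel ash
densities (element-wise heterogeneous material); the element region is the
majority voxel label with LYS winning ties over SCL over the rest. The
defaults (0.5 mm fine / 1 mm coarse) keep a full tuning run at desk scale;
a mesh-convergence study across (1.0, 2.0) → (0.5, 1.0) → (0.5, 0.5) mm
on the reference phantom changes the PSG summary by well under 5% between
the two finest levels.

## Finite-element solution

Linear (constant-strain) tetrahedra, isotropic elasticity, Poisson's ratio
0.3 everywhere, small strains. The proximal cut surface is fully fixed;
7.5 kN is applied over a declared palmar patch on the medial condyle at
60°/30° to the frontal/transverse planes (pushing dorsally and
proximally). The default distribution is literal equal-per-node forces;
an area-weighted consistent-traction option exists and is used by the
closed-form verification tests. Systems up to 6000 free DOFs are solved by
sparse LU; larger ones by Jacobi-preconditioned conjugate gradients at
1e-10 relative residual, warm-started across repeated solves on the same
mesh (with a direct fallback if CG stalls). Both paths are deterministic.

Strains come from the shape-function gradients (one tensor per tet);
maximum principal strain is the algebraically largest eigenvalue (tension
positive). Surface values take the owner tet's strain without nodal
recovery, since the quantity of interest is a strip mean, not a point
value. The PSG summary is the area-weighted mean of the facet max
principal strain over the strip (boundary facets within 1.5 mm of the
groove plane, restricted to the condylar cap).

Verification: the CST patch test is exact; a homogeneous bar reproduces
σ/E to 1e-8 and Poisson contraction to 1e-6; reactions balance the applied
load to 1e-6 relative; the sparse paths agree with a dense direct solve to
1e-8 on small meshes.

## Tuning and validation

Tuning is an exhaustive, deterministic grid search that reuses one mesh
per specimen and updates only the material model: the stiffness is
assembled once per region group and recombined per candidate as
K = K_plain + (1 − a) K_SCL + (1 − d) K_LYS. The adaptive grid is
−1.00…0.50 and the damage grid 0.50…0.95, both at 0.05 steps with
inclusive endpoints (31 and 10 candidates). The objective is
|predicted − measured| on the PSG mean strain, unnormalized. Ties (the
objective is silent on them) go to the smallest-magnitude factor — the
least departure from the unmodified law — and are recorded on the result.
The a_scl(V_SCL) law is an OLS fit over tuning specimens; damage factors
are pooled by arithmetic mean. Validation runs tuned and untuned forward
models over held-out specimens and reports per-specimen differences, the
OLS slope/intercept and R² (squared Pearson correlation) of predicted vs
measured, and the mean relative error in per cent; with fewer than three
specimens the regression is skipped with a warning.

## Synthetic phantoms

The condyle phantom is deliberately idealized: a cylindrical shaft capped
by a spherical condyle, an analytically-thick cortical shell, a
subchondral sclerotic blob grown voxel-by-voxel around a palmaro-distal
surface anchor near the groove until it hits the requested V_SCL (exact to
one voxel), and an optional spherical lytic pocket encased in dense bone
(the generator swaps sclerotic voxels to guarantee the encasement without
changing V_SCL). Ground-truth labels, masks, the anatomical frame, the
groove plane and the load patch are all emitted, and the noiseless labels
round-trip exactly through the segmentation rule. Default scale is
40×40×80 voxels at 0.5 mm. Two specimen classes encode the study
conditions: `CTRL_SPEC` (sclerotic fraction 0.185, no lysis) and
`PSG_SBI_SPEC` (1.6 mm lysis inside a 0.20 sclerotic fraction — fatigue-
injured bones carry more sclerosis, which is what makes their tuned
adaptive factor positive/softening). Noise is optional additive Gaussian
HU noise; there is no partial-volume or beam-hardening model. Recovery
cases produce "measured" targets by running the forward model with known
factors, so parameter recovery can be tested without any real data.

What the phantoms do not show: real condylar anatomy, scanner physics,
segmentation error on real images, or the paper-grade validation numbers
(regression slope/R² against ex-vivo strain), which require the original
specimen data. Passing tests demonstrate that the equations, procedures
and inverse machinery are implemented correctly, not that the tuned
constants generalize to clinical scans.

## Defaults worth knowing

| parameter | default | units | note |
|---|---|---|---|
| threshold_hu | 1500 | HU | SCL/LYS split (≈1390 mgHA cm⁻³) |
| min_lysis_voxels | 8 | voxels | speckle guard |
| distal length | 63.5 | mm | distal isolation |
| fine / coarse edge | 0.5 / 1.0 | mm | phantom meshing |
| strip width | 3.0 | mm | PSG comparison strip |
| load | 7500 | N | at 60°/30° frontal/transverse |
| Poisson ratio | 0.3 | – | all bone |
| density floor | 0.01 | g cm⁻³ | pre-power-law clamp |
| CG tolerance | 1e-10 | relative | deterministic |
| pooled d_lys | 0.65 | – | mean of (0.80, 0.50) |

One behaviour worth knowing: the sensitivity of the PSG strip mean to the
damage factor depends on the stiffness of the surrounding sclerotic bone.
With a softening adaptive factor (the fatigue-injury regime) the strip
strain rises monotonically as the lytic pocket softens, as expected from
compliance. If the surroundings are instead strongly *stiffened*
(a_scl near −1), the stiff shell shields the surface above the pocket and
the strip mean can fall slightly as the pocket softens. The tuning grid
search is agnostic to the sign — it only needs a monotone, well-resolved
response — but interpretation of damage factors tuned under a stiffening
adaptive factor deserves care.

## Known limitations

Homogeneous factors per region (no depth dependence of damage); isotropic
linear elasticity only (no yield, fatigue or fracture propagation); the
a_scl(V_SCL) law's printed coefficients are used verbatim despite their
extreme sensitivity, so the clamp is almost always active; meshing
requires isotropic voxel spacing and commensurate cell edges; the
uniform-nodal load option is mesh-dependent by construction (the
area-weighted option is not).
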