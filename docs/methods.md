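# Methods

`spinefem` builds a fully parametric finite-element model of a
thoracolumbar T11-L1 segment, augments the vertebrae above and below the
sandwich vertebra T12 with bone cement in four clinically motivated
distributions, and compares the load on T12 and its discs across those
distributions.  This note records the model, its assumptions, the
calibration of the synthetic anatomy, and the numerical choices.  All
units are mm, N, MPa (N*mm for moments).

## Model overview

**Geometry.**  Each vertebral body is an elliptical cylinder
(anterior-posterior diameter 32 mm, lateral 42 mm, height 24 mm) with a
1.5 mm cortical shell measured as the true inward parallel curve of the
outer ellipse, a cortical end cap on each free surface, and a 0.5 mm
endplate on every disc-facing surface.  Discs (height 6.3 mm) consist of
an annulus matrix around a nucleus occupying 30% of the cross-section.
Posterior elements are prismatic blocks carrying cortical bone
properties: pedicle bars, a lamina bridge, and spinous/transverse
processes.  The geometry is exactly mirror-symmetric about the
mid-sagittal plane; cement placement is the only symmetry-breaking
input.

**Facet joints.**  Each joint is a tongue-in-groove column behind the
body: the inferior articular process of the upper vertebra (a vertical
cortical plate) slots between two plates of the lower vertebra, with a
10 MPa cartilage layer on each face (thickness 0.10 mm, joint depth 85%
of the pedicle bar, vertical overlap 88% of the disc height).  By
default the two cartilage faces against the upper process are detached
and carry frictionless compression-only penalty springs along the +/-x
face normal, resolved by the same active-set iteration as the
tension-only ligaments.  Axial rotation closes one face of each joint
and is resisted through cartilage compression; flexion/extension and
lateral bending let the plates glide.  A fully bonded mode
(`FacetParams(mode="bonded")`) is retained; it was rejected as the
default because an isotropic bonded layer ties the joint's shear
stiffness to its normal stiffness (ratio ~G/E), which makes it
impossible to hold the segment's rotational stiffness at roughly twice
its sagittal bending stiffness — the proportion the published
range-of-motion (ROM) corridor requires.  The Coulomb friction of real
facet contact (mu ~ 0.1) would transmit at most ~10% of the normal
force tangentially and is neglected.

**Ligaments.**  Seven groups (ALL, PLL, LF, SSL, ISL, ITL, CL) are
tension-only axial trusses with the standard sectional areas
(65/20/40/30/40/1.8/30 mm^2) and moduli (20/20/19.5/15/12/59/7.5 MPa),
the full area at each of the two disc levels, split equally across the
trusses of a group.  Attachment insets (fraction of body height moved
away from the disc boundary) set the free lengths; they are calibration
parameters.

**Materials.**  Isotropic linear elasticity throughout: cortical bone
12000/0.3 (osteoporotic 8040), cancellous 132/0.2 (osteoporotic 34),
endplate 1000/0.4 (osteoporotic 670), cartilage 10/0.4, annulus
4.2/0.45, nucleus 1/0.499, cement 3000/0.4.  The printed osteoporotic
cancellous value of 34 MPa is not 67% of 132; we use the printed value
and expose the arithmetic alternative (88.4) through
`osteoporotic_cancellous_modulus`.  The cement scenarios run
osteoporotic by default; the ROM validation runs healthy bone because
the published corridor comes from healthy-spine segment models.

**Cement.**  Each augmented vertebra (T11 and L1; never T12) receives
6.0 mL of cement as vertical circular cylinders inside the cancellous
cavity: bilateral placement is two mirror-image cylinders (lateral
offset 40% of the half-width), unilateral one cylinder offset 25% of the
half-width toward the chosen side.  The printed cylinder bounding boxes
(10.5x10.5x18 unilateral, 12x12x14 bilateral) are inconsistent with a
6 mL volume under any single reading; we resolve this with
volume-controlled scaling in which every cylinder spans the cancellous
cavity axially (cement in contact with both endplates, the fully bound
configuration that restores the axial load path) and the radius is set
so the per-vertebra volume is exact.  A unilateral cylinder's centroid
offset is the larger of 25% of the lateral half-width and the cylinder
radius, keeping unilateral cement tangent to the midline and confined
to its side; early variants that centred the volume-scaled cylinder or
left a cancellous cushion between cement and endplates suppressed the
cement's mechanical signature on the sandwich vertebra almost entirely.
Cement is realised by re-tagging
mesh elements whose centroid falls inside a cylinder; the mesh is not
re-meshed around cement, so cement-free and cemented models share an
identical mesh and differ only in element materials.

**Loads.**  Six physiological cases: a uniformly distributed 500 N
compressive preload on the superior surface of the T11 body acting
together with a 7.5 N*m moment (flexion +y, extension -y, right bending
+x, left bending -x, left axial rotation +z, right -z, in the
right-handed frame +x anterior, +y subject-left, +z superior).  The
moment is a self-equilibrated consistent nodal force couple over the
surface (zero net force; exact net moment about the area centroid); the
preload is a consistent uniform traction.  All nodes of the L1 inferior
surface are fixed.  The preload produces no parasitic rotation on the
symmetric model, so ROM is reported from the combined load; passing
`preload=0` to `run_validation` gives the pure-moment protocol.

## Discretisation and solver

The template mesher extrudes a structured 2D cross-section (elliptical
rings plus posterior blocks) through the z-layer stack and splits prisms
into tetrahedra with the lowest-global-index diagonal rule, which
guarantees a conforming mesh with shared nodes on every region interface
("fully bound" contacts).  The 2D template is built for the y>=0 half
and mirrored, so the mesh is exactly symmetric about y=0 and reflection
equivariance (mirror of the solution of a mirrored model equals the
solution) holds to solver precision.  Elements are 10-node quadratic
tetrahedra by default (4-point Gauss stiffness; linear TET4 available).
The desk-scale default density is 5 mm solid edges / 1.5 mm cartilage
(about 2x10^4 TET10 elements, 9x10^4 dof, one factorisation ~40 s on one
CPU); the study-scale density of 2 mm / 0.5 mm is available through
`MeshSettings.reference()` and produces node/element counts of the same
order as the reference budget (~3x10^5 nodes / ~2x10^5 elements).  A
convergence helper (`refine_study`) tabulates the flexion T12 stress and
segment ROM against density.

The solid stiffness is factorised once per model (SuperLU, symmetric
mode, minimum-degree ordering, one iterative-refinement step per solve).
Unilateral elements — tension-only ligaments and compression-only facet
springs — enter through a Sherman-Morrison-Woodbury low-rank update, so
the fixed-point active-set iteration (start all active; deactivate
sign-violating elements; repeat until stable, at most 50 passes) costs
one dense solve of order the number of unilateral elements per pass, and
each of the six load cases reuses the same factorisation.  Stresses are
reported per element (TET4: centroid; TET10: average of the Gauss
points); nodal extrapolation is deliberately omitted so maxima are
well defined.

## Outcome measures

Per run: the maximum element von Mises stress over the T12 vertebral
body (cortical shell + cancellous core + endplates), over each disc
(annulus + nucleus), and the maximum nodal displacement magnitude over
the T12 body; segmental ROM from least-squares rigid rotations fitted to
the superior body faces of the levels, projected on the load axis.
Elements adjacent to ligament/contact attachment nodes are excluded from
stress maxima (truss point loads create mesh-dependent local
concentrations), as are elements near the load application and fixed
base when T11/L1 quantities are extracted; posterior elements are
tagged as their own region (`posterior_*`) and excluded from the T12
body metrics for the same reason.  The ordering report ranks the four
cement groups per case and evaluates the comparative flags (B-B
smallest T12 stress, L-L largest, strict B-B < L-B < L-R < L-L
orderings, disc T12/L1 stress L-L > B-B).

## Calibration of the synthetic anatomy

The segment replaces a patient-specific CT geometry, so its dimensions
are idealisations calibrated once against the published T11-L1 ROM
corridor under 7.5 N*m (flexion 6.31 deg, extension 6.12, lateral
bending ~6.85, axial rotation ~3.25, with per-level splits), then
frozen.  Disc height, nucleus fraction, body AP width, facet joint
depth/overlap/cartilage thickness, pedicle attachment span and ligament
insets were adjusted by coarse sensitivity probes followed by a fine
search at the production mesh density.  The calibrated model yields
(5 mm mesh, healthy bone, preload + moment): flexion 6.33, extension
7.41, lateral bending 6.03, axial rotation 3.14 degrees for T11-L1, with
all 18 level/direction entries within +-30% of the corridor and flexion
inside the literature bracket [6.26, 6.60].  Two calibration outcomes
deserve note: the spinous process is short (6 mm) and the posterior
ligament insets are large, because with a stiff unilateral facet column
the posterior ligaments otherwise over-stiffen flexion; and the facet
cartilage is thin (0.10 mm per face) because cartilage compression is
the dominant series compliance of the joint.  These are calibration
artefacts of an idealised geometry, not anatomical claims.

## What the synthetic model does and does not show

The generator reproduces the structural logic of the segment — a
symmetric two-disc column with posterior arches, unilateral facet
contact, tension-only ligaments, and cement struts bonded between the
endplates — and its ROM matches the published corridor.  It does not
reproduce patient-specific cortical thickness variation, endplate
curvature, real cement interdigitation, facet surface geometry, or
muscle forces.  Absolute stress magnitudes therefore differ from
CT-based models (our T12 maxima are of the right order but not equal to
the reference values), and only comparative statements across cement
groups — identical geometry, identical mesh, differing only in which
elements are cement — carry over to real anatomy.  Tests assert the
comparative structure (orderings, symmetry, corridor membership), not
absolute stresses.

## Comparative findings on the synthetic segment

Over the 24-run matrix (osteoporotic bone, default mesh) the model
reproduces part of the comparative structure reported for
patient-specific geometry and not the rest; the ordering report computes
all of it and `tests/test_acceptance.py` asserts each piece separately:

* reproduced — mirror equivariance of plans and load cases (to solver
  precision); the T12/L1 disc peak stress larger under ipsilateral
  unilateral cement (L-L) than under bilateral cement (B-B) in five of
  six directions; the bilateral group carrying the smallest T12 peak
  stress in the sagittally and axially loaded cases; unilateral groups
  loading the sandwich vertebra harder than bilateral ones in flexion
  and extension;
* not reproduced — the strict four-group chain B-B < L-B < L-R < L-L of
  T12 peak stress and displacement.  In this exactly mirror-symmetric
  idealised geometry the L-R/L-L distinction is a coupling between the
  two cement levels through 24 mm of vertebral body and amounts to
  under 0.2% of the T12 maximum, within discretisation noise at the
  default density; separations of several percent in CT-based models
  ride on left-right anatomical asymmetry that the generator
  deliberately omits.  The corresponding tests are expected to fail on
  the shipped model and document this limit.

## Numerical choices and degenerate inputs

* Direct sparse factorisation; a guard rejects singular or
  ill-conditioned constrained systems (e.g. a fully unconstrained
  model).
* Active-set iteration caps at 50 passes and reports the oscillating
  sets on failure.
* Region maxima break ties toward the lowest element id; group rankings
  break stress ties alphabetically.
* Degenerate inputs (zero disc height, overlapping regions, cement that
  would pierce the cortical shell, coincident truss nodes, zero-area
  load surfaces, collinear moment surfaces) raise typed errors naming
  the offending region.
* Meshes, loads and solutions are fully deterministic: identical
  configurations give bit-identical outputs.

## Known limitations

* Small-strain, small-rotation linear elasticity; no damage, fatigue or
  time dependence.
* Facet friction neglected (frictionless unilateral contact).
* The two discs share one nucleus footprint (the column template uses a
  single nucleus ring boundary).
* Cement cylinders are ideal vertical circular cylinders; real cement
  morphology is irregular (published sensitivity work indicates shape
  changes magnitudes, not comparative trends).
* The displacement and stress maxima of T12 are reported over the
  vertebral body; posterior-element maxima are available through
  `region_max` on the `posterior_T12` region but sit at idealised
  attachment details.
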