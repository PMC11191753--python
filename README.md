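# spinefem

Parametric finite-element models of a thoracolumbar T11–L1 spine
segment for studying how the distribution of vertebroplasty bone cement
in the vertebrae **above and below** an untreated "sandwich" vertebra
(T12) changes the mechanical load on that vertebra and its discs.

After multiple vertebral augmentations, a normal vertebra can end up
between two cement-filled neighbours.  Whether that sandwich vertebra
is at elevated fracture risk — and whether the *placement* of the
cement (bilateral vs unilateral, same side vs crossed) matters — is a
biomechanics question usually studied with patient-specific CT-based
finite-element models.  `spinefem` replaces the CT geometry with a
fully parametric, mirror-symmetric synthetic segment so the whole
pipeline is reproducible from code alone:

* **anatomy** — elliptical-cylinder vertebral bodies with a 1.5 mm
  cortical shell and 0.5 mm endplates, two-phase discs (annulus +
  nucleus), prismatic posterior elements, tongue-in-groove facet
  joints, seven tension-only ligament groups, and 6 mL cement cylinders
  per augmented vertebra in four configurations
  (B-B, L-B, L-R, L-L = bilateral/bilateral … left/left);
* **meshing** — a deterministic template mesher producing conforming
  TET4/TET10 meshes with region tags, ligament trusses and facet
  contact springs;
* **fem** — linear elasticity with unilateral (tension-only /
  compression-only) elements solved by an active-set iteration on top
  of a single sparse factorisation per model;
* **loads** — 500 N preload + 7.5 N·m moments in six physiological
  directions, fixed L1 base;
* **postpro / runner** — von Mises stress and displacement maxima per
  region, segmental range of motion (ROM), the 4-group × 6-case
  comparison matrix and its ordering report.

The intended audience is researchers in musculoskeletal biomechanics
who want an open, testable stand-in for cement-augmentation FE studies.

## The model in brief

Each run solves the constrained linear system

    K(μ) u = f,   with tension-only ligaments and compression-only
                  facet contact resolved by an active-set fixed point,

where the material field μ assigns Table-standard isotropic properties
(cortical 12000/8040 MPa normal/osteoporotic, cancellous 132/34,
endplate 1000/670, annulus 4.2, nucleus 1 with ν = 0.499, cartilage 10,
cement 3000, ligaments 7.5–59 MPa with standard sectional areas).
Outcome measures are the element-wise von Mises stress
σ_v = √(½[(σ₁−σ₂)² + (σ₂−σ₃)² + (σ₃−σ₁)²] + 3(τ₁₂²+τ₂₃²+τ₃₁²)),
its maximum over the T12 body and over each disc, the maximum T12
displacement, and the ROM between levels from least-squares rigid
rotations of the endplate faces.  See `docs/methods.md` for the full
account, including how the synthetic anatomy was calibrated once
against the published T11–L1 ROM corridor and then frozen.

## Worked example

```python
import spinefem as sf
from spinefem import runner

# cement-free model: validate the segment's range of motion
table = runner.run_validation(runner.RunConfig())
print(table[["T11-T12", "T12-L1", "T11-L1"]].round(2))
```

```
                T11-T12  T12-L1  T11-L1
case
flexion            3.17    3.17    6.33
extension          3.68    3.73    7.41
right_bending      3.00    3.03    6.03
left_bending       3.00    3.03    6.03
left_rotation      1.61    1.52    3.14
right_rotation     1.61    1.52    3.14
```

Flexion of the full segment is 6.33°, inside the published corridor
[6.26°, 6.60°]; all eighteen level/direction entries lie within ±30% of
the reference study.  The cement comparison runs the same way:

```python
import dataclasses
cfg = dataclasses.replace(runner.RunConfig(), groups=("B-B", "L-L"),
                          cases=("flexion",))
for r in runner.run_matrix(cfg):
    print(r.group, r.case, round(r.summary.max_vms_T12, 2), "MPa")
```

```
B-B flexion 8.81 MPa
L-L flexion 9.07 MPa
```

i.e. with both neighbours augmented on the same side the peak von Mises
stress in the sandwich vertebra is higher than with two bilateral
(symmetric) augmentations — the comparative effect the package exists
to quantify.  A command-line interface wraps the same calls
(`spinefem build | mesh | run | validate | report`).

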