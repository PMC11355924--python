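# osteocurv

Surface-curvature characterization of trabecular-like microstructures.

Trabecular bone is a porous network of plates and rods whose local surface
geometry — how convex, concave or saddle-shaped the bone/marrow interface
is — encodes a surprising amount of information about the structure as a
whole. This package implements a complete, testable pipeline around that
idea, for researchers in bone biomechanics and biomimetic material design:

1. **Synthetic microstructures** — voxelized trabecular-like cubes
   (thresholded anisotropic Gaussian random fields) with controllable
   volume fraction, feature size and anisotropy, plus analytic fixtures
   (sphere, cylinder, plate, torus, lattices) with closed-form properties.
2. **Surface curvature** — marching-cubes extraction of the bone surface
   and per-vertex principal curvatures k1 >= k2 by a finite-difference
   tensor fit, with Gaussian K = k1 k2 and mean H = (k1 + k2)/2.
3. **Curvature projection images** — the 2D summary
   K(x, y) = (1/n) * sum_z k(x, y, z), binning every vertex's curvature
   onto the in-plane voxel grid over the n one-voxel layers along the
   projection axis (n = 172 for a 6 mm cube at 35 um); the four curvature
   kinds stack into one 4-channel image.
4. **Morphometry** — the six global histomorphometric parameters (BV/TV,
   BS, Tb.Th, SMI, DA, Conn.D) and eight plate/rod geometric parameters
   (PN, RN, PA, PT, RD, RL, NND_PP, NND_RR) from a simplified
   individual-trabecula decomposition.
5. **Micro-FE homogenization** — the apparent 6x6 stiffness tensor of a
   cube by voxel-based linear FE (six tetrahedra per voxel, kinematic
   uniform boundary conditions, 15 GPa / 0.3 tissue), rotated to the MIL
   fabric frame and projected orthotropic.
6. **CNN regression** — a small, fully seeded convolutional network
   (implemented in numpy) that predicts any of the above parameter sets
   from the 4-channel curvature projection, trained with Adam on MSE with
   min-max-normalized targets.

## Worked example

```python
import numpy as np
from osteocurv import (GeneratorSpec, generate_grf_cube, extract_surface,
                       principal_curvatures, derived_curvatures,
                       projection_stack)
from osteocurv.histomorphometry import measure_all
from osteocurv.micro_fe import MaterialModel, homogenized_stiffness

vol = generate_grf_cube(GeneratorSpec(shape=(64, 64, 64), target_bvtv=0.25,
                                      correlation_length=3.0, seed=42))
mesh = extract_surface(vol, smooth_sigma=1.0, taubin_iterations=20)
field = derived_curvatures(principal_curvatures(mesh, normal_smooth_iterations=6))
stack, ranges = projection_stack(mesh, field, vol)

histo = measure_all(vol, mesh=mesh)
C = homogenized_stiffness(vol, MaterialModel(15.0, 0.3), tol=1e-6)
print(f"BV/TV  {histo.bvtv:.3f}")
print(f"BS     {histo.bs:.2f} mm^2")
print(f"Tb.Th  {histo.tbth:.3f} mm")
print(f"median H  {np.median(field.mean):.2f} 1/mm")
print(f"C11    {C.c[0, 0]:.3f} GPa")
```

prints (exactly, given the fixed seed):

```
BV/TV  0.249
BS     36.20 mm^2
Tb.Th  0.336 mm
median H  3.16 1/mm
C11    0.759 GPa
```

Read: a quarter-solid cube whose trabeculae are ~0.34 mm thick, with
36 mm^2 of bone surface in a 2.24 mm cube; the median surface point is
convex with mean curvature ~3 /mm (radius ~0.3 mm, matching the strut
scale), and the porous cube is ~26x more compliant along x than the
15 GPa tissue it is made of.

The full experiment — generate a cohort, measure everything, train and
evaluate the CNN — is one call (or the `osteocurv run-all` CLI verb):

```python
from osteocurv import ExperimentConfig, run_experiment
run_experiment(ExperimentConfig(n_samples=300, seed=1), "exp/")
```

which writes `samples.csv`, per-task `report_*.csv` / `loss_*.csv` and a
`manifest.json` with config, timings and file hashes; rerunning with the
same config reproduces the CSVs bit-identically. `osteocurv --help`
lists the stage-by-stage verbs (`generate`, `curvature`, `project`,
`morpho`, `platerod`, `fe`, `run-all`, `ablate`).

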