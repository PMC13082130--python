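# splatmri

Dynamic volumetric MRI reconstruction from continuously acquired
stack-of-stars (SOS) golden-angle radial k-space, with per-stack real-time
inference.

The method jointly solves, in a single one-shot training session on one
scan's k-space data:

* a **reference MR volume** represented as a complex-valued, signed 3D
  Gaussian kernel field (differentiable voxelization onto a dense grid);
* a **low-rank motion model**: nine real Gaussian basis fields (three
  coarse-to-fine spatial levels x three Cartesian directions) whose
  per-stack scores compose deformation vector fields
  `d(x,t) = sum_i w_i(t) * e_i(x)`;
* a **dual-path motion encoder**: nine small MLPs reading z-scored
  k-space-center navigator samples, and a CNN reading low-frequency
  (kz x readout) projection images, each mapping one stack to the nine
  scores.

Training proceeds in stages — I(a) image-domain fit of the motion-averaged
volume, I(b) k-space data consistency + TV, II joint bulk-motion learning at
reduced spatiotemporal resolution with the MLP, III(a) CNN distillation,
III(b) full-resolution joint refinement with a frequency-band regularizer,
IV motion-augmentation fine-tuning of the CNN on randomly rescaled scores —
after which each newly acquired stack maps to scores, a deformation field, a
real-time volume, and a propagated target contour.

A synthetic deformable torso (and cylinder) phantom with analytic motion
fields plus a multi-coil SOS acquisition simulator make the entire pipeline
runnable and testable with no external data.  Everything runs on CPU: the
package ships a small numpy reverse-mode autodiff engine (`splatmri.autodiff`)
with hand-derived adjoints for voxelization, warping, convolution, and the
exact separable Fourier operator.

## CLI

```bash
# simulate a synthetic acquisition (HDF5)
splatmri simulate --out acq.h5 --scenario X1 --seed 1 [--config cfg.yaml]

# staged training -> checkpoint + logs + reference volume
splatmri train --acquisition acq.h5 --out run/ --seed 1 --scale desk

# per-stack real-time inference -> trajectory CSV (+ optional volumes)
splatmri infer --checkpoint run/checkpoint.h5 --acquisition acq.h5 --out inf/

# metric report between two npz bundles (frames + masks)
splatmri evaluate --truth truth.npz --pred pred.npz --out report.json
```

`--scale full` uses the reference schedule (400/300/1200/5000/1500/1000
epochs, 100k reference kernels, 15^3/20^3/25^3 basis lattices); `desk` is a
CPU-sized configuration.

## Layout

| module | role |
|---|---|
| `splatmri.autodiff` | numpy reverse-mode autodiff + Adam |
| `splatmri.grids` | voxel-grid geometry |
| `splatmri.gaussians` | signed real/complex Gaussian clouds, voxelization, initializers |
| `splatmri.phantom` | deformable torso/cylinder phantoms, breathing scenarios, analytic DVFs |
| `splatmri.acquisition` | SOS golden-angle trajectory, coil maps, forward/adjoint operators, navigators, projections |
| `splatmri.motion` | DVF composition, warping, Jacobians, mask propagation |
| `splatmri.encoders` | 9-MLP and CNN motion encoders |
| `splatmri.objectives` | data consistency + TV/basis-norm/zero-mean/Jacobian/frequency regularizers |
| `splatmri.trainer` | staged optimization, schedules, checkpoints |
| `splatmri.realtime` | streaming per-stack inference |
| `splatmri.evaluation` | COME/DSC/SSIM/PSNR, target contouring, reports |
| `splatmri.experiments` | scaled-down experiment protocols |
| `splatmri.io` | HDF5 containers, NIfTI export |
| `splatmri.cli` | `splatmri` command group |
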