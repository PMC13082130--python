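"""Low-rank deformation model: basis fields, scores, warping, Jacobians.

A deformation is composed as d_k(x) = sum_i w_{i,k} * e_{i,k}(x) over three
spatial levels i and three Cartesian directions k (nine basis fields).
Displacements are in millimetres in the world frame and converted to voxel
units inside the sampler, so scores keep physical meaning across grid
resolutions.  Warping is backward (output(x) = input(x + d(x))) with
trilinear interpolation and clamp-to-border policy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, custom_op, stack as t_stack
from .gaussians import GaussianCloud, voxelize
from .grids import VoxelGrid

__all__ = [
    "MotionBasisSet",
    "ScoreSequence",
    "DVFField",
    "compose_dvf",
    "compose_dvf_tensor",
    "warp_volume",
    "warp_volume_tensor",
    "jacobian_determinant",
    "propagate_mask",
    "mask_centroid_mm",
]


@dataclass
class MotionBasisSet:
    """Nine voxelized basis fields in (level, direction) order.

    ``fields`` has shape (9,) + grid.shape; entry 3*i + k is level i,
    direction k with k in (x, y, z).
    """

    fields: np.ndarray
    grid: VoxelGrid

    def __post_init__(self):
        if self.fields.shape != (9,) + self.grid.shape:
            raise ValueError("basis fields must be (9,) + grid.shape")
        if not np.all(np.isfinite(self.fields)):
            raise ValueError("basis fields must be finite")

    @classmethod
    def from_clouds(cls, clouds: list[GaussianCloud], grid: VoxelGrid,
                    ) -> "MotionBasisSet":
        if len(clouds) != 9:
            raise ValueError("expected 9 basis clouds")
        fields = np.stack([voxelize(c, grid).data[0] for c in clouds])
        return cls(fields=fields, grid=grid)


@dataclass
class ScoreSequence:
    """Per-stack 9-vectors of basis scores (mm) with timestamps."""

    scores: np.ndarray        # (n_stacks, 9)
    timestamps_ms: np.ndarray

    def __post_init__(self):
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=np.float64))
        if self.scores.shape[1] != 9:
            raise ValueError("scores must be (n_stacks, 9)")
        if self.scores.shape[0] != np.asarray(self.timestamps_ms).shape[0]:
            raise ValueError("one timestamp per stack required")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    @property
    def n_stacks(self) -> int:
        return self.scores.shape[0]


@dataclass
class DVFField:
    """One time instant's displacement: (grid.shape + (3,)) vectors in mm."""

    displacement_mm: np.ndarray
    grid: VoxelGrid

    def __post_init__(self):
        if self.displacement_mm.shape != self.grid.shape + (3,):
            raise ValueError("displacement must be (grid.shape + (3,))")
        if not np.all(np.isfinite(self.displacement_mm)):
            raise ValueError("displacement must be finite")


def compose_dvf(basis: MotionBasisSet, score) -> np.ndarray:
    """Displacement field (grid.shape + (3,)) in mm for one 9-score vector."""
    score = np.asarray(score, dtype=np.float64)
    if score.shape != (9,):
        raise ValueError("score must be a 9-vector")
    if not np.all(np.isfinite(score)):
        raise ValueError("score must be finite")
    dvf = np.zeros(basis.grid.shape + (3,))
    for k in range(3):
        for i in range(3):
            dvf[..., k] += score[3 * i + k] * basis.fields[3 * i + k]
    return dvf


def compose_dvf_tensor(field_tensors: list[Tensor], score: Tensor) -> Tensor:
    """Differentiable composition; returns a (3,) + grid.shape Tensor."""
    if len(field_tensors) != 9:
        raise ValueError("expected 9 basis field tensors")
    comps = []
    for k in range(3):
        acc = None
        for i in range(3):
            term = score[3 * i + k] * field_tensors[3 * i + k]
            acc = term if acc is None else acc + term
        comps.append(acc)
    return t_stack(comps, axis=0)


# ---------------------------------------------------------------------------
# warping


def _gather_weights(coords: np.ndarray, shape: tuple[int, int, int]):
    """Floor indices, fractions, and clamped corner indices for trilinear."""
    nx, ny, nz = shape
    cx = np.clip(coords[0], 0.0, nx - 1.0)
    cy = np.clip(coords[1], 0.0, ny - 1.0)
    cz = np.clip(coords[2], 0.0, nz - 1.0)
    # per-axis interior flags: the coordinate gradient vanishes at the clamp
    interior = ((coords[0] > 0) & (coords[0] < nx - 1),
                (coords[1] > 0) & (coords[1] < ny - 1),
                (coords[2] > 0) & (coords[2] < nz - 1))
    x0 = np.minimum(np.floor(cx).astype(int), nx - 2) if nx > 1 else np.zeros_like(cx, int)
    y0 = np.minimum(np.floor(cy).astype(int), ny - 2) if ny > 1 else np.zeros_like(cy, int)
    z0 = np.minimum(np.floor(cz).astype(int), nz - 2) if nz > 1 else np.zeros_like(cz, int)
    fx, fy, fz = cx - x0, cy - y0, cz - z0
    return (x0, y0, z0), (fx, fy, fz), interior


def _trilinear(volume: np.ndarray, base, frac):
    (x0, y0, z0), (fx, fy, fz) = base, frac
    nx, ny, nz = volume.shape
    x1 = np.minimum(x0 + 1, nx - 1)
    y1 = np.minimum(y0 + 1, ny - 1)
    z1 = np.minimum(z0 + 1, nz - 1)
    c000 = volume[x0, y0, z0]; c100 = volume[x1, y0, z0]
    c010 = volume[x0, y1, z0]; c110 = volume[x1, y1, z0]
    c001 = volume[x0, y0, z1]; c101 = volume[x1, y0, z1]
    c011 = volume[x0, y1, z1]; c111 = volume[x1, y1, z1]
    out = (c000 * (1 - fx) * (1 - fy) * (1 - fz) + c100 * fx * (1 - fy) * (1 - fz)
           + c010 * (1 - fx) * fy * (1 - fz) + c110 * fx * fy * (1 - fz)
           + c001 * (1 - fx) * (1 - fy) * fz + c101 * fx * (1 - fy) * fz
           + c011 * (1 - fx) * fy * fz + c111 * fx * fy * fz)
    return out


def warp_volume(volume: np.ndarray, dvf: np.ndarray, grid: VoxelGrid,
                ) -> np.ndarray:
    """Backward warp: output(x) = volume(x + d(x)), clamp-to-border.

    ``dvf`` is (grid.shape + (3,)) in mm.  Real and imaginary channels are
    interpolated independently for complex input.
    """
    if dvf.shape != grid.shape + (3,):
        raise ValueError("dvf must live on the volume grid")
    spacing = np.asarray(grid.spacing)
    idx = np.indices(grid.shape, dtype=np.float64)
    coords = idx + np.moveaxis(dvf, -1, 0) / spacing[:, None, None, None]
    base, frac, _ = _gather_weights(coords, grid.shape)
    if np.iscomplexobj(volume):
        return (_trilinear(volume.real, base, frac)
                + 1j * _trilinear(volume.imag, base, frac))
    return _trilinear(volume, base, frac)


def warp_volume_tensor(volume: Tensor, dvf_mm: Tensor, grid: VoxelGrid,
                       ) -> Tensor:
    """Differentiable backward warp (both inputs), single real channel.

    ``volume`` has grid.shape; ``dvf_mm`` is (3,) + grid.shape (mm).
    """
    spacing = np.asarray(grid.spacing)
    nx, ny, nz = grid.shape
    idx = np.indices(grid.shape, dtype=np.float64)
    coords = idx + dvf_mm.data / spacing[:, None, None, None]
    base, frac, interior = _gather_weights(coords, grid.shape)
    x0, y0, z0 = base
    fx, fy, fz = frac
    x1 = np.minimum(x0 + 1, nx - 1)
    y1 = np.minimum(y0 + 1, ny - 1)
    z1 = np.minimum(z0 + 1, nz - 1)
    corners = [(x0, y0, z0), (x1, y0, z0), (x0, y1, z0), (x1, y1, z0),
               (x0, y0, z1), (x1, y0, z1), (x0, y1, z1), (x1, y1, z1)]
    weights = [(1 - fx) * (1 - fy) * (1 - fz), fx * (1 - fy) * (1 - fz),
               (1 - fx) * fy * (1 - fz), fx * fy * (1 - fz),
               (1 - fx) * (1 - fy) * fz, fx * (1 - fy) * fz,
               (1 - fx) * fy * fz, fx * fy * fz]
    # weight derivatives wrt (fx, fy, fz)
    dwx = [-(1 - fy) * (1 - fz), (1 - fy) * (1 - fz), -fy * (1 - fz), fy * (1 - fz),
           -(1 - fy) * fz, (1 - fy) * fz, -fy * fz, fy * fz]
    dwy = [-(1 - fx) * (1 - fz), -fx * (1 - fz), (1 - fx) * (1 - fz), fx * (1 - fz),
           -(1 - fx) * fz, -fx * fz, (1 - fx) * fz, fx * fz]
    dwz = [-(1 - fx) * (1 - fy), -fx * (1 - fy), -(1 - fx) * fy, -fx * fy,
           (1 - fx) * (1 - fy), fx * (1 - fy), (1 - fx) * fy, fx * fy]

    vals = [volume.data[c] for c in corners]
    out = sum(w * v for w, v in zip(weights, vals))

    def backward(g):
        grad_vol = np.zeros_like(volume.data)
        for w, c in zip(weights, corners):
            flat = (c[0] * ny + c[1]) * nz + c[2]
            np.add.at(grad_vol.reshape(-1), flat.ravel(), (g * w).ravel())
        gfx = sum(dw * v for dw, v in zip(dwx, vals)) * g * interior[0]
        gfy = sum(dw * v for dw, v in zip(dwy, vals)) * g * interior[1]
        gfz = sum(dw * v for dw, v in zip(dwz, vals)) * g * interior[2]
        grad_dvf = np.stack([gfx / spacing[0], gfy / spacing[1],
                             gfz / spacing[2]])
        return grad_vol, grad_dvf

    return custom_op([volume, dvf_mm], out, backward)


# ---------------------------------------------------------------------------
# Jacobian and masks


def jacobian_determinant(dvf: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """det of grad(x + d(x)) per voxel; central differences, one-sided at
    the borders, displacements converted to voxel units per axis."""
    if dvf.shape != grid.shape + (3,):
        raise ValueError("dvf must live on the grid")
    if not np.all(np.isfinite(dvf)):
        raise ValueError("dvf must be finite")
    spacing = np.asarray(grid.spacing)
    d_vox = dvf / spacing
    J = np.empty(grid.shape + (3, 3))
    for comp in range(3):
        for ax in range(3):
            J[..., comp, ax] = np.gradient(d_vox[..., comp], axis=ax)
        J[..., comp, comp] += 1.0
    return np.linalg.det(J)


def jacobian_determinant_tensor(dvf_mm: Tensor, grid: VoxelGrid) -> Tensor:
    """Differentiable det(J) for a (3,) + grid.shape displacement Tensor."""
    spacing = np.asarray(grid.spacing)

    def grad_axis(t: Tensor, ax: int) -> Tensor:
        n = t.shape[ax]
        if n == 1:
            return Tensor(np.zeros(t.shape))
        data = np.gradient(t.data, axis=ax)

        def backward(g):
            # adjoint of np.gradient along ax (central diff + one-sided ends)
            out = np.zeros_like(g)
            sl = [slice(None)] * g.ndim

            def take(a, i):
                sl2 = list(sl); sl2[ax] = i
                return a[tuple(sl2)]

            def add(a, i, val):
                sl2 = list(sl); sl2[ax] = i
                a[tuple(sl2)] += val

            add(out, 0, -take(g, 0))
            add(out, 1, take(g, 0))
            add(out, n - 2, -take(g, n - 1))
            add(out, n - 1, take(g, n - 1))
            if n > 2:
                add(out, slice(2, n), 0.5 * take(g, slice(1, n - 1)))
                add(out, slice(0, n - 2), -0.5 * take(g, slice(1, n - 1)))
            return (out,)

        return custom_op([t], data, backward)

    rows = []
    for comp in range(3):
        comp_t = dvf_mm[comp] / spacing[comp]
        row = [grad_axis(comp_t, ax) for ax in range(3)]
        rows.append(row)
    # det of I + J via cofactor expansion
    a = rows[0][0] + 1.0; b = rows[0][1]; c = rows[0][2]
    d = rows[1][0]; e = rows[1][1] + 1.0; f = rows[1][2]
    g_ = rows[2][0]; h = rows[2][1]; i_ = rows[2][2] + 1.0
    return (a * (e * i_ - f * h) - b * (d * i_ - f * g_) + c * (d * h - e * g_))


def propagate_mask(mask: np.ndarray, dvf: np.ndarray, grid: VoxelGrid,
                   threshold: float = 0.5) -> np.ndarray:
    """Warp a binary mask with the image sampler.

    The indicator is warped with trilinear interpolation and thresholded at
    ``threshold`` (ties -> foreground).
    """
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("empty mask")
    warped = warp_volume(mask.astype(np.float64), dvf, grid)
    return warped >= threshold


def mask_centroid_mm(mask: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Center of mass of a binary mask in world millimetres."""
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError("empty mask")
    return grid.index_to_world(idx.mean(axis=0))
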