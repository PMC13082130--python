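"""HDF5 containers for acquisitions and model checkpoints; NIfTI export."""

from __future__ import annotations

import json

import h5py
import nibabel as nib
import numpy as np

from .acquisition import (AcquisitionConfig, NormalizationStats,
                          SOSAcquisition, SOSTrajectory)
from .grids import VoxelGrid

__all__ = [
    "save_acquisition", "load_acquisition",
    "save_checkpoint", "load_checkpoint",
    "export_nifti", "export_dvf_nifti",
]


def _grid_attrs(grid: VoxelGrid) -> dict:
    return {"grid_shape": grid.shape, "grid_spacing": grid.spacing,
            "grid_origin": grid.origin}


def _grid_from_attrs(attrs) -> VoxelGrid:
    return VoxelGrid(shape=tuple(int(v) for v in attrs["grid_shape"]),
                     spacing=tuple(float(v) for v in attrs["grid_spacing"]),
                     origin=tuple(float(v) for v in attrs["grid_origin"]))


def save_acquisition(path, acq: SOSAcquisition) -> None:
    cfg = acq.trajectory.config
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=acq.samples.astype(np.complex64))
        f.create_dataset("angles", data=acq.trajectory.angles_rad)
        f.create_dataset("kz_index", data=acq.trajectory.kz_indices)
        f.create_dataset("readout_cyc", data=acq.trajectory.readout_cyc)
        f.create_dataset("timestamps_ms", data=acq.trajectory.timestamps_ms)
        f.create_dataset("coil_maps", data=acq.coil_maps.astype(np.complex64))
        for k, v in _grid_attrs(acq.grid).items():
            f.attrs[k] = v
        f.attrs["noise_sigma"] = acq.noise_sigma
        for name in ("tr_ms", "n_kz", "n_readout", "n_coils", "n_stacks",
                     "golden_angle_deg"):
            f.attrs[name] = getattr(cfg, name)


def load_acquisition(path) -> SOSAcquisition:
    with h5py.File(path, "r") as f:
        cfg = AcquisitionConfig(
            tr_ms=float(f.attrs["tr_ms"]), n_kz=int(f.attrs["n_kz"]),
            n_readout=int(f.attrs["n_readout"]), n_coils=int(f.attrs["n_coils"]),
            n_stacks=int(f.attrs["n_stacks"]),
            golden_angle_deg=float(f.attrs["golden_angle_deg"]))
        traj = SOSTrajectory(
            angles_rad=f["angles"][...], kz_indices=f["kz_index"][...],
            readout_cyc=f["readout_cyc"][...],
            timestamps_ms=f["timestamps_ms"][...], config=cfg)
        return SOSAcquisition(
            trajectory=traj,
            samples=f["samples"][...].astype(np.complex128),
            coil_maps=f["coil_maps"][...].astype(np.complex128),
            grid=_grid_from_attrs(f.attrs),
            noise_sigma=float(f.attrs.get("noise_sigma", 0.0)))


def save_checkpoint(path, state: dict) -> None:
    """Nested dict of arrays/scalars -> one HDF5 container."""
    with h5py.File(path, "w") as f:
        def write(group, d):
            for k, v in d.items():
                if isinstance(v, dict):
                    write(group.create_group(k), v)
                elif isinstance(v, np.ndarray):
                    group.create_dataset(k, data=v)
                else:
                    group.attrs[k] = json.dumps(v)
        write(f, state)


def load_checkpoint(path) -> dict:
    with h5py.File(path, "r") as f:
        def read(group):
            out = {}
            for k, v in group.items():
                out[k] = read(v) if isinstance(v, h5py.Group) else v[...]
            for k, v in group.attrs.items():
                out[k] = json.loads(v)
            return out
        return read(f)


def export_nifti(path, volume: np.ndarray, grid: VoxelGrid) -> None:
    """Magnitude/phase channels for complex data, plain image otherwise."""
    if np.iscomplexobj(volume):
        data = np.stack([np.abs(volume), np.angle(volume)], axis=-1)
    else:
        data = np.asarray(volume, dtype=np.float64)
    nib.save(nib.Nifti1Image(data.astype(np.float32), grid.affine()), str(path))


def export_dvf_nifti(path, dvf_mm: np.ndarray, grid: VoxelGrid) -> None:
    """4-D displacement (one mm-vector per voxel, world RAS axes)."""
    nib.save(nib.Nifti1Image(np.asarray(dvf_mm, dtype=np.float32),
                             grid.affine()), str(path))
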