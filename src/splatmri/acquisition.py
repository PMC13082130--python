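"""Stack-of-stars golden-angle acquisition and Fourier operators.

A *stack* is the set of radial spokes sharing one in-plane angle, one spoke
per Cartesian kz partition.  Successive stacks advance the in-plane angle by
the golden angle (180 deg * (sqrt(5)-1)/2, taken mod 180 deg).

The multi-coil encoding operator applies the coil sensitivities, a centered
FFT along the Cartesian kz axis, and an exact in-plane discrete Fourier
sum evaluated at the spoke's radial k-space coordinates via a precomputed
(cached) DFT matrix per angle.  At desk-scale matrix sizes this is both
exact (it matches the brute-force DFT oracle to float precision) and fast;
its adjoint is the conjugate transpose, so the inner-product identity holds
to machine precision.

k-space readout coordinates are stored in cycles/FOV; the operator converts
them to cycles/mm using the image grid.  Image coordinates are voxel-
centered with the volume center at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .autodiff import Tensor, custom_op
from .grids import VoxelGrid

__all__ = [
    "GOLDEN_ANGLE_DEG",
    "AcquisitionConfig",
    "SOSTrajectory",
    "SOSAcquisition",
    "NormalizationStats",
    "make_sos_trajectory",
    "simulate_coil_maps",
    "forward_model",
    "forward_model_tensor",
    "adjoint_model",
    "motion_averaged_recon",
    "extract_mlp_navigator",
    "make_cnn_projection",
    "simulate_acquisition",
]

GOLDEN_ANGLE_DEG = 180.0 * (np.sqrt(5.0) - 1.0) / 2.0   # ~111.246 deg


@dataclass(frozen=True)
class AcquisitionConfig:
    """Sequence geometry for one continuously acquired SOS scan."""

    tr_ms: float = 4.5
    n_kz: int = 94
    n_readout: int = 368
    n_coils: int = 8
    n_stacks: int = 673
    golden_angle_deg: float = GOLDEN_ANGLE_DEG

    def __post_init__(self):
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        for name in ("n_kz", "n_readout", "n_coils", "n_stacks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def stack_duration_ms(self) -> float:
        """Temporal resolution of one stack: tr * kz partitions."""
        return self.tr_ms * self.n_kz

    @property
    def scan_duration_min(self) -> float:
        return self.n_stacks * self.stack_duration_ms / 60000.0

    @property
    def score_sampling_rate_hz(self) -> float:
        """One motion-score sample per stack: fs = 1/(tr * n_kz)."""
        return 1000.0 / self.stack_duration_ms

    @property
    def nyquist_hz(self) -> float:
        return 0.5 * self.score_sampling_rate_hz


@dataclass(frozen=True)
class SOSTrajectory:
    """Per-stack in-plane angles, kz ordering, and radial readout coords."""

    angles_rad: np.ndarray       # (n_stacks,)
    kz_indices: np.ndarray       # (n_kz,) integer kz, -n/2 .. n/2-1
    readout_cyc: np.ndarray      # (n_readout,) cycles/FOV along the spoke
    timestamps_ms: np.ndarray    # (n_stacks,) stack midpoints
    config: AcquisitionConfig

    @property
    def n_stacks(self) -> int:
        return self.angles_rad.shape[0]

    def inplane_k_cyc(self, stack: int) -> np.ndarray:
        """(n_readout, 2) in-plane (kx, ky) in cycles/FOV for one stack."""
        a = self.angles_rad[stack]
        return np.stack([self.readout_cyc * np.cos(a),
                         self.readout_cyc * np.sin(a)], axis=1)


def make_sos_trajectory(config: AcquisitionConfig) -> SOSTrajectory:
    """Golden-angle SOS trajectory: stack m at angle m * increment mod 180."""
    m = np.arange(config.n_stacks)
    angles = np.deg2rad((m * config.golden_angle_deg) % 180.0)
    kz = np.arange(config.n_kz) - config.n_kz // 2
    readout = np.arange(config.n_readout, dtype=np.float64) - config.n_readout // 2
    stamps = (m + 0.5) * config.stack_duration_ms
    return SOSTrajectory(angles_rad=angles, kz_indices=kz, readout_cyc=readout,
                         timestamps_ms=stamps, config=config)


@dataclass
class SOSAcquisition:
    """Measured (or simulated) samples plus geometry and coil maps."""

    trajectory: SOSTrajectory
    samples: np.ndarray          # (n_stacks, n_coils, n_kz, n_readout) complex
    coil_maps: np.ndarray        # (n_coils,) + grid.shape complex
    grid: VoxelGrid
    noise_sigma: float = 0.0

    def __post_init__(self):
        cfg = self.trajectory.config
        expect = (self.trajectory.n_stacks, cfg.n_coils, cfg.n_kz, cfg.n_readout)
        if self.samples.shape != expect:
            raise ValueError(f"samples shape {self.samples.shape} != {expect}")
        if self.coil_maps.shape != (cfg.n_coils,) + self.grid.shape:
            raise ValueError("coil maps do not share the image grid")

    @property
    def n_stacks(self) -> int:
        return self.trajectory.n_stacks


# ---------------------------------------------------------------------------
# coil sensitivities


def simulate_coil_maps(grid: VoxelGrid, n_coils: int, seed: int,
                       uniform: bool = False) -> np.ndarray:
    """Smooth complex surface-coil sensitivities around the body contour.

    Gaussian-profile loop coils are placed on an ellipse surrounding the
    in-plane FOV at alternating z offsets; each coil gets a smooth phase
    ramp.  Deterministic under ``seed``.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    if uniform:
        return np.ones((n_coils,) + grid.shape, dtype=np.complex128)
    rng = np.random.default_rng(seed)
    x, y, z = grid.coords()
    fov = np.asarray(grid.fov_mm)
    center = np.asarray(grid.origin) + 0.5 * (np.asarray(grid.shape) - 1) \
        * np.asarray(grid.spacing)
    maps = np.empty((n_coils,) + grid.shape, dtype=np.complex128)
    width = 0.8 * float(fov[:2].mean())
    for c in range(n_coils):
        theta = 2 * np.pi * c / n_coils + rng.uniform(-0.15, 0.15)
        cx = center[0] + 0.55 * fov[0] * np.cos(theta)
        cy = center[1] + 0.55 * fov[1] * np.sin(theta)
        cz = center[2] + fov[2] * (0.2 if c % 2 else -0.2) * rng.uniform(0.5, 1.0)
        r2 = ((x - cx) ** 2 + (y - cy) ** 2) / width ** 2 \
            + ((z - cz) ** 2) / (1.2 * fov[2]) ** 2
        mag = np.exp(-0.5 * r2)
        phase = (0.4 * rng.standard_normal() * (x - center[0]) / fov[0]
                 + 0.4 * rng.standard_normal() * (y - center[1]) / fov[1]
                 + rng.uniform(-np.pi, np.pi))
        maps[c] = mag * np.exp(1j * phase)
    # normalize so root-sum-of-squares is O(1) in the FOV center
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    maps /= max(np.median(rss), 1e-12)
    return maps


# ---------------------------------------------------------------------------
# encoding operators


class SosOperator:
    """Coil encoding + centered z-FFT + exact in-plane radial DFT.

    Instances cache per-angle DFT matrices, so repeated evaluation over the
    same trajectory (training epochs) costs one matmul per stack.
    """

    def __init__(self, grid: VoxelGrid, trajectory: SOSTrajectory):
        self.grid = grid
        self.traj = trajectory
        cfg = trajectory.config
        if cfg.n_kz != grid.shape[2]:
            raise ValueError("kz partition count must equal grid nz")
        nx, ny, _ = grid.shape
        # reject out-of-Nyquist k radii (cycles/FOV must fit the grid box)
        if np.abs(trajectory.readout_cyc).max() > max(nx, ny) / 2 + 1e-9:
            raise ValueError("readout k-coordinates exceed the Nyquist box")
        self._mat_cache: dict[int, np.ndarray] = {}
        xc = grid.axis_coords(0)
        yc = grid.axis_coords(1)
        self._xy = (xc[:, None] + 0 * yc[None, :], 0 * xc[:, None] + yc[None, :])
        self._kz_phase = self._make_kz_phase()

    def _make_kz_phase(self) -> np.ndarray:
        nz = self.grid.shape[2]
        zc = self.grid.axis_coords(2)
        kz_cyc_per_mm = self.traj.kz_indices / (nz * self.grid.spacing[2])
        return np.exp(-2j * np.pi * kz_cyc_per_mm[:, None] * zc[None, :])

    def dft_matrix(self, stack: int) -> np.ndarray:
        """(n_readout, nx*ny) in-plane DFT matrix for one stack angle."""
        if stack not in self._mat_cache:
            k = self.traj.inplane_k_cyc(stack)  # cycles/FOV
            nx, ny, _ = self.grid.shape
            kx_mm = k[:, 0] / (nx * self.grid.spacing[0])
            ky_mm = k[:, 1] / (ny * self.grid.spacing[1])
            X, Y = self._xy
            phase = kx_mm[:, None] * X.ravel()[None, :] \
                + ky_mm[:, None] * Y.ravel()[None, :]
            self._mat_cache[stack] = np.exp(-2j * np.pi * phase)
        return self._mat_cache[stack]

    def forward(self, volume: np.ndarray, coil_maps: np.ndarray,
                stack: int) -> np.ndarray:
        """Samples (n_coils, n_kz, n_readout) of one stack."""
        nx, ny, nz = self.grid.shape
        weighted = coil_maps * volume[None]             # (C, nx, ny, nz)
        kzp = self._kz_phase                            # (n_kz, nz)
        slab = np.einsum("kz,cxyz->ckxy", kzp, weighted, optimize=True)
        E = self.dft_matrix(stack)                      # (R, nx*ny)
        nc, nkz = slab.shape[0], slab.shape[1]
        flat = slab.reshape(nc, nkz, nx * ny)
        return np.einsum("rp,ckp->ckr", E, flat, optimize=True)

    def adjoint(self, samples: np.ndarray, coil_maps: np.ndarray,
                stack: int) -> np.ndarray:
        """Adjoint of :meth:`forward` (sums over coils)."""
        nx, ny, nz = self.grid.shape
        E = self.dft_matrix(stack)
        slab = np.einsum("rp,ckr->ckp", E.conj(), samples, optimize=True)
        slab = slab.reshape(samples.shape[0], samples.shape[1], nx, ny)
        vol = np.einsum("kz,ckxy->cxyz", self._kz_phase.conj(), slab,
                        optimize=True)
        return (coil_maps.conj() * vol).sum(axis=0)

    # -- differentiable wrapper (real/imag channel pair) --------------------

    def forward_tensor(self, vol_re: Tensor, vol_im: Tensor,
                       coil_maps: np.ndarray, stack: int,
                       ) -> tuple[Tensor, Tensor]:
        """Differentiable forward: linear op, backward = adjoint."""
        vol = vol_re.data + 1j * vol_im.data
        out = self.forward(vol, coil_maps, stack)

        def make_backward(part):
            def backward(g):
                grad_vol = self.adjoint(g * part, coil_maps, stack)
                return grad_vol.real.copy(), grad_vol.imag.copy()
            return backward

        out_re = custom_op([vol_re, vol_im], out.real, make_backward(1.0))
        out_im = custom_op([vol_re, vol_im], out.imag, make_backward(1.0j))
        return out_re, out_im


def forward_model(volume: np.ndarray, coil_maps: np.ndarray,
                  trajectory: SOSTrajectory, stack: int,
                  grid: VoxelGrid) -> np.ndarray:
    """One-shot (uncached) forward encoding of a single stack."""
    return SosOperator(grid, trajectory).forward(volume, coil_maps, stack)


def forward_model_tensor(op: SosOperator, vol_re: Tensor, vol_im: Tensor,
                         coil_maps: np.ndarray, stack: int):
    return op.forward_tensor(vol_re, vol_im, coil_maps, stack)


def adjoint_model(samples: np.ndarray, coil_maps: np.ndarray,
                  trajectory: SOSTrajectory, stack: int,
                  grid: VoxelGrid) -> np.ndarray:
    return SosOperator(grid, trajectory).adjoint(samples, coil_maps, stack)


# ---------------------------------------------------------------------------
# simulation and motion-averaged reconstruction


def simulate_acquisition(ground_truth, coil_maps: np.ndarray,
                         trajectory: SOSTrajectory, grid: VoxelGrid,
                         noise_sigma: float = 0.0, seed: int = 0,
                         ) -> SOSAcquisition:
    """Sample each dynamic frame with its stack of the SOS trajectory.

    Frame t supplies the anatomy for stack t (one frame per stack, matching
    the temporal resolution of the sequence).
    """
    cfg = trajectory.config
    if ground_truth.n_frames < trajectory.n_stacks:
        raise ValueError("ground truth has fewer frames than stacks")
    op = SosOperator(grid, trajectory)
    rng = np.random.default_rng(seed)
    samples = np.empty((trajectory.n_stacks, cfg.n_coils, cfg.n_kz,
                        cfg.n_readout), dtype=np.complex128)
    for t in range(trajectory.n_stacks):
        samples[t] = op.forward(ground_truth.frames[t], coil_maps, t)
    if noise_sigma > 0:
        scale = noise_sigma * np.abs(samples).std()
        samples += scale * (rng.standard_normal(samples.shape)
                            + 1j * rng.standard_normal(samples.shape))
    return SOSAcquisition(trajectory=trajectory, samples=samples,
                          coil_maps=coil_maps, grid=grid,
                          noise_sigma=noise_sigma)


def _coil_compress(samples: np.ndarray, n_virtual: int) -> np.ndarray:
    """SVD coil compression across the coil axis of all samples."""
    ns, nc, nkz, nr = samples.shape
    mat = np.moveaxis(samples, 1, 0).reshape(nc, -1)
    u, _, _ = np.linalg.svd(mat @ mat.conj().T)
    comp = u[:, :n_virtual].conj().T @ mat
    return np.moveaxis(comp.reshape(n_virtual, ns, nkz, nr), 0, 1)


def motion_averaged_recon(acq: SOSAcquisition, n_virtual_coils: int = 1,
                          ) -> np.ndarray:
    """Adjoint (inverse-NUFFT style) reconstruction over all spokes.

    Coil-compresses to ``n_virtual_coils``, applies a radial ramp density
    compensation in-plane, grids every spoke back with the adjoint operator
    under unit sensitivities, and rescales so the forward model of the
    result matches the measured data in least squares.
    """
    cfg = acq.trajectory.config
    if acq.n_stacks == 0:
        raise ValueError("empty acquisition")
    if n_virtual_coils > cfg.n_coils:
        raise ValueError("n_virtual_coils exceeds physical coil count")
    comp = _coil_compress(acq.samples, n_virtual_coils)
    ramp = np.abs(acq.trajectory.readout_cyc)
    if ramp.min() == 0:
        ramp[ramp == 0] = 0.25
    op = SosOperator(acq.grid, acq.trajectory)
    unit = np.ones((n_virtual_coils,) + acq.grid.shape, dtype=np.complex128)
    vol = np.zeros(acq.grid.shape, dtype=np.complex128)
    for t in range(acq.n_stacks):
        weighted = comp[t] * ramp[None, None, :]
        per_coil = np.stack([
            op.adjoint(weighted[c:c + 1], unit[c:c + 1], t)
            for c in range(n_virtual_coils)])
        if n_virtual_coils == 1:
            vol += per_coil[0]
        else:
            mag = np.sqrt((np.abs(per_coil) ** 2).sum(axis=0))
            vol += mag * np.exp(1j * np.angle(per_coil[0]))
    if np.abs(vol).max() == 0:
        return vol
    # least-squares intensity calibration against the measured k-space
    num = 0.0
    den = 0.0
    step = max(1, acq.n_stacks // 16)
    for t in range(0, acq.n_stacks, step):
        pred = op.forward(vol, acq.coil_maps, t)
        num += np.vdot(pred, acq.samples[t]).real
        den += np.vdot(pred, pred).real
    if den > 0:
        vol *= num / den
    return vol


# ---------------------------------------------------------------------------
# motion-encoder inputs


@dataclass
class NormalizationStats:
    """Per-channel z-score statistics of the navigator features."""

    mean: np.ndarray
    std: np.ndarray
    eps: float = 1e-6

    def apply(self, features: np.ndarray) -> np.ndarray:
        return (features - self.mean) / np.maximum(self.std, self.eps)


def _raw_navigator(stack_samples: np.ndarray, kz_indices: np.ndarray,
                   n_readout: int, k_max: int) -> np.ndarray:
    """Real/imag k-space-center features of one stack, unnormalized."""
    n_kz = kz_indices.shape[0]
    sel = np.flatnonzero(np.abs(kz_indices) <= k_max)
    if sel.size == 0 or 2 * k_max + 1 > n_kz:
        raise ValueError("k_max exceeds the available kz partitions")
    center = n_readout // 2
    vals = stack_samples[:, sel, center]              # (coils, n_sel)
    return np.concatenate([vals.real.ravel(), vals.imag.ravel()])


def extract_mlp_navigator(stack_samples: np.ndarray,
                          trajectory: SOSTrajectory, k_max: int,
                          stats: NormalizationStats | None = None,
                          ) -> np.ndarray:
    """Navigator feature vector of one stack.

    Takes the kx=ky=0 sample of the central ``2*k_max+1`` kz partitions for
    each coil, splits real/imaginary, concatenates, and (when ``stats`` is
    given) z-scores per channel.  Length = n_kz_selected * n_coils * 2.
    """
    feats = _raw_navigator(stack_samples, trajectory.kz_indices,
                           trajectory.config.n_readout, k_max)
    if stats is not None:
        feats = stats.apply(feats)
    return feats


def fit_normalization(all_stack_samples: np.ndarray,
                      trajectory: SOSTrajectory, k_max: int,
                      ) -> NormalizationStats:
    """Z-score statistics over the training stacks (>= 2 required)."""
    if all_stack_samples.shape[0] < 2:
        raise ValueError("need at least 2 stacks to fit normalization")
    feats = np.stack([
        _raw_navigator(all_stack_samples[t], trajectory.kz_indices,
                       trajectory.config.n_readout, k_max)
        for t in range(all_stack_samples.shape[0])])
    return NormalizationStats(mean=feats.mean(axis=0), std=feats.std(axis=0))


CNN_PATCH_KZ = 3
CNN_PATCH_READOUT = 6


def make_cnn_projection(stack_samples: np.ndarray,
                        patch_kz: int = CNN_PATCH_KZ,
                        patch_readout: int = CNN_PATCH_READOUT) -> np.ndarray:
    """Low-frequency projection image of one stack for the CNN encoder.

    Per coil, keeps the central ``patch_kz x patch_readout`` patch of the
    (kz, readout) plane, zero-fills, applies a centered 2-D inverse FFT,
    and combines coils by root-sum-of-squares.  Output shape equals the
    (n_kz, n_readout) plane.
    """
    nc, nkz, nr = stack_samples.shape
    if patch_kz > nkz or patch_readout > nr:
        raise ValueError("patch larger than the stack k-space plane")
    zk0 = nkz // 2 - patch_kz // 2
    zr0 = nr // 2 - patch_readout // 2
    padded = np.zeros_like(stack_samples)
    padded[:, zk0:zk0 + patch_kz, zr0:zr0 + patch_readout] = \
        stack_samples[:, zk0:zk0 + patch_kz, zr0:zr0 + patch_readout]
    imgs = np.fft.ifft2(np.fft.ifftshift(padded, axes=(1, 2)), axes=(1, 2))
    imgs = np.fft.fftshift(imgs, axes=(1, 2))
    return np.sqrt((np.abs(imgs) ** 2).sum(axis=0))
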