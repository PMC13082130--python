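"""Evaluation metrics and the experiment report.

COME is the Euclidean distance between mask centers of mass in mm; DSC the
Dice overlap; SSIM the standard Gaussian-windowed (sigma 1.5, 11^3 support)
structural similarity on magnitude images, averaged inside a region of
interest.  All metrics binarize label inputs, so results do not depend on
label values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .grids import VoxelGrid

__all__ = ["come", "dsc", "ssim", "psnr", "MetricReport", "evaluate_experiment",
           "locate_target_sphere", "sphere_mask", "fit_reference_target_mask"]

_SSIM_SIGMA = 1.5
_SSIM_TRUNCATE = 3.5            # 11-voxel support at sigma 1.5
_K1, _K2 = 0.01, 0.03


def come(mask_a: np.ndarray, mask_b: np.ndarray,
         spacing: tuple[float, float, float]) -> float:
    """Center-of-mass distance between two masks in millimetres."""
    a = np.asarray(mask_a) != 0
    b = np.asarray(mask_b) != 0
    if not a.any() or not b.any():
        raise ValueError("COME requires two nonempty masks")
    sp = np.asarray(spacing, dtype=np.float64)
    ca = np.argwhere(a).mean(axis=0) * sp
    cb = np.argwhere(b).mean(axis=0) * sp
    return float(np.linalg.norm(ca - cb))


def dsc(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A^B| / (|A| + |B|)."""
    a = np.asarray(mask_a) != 0
    b = np.asarray(mask_b) != 0
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("DSC undefined for two empty masks")
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def ssim(vol_a: np.ndarray, vol_b: np.ndarray,
         data_range: float | None = None,
         roi: np.ndarray | None = None) -> float:
    """Gaussian-windowed SSIM between magnitude volumes.

    ``vol_a`` is the reference: the dynamic range defaults to its maximum.
    The SSIM map is averaged inside ``roi`` (cropped away from the filter
    border), or over the whole valid region when no ROI is given.
    """
    a = np.abs(np.asarray(vol_a)).astype(np.float64)
    b = np.abs(np.asarray(vol_b)).astype(np.float64)
    if a.shape != b.shape:
        raise ValueError("volumes must share a grid")
    if data_range is None:
        data_range = float(a.max() - a.min())
        if data_range == 0:
            data_range = 1.0
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2

    def filt(x):
        return gaussian_filter(x, sigma=_SSIM_SIGMA, truncate=_SSIM_TRUNCATE)

    ua, ub = filt(a), filt(b)
    va = filt(a * a) - ua * ua
    vb = filt(b * b) - ub * ub
    cov = filt(a * b) - ua * ub
    smap = ((2 * ua * ub + c1) * (2 * cov + c2)) \
        / ((ua * ua + ub * ub + c1) * (va + vb + c2))
    pad = int(_SSIM_TRUNCATE * _SSIM_SIGMA + 0.5)
    valid = np.zeros(a.shape, dtype=bool)
    valid[tuple(slice(pad, max(n - pad, pad + 1)) for n in a.shape)] = True
    if roi is not None:
        valid &= np.asarray(roi) != 0
        if not valid.any():
            valid = np.asarray(roi) != 0
    return float(smap[valid].mean())


def psnr(vol_a: np.ndarray, vol_b: np.ndarray,
         data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio (dB) of magnitudes, reference first."""
    a = np.abs(np.asarray(vol_a)).astype(np.float64)
    b = np.abs(np.asarray(vol_b)).astype(np.float64)
    if data_range is None:
        data_range = float(a.max() - a.min()) or 1.0
    mse = np.mean((a - b) ** 2)
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(data_range ** 2 / mse))


def sphere_mask(grid: VoxelGrid, center_mm: np.ndarray,
                diameter_mm: float) -> np.ndarray:
    """Hard spherical indicator sampled at voxel centers."""
    x, y, z = grid.coords()
    r = diameter_mm / 2.0
    return ((x - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2
            + (z - center_mm[2]) ** 2) < r * r


def locate_target_sphere(reference_magnitude: np.ndarray, grid: VoxelGrid,
                         diameter_mm: float,
                         search_center_mm: np.ndarray | None = None,
                         search_radius_mm: float | None = None,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Contour a spherical tracking target in a reconstructed reference.

    Matched-filters the magnitude image with a zero-mean spherical
    template, restricts the response to an optional search ball, refines
    the peak to subvoxel precision with a separable quadratic fit, and
    returns ``(center_mm, mask)``.
    """
    mag = np.abs(np.asarray(reference_magnitude)).astype(np.float64)
    sp = np.asarray(grid.spacing)
    r_vox = diameter_mm / 2.0 / sp
    half = np.ceil(r_vox + 1).astype(int)
    tx = np.arange(-half[0], half[0] + 1)[:, None, None] * sp[0]
    ty = np.arange(-half[1], half[1] + 1)[None, :, None] * sp[1]
    tz = np.arange(-half[2], half[2] + 1)[None, None, :] * sp[2]
    template = (tx ** 2 + ty ** 2 + tz ** 2 < (diameter_mm / 2.0) ** 2
                ).astype(np.float64)
    template -= template.mean()
    resp = fftconvolve(mag - mag.mean(), template[::-1, ::-1, ::-1],
                       mode="same")
    if search_center_mm is not None and search_radius_mm is not None:
        x, y, z = grid.coords()
        ball = ((x - search_center_mm[0]) ** 2 + (y - search_center_mm[1]) ** 2
                + (z - search_center_mm[2]) ** 2) <= search_radius_mm ** 2
        resp = np.where(ball, resp, -np.inf)
    peak = np.unravel_index(np.argmax(resp), resp.shape)
    center_idx = np.asarray(peak, dtype=np.float64)
    # separable 3-point quadratic refinement
    for ax in range(3):
        i = peak[ax]
        if 0 < i < resp.shape[ax] - 1:
            sl = list(peak)
            sl[ax] = slice(i - 1, i + 2)
            v = resp[tuple(sl)]
            if np.all(np.isfinite(v)):
                denom = v[0] - 2 * v[1] + v[2]
                if denom != 0:
                    center_idx[ax] += 0.5 * (v[0] - v[2]) / denom
    center_mm = grid.index_to_world(center_idx)
    return center_mm, sphere_mask(grid, center_mm, diameter_mm)


def fit_reference_target_mask(reference_volume: np.ndarray, anatomy,
                              diameter_mm: float = 30.0,
                              si_bounds: tuple[float, float] = (-20.0, 25.0),
                              ap_bounds: tuple[float, float] = (-15.0, 15.0),
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Contour the tracking target in a solved reference volume.

    The solved reference sits at an unknown (roughly time-averaged) motion
    state of the generating anatomy.  This fits that state's (si, ap)
    displacement by maximizing the normalized cross-correlation between the
    reference magnitude and re-rendered anatomy states inside a window
    around the target, then returns the analytic target center and its
    spherical mask.  Used by the synthetic-experiment harness, where the
    generating anatomy is known.
    """
    from .phantom import render_anatomy

    grid = anatomy.grid
    mag = np.abs(np.asarray(reference_volume))
    target = anatomy.organ(anatomy.tumor_label)
    c0 = np.asarray(target.center_mm)
    x, y, z = grid.coords()
    span = max(abs(b) for b in (*si_bounds, *ap_bounds))
    window = ((x - c0[0]) ** 2 + (y - c0[1]) ** 2 + (z - c0[2]) ** 2
              ) < (diameter_mm + span) ** 2
    ref_w = mag[window]
    ref_w = ref_w - ref_w.mean()

    def ncc(si, ap):
        img, _ = render_anatomy(anatomy, si, ap)
        v = np.abs(img)[window]
        v = v - v.mean()
        denom = np.linalg.norm(ref_w) * np.linalg.norm(v)
        return float(ref_w @ v / denom) if denom > 0 else -1.0

    # coarse grid then local quadratic-free refinement
    si_grid = np.linspace(*si_bounds, 10)
    ap_grid = np.linspace(*ap_bounds, 7)
    best = max(((ncc(si, ap), si, ap) for si in si_grid for ap in ap_grid),
               key=lambda r: r[0])
    from scipy.optimize import minimize
    res = minimize(lambda p: -ncc(p[0], p[1]), x0=[best[1], best[2]],
                   method="Nelder-Mead",
                   options={"xatol": 0.02, "fatol": 1e-7})
    si, ap = res.x
    center = c0 + np.array([0.0, ap, si])
    return center, sphere_mask(grid, center, diameter_mm)


@dataclass
class MetricReport:
    """Per-frame metrics and their aggregates for one experiment arm."""

    ssim_per_frame: np.ndarray
    psnr_per_frame: np.ndarray
    come_per_frame_mm: np.ndarray
    dsc_per_frame: np.ndarray
    trajectory_true_mm: np.ndarray   # (T, 3) target centroids
    trajectory_pred_mm: np.ndarray
    protocol: str = "same_scenario"

    def __post_init__(self):
        if np.any(self.come_per_frame_mm < 0):
            raise ValueError("COME must be nonnegative")
        if np.any((self.dsc_per_frame < 0) | (self.dsc_per_frame > 1)):
            raise ValueError("DSC must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.come_per_frame_mm.shape[0]

    def summary(self) -> dict[str, tuple[float, float]]:
        out = {}
        for name, arr in (("ssim", self.ssim_per_frame),
                          ("psnr", self.psnr_per_frame),
                          ("come_mm", self.come_per_frame_mm),
                          ("dsc", self.dsc_per_frame)):
            arr = np.asarray(arr, dtype=np.float64)
            arr = arr[np.isfinite(arr)]
            out[name] = (float(arr.mean()), float(arr.std())) if arr.size \
                else (float("nan"), float("nan"))
        return out

    def to_dict(self) -> dict:
        means = self.summary()
        return {
            "protocol": self.protocol,
            "n_frames": int(self.n_frames),
            "mean": {k: v[0] for k, v in means.items()},
            "std": {k: v[1] for k, v in means.items()},
        }


def evaluate_experiment(truth_frames: np.ndarray, truth_masks: np.ndarray,
                        pred_frames: np.ndarray, pred_masks: np.ndarray,
                        grid: VoxelGrid, roi: np.ndarray | None = None,
                        protocol: str = "same_scenario") -> MetricReport:
    """Frame-wise SSIM/PSNR/COME/DSC of predictions against ground truth.

    ``*_frames`` may be None to skip image metrics (motion-only arms).
    """
    if pred_masks.shape != truth_masks.shape:
        raise ValueError("mask sequences must share shape")
    T = truth_masks.shape[0]
    ssim_v = np.full(T, np.nan)
    psnr_v = np.full(T, np.nan)
    come_v = np.empty(T)
    dsc_v = np.empty(T)
    traj_t = np.empty((T, 3))
    traj_p = np.empty((T, 3))
    sp = np.asarray(grid.spacing)
    for t in range(T):
        mt = truth_masks[t] != 0
        mp = pred_masks[t] != 0
        come_v[t] = come(mt, mp, grid.spacing)
        dsc_v[t] = dsc(mt, mp)
        traj_t[t] = np.argwhere(mt).mean(axis=0) * sp
        traj_p[t] = np.argwhere(mp).mean(axis=0) * sp if mp.any() else np.nan
        if truth_frames is not None and pred_frames is not None:
            dr = float(np.abs(truth_frames[t]).max()) or 1.0
            ssim_v[t] = ssim(truth_frames[t], pred_frames[t],
                             data_range=dr, roi=roi)
            psnr_v[t] = psnr(truth_frames[t], pred_frames[t], data_range=dr)
    return MetricReport(ssim_per_frame=ssim_v, psnr_per_frame=psnr_v,
                        come_per_frame_mm=come_v, dsc_per_frame=dsc_v,
                        trajectory_true_mm=traj_t, trajectory_pred_mm=traj_p,
                        protocol=protocol)
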