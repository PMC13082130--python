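"""Training objectives: k-space data consistency and the five regularizers.

Conventions fixed here so tests can be exact:

* the complex L1 data term treats real and imaginary parts as separate
  channels and averages (|Re| + |Im|)/2 over all samples;
* total variation is the voxel mean of the l1 norm of forward differences,
  channels summed for complex input;
* the basis-normality term penalizes the squared deviation of each field's
  squared voxel L2 norm from one, averaged over the nine fields;
* the zero-mean-score term averages the squared temporal mean over the
  nine channels;
* the Jacobian term averages (det J - 1)^2 over time and an intensity-
  derived region of interest;
* the frequency term compares mean spectral power (mean-removed magnitude-
  squared DFT, no windowing) inside scanner-frequency bands against their
  flanking baseline bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .acquisition import AcquisitionConfig
from .autodiff import Tensor, as_tensor
from .grids import VoxelGrid
from .motion import MotionBasisSet, ScoreSequence, jacobian_determinant

__all__ = [
    "LossWeights",
    "FrequencyBands",
    "ROIMask",
    "loss_data_consistency",
    "loss_tv",
    "loss_mbc_norm",
    "loss_zero_mean",
    "loss_jacobian",
    "build_frequency_bands",
    "fold_frequency",
    "loss_frequency",
    "roi_from_reference",
    "SCANNER_REFERENCE_HZ",
]

SCANNER_REFERENCE_HZ = 60.7353
DEFAULT_HALF_WIDTH_HZ = 0.05
DEFAULT_N_HARMONICS = 3
DEFAULT_ROI_THRESHOLD = 0.1


@dataclass(frozen=True)
class LossWeights:
    """Regularizer weights (defaults from the reference configuration)."""

    tv: float = 2e-6
    mbc: float = 1e-2
    zms: float = 1e-4
    jac: float = 1e-1
    freq: float = 1.0

    def __post_init__(self):
        if min(self.tv, self.mbc, self.zms, self.jac, self.freq) < 0:
            raise ValueError("loss weights must be nonnegative")


# ---------------------------------------------------------------------------
# data consistency and image regularizers


def _pair(t) -> Tensor:
    return t if isinstance(t, Tensor) else Tensor(t)


def loss_data_consistency(pred_re, pred_im, meas: np.ndarray) -> Tensor:
    """Channel-mean complex L1: mean of (|Re residual| + |Im residual|)/2."""
    pred_re, pred_im = _pair(pred_re), _pair(pred_im)
    if pred_re.shape != meas.shape or pred_im.shape != meas.shape:
        raise ValueError("prediction/measurement shape mismatch")
    res_re = (pred_re - Tensor(meas.real)).abs().mean()
    res_im = (pred_im - Tensor(meas.imag)).abs().mean()
    return (res_re + res_im) * 0.5


def loss_tv(*channels) -> Tensor:
    """Mean over voxels of the l1 norm of forward-difference gradients,
    summed over the given channels (e.g. real and imaginary)."""
    total = None
    nvox = None
    for ch in channels:
        ch = _pair(ch)
        nvox = ch.size
        for ax in range(ch.ndim):
            n = ch.shape[ax]
            if n < 2:
                continue
            sl_hi = [slice(None)] * ch.ndim
            sl_lo = [slice(None)] * ch.ndim
            sl_hi[ax] = slice(1, n)
            sl_lo[ax] = slice(0, n - 1)
            diff = (ch[tuple(sl_hi)] - ch[tuple(sl_lo)]).abs().sum()
            total = diff if total is None else total + diff
    if total is None:
        return Tensor(0.0)
    return total / float(nvox)


def loss_mbc_norm(basis) -> Tensor:
    """Mean over the 9 fields of (||e||_2^2 - 1)^2 (voxel-wise L2 norm)."""
    if isinstance(basis, MotionBasisSet):
        fields = [Tensor(f) for f in basis.fields]
    else:
        fields = [_pair(f) for f in basis]
    if len(fields) != 9:
        raise ValueError("nine basis fields required")
    total = None
    for f in fields:
        sq = (f * f).sum()
        dev = (sq - 1.0)
        term = dev * dev
        total = term if total is None else total + term
    return total / 9.0


def loss_zero_mean(scores) -> Tensor:
    """Mean over channels of the squared temporal mean of each channel."""
    if isinstance(scores, ScoreSequence):
        scores = Tensor(scores.scores)
    scores = _pair(scores)
    if scores.ndim != 2:
        raise ValueError("scores must be (n_stacks, channels)")
    ch_mean = scores.mean(axis=0)
    return (ch_mean * ch_mean).mean()


def loss_jacobian(dets, roi: np.ndarray) -> Tensor:
    """Mean over time and ROI voxels of (det(J) - 1)^2.

    ``dets`` is a sequence of det(J) volumes (arrays or Tensors).
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    dets = list(dets)
    idx = np.nonzero(roi.ravel())[0]
    total = None
    for det in dets:
        det = _pair(det)
        dev = det.reshape(det.size)[idx] - 1.0
        term = (dev * dev).sum()
        total = term if total is None else total + term
    return total / float(len(dets) * idx.size)


def loss_jacobian_field(dvfs, grid: VoxelGrid, roi: np.ndarray) -> float:
    """Numpy convenience: list of (grid.shape + (3,)) DVFs -> scalar."""
    dets = [jacobian_determinant(d, grid) for d in dvfs]
    return float(loss_jacobian(dets, roi).data)


# ---------------------------------------------------------------------------
# frequency regularization


def fold_frequency(f_hz: float, fs_hz: float) -> float:
    """Alias a frequency into the Nyquist range [0, fs/2]."""
    fn = fs_hz / 2.0
    return abs(((f_hz + fn) % fs_hz) - fn)


@dataclass(frozen=True)
class FrequencyBands:
    """Target bands C and flanking baseline bands B in [0, fN] (Hz)."""

    target: tuple[tuple[float, float], ...]
    baseline: tuple[tuple[float, float], ...]
    fs_hz: float

    @property
    def n_peaks(self) -> int:
        return len(self.target)

    @property
    def nyquist_hz(self) -> float:
        return self.fs_hz / 2.0


def build_frequency_bands(config: AcquisitionConfig,
                          reference_hz: float = SCANNER_REFERENCE_HZ,
                          n_harmonics: int = DEFAULT_N_HARMONICS,
                          half_width_hz: float = DEFAULT_HALF_WIDTH_HZ,
                          ) -> FrequencyBands:
    """Fold the scanner reference frequency and harmonics into [0, fN].

    Each folded harmonic becomes a target band (center +- half width);
    its equal-width flanks become the baseline band.  Overlapping target
    bands are merged.
    """
    fs = config.score_sampling_rate_hz
    fn = config.nyquist_hz
    if half_width_hz >= fn / 4.0:
        raise ValueError("half_width too large for the Nyquist range")
    centers = sorted({round(fold_frequency(m * reference_hz, fs), 12)
                      for m in range(1, n_harmonics + 1)})
    intervals = [(max(0.0, c - half_width_hz), min(fn, c + half_width_hz))
                 for c in centers]
    merged: list[list[float]] = []
    for lo, hi in intervals:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    target = tuple((lo, hi) for lo, hi in merged)
    baseline = []
    for lo, hi in target:
        w = hi - lo
        baseline.append((max(0.0, lo - w), lo))
        baseline.append((hi, min(fn, hi + w)))
    return FrequencyBands(target=target, baseline=tuple(baseline), fs_hz=fs)


def _band_masks(bands: FrequencyBands, freqs: np.ndarray):
    """(target mask, baseline mask) pairs; baselines are stored pairwise
    (left flank, right flank) per target band."""
    masks = []
    for i, (lo, hi) in enumerate(bands.target):
        c_mask = (freqs >= lo) & (freqs <= hi)
        b_mask = np.zeros_like(c_mask)
        for blo, bhi in bands.baseline[2 * i:2 * i + 2]:
            b_mask |= (freqs > blo) & (freqs < bhi) & ~c_mask
        masks.append((c_mask, b_mask))
    return masks


def loss_frequency(scores, bands: FrequencyBands) -> Tensor:
    """Mean absolute difference of band vs baseline spectral power.

    ``scores`` is (n_stacks, channels) (Tensor or array or ScoreSequence),
    sampled uniformly at ``bands.fs_hz``.  Power is the magnitude-squared
    DFT of the mean-removed sequence; both band means are averaged over
    channels before the absolute difference.
    """
    if isinstance(scores, ScoreSequence):
        scores = Tensor(scores.scores)
    scores = _pair(scores)
    n = scores.shape[0]
    freqs = np.fft.rfftfreq(n, d=1.0 / bands.fs_hz)
    centered = scores - scores.mean(axis=0, keepdims=True)
    # real DFT as two matmuls (differentiable)
    t = np.arange(n)
    cos = np.cos(-2 * np.pi * np.outer(freqs / bands.fs_hz, t))
    sin = np.sin(-2 * np.pi * np.outer(freqs / bands.fs_hz, t))
    re = Tensor(cos) @ centered
    im = Tensor(sin) @ centered
    power = re * re + im * im            # (n_freqs, channels)
    total = None
    count = 0
    for c_mask, b_mask in _band_masks(bands, freqs):
        if not c_mask.any() or not b_mask.any():
            continue
        p_c = power[np.nonzero(c_mask)[0]].mean()
        p_b = power[np.nonzero(b_mask)[0]].mean()
        term = (p_c - p_b).abs()
        total = term if total is None else total + term
        count += 1
    if total is None:
        return Tensor(0.0)
    return total / float(count)


# ---------------------------------------------------------------------------
# region of interest


@dataclass(frozen=True)
class ROIMask:
    """Anatomy-support mask derived from the reference magnitude."""

    mask: np.ndarray

    def __post_init__(self):
        if not np.asarray(self.mask).any():
            raise ValueError("ROI mask must be nonempty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def roi_from_reference(magnitude: np.ndarray,
                       threshold_fraction: float = DEFAULT_ROI_THRESHOLD,
                       ) -> ROIMask:
    """Threshold at a fraction of the robust (99th percentile) maximum,
    keep the largest connected component, fill holes."""
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in (0, 1)")
    magnitude = np.abs(np.asarray(magnitude))
    robust_max = np.percentile(magnitude, 99)
    raw = magnitude > threshold_fraction * robust_max
    if not raw.any():
        raise ValueError("thresholding produced an empty ROI")
    labels, n = ndimage.label(raw)
    if n > 1:
        sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))
        raw = labels == (1 + int(np.argmax(sizes)))
    filled = ndimage.binary_fill_holes(raw)
    return ROIMask(mask=filled)
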