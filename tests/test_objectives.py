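import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splatmri.acquisition import AcquisitionConfig
from splatmri.autodiff import Tensor
from splatmri.grids import VoxelGrid
from splatmri.motion import jacobian_determinant
from splatmri.objectives import (LossWeights, build_frequency_bands,
                                 fold_frequency, loss_data_consistency,
                                 loss_frequency, loss_jacobian, loss_mbc_norm,
                                 loss_tv, loss_zero_mean, roi_from_reference)

from conftest import numeric_gradient


def test_loss_weights_defaults_match_reference_configuration():
    w = LossWeights()
    assert (w.tv, w.mbc, w.zms, w.jac, w.freq) == (2e-6, 1e-2, 1e-4, 1e-1, 1.0)


def test_loss_weights_nonnegative():
    with pytest.raises(ValueError):
        LossWeights(tv=-1.0)


# -- data consistency --------------------------------------------------------


def test_dc_identical_inputs_zero(rng):
    meas = rng.normal(size=(2, 3, 4)) + 1j * rng.normal(size=(2, 3, 4))
    val = loss_data_consistency(meas.real, meas.imag, meas)
    assert val.item() == 0.0


def test_dc_unit_residual_convention():
    meas = np.zeros((4, 4), complex)
    pred_re = np.ones((4, 4))
    pred_im = np.zeros((4, 4))
    # residual 1+0j everywhere -> (|1| + |0|)/2 = 0.5
    assert loss_data_consistency(pred_re, pred_im, meas).item() == 0.5


def test_dc_homogeneity(rng):
    meas = np.zeros((3, 5), complex)
    re = rng.normal(size=(3, 5))
    im = rng.normal(size=(3, 5))
    one = loss_data_consistency(re, im, meas).item()
    three = loss_data_consistency(3 * re, 3 * im, meas).item()
    assert three == pytest.approx(3 * one)


def test_dc_shape_mismatch_rejected(rng):
    with pytest.raises(ValueError):
        loss_data_consistency(np.zeros((2, 2)), np.zeros((2, 2)),
                              np.zeros((3, 3), complex))


# -- total variation ---------------------------------------------------------


def test_tv_constant_zero():
    assert loss_tv(np.full((5, 5, 5), 3.0)).item() == 0.0


def test_tv_ramp_closed_form():
    n = 6
    ramp = np.broadcast_to(2.5 * np.arange(n)[:, None, None],
                           (n, n, n)).copy()
    # (n-1)*n*n interior differences of 2.5 each, divided by n^3 voxels
    expected = 2.5 * (n - 1) * n * n / n ** 3
    assert loss_tv(ramp).item() == pytest.approx(expected)


def test_tv_matches_dense_loop(rng):
    vol = rng.normal(size=(6, 5, 4))
    total = 0.0
    for ax in range(3):
        total += np.abs(np.diff(vol, axis=ax)).sum()
    assert loss_tv(vol).item() == pytest.approx(total / vol.size, rel=1e-12)


def test_tv_gradient(rng):
    vol = Tensor(rng.normal(size=(4, 4, 3)), requires_grad=True)

    def loss():
        return loss_tv(vol)

    loss().backward()
    num = numeric_gradient(loss, vol, eps=1e-7)
    assert np.allclose(vol.grad, num, atol=1e-5)


# -- basis norm / zero-mean --------------------------------------------------


def test_mbc_norm_unit_fields_zero(rng):
    fields = []
    for _ in range(9):
        f = rng.normal(size=(4, 4, 4))
        fields.append(f / np.linalg.norm(f))
    assert loss_mbc_norm(fields).item() == pytest.approx(0.0, abs=1e-12)


def test_mbc_norm_zero_fields_one():
    fields = [np.zeros((4, 4, 4))] * 9
    assert loss_mbc_norm(fields).item() == 1.0


def test_mbc_norm_one_field_norm_two(rng):
    fields = []
    for i in range(9):
        f = rng.normal(size=(4, 4, 4))
        f /= np.linalg.norm(f)
        if i == 0:
            f *= np.sqrt(2.0)     # ||e||^2 = 2
        fields.append(f)
    assert loss_mbc_norm(fields).item() == pytest.approx(1.0 / 9.0)


def test_zero_mean_antisymmetric_scores_zero():
    t = np.linspace(0, 2 * np.pi, 16, endpoint=False)
    scores = np.stack([np.sin(t + 0.3 * i) for i in range(9)], axis=1)
    scores -= scores.mean(axis=0, keepdims=True)
    assert loss_zero_mean(scores).item() == pytest.approx(0.0, abs=1e-24)


def test_zero_mean_constant_scores():
    c = 1.7
    scores = np.full((12, 9), c)
    assert loss_zero_mean(scores).item() == pytest.approx(c ** 2)


def test_zero_mean_homogeneity(rng):
    scores = rng.normal(size=(10, 9))
    one = loss_zero_mean(scores).item()
    assert loss_zero_mean(2 * scores).item() == pytest.approx(4 * one)


# -- Jacobian ----------------------------------------------------------------


def test_jacobian_loss_zero_dvf():
    grid = VoxelGrid((6, 6, 6), (2.0, 2.0, 2.0))
    det = jacobian_determinant(np.zeros(grid.shape + (3,)), grid)
    roi = np.ones(grid.shape, bool)
    assert loss_jacobian([det], roi).item() == 0.0


def test_jacobian_loss_uniform_dilation_closed_form():
    grid = VoxelGrid((8, 8, 8), (2.0, 2.0, 2.0))
    alpha = 0.05
    x, y, z = grid.coords()
    dvf = np.stack(np.broadcast_arrays(alpha * x, alpha * y, alpha * z),
                   axis=-1)
    det = jacobian_determinant(dvf, grid)
    roi = np.zeros(grid.shape, bool)
    roi[2:-2, 2:-2, 2:-2] = True      # interior: central differences exact
    expected = ((1 + alpha) ** 3 - 1) ** 2
    assert loss_jacobian([det], roi).item() == pytest.approx(expected)


def test_jacobian_loss_matches_dense_loop(rng):
    grid = VoxelGrid((5, 5, 5), (2.0, 2.0, 3.0))
    dets = [rng.normal(size=grid.shape) for _ in range(3)]
    roi = rng.random(grid.shape) > 0.4
    manual = np.mean([((d[roi] - 1) ** 2).mean() for d in dets])
    assert loss_jacobian(dets, roi).item() == pytest.approx(manual, rel=1e-12)


def test_jacobian_loss_empty_roi_rejected():
    with pytest.raises(ValueError):
        loss_jacobian([np.ones((3, 3, 3))], np.zeros((3, 3, 3), bool))


# -- frequency bands ---------------------------------------------------------


FULL_SCALE_CONFIG = AcquisitionConfig(tr_ms=4.5, n_kz=94, n_readout=368,
                                n_coils=8, n_stacks=673)


def test_score_sampling_rate_printed_protocol():
    assert FULL_SCALE_CONFIG.score_sampling_rate_hz == pytest.approx(2.3641, abs=2e-4)
    assert FULL_SCALE_CONFIG.nyquist_hz == pytest.approx(1.1820, abs=1e-4)


def test_fold_reference_frequency_oracle():
    fs = FULL_SCALE_CONFIG.score_sampling_rate_hz
    f = 60.7353
    # brute-force folding: subtract fs until within [0, fs), mirror about fN
    r = f % fs
    expected = r if r <= fs / 2 else fs - r
    assert fold_frequency(f, fs) == pytest.approx(expected, abs=1e-12)
    assert 0.0 <= fold_frequency(f, fs) <= fs / 2


def test_fold_below_nyquist_unchanged():
    fs = 2.0
    assert fold_frequency(0.3, fs) == pytest.approx(0.3)


@settings(max_examples=60, deadline=None)
@given(st.floats(min_value=0.0, max_value=500.0),
       st.floats(min_value=0.5, max_value=10.0))
def test_folding_idempotent(f, fs):
    once = fold_frequency(f, fs)
    assert fold_frequency(once, fs) == pytest.approx(once, abs=1e-9)
    assert 0.0 <= once <= fs / 2 + 1e-12


def test_build_bands_structure():
    bands = build_frequency_bands(FULL_SCALE_CONFIG)
    fn = FULL_SCALE_CONFIG.nyquist_hz
    assert bands.n_peaks >= 1
    for lo, hi in bands.target:
        assert 0.0 <= lo <= hi <= fn
    assert len(bands.baseline) == 2 * bands.n_peaks


def test_build_bands_half_width_guard():
    with pytest.raises(ValueError):
        build_frequency_bands(FULL_SCALE_CONFIG, half_width_hz=1.0)


def test_loss_frequency_flat_spectrum_near_zero():
    cfg = AcquisitionConfig(tr_ms=4.5, n_kz=94, n_readout=16, n_coils=1,
                            n_stacks=64)
    bands = build_frequency_bands(cfg, half_width_hz=0.05)
    # impulse at t=0 has an exactly flat magnitude spectrum
    scores = np.zeros((64, 9))
    scores[0, :] = 1.0
    val = loss_frequency(scores - scores.mean(0), bands).item()
    assert val < 1e-9


def test_loss_frequency_sinusoid_in_band():
    cfg = AcquisitionConfig(tr_ms=4.5, n_kz=94, n_readout=16, n_coils=1,
                            n_stacks=128)
    fs = cfg.score_sampling_rate_hz
    bands = build_frequency_bands(cfg, half_width_hz=0.05)
    lo, hi = bands.target[0]
    center = (lo + hi) / 2
    # snap to the nearest DFT bin inside the band
    freqs = np.fft.rfftfreq(128, d=1 / fs)
    bin_f = freqs[np.argmin(np.abs(freqs - center))]
    t = np.arange(128) / fs
    scores = np.zeros((128, 9))
    scores[:, 0] = np.sin(2 * np.pi * bin_f * t)
    val = loss_frequency(scores, bands).item()
    assert val > 0
    # adding a sinusoid far outside all bands leaves the loss unchanged
    far = freqs[np.argmin(np.abs(freqs - 0.9 * fs / 2))]
    in_any = any(lo2 - (hi2 - lo2) <= far <= hi2 + (hi2 - lo2)
                 for lo2, hi2 in bands.target)
    if not in_any:
        scores2 = scores.copy()
        scores2[:, 1] += np.sin(2 * np.pi * far * t)
        assert loss_frequency(scores2, bands).item() == pytest.approx(
            val, rel=1e-9)


def test_loss_frequency_gradient(rng):
    cfg = AcquisitionConfig(tr_ms=4.5, n_kz=94, n_readout=16, n_coils=1,
                            n_stacks=32)
    bands = build_frequency_bands(cfg)
    scores = Tensor(rng.normal(size=(32, 9)), requires_grad=True)

    def loss():
        return loss_frequency(scores, bands)

    loss().backward()
    num = numeric_gradient(loss, scores, eps=1e-6)
    rel = np.abs(scores.grad - num).max() / (np.abs(num).max() + 1e-12)
    assert rel < 1e-4


# -- ROI ---------------------------------------------------------------------


def test_roi_bright_cube_exact():
    vol = np.zeros((12, 12, 12))
    vol[3:9, 3:9, 3:9] = 1.0
    roi = roi_from_reference(vol, threshold_fraction=0.5)
    assert np.array_equal(roi.mask, vol > 0.5)


def test_roi_threshold_contract():
    with pytest.raises(ValueError):
        roi_from_reference(np.ones((4, 4, 4)), threshold_fraction=0.0)
    with pytest.raises(ValueError):
        roi_from_reference(np.ones((4, 4, 4)), threshold_fraction=1.0)


def test_roi_keeps_largest_component_and_fills_holes():
    vol = np.zeros((16, 16, 16))
    vol[2:12, 2:12, 2:12] = 1.0
    vol[5:8, 5:8, 5:8] = 0.0          # hole -> filled
    vol[14:16, 14:16, 14:16] = 1.0    # small distant blob -> dropped
    roi = roi_from_reference(vol, threshold_fraction=0.5)
    assert roi.mask[6, 6, 6]
    assert not roi.mask[15, 15, 15]


def test_roi_phantom_body_volume():
    # thresholding at half the body magnitude recovers the soft edge's
    # midpoint, i.e. the analytic boundary
    from splatmri.phantom import (MotionScenario, build_torso_phantom,
                                  render_ground_truth)
    grid = VoxelGrid((64, 64, 32), (3.0, 3.0, 3.5))
    anatomy = build_torso_phantom(grid, seed=5, texture_scale=0.0)
    truth = render_ground_truth(
        anatomy, MotionScenario("X1", si_amplitude_mm=0, ap_amplitude_mm=0),
        1, 423.0)
    mag = np.abs(truth.frames[0])
    body = anatomy.organ("body")
    frac = 0.5 * body.magnitude / np.percentile(mag, 99)
    roi = roi_from_reference(mag, threshold_fraction=frac)
    analytic = 4.0 / 3.0 * np.pi * np.prod(body.radii_mm)
    assert roi.n_voxels * np.prod(grid.spacing) == pytest.approx(analytic,
                                                                 rel=0.05)
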