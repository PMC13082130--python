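import numpy as np
import pytest

from splatmri.acquisition import (GOLDEN_ANGLE_DEG, AcquisitionConfig,
                                  SosOperator, extract_mlp_navigator,
                                  fit_normalization, make_cnn_projection,
                                  make_sos_trajectory, motion_averaged_recon,
                                  simulate_acquisition, simulate_coil_maps)
from splatmri.grids import VoxelGrid


@pytest.fixture
def small_traj():
    cfg = AcquisitionConfig(tr_ms=4.5, n_kz=4, n_readout=4, n_coils=2,
                            n_stacks=6)
    return make_sos_trajectory(cfg)


def test_stack_duration_and_scan_length():
    cfg = AcquisitionConfig(tr_ms=4.5, n_kz=94, n_readout=368, n_coils=8,
                            n_stacks=673)
    assert cfg.stack_duration_ms == pytest.approx(423.0)
    assert cfg.scan_duration_min == pytest.approx(4.74, abs=0.01)


def test_full_scale_trajectory_shape():
    cfg = AcquisitionConfig(n_kz=94, n_readout=368, n_coils=8, n_stacks=673)
    traj = make_sos_trajectory(cfg)
    assert traj.angles_rad.shape == (673,)
    assert traj.kz_indices.shape == (94,)
    assert traj.readout_cyc.shape == (368,)
    assert np.array_equal(np.sort(traj.kz_indices), np.arange(-47, 47))


def test_first_stack_angle_zero(small_traj):
    assert small_traj.angles_rad[0] == 0.0


def test_golden_angle_increment_closed_form():
    cfg = AcquisitionConfig(n_kz=4, n_readout=4, n_coils=1, n_stacks=50)
    traj = make_sos_trajectory(cfg)
    expected = 180.0 * (np.sqrt(5.0) - 1.0) / 2.0
    assert GOLDEN_ANGLE_DEG == pytest.approx(expected)
    assert GOLDEN_ANGLE_DEG == pytest.approx(111.2461, abs=1e-3)
    deg = np.rad2deg(traj.angles_rad)
    diffs = np.diff(deg) % 180.0
    assert np.allclose(diffs, expected % 180.0, atol=1e-9)


def test_angles_dense_fibonacci_gap_shrinks():
    def max_gap(n):
        cfg = AcquisitionConfig(n_kz=2, n_readout=4, n_coils=1, n_stacks=n)
        deg = np.sort(np.rad2deg(make_sos_trajectory(cfg).angles_rad))
        gaps = np.diff(np.r_[deg, deg[0] + 180.0])
        return gaps.max()

    gaps = [max_gap(n) for n in (8, 13, 21, 34)]
    assert all(g1 > g2 for g1, g2 in zip(gaps, gaps[1:]))


def test_timestamps_are_stack_midpoints(small_traj):
    cfg = small_traj.config
    expected = (np.arange(cfg.n_stacks) + 0.5) * cfg.tr_ms * cfg.n_kz
    assert np.allclose(small_traj.timestamps_ms, expected)


def test_spokes_pass_through_center(small_traj):
    for m in range(small_traj.n_stacks):
        k = small_traj.inplane_k_cyc(m)
        assert np.min(np.linalg.norm(k, axis=1)) == 0.0


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        AcquisitionConfig(tr_ms=0.0)
    with pytest.raises(ValueError):
        AcquisitionConfig(n_coils=0)


# -- coil maps ---------------------------------------------------------------


def test_uniform_coil_map_flag(small_grid):
    maps = simulate_coil_maps(small_grid, 1, seed=0, uniform=True)
    assert np.all(maps == 1.0)


def test_coil_maps_deterministic_and_nonzero(small_grid):
    a = simulate_coil_maps(small_grid, 8, seed=4)
    b = simulate_coil_maps(small_grid, 8, seed=4)
    assert np.array_equal(a, b)
    assert a.shape == (8,) + small_grid.shape
    rss = np.sqrt((np.abs(a) ** 2).sum(axis=0))
    assert np.all(rss > 0)


# -- forward / adjoint -------------------------------------------------------


def brute_force_stack(volume, maps, traj, grid, stack):
    k = traj.inplane_k_cyc(stack)
    nx, ny, nz = grid.shape
    kx = k[:, 0] / (nx * grid.spacing[0])
    ky = k[:, 1] / (ny * grid.spacing[1])
    kz = traj.kz_indices / (nz * grid.spacing[2])
    xc, yc, zc = (grid.axis_coords(i) for i in range(3))
    out = np.zeros((maps.shape[0], len(kz), len(kx)), dtype=np.complex128)
    for c in range(maps.shape[0]):
        w = maps[c] * volume
        for ik in range(len(kz)):
            for ir in range(len(kx)):
                phase = np.exp(-2j * np.pi * (
                    kx[ir] * xc[:, None, None] + ky[ir] * yc[None, :, None]
                    + kz[ik] * zc[None, None, :]))
                out[c, ik, ir] = (w * phase).sum()
    return out


def test_forward_matches_direct_dft(rng, small_traj):
    grid = VoxelGrid((4, 4, 4), (2.0, 2.0, 3.0))
    vol = rng.normal(size=grid.shape) + 1j * rng.normal(size=grid.shape)
    maps = simulate_coil_maps(grid, 2, seed=1)
    op = SosOperator(grid, small_traj)
    for stack in (0, 3):
        direct = brute_force_stack(vol, maps, small_traj, grid, stack)
        fast = op.forward(vol, maps, stack)
        rel = np.abs(fast - direct).max() / np.abs(direct).max()
        assert rel < 1e-5


def test_zero_volume_zero_samples(small_traj):
    grid = VoxelGrid((4, 4, 4), (2.0, 2.0, 3.0))
    maps = simulate_coil_maps(grid, 2, seed=1)
    op = SosOperator(grid, small_traj)
    out = op.forward(np.zeros(grid.shape, complex), maps, 0)
    assert np.all(out == 0)


def test_forward_linear(rng, small_traj):
    grid = VoxelGrid((4, 4, 4), (2.0, 2.0, 3.0))
    maps = simulate_coil_maps(grid, 2, seed=1)
    op = SosOperator(grid, small_traj)
    a = rng.normal(size=grid.shape) + 1j * rng.normal(size=grid.shape)
    b = rng.normal(size=grid.shape) + 1j * rng.normal(size=grid.shape)
    lhs = op.forward(2.0 * a + 3.0 * b, maps, 1)
    rhs = 2.0 * op.forward(a, maps, 1) + 3.0 * op.forward(b, maps, 1)
    assert np.allclose(lhs, rhs, atol=1e-9 * np.abs(rhs).max())


def test_hermitian_volume_conjugate_symmetric_samples(rng):
    # real, centro-symmetric volume -> s(-k) = conj(s(k)) on a symmetric spoke
    grid = VoxelGrid((5, 5, 5), (2.0, 2.0, 2.0))
    cfg = AcquisitionConfig(n_kz=5, n_readout=5, n_coils=1, n_stacks=1)
    traj = make_sos_trajectory(cfg)
    vol = rng.normal(size=grid.shape)
    vol = 0.5 * (vol + vol[::-1, ::-1, ::-1])   # symmetric about the center
    maps = simulate_coil_maps(grid, 1, seed=0, uniform=True)
    s = SosOperator(grid, traj).forward(vol.astype(complex), maps, 0)
    assert np.allclose(s[0], np.conj(s[0][::-1, ::-1]), atol=1e-9)


def test_adjoint_inner_product_identity(rng, small_traj):
    grid = VoxelGrid((8, 8, 4), (2.0, 2.0, 3.0))
    cfg = AcquisitionConfig(n_kz=4, n_readout=8, n_coils=3, n_stacks=4)
    traj = make_sos_trajectory(cfg)
    maps = simulate_coil_maps(grid, 3, seed=2)
    op = SosOperator(grid, traj)
    x = rng.normal(size=grid.shape) + 1j * rng.normal(size=grid.shape)
    y = rng.normal(size=(3, 4, 8)) + 1j * rng.normal(size=(3, 4, 8))
    lhs = np.vdot(y, op.forward(x, maps, 2))
    rhs = np.vdot(op.adjoint(y, maps, 2), x)
    assert abs(lhs - rhs) / abs(lhs) < 1e-6


def test_out_of_nyquist_rejected():
    grid = VoxelGrid((4, 4, 4), (2.0, 2.0, 3.0))
    cfg = AcquisitionConfig(n_kz=4, n_readout=16, n_coils=1, n_stacks=1)
    with pytest.raises(ValueError):
        SosOperator(grid, make_sos_trajectory(cfg))


# -- motion-averaged reconstruction -----------------------------------------


def test_motion_averaged_recon_zero_kspace(tiny_problem):
    acq = tiny_problem["acq"]
    import dataclasses
    silent = dataclasses.replace(acq, samples=np.zeros_like(acq.samples))
    assert np.all(motion_averaged_recon(silent, 1) == 0)


def test_motion_averaged_recon_static_correlates(tiny_problem):
    from splatmri.phantom import render_ground_truth, MotionScenario
    grid = tiny_problem["grid"]
    anatomy = tiny_problem["anatomy"]
    static = render_ground_truth(
        anatomy, MotionScenario("X1", si_amplitude_mm=0, ap_amplitude_mm=0),
        tiny_problem["config"].n_stacks,
        tiny_problem["config"].stack_duration_ms)
    acq = simulate_acquisition(static, tiny_problem["maps"],
                               tiny_problem["trajectory"], grid)
    iavg = motion_averaged_recon(acq, 1)
    ncc = np.corrcoef(np.abs(iavg).ravel(),
                      np.abs(static.frames[0]).ravel())[0, 1]
    assert ncc > 0.9


def test_motion_averaged_recon_coil_guard(tiny_problem):
    with pytest.raises(ValueError):
        motion_averaged_recon(tiny_problem["acq"], n_virtual_coils=99)


# -- encoder inputs ----------------------------------------------------------


def test_navigator_feature_lengths(tiny_problem):
    acq = tiny_problem["acq"]
    nav = extract_mlp_navigator(acq.samples[0], acq.trajectory, k_max=1)
    assert nav.shape == (3 * acq.trajectory.config.n_coils * 2,)


def test_navigator_lengths_match_protocol_arithmetic():
    # 3 central kz x 8 coils x (re, im) = 48; 9 central kz -> 144
    assert 3 * 8 * 2 == 48
    assert 9 * 8 * 2 == 144


def test_navigator_kmax_guard(tiny_problem):
    acq = tiny_problem["acq"]
    with pytest.raises(ValueError):
        extract_mlp_navigator(acq.samples[0], acq.trajectory, k_max=50)


def test_normalization_zscores_training_set(tiny_problem):
    acq = tiny_problem["acq"]
    stats = fit_normalization(acq.samples, acq.trajectory, k_max=1)
    feats = np.stack([
        extract_mlp_navigator(acq.samples[t], acq.trajectory, 1, stats)
        for t in range(acq.n_stacks)])
    assert np.allclose(feats.mean(axis=0), 0.0, atol=1e-10)
    live = stats.std > stats.eps
    assert np.allclose(feats.std(axis=0)[live], 1.0, atol=1e-8)


def test_normalization_constant_channel_maps_to_zero():
    from splatmri.acquisition import NormalizationStats
    stats = NormalizationStats(mean=np.array([5.0]), std=np.array([0.0]))
    assert stats.apply(np.array([5.0]))[0] == 0.0


def test_normalization_needs_two_stacks(tiny_problem):
    acq = tiny_problem["acq"]
    with pytest.raises(ValueError):
        fit_normalization(acq.samples[:1], acq.trajectory, k_max=1)


def test_projection_zero_fill_identity():
    rng = np.random.default_rng(0)
    plane = rng.normal(size=(1, 3, 6)) + 1j * rng.normal(size=(1, 3, 6))
    proj = make_cnn_projection(plane)
    expected = np.abs(np.fft.fftshift(np.fft.ifft2(
        np.fft.ifftshift(plane[0]))))
    assert np.allclose(proj, expected, atol=1e-12)


def test_projection_rss_coil_scaling(tiny_problem):
    acq = tiny_problem["acq"]
    one = make_cnn_projection(acq.samples[0][:1])
    two = make_cnn_projection(np.concatenate([acq.samples[0][:1]] * 2))
    assert np.allclose(two, np.sqrt(2.0) * one, atol=1e-10)


def test_projection_zero_stack(tiny_problem):
    shape = tiny_problem["acq"].samples[0].shape
    assert np.all(make_cnn_projection(np.zeros(shape, complex)) == 0)


def test_projection_patch_guard():
    with pytest.raises(ValueError):
        make_cnn_projection(np.zeros((1, 2, 4), complex))
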