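import numpy as np
import pytest

from splatmri.acquisition import (AcquisitionConfig, make_sos_trajectory,
                                  simulate_acquisition, simulate_coil_maps)
from splatmri.grids import VoxelGrid
from splatmri.phantom import (MotionScenario, build_torso_phantom,
                              render_ground_truth)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return VoxelGrid((8, 8, 8), (2.0, 2.0, 3.0))


@pytest.fixture
def desk_grid():
    return VoxelGrid((24, 24, 12), (8.0, 8.0, 10.0))


@pytest.fixture(scope="session")
def tiny_problem():
    """A small simulated acquisition shared by slow-ish tests."""
    grid = VoxelGrid((16, 16, 8), (12.0, 12.0, 14.0))
    cfg = AcquisitionConfig(tr_ms=4.5, n_kz=8, n_readout=16, n_coils=3,
                            n_stacks=12)
    traj = make_sos_trajectory(cfg)
    anatomy = build_torso_phantom(grid, seed=5, texture_scale=0.0)
    truth = render_ground_truth(
        anatomy, MotionScenario("X1", si_amplitude_mm=8, ap_amplitude_mm=4,
                                period_s=1.5),
        cfg.n_stacks, cfg.stack_duration_ms)
    maps = simulate_coil_maps(grid, cfg.n_coils, seed=2)
    acq = simulate_acquisition(truth, maps, traj, grid, seed=3)
    return {"grid": grid, "config": cfg, "trajectory": traj,
            "anatomy": anatomy, "truth": truth, "maps": maps, "acq": acq}


def numeric_gradient(build_loss, param, eps=1e-6):
    """Central-difference gradient of a scalar loss wrt a Tensor param."""
    num = np.zeros_like(param.data)
    it = np.nditer(param.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = param.data[i]
        param.data[i] = orig + eps
        lp = build_loss().item()
        param.data[i] = orig - eps
        lm = build_loss().item()
        param.data[i] = orig
        num[i] = (lp - lm) / (2 * eps)
    return num
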