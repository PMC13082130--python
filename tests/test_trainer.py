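import dataclasses

import numpy as np
import pytest

from splatmri.motion import ScoreSequence
from splatmri.trainer import (REFERENCE_EPOCHS, StageSchedule, TrainedModel,
                              finalize_model, initialize_state, perturb_scores,
                              run_full_training, stage_1a, stage_2, stage_3a,
                              stage_3b, stage_4_augment, stage_1b)

TINY = dict(epochs=(10, 4, 12, 15, 6, 6), n_reference_points=250,
            mbc_levels=(2, 3, 4), batch_stacks=3)


@pytest.fixture(scope="module")
def tiny_trained(tiny_problem):
    acq = tiny_problem["acq"]
    schedule = StageSchedule.desk(seed=0, **TINY)
    state, iavg = initialize_state(acq, schedule)
    stage_1a(state, iavg)
    stage_1b(state, acq)
    stage_2(state, acq)
    return state, acq


def test_reference_schedule_matches_protocol():
    sched = StageSchedule()
    assert sched.epochs == REFERENCE_EPOCHS == (400, 300, 1200, 5000, 1500,
                                                1000)
    assert sched.lr_cnn_warmup == 2e-3
    assert sched.lr_cnn == 1e-4
    assert sched.lr_mlp == 5e-4
    assert sched.r1_range == (0.2, 2.6)
    assert sched.r2_range == (0.4, 1.6)
    w = sched.weights
    assert (w.tv, w.mbc, w.zms, w.jac, w.freq) == (2e-6, 1e-2, 1e-4, 1e-1, 1.0)


def test_schedule_validation():
    with pytest.raises(ValueError):
        StageSchedule(epochs=(-1, 0, 0, 0, 0, 0))
    with pytest.raises(ValueError):
        StageSchedule(lr_mlp=0.0)


# -- stage I -----------------------------------------------------------------


def test_stage_1a_reduces_image_loss(tiny_problem):
    acq = tiny_problem["acq"]
    schedule = StageSchedule.desk(seed=1, **{**TINY, "epochs":
                                             (250, 0, 0, 0, 0, 0)})
    state, iavg = initialize_state(acq, schedule)
    stage_1a(state, iavg)
    losses = [h["loss"] for h in state.history if h["stage"] == "1a"]
    assert losses[-1] < 0.2 * losses[0]


def test_stage_1a_zero_target_shrinks_densities(tiny_problem):
    acq = tiny_problem["acq"]
    schedule = StageSchedule.desk(seed=1, **{**TINY, "epochs":
                                             (40, 0, 0, 0, 0, 0)})
    state, _ = initialize_state(acq, schedule)
    before = np.abs(state.ref_cloud.densities.data).mean()
    stage_1a(state, np.zeros(acq.grid.shape, complex))
    after = np.abs(state.ref_cloud.densities.data).mean()
    assert after < 0.5 * before


def test_stage_1b_decreases_data_consistency(tiny_trained):
    state, _ = tiny_trained
    losses = [h["dc"] for h in state.history if h["stage"] == "1b"]
    assert losses[-1] <= losses[0]


# -- freezing contracts ------------------------------------------------------


def test_stage_3a_freezes_reference_mbc_and_mlp(tiny_trained, tiny_problem):
    state, acq = tiny_trained
    ref_before = {k: v.copy() for k, v in state.ref_cloud.state_dict().items()}
    mbc_before = [c.state_dict() for c in state.mbc_clouds]
    mlp_before = state.mlp.state_dict()
    stage_3a(state, acq)
    for k, v in state.ref_cloud.state_dict().items():
        assert np.array_equal(v, ref_before[k])
    for c, before in zip(state.mbc_clouds, mbc_before):
        for k, v in c.state_dict().items():
            assert np.array_equal(v, before[k])
    for k, v in state.mlp.state_dict().items():
        assert np.array_equal(v, mlp_before[k])


def test_stage_4_freezes_reference_and_mbc(tiny_trained, tiny_problem):
    state, acq = tiny_trained
    stage_3b(state, acq)
    ref_before = {k: v.copy() for k, v in state.ref_cloud.state_dict().items()}
    mbc_before = [c.state_dict() for c in state.mbc_clouds]
    cnn_before = state.cnn.state_dict()
    stage_4_augment(state, acq)
    for k, v in state.ref_cloud.state_dict().items():
        assert np.array_equal(v, ref_before[k])
    for c, before in zip(state.mbc_clouds, mbc_before):
        for k, v in c.state_dict().items():
            assert np.array_equal(v, before[k])
    # the CNN, by contrast, must have moved
    assert any(not np.array_equal(v, cnn_before[k])
               for k, v in state.cnn.state_dict().items())


# -- score perturbation ------------------------------------------------------


def make_scores(values):
    arr = np.asarray(values, dtype=float)
    return ScoreSequence(scores=arr, timestamps_ms=np.arange(arr.shape[0]))


def test_perturb_identity_ranges():
    seq = make_scores(np.random.default_rng(0).normal(size=(6, 9)))
    out = perturb_scores(seq, r1_range=(1.0, 1.0), r2_range=(1.0, 1.0))
    assert np.allclose(out.scores, seq.scores)


def test_perturb_arithmetic():
    seq = make_scores(np.full((3, 9), 2.0))
    out = perturb_scores(seq, r1_range=(0.5, 0.5), r2_range=(1.5, 1.5))
    assert np.allclose(out.scores, 1.5)


def test_perturb_r1_shared_across_channels():
    rngseq = make_scores(np.ones((5, 9)))
    out = perturb_scores(rngseq, r1_range=(0.2, 2.6), r2_range=(1.0, 1.0),
                         seed=3)
    ratio = out.scores / rngseq.scores
    # r1 varies over time but is constant across the nine channels
    assert np.allclose(ratio.std(axis=1), 0.0)
    assert ratio.std(axis=0).max() > 0


def test_perturb_si_only_keeps_other_channels():
    seq = make_scores(np.random.default_rng(1).normal(size=(4, 9)))
    out = perturb_scores(seq, r1_range=(2.0, 2.0), r2_range=(1.0, 1.0),
                         si_only=True)
    keep = [0, 1, 3, 4, 6, 7]
    z = [2, 5, 8]
    assert np.allclose(out.scores[:, keep], seq.scores[:, keep])
    assert not np.allclose(out.scores[:, z], seq.scores[:, z])


def test_perturb_default_ranges_match_protocol():
    sched = StageSchedule()
    assert sched.r1_range == (0.2, 2.6)
    assert sched.r2_range == (0.4, 1.6)


# -- full pipeline -----------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_model(tiny_problem):
    acq = tiny_problem["acq"]
    return run_full_training(acq, StageSchedule.desk(seed=2, **TINY))


def test_full_training_outputs(tiny_model, tiny_problem):
    acq = tiny_problem["acq"]
    model = tiny_model
    assert model.scores.shape == (acq.n_stacks, 9)
    assert model.basis_fields.shape == (9,) + acq.grid.shape
    assert model.reference_volume.shape == acq.grid.shape
    vol = model.dynamic_volume(0)
    assert vol.shape == acq.grid.shape and np.iscomplexobj(vol)


def test_checkpoint_roundtrip_reproduces_scores(tiny_model, tmp_path):
    from splatmri.io import load_checkpoint, save_checkpoint
    path = tmp_path / "ckpt.h5"
    save_checkpoint(path, tiny_model.checkpoint_state())
    loaded = TrainedModel.from_checkpoint_state(load_checkpoint(path))
    assert np.allclose(loaded.scores, tiny_model.scores)
    assert np.allclose(loaded.reference_volume, tiny_model.reference_volume)
    assert np.allclose(loaded.basis_fields, tiny_model.basis_fields)


def test_training_determinism(tiny_problem):
    acq = tiny_problem["acq"]
    micro = dict(epochs=(4, 2, 4, 4, 2, 2), n_reference_points=100,
                 mbc_levels=(2, 3, 4), batch_stacks=2)
    a = run_full_training(acq, StageSchedule.desk(seed=9, **micro))
    b = run_full_training(acq, StageSchedule.desk(seed=9, **micro))
    sa, sb = a.checkpoint_state(), b.checkpoint_state()

    def compare(x, y):
        if isinstance(x, dict):
            assert set(x) == set(y)
            for k in x:
                compare(x[k], y[k])
        elif isinstance(x, np.ndarray):
            assert np.array_equal(x, y)
        else:
            assert x == y

    compare(sa, sb)
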