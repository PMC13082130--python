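"""Progressive staged optimization of the reference cloud, motion basis
clouds, and the dual-path motion encoder.

Stages (epoch counts from the reference configuration, adjustable for desk
scale):

* I(a)  image-domain L1 fit of the complex reference cloud to the
        motion-averaged volume (reference parameters only);
* I(b)  k-space data consistency over all spokes + total variation
        (reference parameters only, no motion);
* II    joint reference + basis clouds + MLP encoder at half in-plane
        resolution, each stack's spokes pooled with its two temporal
        neighbors under the center stack's motion state;
* III(a) CNN encoder distillation to the frozen MLP's scores;
* III(b) joint refinement at native resolution, one stack per motion
        state, CNN-driven, plus the frequency regularizer;
* IV    motion augmentation: reference and basis clouds frozen, the CNN
        is fine-tuned on synthetically perturbed scores rendered through
        the full acquisition model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

from .acquisition import (AcquisitionConfig, NormalizationStats, SOSAcquisition,
                          SOSTrajectory, SosOperator, extract_mlp_navigator,
                          fit_normalization, make_cnn_projection,
                          motion_averaged_recon)
from .autodiff import Adam, Tensor, no_grad
from .encoders import CNNEncoder, MLPEncoder
from .gaussians import (DEFAULT_MBC_LEVELS, DEFAULT_REFERENCE_POINTS,
                        FrozenVoxelizer, GaussianCloud, init_mbc_clouds,
                        init_reference_cloud, voxelize)
from .grids import VoxelGrid
from .motion import (ScoreSequence, compose_dvf, compose_dvf_tensor,
                     jacobian_determinant_tensor, warp_volume,
                     warp_volume_tensor)
from .objectives import (LossWeights, build_frequency_bands, loss_data_consistency,
                         loss_frequency, loss_jacobian, loss_mbc_norm,
                         loss_tv, loss_zero_mean, roi_from_reference)

__all__ = [
    "StageSchedule", "TrainState", "TrainedModel", "StageDivergence",
    "initialize_state", "stage_1a", "stage_1b", "stage_2", "stage_3a",
    "stage_3b", "perturb_scores", "stage_4_augment", "run_full_training",
    "finalize_model",
]

REFERENCE_EPOCHS = (400, 300, 1200, 5000, 1500, 1000)


class StageDivergence(RuntimeError):
    """Raised when a stage's loss blows past 10x its initial value."""

    def __init__(self, stage: str, initial: float, current: float):
        super().__init__(f"stage {stage} diverged: loss {current:.3e} "
                         f"(initial {initial:.3e})")
        self.stage = stage


@dataclass(frozen=True)
class StageSchedule:
    """Epochs, rates, weights, and resolution policy for all stages."""

    epochs: tuple[int, int, int, int, int, int] = REFERENCE_EPOCHS
    lr_mlp: float = 5e-4            # torso/clinical setting
    lr_cnn_warmup: float = 2e-3     # Stage III(a)
    lr_cnn: float = 1e-4            # later stages
    lr_positions: float = 2e-4
    lr_log_scales: float = 5e-3
    lr_quaternions: float = 1e-3
    lr_densities: float = 1e-2
    weights: LossWeights = field(default_factory=LossWeights)
    stage2_downsample: int = 2
    stage2_merge_radius: int = 1
    batch_stacks: int = 6           # stacks per optimization step
    n_reference_points: int = DEFAULT_REFERENCE_POINTS
    mbc_levels: tuple = DEFAULT_MBC_LEVELS
    navigator_kmax: int = 1         # three central kz partitions
    mlp_hidden: tuple[int, int] = (64, 64)
    r1_range: tuple[float, float] = (0.2, 2.6)
    r2_range: tuple[float, float] = (0.4, 1.6)
    si_only_augment: bool = False
    truncation_sigmas: float = 4.0
    mbc_geometry_frozen: bool = False   # densities-only MBC training (fast path)
    mbc_sigma_factor: float = 0.5       # kernel width / lattice pitch
    seed: int = 0

    def __post_init__(self):
        if any(e < 0 for e in self.epochs):
            raise ValueError("epoch counts must be >= 0")
        for r in (self.lr_mlp, self.lr_cnn, self.lr_cnn_warmup):
            if r <= 0:
                raise ValueError("learning rates must be positive")

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "StageSchedule":
        """Scaled-down schedule for CPU-sized experiments."""
        defaults = dict(
            epochs=(100, 20, 180, 300, 90, 120),
            n_reference_points=1400,
            mbc_levels=(3, 4, 6),
            mbc_sigma_factor=0.8,
            batch_stacks=5,
            truncation_sigmas=3.0,
            lr_mlp=5e-3,           # few desk steps need a larger rate
            lr_cnn=5e-4,
            mbc_geometry_frozen=True,
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class TrainState:
    """Everything the stages mutate."""

    grid: VoxelGrid
    schedule: StageSchedule
    ref_cloud: GaussianCloud
    mbc_clouds: list[GaussianCloud]
    mlp: MLPEncoder
    cnn: CNNEncoder
    stats: NormalizationStats
    rng: np.random.Generator
    iavg: np.ndarray | None = None
    roi: np.ndarray | None = None
    solved_scores: np.ndarray | None = None
    history: list[dict] = field(default_factory=list)
    stages_run: list[str] = field(default_factory=list)

    def log(self, stage: str, epoch: int, **parts) -> None:
        self.history.append({"stage": stage, "epoch": epoch, **parts})


# ---------------------------------------------------------------------------
# setup helpers


def _ref_param_groups(sched: StageSchedule, cloud: GaussianCloud):
    return [([cloud.positions], sched.lr_positions),
            ([cloud.log_scales], sched.lr_log_scales),
            ([cloud.quaternions], sched.lr_quaternions),
            ([cloud.densities], sched.lr_densities)]


def _make_optimizer(groups) -> Adam:
    opt = Adam([], lr=1.0)
    for params, lr in groups:
        opt.add_group(params, lr)
    return opt


def _navigators(acq: SOSAcquisition, k_max: int,
                stats: NormalizationStats) -> np.ndarray:
    return np.stack([
        extract_mlp_navigator(acq.samples[t], acq.trajectory, k_max, stats)
        for t in range(acq.n_stacks)])


def _projections(acq: SOSAcquisition) -> np.ndarray:
    return np.stack([make_cnn_projection(acq.samples[t])
                     for t in range(acq.n_stacks)])


def _downsample_inplane(vol: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean in-plane downsampling (leading axes preserved)."""
    *lead, nx, ny, nz = vol.shape
    f = factor
    return vol.reshape(*lead, nx // f, f, ny // f, f, nz).mean(axis=(-4, -2))


def _low_res_problem(acq: SOSAcquisition, factor: int):
    """Halved in-plane grid plus the matching reduced-Nyquist k-space."""
    grid_lo = acq.grid.downsample_inplane(factor)
    # cycles/FOV are resolution-independent (the FOV is preserved); only
    # samples beyond the reduced Nyquist box are dropped
    keep = np.abs(acq.trajectory.readout_cyc) <= min(grid_lo.shape[:2]) / 2
    traj_lo = replace(
        acq.trajectory, readout_cyc=acq.trajectory.readout_cyc[keep],
        config=replace(acq.trajectory.config,
                       n_readout=int(keep.sum())))
    samples_lo = acq.samples[:, :, :, keep]
    maps_lo = _downsample_inplane(acq.coil_maps, factor)
    return grid_lo, traj_lo, samples_lo, maps_lo


def initialize_state(acq: SOSAcquisition, schedule: StageSchedule,
                     ) -> tuple[TrainState, np.ndarray]:
    """Motion-averaged reconstruction and all component initializations."""
    rng = np.random.default_rng(schedule.seed)
    iavg = motion_averaged_recon(acq, n_virtual_coils=1)
    ref = init_reference_cloud(iavg, acq.grid, schedule.n_reference_points,
                               seed=schedule.seed).requires_grad_()
    mbc = [c.requires_grad_() for c in
           init_mbc_clouds(acq.grid, schedule.mbc_levels,
                           sigma_factor=schedule.mbc_sigma_factor)]
    stats = fit_normalization(acq.samples, acq.trajectory,
                              schedule.navigator_kmax)
    n_feat = (2 * schedule.navigator_kmax + 1) * acq.trajectory.config.n_coils * 2
    mlp = MLPEncoder(n_feat, hidden=schedule.mlp_hidden, seed=schedule.seed + 1)
    cnn = CNNEncoder(seed=schedule.seed + 2)
    roi = roi_from_reference(np.abs(iavg)).mask
    state = TrainState(grid=acq.grid, schedule=schedule, ref_cloud=ref,
                       mbc_clouds=mbc, mlp=mlp, cnn=cnn, stats=stats,
                       rng=rng, iavg=iavg, roi=roi)
    return state, iavg


# ---------------------------------------------------------------------------
# stages


def _guard(stage: str, initial: float | None, current: float) -> float:
    if initial is None:
        return current
    if np.isfinite(initial) and current > 10.0 * max(abs(initial), 1e-12):
        raise StageDivergence(stage, initial, current)
    return initial


def stage_1a(state: TrainState, iavg: np.ndarray) -> TrainState:
    """Image-domain L1 fit of the reference cloud to the averaged volume."""
    sched = state.schedule
    epochs = sched.epochs[0]
    opt = _make_optimizer(_ref_param_groups(sched, state.ref_cloud))
    target_re = Tensor(iavg.real)
    target_im = Tensor(iavg.imag)
    initial = None
    for epoch in range(epochs):
        opt.zero_grad()
        vox = voxelize(state.ref_cloud, state.grid, sched.truncation_sigmas)
        loss = ((vox[0] - target_re).abs().mean()
                + (vox[1] - target_im).abs().mean()) * 0.5
        loss.backward()
        opt.step()
        val = loss.item()
        initial = _guard("I(a)", initial, val)
        state.log("1a", epoch, loss=val)
    state.stages_run.append("1a")
    return state


def _dc_stack(op: SosOperator, vol_re: Tensor, vol_im: Tensor,
              coil_maps: np.ndarray, stack: int, measured: np.ndarray):
    pre, pim = op.forward_tensor(vol_re, vol_im, coil_maps, stack)
    return loss_data_consistency(pre, pim, measured)


def stage_1b(state: TrainState, acq: SOSAcquisition) -> TrainState:
    """k-space data consistency + TV, still motion-free."""
    sched = state.schedule
    epochs = sched.epochs[1]
    opt = _make_optimizer(_ref_param_groups(sched, state.ref_cloud))
    op = SosOperator(state.grid, acq.trajectory)
    initial = None
    for epoch in range(epochs):
        stacks = state.rng.choice(acq.n_stacks,
                                  size=min(sched.batch_stacks, acq.n_stacks),
                                  replace=False)
        opt.zero_grad()
        vox = voxelize(state.ref_cloud, state.grid, sched.truncation_sigmas)
        dc = None
        for t in stacks:
            term = _dc_stack(op, vox[0], vox[1], acq.coil_maps, int(t),
                             acq.samples[t])
            dc = term if dc is None else dc + term
        dc = dc / float(len(stacks))
        tv = loss_tv(vox[0], vox[1])
        loss = dc + sched.weights.tv * tv
        loss.backward()
        opt.step()
        val = loss.item()
        initial = _guard("I(b)", initial, val)
        state.log("1b", epoch, loss=val, dc=dc.item(), tv=tv.item())
    state.stages_run.append("1b")
    return state


def _mbc_field_fn(state: TrainState, grid: VoxelGrid):
    """Returns a closure producing the 9 voxelized basis-field Tensors."""
    sched = state.schedule
    if sched.mbc_geometry_frozen:
        voxelizers = [FrozenVoxelizer(c, grid, sched.truncation_sigmas)
                      for c in state.mbc_clouds]
        return lambda: [vx(c.densities)
                        for vx, c in zip(voxelizers, state.mbc_clouds)]
    return lambda: [voxelize(c, grid, sched.truncation_sigmas)[0]
                    for c in state.mbc_clouds]


def _mbc_param_groups(state: TrainState):
    sched = state.schedule
    groups = []
    for c in state.mbc_clouds:
        if sched.mbc_geometry_frozen:
            groups.append(([c.densities], sched.lr_densities))
        else:
            groups += _ref_param_groups(sched, c)
    return groups


def _motion_epoch(state: TrainState, acq: SOSAcquisition, *, stage: str,
                  grid: VoxelGrid, traj: SOSTrajectory, samples: np.ndarray,
                  coil_maps: np.ndarray, op: SosOperator, roi: np.ndarray,
                  score_fn, opt: Adam, epoch: int, field_fn,
                  merge_radius: int = 0, bands=None, initial=None) -> float:
    """One optimization step shared by Stages II and III(b)."""
    sched = state.schedule
    n_stacks = samples.shape[0]
    opt.zero_grad()
    vox = voxelize(state.ref_cloud, grid, sched.truncation_sigmas)
    fields = field_fn()
    scores = score_fn()                    # (n_stacks, 9) Tensor
    batch = state.rng.choice(n_stacks, size=min(sched.batch_stacks, n_stacks),
                             replace=False)
    dc = None
    dets = []
    for t in batch:
        t = int(t)
        dvf = compose_dvf_tensor(fields, scores[t])
        wre = warp_volume_tensor(vox[0], dvf, grid)
        wim = warp_volume_tensor(vox[1], dvf, grid)
        neighbors = range(max(0, t - merge_radius),
                          min(n_stacks, t + merge_radius + 1))
        for u in neighbors:
            term = _dc_stack(op, wre, wim, coil_maps, u, samples[u])
            dc = term if dc is None else dc + term
        dets.append(jacobian_determinant_tensor(dvf, grid))
    dc = dc / float(sum(min(n_stacks, t + merge_radius + 1)
                        - max(0, t - merge_radius) for t in batch))
    tv = loss_tv(vox[0], vox[1])
    mbc = loss_mbc_norm(fields)
    zms = loss_zero_mean(scores)
    jac = loss_jacobian(dets, roi)
    loss = (dc + sched.weights.tv * tv + sched.weights.mbc * mbc
            + sched.weights.zms * zms + sched.weights.jac * jac)
    parts = {"dc": dc.item(), "tv": tv.item(), "mbc": mbc.item(),
             "zms": zms.item(), "jac": jac.item()}
    if bands is not None:
        freq = loss_frequency(scores, bands)
        loss = loss + sched.weights.freq * freq
        parts["freq"] = freq.item()
    loss.backward()
    opt.step()
    val = loss.item()
    state.log(stage, epoch, loss=val, **parts)
    return val


def stage_2(state: TrainState, acq: SOSAcquisition) -> TrainState:
    """Joint bulk-motion learning at reduced spatiotemporal resolution."""
    sched = state.schedule
    epochs = sched.epochs[2]
    grid_lo, traj_lo, samples_lo, maps_lo = _low_res_problem(
        acq, sched.stage2_downsample)
    op = SosOperator(grid_lo, traj_lo)
    roi_lo = roi_from_reference(
        np.abs(_downsample_inplane(state.iavg, sched.stage2_downsample))).mask
    navs = Tensor(_navigators(acq, sched.navigator_kmax, state.stats))
    groups = _ref_param_groups(sched, state.ref_cloud)
    groups += _mbc_param_groups(state)
    groups.append((state.mlp.parameters(), sched.lr_mlp))
    opt = _make_optimizer(groups)
    field_fn = _mbc_field_fn(state, grid_lo)
    initial = None
    for epoch in range(epochs):
        val = _motion_epoch(
            state, acq, stage="2", grid=grid_lo, traj=traj_lo,
            samples=samples_lo, coil_maps=maps_lo, op=op, roi=roi_lo,
            score_fn=lambda: state.mlp.forward(navs), opt=opt, epoch=epoch,
            field_fn=field_fn, merge_radius=sched.stage2_merge_radius)
        initial = _guard("II", initial, val)
    state.stages_run.append("2")
    return state


def stage_3a(state: TrainState, acq: SOSAcquisition) -> TrainState:
    """CNN warm start: distill the frozen MLP's scores."""
    sched = state.schedule
    epochs = sched.epochs[3]
    navs = _navigators(acq, sched.navigator_kmax, state.stats)
    with no_grad():
        targets = state.mlp.forward(Tensor(navs)).data
    projections = _projections(acq)[:, None]      # (N,1,H,W)
    proj_t = Tensor(projections)
    opt = _make_optimizer([(state.cnn.parameters(), sched.lr_cnn_warmup)])
    state.cnn.train(True)
    initial = None
    for epoch in range(epochs):
        opt.zero_grad()
        pred = state.cnn.forward(proj_t)
        loss = (pred - Tensor(targets)).abs().mean()
        loss.backward()
        opt.step()
        val = loss.item()
        initial = _guard("III(a)", initial, val)
        state.log("3a", epoch, loss=val)
    state.cnn.eval()
    state.stages_run.append("3a")
    return state


def stage_3b(state: TrainState, acq: SOSAcquisition) -> TrainState:
    """Full-resolution joint refinement driven by the CNN encoder.

    Batch-normalization layers run with their Stage III(a) statistics
    frozen so per-step batches stay deterministic and well defined.
    """
    sched = state.schedule
    epochs = sched.epochs[4]
    op = SosOperator(state.grid, acq.trajectory)
    bands = build_frequency_bands(acq.trajectory.config)
    projections = Tensor(_projections(acq)[:, None])
    groups = _ref_param_groups(sched, state.ref_cloud)
    groups += _mbc_param_groups(state)
    groups.append((state.cnn.parameters(), sched.lr_cnn))
    opt = _make_optimizer(groups)
    field_fn = _mbc_field_fn(state, state.grid)
    state.cnn.eval()   # frozen BN statistics; weights keep training
    initial = None
    for epoch in range(epochs):
        val = _motion_epoch(
            state, acq, stage="3b", grid=state.grid, traj=acq.trajectory,
            samples=acq.samples, coil_maps=acq.coil_maps, op=op,
            roi=state.roi, score_fn=lambda: state.cnn.forward(projections),
            opt=opt, epoch=epoch, field_fn=field_fn, bands=bands)
        initial = _guard("III(b)", initial, val)
    with no_grad():
        state.solved_scores = state.cnn.forward(projections).data.copy()
    state.stages_run.append("3b")
    return state


def perturb_scores(scores: ScoreSequence, r1_range=(0.2, 2.6),
                   r2_range=(0.4, 1.6), seed: int | np.random.Generator = 0,
                   si_only: bool = False) -> ScoreSequence:
    """Randomly rescale solved scores: w' = r1(t) * r2(level, dir) * w.

    ``r1`` is drawn per time instance and shared across the nine channels;
    ``r2`` once per (level, direction) pair.  With ``si_only``, channels of
    the x/y directions keep their solved values.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    w = scores.scores
    r1 = rng.uniform(*r1_range, size=(w.shape[0], 1))
    r2 = rng.uniform(*r2_range, size=(1, 9))
    perturbed = r1 * r2 * w
    if si_only:
        keep = np.ones(9, dtype=bool)
        keep[[2, 5, 8]] = False          # all but the z-direction channels
        perturbed[:, keep] = w[:, keep]
    return ScoreSequence(scores=perturbed, timestamps_ms=scores.timestamps_ms)


def stage_4_augment(state: TrainState, acq: SOSAcquisition,
                    n_augmented_epochs: int | None = None) -> TrainState:
    """Motion-augmentation fine-tuning of the CNN encoder only."""
    sched = state.schedule
    epochs = sched.epochs[5] if n_augmented_epochs is None else n_augmented_epochs
    if state.solved_scores is None:
        raise RuntimeError("stage III(b) must run before augmentation")
    op = SosOperator(state.grid, acq.trajectory)
    with no_grad():
        vox = voxelize(state.ref_cloud, state.grid, sched.truncation_sigmas).data
        fields = np.stack([
            voxelize(c, state.grid, sched.truncation_sigmas).data[0]
            for c in state.mbc_clouds])
    ref_vol = vox[0] + 1j * vox[1]
    from .motion import MotionBasisSet
    basis = MotionBasisSet(fields=fields, grid=state.grid)
    seq = ScoreSequence(scores=state.solved_scores,
                        timestamps_ms=acq.trajectory.timestamps_ms)
    opt = _make_optimizer([(state.cnn.parameters(), sched.lr_cnn)])
    state.cnn.eval()   # frozen BN statistics
    initial = None
    for epoch in range(epochs):
        perturbed = perturb_scores(seq, sched.r1_range, sched.r2_range,
                                   seed=state.rng, si_only=sched.si_only_augment)
        batch = state.rng.choice(acq.n_stacks,
                                 size=min(sched.batch_stacks, acq.n_stacks),
                                 replace=False)
        projs = []
        targets = []
        for t in batch:
            t = int(t)
            w_aug = perturbed.scores[t]
            dvf = compose_dvf(basis, w_aug)
            warped = warp_volume(ref_vol, dvf, state.grid)
            sim = op.forward(warped, acq.coil_maps, t)
            projs.append(make_cnn_projection(sim))
            targets.append(w_aug)
        opt.zero_grad()
        pred = state.cnn.forward(Tensor(np.stack(projs)[:, None]))
        loss = (pred - Tensor(np.stack(targets))).abs().mean()
        loss.backward()
        opt.step()
        val = loss.item()
        initial = _guard("IV", initial, val)
        state.log("4", epoch, loss=val)
    state.stages_run.append("4")
    return state


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class TrainedModel:
    """Frozen artifacts of a training run."""

    grid: VoxelGrid
    config: AcquisitionConfig
    reference_volume: np.ndarray        # complex, grid.shape
    basis_fields: np.ndarray            # (9,) + grid.shape
    scores: np.ndarray                  # (n_stacks, 9) solved at training
    timestamps_ms: np.ndarray
    cnn: CNNEncoder
    mlp: MLPEncoder
    stats: NormalizationStats
    navigator_kmax: int
    ref_cloud_state: dict
    mbc_cloud_states: list[dict]
    history: list[dict] = field(default_factory=list)

    def dynamic_volume(self, stack: int) -> np.ndarray:
        from .motion import MotionBasisSet
        basis = MotionBasisSet(fields=self.basis_fields, grid=self.grid)
        dvf = compose_dvf(basis, self.scores[stack])
        return warp_volume(self.reference_volume, dvf, self.grid)

    def dynamic_dvf(self, stack: int) -> np.ndarray:
        from .motion import MotionBasisSet
        basis = MotionBasisSet(fields=self.basis_fields, grid=self.grid)
        return compose_dvf(basis, self.scores[stack])

    # -- persistence --------------------------------------------------------

    def checkpoint_state(self) -> dict:
        return {
            "grid": {"shape": np.asarray(self.grid.shape),
                     "spacing": np.asarray(self.grid.spacing),
                     "origin": np.asarray(self.grid.origin)},
            "config": dataclasses.asdict(self.config),
            "reference_volume_re": self.reference_volume.real,
            "reference_volume_im": self.reference_volume.imag,
            "basis_fields": self.basis_fields,
            "scores": self.scores,
            "timestamps_ms": np.asarray(self.timestamps_ms),
            "cnn": self.cnn.state_dict(),
            "mlp": self.mlp.state_dict(),
            "stats": {"mean": self.stats.mean, "std": self.stats.std},
            "navigator_kmax": self.navigator_kmax,
            "ref_cloud": self.ref_cloud_state,
            "mbc_clouds": {str(i): s for i, s in
                           enumerate(self.mbc_cloud_states)},
        }

    @classmethod
    def from_checkpoint_state(cls, st: dict) -> "TrainedModel":
        grid = VoxelGrid(shape=tuple(int(v) for v in st["grid"]["shape"]),
                         spacing=tuple(float(v) for v in st["grid"]["spacing"]),
                         origin=tuple(float(v) for v in st["grid"]["origin"]))
        config = AcquisitionConfig(**st["config"])
        mlp_state = st["mlp"]
        n_feat = mlp_state["net0_l0_w"].shape[0]
        hidden = (mlp_state["net0_l0_w"].shape[1],
                  mlp_state["net0_l1_w"].shape[1])
        mlp = MLPEncoder(n_feat, hidden=hidden)
        mlp.load_state_dict(mlp_state)
        cnn = CNNEncoder()
        cnn.load_state_dict(st["cnn"])
        cnn.eval()
        stats = NormalizationStats(mean=st["stats"]["mean"],
                                   std=st["stats"]["std"])
        mbc_states = [st["mbc_clouds"][str(i)] for i in range(9)]
        return cls(grid=grid, config=config,
                   reference_volume=st["reference_volume_re"]
                   + 1j * st["reference_volume_im"],
                   basis_fields=st["basis_fields"], scores=st["scores"],
                   timestamps_ms=st["timestamps_ms"], cnn=cnn, mlp=mlp,
                   stats=stats, navigator_kmax=int(st["navigator_kmax"]),
                   ref_cloud_state=st["ref_cloud"],
                   mbc_cloud_states=mbc_states)


def run_full_training(acq: SOSAcquisition, schedule: StageSchedule,
                      ) -> TrainedModel:
    """Initialization followed by Stages I(a) through IV, fully seeded."""
    state, iavg = initialize_state(acq, schedule)
    try:
        stage_1a(state, iavg)
        stage_1b(state, acq)
        stage_2(state, acq)
        stage_3a(state, acq)
        stage_3b(state, acq)
        stage_4_augment(state, acq)
    except StageDivergence as exc:
        raise StageDivergence(exc.stage, 0.0, 0.0) from exc
    return finalize_model(state, acq)


def finalize_model(state: TrainState, acq: SOSAcquisition) -> TrainedModel:
    sched = state.schedule
    with no_grad():
        vox = voxelize(state.ref_cloud, state.grid, sched.truncation_sigmas).data
        fields = np.stack([
            voxelize(c, state.grid, sched.truncation_sigmas).data[0]
            for c in state.mbc_clouds])
        if state.solved_scores is not None:
            scores = state.solved_scores
        else:
            projections = Tensor(_projections(acq)[:, None])
            state.cnn.eval()
            scores = state.cnn.forward(projections).data
    return TrainedModel(
        grid=state.grid, config=acq.trajectory.config,
        reference_volume=vox[0] + 1j * vox[1], basis_fields=fields,
        scores=scores, timestamps_ms=acq.trajectory.timestamps_ms,
        cnn=state.cnn, mlp=state.mlp, stats=state.stats,
        navigator_kmax=sched.navigator_kmax,
        ref_cloud_state=state.ref_cloud.state_dict(),
        mbc_cloud_states=[c.state_dict() for c in state.mbc_clouds],
        history=state.history)
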