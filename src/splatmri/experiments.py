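"""Scaled-down experiment harness mirroring the synthetic-torso protocols.

The full-scale protocol (368x368x94 voxels, 673 stacks, GPU-hours of
training) is not desk-reproducible; this harness runs the same pipeline on
a reduced grid with proportionally scaled motion amplitudes and a
compressed time axis, and computes the same quantities: same-scenario
dynamic-reconstruction COME/DSC/SSIM and cross-scenario real-time COME/DSC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import (AcquisitionConfig, make_sos_trajectory,
                          simulate_acquisition, simulate_coil_maps)
from .evaluation import dsc, fit_reference_target_mask, ssim
from .grids import VoxelGrid
from .motion import mask_centroid_mm, propagate_mask
from .objectives import roi_from_reference
from .phantom import (MotionScenario, build_torso_phantom,
                      render_ground_truth)
from .realtime import RealtimeSession, infer_stack
from .trainer import StageSchedule, TrainedModel, run_full_training

__all__ = ["DeskProtocol", "ScenarioResult", "run_scenario",
            "dynamic_metrics", "realtime_metrics", "run_torso_protocol"]

TORSO_SCENARIOS = ("X1", "X2", "X3", "X4", "X5", "X6")


@dataclass(frozen=True)
class DeskProtocol:
    """Reduced-scale experiment geometry and schedule."""

    grid_shape: tuple[int, int, int] = (28, 28, 14)
    grid_spacing: tuple[float, float, float] = (6.8, 6.8, 8.0)
    n_stacks: int = 44
    n_coils: int = 4
    tr_ms: float = 4.5
    amplitude_scale: float = 0.4     # fraction of the full-scale amplitudes
    period_s: float = 1.5            # compressed breathing period
    anatomy_seed: int = 3
    epochs: tuple = (80, 15, 160, 250, 80, 100)
    n_reference_points: int = 1200

    def grid(self) -> VoxelGrid:
        return VoxelGrid(self.grid_shape, self.grid_spacing)

    def sequence(self) -> AcquisitionConfig:
        return AcquisitionConfig(tr_ms=self.tr_ms, n_kz=self.grid_shape[2],
                                 n_readout=self.grid_shape[0],
                                 n_coils=self.n_coils,
                                 n_stacks=self.n_stacks)

    def scenario(self, kind: str, seed: int = 0) -> MotionScenario:
        s = self.amplitude_scale
        return MotionScenario(
            kind, si_amplitude_mm=20.0 * s, ap_amplitude_mm=10.0 * s,
            baseline_step_mm=8.0 * s, drift_mm_per_frame=0.02 * s,
            period_s=self.period_s, seed=seed)

    def schedule(self, seed: int) -> StageSchedule:
        return StageSchedule.desk(seed=seed, epochs=self.epochs,
                                  n_reference_points=self.n_reference_points)


@dataclass
class ScenarioResult:
    """Trained model plus the inputs needed for evaluation."""

    kind: str
    model: TrainedModel
    ground_truth: object
    anatomy: object
    acquisition: object
    ref_target_mask: np.ndarray = field(default=None)
    ref_target_center: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.ref_target_mask is None:
            center, mask = fit_reference_target_mask(
                self.model.reference_volume, self.anatomy)
            self.ref_target_center = center
            self.ref_target_mask = mask


def make_acquisition(protocol: DeskProtocol, kind: str, seed: int):
    grid = protocol.grid()
    seq = protocol.sequence()
    anatomy = build_torso_phantom(grid, seed=protocol.anatomy_seed,
                                  texture_scale=0.0)
    truth = render_ground_truth(anatomy, protocol.scenario(kind, seed),
                                seq.n_stacks, seq.stack_duration_ms)
    maps = simulate_coil_maps(grid, seq.n_coils, seed=seed + 11)
    traj = make_sos_trajectory(seq)
    acq = simulate_acquisition(truth, maps, traj, grid, seed=seed + 13)
    return anatomy, truth, acq


def run_scenario(protocol: DeskProtocol, kind: str, seed: int,
                 ) -> ScenarioResult:
    """Simulate one scenario's acquisition and train the full pipeline."""
    anatomy, truth, acq = make_acquisition(protocol, kind, seed)
    model = run_full_training(acq, protocol.schedule(seed))
    return ScenarioResult(kind=kind, model=model, ground_truth=truth,
                          anatomy=anatomy, acquisition=acq)


def dynamic_metrics(result: ScenarioResult) -> dict[str, np.ndarray]:
    """Same-scenario dynamic-reconstruction COME/DSC/SSIM per stack."""
    model = result.model
    truth = result.ground_truth
    grid = model.grid
    roi = roi_from_reference(np.abs(model.reference_volume)).mask
    n = model.scores.shape[0]
    come_v = np.empty(n)
    dsc_v = np.empty(n)
    ssim_v = np.empty(n)
    for t in range(n):
        dvf = model.dynamic_dvf(t)
        pred_mask = propagate_mask(result.ref_target_mask, dvf, grid)
        true_mask = truth.tumor_mask(t)
        come_v[t] = np.linalg.norm(mask_centroid_mm(pred_mask, grid)
                                   - mask_centroid_mm(true_mask, grid))
        dsc_v[t] = dsc(true_mask, pred_mask)
        ssim_v[t] = ssim(truth.frames[t], model.dynamic_volume(t),
                         data_range=float(np.abs(truth.frames[t]).max()),
                         roi=roi)
    return {"come_mm": come_v, "dsc": dsc_v, "ssim": ssim_v}


def realtime_metrics(trained: ScenarioResult, test_truth, test_acq,
                     ) -> dict[str, np.ndarray]:
    """Cross-scenario real-time COME/DSC: per-stack CNN inference."""
    session = RealtimeSession(model=trained.model,
                              target_mask=trained.ref_target_mask)
    grid = trained.model.grid
    n = test_acq.n_stacks
    come_v = np.empty(n)
    dsc_v = np.empty(n)
    for t in range(n):
        res = infer_stack(session, test_acq.samples[t], stack=t)
        true_mask = test_truth.tumor_mask(t)
        come_v[t] = np.linalg.norm(res.centroid_mm
                                   - mask_centroid_mm(true_mask, grid))
        dsc_v[t] = dsc(true_mask, res.mask)
    return {"come_mm": come_v, "dsc": dsc_v}


def run_torso_protocol(seed: int, protocol: DeskProtocol | None = None,
                      scenarios=TORSO_SCENARIOS, cross_scenario: bool = True,
                      verbose: bool = False) -> dict:
    """Train per scenario, evaluate both arms, return aggregate means.

    Mirrors the synthetic-torso evaluation: same-scenario dynamic
    reconstruction (COME/DSC/SSIM) and cross-scenario real-time inference
    (COME/DSC), averaged over stacks and scenarios/pairs.
    """
    protocol = protocol or DeskProtocol()
    results: dict[str, ScenarioResult] = {}
    dyn = {"come_mm": [], "dsc": [], "ssim": []}
    for i, kind in enumerate(scenarios):
        res = run_scenario(protocol, kind, seed + 101 * i)
        results[kind] = res
        metrics = dynamic_metrics(res)
        for k in dyn:
            dyn[k].append(metrics[k])
        if verbose:
            print(f"[{kind}] dynamic COME={metrics['come_mm'].mean():.2f} mm "
                  f"DSC={metrics['dsc'].mean():.3f} "
                  f"SSIM={metrics['ssim'].mean():.4f}", flush=True)
    out = {
        "dynamic_come_mm": float(np.mean([v.mean() for v in dyn["come_mm"]])),
        "dynamic_dsc": float(np.mean([v.mean() for v in dyn["dsc"]])),
        "dynamic_ssim": float(np.mean([v.mean() for v in dyn["ssim"]])),
        "per_scenario": {k: {"come_mm": float(np.mean(dyn["come_mm"][i])),
                             "dsc": float(np.mean(dyn["dsc"][i])),
                             "ssim": float(np.mean(dyn["ssim"][i]))}
                         for i, k in enumerate(scenarios)},
        "n_stacks": protocol.n_stacks,
        "n_scenarios": len(scenarios),
    }
    if cross_scenario and len(scenarios) > 1:
        rt_come = []
        rt_dsc = []
        for train_kind in scenarios:
            for test_kind in scenarios:
                if test_kind == train_kind:
                    continue
                test = results[test_kind]
                m = realtime_metrics(results[train_kind],
                                     test.ground_truth, test.acquisition)
                rt_come.append(m["come_mm"].mean())
                rt_dsc.append(m["dsc"].mean())
        out["realtime_come_mm"] = float(np.mean(rt_come))
        out["realtime_dsc"] = float(np.mean(rt_dsc))
        if verbose:
            print(f"cross-scenario realtime COME={out['realtime_come_mm']:.2f}"
                  f" mm DSC={out['realtime_dsc']:.3f}", flush=True)
    return out
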