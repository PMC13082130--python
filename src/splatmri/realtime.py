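"""Streaming per-stack inference with a frozen trained model.

Each incoming stack is mapped, independently of every other stack, to its
nine motion scores (CNN path), the composed displacement field, the warped
real-time volume, the propagated target mask, and the target centroid in
millimetres.  No parameters are updated and no temporal smoothing is
applied.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import SOSAcquisition, make_cnn_projection
from .encoders import cnn_forward
from .motion import (MotionBasisSet, compose_dvf, mask_centroid_mm,
                     propagate_mask, warp_volume)
from .trainer import TrainedModel

__all__ = ["RealtimeSession", "InferenceResult", "infer_stack", "run_stream"]


@dataclass(frozen=True)
class InferenceResult:
    """Outputs for one stack."""

    stack: int
    timestamp_ms: float
    scores: np.ndarray           # (9,)
    dvf_mm: np.ndarray           # grid.shape + (3,)
    volume: np.ndarray           # complex grid.shape
    mask: np.ndarray
    centroid_mm: np.ndarray      # (3,)
    latency_ms: float = 0.0


@dataclass
class RealtimeSession:
    """Frozen model plus the reference-frame target mask."""

    model: TrainedModel
    target_mask: np.ndarray
    records: list[InferenceResult] = field(default_factory=list)

    def __post_init__(self):
        if not np.asarray(self.target_mask).any():
            raise ValueError("target mask at the reference frame is empty")
        self.model.cnn.eval()
        self._basis = MotionBasisSet(fields=self.model.basis_fields,
                                     grid=self.model.grid)

    @property
    def grid(self):
        return self.model.grid


def infer_stack(session: RealtimeSession, stack_samples: np.ndarray,
                stack: int = 0, timestamp_ms: float = 0.0) -> InferenceResult:
    """Pure function of (session, stack samples) -> real-time outputs."""
    model = session.model
    cfg = model.config
    if stack_samples.shape != (cfg.n_coils, cfg.n_kz, cfg.n_readout):
        raise ValueError("stack geometry does not match the trained model")
    t0 = time.perf_counter()
    projection = make_cnn_projection(stack_samples)
    scores = cnn_forward(model.cnn, projection)
    dvf = compose_dvf(session._basis, scores)
    volume = warp_volume(model.reference_volume, dvf, model.grid)
    mask = propagate_mask(session.target_mask, dvf, model.grid)
    if mask.any():
        centroid = mask_centroid_mm(mask, model.grid)
    else:
        centroid = np.full(3, np.nan)
    latency = (time.perf_counter() - t0) * 1000.0
    result = InferenceResult(stack=stack, timestamp_ms=timestamp_ms,
                             scores=scores, dvf_mm=dvf, volume=volume,
                             mask=mask, centroid_mm=centroid,
                             latency_ms=latency)
    session.records.append(result)
    return result


def run_stream(session: RealtimeSession, acq: SOSAcquisition,
               keep_volumes: bool = False,
               ) -> tuple[pd.DataFrame, list[InferenceResult] | None]:
    """Iterate :func:`infer_stack` over an acquisition in order.

    Returns the trajectory table (one row per stack) and, when
    ``keep_volumes`` is set, the full per-stack results.
    """
    rows = []
    results = [] if keep_volumes else None
    for t in range(acq.n_stacks):
        res = infer_stack(session, acq.samples[t], stack=t,
                          timestamp_ms=float(acq.trajectory.timestamps_ms[t]))
        row = {"stack": t, "time_ms": res.timestamp_ms,
               "centroid_x_mm": res.centroid_mm[0],
               "centroid_y_mm": res.centroid_mm[1],
               "centroid_z_mm": res.centroid_mm[2],
               "latency_ms": res.latency_ms}
        for i in range(9):
            row[f"score_{i}"] = res.scores[i]
        rows.append(row)
        if keep_volumes:
            results.append(res)
    columns = (["stack", "time_ms"] + [f"score_{i}" for i in range(9)]
               + ["centroid_x_mm", "centroid_y_mm", "centroid_z_mm",
                  "latency_ms"])
    table = pd.DataFrame(rows, columns=columns) if rows else \
        pd.DataFrame(columns=columns)
    return table, results
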