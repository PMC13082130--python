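"""Synthetic deformable anatomies with analytic motion.

Stand-ins for the two physical test objects used to exercise the pipeline:
an abdominal torso (body, lungs, liver, spine, and a 30 mm spherical liver
tumor as the tracking target) and a cylinder phantom with a movable bright
insert.  Organ boundaries are analytic primitives with a soft (erf) edge of
about one voxel so rendered frames are band-limited; every frame is rendered
by evaluating the reference anatomy at analytically displaced coordinates,
so the stored deformation fields are exact.

Six breathing scenarios (X1..X6) vary amplitude, frequency, baseline and
drift; the cylinder scenarios move along the superior-inferior axis only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import erf

from .grids import VoxelGrid

__all__ = [
    "Organ",
    "AnatomyModel",
    "MotionScenario",
    "DynamicGroundTruth",
    "build_torso_phantom",
    "build_cylinder_phantom",
    "make_breathing_trace",
    "render_ground_truth",
    "SCENARIO_KINDS",
]

SCENARIO_KINDS = ("X1", "X2", "X3", "X4", "X5", "X6",
                  "QUASAR_sinusoid", "QUASAR_irregular")

TUMOR_DIAMETER_MM = 30.0
X1_SI_AMPLITUDE_MM = 20.0   # peak-to-valley, superior-inferior
X1_AP_AMPLITUDE_MM = 10.0   # peak-to-valley, anterior-posterior
X2_BASELINE_STEP_MM = 8.0
X3_DRIFT_MM_PER_FRAME = 0.02
EDGE_WIDTH_VOXELS = 1.5

# organ tissue magnitudes (arbitrary units, representative T1w-like contrast)
_SIGNALS = {
    "body": 0.55, "lung_left": 0.08, "lung_right": 0.08,
    "liver": 1.0, "spine": 0.75, "tumor": 1.45,
    "water_shell": 0.15, "insert": 1.0, "target": 0.05,
}

LABELS = {"body": 1, "lung_left": 2, "lung_right": 3, "liver": 4,
          "spine": 5, "tumor": 6, "water_shell": 1, "insert": 2, "target": 6}


@dataclass(frozen=True)
class Organ:
    """One geometric primitive with a complex tissue signal.

    ``texture`` holds random-cosine coefficients (K, 5): rows of
    (kx, ky, kz, phase, amplitude) in cycles/mm; the band-limited texture
    moves rigidly with the organ, giving the data-consistency term
    intensity gradients inside otherwise uniform tissue.
    """

    name: str
    primitive: str                       # 'ellipsoid' | 'sphere' | 'cylinder'
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]  # cylinder: (rx, ry, half-length z)
    magnitude: float
    phase: float
    texture: np.ndarray | None = None

    @property
    def signal(self) -> complex:
        return self.magnitude * np.exp(1j * self.phase)

    def textured_magnitude(self, x, y, z):
        """Magnitude field at (possibly warped) world coordinates."""
        if self.texture is None or self.texture.size == 0:
            return self.magnitude
        k = self.texture
        tex = np.zeros(np.broadcast_shapes(np.shape(x), np.shape(y),
                                           np.shape(z)))
        for kx, ky, kz, ph, amp in k:
            tex += amp * np.cos(2 * np.pi * (kx * x + ky * y + kz * z) + ph)
        return self.magnitude * (1.0 + tex)

    def radial(self, x, y, z):
        """Normalized boundary function: <1 inside, 1 on the surface."""
        cx, cy, cz = self.center_mm
        rx, ry, rz = self.radii_mm
        if self.primitive in ("ellipsoid", "sphere"):
            return np.sqrt(((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2
                           + ((z - cz) / rz) ** 2)
        if self.primitive == "cylinder":
            r_xy = np.sqrt(((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2)
            r_z = np.abs(z - cz) / rz
            return np.maximum(r_xy, r_z)
        raise ValueError(f"unknown primitive {self.primitive!r}")


@dataclass
class AnatomyModel:
    """Organ stack (painted in order) on a voxel grid with one tracking target."""

    organs: list[Organ]
    grid: VoxelGrid
    tumor_label: str
    moving: dict[str, str] = field(default_factory=dict)  # organ -> 'field'|'rigid'|'static'

    def __post_init__(self):
        names = [o.name for o in self.organs]
        if names.count(self.tumor_label) != 1:
            raise ValueError("tracking target must be present exactly once")
        for o in self.organs:
            if o.magnitude < 0:
                raise ValueError("organ magnitudes must be >= 0")
            if not (-np.pi <= o.phase < np.pi):
                raise ValueError("organ phases must lie in [-pi, pi)")
            lo = np.asarray(o.center_mm) - np.asarray(o.radii_mm)
            hi = np.asarray(o.center_mm) + np.asarray(o.radii_mm)
            bb_lo = np.asarray(self.grid.origin) - 0.5 * np.asarray(self.grid.spacing)
            bb_hi = bb_lo + np.asarray(self.grid.fov_mm)
            if np.any(lo < bb_lo - 1e-9) or np.any(hi > bb_hi + 1e-9):
                raise ValueError(f"organ {o.name!r} does not fit inside the grid")

    def organ(self, name: str) -> Organ:
        return next(o for o in self.organs if o.name == name)


# ---------------------------------------------------------------------------
# phantom construction


def _make_texture(rng: np.random.Generator, amplitude: float, n_waves: int = 24,
                  min_wavelength_mm: float = 25.0,
                  max_wavelength_mm: float = 90.0) -> np.ndarray:
    """Random-cosine texture coefficients (n_waves, 5)."""
    if amplitude <= 0:
        return np.zeros((0, 5))
    wl = rng.uniform(min_wavelength_mm, max_wavelength_mm, size=n_waves)
    direction = rng.normal(size=(n_waves, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    kvec = direction / wl[:, None]
    phases = rng.uniform(0, 2 * np.pi, size=n_waves)
    amps = np.full(n_waves, amplitude / np.sqrt(n_waves / 2.0))
    return np.column_stack([kvec, phases, amps])


TEXTURE_AMPLITUDE = {"body": 0.15, "liver": 0.15, "lung_left": 0.3,
                     "lung_right": 0.3, "spine": 0.1, "tumor": 0.0,
                     "water_shell": 0.08, "insert": 0.1, "target": 0.0}


def _grid_center(grid: VoxelGrid) -> np.ndarray:
    """Center of the grid bounding box (mm)."""
    lo = np.asarray(grid.origin) - 0.5 * np.asarray(grid.spacing)
    return lo + 0.5 * np.asarray(grid.fov_mm)


def build_torso_phantom(grid: VoxelGrid, seed: int,
                        texture_scale: float = 1.0) -> AnatomyModel:
    """Torso with body, two lungs, liver, spine, and a 30 mm liver tumor.

    Organ phases are drawn once, uniformly on [-pi, pi), from ``seed``.
    Proportions scale with the grid FOV so the same anatomy works at full
    and desk scale.
    """
    fov = np.asarray(grid.fov_mm)
    if np.any(fov < TUMOR_DIAMETER_MM * 1.6):
        raise ValueError("grid too small to contain the 30 mm tracking target")
    rng = np.random.default_rng(seed)
    fx, fy, fz = fov
    c0 = _grid_center(grid)

    body_r = (0.44 * fx, 0.36 * fy, 0.49 * fz)
    lung_z = 0.17 * fz
    liver_c = (0.12 * fx, 0.02 * fy, -0.05 * fz)
    tumor_r = TUMOR_DIAMETER_MM / 2.0
    # upper liver segment: superior-anterior octant of the liver ellipsoid
    tumor_c = (liver_c[0] + 0.02 * fx, liver_c[1] - 0.03 * fy, liver_c[2] - 0.07 * fz)

    specs = [
        ("body", "ellipsoid", (0.0, 0.0, 0.0), body_r),
        ("lung_left", "ellipsoid", (-0.18 * fx, -0.02 * fy, -0.20 * fz),
         (0.14 * fx, 0.17 * fy, lung_z)),
        ("lung_right", "ellipsoid", (0.18 * fx, -0.02 * fy, -0.20 * fz),
         (0.14 * fx, 0.17 * fy, lung_z)),
        ("liver", "ellipsoid", liver_c, (0.20 * fx, 0.22 * fy, 0.16 * fz)),
        ("spine", "cylinder", (0.0, 0.24 * fy, 0.0),
         (0.045 * fx, 0.05 * fy, 0.46 * fz)),
        ("tumor", "sphere", tumor_c, (tumor_r, tumor_r, tumor_r)),
    ]
    specs = [(n, p, tuple(np.asarray(c) + c0), r) for n, p, c, r in specs]
    organs = [Organ(name, prim, center, radii, _SIGNALS[name],
                    float(rng.uniform(-np.pi, np.pi)),
                    texture=_make_texture(
                        rng, texture_scale * TEXTURE_AMPLITUDE.get(name, 0.0)))
              for name, prim, center, radii in specs]
    moving = {"body": "static", "spine": "field", "lung_left": "field",
              "lung_right": "field", "liver": "field", "tumor": "field"}
    return AnatomyModel(organs=organs, grid=grid, tumor_label="tumor",
                        moving=moving)


def build_cylinder_phantom(grid: VoxelGrid, seed: int,
                           texture_scale: float = 1.0) -> AnatomyModel:
    """Cylinder phantom: static water shell, movable bright insert with a
    dark spherical target mounted inside (tracking target)."""
    fov = np.asarray(grid.fov_mm)
    if np.any(fov < TUMOR_DIAMETER_MM * 1.6):
        raise ValueError("grid too small to contain the 30 mm tracking target")
    rng = np.random.default_rng(seed)
    fx, fy, fz = fov
    c0 = _grid_center(grid)
    target_r = TUMOR_DIAMETER_MM / 2.0
    specs = [
        ("water_shell", "cylinder", (0, 0, 0), (0.42 * fx, 0.42 * fy, 0.46 * fz)),
        ("insert", "cylinder", (0, 0, 0), (0.2 * fx, 0.2 * fy, 0.14 * fz)),
        ("target", "sphere", (0, 0, 0), (target_r,) * 3),
    ]
    specs = [(n, p, tuple(np.asarray(c) + c0), r) for n, p, c, r in specs]
    organs = [Organ(name, prim, center, radii, _SIGNALS[name],
                    float(rng.uniform(-np.pi, np.pi)),
                    texture=_make_texture(
                        rng, texture_scale * TEXTURE_AMPLITUDE.get(name, 0.0)))
              for name, prim, center, radii in specs]
    moving = {"water_shell": "static", "insert": "rigid", "target": "rigid"}
    return AnatomyModel(organs=organs, grid=grid, tumor_label="target",
                        moving=moving)


# ---------------------------------------------------------------------------
# breathing traces


@dataclass(frozen=True)
class MotionScenario:
    """Respiratory scenario descriptor.

    ``kind`` selects the temporal pattern; amplitudes are peak-to-valley in
    mm.  Cylinder ('QUASAR_*') kinds move along SI only.
    """

    kind: str
    si_amplitude_mm: float = X1_SI_AMPLITUDE_MM
    ap_amplitude_mm: float = X1_AP_AMPLITUDE_MM
    period_s: float = 4.0
    baseline_step_mm: float = X2_BASELINE_STEP_MM
    drift_mm_per_frame: float = X3_DRIFT_MM_PER_FRAME
    seed: int = 0

    def __post_init__(self):
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.si_amplitude_mm < 0 or self.ap_amplitude_mm < 0:
            raise ValueError("amplitudes must be >= 0")

    @property
    def si_only(self) -> bool:
        return self.kind.startswith("QUASAR")


def _rescale_peak_to_valley(x: np.ndarray, target: float) -> np.ndarray:
    span = x.max() - x.min()
    if span <= 0 or target <= 0:
        return np.zeros_like(x)
    return (x - x.min()) * (target / span)


def make_breathing_trace(scenario: MotionScenario, n_frames: int,
                         frame_period_ms: float) -> np.ndarray:
    """Per-frame (si_mm, ap_mm) displacements, shape (n_frames, 2).

    The trace is zero at frame 0 (the reference state).  Breathing-type
    scenarios are exhale-baseline ``sin^2`` patterns rescaled so their
    peak-to-valley spans equal the scenario amplitudes exactly.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    t = np.arange(n_frames) * (frame_period_ms / 1000.0)  # seconds
    k = scenario.kind
    rng = np.random.default_rng(scenario.seed)

    if k == "QUASAR_sinusoid":
        si = scenario.si_amplitude_mm * np.sin(2 * np.pi * t / scenario.period_s)
        return np.stack([si, np.zeros_like(si)], axis=1)
    if k == "QUASAR_irregular":
        # cycle-to-cycle amplitude and period jitter
        si = np.zeros(n_frames)
        phase = 0.0
        amp = scenario.si_amplitude_mm
        cur_T = scenario.period_s
        cur_A = amp
        for i in range(n_frames):
            si[i] = cur_A * np.sin(phase)
            dt = frame_period_ms / 1000.0
            phase += 2 * np.pi * dt / cur_T
            if phase >= 2 * np.pi:
                phase -= 2 * np.pi
                cur_A = amp * rng.uniform(0.75, 1.25)
                cur_T = scenario.period_s * rng.uniform(0.85, 1.15)
        return np.stack([si, np.zeros_like(si)], axis=1)

    T = scenario.period_s
    shape = np.sin(np.pi * t / T) ** 2           # inhale peaks, exhale baseline
    if k == "X1":
        si, ap = shape.copy(), shape.copy()
    elif k == "X2":
        si, ap = shape.copy(), shape.copy()
    elif k == "X3":
        mod = 1.0 + 0.3 * np.sin(2 * np.pi * t / (8.0 * T))
        si, ap = shape * mod, shape * mod
    elif k == "X4":
        # frequency decreasing, amplitude increasing over the scan
        dur = max(t[-1], 1e-9)
        freq = (1.0 / T) * (1.0 - 0.4 * t / dur)
        phase = 2 * np.pi * np.cumsum(np.r_[0.0, freq[:-1]]) * (frame_period_ms / 1000.0)
        grow = 1.0 + 0.5 * t / dur
        si = np.sin(phase / 2.0) ** 2 * grow
        ap = si.copy()
    elif k == "X5":
        shape = np.sin(np.pi * t / (2.0 * T)) ** 2   # slow breathing
        si, ap = shape.copy(), shape.copy()
    elif k == "X6":
        mod = 1.0 + 0.3 * np.sin(2 * np.pi * t / (6.0 * T))
        dur = max(t[-1], 1e-9)
        freq = (1.0 / T) * (1.0 - 0.3 * t / dur)
        phase = 2 * np.pi * np.cumsum(np.r_[0.0, freq[:-1]]) * (frame_period_ms / 1000.0)
        si = np.sin(phase / 2.0) ** 2 * mod
        ap = si.copy()
    else:  # pragma: no cover
        raise ValueError(f"unknown scenario kind {k!r}")

    si = _rescale_peak_to_valley(si, scenario.si_amplitude_mm)
    ap = _rescale_peak_to_valley(ap, scenario.ap_amplitude_mm)
    if k in ("X2", "X6"):
        si = si + scenario.baseline_step_mm * (np.arange(n_frames) >= n_frames // 2)
    if k in ("X3", "X6"):
        si = si + scenario.drift_mm_per_frame * np.arange(n_frames)
    si = si - si[0]
    ap = ap - ap[0]
    return np.stack([si, ap], axis=1)


# ---------------------------------------------------------------------------
# motion field and rendering


@dataclass
class DynamicGroundTruth:
    """Rendered frame sequence with exact deformation fields and masks."""

    frames: np.ndarray        # (T,) + grid.shape, complex
    dvfs: np.ndarray          # (T,) + grid.shape + (3,), mm (pull-back field)
    masks: np.ndarray         # (T,) + grid.shape, integer labels
    frame_period_ms: float
    grid: VoxelGrid
    trace_mm: np.ndarray      # (T, 2) (si, ap)
    tumor_label_value: int = LABELS["tumor"]

    def __post_init__(self):
        T = self.frames.shape[0]
        if not (self.dvfs.shape[0] == T and self.masks.shape[0] == T
                and self.trace_mm.shape[0] == T):
            raise ValueError("frames/dvfs/masks/trace must share length")
        if np.any(self.dvfs[0] != 0):
            raise ValueError("DVF at the reference frame must be zero")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def tumor_mask(self, t: int) -> np.ndarray:
        return self.masks[t] == self.tumor_label_value

    @property
    def duration_minutes(self) -> float:
        return self.n_frames * self.frame_period_ms / 60000.0


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def motion_weight(anatomy: AnatomyModel, x, y, z) -> np.ndarray:
    """Separable spatial profile of the respiratory field.

    Equals exactly 1 on a plateau covering the liver/tumor region, decays
    smoothly to 0 at the body wall (in-plane) and toward the lung apex and
    the inferior end of the body (through-plane).
    """
    if any(m == "rigid" for m in anatomy.moving.values()):
        # movable-insert phantom: full amplitude on a plateau spanning the
        # interior of the static outer container, zero at its wall
        f_outer = anatomy.organs[0].radial(x, y, z)
        return _smoothstep((0.88 - f_outer) / 0.18)
    body = anatomy.organ("body") if any(o.name == "body" for o in anatomy.organs) \
        else anatomy.organs[0]
    f_body = body.radial(x, y, z)
    w_wall = _smoothstep((0.90 - f_body) / 0.30)   # -> 0 before the body wall
    rz = body.radii_mm[2]
    zn = (z - body.center_mm[2]) / rz      # -1 superior apex .. +1 inferior
    wz = _smoothstep((zn + 0.95) / 0.45) * _smoothstep((0.95 - zn) / 0.45)
    return w_wall * wz


def displacement_field(anatomy: AnatomyModel, si_mm: float, ap_mm: float,
                       x, y, z, rigid: bool = False):
    """Analytic pull-back displacement (dx, dy, dz) in mm at world coordinates."""
    if rigid:
        w = np.ones(np.broadcast_shapes(np.shape(x), np.shape(y), np.shape(z)))
    else:
        w = motion_weight(anatomy, x, y, z)
    # pull-back convention: frame(x) = reference(x + d(x)), so the rendered
    # object translates by +(si, ap)
    return np.zeros_like(w), -ap_mm * w, -si_mm * w


def render_anatomy(anatomy: AnatomyModel, si_mm: float = 0.0, ap_mm: float = 0.0,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Render one motion state: complex image and label mask.

    The image at x equals the reference anatomy evaluated at x + d(x)
    (exact backward warp); masks use the hard (no soft edge) indicator.
    """
    grid = anatomy.grid
    x, y, z = grid.coords()
    x, y, z = np.broadcast_arrays(x, y, z)
    image = np.zeros(grid.shape, dtype=np.complex128)
    mask = np.zeros(grid.shape, dtype=np.int16)
    edge = EDGE_WIDTH_VOXELS * float(np.mean(grid.spacing))
    moving_coords = None
    for organ in anatomy.organs:
        mode = anatomy.moving.get(organ.name, "field")
        if si_mm == 0.0 and ap_mm == 0.0:
            xs = xt = x; ys = yt = y; zs = zt = z
        else:
            if mode == "rigid":
                ddx, ddy, ddz = displacement_field(anatomy, si_mm, ap_mm,
                                                   x, y, z, rigid=True)
                xs, ys, zs = x + ddx, y + ddy, z + ddz
                xt, yt, zt = xs, ys, zs
            else:
                if moving_coords is None:
                    ddx, ddy, ddz = displacement_field(anatomy, si_mm, ap_mm,
                                                       x, y, z)
                    moving_coords = (x + ddx, y + ddy, z + ddz)
                xt, yt, zt = moving_coords
                # a static organ keeps its outline but its interior tissue
                # (texture) still follows the motion field
                xs, ys, zs = (x, y, z) if mode == "static" else moving_coords
        f = organ.radial(xs, ys, zs)
        # soft edge ~1 voxel wide in world units
        scale = float(np.mean(organ.radii_mm))
        ind = 0.5 * (1.0 - erf((f - 1.0) * scale / (edge * np.sqrt(2.0))))
        value = organ.textured_magnitude(xt, yt, zt) * np.exp(1j * organ.phase)
        image = image * (1.0 - ind) + value * ind
        hard = f < 1.0
        mask[hard] = LABELS.get(organ.name, 0)
    return image, mask


def render_ground_truth(anatomy: AnatomyModel, scenario: MotionScenario,
                        n_frames: int, frame_period_ms: float = 423.0,
                        ) -> DynamicGroundTruth:
    """Render the dynamic sequence with exact per-voxel deformation fields."""
    trace = make_breathing_trace(scenario, n_frames, frame_period_ms)
    grid = anatomy.grid
    x, y, z = grid.coords()
    x, y, z = np.broadcast_arrays(x, y, z)
    w = motion_weight(anatomy, x, y, z)
    frames = np.empty((n_frames,) + grid.shape, dtype=np.complex128)
    masks = np.empty((n_frames,) + grid.shape, dtype=np.int16)
    dvfs = np.zeros((n_frames,) + grid.shape + (3,))
    for ti in range(n_frames):
        si, ap = trace[ti]
        frames[ti], masks[ti] = render_anatomy(anatomy, si, ap)
        if si != 0.0 or ap != 0.0:
            dvfs[ti, ..., 1] = -ap * w
            dvfs[ti, ..., 2] = -si * w
    return DynamicGroundTruth(frames=frames, dvfs=dvfs, masks=masks,
                              frame_period_ms=frame_period_ms, grid=grid,
                              trace_mm=trace,
                              tumor_label_value=LABELS[anatomy.tumor_label])
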