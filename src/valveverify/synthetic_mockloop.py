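"""Synthetic mock-loop data with known ground truth.

Generates every input the downstream analysis consumes: cyclic
left-ventricular / aortic pressure traces, transvalvular flow traces,
endoscope-like greyscale frame stacks with a known orifice area, and 3D
leaflet-surface point clouds with a known orifice.  All generators are
deterministic given a seed, and each records its ground truth so extraction
error can be measured rather than assumed.

The pressure-difference template is parametric: a half-sine systolic hump of
height ``dp_peak`` over ``systolic_fraction`` of the cycle, followed by a
constant negative diastolic plateau ``diastolic_dp``.  The synthetic flow
follows a quasi-static orifice (Bernoulli) law so signal statistics have
closed forms.  Neither is a haemodynamic model of the bench loop; they are
test scaffolding with analytic ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traces import TimeTrace, uniform_grid
from .units import MMHG_TO_PA, WATER_DENSITY, stroke_volume_ml

DEFAULT_DT = 1.0e-3  # s, sampling period of synthetic traces


@dataclass
class MockLoopSpec:
    """Operating point of the synthetic mock loop.

    Defaults correspond to the baseline (d0, no dobutamine) condition:
    75 bpm, 3.2 L/min, 0.8 s cycle.
    """

    heart_rate: float = 75.0  # beats/min
    cardiac_output: float = 3.2  # L/min
    cycle_time: float = 0.8  # s
    n_cycles: int = 6
    systolic_fraction: float = 0.35
    dp_peak: float = 69.0  # mmHg; half-sine of this peak has mean 2/pi*peak ~ 44
    diastolic_dp: float = -70.0  # mmHg, LV pressure far below aortic in diastole
    noise_sd: float = 0.0  # fraction of dp_peak, per-sample Gaussian
    seed: int = 0
    dt: float = DEFAULT_DT

    def validate(self) -> None:
        if self.cycle_time <= 0:
            raise ValueError("cycle_time must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not 0.0 < self.systolic_fraction < 1.0:
            raise ValueError("systolic_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.dp_peak <= 0:
            raise ValueError("dp_peak must be positive")
        if self.diastolic_dp >= 0:
            raise ValueError("diastolic_dp must be negative")


@dataclass
class FrameStack:
    """Endoscope-like greyscale frames with stored ground truth.

    frames are float arrays in [0, 1], all the same shape; the valve housing
    is the circle (valve_center, valve_radius) in pixels.  ``true_area_cm2``
    is the rasterized (supersampled) orifice area of each frame.
    """

    frames: list
    px_per_cm: float
    timestamps: np.ndarray
    valve_center: tuple
    valve_radius: float
    true_area_cm2: np.ndarray = field(default=None)

    def __post_init__(self):
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError("all frames must share one shape")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        if self.frames:
            nr, nc = self.frames[0].shape
            r0, c0 = self.valve_center
            if (r0 - self.valve_radius < 0 or c0 - self.valve_radius < 0
                    or r0 + self.valve_radius > nr or c0 + self.valve_radius > nc):
                raise ValueError("valve circle must fit inside the frame")


@dataclass
class LeafletCloud:
    """Point cloud sampling three leaflet surfaces around a central orifice.

    points are in mm; ``leaflet_label`` in {1, 2, 3}; ``axis`` is the unit
    valve axis along which the orifice is open.
    """

    points: np.ndarray  # (n, 3) mm
    leaflet_label: np.ndarray  # (n,) int
    calcified: np.ndarray  # (n,) bool
    axis: np.ndarray  # (3,) unit
    true_area_cm2: float = 0.0

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        if not np.isclose(np.linalg.norm(self.axis), 1.0, atol=1e-8):
            raise ValueError("axis must have unit norm")
        if len(set(np.unique(self.leaflet_label)) & {1, 2, 3}) < 3 and len(self.points) > 0:
            raise ValueError("all three leaflet labels must be present")


def _dp_template(spec: MockLoopSpec) -> np.ndarray:
    """Noise-free pressure-difference template over one cycle, mmHg."""
    t = uniform_grid(spec.cycle_time, spec.dt)
    ts = spec.systolic_fraction * spec.cycle_time
    dp = np.where(t < ts, spec.dp_peak * np.sin(np.pi * t / ts), spec.diastolic_dp)
    # short linear blend (2% of the cycle) after systole so the plateau is
    # reached continuously rather than with a jump
    blend = 0.02 * spec.cycle_time
    mask = (t >= ts) & (t < ts + blend)
    dp[mask] = spec.diastolic_dp * (t[mask] - ts) / blend
    return dp


def generate_pressure_traces(spec: MockLoopSpec) -> tuple[TimeTrace, TimeTrace]:
    """Left-ventricular and aortic pressure traces over n_cycles, in mmHg.

    The aortic trace is a smooth template around 80 mmHg; the LV trace is
    the aortic trace plus the transvalvular pressure-difference template.
    Per-sample i.i.d. Gaussian noise of sd noise_sd * dp_peak is added to
    both independently.
    """
    spec.validate()
    t1 = uniform_grid(spec.cycle_time, spec.dt)
    ts = spec.systolic_fraction * spec.cycle_time
    pao_1 = 80.0 + 5.0 * np.sin(np.pi * np.clip(t1 / ts, 0, 1)) - 4.0 * t1 / spec.cycle_time
    dp_1 = _dp_template(spec)

    pao = np.tile(pao_1, spec.n_cycles)
    plv = pao + np.tile(dp_1, spec.n_cycles)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        sd = spec.noise_sd * spec.dp_peak
        plv = plv + rng.normal(0.0, sd, size=plv.shape)
        pao = pao + rng.normal(0.0, sd, size=pao.shape)

    t = uniform_grid(spec.n_cycles * spec.cycle_time, spec.dt)
    meta = {"cycle_time": spec.cycle_time, "n_cycles": spec.n_cycles}
    return (TimeTrace(t, plv, "mmHg", dict(meta)), TimeTrace(t, pao, "mmHg", dict(meta)))


def generate_flow_trace(dp: TimeTrace, orifice_area: float, discharge_coeff: float = 1.0) -> TimeTrace:
    """Quasi-static orifice flow in mL/s from a pressure difference in mmHg.

    Q = Cd * A * sqrt(2 * max(dp, 0) / rho) with water density; zero where
    the pressure difference is non-positive.  ``orifice_area`` is in cm^2.
    """
    if orifice_area <= 0:
        raise ValueError("orifice_area must be positive")
    dp_pa = np.maximum(dp.value, 0.0) * MMHG_TO_PA
    v = np.sqrt(2.0 * dp_pa / WATER_DENSITY)  # m/s
    q_m3s = discharge_coeff * (orifice_area * 1e-4) * v
    return TimeTrace(dp.t, q_m3s * 1e6, "mL/s", dict(dp.meta))


def scale_flow_to_co(q: TimeTrace, cardiac_output: float, heart_rate: float) -> TimeTrace:
    """Scale a one-cycle flow trace so its positive-phase integral is CO/HR.

    cardiac_output in L/min, heart_rate in beats/min; returns the trace
    multiplied by a single positive factor.
    """
    sv_target = stroke_volume_ml(cardiac_output, heart_rate)
    pos = np.trapezoid(np.maximum(q.value, 0.0), q.t)
    if pos <= 0:
        raise ValueError("flow trace has no net positive phase; cannot scale")
    factor = sv_target / pos
    out = q.copy()
    out.value = out.value * factor
    out.meta["stroke_volume_ml"] = sv_target
    return out


def add_pump_return(q: TimeTrace, return_volume: float = 5.0) -> TimeTrace:
    """Insert a negative diastolic lobe of integral -return_volume (mL).

    The lobe is a half-sine placed in the middle 80% of the longest zero-flow
    window and rescaled so its trapezoidal integral is exactly the requested
    volume.  Positive-phase samples are untouched.
    """
    if return_volume == 0:
        return q.copy()
    if return_volume < 0:
        raise ValueError("return_volume must be non-negative")
    zero = np.abs(q.value) < 1e-12
    if not zero.any():
        raise ValueError("no zero-flow window available for the pump return")
    # longest run of zeros
    padded = np.concatenate([[0], zero.astype(int), [0]])
    edges = np.diff(padded)
    starts, ends = np.where(edges == 1)[0], np.where(edges == -1)[0]
    lengths = ends - starts
    k = int(np.argmax(lengths))
    i0, i1 = starts[k], ends[k]
    n = i1 - i0
    if n < 8:
        raise ValueError("zero-flow window too short to host the pump return")
    lo = i0 + n // 10
    hi = i1 - n // 10
    idx = np.arange(lo, hi)
    tau = q.t[idx[-1]] - q.t[idx[0]]
    lobe = -np.sin(np.pi * (q.t[idx] - q.t[idx[0]]) / tau)
    lobe_int = np.trapezoid(lobe, q.t[idx])  # negative
    out = q.copy()
    out.value[idx] = lobe * (return_volume / -lobe_int)
    out.meta["pump_return_ml"] = return_volume
    return out


def _orifice_radius(area_cm2: float, lobe_amplitude: float) -> float:
    """Base radius r0 of the 3-lobed boundary r(th) = r0 (1 + e cos 3th)
    enclosing the requested area: A = pi r0^2 (1 + e^2/2)."""
    return np.sqrt(area_cm2 / (np.pi * (1.0 + 0.5 * lobe_amplitude**2)))


def render_endoscope_frames(ava: TimeTrace, shape: tuple = (480, 480), px_per_cm: float = 100.0,
                            noise_sd: float = 0.0, seed: int = 0,
                            lobe_amplitude: float = 0.25) -> FrameStack:
    """Render greyscale frames of a dark multi-lobed orifice on a bright annulus.

    ``ava`` gives the target orifice area (cm^2) per frame.  As seen by the
    endoscope the open orifice looks into the dark ventricle, so orifice
    pixels are dark (~0.1) on bright leaflet tissue (~0.85, which also fills
    the background so a closed valve yields a featureless frame).
    Frames are rasterized at 4x supersampling and averaged down; the
    resulting supersampled pixel count is stored as the per-frame
    ground-truth area.
    """
    if np.any(ava.value < 0):
        raise ValueError("areas must be non-negative")
    nr, nc = shape
    center = (nr / 2.0, nc / 2.0)
    valve_radius = 0.45 * min(nr, nc)

    ss = 4
    rr, cc = np.mgrid[0:nr * ss, 0:nc * ss]
    y = (rr + 0.5) / ss - center[0]
    x = (cc + 0.5) / ss - center[1]
    rad = np.hypot(y, x)
    theta = np.arctan2(y, x)

    rng = np.random.default_rng(seed)
    frames, true_areas = [], []
    for a in ava.value:
        img_ss = np.full((nr * ss, nc * ss), 0.85)
        if a > 0:
            r0_cm = _orifice_radius(a, lobe_amplitude)
            r_b = r0_cm * px_per_cm * (1.0 + lobe_amplitude * np.cos(3.0 * theta))
            if r0_cm * px_per_cm * (1.0 + lobe_amplitude) >= valve_radius:
                raise ValueError("orifice larger than the valve circle")
            orifice = rad <= r_b
            img_ss[orifice] = 0.10
            true_areas.append(orifice.sum() / (ss * px_per_cm) ** 2)
        else:
            true_areas.append(0.0)
        img = img_ss.reshape(nr, ss, nc, ss).mean(axis=(1, 3))
        if noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, noise_sd, size=img.shape), 0.0, 1.0)
        frames.append(img)

    return FrameStack(frames=frames, px_per_cm=px_per_cm, timestamps=ava.t.copy(),
                      valve_center=center, valve_radius=valve_radius,
                      true_area_cm2=np.array(true_areas))


def generate_leaflet_cloud(opening_area: float, n_points: int = 60000, seed: int = 0,
                           outer_radius_cm: float = 1.9, lobe_amplitude: float = 0.25,
                           belly_depth_cm: float = 0.6) -> LeafletCloud:
    """Sample three leaflet surfaces around a central orifice of known area.

    Points (in mm) cover the annular region between the 3-lobed orifice
    boundary and the outer housing radius, on a jittered structured polar
    grid dense enough that a 150x150 raster of the projection closes around
    the orifice.  Leaflets belly axially by ``belly_depth_cm`` toward the
    ventricle, so the cloud is genuinely 3D; the projection along ``axis``
    recovers ``opening_area``.
    """
    if opening_area < 0:
        raise ValueError("opening_area must be non-negative")
    if n_points < 5000:
        raise ValueError("n_points < 5000 cannot resolve the orifice at the default raster")
    rng = np.random.default_rng(seed)
    r0 = _orifice_radius(opening_area, lobe_amplitude) if opening_area > 0 else 0.0

    n_theta = int(np.sqrt(n_points * 2 * np.pi * outer_radius_cm / max(outer_radius_cm - r0, 0.1)))
    n_r = max(n_points // n_theta, 4)
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    s = np.linspace(0.0, 1.0, n_r)
    TH, S = np.meshgrid(theta, s)
    TH = TH + rng.uniform(-0.5, 0.5, TH.shape) * (2 * np.pi / n_theta)
    r_in = r0 * (1.0 + lobe_amplitude * np.cos(3.0 * TH))
    R = r_in + S * (outer_radius_cm - r_in)
    R = R + np.clip(rng.uniform(0.0, 0.5, R.shape) * (outer_radius_cm - r_in) / n_r,
                    0.0, None)
    x = R * np.cos(TH)
    y = R * np.sin(TH)
    # leaflet belly: deepest at the free edge (orifice boundary), zero at wall
    frac = np.clip((outer_radius_cm - R) / np.maximum(outer_radius_cm - r_in, 1e-9), 0.0, 1.0)
    z = -belly_depth_cm * frac**1.5

    pts_cm = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    angle = np.arctan2(pts_cm[:, 1], pts_cm[:, 0]) % (2 * np.pi)
    label = 1 + (angle // (2 * np.pi / 3)).astype(int)
    label = np.clip(label, 1, 3)
    calc = rng.random(len(pts_cm)) < 0.05
    return LeafletCloud(points=pts_cm * 10.0, leaflet_label=label, calcified=calc,
                        axis=np.array([0.0, 0.0, 1.0]), true_area_cm2=float(opening_area))
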