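"""Synthetic fencer and apparatus timeline.

Generates, for each planned trial, the two signals the real apparatus
would record — rear/front force-plate time series (1000 Hz) and sword
marker trajectories (250 Hz) — together with the ground-truth event
times, so the downstream event detectors and statistics can be validated
against known injected parameters.

Behavioural model
-----------------
* **Reaction time**: lognormal around a condition-specific median,
  truncated to [0.10, 0.60] s; with a small probability the fencer
  anticipates instead (uniform 0.05-0.10 s, below the ~100 ms
  physiological minimum).
* **Movement time**: a base duration plus Gaussian trial-to-trial jitter,
  lengthened by a fixed penalty when the target jumps mid-movement.
* **Aiming**: the sword is steered at the target centre plus isotropic
  2-D Gaussian scatter whose SD depends on the condition.
* **Ground reaction force**: quiescent en-garde loading (a fraction of
  body weight on the rear plate), then an explosive push: the forward
  component is a symmetric raised cosine, the vertical component a
  smooth rear-foot unloading plus an earlier, shorter raised-cosine
  thrust whose amplitude is solved so the peak force *norm* reaches
  ``push_peak`` x BW.  The push is positioned so the forward component
  crosses 1% BW (the onset definition) exactly at the nominal onset.
* **Sword path**: minimum-jerk reach along the line from the guard
  position through the aim point to a collinear point slightly beyond
  the touch plane, so the plane crossing is transversal and lands
  exactly at onset + MT.  When the target jumps, the remainder of the
  path is re-planned as a quintic from the current kinematic state
  toward the new aim point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .geometry import (
    DISTANCE_COEFF,
    VERTICAL_COEFF,
    ZONE_FRACTION,
    FencerProfile,
    TargetSpec,
    build_plastron,
    corner_zones,
    sample_target,
)
from .scenario import CUE_LEAD, MOVING_LIKE, Condition, TrialPlan, TrialSpec
from .trigger import DEFAULT_THRESHOLD_BW, DISPLAY_LATENCY, scan_trigger

__all__ = [
    "ApparatusConfig",
    "FencerBehavior",
    "ForceRecording",
    "SwordRecording",
    "GroundTruth",
    "SimulatedTrial",
    "sample_reaction_time",
    "generate_grf",
    "generate_sword_trajectory",
    "simulate_trial",
    "simulate_plan",
    "simulate_calibration_assaults",
    "simulate_trial_results",
    "sample_cohort",
    "perturb_behavior",
]

#: default per-condition reaction-time medians (s); Fixed is fastest,
#: knowing the target cannot move removes response alternatives
_RT_MEDIANS = {
    Condition.FIXED: 0.280,
    Condition.MOVING: 0.345,
    Condition.UNCERTAIN_FIXED: 0.347,
    Condition.UNCERTAIN_MOVING: 0.330,
}

#: default per-condition aiming scatter (m); chosen so the mean radial
#: error sigma*sqrt(pi/2) matches typical cohort accuracies per condition
_AIM_SIGMAS = {
    Condition.FIXED: 0.033,
    Condition.MOVING: 0.059,
    Condition.UNCERTAIN_FIXED: 0.040,
    Condition.UNCERTAIN_MOVING: 0.072,
}


@dataclass(frozen=True)
class FencerBehavior:
    """Tunable behavioural parameters of the synthetic fencer."""

    rt_median: dict[Condition, float] = field(
        default_factory=lambda: dict(_RT_MEDIANS)
    )
    rt_sigma: float = 0.25  # lognormal shape
    rt_bounds: tuple[float, float] = (0.10, 0.60)  # s, truncation
    anticipation_prob: float = 0.02
    anticipation_range: tuple[float, float] = (0.05, 0.10)  # s
    mt_base: float = 0.788  # s
    mt_sigma: float = 0.055  # s, trial-to-trial jitter
    mt_penalty_moving: float = 0.098  # s, added when the target jumps
    aim_sigma: dict[Condition, float] = field(
        default_factory=lambda: dict(_AIM_SIGMAS)
    )
    push_peak: float = 1.45  # x BW, peak rear-plate force norm
    push_forward_peak: float = 0.94  # x BW, peak forward component
    push_duration: float = 0.5  # s
    push_vertical_frac: float = 0.6  # vertical thrust duration / push_duration
    guard_rear_load: float = 0.55  # fraction of BW on the rear plate at rest
    grf_noise_bw: float = 0.002  # force noise SD, x BW
    marker_noise: float = 0.0003  # m, optoelectronic noise SD
    guard_tip_frac: tuple[float, float] = (0.54, 0.75)  # tip start (x/screen_x, z/height)
    blade_offset: tuple[float, float, float] = (-0.85, 0.0, 0.02)  # base marker - tip, m
    overshoot_frac: float = 0.02  # planned endpoint beyond the aim point

    def __post_init__(self) -> None:
        if not 0.0 <= self.anticipation_prob < 0.5:
            raise ValueError("anticipation_prob must be in [0, 0.5)")
        for cond, m in self.rt_median.items():
            if m < self.rt_bounds[0]:
                raise ValueError(f"rt_median[{cond}] below the non-anticipated floor")
        positive = {
            "rt_sigma": self.rt_sigma,
            "mt_base": self.mt_base,
            "push_peak": self.push_peak,
            "push_forward_peak": self.push_forward_peak,
            "push_duration": self.push_duration,
            "guard_rear_load": self.guard_rear_load,
        }
        for name, val in positive.items():
            if val <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ApparatusConfig:
    """Recording rates, display latency and trigger threshold."""

    force_rate: float = 1000.0  # Hz
    marker_rate: float = 250.0  # Hz
    display_latency: float = DISPLAY_LATENCY  # s
    threshold_bw: float = DEFAULT_THRESHOLD_BW  # x BW
    zone_fraction: tuple[float, float] = ZONE_FRACTION
    vertical_coeff: float = VERTICAL_COEFF
    distance_coeff: float = DISTANCE_COEFF
    cue_lead: float = CUE_LEAD  # s


@dataclass(frozen=True)
class ForceRecording:
    """Uniformly sampled 3-D forces (N) under the rear and front feet."""

    rate: float  # Hz
    t0: float  # s, time of the first sample
    rear: np.ndarray  # (n, 3): Fx forward, Fy lateral, Fz vertical
    front: np.ndarray  # (n, 3)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.rear.shape[0]) / self.rate


@dataclass(frozen=True)
class SwordRecording:
    """Uniformly sampled 3-D positions (m) of the blade-base and tip markers."""

    rate: float  # Hz
    t0: float
    base: np.ndarray  # (n, 3)
    tip: np.ndarray  # (n, 3)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.tip.shape[0]) / self.rate


@dataclass(frozen=True)
class GroundTruth:
    """Simulated event times and endpoints, for validating the detectors."""

    stimulus_time: float
    onset_time: float
    trigger_time: float | None
    display_time: float | None
    touch_time: float
    intended_touch_point: tuple[float, float]  # aim point (y, z), m
    touch_point: tuple[float, float]  # actual plane crossing (y, z), m
    rt: float
    mt: float
    anticipated: bool
    msv: float  # planned peak forward tip velocity, m/s

    def __post_init__(self) -> None:
        seq = [self.stimulus_time, self.onset_time]
        if self.trigger_time is not None:
            seq.append(self.trigger_time)
        if self.display_time is not None:
            seq.append(self.display_time)
        seq.append(self.touch_time)
        if any(b < a - 1e-9 for a, b in zip(seq, seq[1:])):
            raise ValueError(f"event times out of order: {seq}")


@dataclass(frozen=True)
class SimulatedTrial:
    spec: TrialSpec
    force: ForceRecording
    sword: SwordRecording
    truth: GroundTruth
    initial_target: TargetSpec
    final_target: TargetSpec


# ---------------------------------------------------------------------------
# reaction time


def _sample_rt_array(
    median: np.ndarray,
    sigma: float,
    bounds: tuple[float, float],
    anticipation_prob: float,
    anticipation_range: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized truncated-lognormal RT with an anticipation branch."""
    median = np.asarray(median, dtype=float)
    mu = np.log(median)
    lo = ndtr((np.log(bounds[0]) - mu) / sigma)
    hi = ndtr((np.log(bounds[1]) - mu) / sigma)
    u = rng.uniform(lo, hi)
    rt = np.exp(mu + sigma * ndtri(u))
    antic = rng.random(median.shape) < anticipation_prob
    if antic.any():
        rt = np.where(
            antic, rng.uniform(*anticipation_range, size=median.shape), rt
        )
    return rt


def sample_reaction_time(
    behavior: FencerBehavior, condition: Condition, rng: np.random.Generator
) -> float:
    """Draw one reaction time (s) for the given condition.

    With probability ``anticipation_prob`` the fencer guesses and the RT
    falls in the anticipation band [0.05, 0.10) s; otherwise it is
    lognormal with the condition's median, truncated to ``rt_bounds``.
    """
    return float(
        _sample_rt_array(
            np.asarray([behavior.rt_median[condition]]),
            behavior.rt_sigma,
            behavior.rt_bounds,
            behavior.anticipation_prob,
            behavior.anticipation_range,
            rng,
        )[0]
    )


# ---------------------------------------------------------------------------
# ground reaction forces


def _raised_cosine(u: np.ndarray) -> np.ndarray:
    """0 -> 1 -> 0 smooth pulse on u in [0, 1], zero outside."""
    u = np.asarray(u, dtype=float)
    out = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(u, 0.0, 1.0)))
    return np.where((u >= 0.0) & (u <= 1.0), out, 0.0)


def _unload(u: np.ndarray) -> np.ndarray:
    """1 -> 0 smooth rear-foot unloading on u in [0, 1]."""
    u = np.asarray(u, dtype=float)
    out = 0.5 * (1.0 + np.cos(np.pi * np.clip(u, 0.0, 1.0)))
    return np.where(u < 0.0, 1.0, np.where(u > 1.0, 0.0, out))


@lru_cache(maxsize=64)
def _vertical_amplitude(
    push_peak: float, forward_peak: float, guard_load: float, vertical_frac: float
) -> float:
    """Vertical raised-cosine amplitude (x BW) such that the peak
    rear-plate norm equals ``push_peak`` x BW.  Dimensionless, so it is
    independent of body weight and push duration."""
    u = np.linspace(0.0, 1.0, 2001)
    fx = forward_peak * _raised_cosine(u)
    rcv = _raised_cosine(u / vertical_frac)

    def excess(az: float) -> float:
        fz = guard_load * _unload(u) + az * rcv
        return float(np.max(np.hypot(fx, fz))) - push_peak

    if excess(0.0) >= 0.0:
        return 0.0
    return float(brentq(excess, 0.0, 5.0, xtol=1e-10))


def _onset_lead(behavior: FencerBehavior) -> float:
    """Time between push start and the forward component crossing 1% BW."""
    frac = 0.02 / behavior.push_forward_peak  # rc(u) = 0.01/Ax
    u = np.arccos(1.0 - frac) / (2.0 * np.pi)
    return float(u * behavior.push_duration)


def generate_grf(
    profile: FencerProfile,
    behavior: FencerBehavior,
    onset_time: float,
    duration: float,
    rate: float = 1000.0,
    rng: np.random.Generator | None = None,
    shape: str = "raised_cosine",
) -> ForceRecording:
    """Synthesize rear/front plate forces for one trial.

    Before the push the rear plate carries ``guard_rear_load`` x BW
    vertically with zero-mean noise on every component.  The push is
    placed so that the forward component crosses 1% BW exactly at
    ``onset_time`` (the onset definition used by the event detector).

    ``shape="triangular"`` replaces the push with a pure-forward
    symmetric triangular pulse starting exactly at ``onset_time`` (zero
    baseline, no vertical force): an analytic fixture whose half-impulse
    point is the apex.
    """
    if behavior.push_peak <= DEFAULT_THRESHOLD_BW:
        warnings.warn(
            f"push_peak {behavior.push_peak} <= {DEFAULT_THRESHOLD_BW} x BW: "
            "the target-jump trigger will never fire",
            stacklevel=2,
        )
    bw = profile.bw
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    D = behavior.push_duration

    rear = np.zeros((n, 3))
    front = np.zeros((n, 3))
    if shape == "triangular":
        u = (t - onset_time) / D
        tri = 1.0 - np.abs(2.0 * np.clip(u, 0.0, 1.0) - 1.0)
        tri = np.where((u >= 0.0) & (u <= 1.0), tri, 0.0)
        rear[:, 0] = behavior.push_forward_peak * bw * tri
    elif shape == "raised_cosine":
        push_start = onset_time - _onset_lead(behavior)
        u = (t - push_start) / D
        az = _vertical_amplitude(
            behavior.push_peak,
            behavior.push_forward_peak,
            behavior.guard_rear_load,
            behavior.push_vertical_frac,
        )
        rear[:, 0] = behavior.push_forward_peak * bw * _raised_cosine(u)
        rear[:, 2] = bw * (
            behavior.guard_rear_load * _unload(u)
            + az * _raised_cosine(u / behavior.push_vertical_frac)
        )
        front[:, 2] = (1.0 - behavior.guard_rear_load) * bw * _unload(u)
    else:
        raise ValueError(f"unknown push shape {shape!r}")

    if rng is not None and behavior.grf_noise_bw > 0:
        sd = behavior.grf_noise_bw * bw
        rear += rng.normal(0.0, sd, rear.shape)
        front += rng.normal(0.0, sd, front.shape)
    return ForceRecording(rate=rate, t0=0.0, rear=rear, front=front)


# ---------------------------------------------------------------------------
# sword trajectory


def _minjerk_s(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _minjerk_ds(tau: np.ndarray) -> np.ndarray:
    return 30 * tau**2 - 60 * tau**3 + 30 * tau**4


def _minjerk_dds(tau: np.ndarray) -> np.ndarray:
    return 60 * tau - 180 * tau**2 + 120 * tau**3


@lru_cache(maxsize=8)
def crossing_fraction(overshoot_frac: float) -> float:
    """Normalized time tau* at which a minimum-jerk reach planned to
    1 + overshoot of the aim distance passes the aim point itself."""
    target = 1.0 / (1.0 + overshoot_frac)
    return float(brentq(lambda tau: _minjerk_s(np.asarray(tau)) - target, 0.5, 1.0 - 1e-12))


def _quintic_coeffs(
    p0: np.ndarray, v0: np.ndarray, a0: np.ndarray, p1: np.ndarray, T: float
) -> np.ndarray:
    """Per-axis quintic from state (p0, v0, a0) at t=0 to rest (p1, 0, 0)
    at t=T.  Returns coefficients (3 axes x 6), lowest order first."""
    c = np.zeros((3, 6))
    c[:, 0] = p0
    c[:, 1] = v0
    c[:, 2] = a0 / 2.0
    A = np.array(
        [
            [T**3, T**4, T**5],
            [3 * T**2, 4 * T**3, 5 * T**4],
            [6 * T, 12 * T**2, 20 * T**3],
        ]
    )
    for ax in range(3):
        b = np.array(
            [
                p1[ax] - (c[ax, 0] + c[ax, 1] * T + c[ax, 2] * T**2),
                -(c[ax, 1] + 2 * c[ax, 2] * T),
                -2 * c[ax, 2],
            ]
        )
        c[ax, 3:] = np.linalg.solve(A, b)
    return c


def _quintic_eval(c: np.ndarray, t: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Evaluate the quintic (or a derivative) at times t; (len(t), 3)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros((t.size, 3))
    for ax in range(3):
        poly = np.polynomial.Polynomial(c[ax])
        out[:, ax] = poly.deriv(deriv)(t) if deriv else poly(t)
    return out


@dataclass(frozen=True)
class _ReachPath:
    """Piecewise path of the sword tip for one trial (times absolute)."""

    onset: float
    p0: np.ndarray
    pf1: np.ndarray
    T1: float  # segment-1 total duration (beyond the plane crossing)
    t_replan: float | None
    coeffs2: np.ndarray | None  # quintic coefficients, local time t - t_replan
    T2: float | None
    touch_time: float
    touch_point: tuple[float, float]

    def position(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        pos = np.empty((t.size, 3))
        before = t < self.onset
        pos[before] = self.p0
        if self.t_replan is None:
            seg1 = ~before
        else:
            seg1 = (~before) & (t < self.t_replan)
            seg2 = t >= self.t_replan
            pos[seg2] = _quintic_eval(self.coeffs2, t[seg2] - self.t_replan)
        tau = np.clip((t[seg1] - self.onset) / self.T1, 0.0, 1.0)
        pos[seg1] = self.p0 + np.outer(_minjerk_s(tau), self.pf1 - self.p0)
        return pos

    def forward_velocity(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        v = np.zeros(t.size)
        if self.t_replan is None:
            seg1 = t >= self.onset
        else:
            seg1 = (t >= self.onset) & (t < self.t_replan)
            seg2 = t >= self.t_replan
            v[seg2] = _quintic_eval(self.coeffs2, t[seg2] - self.t_replan, deriv=1)[:, 0]
        tau = np.clip((t[seg1] - self.onset) / self.T1, 0.0, 1.0)
        v[seg1] = _minjerk_ds(tau) * (self.pf1[0] - self.p0[0]) / self.T1
        return v


def _first_crossing(c: np.ndarray, T: float, screen_x: float) -> float:
    """First time in (0, T] at which the quintic's x coordinate reaches
    screen_x (local time)."""
    grid = np.linspace(0.0, T, 256)
    x = _quintic_eval(c, grid)[:, 0] - screen_x
    idx = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0))
    if idx.size == 0:
        if x[0] >= 0:
            return 0.0
        raise RuntimeError("replanned path never reaches the touch plane")
    i = idx[0]
    f = lambda tt: _quintic_eval(c, np.asarray([tt]))[0, 0] - screen_x
    return float(brentq(f, grid[i], grid[i + 1], xtol=1e-10))


def plan_reach(
    profile: FencerProfile,
    behavior: FencerBehavior,
    onset_time: float,
    mt_initial: float,
    aim_initial: tuple[float, float],
    screen_x: float,
    display_time: float | None = None,
    aim_final: tuple[float, float] | None = None,
    mt_final: float | None = None,
) -> _ReachPath:
    """Plan the tip path; re-plan at ``display_time`` if a jump occurred.

    The nominal reach is minimum-jerk from the guard position toward a
    point ``overshoot_frac`` beyond the aim along the same line, with
    total duration scaled so the plane crossing happens at
    ``onset_time + mt_initial`` exactly.  On a jump the remaining path is
    a quintic from the current state to the new (collinear-extended) aim,
    its duration refined so the crossing lands at ``onset_time +
    mt_final``.  A display falling after the planned touch is ignored.
    """
    x0 = behavior.guard_tip_frac[0] * screen_x
    z0 = behavior.guard_tip_frac[1] * profile.height
    y0 = 0.08 if profile.handedness == "right" else -0.08
    p0 = np.array([x0, y0, z0])
    delta = behavior.overshoot_frac
    tau_star = crossing_fraction(delta)

    aim1 = np.array([screen_x, aim_initial[0], aim_initial[1]])
    pf1 = p0 + (1.0 + delta) * (aim1 - p0)
    T1 = mt_initial / tau_star
    touch_time = onset_time + mt_initial
    touch_point = (float(aim1[1]), float(aim1[2]))

    replan = (
        display_time is not None
        and aim_final is not None
        and display_time < touch_time
    )
    if not replan:
        return _ReachPath(
            onset=onset_time,
            p0=p0,
            pf1=pf1,
            T1=T1,
            t_replan=None,
            coeffs2=None,
            T2=None,
            touch_time=touch_time,
            touch_point=touch_point,
        )

    td = float(display_time)
    tau_d = (td - onset_time) / T1
    pd = p0 + _minjerk_s(np.asarray(tau_d)) * (pf1 - p0)
    vd = _minjerk_ds(np.asarray(tau_d)) * (pf1 - p0) / T1
    ad = _minjerk_dds(np.asarray(tau_d)) * (pf1 - p0) / T1**2
    aim2 = np.array([screen_x, aim_final[0], aim_final[1]])
    pf2 = pd + (1.0 + delta) * (aim2 - pd)
    t_target = (onset_time + (mt_final if mt_final is not None else mt_initial)) - td

    # secant refinement of the segment duration so the plane crossing
    # lands at the planned touch time
    T2 = t_target / tau_star
    c = _quintic_coeffs(pd, vd, ad, pf2, T2)
    err = _first_crossing(c, T2, screen_x) - t_target
    T2_prev, err_prev = T2, err
    T2 = T2 * 1.05
    for _ in range(12):
        c = _quintic_coeffs(pd, vd, ad, pf2, T2)
        err = _first_crossing(c, T2, screen_x) - t_target
        if abs(err) < 1e-9 or err == err_prev:
            break
        T2, T2_prev, err_prev = (
            T2 - err * (T2 - T2_prev) / (err - err_prev),
            T2,
            err,
        )
    cross_local = _first_crossing(c, T2, screen_x)
    pt = _quintic_eval(c, np.asarray([cross_local]))[0]
    return _ReachPath(
        onset=onset_time,
        p0=p0,
        pf1=pf1,
        T1=T1,
        t_replan=td,
        coeffs2=c,
        T2=T2,
        touch_time=td + cross_local,
        touch_point=(float(pt[1]), float(pt[2])),
    )


def generate_sword_trajectory(
    profile: FencerProfile,
    behavior: FencerBehavior,
    path: _ReachPath,
    duration: float,
    rate: float = 250.0,
    rng: np.random.Generator | None = None,
) -> SwordRecording:
    """Sample the planned reach into marker time series.

    The blade-base marker is the tip offset by a fixed blade vector, and
    both markers receive isotropic Gaussian noise of SD
    ``behavior.marker_noise`` when an ``rng`` is given.
    """
    n = int(round(duration * rate))
    if n < 5:
        raise ValueError("recording too short")
    t = np.arange(n) / rate
    tip = path.position(t)
    base = tip + np.asarray(behavior.blade_offset)
    if rng is not None and behavior.marker_noise > 0:
        tip = tip + rng.normal(0.0, behavior.marker_noise, tip.shape)
        base = base + rng.normal(0.0, behavior.marker_noise, base.shape)
    return SwordRecording(rate=rate, t0=0.0, base=base, tip=tip)


# ---------------------------------------------------------------------------
# full trial assembly


def simulate_trial(
    profile: FencerProfile,
    behavior: FencerBehavior,
    spec: TrialSpec,
    rng: np.random.Generator,
    apparatus: ApparatusConfig = ApparatusConfig(),
) -> SimulatedTrial:
    """Simulate one complete trial timeline.

    Cue at t = 0; stimulus (target appearance) at cue_lead + foreperiod;
    movement onset at stimulus + RT; the target jump (Moving-type
    conditions) fires from the force-norm trigger and is displayed one
    latency later; the touch closes the trial.
    """
    plastron = build_plastron(
        profile, apparatus.vertical_coeff, apparatus.distance_coeff
    )
    zones = corner_zones(plastron, apparatus.zone_fraction)
    initial_target = sample_target(
        zones[spec.initial_zone], spec.diameter, rng
    )

    stimulus = apparatus.cue_lead + spec.foreperiod
    rt = sample_reaction_time(behavior, spec.condition, rng)
    onset = stimulus + rt
    mt_nom = max(0.3, rng.normal(behavior.mt_base, behavior.mt_sigma))
    duration = onset + mt_nom + behavior.mt_penalty_moving + 0.5

    force = generate_grf(
        profile, behavior, onset, duration, apparatus.force_rate, rng
    )
    moving = spec.condition in MOVING_LIKE
    trig = scan_trigger(
        force,
        apparatus.threshold_bw,
        stimulus,
        profile.bw,
        apparatus.display_latency,
        moving,
    )

    sigma = behavior.aim_sigma[spec.condition]
    aim1 = np.asarray(initial_target.center) + rng.normal(0.0, sigma, 2)
    final_target = initial_target
    aim2 = None
    mt_final = mt_nom
    display = trig.display_time if trig.fired else None
    if moving and display is not None and display < onset + mt_nom:
        final_target = sample_target(zones[spec.final_zone], spec.diameter, rng)
        aim2 = tuple(np.asarray(final_target.center) + rng.normal(0.0, sigma, 2))
        mt_final = mt_nom + behavior.mt_penalty_moving
    else:
        display = None

    path = plan_reach(
        profile,
        behavior,
        onset,
        mt_nom,
        (float(aim1[0]), float(aim1[1])),
        plastron.screen_x,
        display_time=display,
        aim_final=aim2,
        mt_final=mt_final,
    )
    sword = generate_sword_trajectory(
        profile, behavior, path, path.touch_time + 0.08, apparatus.marker_rate, rng
    )
    grid = np.linspace(onset, path.touch_time, 512)
    msv = float(np.max(path.forward_velocity(grid)))
    intended = aim2 if aim2 is not None else (float(aim1[0]), float(aim1[1]))
    truth = GroundTruth(
        stimulus_time=stimulus,
        onset_time=onset,
        trigger_time=trig.trigger_time,
        display_time=display,
        touch_time=path.touch_time,
        intended_touch_point=(float(intended[0]), float(intended[1])),
        touch_point=path.touch_point,
        rt=rt,
        mt=path.touch_time - onset,
        anticipated=rt < 0.1,
        msv=msv,
    )
    return SimulatedTrial(
        spec=spec,
        force=force,
        sword=sword,
        truth=truth,
        initial_target=initial_target,
        final_target=final_target,
    )


def simulate_plan(
    profile: FencerProfile,
    behavior: FencerBehavior,
    plan: TrialPlan,
    rng: np.random.Generator,
    apparatus: ApparatusConfig = ApparatusConfig(),
) -> list[SimulatedTrial]:
    """Simulate every trial of a plan in order."""
    return [
        simulate_trial(profile, behavior, spec, rng, apparatus)
        for spec in plan.trials
    ]


def simulate_calibration_assaults(
    profile: FencerProfile,
    behavior: FencerBehavior,
    n: int,
    rng: np.random.Generator,
    rate: float = 1000.0,
) -> list[tuple[ForceRecording, float, float]]:
    """Simulate standard (unperturbed) lunges for threshold calibration.

    Returns ``(recording, onset, touch)`` triples ready for
    :func:`lungesim.trigger.derive_force_threshold`.
    """
    out = []
    for _ in range(n):
        onset = 0.5 + rng.uniform(0.0, 0.2)
        mt = max(0.3, rng.normal(behavior.mt_base, behavior.mt_sigma))
        rec = generate_grf(profile, behavior, onset, onset + mt + 0.2, rate, rng)
        out.append((rec, onset, onset + mt))
    return out


# ---------------------------------------------------------------------------
# fast result-level simulation (no signal synthesis)


def simulate_trial_results(
    profile: FencerProfile,
    behavior: FencerBehavior,
    plan: TrialPlan,
    rng: np.random.Generator,
    apparatus: ApparatusConfig = ApparatusConfig(),
) -> pd.DataFrame:
    """Draw the six performance variables directly from the behavioural
    model, bypassing signal synthesis and event detection.

    This is the analytic shortcut used for large calibration studies
    (statistical power, type-I error) where thousands of replicate
    cohorts are needed; it assumes the trigger always fires in
    Moving-type trials and uses the closed-form minimum-jerk peak
    velocity for MSV.  The full signal path is validated separately.
    """
    specs = plan.trials
    n = len(specs)
    cond = np.array([s.condition for s in specs], dtype=object)
    diam = np.array([s.diameter for s in specs])
    medians = np.array([behavior.rt_median[c] for c in cond])
    sigmas = np.array([behavior.aim_sigma[c] for c in cond])
    jump = np.array([c in MOVING_LIKE for c in cond])

    rt = _sample_rt_array(
        medians,
        behavior.rt_sigma,
        behavior.rt_bounds,
        behavior.anticipation_prob,
        behavior.anticipation_range,
        rng,
    )
    mt = np.maximum(0.3, rng.normal(behavior.mt_base, behavior.mt_sigma, n))
    mt = mt + jump * behavior.mt_penalty_moving
    err = rng.normal(0.0, 1.0, (n, 2)) * sigmas[:, None]
    accuracy = np.hypot(err[:, 0], err[:, 1])
    success = accuracy <= diam / 2

    screen_x = apparatus.distance_coeff * profile.height
    lx = (1.0 + behavior.overshoot_frac) * (
        screen_x - behavior.guard_tip_frac[0] * screen_x
    )
    tau_star = crossing_fraction(behavior.overshoot_frac)
    msv = 1.875 * lx / (mt / tau_star)

    return pd.DataFrame(
        {
            "fencer_id": profile.id,
            "trial": [s.index for s in specs],
            "session": [s.session for s in specs],
            "condition": [s.condition.value for s in specs],
            "diameter": diam,
            "success": success,
            "accuracy": accuracy,
            "rt": rt,
            "mt": mt,
            "rrt": rt + mt,
            "msv": msv,
            "anticipated": rt < 0.1,
            "valid": True,
        }
    )


# ---------------------------------------------------------------------------
# cohorts


def sample_cohort(
    n: int,
    rng: np.random.Generator,
    height_mean: float = 1.78,
    height_sd: float = 0.06,
    mass_mean: float = 75.0,
    mass_sd: float = 8.0,
) -> list[FencerProfile]:
    """Draw anthropometric profiles for a cohort of ``n`` fencers.

    Heights and masses are normal around typical adult-male fencer
    values; handedness alternates so both occlusion exclusions are
    exercised.
    """
    heights = np.clip(rng.normal(height_mean, height_sd, n), 1.55, 2.10)
    masses = np.clip(rng.normal(mass_mean, mass_sd, n), 45.0, 130.0)
    levels = ["national"] * 5 + ["regional"] * 5 + ["recreational"]
    return [
        FencerProfile(
            id=f"F{i + 1:02d}",
            height=float(heights[i]),
            mass=float(masses[i]),
            handedness="right" if i % 2 == 0 else "left",
            level=levels[i % len(levels)],
        )
        for i in range(n)
    ]


def perturb_behavior(
    base: FencerBehavior,
    rng: np.random.Generator,
    rt_scale_sd: float = 0.12,
    mt_shift_sd: float = 0.06,
    aim_scale_sd: float = 0.20,
) -> FencerBehavior:
    """Between-fencer variation: scale RT medians and aiming scatter by a
    common lognormal factor and shift the base movement time, keeping the
    within-condition structure (the injected effects) intact."""
    rt_f = float(np.exp(rng.normal(0.0, rt_scale_sd)))
    aim_f = float(np.exp(rng.normal(0.0, aim_scale_sd)))
    mt_shift = float(rng.normal(0.0, mt_shift_sd))
    return replace(
        base,
        rt_median={c: max(base.rt_bounds[0], m * rt_f) for c, m in base.rt_median.items()},
        aim_sigma={c: s * aim_f for c, s in base.aim_sigma.items()},
        mt_base=max(0.4, base.mt_base + mt_shift),
    )
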