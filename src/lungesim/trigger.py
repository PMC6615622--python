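"""Impulse-based threshold derivation and the target-jump trigger engine.

The target jump must fire once the attack is mechanically irreversible.
Offline, that point is defined on calibration assaults as the instant at
which a fraction (default one half) of the total forward impulse of the
lunge has been produced by the rear foot; the rear-plate force *norm* at
that instant, expressed as a multiple of body weight, becomes a
time-independent threshold usable in real time (about 1.06 x BW for
standard lunges).  Online, the engine fires at the first force sample
after the stimulus whose rear-plate norm strictly exceeds the threshold,
and the display changes one fixed latency later (35 ms by default).

Conventions kept deliberately distinct: the *impulse* integrates the
forward (x) component only, while the *trigger* compares the full force
norm; the offline derivation interpolates between samples, while the
online trigger works at sample resolution (real-time semantics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np
from scipy.integrate import cumulative_trapezoid

if TYPE_CHECKING:  # pragma: no cover
    from .fencer_sim import ForceRecording
    from .geometry import FencerProfile

#: default end-to-end latency between force acquisition and stimulus
#: display, s (capture and rendering latencies collapsed into one number)
DISPLAY_LATENCY = 0.035

#: default fraction of total forward impulse defining irreversibility
IMPULSE_FRACTION = 0.5

#: nominal trigger threshold as a multiple of body weight
DEFAULT_THRESHOLD_BW = 1.06


@dataclass(frozen=True)
class ThresholdModel:
    """Result of the offline calibration."""

    impulse_fraction: float
    force_fraction_bw: float  # threshold, x body weight
    n_calibration_trials: int

    def __post_init__(self) -> None:
        if not 0.0 < self.impulse_fraction < 1.0:
            raise ValueError("impulse_fraction must be in (0, 1)")
        if self.force_fraction_bw <= 0:
            raise ValueError("force_fraction_bw must be positive")


@dataclass(frozen=True)
class TriggerEvent:
    """Outcome of the online engine for one trial.

    ``fired`` is True only when a display change was actually emitted;
    in Fixed-type conditions the threshold crossing time is still logged
    (``trigger_time``) but no jump happens and ``display_time`` is None.
    """

    trigger_time: float | None
    display_time: float | None
    fired: bool


def cumulative_forward_impulse(
    rec: "ForceRecording", window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative trapezoidal integral of the forward rear-plate force.

    Returns ``(t, impulse)`` over ``window = (t_a, t_b)``, with the
    integral starting at 0 at ``t_a``.  By convention the window runs
    from the detected movement onset to the screen touch.
    """
    t = rec.t
    t_a, t_b = window
    mask = (t >= t_a) & (t <= t_b)
    if mask.sum() < 2:
        raise ValueError(f"empty or degenerate integration window {window}")
    tw = t[mask]
    fx = rec.rear[mask, 0]
    imp = cumulative_trapezoid(fx, tw, initial=0.0)
    return tw, imp


def derive_force_threshold(
    calibration_recs: Sequence[tuple["ForceRecording", float, float]],
    profile: "FencerProfile",
    impulse_fraction: float = IMPULSE_FRACTION,
) -> ThresholdModel:
    """Convert the impulse criterion into a force-norm threshold.

    For each calibration recording ``(rec, onset, touch)``, find the
    time ``t*`` at which the cumulative forward impulse over
    ``[onset, touch]`` reaches ``impulse_fraction`` of its total (linear
    interpolation between samples), read the rear-plate force norm at
    ``t*`` as a multiple of body weight, and average across recordings.
    """
    if not calibration_recs:
        raise ValueError("at least one calibration recording is required")
    values = []
    for rec, onset, touch in calibration_recs:
        tw, imp = cumulative_forward_impulse(rec, (onset, touch))
        total = imp[-1]
        if total <= 0:
            warnings.warn("calibration trial with non-positive total impulse skipped")
            continue
        target = impulse_fraction * total
        # first index at or above the target level (argmax tolerates the
        # small non-monotonicity sensor noise induces); interpolate backwards
        k = int(np.argmax(imp >= target))
        if k == 0:
            t_star = tw[0]
        else:
            k = min(k, len(tw) - 1)
            denom = imp[k] - imp[k - 1]
            frac = 0.0 if denom == 0 else (target - imp[k - 1]) / denom
            t_star = tw[k - 1] + frac * (tw[k] - tw[k - 1])
        norm = np.linalg.norm(rec.rear, axis=1)
        values.append(float(np.interp(t_star, rec.t, norm)) / profile.bw)
    if not values:
        raise ValueError("all calibration trials had zero total impulse")
    return ThresholdModel(
        impulse_fraction=impulse_fraction,
        force_fraction_bw=float(np.mean(values)),
        n_calibration_trials=len(values),
    )


def run_trigger(
    stream: Iterable[tuple[float, float]],
    threshold_bw: float,
    stimulus_time: float,
    bw: float,
    latency: float = DISPLAY_LATENCY,
    moving: bool = True,
) -> TriggerEvent:
    """Streaming trigger: fire at the first sample strictly after the
    stimulus whose rear-plate force norm strictly exceeds the threshold.

    ``stream`` yields ``(t, norm)`` pairs in time order (see
    :func:`norm_stream`).  Crossings before the stimulus are ignored —
    the target jump cannot occur until the fencer actually moves in
    response to it.  Fires at most once; ``display_time = trigger_time +
    latency``.  In Fixed-type conditions (``moving=False``) the crossing
    is logged but no display change is emitted.
    """
    if threshold_bw <= 0:
        raise ValueError("threshold must be positive")
    level = threshold_bw * bw
    for t, norm in stream:
        if t > stimulus_time and norm > level:
            if moving:
                return TriggerEvent(
                    trigger_time=float(t),
                    display_time=float(t) + latency,
                    fired=True,
                )
            return TriggerEvent(trigger_time=float(t), display_time=None, fired=False)
    return TriggerEvent(trigger_time=None, display_time=None, fired=False)


def norm_stream(rec: "ForceRecording") -> Iterable[tuple[float, float]]:
    """Adapt a completed recording into the sample stream the online
    engine consumes."""
    norms = np.linalg.norm(rec.rear, axis=1)
    return zip(rec.t.tolist(), norms.tolist())


def scan_trigger(
    rec: "ForceRecording",
    threshold_bw: float,
    stimulus_time: float,
    bw: float,
    latency: float = DISPLAY_LATENCY,
    moving: bool = True,
) -> TriggerEvent:
    """Vectorized offline scan of a completed recording; must agree with
    :func:`run_trigger` on the equivalent stream (equivalence is a tested
    invariant)."""
    norms = np.linalg.norm(rec.rear, axis=1)
    hits = np.flatnonzero((rec.t > stimulus_time) & (norms > threshold_bw * bw))
    if hits.size == 0:
        return TriggerEvent(trigger_time=None, display_time=None, fired=False)
    t0 = float(rec.t[hits[0]])
    if moving:
        return TriggerEvent(trigger_time=t0, display_time=t0 + latency, fired=True)
    return TriggerEvent(trigger_time=t0, display_time=None, fired=False)
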