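"""Event detection and per-trial performance variables.

Six variables summarize each attack:

* **Success** — did the sword tip land within the target radius of the
  *final* target position (a Moving-trial touch on the initial position
  is a miss);
* **Accuracy** — Euclidean distance (m), in the touch plane, from the
  touch point to the final target centre;
* **RT** — stimulus appearance to movement onset, the first force
  sample whose forward rear-plate component exceeds 1% of body weight;
* **MT** — movement onset to screen touch;
* **RRT** — RT + MT (exact by construction);
* **MSV** — maximum antero-posterior velocity of the blade-base marker.

Condition summaries average all trials of a cell regardless of success.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .fencer_sim import ForceRecording, SimulatedTrial, SwordRecording
from .geometry import FencerProfile, TargetSpec
from .scenario import UNCERTAIN, Condition, TrialSpec

#: onset threshold as a fraction of body weight (forward component)
ONSET_FRACTION_BW = 0.01

#: RT below this is physiologically impossible: the fencer anticipated
ANTICIPATION_LIMIT = 0.1  # s

#: zero-phase low-pass cutoff applied before differentiating marker data
MSV_CUTOFF_HZ = 10.0

VARIABLES = ("success", "accuracy", "rt", "mt", "rrt", "msv")


class NoOnsetError(RuntimeError):
    """Forward force never exceeded the onset threshold after the stimulus."""


class NoTouchError(RuntimeError):
    """The sword tip never crossed the touch plane."""


@dataclass(frozen=True)
class TrialEvents:
    """Detected event times and touch location for one trial."""

    stimulus_time: float
    onset_time: float
    touch_time: float
    touch_point: tuple[float, float]


@dataclass(frozen=True)
class TrialResult:
    """The six performance variables for one attack."""

    success: bool
    accuracy: float  # m
    rt: float  # s
    mt: float  # s
    rrt: float  # s
    msv: float  # m/s
    anticipated: bool
    condition: Condition
    diameter: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid:
            if abs(self.rrt - (self.rt + self.mt)) > 1e-12:
                raise ValueError("RRT must equal RT + MT exactly")
            if self.accuracy < 0:
                raise ValueError("accuracy must be non-negative")
            if self.success and self.accuracy > self.diameter / 2:
                raise ValueError("a successful touch cannot lie outside the target")


def detect_movement_onset(
    force: ForceRecording,
    stimulus_time: float,
    profile: FencerProfile,
    fraction_bw: float = ONSET_FRACTION_BW,
) -> float:
    """Movement onset: first sample after the stimulus whose forward
    rear-plate force exceeds ``fraction_bw`` of body weight."""
    t = force.t
    if stimulus_time < t[0] or stimulus_time > t[-1]:
        raise ValueError("recording does not cover the stimulus time")
    level = fraction_bw * profile.bw
    hits = np.flatnonzero((t > stimulus_time) & (force.rear[:, 0] > level))
    if hits.size == 0:
        raise NoOnsetError(
            f"forward force never exceeded {fraction_bw:.0%} BW after the stimulus"
        )
    return float(t[hits[0]])


def detect_touch(
    sword: SwordRecording, screen_x: float
) -> tuple[float, tuple[float, float]]:
    """Screen touch: first crossing of the plane ``x = screen_x`` by the
    tip marker, with time and (y, z) linearly interpolated between the
    straddling samples (exact for straight-line motion)."""
    x = sword.tip[:, 0]
    t = sword.t
    at = np.flatnonzero(x >= screen_x)
    if at.size == 0:
        raise NoTouchError("sword tip never reached the touch plane")
    k = int(at[0])
    if k == 0 or x[k] == screen_x:
        # grazing or starting on the plane: take that sample as-is
        return float(t[k]), (float(sword.tip[k, 1]), float(sword.tip[k, 2]))
    frac = (screen_x - x[k - 1]) / (x[k] - x[k - 1])
    tt = t[k - 1] + frac * (t[k] - t[k - 1])
    yz = sword.tip[k - 1, 1:] + frac * (sword.tip[k, 1:] - sword.tip[k - 1, 1:])
    return float(tt), (float(yz[0]), float(yz[1]))


def compute_msv(sword: SwordRecording, cutoff_hz: float = MSV_CUTOFF_HZ) -> float:
    """Maximum antero-posterior velocity of the blade-base marker.

    The x position is zero-phase low-pass filtered (4th-order
    Butterworth, default 10 Hz) before central differencing; the filter
    is exact on linear signals, so a constant-velocity segment passes
    through unchanged.
    """
    x = sword.base[:, 0]
    if x.size < 5:
        raise ValueError("recording too short for a velocity estimate")
    sos = butter(4, cutoff_hz, btype="low", fs=sword.rate, output="sos")
    # generous odd-extension padding keeps the zero-phase filter exact on
    # linear segments right up to the recording edges
    padlen = min(x.size - 2, int(0.5 * sword.rate))
    xf = sosfiltfilt(sos, x, padlen=padlen)
    v = np.gradient(xf, 1.0 / sword.rate)
    return float(np.max(v))


def score_trial(
    events: TrialEvents,
    trial: TrialSpec,
    final_target: TargetSpec,
    msv: float,
) -> TrialResult:
    """Assemble the six variables from detected events.

    Accuracy is measured to the *final* target centre; a touch exactly on
    the target boundary (accuracy == diameter/2) counts as a success.
    """
    dy = events.touch_point[0] - final_target.y
    dz = events.touch_point[1] - final_target.z
    accuracy = float(np.hypot(dy, dz))
    rt = events.onset_time - events.stimulus_time
    mt = events.touch_time - events.onset_time
    return TrialResult(
        success=accuracy <= trial.diameter / 2,
        accuracy=accuracy,
        rt=rt,
        mt=mt,
        rrt=rt + mt,
        msv=msv,
        anticipated=rt < ANTICIPATION_LIMIT,
        condition=trial.condition,
        diameter=trial.diameter,
    )


def analyze_trial(
    sim: SimulatedTrial, profile: FencerProfile, screen_x: float
) -> TrialResult:
    """Run the full detection pipeline on one simulated (or recorded)
    trial; an undetectable onset or touch yields an invalid result."""
    try:
        onset = detect_movement_onset(sim.force, sim.truth.stimulus_time, profile)
        touch_time, touch_point = detect_touch(sim.sword, screen_x)
    except (NoOnsetError, NoTouchError):
        return TrialResult(
            success=False,
            accuracy=np.nan,
            rt=np.nan,
            mt=np.nan,
            rrt=np.nan,
            msv=np.nan,
            anticipated=False,
            condition=sim.spec.condition,
            diameter=sim.spec.diameter,
            valid=False,
        )
    events = TrialEvents(
        stimulus_time=sim.truth.stimulus_time,
        onset_time=onset,
        touch_time=touch_time,
        touch_point=touch_point,
    )
    return score_trial(events, sim.spec, sim.final_target, compute_msv(sim.sword))


def results_frame(
    results: list[TrialResult], fencer_id: str, plan_trials: list[TrialSpec]
) -> pd.DataFrame:
    """Tidy per-trial results table (one row per attack)."""
    rows = []
    for spec, r in zip(plan_trials, results):
        rows.append(
            {
                "fencer_id": fencer_id,
                "trial": spec.index,
                "session": spec.session,
                "condition": r.condition.value,
                "diameter": r.diameter,
                "success": r.success,
                "accuracy": r.accuracy,
                "rt": r.rt,
                "mt": r.mt,
                "rrt": r.rrt,
                "msv": r.msv,
                "anticipated": r.anticipated,
                "valid": r.valid,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# summaries


#: analysis cells: the four conditions, the pooled Uncertain condition,
#: the two target sizes (all conditions pooled), and the overall pool
CELLS = (
    "Fixed",
    "Moving",
    "UncertainFixed",
    "UncertainMoving",
    "Uncertain",
    "Small",
    "Big",
    "All",
)

_SMALL, _BIG = 0.05, 0.10


def _cell_mask(df: pd.DataFrame, cell: str) -> pd.Series:
    if cell == "Uncertain":
        return df["condition"].isin([c.value for c in UNCERTAIN])
    if cell == "Small":
        return df["diameter"] < (_SMALL + _BIG) / 2
    if cell == "Big":
        return df["diameter"] >= (_SMALL + _BIG) / 2
    if cell == "All":
        return pd.Series(True, index=df.index)
    return df["condition"] == cell


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-fencer, per-cell means of the six variables.

    Success is expressed as a percentage.  Means are taken over all
    valid trials of a cell regardless of success; an empty cell is
    reported with NaN means and n = 0.
    """
    rows = []
    for fencer_id, sub in results.groupby("fencer_id", sort=True):
        sub = sub[sub["valid"]]
        for cell in CELLS:
            cell_df = sub[_cell_mask(sub, cell)]
            row = {"fencer_id": fencer_id, "cell": cell, "n": len(cell_df)}
            for var in VARIABLES:
                if len(cell_df) == 0:
                    row[var] = np.nan
                elif var == "success":
                    row[var] = 100.0 * cell_df["success"].mean()
                else:
                    row[var] = cell_df[var].mean()
            rows.append(row)
    return pd.DataFrame(rows)


def rank_fencers(summaries: pd.DataFrame) -> pd.DataFrame:
    """Fencers ordered by pooled mean accuracy, best (smallest) first."""
    pooled = summaries[summaries["cell"] == "All"].copy()
    return pooled.sort_values("accuracy", kind="stable").reset_index(drop=True)
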