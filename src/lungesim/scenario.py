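"""Randomized 120-trial attack protocol.

Each fencer performs 120 lunges split into 4 sessions of 30 consecutive
trials.  Four task conditions are cued by a colour projected around the
plastron 3 s before the target appears:

* **Fixed** (green) — the target will not move during the attack;
* **Moving** (red) — the target will jump once the attack is committed;
* **Uncertain** (blue) — the target may or may not move, resolving into
  the **UncertainFixed** and **UncertainMoving** sub-conditions.

Composition is fully determined: 16 Fixed trials (4 repetitions x 4
zones), 44 Moving trials (4 repetitions x 11 allowed zone transitions),
and the same again under uncertainty.  Of the 4x3 = 12 ordered zone
transitions, the one in which the sword arm would occlude the final
target is excluded: upper-contralateral to lower-lateral, i.e. UL->LR
for a right-handed fencer and UR->LL for a left-handed one.  Each
4-repetition cell is split 2/2 across the two target diameters so size
is orthogonal to condition and zone.  The target appears after a random
foreperiod of 0.5-1.2 s once the fencer is en garde.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import DIAMETERS, ZONE_LABELS, FencerProfile


class Condition(str, Enum):
    FIXED = "Fixed"
    MOVING = "Moving"
    UNCERTAIN_FIXED = "UncertainFixed"
    UNCERTAIN_MOVING = "UncertainMoving"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: cue colour projected around the plastron; the Uncertain sub-conditions
#: share the blue cue (the fencer cannot distinguish them in advance)
CUE_COLORS = {
    Condition.FIXED: "green",
    Condition.MOVING: "red",
    Condition.UNCERTAIN_FIXED: "blue",
    Condition.UNCERTAIN_MOVING: "blue",
}

#: conditions in which the target actually jumps mid-movement
MOVING_LIKE = (Condition.MOVING, Condition.UNCERTAIN_MOVING)

#: conditions pooled as "Uncertain" in the analysis
UNCERTAIN = (Condition.UNCERTAIN_FIXED, Condition.UNCERTAIN_MOVING)

FOREPERIOD_RANGE = (0.5, 1.2)  # s
N_TRIALS = 120
N_SESSIONS = 4
TRIALS_PER_SESSION = 30
REPS_PER_CELL = 4
#: expected composition per condition
COMPOSITION = {
    Condition.FIXED: 16,
    Condition.MOVING: 44,
    Condition.UNCERTAIN_FIXED: 16,
    Condition.UNCERTAIN_MOVING: 44,
}

#: seconds the cue colour is shown before the en-garde foreperiod starts
CUE_LEAD = 3.0


@dataclass(frozen=True)
class TrialSpec:
    """One planned attack."""

    index: int  # 1..120 in execution order
    session: int  # 1..4
    condition: Condition
    cue_color: str
    initial_zone: str
    final_zone: str | None  # present iff the target jumps
    diameter: float  # m
    foreperiod: float  # s


@dataclass(frozen=True)
class TrialPlan:
    """The full randomized protocol for one fencer."""

    fencer_id: str
    handedness: str
    seed: int
    trials: tuple[TrialSpec, ...]
    inter_trial_delay: float = 10.0  # s
    inter_session_break: float = 60.0  # s
    cue_lead: float = CUE_LEAD  # s


def excluded_transition(handedness: str) -> tuple[str, str]:
    """Zone transition removed from the protocol because the sword arm
    would occlude the final target: upper contralateral -> lower lateral."""
    if handedness == "right":
        return ("UL", "LR")
    if handedness == "left":
        return ("UR", "LL")
    raise ValueError(f"unknown handedness {handedness!r}")


def allowed_transitions(handedness: str) -> list[tuple[str, str]]:
    """The 11 ordered zone pairs a Moving target may take."""
    excl = excluded_transition(handedness)
    return [p for p in permutations(ZONE_LABELS, 2) if p != excl]


def _cell_diameters(reps: int) -> list[float]:
    """Split a cell's repetitions evenly across the two target sizes."""
    half, rem = divmod(reps, 2)
    return [DIAMETERS[0]] * (half + rem) + [DIAMETERS[1]] * half


def generate_plan(
    profile: FencerProfile, seed: int, reps: int = REPS_PER_CELL
) -> TrialPlan:
    """Build the randomized 120-trial plan for one fencer.

    Deterministic given (profile.handedness, seed): the cell structure is
    enumerated in a fixed order, shuffled with one global permutation,
    then chunked into 4 sessions of 30.
    """
    rng = np.random.default_rng(seed)
    cells: list[tuple[Condition, str, str | None, float]] = []
    for cond in (Condition.FIXED, Condition.UNCERTAIN_FIXED):
        for zone in ZONE_LABELS:
            for d in _cell_diameters(reps):
                cells.append((cond, zone, None, d))
    for cond in (Condition.MOVING, Condition.UNCERTAIN_MOVING):
        for (z0, z1) in allowed_transitions(profile.handedness):
            for d in _cell_diameters(reps):
                cells.append((cond, z0, z1, d))

    order = rng.permutation(len(cells))
    foreperiods = rng.uniform(*FOREPERIOD_RANGE, size=len(cells))
    trials = []
    for i, cell_idx in enumerate(order):
        cond, z0, z1, d = cells[cell_idx]
        trials.append(
            TrialSpec(
                index=i + 1,
                session=i // TRIALS_PER_SESSION + 1,
                condition=cond,
                cue_color=CUE_COLORS[cond],
                initial_zone=z0,
                final_zone=z1,
                diameter=d,
                foreperiod=float(foreperiods[i]),
            )
        )
    return TrialPlan(
        fencer_id=profile.id,
        handedness=profile.handedness,
        seed=seed,
        trials=tuple(trials),
    )


def validate_plan(plan: TrialPlan) -> list[str]:
    """Check every protocol invariant; returns violations as strings
    (empty list iff the plan is valid)."""
    v: list[str] = []
    n = len(plan.trials)
    if n != N_TRIALS:
        v.append(f"trial count {n} != {N_TRIALS}")
    counts = {c: 0 for c in Condition}
    sessions: dict[int, int] = {}
    try:
        excl = excluded_transition(plan.handedness)
    except ValueError as e:
        v.append(str(e))
        excl = None
    for t in plan.trials:
        counts[t.condition] = counts.get(t.condition, 0) + 1
        sessions[t.session] = sessions.get(t.session, 0) + 1
        moving = t.condition in MOVING_LIKE
        if moving and t.final_zone is None:
            v.append(f"trial {t.index}: {t.condition} lacks a final zone")
        if not moving and t.final_zone is not None:
            v.append(f"trial {t.index}: {t.condition} has a final zone")
        if t.final_zone is not None and t.final_zone == t.initial_zone:
            v.append(f"trial {t.index}: final zone equals initial zone")
        if excl and (t.initial_zone, t.final_zone) == excl:
            v.append(f"trial {t.index}: uses occluded transition {excl[0]}->{excl[1]}")
        if not FOREPERIOD_RANGE[0] <= t.foreperiod <= FOREPERIOD_RANGE[1]:
            v.append(f"trial {t.index}: foreperiod {t.foreperiod:.3f} s out of range")
        if t.initial_zone not in ZONE_LABELS:
            v.append(f"trial {t.index}: unknown zone {t.initial_zone!r}")
        if t.diameter not in DIAMETERS:
            v.append(f"trial {t.index}: diameter {t.diameter} not in {DIAMETERS}")
        if t.cue_color != CUE_COLORS.get(t.condition):
            v.append(f"trial {t.index}: cue colour {t.cue_color!r} mismatched")
    for cond, expected in COMPOSITION.items():
        if counts.get(cond, 0) != expected:
            v.append(f"{cond.value} count {counts.get(cond, 0)} != {expected}")
    for s, cnt in sorted(sessions.items()):
        if cnt != TRIALS_PER_SESSION:
            v.append(f"session {s} has {cnt} trials != {TRIALS_PER_SESSION}")
    return v


# ---------------------------------------------------------------------------
# serialization


def plan_to_frame(plan: TrialPlan) -> pd.DataFrame:
    rows = [
        {
            "index": t.index,
            "session": t.session,
            "condition": t.condition.value,
            "cue_color": t.cue_color,
            "initial_zone": t.initial_zone,
            "final_zone": t.final_zone if t.final_zone is not None else "",
            "diameter": t.diameter,
            "foreperiod": t.foreperiod,
        }
        for t in plan.trials
    ]
    return pd.DataFrame(rows)


def write_plan(plan: TrialPlan, path: str | Path) -> None:
    """Write a plan as CSV (one row per trial) or JSON by extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "fencer_id": plan.fencer_id,
            "handedness": plan.handedness,
            "seed": plan.seed,
            "inter_trial_delay": plan.inter_trial_delay,
            "inter_session_break": plan.inter_session_break,
            "cue_lead": plan.cue_lead,
            "trials": [
                {**asdict(t), "condition": t.condition.value} for t in plan.trials
            ],
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        df = plan_to_frame(plan)
        df.attrs = {}
        header = (
            f"# fencer_id={plan.fencer_id} handedness={plan.handedness} "
            f"seed={plan.seed}\n"
        )
        path.write_text(header + df.to_csv(index=False))


def read_plan(path: str | Path) -> TrialPlan:
    """Round-trip reader for :func:`write_plan` output."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        trials = tuple(
            TrialSpec(
                index=t["index"],
                session=t["session"],
                condition=Condition(t["condition"]),
                cue_color=t["cue_color"],
                initial_zone=t["initial_zone"],
                final_zone=t["final_zone"],
                diameter=t["diameter"],
                foreperiod=t["foreperiod"],
            )
            for t in payload["trials"]
        )
        return TrialPlan(
            fencer_id=payload["fencer_id"],
            handedness=payload["handedness"],
            seed=payload["seed"],
            trials=trials,
            inter_trial_delay=payload["inter_trial_delay"],
            inter_session_break=payload["inter_session_break"],
            cue_lead=payload["cue_lead"],
        )
    text = path.read_text().splitlines()
    meta = {}
    if text and text[0].startswith("#"):
        for tok in text[0].lstrip("# ").split():
            k, _, val = tok.partition("=")
            meta[k] = val
        body = "\n".join(text[1:])
    else:
        body = "\n".join(text)
    from io import StringIO

    df = pd.read_csv(StringIO(body), keep_default_na=False)
    trials = tuple(
        TrialSpec(
            index=int(r["index"]),
            session=int(r["session"]),
            condition=Condition(r["condition"]),
            cue_color=r["cue_color"],
            initial_zone=r["initial_zone"],
            final_zone=r["final_zone"] or None,
            diameter=float(r["diameter"]),
            foreperiod=float(r["foreperiod"]),
        )
        for _, r in df.iterrows()
    )
    return TrialPlan(
        fencer_id=meta.get("fencer_id", "unknown"),
        handedness=meta.get("handedness", "right"),
        seed=int(meta.get("seed", 0)),
        trials=trials,
    )
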