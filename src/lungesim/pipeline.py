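"""End-to-end plan -> simulate -> analyze orchestration.

Runs a whole cohort through the full signal path: per fencer, a
randomized 120-trial plan is generated and simulated at the native
recording rates, the event detectors extract the six performance
variables from the synthetic recordings, and the cohort results feed the
paired comparison tables.  Artifacts (plans, per-trial results, summary
tables, per-fencer report) land in the output directory together with a
manifest recording the seed and configuration hash for exact replay.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, to_dict
from .fencer_sim import (
    perturb_behavior,
    sample_cohort,
    simulate_trial,
)
from .geometry import FencerProfile, build_plastron
from .metrics import analyze_trial, results_frame, summarize
from .scenario import generate_plan, validate_plan, write_plan
from .stats import build_comparison_table, render_reports

log = logging.getLogger("lungesim")


def write_recordings(sim, outdir: Path, trial_index: int) -> None:
    """Tidy CSV dump of one trial's recordings plus a ground-truth sidecar."""
    f = sim.force
    force_df = pd.DataFrame(
        {
            "t": f.t,
            "rear_fx": f.rear[:, 0],
            "rear_fy": f.rear[:, 1],
            "rear_fz": f.rear[:, 2],
            "front_fx": f.front[:, 0],
            "front_fy": f.front[:, 1],
            "front_fz": f.front[:, 2],
        }
    )
    s = sim.sword
    sword_df = pd.DataFrame(
        {
            "t": s.t,
            "tip_x": s.tip[:, 0],
            "tip_y": s.tip[:, 1],
            "tip_z": s.tip[:, 2],
            "base_x": s.base[:, 0],
            "base_y": s.base[:, 1],
            "base_z": s.base[:, 2],
        }
    )
    force_df.to_csv(outdir / f"trial{trial_index:03d}_force.csv", index=False)
    sword_df.to_csv(outdir / f"trial{trial_index:03d}_sword.csv", index=False)
    truth = sim.truth
    sidecar = {
        "stimulus_time": truth.stimulus_time,
        "onset_time": truth.onset_time,
        "trigger_time": truth.trigger_time,
        "display_time": truth.display_time,
        "touch_time": truth.touch_time,
        "intended_touch_point": list(truth.intended_touch_point),
        "touch_point": list(truth.touch_point),
        "rt": truth.rt,
        "mt": truth.mt,
        "anticipated": truth.anticipated,
        "msv": truth.msv,
        "initial_target": [sim.initial_target.y, sim.initial_target.z],
        "final_target": [sim.final_target.y, sim.final_target.z],
        "diameter": sim.spec.diameter,
    }
    (outdir / f"trial{trial_index:03d}_truth.json").write_text(
        json.dumps(sidecar, indent=2)
    )


def simulate_fencer(
    profile: FencerProfile,
    behavior,
    seed: int,
    config: RunConfig,
    outdir: Path | None = None,
) -> pd.DataFrame:
    """Plan and simulate one fencer's full session; returns the per-trial
    results table."""
    plan = generate_plan(profile, seed)
    violations = validate_plan(plan)
    if violations:  # pragma: no cover - generate_plan output is always valid
        raise RuntimeError(f"invalid plan for {profile.id}: {violations}")
    rng = np.random.default_rng(seed)
    screen_x = config.apparatus.distance_coeff * profile.height
    sims, results = [], []
    never_fired = 0
    for spec in plan.trials:
        sim = simulate_trial(profile, behavior, spec, rng, config.apparatus)
        result = analyze_trial(sim, profile, screen_x)
        results.append(result)
        if spec.condition.value.endswith("Moving") and sim.truth.display_time is None:
            never_fired += 1
        if outdir is not None and config.save_recordings:
            write_recordings(sim, outdir, spec.index)
        log.info(
            "%s trial %3d %-16s %s",
            profile.id,
            spec.index,
            spec.condition.value,
            "TOUCH" if result.success else "MISS",
        )
    if never_fired:
        warnings.warn(
            f"{profile.id}: trigger never fired in {never_fired} Moving-type "
            "trials (target did not jump)",
            stacklevel=2,
        )
    if outdir is not None:
        write_plan(plan, outdir / "plan.csv")
    return results_frame(results, profile.id, list(plan.trials))


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run a full cohort and write every artifact; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    cohort_rng = np.random.default_rng(master.spawn(1)[0])
    profiles = sample_cohort(
        config.cohort.n_fencers,
        cohort_rng,
        config.cohort.height_mean,
        config.cohort.height_sd,
        config.cohort.mass_mean,
        config.cohort.mass_sd,
    )
    fencer_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in master.spawn(len(profiles) + 1)[1:]]

    frames = []
    for profile, fseed in zip(profiles, fencer_seeds):
        behavior = perturb_behavior(config.behavior, cohort_rng)
        fdir = outdir / profile.id
        fdir.mkdir(exist_ok=True)
        frames.append(simulate_fencer(profile, behavior, fseed, config, fdir))
    results = pd.concat(frames, ignore_index=True)
    results.to_csv(outdir / "results.csv", index=False)

    summaries = summarize(results)
    summaries.to_csv(outdir / "summaries.csv", index=False)
    table = build_comparison_table(summaries)
    render_reports(
        table,
        summaries,
        outdir / "table_conditions.csv",
        outdir / "table_sizes.csv",
        outdir / "report.json",
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "config": to_dict(config),
        "fencers": [p.id for p in profiles],
        "fencer_seeds": fencer_seeds,
        "artifacts": [
            "results.csv",
            "summaries.csv",
            "table_conditions.csv",
            "table_sizes.csv",
            "report.json",
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
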