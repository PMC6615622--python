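"""Monte-Carlo calibration of the paired-comparison machinery.

Two study designs, both built on the fast result-level simulator:

* **Power**: replicate cohorts whose behavioural model injects real
  condition effects (the default Moving-condition MT penalty and
  aiming-scatter inflation); the Fixed/Moving contrast should come out
  significant in nearly every replicate.
* **Type-I error**: replicate cohorts generated under a null behaviour
  (no condition differences at all); the fraction of starred contrasts
  should match the attainable level of the exact Wilcoxon test, which
  for discrete small-n distributions sits just below the nominal 0.05.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .fencer_sim import (
    FencerBehavior,
    perturb_behavior,
    sample_cohort,
    simulate_trial_results,
)
from .metrics import summarize
from .scenario import Condition, generate_plan
from .stats import (
    CONTRAST_PAIRS,
    _exact_distribution,
    _paired_diffs,
    wilcoxon_signed_rank,
)

__all__ = [
    "null_behavior",
    "attainable_alpha",
    "simulate_cohort_results",
    "contrast_pvalue",
    "power_study",
    "type1_study",
]


def null_behavior(base: FencerBehavior | None = None) -> FencerBehavior:
    """A behaviour with no condition effects: common RT median and aiming
    scatter across conditions and no target-jump MT penalty."""
    base = base or FencerBehavior()
    return replace(
        base,
        rt_median={c: 0.32 for c in Condition},
        aim_sigma={c: 0.050 for c in Condition},
        mt_penalty_moving=0.0,
    )


def attainable_alpha(n: int, alpha: float = 0.05) -> float:
    """Largest two-sided p-value of the exact no-tie Wilcoxon null
    distribution at sample size ``n`` that does not exceed ``alpha``:
    the true size of a nominal-``alpha`` test."""
    doubled = tuple(2 * r for r in range(1, n + 1))
    counts = _exact_distribution(doubled)
    total = counts.sum()
    cum = np.cumsum(counts)
    achievable = set()
    for w2 in range(counts.size):
        p_low = cum[w2] / total
        p_high = (total - (cum[w2 - 1] if w2 > 0 else 0.0)) / total
        achievable.add(min(1.0, 2.0 * min(p_low, p_high)))
    below = [p for p in achievable if p <= alpha]
    return max(below) if below else 0.0


def simulate_cohort_results(
    behavior: FencerBehavior,
    n_fencers: int,
    rng: np.random.Generator,
    between_fencer: bool = True,
) -> pd.DataFrame:
    """Fast result-level simulation of one whole cohort."""
    profiles = sample_cohort(n_fencers, rng)
    frames = []
    for profile in profiles:
        b = perturb_behavior(behavior, rng) if between_fencer else behavior
        plan = generate_plan(profile, int(rng.integers(2**31 - 1)))
        frames.append(simulate_trial_results(profile, b, plan, rng))
    return pd.concat(frames, ignore_index=True)


def contrast_pvalue(
    summaries: pd.DataFrame, pair: tuple[str, str], variable: str
) -> float:
    """Wilcoxon p for one contrast from per-fencer cell summaries."""
    d, _ = _paired_diffs(summaries, pair, variable)
    return wilcoxon_signed_rank(d)


def power_study(
    n_replicates: int = 200,
    n_fencers: int = 11,
    seed: int = 0,
    variables: tuple[str, ...] = ("mt", "accuracy"),
    pair: tuple[str, str] = ("Fixed", "Moving"),
    behavior: FencerBehavior | None = None,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Fraction of replicate cohorts in which each contrast is
    significant at ``alpha``, under the injected condition effects."""
    behavior = behavior or FencerBehavior()
    rng = np.random.default_rng(seed)
    hits = {v: 0 for v in variables}
    for _ in range(n_replicates):
        summaries = summarize(
            simulate_cohort_results(behavior, n_fencers, rng)
        )
        for v in variables:
            if contrast_pvalue(summaries, pair, v) < alpha:
                hits[v] += 1
    return {v: hits[v] / n_replicates for v in variables}


def type1_study(
    n_replicates: int = 1000,
    n_fencers: int = 11,
    seed: int = 0,
    variables: tuple[str, ...] = ("accuracy", "mt"),
    behavior: FencerBehavior | None = None,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Per-contrast false-positive rate under the null behaviour.

    Returns the star rate averaged over the six condition contrasts for
    each variable, plus the attainable test size ``"attainable_alpha"``
    for reference.
    """
    behavior = null_behavior(behavior)
    rng = np.random.default_rng(seed)
    hits = {v: 0 for v in variables}
    n_tests = 0
    for _ in range(n_replicates):
        summaries = summarize(
            simulate_cohort_results(behavior, n_fencers, rng)
        )
        n_tests += len(CONTRAST_PAIRS)
        for v in variables:
            for pair in CONTRAST_PAIRS:
                if contrast_pvalue(summaries, pair, v) < alpha:
                    hits[v] += 1
    out = {v: hits[v] / n_tests for v in variables}
    out["attainable_alpha"] = attainable_alpha(n_fencers, alpha)
    return out
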