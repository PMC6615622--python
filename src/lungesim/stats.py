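"""Paired nonparametric comparison engine.

Per-fencer condition means are compared with Wilcoxon signed-rank tests
(two-sided); effect sizes are matched-pairs rank-biserial correlations
r = (W+ - W-) / (n(n+1)/2), whose magnitude is 1 exactly when every
paired difference has the same sign.  Six condition contrasts are
tested — Fixed/Moving, Fixed/Uncertain, Moving/Uncertain,
U.Fixed/U.Moving, Fixed/U.Fixed and Moving/U.Moving — plus a target-size
contrast (Small vs Big, all conditions pooled); the Fixed/U.Moving and
Moving/U.Fixed pairs are deliberately never tested.  Raw p-values are
reported (no multiplicity correction by default; Holm is available as an
option), with the usual star coding: * p<0.05, ** p<0.01, *** p<0.001.

The test is exact (full sign-flip permutation distribution, zeros
discarded, mid-ranks for ties) for n <= 25 and falls back to the normal
approximation with continuity and tie corrections above that.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .metrics import VARIABLES

#: contrasts as (first, second) analysis cells; the shift is the mean of
#: per-fencer (second - first) differences
CONTRAST_PAIRS = (
    ("Fixed", "Moving"),
    ("Fixed", "Uncertain"),
    ("Moving", "Uncertain"),
    ("UncertainFixed", "UncertainMoving"),
    ("Fixed", "UncertainFixed"),
    ("Moving", "UncertainMoving"),
)

#: pairs that are never tested (the pooled Uncertain condition already
#: contains the sub-condition, making the pairing uninterpretable)
EXCLUDED_PAIRS = (
    ("Fixed", "UncertainMoving"),
    ("Moving", "UncertainFixed"),
)

SIZE_PAIR = ("Big", "Small")

#: largest sample size for which the exact permutation distribution is used
EXACT_MAX_N = 25


def _signed_rank_stats(diffs: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(W+, W-, midranks of |d|) after discarding zero differences."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        return 0.0, 0.0, np.empty(0)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    return w_plus, w_minus, ranks


@lru_cache(maxsize=256)
def _exact_distribution(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Counts of achievable 2*W+ over all 2^n sign assignments, by
    dynamic programming over the (doubled, hence integer) ranks."""
    total = sum(doubled_ranks)
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(diffs: np.ndarray, exact_max_n: int = EXACT_MAX_N) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Zero differences are discarded before ranking; ties in |d| take
    mid-ranks.  For n <= ``exact_max_n`` the p-value comes from the
    exact conditional sign-flip distribution; beyond that, the normal
    approximation with continuity and tie corrections is used.  All
    differences zero returns p = 1 with a warning.
    """
    w_plus, w_minus, ranks = _signed_rank_stats(diffs)
    n = ranks.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    if n <= exact_max_n:
        doubled = tuple(int(round(2 * r)) for r in sorted(ranks))
        counts = _exact_distribution(doubled)
        total = counts.sum()  # 2^n
        w2 = int(round(2 * w_plus))
        p_low = counts[: w2 + 1].sum() / total
        p_high = counts[w2:].sum() / total
        return float(min(1.0, 2.0 * min(p_low, p_high)))
    # normal approximation with continuity correction and tie correction
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def rank_biserial(diffs: np.ndarray) -> float:
    """Matched-pairs rank-biserial correlation (W+ - W-) / (n(n+1)/2).

    +1/-1 when every non-zero difference shares a sign; 0 for exactly
    balanced signed ranks (or all-zero differences, with a warning).
    """
    w_plus, w_minus, ranks = _signed_rank_stats(diffs)
    n = ranks.size
    if n == 0:
        warnings.warn("all paired differences are zero; r = 0", stacklevel=2)
        return 0.0
    return float((w_plus - w_minus) / (n * (n + 1) / 2.0))


def stars(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (optional; raw p-values are the default)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty_like(p)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


@dataclass(frozen=True)
class PairedContrast:
    """One variable x condition-pair comparison across fencers."""

    variable: str
    pair: tuple[str, str]
    diffs: tuple[float, ...]  # per-fencer (second - first)
    mean_shift: float
    sd_shift: float
    p_value: float
    rank_biserial: float
    stars: str
    n: int


@dataclass(frozen=True)
class ComparisonTable:
    """All tested contrasts: the software twin of the per-condition and
    per-size comparison tables."""

    contrasts: tuple[PairedContrast, ...]
    excluded_pairs: tuple[tuple[str, str], ...] = EXCLUDED_PAIRS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": c.variable,
                    "first": c.pair[0],
                    "second": c.pair[1],
                    "shift": c.mean_shift,
                    "sd": c.sd_shift,
                    "p": c.p_value,
                    "stars": c.stars,
                    "rank_biserial": c.rank_biserial,
                    "n": c.n,
                }
                for c in self.contrasts
            ]
        )

    def condition_frame(self) -> pd.DataFrame:
        df = self.to_frame()
        return df[df["second"] != SIZE_PAIR[1]].reset_index(drop=True)

    def size_frame(self) -> pd.DataFrame:
        df = self.to_frame()
        return df[df["second"] == SIZE_PAIR[1]].reset_index(drop=True)


def _paired_diffs(
    summaries: pd.DataFrame, pair: tuple[str, str], variable: str
) -> tuple[np.ndarray, list[str]]:
    """Per-fencer (second - first) differences; fencers with an empty
    cell are excluded and logged."""
    wide = summaries.pivot(index="fencer_id", columns="cell", values=variable)
    counts = summaries.pivot(index="fencer_id", columns="cell", values="n")
    first, second = pair
    ok = (counts[first] > 0) & (counts[second] > 0)
    excluded = [str(f) for f in wide.index[~ok]]
    d = (wide.loc[ok, second] - wide.loc[ok, first]).to_numpy(dtype=float)
    return d, excluded


def build_comparison_table(
    summaries: pd.DataFrame,
    variables: tuple[str, ...] = VARIABLES,
    min_fencers: int = 5,
    holm: bool = False,
) -> ComparisonTable:
    """Build every tested contrast from per-fencer cell summaries.

    ``summaries`` is the output of :func:`lungesim.metrics.summarize`
    for a whole cohort.  Fencers missing a cell are dropped from that
    contrast (with a warning); a contrast with fewer than
    ``min_fencers`` complete pairs raises.
    """
    contrasts = []
    pairs = list(CONTRAST_PAIRS) + [SIZE_PAIR]
    for variable in variables:
        for pair in pairs:
            d, excluded = _paired_diffs(summaries, pair, variable)
            if excluded:
                warnings.warn(
                    f"{variable} {pair}: fencers {excluded} excluded "
                    "(empty cell)",
                    stacklevel=2,
                )
            if d.size < min_fencers:
                raise ValueError(
                    f"contrast {variable} {pair}: only {d.size} complete pairs"
                )
            p = wilcoxon_signed_rank(d)
            contrasts.append(
                PairedContrast(
                    variable=variable,
                    pair=pair,
                    diffs=tuple(float(x) for x in d),
                    mean_shift=float(d.mean()),
                    sd_shift=float(d.std(ddof=1)),
                    p_value=p,
                    rank_biserial=rank_biserial(d),
                    stars=stars(p),
                    n=int(d.size),
                )
            )
    if holm:
        adj = holm_adjust(np.array([c.p_value for c in contrasts]))
        contrasts = [
            PairedContrast(
                variable=c.variable,
                pair=c.pair,
                diffs=c.diffs,
                mean_shift=c.mean_shift,
                sd_shift=c.sd_shift,
                p_value=float(pa),
                rank_biserial=c.rank_biserial,
                stars=stars(float(pa)),
                n=c.n,
            )
            for c, pa in zip(contrasts, adj)
        ]
    return ComparisonTable(contrasts=tuple(contrasts))


# ---------------------------------------------------------------------------
# reports


def format_table(table: ComparisonTable) -> str:
    """Human-readable text rendering (Shift +/- SD, p, stars, rank corr)."""
    lines = [
        f"{'Variable':<10} {'Compared':<30} {'Shift':>12} {'p':>7} "
        f"{'':<3} {'Rank Corr.':>10}"
    ]
    for c in table.contrasts:
        pair = f"{c.pair[0]} / {c.pair[1]}"
        lines.append(
            f"{c.variable:<10} {pair:<30} "
            f"{c.mean_shift:>7.3f} ± {c.sd_shift:<5.3f} "
            f"{c.p_value:>6.3f} {c.stars:<3} {c.rank_biserial:>9.3f}"
        )
    lines.append(
        "NB: pairs "
        + ", ".join(f"{a}/{b}" for a, b in table.excluded_pairs)
        + " are not tested."
    )
    return "\n".join(lines)


def render_reports(
    table: ComparisonTable,
    summaries: pd.DataFrame,
    condition_csv: str | Path,
    size_csv: str | Path,
    report_json: str | Path,
) -> None:
    """Write the condition-contrast CSV, the size-contrast CSV, and a
    per-fencer JSON report (fencers sorted by pooled mean accuracy)."""
    from .metrics import rank_fencers

    table.condition_frame().to_csv(condition_csv, index=False)
    table.size_frame().to_csv(size_csv, index=False)
    ranked = rank_fencers(summaries)
    per_fencer = []
    for fencer_id in ranked["fencer_id"]:
        cells = summaries[summaries["fencer_id"] == fencer_id]
        per_fencer.append(
            {
                "fencer_id": str(fencer_id),
                "cells": {
                    row["cell"]: {
                        "n": int(row["n"]),
                        **{
                            v: (None if pd.isna(row[v]) else float(row[v]))
                            for v in VARIABLES
                        },
                    }
                    for _, row in cells.iterrows()
                },
            }
        )
    payload = {
        "fencers_by_accuracy": per_fencer,
        "excluded_pairs": [list(p) for p in table.excluded_pairs],
    }
    Path(report_json).write_text(json.dumps(payload, indent=2))
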