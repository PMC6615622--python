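# Methods

This note documents the models behind `lungesim`, their assumptions, the
parameters that matter, and the numerical choices made where the design
was genuinely open.

## Coordinate frame and geometry

`x` is antero-posterior (origin at the initial rear-foot position,
positive toward the screen), `y` mediolateral (positive to the fencer's
right), `z` vertical. The touch plane sits at `x = 1.5 × height` (the
standardized long-lunge distance), so touch detection reduces to a plane
crossing. The plastron is a constant 0.26 × 0.82 m rectangle; only its
placement scales with the fencer.

Two geometric quantities have no published value and are explicit
configuration, not constants:

* **Vertical plastron placement** — "adapted to the size of the subject"
  without a formula; we centre it at 0.47 × height, the approximate
  mid-point of the shoulder-to-knee band in standard anthropometric
  tables (`ApparatusConfig.vertical_coeff`).
* **Corner-zone size** — the zones are drawn but not dimensioned; the
  default is 45% of plastron width × 30% of height per corner
  (`ApparatusConfig.zone_fraction`), comfortably larger than the biggest
  (0.10 m) target in both directions.

Target centres are drawn uniformly over the zone rectangle shrunk by the
target radius (not by rejection), so every sampled circle lies wholly
inside its zone by construction.

## Protocol generation

The 120-trial composition is fully determined: per condition, each cell
(a zone for Fixed-type, an ordered zone transition for Moving-type) gets
4 repetitions; the occluded transition (upper-contralateral →
lower-lateral, i.e. UL→LR for right-handers) is removed, leaving 11 of
12 transitions and hence 44 Moving-type trials. The published protocol
does not state how the two target sizes were allocated; we split each
4-repetition cell 2/2 so size is orthogonal to condition and zone
(`generate_plan(reps=...)` exposes the cell size). The trial order is one
global permutation chunked into 4 sessions of 30 — the source describes
randomization over the whole set of 120 attacks, not per session.
Foreperiods are i.i.d. uniform on [0.5, 1.2] s.

## Ground reaction force model

The rear plate carries `guard_rear_load` (default 0.55) × BW vertically
at rest, with zero-mean Gaussian noise (0.2% BW per component). The push
is built from closed-form pieces over `push_duration` (0.5 s):

* forward: a symmetric raised cosine, peak `push_forward_peak` (0.94) × BW;
* vertical: a smooth half-cosine unloading of the static load (the rear
  foot progressively leaves the plate) plus a shorter raised-cosine
  thrust occupying the first 60% of the push, whose amplitude is solved
  numerically (Brent) so the **peak force norm** equals `push_peak`
  (1.45) × BW.

This two-component construction is what lets a single parameter set
satisfy two constraints that a symmetric pulse cannot satisfy together:
the half-forward-impulse instant falls at mid-push, where the vertical
thrust has largely decayed, so the norm there is ≈1.06 × BW (the derived
trigger threshold), while the norm peak earlier in the push reaches
1.45 × BW. The push is time-shifted so that the forward component crosses
1% BW — the onset definition used by the detector — exactly at the
nominal onset time, avoiding any discontinuity at onset.

A pure-forward symmetric triangular pulse (`shape="triangular"`) is
provided as an analytic fixture: half its impulse is produced exactly at
the apex, so the derived threshold must equal the peak force.

## Trigger semantics

Offline derivation and the online engine deliberately differ:

* the **impulse** integrates the forward (x) rear-plate component only,
  over [detected onset, touch], trapezoidally, with linear interpolation
  to locate the half-impulse instant;
* the **trigger** compares the full rear-plate force **norm**, fires at
  the *first sample strictly after the stimulus* that strictly exceeds
  threshold × BW (no interpolation — real-time semantics), at most once;
  the display changes exactly one latency (35 ms, capture and rendering
  collapsed into one configurable number) later. Crossings before the
  stimulus are ignored: the jump cannot occur until the fencer actually
  moves. In Fixed-type conditions the crossing is logged but no display
  change is emitted.

Only the rear plate feeds the trigger and the onset detector; the front
plate is synthesized for completeness but not analyzed.

## Sword trajectory

No kinematic model of the blade between onset and touch is published;
we use a minimum-jerk reach, the standard model for rapid aimed
movements, and none of the package's validated claims depend on its
specific shape. The tip travels in a straight line from the guard
position (x at 54% of the screen distance, z at 75% of height) through
the aim point to a collinear endpoint 2% beyond it, with total duration
scaled so the plane crossing happens exactly at onset + MT. Planning
through to a point *beyond* the plane makes the crossing transversal
(nonzero impact velocity); planning to a point on the plane would make
the arrival tangent and sampled-crossing detection ill-posed.

When the target jumps, the remaining path is re-planned at display time
as a quintic from the current position/velocity/acceleration to the new
collinear-extended aim, its duration refined by a few secant iterations
so the crossing lands at onset + MT + `mt_penalty_moving`. The replanned
path curves (its initial velocity points at the old aim), so the actual
touch point is evaluated from the polynomial at the crossing rather than
assumed equal to the aim; ground truth records both. The blade-base
marker is the tip offset by a fixed blade vector; both markers get
isotropic Gaussian noise (0.3 mm SD by default).

## Behavioural parameters

Defaults are seeded from typical cohort-level values for regional-to-
national épéeists and are configuration, not constants:

| parameter | default | meaning |
|---|---|---|
| `rt_median` | 0.280 / 0.345 / 0.347 / 0.330 s (F/M/UF/UM) | condition-wise lognormal RT medians |
| `rt_sigma` | 0.25 | lognormal shape; RT truncated to [0.10, 0.60] s |
| `anticipation_prob` | 0.02 | chance of a guess, RT uniform in [0.05, 0.10) s |
| `mt_base`, `mt_sigma` | 0.788, 0.055 s | movement time and trial-to-trial jitter |
| `mt_penalty_moving` | 0.098 s | MT lengthening when the target jumps |
| `aim_sigma` | 0.033 / 0.059 / 0.040 / 0.072 m | isotropic 2-D aiming scatter per condition |

`mt_sigma` is a deliberate addition to the minimal behavioural surface:
without trial-to-trial MT variance the paired statistics would be
degenerate. For an isotropic 2-D normal the mean radial error is
σ√(π/2), which is how the `aim_sigma` defaults map to condition-wise
mean accuracies of roughly 0.04–0.09 m. Between-fencer heterogeneity
(`perturb_behavior`) scales RT medians and aim scatter by common
lognormal factors and shifts `mt_base`, leaving the injected
condition structure intact.

What the generator does **not** emulate: heavy-tailed or
strategy-dependent error distributions (a Gaussian matched to mean
accuracy yields lower success rates than human fencers achieve at the
same mean error), anticipatory postural adjustments, fatigue or learning
across sessions, blade bending at impact, and the ~16 mm marker-offset
artefact at touch. Passing tests therefore validate the *machinery* —
detection, triggering, statistics — not the fidelity of human motor
behaviour.

## Event detection and variables

Onset detection mirrors the trigger's sample-resolution rule (first
sample strictly exceeding 1% BW after the stimulus); touch detection
interpolates linearly between the straddling marker samples — accuracy
benefits from sub-sample precision, and interpolation is exact on
locally-linear paths. MSV low-pass filters the blade-base x position at
10 Hz (4th-order Butterworth, zero-phase, with generous odd-extension
padding so linear segments pass through exactly) before central
differencing. A touch exactly on the target boundary counts as a
success. Trials whose onset or touch cannot be detected are flagged
invalid and dropped from summaries (and reported), not imputed. RRT is
computed as RT + MT, making the identity exact by construction.

## Statistics

The Wilcoxon signed-rank test is implemented with Wilcoxon's original
zero-handling (zeros discarded before ranking) and mid-ranks for ties.
For n ≤ 25 the two-sided p comes from the exact conditional sign-flip
distribution, computed by dynamic programming over doubled ranks (so
mid-ranks stay integral); above that, the normal approximation with
continuity and tie corrections. Cohorts of ~11 always take the exact
path. The exact distribution is discrete: at n = 11 the largest
achievable two-sided p below 0.05 is ≈0.042, which is why the null
calibration study compares the observed star rate to this attainable
level rather than to a literal 5%.

Raw p-values are reported, matching the convention of small-cohort
paired designs in this literature; Holm adjustment is available
(`build_comparison_table(holm=True)`) but off by default. The
Fixed/UncertainMoving and Moving/UncertainFixed pairs are never tested.
Shift signs follow the (second − first) convention, e.g. a negative
Fixed/Moving success shift means success is lower under Moving.

## Problem sizes and numerical choices

The Monte-Carlo calibration studies (power: 200 replicate 11-fencer
cohorts; type-I: 1000 replicates) use the result-level simulator
(`simulate_trial_results`), which draws the six variables directly from
the behavioural model instead of synthesizing and re-detecting signals;
the full signal path is validated separately on a 500-trial recovery
study (detector biases: |RT| < 1 force sample, |MT| < 1 marker sample,
accuracy < 1 mm with noiseless markers). Threshold calibration uses 50
simulated assaults. Trigger invariants are checked on 200 randomized
recordings. Secant refinement of the replanned segment stops at 1 ns of
crossing-time error; the vertical-amplitude Brent solve uses a 2001-point
norm grid and 1e-10 tolerance.

## Known limitations

* The trajectory and GRF families are stand-ins with the right coarse
  structure, not fitted biomechanical models.
* The fast result-level path assumes the trigger always fires in
  Moving-type trials (true under default push parameters) and uses the
  nominal minimum-jerk peak velocity for MSV, ignoring re-planning's
  small effect on peak tip speed.
* Success rates of the synthetic cohort are lower than human cohorts at
  matched mean accuracy (Gaussian aiming; see above), so absolute success
  levels should not be compared against human data.
* Only the rear plate is modelled meaningfully; front-plate dynamics are
  placeholders.
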