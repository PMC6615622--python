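# lungesim

A software twin of an instrumented fencing-lunge simulator. It targets
researchers in motor control and sports biomechanics who study how fencers
react when an attack's target may move mid-movement (an *open-skill*,
double-step perturbation paradigm), and who need the full experiment —
protocol, apparatus timing, recordings, performance variables, statistics —
to be simulatable, analyzable and testable end to end with no hardware.

## What it simulates

A fencer stands en garde on two force plates (1000 Hz), a distance of
1.5× their standing height from a screen showing an opponent's plastron
(a 0.26 × 0.82 m rectangle). A circular target (0.05 or 0.10 m diameter)
appears in one of four corner zones after a random foreperiod of
0.5–1.2 s; the fencer lunges and the sword tip's touch is recorded by
motion capture (250 Hz). Three cued task conditions: **Fixed** (green —
the target will not move), **Moving** (red — it will jump once the attack
is committed) and **Uncertain** (blue — it may or may not), giving four
outcome conditions (Fixed, Moving, UncertainFixed, UncertainMoving) in a
fixed 16/44/16/44 composition over 120 trials and 4 sessions.

The target jump is driven by the fencer's own ground reaction force. On
calibration lunges, the attack is deemed mechanically irreversible at the
instant half its total forward impulse

$$J(t)=\int_{t_\text{onset}}^{t} F_x^\text{rear}(\tau)\,d\tau$$

has been produced; the rear-plate force *norm* at that instant, ≈1.06×
body weight, becomes the real-time trigger threshold. The display changes
one controlled latency (35 ms) after the threshold crossing. Six
variables are computed per attack: **Success**, **Accuracy** (distance of
the touch to the *final* target centre), **RT** (stimulus → forward GRF
> 1% BW), **MT** (onset → touch), **RRT = RT + MT**, and **MSV** (peak
antero-posterior blade-base velocity). Per-fencer condition means are
compared with exact Wilcoxon signed-rank tests and matched-pairs
rank-biserial correlations $r=(W^+-W^-)/\tfrac{n(n+1)}{2}$.

The synthetic fencer (module `fencer_sim`) generates realistic GRF pushes
and minimum-jerk sword reaches with mid-movement re-planning, with every
behavioural parameter (condition-wise RT medians, MT penalty on target
jumps, aiming scatter, anticipation rate…) injectable and recoverable —
so the whole detection and statistics chain can be validated against
known ground truth.

## Worked example

```
$ cat fencer.json
{"id": "F01", "height": 1.78, "mass": 75.0, "handedness": "right", "level": "regional"}

$ lungesim plan --profile fencer.json --seed 42 -o plan.csv
$ head -4 plan.csv
# fencer_id=F01 handedness=right seed=42
index,session,condition,cue_color,initial_zone,final_zone,diameter,foreperiod
1,1,Fixed,green,UL,,0.1,1.0487287463744894
2,1,Moving,red,UR,LL,0.1,0.9650194782291712
```

Each row is one planned attack: trial 2 is a Moving trial (red cue) whose
target appears in the upper-right zone and will jump to the lower-left
once the fencer's rear-plate force norm exceeds the trigger threshold.
A right-hander's plan never contains the occluded UL→LR transition.

```
$ lungesim calibrate --profile fencer.json --n 50 --seed 7
trigger threshold: 106.2% BW (50 assaults, impulse fraction 0.5)
```

Fifty simulated standard lunges put the half-impulse force norm at 106.2%
of body weight — the threshold the trigger engine then uses.

```
$ lungesim all --config config.yaml -o cohort/     # cohort: {n_fencers: 11}, seed: 1
cohort of 11 fencers complete; artifacts in cohort/ (config 86c2887a9c760313)

$ lungesim analyze --results cohort/results.csv -o tables/
Variable   Compared                              Shift       p     Rank Corr.
success    Fixed / Moving                 -24.793 ± 9.502  0.001 ***    -1.000
...
accuracy   Fixed / Moving                   0.032 ± 0.016  0.001 ***     1.000
...
rt         Moving / Uncertain              -0.010 ± 0.019  0.175        -0.485
NB: pairs Fixed/UncertainMoving, Moving/UncertainFixed are not tested.
```

Shift is the mean over fencers of the per-fencer (second − first)
condition difference: with the default injected effects, accuracy worsens
by ~3 cm and success drops by ~25 points from Fixed to Moving (unanimous
across fencers, rank correlation ±1), while Moving and Uncertain do not
differ — the fencers treat "may move" like "will move". `cohort/` also
contains `results.csv` (one row per attack), `summaries.csv`,
`report.json` (fencers ranked by pooled accuracy) and a `manifest.json`
whose seed and config hash replay the run byte-for-byte.

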