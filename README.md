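# ratgait

Video-derived gait analysis for the rat foot-drop model, with a
synthetic cohort simulator.

Unilateral avulsion of the lumbar (L5/L6) ventral roots denervates the
ankle dorsiflexors, producing **foot drop**: during the swing phase the
foot stays plantarflexed, toe spread collapses on contact, stance is
prolonged and the animal slows down. `ratgait` implements the complete
quantitative workflow used to characterise that deficit and its
recovery from walkway video:

- **gait-cycle segmentation** from paw-contact signals, with the four
  gait events per cycle — initial contact, mid-stance (contralateral
  swinging limb opposite the stance limb), pre-swing (toe-off) and
  mid-swing (swinging limb opposite the contralateral stance limb);
- **nine spatiotemporal indices** per hindlimb: stride length, step
  length, print length, toe spread (toe 1–5), intermediary toe spread
  (toe 2–4), stance time, swing time, double-support time and walking
  speed, averaged over at least 10 footsteps per subject-day;
- **ankle kinematics**: the interior angle at the lateral malleolus
  between the shank landmark and the fifth metatarsal head, reported at
  the four gait events (foot drop elevates the pre- and mid-swing
  angle);
- **open-field summaries**: total distance, movement time and immobile
  time over a 10-minute session;
- **split-plot statistics**: mixed ANOVA (lesion group between
  subjects × assessment day within subjects), Fisher-LSD group
  contrasts per day, and Bonferroni-corrected time contrasts per group.

Because no deposited recordings exist, the package ships a first-class
**simulator** that generates walkway trials (landmark series at 60 fps,
0.24 mm calibration, digitized footprints) and open-field tracks with
the study's structure — four groups (sham, L5, L6, L5+L6; n = 5/5/9/6),
six assessment days (pre, 1, 5, 7, 14, 21), a right-side-only deficit
with exponential recovery plateauing around two weeks — and records all
generating values as ground truth, so every analysis stage is testable
against a known answer.

## The model in brief

A gait cycle of duration *T* with duty factor *d* puts the paw in
stance for *dT* and swing for *(1−d)T*; heel strikes advance by the
stride length *S*, so walking speed is *S/T*. The ankle angle
interpolates through its four event values with a piecewise-cosine
waveform. A lesion preset applies day-1 deltas Δ to the affected-side
parameters, attenuated on post-lesion day *t* by

    scale(t) = π₀ + (1 − π₀)·exp(−(t − 1)/τ),   τ = 5 d,  π₀ = 0.3,

so deficits are maximal at day 1, recover monotonically and retain a
residual plateau. The statistics layer decomposes the summary values as
SS_total = SS_group + SS_subj(group) + SS_day + SS_day×group + SS_error,
testing group against the between-subject error and day and the
interaction against the within-subject error.

## Worked example

```python
import ratgait as rg

params = rg.make_preset("L5L6", "d1")      # combined-lesion day-1 preset
print(params.right.toe_spread)             # 11.61 (mm, affected side)
print(params.left.toe_spread)              # 18.0  (intact side)

trial = rg.simulate_trial(params, n_cycles=10, seed=0)
out = rg.analyze_trial(trial)
```

Running `python examples/02_footdrop_cohort.py` (sham vs L5+L6 cohort,
seed 0) prints:

```
day    toe spread sham toe spread L5L6  mid-swing sham  mid-swing L5L6
pre              18.33           18.25            94.4            94.2
d1               18.45           11.70            94.5           116.6
d5               18.42           14.26            94.9           108.0
d7               18.32           14.96            94.5           105.5
d14              18.38           15.98            94.9           102.1
d21              18.30           16.27            94.6           101.1
```

Reading: on post-lesion day 1 the affected-side toe spread collapses
from ~18 mm to ~11.7 mm and the mid-swing ankle angle jumps by ~22°
(the dropped, plantarflexed foot); both recover over the following two
weeks without returning to baseline. The other examples cover exact
parameter recovery on a noise-free trial (`01`), open-field summaries
against generator truth (`03`) and the ANOVA/post-hoc layer (`04`).

A thin CLI wraps the same API:

```sh
ratgait simulate --seed 1 --out data/         # write a cohort to disk
ratgait analyze --in data/ --out results/     # summary + ANOVA tables
ratgait report --in results/ --metric toe_spread_mm
```

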