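# Methods

## Scope and data flow

`ratgait` starts where image processing ends: its inputs are per-frame
2D landmark positions (knee/shank, ankle, fifth metatarsal head; lateral
view, x = direction of travel, z = vertical), boolean paw-contact
signals, digitized footprints (heel + five toes; bottom view, y =
mediolateral) and open-field position tracks. Video capture, mirror
optics and frame segmentation are out of scope. The pipeline runs
events → spatial indices → ankle kinematics → open field → statistics,
and is a pure function of (inputs, config, seed).

## Generative gait model

**Shared vs limb-local parameters.** In steady straight-line gait each
limb advances exactly the body displacement per cycle; two limbs with
different stride lengths would drift apart and produce negative step
lengths within a few strides. Cycle duration, stride length and the
left–right heel offset are therefore *shared* (whole-body) parameters,
while duty factor, footprint geometry (toe spread, intermediary toe
spread, print length) and the event ankle angles are *limb-local*.
Lesion presets put their temporal/speed deficits on the shared
parameters (so they appear, attenuated, in both limbs' stance/swing
times and speed — mirroring the bilateral stance-time changes such
lesions actually produce) and everything else on the right limb only;
the intact limb's local parameters are bit-identical to baseline under
every preset.

**Kinematics.** Heel strikes are placed at stride increments; the
contralateral limb is phase-lagged by 0.5 cycle and leads by the step
offset. During stance the ankle is planted over the print; during swing
it follows a cosine-eased advance with sinusoidal lift. The ankle angle
follows a piecewise-cosine waveform through its four event values,
with nodes at the stance onset, stance midpoint, toe-off and swing
midpoint; the knee and mt5 landmarks are constructed by rotating a
fixed shank direction by the target angle, so the interior angle
recovered downstream equals the generated waveform identically.

**Baseline defaults** (config-overridable; chosen as plausible
adult-rat magnitudes, since no baseline table exists to copy): cycle
0.5 s, duty factor 0.6, stride 140 mm, step offset 70 mm, toe spread
18 mm, intermediary toe spread 9 mm, print length 30 mm, ankle angles
90°/80°/110°/95° at initial contact / mid-stance / pre-swing /
mid-swing; walking speed is derived (stride/cycle = 280 mm/s).
Acquisition defaults are 60 fps and 0.24 mm per pixel (frame period
16.67 ms); bottom-view coordinates are snapped to the calibration grid.

**Lesion presets.** The combined L5+L6 day-1 deltas anchor the
affected-side means at the reported day-1 footprint geometry: toe
spread 18 → 11.61 mm, intermediary toe spread 9 → 6.88 mm. The
remaining deltas follow the observed deficit directions — duty factor
+0.15 (stance 0.30 → 0.42 s), print length +4 mm (toe drag lengthens
the print), pre-swing +12°, mid-swing +23°, and shared stride −35 mm
with cycle +0.06 s (slower, shorter-striding gait). Single-root (L5 or
L6) presets use 25 % of the combined deltas per parameter, reflecting
that single-root avulsion produces only sub-threshold foot drop.
Recovery multiplies every delta by
`π₀ + (1 − π₀)·exp(−(day − 1)/τ)` with τ = 5 days and plateau
π₀ = 0.3: deficits are maximal at day 1, decay monotonically, and days
14–21 differ by < 4 % of the day-1 deficit (the two-week plateau). The
pre-lesion day carries no deficit.

**Noise model.** Gaussian per-cycle jitter on cycle duration (SD
0.010 s), body displacement (4 mm), step offset (2 mm) and duty factor
(0.010); per-print jitter on toe spread (0.55 mm), intermediary spread
(0.35 mm) and print length (0.8 mm); per-cycle jitter on each event
angle (2°). Cohorts add subject random intercepts (consistent across
days; SDs 4 mm stride, 0.015 s cycle, 0.010 duty, 0.55/0.30/1.0 mm
footprint geometry, 1.5° angles). This intercept-plus-residual
structure is exactly the compound-symmetric error the split-plot ANOVA
assumes, which is also why no sphericity correction is applied. All
randomness derives from one master seed via spawned `SeedSequence`s.

**Default cohort.** 4 groups × n = 5/5/9/6 × 6 days × 3 walkway passes
of 4 cycles (5 footprints) per limb — 15 pooled footsteps per
subject-day, satisfying the ≥ 10-footstep validity rule, with each pass
exceeding the 4-step minimum. These sizes keep a full cohort simulation
plus analysis around ten seconds while preserving the study's layout.

## Measurement conventions

- **Cycles**: rising edge → next rising edge of the debounced contact
  signal (bouts shorter than 3 frames = 50 ms are flicker and removed);
  a bout beginning at frame 0 counts as a cycle start; partial cycles
  at the edges are discarded. Frame indices are 0-based; contact
  intervals are half-open `[start, end)`.
- **Mid-stance / mid-swing** are operationalised as the contralateral
  ankle's x-position crossing the own ankle's x ("opposite"), located
  by sign change with linear interpolation and rounded to the nearest
  frame. For symmetric gait these crossings coincide with the phase
  midpoints where the generator places its truth events; under strongly
  asymmetric duty factors the crossing legitimately shifts off the
  temporal midpoint by a few frames. Cycles without a crossing (e.g. a
  stationary contralateral limb) carry a missing-event flag and are
  excluded from that event's ROM average only.
- **Step length** is measured along the travel (x) axis between a heel
  strike and the preceding contralateral one (stride length is full
  Euclidean); consecutive ipsilateral prints skip that pair.
- **Double support** is counted from raw contact-signal overlap within
  the cycle, not from cycle arithmetic, making it robust to asymmetric
  gait. The first cycle of a recording can undercount double support by
  up to 3 frames because the contralateral limb's pre-recording stance
  is not observed; averaged over a ≥ 4-cycle pass this stays within one
  frame period of the true value.
- **Walking speed**: per limb, first-to-last heel x-displacement over
  the elapsed time between those contact starts, averaged over limbs.
- **Averaging**: unweighted across pooled footsteps/cycles of a
  subject-day; passes with < 4 steps are excluded; summaries with < 10
  pooled footsteps (or < 10 angles per event) are flagged invalid and
  excluded from statistics.
- **Open field**: immobility is instantaneous speed < 2 cm/s sustained
  ≥ 1 s (both configurable; commercial trackers do not publish their
  criterion); movement + immobile time equals the session duration by
  construction.

## Statistics

`mixed_anova` implements the classical univariate split-plot
decomposition in closed form: group is tested against subjects-within-
groups, day and day×group against the within-subject error. With a
single between factor the group SS is identical under Type I/II/III;
for unbalanced groups the day marginal means are sample-size weighted
(Type-I/II convention, group entered first), which coincides with every
convention on balanced data — the configuration the oracle tests use.
Degrees of freedom are uncorrected. An independent implementation
(pingouin) is used in the test suite as a cross-check, never as the
implementation.

Fisher-LSD contrasts compare groups pairwise at one time point using
the one-way pooled error at that time (what a separate per-day ANOVA
gives); an externally pooled error term can be supplied instead. LSD
p-values are unadjusted by definition; a flag (default on in the
pipeline) withholds significance unless an omnibus F is itself
significant. Time-course contrasts within a group use one-way ANOVA
with Bonferroni adjustment, `p_adj = min(1, p·m)`, `m = t(t−1)/2`.

## What the simulator does and does not establish

Passing tests show the *measurement* layer is correct (exact recovery
at zero noise, unbiased recovery within sampling error at study noise,
correct ANOVA arithmetic and type-I error) under the generator's
assumptions: steady straight-line gait, strict alternation, Gaussian
noise, compound-symmetric subject structure, and a smooth exponential
recovery. Real walkway data add pauses, missed or merged footprints,
digitisation outliers, optical distortion and non-Gaussian
between-animal variation, none of which are emulated. Two known
divergences from the real study: single-root groups here differ from
sham by design (25 % deltas) and can reach statistical significance at
the default noise, whereas the study mostly found them
indistinguishable from sham; and shared-parameter deficits make left
stance/swing times shift slightly with the lesion, so "right-side-only"
claims are evaluated on limb-local indices (footprint geometry and
swing-phase ROM). The printed interaction subscripts of the original
analysis imply one fewer analysed subject (N = 24) than the stated
group sizes (N = 25); the design-determined numerator df (15) is the
quantity checked here.
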