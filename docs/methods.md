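# Methods

This note documents the models, algorithms, and numerical choices behind
`gapclosure`: what is simulated, how the analysis works, which parameters
matter, and what the synthetic benchmarks do and do not establish.

## The scientific setting

A cat walks on a treadmill at a constant belt speed of 0.45 m/s while an
obstacle, mounted on a second belt, advances toward it.  Two obstacles 3 m
apart (10 cm cross-section) produce an approach of roughly 12–14 steps; the
obstacle becomes visible about 2 m out.  The closing gap is described by two
variables:

- **DTC** (distance-to-contact, cm): remaining distance between the head and
  the obstacle;
- **TTC** (time-to-contact, ms): time until contact given the future closure
  speed, `TTC = DTC / v` at constant speed.

In the **matched task** the obstacle moves at the belt speed, so DTC and TTC
are proportional with a single constant (45 cm ↔ 1000 ms).  In the **visual
dissociation task** the obstacle is slowed to 0.3 m/s, changing the constant
(45 cm ↔ 1500 ms).  A neuron whose discharge onset is triggered at a fixed
*distance* therefore fires earlier in time in the dissociation task, while a
neuron triggered at a fixed *time-to-contact* fires at the same moment in
both — the dissociation at the heart of the analysis.  A third condition
accelerates the obstacle (0.3 → ~0.65 m/s over 450 ms, then symmetrically
back), triggered 200 ms after a designated contralateral or ipsilateral
flexor (brachialis, Br) burst one or two step cycles before the step over the
obstacle (conditions 1L, 2L, 1R, 2R; the letter names the lead sequence).

All times are in ms with `t = 0` at the lead-limb Br burst onset of the step
over the obstacle; distances are in cm; speeds are accepted in m/s.

## Task kinematics

Gap traces are built on a 1-ms grid, *anchored backward* from the step over
the obstacle: DTC at `t = 0` equals a configurable crossing offset (default
0) and grows backward in time by integrating the closure speed.  Anchoring
matches the way all analyses are aligned (to the Br onset) and makes the
acceleration trigger times well defined, because gait events are specified
relative to `t = 0`.  TTC at each sample is the forward time until DTC first
reaches zero under the realized trajectory (analytic at constant speed,
interpolated crossing otherwise), so the identity `TTC = DTC / v` holds
exactly in the constant-speed tasks.

Fore–aft drift of the animal is modelled as a stationary AR(1) positional
fluctuation (default SD 3 cm, correlation time 1000 ms, disabled by default
in the generator), sampled on a 100-ms grid and interpolated so the implied
drift velocity stays small against the obstacle speed; enabling it decouples
DTC and TTC the way head-marker measurements do.

Gait timelines place alternating left/right Br onsets 500 ms apart (full
cycle 1000 ms) with optional Gaussian jitter (default 15 ms), the lead-limb
onset fixed at `t = 0`, and burst offsets at half a step period.

The acceleration episode closes an extra 15.75 cm relative to the
unperturbed approach (trapezoidal integral of the speed excess) — about half
a step cycle at 0.3 m/s, which is what makes late accelerations reverse the
limb sequence (below).

## Synthetic cells

Each cell has a ground-truth category: **DTC** (distance trigger, drawn
uniformly 20–40 cm), **TTC** (time trigger, 300–1000 ms), **BOTH** (earlier
of two triggers), **NONE** (task-independent onset at −500 ms with 400 ms
jitter, so that neither gap variable is constant at onset once noise is
accounted for), or **STEP_RELATED** (sinusoidal modulation locked to the
step cycle).  The discharge envelope is baseline until the (jittered)
trigger crossing, rises linearly to the peak at the lead-limb Br onset, and
decays exponentially (default time constant 300 ms).  Because the envelope
is anchored to whichever limb leads, synthetic cells are limb-independent
and step-advanced by construction.

Baseline and peak rates default to 10 and 60 spk/s; reported data do not
pin firing rates numerically, so these are set to values typical of the
recorded discharge profiles and are configurable.  Default onset jitter is 150 ms, inside the published range of
onset SDs (~120–230 ms).  Spikes are an inhomogeneous Poisson realization by
thinning with a 1-ms refractory gap.

A default session mirrors the recording protocol: 10 matched trials per lead
limb, 5 visual-dissociation trials per lead, 3 trials per acceleration
condition, and 20 unobstructed steps — 62 trials per cell.  Sessions failing
the inclusion rule (≥ 5 unobstructed steps and ≥ 3 trials per acceleration
condition) are generated but flagged, and their cells are excluded from
reports.  Every trial carries a child seed from which its gait, gap, envelope
jitter and spikes derive, so stored sessions regenerate bit-for-bit.

## Single-trial onset detection

The per-trial chain is: instantaneous frequency (1000/ISI, sample-and-hold
on a 1-ms grid), zero-phase 4th-order Butterworth low-pass at 50 Hz, then a
threshold rule — the earliest deviation beyond 2 SD of the baseline (window
2.5–3 s before the step), sustained for at least 50 ms, in either direction.
Zero-phase filtering avoids a systematic onset lag; the 50-ms sustainment
suppresses single-sample crossings.

Two departures from the naive rule were forced by the statistics of spiking
rates and are central to the package's accuracy:

1. **Pooled baseline statistics.**  A single 500-ms window contains ~5
   interspike intervals at 10 spk/s; its SD estimate is essentially
   meaningless (observed range 0.1–19 spk/s for a true baseline of 10).
   Baseline mean and SD are therefore pooled over the same window across
   the trials of a group.

2. **Model-based localization with group pooling.**  The threshold crossing
   carries a rate-dependent delay, and for ramps from 10 to 60 spk/s the
   Fisher information bounds any single-trial onset estimator to roughly
   100–180 ms SD.  Detection therefore proceeds in three stages per group
   of like trials (one cell, one task; the gap statistics do not depend on
   the lead limb): (i) the 2 SD rule *gates* each trial (presence and
   direction of a discharge change, on a 1.5-Hz-smoothed copy so the gate
   itself is stable); (ii) the *candidate* onset per trial is the Poisson
   maximum-likelihood breakpoint of a ramp model whose vertex is pinned at
   `t = 0` — the structure the discharge actually has — with the baseline
   fixed at the pooled estimate, the amplitude profiled out by Newton
   steps, and the breakpoint searched within 800 ms of the group-average
   onset (a hinge fit to the averaged trace, re-centred once on the
   candidate median); (iii) reported per-trial onsets are *shrunk* toward
   the group onset by an empirical-Bayes factor `k = max(0, 1 − σ₀²/S²)`
   (σ₀ = 250 ms assumed localization noise, S² the observed candidate
   variance), so replicate trials pool while genuinely jittered trials keep
   their structure.

   Group-level statistics (the ANOVAs below) always use the *raw*
   candidates: running an F-test on shrunk estimates would understate the
   within-group variance.

Onsets are mapped to DTC/TTC by linear interpolation on the trial's gap
trace.  End-of-discharge times for the limb-independence flag come from the
lead-condition averaged traces (detection on a heavily smoothed copy with a
threshold shared between lead conditions, since threshold-crossing times on
the shallow decay are otherwise noise-dominated).

## Classification

Per-trial DTC- and TTC-at-onset values are grouped into the four
task × lead-condition cells.  Onset-time outliers beyond the Tukey fences
(1.5 × IQR, linear-interpolation quartiles) are removed per group.  Two
classical one-way fixed-effects ANOVAs (α = 0.01) test each gap variable
across the four groups; the category follows the dual rule: a cell is
**DTC-related** iff the TTC ANOVA is significant and the DTC ANOVA is not
(its onset tracks a constant distance), **TTC-related** in the mirror case,
**BOTH** if both are significant, **NONE** otherwise.  Post-hoc pairwise
t-tests are Bonferroni-corrected at α = 0.05 across the six pairs.
Step-advanced (averaged onset earlier than −200 ms) and limb-independent
(end-of-discharge difference between lead conditions < 200 ms) flags follow
the standard definitions.

### Modulation index

Trial-averaged rates are re-expressed as functions of DTC (grid 0–45 cm,
1-cm steps) and of TTC (grid 0–1500 ms, 10-ms steps) through the gap traces,
lightly smoothed along the grid (Gaussian SD 2.25 cm / 50 ms).  At each grid
point the four task × lead profiles are Z-scored (sample SD), and the index
is the grid average of `mean(Z_vd) − mean(Z_matched)`.  The exact
construction of the published index is underdetermined; this one was chosen,
and its grids calibrated, so that ideal cells land on the published
landmarks: distance-tuned cells near `(index_dtc, index_ttc) = (0, 1)`,
time-tuned cells near `(−1, 0)`, untuned cells near the origin.  The grid
spans correspond to the distance and time covered during the final step
cycle of the approach (45 cm at the matched speed ≈ 1000 ms; the same 45 cm
at the slowed speed ≈ 1500 ms), which balances the covered fraction of the
two axes.  A within-group bootstrap over trials (1000 resamples) yields
percentile confidence intervals.

## Population analysis

Peri-event histograms use 2-ms bins over [−3200, +2000] ms around the
lead-limb Br onset, smoothed with the same 50-Hz zero-phase filter as the
single-trial pipeline.  Population traces average per-cell rates after
normalization — by default all cells are scaled by the peak rate of the
strongest cell (group-max), preserving relative amplitudes; Z-scoring is
available.  The population ramp onset is amplitude-referenced: the last
upward crossing of baseline + 20% of the ramp amplitude before the peak.
(A 2 SD threshold would shrink with the number of averaged trials, making
onsets incomparable across conditions.)  The onset-to-peak slope is
`(max rate − rate at onset) / (t_max − t_onset)` in spk/s².

Because acceleration delays the trigger crossing while the peak stays
locked to the step, distance-tuned populations under the 1L condition show
later onsets and steeper ramps than in the unperturbed slowed approach; the
synthetic slope ratio is about 1.6–1.8 (the published ratios, ~3×, depend
on unrecorded firing-rate profiles and are matched only in direction).

## Limb-selection model

The threshold model sums, on each side, a gap-closure ramp (0 at 60 cm,
peak at contact) with a periodic limb-state gate that is high during the
last quarter of that limb's cycle (end of stance), the two limbs in
antiphase.  The threshold defaults to 90% of (ramp peak + gate amplitude),
so crossing requires coincidence of an advanced ramp and an appropriate
limb state; "integration" is read literally as summation, not leaky
accumulation.  Exact ties select the left (contralateral) limb.  The model
is simulated *forward* (obstacle starts 60 cm out; the gait rhythm is
fixed), unlike the anchored analysis traces — the phenomenon of interest is
precisely how the arrival time moves relative to the gait.  Sweeping the
gait phase at ramp start over one cycle yields exactly two selection
regimes; rescaling ramp, gates and threshold jointly changes nothing; and a
late acceleration episode, which advances contact by ~525 ms ≈ half a
cycle, reverses the selected limb.  Gate widths, amplitudes and the
threshold have no published values; the defaults above are package choices.

## Validation studies and their scope

`gapclosure.experiments` defines the canned studies (all seeded, generated
cell-by-cell so memory stays flat):

- **Index landmarks**: 100 ideal DTC and 100 ideal TTC cells, 50 ms jitter,
  20 trials per task × lead.  Mean indices land near (0.06, 0.88) and
  (−0.79, −0.01) respectively.
- **Category recovery**: 40 DTC, 40 TTC, 20 NONE cells at 150 ms jitter
  with inclusion-satisfying counts (20 per task × lead used here).  The
  pipeline recovers ~75% of labels with no DTC↔TTC swaps; with the *true*
  injected onsets the same statistics recover ~92%, so the shortfall is the
  information-limited single-trial detection at 10 → 60 spk/s, not the
  statistical machinery.  Errors concentrate in BOTH/NONE, as they should:
  small-trigger time-tuned cells lack power on the DTC axis, and untuned
  cells — whose onsets are by construction time-locked — drift into the
  TTC category when power suffices.
- **Onset accuracy**: 500 matched trials of one cell at zero jitter; median
  absolute error ~10 ms (the shrinkage estimator pools replicates, which is
  optimal exactly when trials share one true onset).
- **Population ramps**: distance-tuned ramps rise ~250 ms earlier in the
  dissociation task; time-tuned ramps superimpose within estimator noise.
- **Acceleration slope**: ratio ~1.6–1.8 under 1L.

What passing these does **not** show: real parietal neurons are not
Poisson, not perfectly limb-independent, and not drawn from clean
trigger distributions; the published cell counts (14/15/6/16 of 51) are
properties of undeposited recordings and are not reproduced.  The synthetic
generator emulates the *structure* of the protocol — trial counts, task
speeds, acceleration timing, onset jitter scales — so the pipeline can be
verified against ground truth, nothing more.

## Numerical conventions

- 1-ms time grids throughout; PEH bins 2 ms.
- Population SD (ddof 0) for baseline statistics; sample SD (ddof 1) inside
  the modulation index and the shrinkage factor.
- Type-7 (linear interpolation) quartiles for the Tukey fences.
- Zero-phase filtering via second-order sections (`sosfiltfilt`).
- Degenerate inputs: silent baselines fall back to an absolute 1 spk/s
  threshold (flagged); all-equal ANOVA inputs return p = 1; cells with
  fewer than two detected onsets in any group are excluded with a reason.
- All randomness flows from a single root seed through per-trial child
  seeds (fixed `spawn` order), keeping sessions byte-reproducible.
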