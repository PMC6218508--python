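# Methods

This note documents the models, estimators and numerical choices behind
`cocoadapt`: a pipeline for analyzing force-field adaptation experiments
with center-out reaching, channel-trial force measurements and surface
EMG, paired with a forward simulator of the same paradigm that provides
ground truth for validation.

## The paradigm being modeled

Participants make 12 cm center-out reaches to four targets (0°, 90°, 180°,
270°) holding a planar robotic manipulandum. A session runs through a
pre-exposure phase (100 null-field trials in 20 blocks), an optional pulse
phase (50 stationary force pulses of 5 N for 500 ms, used to pre-train
either high or low muscle co-contraction), four post-pulse null trials, an
exposure phase in a velocity-dependent curl field, and a post-exposure
phase (100 null trials). Each block of five trials contains one reach to
each target plus one *channel trial* to the 90° target, in pseudorandom
order with two placement rules: a channel trial is never the first trial
of a block and never falls within the first four movements after a rest
break. Rest breaks occur after pre-exposure and after every 13 exposure
blocks (not at the end of exposure).

The curl field applies

    f = b [[0, -1], [1, 0]] v,

with gain `b = ±16 Ns/m` (sign = clockwise/counterclockwise, fixed per
participant, counterbalanced across participants). On channel trials the
hand is clamped to the straight home-target line by a stiff virtual wall
(6,000 N/m, 5 Ns/m perpendicular to the reach), so lateral wall forces
expose the predictive compensation with kinematic error near zero.

One internal inconsistency of the design as usually quoted is handled
explicitly: the exposure phase is described both as "410 trials" and "83
blocks" (= 415). We take the trial count as authoritative — the default
is 410 trials = 82 blocks — and leave the length configurable.

## Analysis definitions

* **Movement onset / end** — first sample more than 0.3 cm from the home
  center; first subsequent sample within 0.3 cm of the target center.
* **Maximum perpendicular error (MPE)** — largest distance between the
  hand path over [onset, end] and the straight line from the *initial
  hand position* (position at onset, not the nominal home center) to the
  target, signed by the side of the line at the extremum. Signs are
  adjusted by training field direction (clockwise sessions flipped) so
  cohorts pool; with this convention exposure-phase MPE is positive and
  post-exposure after-effects come out negative. MPE is windowed to
  [onset, end]; restricting to the movement window (rather than the whole
  recording) is the convention adopted here.
* **Adaptation (%)** — regression through the origin of the measured
  lateral channel force `f_a(t)` on the ideal fully-compensating force
  `f_i(t)` (the exposure field evaluated on the actual channel-trial
  velocity, negated), over the portion of movement with hand speed above
  1 cm/s; `k = Σ f_a f_i / Σ f_i²`, reported as `100 k`. The speed mask
  is implemented as the contiguous above-threshold interval containing
  the speed peak ("from when the hand speed exceeded 1 cm/s to when it
  dropped below"), used identically for the oscillation index.
* **Oscillation index** — path length of the channel force profile after
  normalizing amplitude by its range (max − min) and time to [0, 1],
  computed at the native sample count of the masked segment. A monotone
  profile gives a value in [√2, 2]; oscillations lengthen the path. The
  2-D curve length in the (time, force) unit square is the default
  reading of "path length"; the total-variation alternative is available
  via `mode="variation"`.
* **EMG pipeline** — raw 2 kHz EMG is band-pass filtered 30–500 Hz with a
  Butterworth of total design order 10 applied forward-backward
  (`sosfiltfilt`; zero phase, effective order doubled), then full-wave
  rectified. Windows: movement-early = −200…+130 ms and movement-later =
  +130…+400 ms relative to movement onset (feedback responses to smooth
  perturbations first appear ≈130 ms after onset, so the early window is
  feedforward-only); pulse-early = −200…0 ms and pulse-later = 0…+130 ms
  relative to pulse onset. Each muscle is normalized by its mean
  rectified early-window activity over pre-exposure non-channel trials
  (per participant) — a pure per-muscle rescaling that leaves temporal
  profiles untouched.
* **Global EMG** — sum over the six muscles of the normalized window mean
  minus the matching pre-exposure baseline sum. Baselines are
  window-matched: the early-window baseline sum is exactly 6 by
  construction, the later-window baseline is measured from the same
  pre-exposure trials. (A single early baseline for all windows is the
  plausible alternative; window-matched was chosen so that pre-exposure
  global EMG is zero in *both* windows by construction.)
  Pulse-trial windows are referenced to the early (stationary-hand,
  feedforward) baseline, the only reference pre-exposure provides.
  Channel trials are included in exposure-phase EMG averages.
* **Cohort statistics** — initial and final adaptation are means over the
  first and last 13 exposure blocks of channel trials. The regression
  predictor "global EMG, early and later periods combined" is the mean of
  the two window values (a sum is available via `combine="sum"`; the
  combination rule is not stated in the source). Simple OLS with
  intercept relates per-participant global EMG to initial/final
  adaptation; a multiple regression adds the matched-window oscillation
  index to check that force oscillations do not mediate the relationship.
  Group contrasts are reported as mean ± s.e.m.; omnibus ANOVA machinery
  is deliberately out of scope.

## The simulator

The simulator exists to give the pipeline inputs with known ground truth,
not to be a biomechanical arm model.

**Plant and controller.** The hand + handle is a 2 kg planar point mass.
The controller output is feedforward inverse dynamics of a minimum-jerk
desired trajectory (0.12 m, 0.45 s nominal → 50 cm/s peak, inside the
paradigm's 40–60 cm/s window; per-trial duration jitter SD 0.02 s), plus
the learned curl-field compensation `-k·f_curl(v_desired)` applied on
every reaching trial (this is what produces wall forces on channel trials
and after-effects on post-exposure nulls), plus impedance feedback
`-K(c)(x - x_d) - D(c)(v - v_d)`.

**Impedance.** `K(c) = K_base + 300·c` N/m where `c ≥ 0` is the
dimensionless co-contraction level; `D(c) = 12 + √(300·m)·√c` Ns/m (the
√-scaling is a critical-damping heuristic; no viscous law is specified by
the paradigm). `K_base` is task-dependent: 250 N/m during reaching
(voluntary movement engages substantial feedback gains even when
"relaxed") but 20 N/m during the stationary pulse phase, where the
relaxed instruction is to not resist at all. This split is what lets the
same parameterization produce both ≈20 cm pulse excursions in the relaxed
group and only ≈4 cm first-block MPE. Group defaults: stiff c = 2.0,
control c = 0.4, relaxed c = 0.0; everyone reaches at the control level
(c = 0.4) during pre-exposure, before any instruction differentiates the
groups. Between-participant variability: lognormal jitter on c (CV 0.25)
and on the learning rate (CV 0.15).

**Environment forces.** Null: none. Field: the curl law on the actual
velocity (orthogonal to velocity, hence zero power — asserted to machine
precision in tests). Channel: spring-damper wall (6,000 N/m, 5 Ns/m)
perpendicular to the home-target line; the recorded handle force is the
wall reaction (the force the hand exerts on the wall). Pulse: a constant
5 N force for 500 ms in the trial's direction.

**Learner.** A single-state linear system updated per trial: on field
trials `k ← A·k + B_eff·(1 - k)`; on channel/null trials `k ← A·k`; one
extra retention step at each rest break (time-dependent forgetting).
Defaults `A = 0.998`, `B = 0.02`, and `B_eff = B + slope·c` with
`slope = 0.004`. The positive slope is the mechanism that makes stiff
cohorts adapt faster early (the headline effect of the paradigm); setting
`coco_learning_slope = 0` yields a null world in which co-contraction has
no causal effect on learning, used for specificity testing. With these
defaults the simulated initial/final adaptation (≈45/85% stiff, ≈35/80%
relaxed) sits in the empirically reported range for this class of
experiment.

**Trial duration.** Integration is fixed-step semi-implicit Euler at
1 kHz (stable for the channel stiffness: ω·dt ≈ 0.055). A reaching trial
records a 0.3 s pre-movement hold (so EMG windows extending 200 ms before
onset always have data), the reach, and then continues until the hand has
been within 0.3 cm of the target (the paradigm ends trials on arrival),
plus a tail of at least 0.35 s, capped at 2 s. A fixed short tail is not
an option: early-exposure low-impedance trials settle slowly and would
otherwise end before the movement-end criterion ever fires.

**Motor noise.** Ornstein-Uhlenbeck force noise (SD 0.25 N, τ = 40 ms)
added to the command. Noise is signal-independent; the empirical
observation that impedance grows faster than force variability under
co-contraction is *not* modeled — a deliberate simplification, noted so
that nobody mistakes its absence for an oversight.

**Synthetic EMG.** Each muscle has a preferred force direction at the
hand; the six muscles form three antagonist pairs spread evenly over
direction (axes 30°/90°/150°), so the summed rectified drive of the
montage is nearly direction-independent — the property that makes the
global EMG statistic's pre-exposure baseline transfer across targets.
The envelope is `baseline + coco_gain·c + force_gain·⌊u·p̂⌋₊` evaluated
for the feedforward command at zero lag plus the feedback correction
delayed by 130 ms (the physiological feedback latency). The raw signal is
this envelope multiplied by zero-mean broadband Gaussian noise at 2 kHz,
so the pipeline's band-pass + rectification recovers the envelope up to a
fixed rectification constant (estimated numerically once, exposed as
`emg.rectification_constant()`; it cancels under per-muscle
normalization). EMG units are arbitrary, as for real surface EMG — only
normalized quantities are interpreted.

**What the simulator does not emulate.** Two-link arm dynamics, stiffness
anisotropy, signal-dependent noise, EMG cross-talk, electrode artifacts,
analog acquisition filters, and any structure in how humans schedule
co-contraction within a trial. Passing tests therefore show that the
*pipeline* measures what it claims on data with the assumed statistical
structure — not that real arms behave like the point-mass plant.

## Validation design and known limitations

Ground-truth `k_internal` is stored per trial, so the central check is
parameter recovery: pooled over the full default 36-participant
experiment, per-trial adaptation scores regressed on `100·k_internal`
give slope ≈ 0.92–0.95 with R² ≈ 0.99.

The slope is below 1 for a physical reason worth understanding: on a
channel trial the compensatory push deflects the hand ≈1 mm into the
wall, and the arm's own stiffness pulls back, so the wall sees only
`K_ch/(K_ch + K_arm)` of the push (≈0.96 relaxed, ≈0.88 for a strongly
co-contracted arm). This measurement attenuation is inherent to
channel-trial scoring, not an estimator defect — the estimator recovers
proportional profiles exactly to 1e-9 and is unbiased under additive
noise.

The same attenuation has a consequence for specificity testing: in a
three-group null world (learning independent of co-contraction) the
instructed stiffness contrast *systematically* depresses measured
adaptation in the stiff group, producing a spurious negative EMG →
adaptation slope of about −3 standard errors. The null-specificity check
is therefore run on cohorts drawn from a single uninstructed population
with natural co-contraction variability, where the regression is
demonstrably unbiased (mean t-statistic ≈ 0) and the ±2 SE coverage
holds. Analysts applying this pipeline to instructed-impedance designs
should keep the attenuation confound in mind; it biases *against* the
positive co-contraction-learning association, so it cannot manufacture
the headline effect. In the default synthetic world the confound also
shows up in the *final*-window regression: at asymptote the groups' true
adaptation levels nearly converge, so the attenuation dominates and the
final EMG → adaptation slope comes out negative — unlike the initial
window, where the learning-rate effect wins and the slope is reliably
positive.

Problem sizes used by the long-running validation suites (package
choices): parameter recovery uses the complete default 36-participant
experiment; the group-ordering reproduction uses 20 seeds of 12
participants with a 26-block exposure (initial window = 13 blocks still
well-defined); the null-specificity check uses 100 cohorts of 20
participants with one pre-exposure block and a 13-block exposure.

## Numerical details

* Degenerate inputs raise structured errors rather than returning NaN: a
  reach that never leaves home or never arrives ("movement not
  detected"), a zero-energy ideal force ("ill-posed regression"), a
  constant force profile ("degenerate profile"), a dead EMG electrode
  (named muscle), windows outside the recorded span, collinear
  regression designs (named condition number).
* Speed-window flags are raised only strictly outside 40–60 cm/s
  (inclusive bounds are "ok", matching the "less than / greater than"
  phrasing of the task rule).
* Time normalization is linear interpolation onto 1000 points between
  onset and end; waveform averages keep the pre-onset segment in real
  time.
* Session serialization is JSON metadata plus per-trial CSVs (kinematics
  at 1 kHz, EMG at 2 kHz); reads use round-trip float parsing so a
  write-read cycle is bit-exact.
* All randomness flows through `numpy.random.Generator` seeded from a
  single `SeedSequence`; identical seeds give bit-identical datasets.
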