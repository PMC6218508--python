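# cocoadapt

Analysis toolkit for **force-field adaptation experiments** — center-out
reaching in a velocity-dependent curl field, with channel-trial force
measurements and surface EMG — bundled with a forward **simulator of the
paradigm** so every stage of the analysis can be validated against known
ground truth. It is aimed at motor-learning researchers who want the
standard curl-field analysis chain (adaptation scoring, kinematic error,
co-contraction proxies) as tested, reusable code rather than lab scripts.

## What it computes

* **Adaptation (%)** on channel trials — the hand is clamped to the
  straight home→target line by a stiff virtual wall (6,000 N/m, 5 Ns/m),
  and the lateral force pressed into the wall reveals predictive
  compensation. With measured force `f_a(t)` and ideal compensating force
  `f_i(t) = `(curl field on the actual velocity, negated), adaptation is
  the through-origin regression coefficient

      k = Σ f_a(t) f_i(t) / Σ f_i(t)²,   adaptation = 100 k,

  over the portion of movement with hand speed > 1 cm/s.
* **Maximum perpendicular error (MPE)** — the signed largest distance
  between the hand path and the straight line from the initial hand
  position to the target, sign-adjusted for field direction so
  clockwise- and counterclockwise-trained participants pool.
* **Oscillation index** — path length of the channel force profile after
  range- and time-normalization (monotone profiles lie in [√2, 2]).
* **Global EMG** — six-channel surface EMG is band-pass filtered
  30–500 Hz (10th-order zero-phase Butterworth), rectified, normalized
  per muscle by pre-exposure activity, and summarized per trial as the
  summed normalized mean minus the pre-exposure baseline, in an early
  (feedforward, −200…+130 ms re onset) and a later (+130…+400 ms) window.
* **Cohort regressions** — per-participant initial/final adaptation
  (first/last 13 exposure blocks) against global EMG, with the
  oscillation index as a second predictor in a multiple regression.

The simulator forward-models the whole experiment: a point-mass hand with
co-contraction-dependent impedance, the curl field `f = b·rot90(v)`
(`b = ±16 Ns/m`), channel walls, 5 N / 500 ms force pulses, a
trial-to-trial learner `k ← A·k + B_eff(1−k)` whose effective learning
rate can depend on co-contraction, and synthetic EMG whose rectified
envelope tracks co-contraction and force output. See `docs/methods.md`
for the model, its parameters, and its limitations.

## Worked example

```python
import numpy as np
from cocoadapt import (CocontractionAdaptationModel, ScheduleSpec,
                       SimConfig, iter_experiment)

spec = ScheduleSpec()          # 100 pre + 50 pulse + 4 + 410 exposure + 100 post
cfg = SimConfig()              # stiff / relaxed / control co-contraction levels
sessions = iter_experiment(spec, cfg, seed=1, n_per_group=12)

model = CocontractionAdaptationModel(sessions)
res = model.fit()
print(res.summary())
init = res.cohort.groupby("group")["initial_adaptation_pct"].mean()
print(init.round(1).to_dict())
print(res.ols_initial)
```

Output (seed 1):

```
{'control': 39.5, 'relaxed': 36.3, 'stiff': 41.9}
beta = 0.658 (SE 0.178), R^2 = 0.286, F(1, 34) = 13.61, P = 0.000782
```

Read: the pre-trained stiff cohort adapts more than the relaxed cohort in
the first 13 exposure blocks (41.9% vs 36.3% of the field compensated),
and across all 36 simulated participants, initial adaptation rises by
0.66 percentage points per unit of global EMG — the qualitative signature
the paradigm is designed to produce, here recovered end-to-end from raw
synthetic force and EMG traces. `res.cohort` also carries the simulator's
ground-truth learning parameters; regressing the per-trial adaptation
scores on true `100·k_internal` gives slope ≈ 0.94 with R² ≈ 0.99 (the
small shortfall is the channel-wall measurement attenuation discussed in
`docs/methods.md`).

Plots and a machine-readable summary: `res.save_report("report/")` writes
block-by-block time courses of MPE, adaptation and global EMG (rest
breaks marked), the regression scatter with its 95% confidence band, and
`summary.json`.

## Command line

```bash
cocoadapt simulate --out data/ --seed 1 --n-per-group 12
cocoadapt analyze  --data data/ --out metrics/
cocoadapt report   --metrics metrics/ --out report/
```

Sessions are stored as a JSON metadata document plus per-trial CSVs
(kinematics at 1 kHz, EMG at 2 kHz); the round trip is lossless.

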