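# saccland

Saccade landing-point prediction from the first milliseconds of the
movement, for gaze-contingent displays that must compensate their update
latency.

## The problem

A saccade relocates gaze in 15–200 ms at up to ~1,000 °/s. Any
gaze-contingent system (foveated rendering, vision simulation, reading
research) updates its display at least 10–12 ms after the gaze moved, so
by the time the update lands the eye is somewhere else. If the landing
point `(x_M, y_M)` of a saccade can be predicted from its first
`N = 10 … 35` ms of samples — and refreshed every 5 ms in flight — the
display can be updated *at the destination* while vision is suppressed
mid-saccade.

## The method

A two-layer LSTM reads the raw 1 kHz coordinate sequence, truncated to a
horizon `N` (zero-padded when the saccade is shorter), and predicts the
landing point through a linear head. Training uses a *fine-grained* dual
objective

```
L3 = L1 + β·L2,   β = 0.7
```

where `L1` is the regression loss on the landing point and `L2` is a
categorical cross-entropy on a discretized target — an 8×8 grid of screen
cells (64 classes) for coordinate targets, or 32 equidistant bins for
displacement ([0.1°, 40°]) and direction ([0, π]). The coarse
classification term stabilises and shapes the representation; the final
prediction always comes from the regression head. One model per horizon
`N ∈ {10, 15, 20, 25, 30, 35}` forms the in-flight ensemble: at each 5 ms
refresh the largest-horizon model not exceeding the available samples
answers.

The package also provides:

* a velocity-threshold saccade detector (Savitzky–Golay smoothing,
  30 °/s onset sustained 10 ms, amplitude/duration/velocity-shape
  filters, cubic-spline blink interpolation, raw-trajectory restoration);
* a calibrated synthetic saccade simulator (truncated-lognormal
  amplitudes with mean 5.8°, main-sequence durations `21 + 2.2·A` ms,
  capped Gaussian velocity profiles, curvature, tracker noise, per-user
  neuromotor variability) so everything is testable without an eye
  tracker;
* published baselines: per-horizon polynomial amplitude fitting
  (18 parameters), a 32×32 ReLU FFNN, a simple RNN, and a center-bias
  Gaussian reference;
* a subject-disjoint (open-set) evaluation protocol with per-user-weighted
  error aggregation and length/age/genre stratification.

The sequence models are implemented in NumPy inside the package
(`saccland.nn`), gradient-checked against finite differences; no deep
learning framework is required.

## Worked example

```python
import numpy as np
from saccland import (LandingPointModel, CenterBiasModel, SimulatorParams,
                      synth_corpus, evaluate, make_splits)

saccades, metas = synth_corpus(10, 250, SimulatorParams(), seed=3)
ids = sorted({s.participant_id for s in saccades})
plan = make_splits(ids, n_repeats=1, seed=3)[0]
train = [s for s in saccades if s.participant_id in plan.train_participants]
test = [s for s in saccades if s.participant_id in plan.test_participants]

model = LandingPointModel(train, target="coordinates", loss="l3", units=(32, 32))
results = model.fit(seed=0, epochs=40, batch_size=64)
print(results.summary())

report = evaluate(results.ensemble, test,
                  allowed_participants=plan.test_participants)
print(report.summary())

center_bias = CenterBiasModel.fit(train, seed=1)
print("center bias:",
      round(evaluate(center_bias, test).headline_mean, 3), "deg")
```

```
Saccade landing-point predictor
===============================================
target:          coordinates
loss:            l3 (beta=0.7)
LSTM units:      32 x 32
parameters/N:    14,978
training set:    2,000 saccades
epochs:          40   seed: 0
-----------------------------------------------
horizon N (ms)   final training loss
      10                 30.3598
      15                 17.0002
      20                 10.4873
      25                  6.9261
      30                  5.5928
      35                  4.3565

Open-set evaluation report
==============================================
test users:       2
test saccades:    500
headline error:   2.296 deg
----------------------------------------------
  E_d<5          1.441 deg
  E_d<15         1.853 deg
  E_d>15         8.566 deg
  E_all          2.296 deg
  N = 10 ms        4.347 deg
  N = 15 ms        2.751 deg
  N = 20 ms        1.919 deg
  N = 25 ms        1.704 deg
  N = 30 ms        1.557 deg
  N = 35 ms        1.496 deg

center bias: 12.799 deg
```

Reading the numbers: the per-horizon training losses fall as the horizon
grows — with more of the saccade visible, the landing point is less
uncertain. The headline open-set error (mean over held-out users of each
user's mean error, itself averaged over the six horizon models) is 2.3°
against a 12.8° center-bias draw; errors grow steeply with saccade length
(1.4° under 5°, 8.6° beyond 15°) and shrink monotonically as more samples
become available (4.3° at 10 ms down to 1.5° at 35 ms).

In-flight use — one refreshed prediction every 5 ms:

```python
preds = results.inflight(test[0])
for p in preds:
    print(p.elapsed_ms, "ms ->", round(p.xL, 2), round(p.yL, 2))
```

```
10 ms -> 10.47 -4.49
15 ms -> 10.98 -6.6
20 ms -> 12.97 -6.81
25 ms -> 13.05 -6.92
```

for a 29 ms saccade that actually landed at (13.88, −7.82): each update
moves the estimate toward the true landing point.

## Command line

```
saccland simulate --users 20 --saccades-per-user 500 --seed 7 --out-dir corpus/
saccland detect   --in trace.csv --out saccades.csv [--params params.yaml]
saccland train    --corpus corpus/ --target coordinates --loss l3 --units 64 --out models/
saccland evaluate --corpus corpus/ --method lstm --repeats 10 --seed 7 --out report/
```

See `docs/methods.md` for the model and generator details, numerical
choices, and known limitations.
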