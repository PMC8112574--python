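# Methods

`saccland` predicts where a saccade will land from the first few
milliseconds of eye-tracker samples, so that a gaze-contingent display can
be updated *during* the movement instead of one system latency after it.
This note documents the models, the synthetic data they are exercised on,
and the numerical choices a user may want to audit or change.

## Problem setting and conventions

Gaze is sampled at 1,000 Hz; positions are degrees of visual angle on a
33 × 19° viewing area, origin at the screen centre, x rightward, y upward.
A saccade is represented by its trajectory `(x_1, y_1) … (x_M, y_M)` at
1 ms steps; its amplitude `d` is the straight-line onset→landing distance
(not the path length), its direction `α = atan2(Δy, Δx) ∈ (−π, π]`, and its
duration `M` ms. The prediction problem: given the first `N` samples,
estimate the landing point `(x_M, y_M)`.

## Saccade detection

The offline cascade follows the standard velocity-threshold design:

1. **Blink handling.** Invalid samples are absorbed outward sample-by-sample
   while the adjacent valid-to-valid step speed exceeds 30 °/s (blink
   artefacts produce spurious fast excursions), then the gap is filled with
   a cubic spline through the remaining valid samples. Gaps touching a
   trace boundary cannot be bridged and are dropped with a warning.
2. **Smoothing.** 3rd-order Savitzky–Golay filter, 15-sample window,
   reflective (mirror) boundary padding. An order-3 filter reproduces
   cubic segments exactly, so the saccadic waveform is preserved while
   sample noise is attenuated.
3. **Thresholding.** Speed is the first difference of position × 1000.
   Onset requires speed > 30 °/s sustained for ≥ 10 ms; completion is the
   first sample back under 30 °/s.
4. **Filters.** Amplitude in (1°, 40°), duration > 15 ms, initial speed
   < 0.075 °/ms (read at the onset sample), terminal speed < 0.3 °/ms (at
   the offset sample), and speed at the first duration quartile
   (index onset + round(M/4)) at least 0.15 × peak speed. The quartile rule
   removes pursuit-like movements with uniformly low early velocity.
5. **Raw restoration.** Accepted saccades get their unsmoothed trajectory
   back: a real-time consumer only ever sees raw samples, so the predictor
   must be trained and evaluated on them.

On a noiseless simulated corpus (500 saccades, 2–20°, ≥ 250 ms fixations)
the cascade reaches recall ≥ 0.95 with median absolute amplitude error
well under 0.5°; both figures are recomputed by `scripts/acceptance.py`.

## The landing-point predictor

Two stacked LSTM layers (32, 64 or 128 units each) read the raw coordinate
sequence, truncated to a horizon `N ∈ {10, 15, 20, 25, 30, 35}` ms and
zero-padded at the end when the saccade is shorter. Heads on the final
hidden state:

* a **linear regression head** `T` (2 units for coordinate targets, 1 for
  angle/displacement targets), and/or
* a **softmax classification head** `T̂` over a discretized target: an
  8 × 8 = 64-cell grid over the screen for coordinates, or 32 equidistant
  values for displacement ([0.1°, 40°]) and angle ([0, π]).

Three objectives:

* `L1` — plain regression (squared Euclidean error during training; all
  *reported* errors are unsquared ℓ2 norms);
* `L2` — categorical cross-entropy `−log p̂[T̂]` on the discretized target
  (probabilities floored at 1e-12);
* `L3 = L1 + β·L2` with β = 0.7 — the fine-grained combination. The
  cross-entropy term acts as an auxiliary coarse-localisation signal that
  shapes the representation; the final prediction always comes from the
  regression head.

Two target strategies: regress the landing coordinates directly, or train
an (angle, displacement) pair of networks and compose
`x_L = x_1 + d·cos α`, `y_L = y_1 + d·sin α`.

Six models are trained per ensemble, one per horizon. In flight, the
prediction is refreshed every 5 ms using the largest-horizon model whose
`N` does not exceed the samples available; below 10 samples no prediction
is made.

The angle discretization range [0, π] cannot represent downward saccades;
it is kept as specified for the classification head (values clamp), while
the regression target uses the full `(−π, π]`. None of the headline
configurations route predictions through the angle bins.

### Parameter accounting

Each LSTM layer holds `4·((I + H)·H + H)` parameters; heads add
`H·G + G`. The standard configurations come to 12,866 (32×32, regression
head only), 14,978 (32×32 with both heads), 54,466 (64×64), 207,170
(128×128), and the feed-forward baseline at horizon 10 to 1,794.

### Training

Backprop-through-time with Adam (lr 1e-3, β₁ 0.9, β₂ 0.999), batch 256,
up to 60 epochs, no early stopping. Inputs are raw screen coordinates in
degrees, un-normalised. Weights are float32 and initialised
glorot-uniform (input kernels) / orthogonal (recurrent kernels) with a
forget-gate bias of 1, all from one seeded generator: a fixed seed
reproduces training bit-for-bit. The implementation is plain NumPy —
the networks are small enough (≲ 210 K parameters) that vectorised BLAS
matmuls train an ensemble in minutes on one CPU core; gradients are
verified against central finite differences in the test suite.

On small corpora (a few thousand saccades) batch 256 yields too few Adam
updates to converge within a reasonable epoch budget; the
convergence-sensitive tests therefore drop the batch size to 64 rather
than raising the learning rate.

## Baselines

* **Polynomial fitting** — per horizon, a least-squares degree-2 polynomial
  from the observed partial displacement (onset → last available sample)
  to the full amplitude: 3 × 6 = 18 parameters. Direction is the angle
  between the first and last available samples; landing is composed
  polar-style. With zero partial displacement the direction is undefined
  and defaults to 0 (flagged degenerate contract).
* **FFNN** — flattened N×2 input, two 32-unit ReLU layers, 2-unit linear
  output, squared-error loss.
* **Simple RNN** — two 32-unit tanh recurrent layers, linear head.
* **Center bias** — a 2D Gaussian fitted to training landing points;
  predictions are random draws ignoring the saccade. This is the floor any
  informed method must beat.

All baselines expose the same per-horizon predict interface as the LSTM
ensemble, so the evaluation protocol is method-agnostic.

## Synthetic data generator

The generator emulates the statistics of large natural-viewing corpora so
the pipeline is testable without an eye tracker:

* **Amplitudes**: lognormal (log-scale σ = 0.8) truncated to [1°, 40°],
  with location solved numerically so the truncated mean is 5.8°.
  Amplitudes whose endpoints cannot fit on the 33 × 19° screen from the
  sampled start point are redirected/shortened (a geometric truncation of
  the extreme tail, < 1 % of draws).
* **Durations**: main-sequence affine law `M = 21 + 2.2·A` ms, rounded;
  the mean-amplitude saccade (5.8°) then lasts ≈ 34 ms, so the corpus
  means match jointly.
* **Velocity**: a Gaussian speed bump centred at `round(M/2)` with
  σ = M/6, normalised so its time-integral equals the amplitude exactly;
  the peak is capped at the main-sequence saturation `η(1 − e^{−A/c})`
  (η = 750 °/s, c = 16°) by widening σ until it fits. Real saccade
  profiles are asymmetric (lognormal/compressed-exponential families);
  the symmetric Gaussian is an acceptable simplification for testing.
* **Curvature**: a single perpendicular arc `h·sin(πt/M)` with `h` uniform
  up to 0.15·A and random sign. Real trajectories can be more complex.
* **Noise**: i.i.d. Gaussian 0.1° per sample (typical video-tracker
  magnitude at 1 kHz); fixations jitter with σ = 0.05°.
* **Per-user variability**: lognormal(0, 0.1) multipliers on the velocity
  ceiling and on the duration slope give each simulated participant a
  stable neuromotor signature; ages are uniform on [20, 80]. This is what
  makes subject-disjoint evaluation non-trivial.
* **Sessions**: fixations (200–400 ms) alternate with saccades; optional
  blink gaps (50–150 ms of invalid samples) exercise the interpolation
  path.

### What passing tests do and do not show

The generator produces near-straight, symmetric-profile, lightly-noised
saccades. Consequently the *polynomial baseline is stronger here than on
real data* — displacement extrapolation is nearly sufficient — so
method-ordering results on synthetic data are qualitative trends, not
reproductions of real-data error tables. Velocity-profile asymmetry,
oculomotor tremor, glissades/dynamic overshoot, pursuit contamination and
stimulus-driven direction statistics are all absent; absolute errors on
real recordings will differ.

One generator-specific interaction worth knowing: lowering a user's
velocity ceiling η at fixed duration *widens* the capped profile, which
increases early-phase displacement and makes prediction *easier*. A
coherent "slower oculomotor system" therefore must lengthen durations
(the slope multiplier), which is how the age-effect recovery test injects
its group difference.

## Evaluation protocol

Open-set: participants are split 80 % / 20 % (test size rounded, at least
1), models never see test participants, and the split is repeated with
fresh randomisation (10 repeats by default). Because participants
contribute unequal saccade counts, every reported mean is a mean of
per-user means. A saccade's headline error is the mean of the six
per-horizon ℓ2 errors; length strata use thresholds at 5° and 15° (the
"< 15°" stratum includes "< 5°"; "> 15°" means ≥ 15°). The
across-repeat spread is the sample standard deviation of the 10 headline
means. Feeding a saccade from a training participant into `evaluate`
raises a protocol violation.

## Problem sizes used in tests and the acceptance script

The packaged experiments run at reduced scale: 25 users × 500 saccades,
the 64×64 fine-grained ensemble trained for 15 epochs on the 20 training
users (10,000 saccades), evaluated on the 5 held-out users. Trend tests
that compare converged methods use 10 users × 250 saccades with batch 64.
These sizes give stable qualitative results (center-bias margin, horizon
monotonicity, in-flight improvement) while an ensemble trains in a few
minutes on one core; they are not the corpus scale of a real eye-tracking
database, and absolute error values scale accordingly.

## Known limitations

* No GPU path and no bidirectional variant (the forward six-horizon
  ensemble is the deployment-relevant configuration).
* The simulator does not model smooth pursuit, vergence, microsaccades
  (< 1°, excluded by the filters anyway) or stimulus-driven gaze placement.
* Resampling of non-1 kHz recordings is out of scope; input must be on a
  complete 1 ms grid.
* The polynomial baseline reconstructs the published idea (18 parameters,
  displacement→amplitude fit) from its description; the original feature
  set is not recoverable.
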