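# Methods

## Data and response definition

The packaged table holds mean (n = 3) measured meropenem concentrations
for seven spiked plasma levels (0.44, 4.38, 17.5, 35.1, 52.6, 70.1,
87.6 mg/L) at nineteen −20 °C storage durations (0, 7, …, 364 days);
day-0 aliquots spent the whole study at −80 °C and act as degradation-free
controls. Only the printed triplicate means are modelled; replicate-level
variance is not.

The modelled response is the fraction remaining. Two reference scales are
supported and the distinction matters:

- `baseline` (default): `Y = Ct / Ct(day 0)`, each experiment's measured
  −80 °C control as denominator. The day-0 measurement absorbs the
  analytical offset between nominal and recovered concentration (controls
  recover 94–105% of nominal), so `Y(0) = 1` by construction. The fitted
  coefficients on this scale are the package's reference results.
- `spiked`: `Y = Ct / C0,nominal`. Kept as an option; record-level
  `relative_remaining` is defined on this scale.

Day-0 records are included in every fit: they are ordinary observations
at storage time zero, and excluding them degrades the time-coefficient
leverage for no principled reason.

## Quadratic response surface

Predictors — storage days and measured concentration — are z-scored
(centering reduces linear/quadratic collinearity; scaling puts days and
mg/L on one scale). The SD denominator is population (divide by n) by
default and switchable to sample (n−1); predictions are provably
invariant to the choice (the quadratic family is closed under affine
predictor maps), only the coefficient parameterization moves, and by far
less than the printed precision.

The design is `[1, x1, x2, x1², x1·x2, x2²]` — graded-lexicographic
order, with the interaction *before* the concentration-squared term.
This matches the order in which the published coefficient values read
term by term; note that the conventional symbol order (squares before
interaction) would swap the last two printed values.

The surface is fitted by OLS (via statsmodels; a QR-based path, checked
in the tests against an explicit normal-equations solve at 1e-10). The
model object carries the coefficient covariance, residual variance,
df = n − 6, and the overall F on (5, n−6) df testing the five
non-intercept terms against an intercept-only model. Coefficient t-tests
use the covariance diagonal with the residual df; confidence and
prediction intervals are the usual t-based forms. Rank-deficient designs
raise instead of silently pseudo-inverting. On the packaged table the
fit gives F = 371.8, R² = 0.936, with every term significant at 5%
except storage-time squared.

## Neural-network comparator

A 2-input, 1-output multilayer perceptron with tanh hidden units,
trained by L-BFGS on MSE plus an L2 penalty (scikit-learn's MLP behind
the package's estimator surface). The admissible space is 1–2 hidden
layers of 2–32 neurons and penalties in [1e-4, 1e-1]; the concrete grid
is widths {2, 4, 8, 16, 32} × {1, 2} layers (second layer same width) ×
penalties {1e-4, 1e-3, 1e-2, 1e-1} — 40 candidates, log-spaced coverage
of the ranges at desk scale. One seeded initialization per candidate, no
restarts; `max_iter` 5000 with tolerance 1e-8 on the objective. Training
is bit-reproducible given (data, hyperparameters, seed).

Because the objective is non-convex, training MSE is only monotone in
the penalty up to local-minimum scatter; the test suite treats relative
decreases within 3% as that scatter and requires monotonicity on at
least 90% of adjacent penalty pairs.

## Validation protocol

Leave-one-experiment-out: one fold per spiked level, the held-out set
being that level's full 19-point time series. Standardizers are fitted
on the training folds only. The polynomial uses the plain outer loop;
the network nests an inner LOEO over the training experiments to pick
hyperparameters by mean validation MSE (ties toward fewer parameters,
then larger penalty), refits the winner on the full outer-training set,
and scores once on the held-out experiment.

Metrics are on the percentage scale: per-experiment RMSE and R² (the
held-out experiment's own mean as the R² baseline — the only choice that
makes per-experiment values comparable), summarized as mean ± sample SD
over the seven folds. Held-out (observed, predicted) pairs are pooled
for Pearson correlation (Fisher-z CI, n−2 df t-test) and Bland–Altman
agreement: differences are prediction − observation, bias is their mean,
limits of agreement bias ± 1.96·SD, with normal-theory CIs
(bias: ±t·sd/√n; limits: ±t·sd·√(3/n)).

Two prediction read-outs exist for the held-out experiment. The default
plugs each record's observed (day, measured concentration) into the
surface. The `trajectory` option instead simulates the experiment
forward from its initial concentration via the fixed-point solve, so
predictions use only the storage day — the read-out that matches how the
model is used prospectively, and the one whose pooled Bland–Altman
statistics land on the study's published bias and p-value.

On the packaged table the polynomial LOEO gives per-fold RMSE
5.76/3.66/4.73/4.59/5.42/3.50/5.92%, mean 4.80%, mean R² 0.898, pooled
r 0.958, bias −0.10 percentage points. The published summary row (mean
4.10%, R² 0.932, r 0.969) is *not* recoverable from the published
rounded table under any evaluation variant we tried; indeed the
published lowest-concentration row (RMSE 5.68%, R² 0.868) is internally
inconsistent with the same fold's network row — the two imply held-out
observation SDs of 15.6 and 11.9 percentage points for the *same*
observations (the table's actual SD is 11.8). The published
cross-validation numbers were evidently computed on unrounded raw data,
with at least one entry in error. The full-data deterministic results —
the equation, F, t-values, and every threshold-crossing day — do
reproduce from the printed table.

## Simulation and back-calculation

Forward simulation from an initial concentration C0 solves, for each
day on a 1-day grid (default horizon 364), the fixed point
`Ct = C0 · f(t, Ct)` by iteration from `Ct = C0` (relative tolerance
1e-9, 100 iterations, bracketed root-finding on [0, 1.2·C0] as
fallback). The mean-response 95% CI is evaluated at the solved point;
degradation is significant on the first grid day whose lower bound is
below the threshold (0.85 default; 0.80 is the conventional variant
near the lower limit of quantification, giving day 176 for the
0.44 mg/L level). No sub-day interpolation; uncertainty in the solved
Ct itself is not propagated into the band (no published recipe exists) —
a documented limitation. The mean-response CI, not the prediction
interval, defines significance (the prediction-interval alternative is
exposed as an option); it reproduces the ~80–135-day crossings.

Back-calculation inverts the surface pointwise: estimated initial =
measured / predicted remaining at (storage days, measured). It is the
exact inverse of the forward solve up to solver tolerance (round-trip
within 0.1% everywhere on the design). Estimates target the day-0
*measured* baseline; against it, mid-range experiments back-calculate
with mean relative error under 15% (the assay's accepted variability),
though individual anomalous time points — notably the day-308 dip
present across all levels — can miss by ~20%. Inputs outside the fitted
ranges (0–364 days, 0.30–86.9 mg/L) are flagged as extrapolation.

## Synthetic-data generator

`synthgen` emulates the study design: the default truth is the fitted
surface at printed precision on a fixed standardized reference scale
(the packaged table's predictor moments), the default grid is the 7 × 19
design, and noise is multiplicative Gaussian with CV 0.05 — measurement
error in this assay is scale-proportional across 0.44–87.6 mg/L, and 5%
sits well inside the 15%/20% acceptability bands of bioanalytical
validation. Noise-free measurements come from the same fixed-point
construction as the simulator; observations multiply them by (1 + ε),
truncated at zero. Generation is vectorized and seeded.

Because the noisy measurement is also a *predictor*, refitting on noisy
data is attenuated (errors-in-variables, ≈2% on the time coefficient at
CV 5%). The generator therefore returns the noise-free concentrations so
recovery studies can separate estimator bias from attenuation; the
fixed reference scale makes recovered and true coefficient vectors
directly comparable without refitting the standardizer.

What passing synthetic tests do *not* show: real plasma data have
replicate-level structure, occasional systematic batch anomalies (the
day-308 dip), and possible matrix effects; none are emulated.

## Problem sizes in the test suite

Monte Carlo checks use 2000 replicates (t-test size), 500 (coefficient
recovery, both OLS-only and fast), and 100 seeds (end-to-end pipeline
and threshold-day recovery). The nested network cross-validation runs
the full 40-candidate grid and is exercised at three seeds.

## Known limitations

- Single temperature (−20 °C); no Arrhenius extrapolation or mechanistic
  hydrolysis kinetics.
- Not externally validated on patient samples; extrapolation beyond the
  fitted concentration/time ranges is flagged but not prevented.
- The network's results are reproducible only given the package's own
  grid and seeds; the admissible hyperparameter space is wider than any
  finite grid.
- Mean-only modelling: no replicate-level or heteroscedastic error
  model for the differences in the agreement analysis.
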