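# Methods

This note documents the statistical models implemented in `keraopt`, the
choices made where the methodology is genuinely open, and what the test
suite does and does not establish.

## Factor coding and designs

Every factor carries a center `X₀` and step `ΔX`, defining the coded scale
`x = (X − X₀)/ΔX`. All fitting happens in coded units; conversion back to
actual units is exact algebra, never a refit.

The 12-run Plackett–Burman design is built from the standard cyclic
generator row `+ + − + + + − − − + −` (eleven cyclic shifts plus an all-low
run). Any balanced orthogonal 12-run two-level matrix estimates the same
main effects, so the generator choice does not affect any analysis result;
the embedded screening table is stored verbatim and used directly for all
reproduction tests.

The central composite design concatenates `2^k` factorial points, `2k`
axial points at distance α (default the rotatable `(2^k)^(1/4)`), and
`n_center` center points, repeated per replicate. Run order is metadata:
every fit in the package is order-invariant. The study geometry is k = 3,
α = 1.682, 6 center points, 2 replicates → 40 runs.

## Screening analysis

The first-order model is fit by least squares on the ±1 coded columns. For
a balanced orthogonal design the main effect equals twice the OLS slope,
and each factor's sum of squares is `n·(effect/2)²`; contribution percent
is that SS over the total corrected SS, so contributions sum to the model
R². t tests use the residual df (n − k − 1 = 5 for six factors in twelve
runs), giving the two-sided critical value 2.57 used as the Pareto
reference line at α = 0.05. Predicted R² is `1 − PRESS/SS_total` with
PRESS from the closed-form leave-one-out identity `(e_i/(1 − h_ii))²`; the
statistic's name is standard but its formula is rarely printed, so the
closed form is pinned by an explicit refit-each-leave-one-out test.

## Second-order surface and ANOVA

The quadratic is fit by OLS on `{1, xᵢ, xᵢ², xᵢxⱼ}`. ANOVA rows use
adjusted (partial, Type-III style) sums of squares — the increase in
residual SS when the term, or the whole linear/square/interaction group, is
dropped and the model refit. With correlated square terms (as in any CCD)
the group row is *not* the sum of its member rows; this matches how the
standard DOE packages print such tables. Pure error comes only from
replicate groups (runs with identical coded settings — including center
points across replicate blocks), lack of fit is the remainder of the
residual, and its F uses the pure-error mean square as denominator.
Goodness statistics are reported on the percent scale (R² family) with
s = √MS_error and PRESS as above.

Uncoding expands `x = (X − c)/s` symbolically: square coefficients divide
by `s²`, cross terms by `sᵢsⱼ`, linear and constant terms collect the
induced shifts. A property test checks coded and uncoded predictions agree
to 1e-8 at random points under random codings.

### Optimization

The fitted quadratic is maximized over a coded region — by default the
cuboid `[−1.682, 1.682]³` spanned by the design (the reported optimum is
interior, so cuboid vs sphere is not binding). When the quadratic part is
negative definite and the stationary point `x* = −½B⁻¹g` lies inside the
region it is returned analytically; otherwise a deterministic multistart
(the 2^k region corners plus the center) runs a bounded Nelder–Mead
simplex (cuboid) or SLSQP with a radius constraint (sphere — SLSQP because
the simplex method has no general nonlinear-constraint support). No
randomness is involved, so optima are reproducible without seeds.

On the embedded 40-run table the optimum is coded (−0.115, −0.152, +0.244),
i.e. 0.533 mg KH₂PO₄/g, 1.424 mg NH₄Cl/g, 11.35 days, predicting
1,647 µg/g. This sits well inside the design region and within 0.1 coded
units of the laboratory-validated composition.

## Neural network

`NetworkSpec` defaults to 3 → 4 → 5 → 1 with tanh hidden activations and a
linear output (47 trainable parameters). Inputs are taken in coded design
units; the response is standardized on the training subset (mean/sd), and
predictions are descaled. Training is full-batch gradient descent on
`mean((ŷ − y)²) + λ·Σw²` — the squared penalty applies to weights only,
the usual weight-decay convention — at learning rate 0.1 for 10,000 tours.
λ defaults to 0.01 on the standardized scale. The holdback fraction 0.45
reserves 18 of 40 runs for validation; the published split ships with the
fixture and is used when present, otherwise a seeded random split is drawn.
Several seeded restarts (default 20) emulate trial-and-error retraining;
the network with the highest validation R² is kept. Backpropagation is
verified against central finite differences to 1e-6 at every layer shape
used in tests.

Known limitation: with 22 training points and 47 parameters the kept
network's overall R² on all 40 runs plateaus near 0.973–0.976 under this
trainer, slightly below the quadratic model's 0.9832. A systematic sweep
(penalty 0 → 0.2, learning rate 0.02 → 0.5, L-BFGS instead of gradient
descent, per-tour validation selection, momentum, standardized inputs,
swapped hidden-layer order, up to 100 restarts) did not close the gap; the
commercial tool that produced the reference network uses a penalized
least-squares trainer with a validation-tuned penalty whose internals are
not published. The corresponding acceptance test records this gap rather
than hiding it. The defaults above were chosen once and are also the best
of the sweep, so nothing was sacrificed to keep them.

## Metrics and comparison

Per prediction subset: `R² = 1 − SSE/SS_total` using the subset's own
observed variance (so a validation subset can outscore training — as it
does here for the quadratic model), `RMSE = √(SSE/n)`, MAD the mean
absolute residual. The comparison winner is decided on overall R² with
RMSE as tiebreak. Residual diagnostics use normal plotting positions
`(i − 0.375)/(n + 0.25)`. Pearson correlation and fold change
(optimized/baseline, baseline > 0) round out the utilities used for isolate
screening and yield accounting.

The six-isolate keratinase/amino-acid correlation computed from the
embedded values is r = 0.961; the source reports 0.967. The difference is
consistent with the printed per-isolate values themselves being rounded,
and tests assert agreement within ±0.01.

## Synthetic data

`simulate_pb_response` draws `baseline + Σ x·(effect/2) + N(0, σ)` on a
two-level design; `simulate_ccd_response` draws a known quadratic surface
plus `N(0, σ)`. The default surface noise σ = 42.6 is the square root of
the pure-error mean square of the replicated study design (45,371/25 ≈
1,815) — the replication noise the real experiment exhibited. Noise is
homoscedastic Gaussian, matching the ANOVA framework's assumption; the
generators emulate the *statistical* structure only, not fermentation
kinetics (no growth/enzyme dynamics, no heteroscedasticity, no run-order
drift). Passing recovery tests therefore show the estimators are correct
under the model's own assumptions, not that the model is true of any real
fermentation.

Simulation-based tests use fixed seeds: 200 seeds for coefficient-recovery
and power checks (seconds of runtime), 500 for the null-contribution
check. Under the null, each of the 11 orthogonal contrasts of the 12-run
design absorbs on average 1/11 of the total variation, which the test
verifies for the 6 assigned columns.

## Numerical notes

* OLS uses `lstsq` with an explicit rank check that names collinear
  columns; leverages come from `(X'X)^{-1}` directly (models here have at
  most 10 terms).
* Degenerate inputs are rejected with specific errors: non-finite factor
  levels, unbalanced screening columns, saturated screening designs
  (zero residual df), zero-variance inputs to correlation/R², holdback
  splits that empty a subset, non-positive fold-change baselines.
* Zero-variance observed subsets report R² as undefined (`None`) rather
  than raising inside metric aggregation.
* Thousands separators in the transcribed study tables were stripped when
  the fixtures were embedded; values are otherwise digit-exact to the
  printed tables, and replicated printed rows are stored as distinct runs
  with replicate ids.
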