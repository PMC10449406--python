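# Methods

## The model

`samplingcost` studies a class of incremental-processing algorithms whose
running time scales intrinsically with surprisal: algorithms that repeatedly
*sample* candidate hypotheses (meanings, parses) from the comprehender's
prior until one explains the observed word.  Writing `I = -ln p` for the
surprisal of the word (its negative log probability given context, in nats
throughout), two idealized members of the class are analyzed exactly.

**Guessing with replacement.**  Each guess is an independent draw from the
prior; the probability that a draw explains the word is the word's marginal
probability `p`.  The number of draws `M` is geometric, so

    E[M]   = 1/p        = e^I
    Var[M] = (1-p)/p^2  = e^{2I} - e^I.

Both moments are strictly increasing — the mean exponentially — in
surprisal, and the variance is superlinear in the mean.

**Guessing without replacement.**  Rejected hypotheses are removed from the
pool.  Index the hypotheses that do not explain the word `1..K` with weights
`u_1..u_K`, and collapse the explaining mass into a target item `0` with
weight `u_0`.  At each step an item is drawn with probability proportional
to the weights of items not yet drawn; the draw count `N` is `1 + Σ X_i`
where `X_i` indicates that item `i` precedes the target.  The key fact
(transparent in the exponential-race formulation below) is the precedence
probability

    Pr(i before j) = u_i / (u_i + u_j),

which depends on no other weight.  With `u_ab := u_a + u_b`,
`u_abc := u_a + u_b + u_c`:

    E[N]   = 1 + Σ_i u_i / u_i0
    Var[N] = Σ_i (E[X_i] - E[X_i]^2) + Σ_{i≠j} (E[X_i X_j] - E[X_i] E[X_j]),

with the cross-moment expanded over the two orders in which both `i` and `j`
can precede the target:

    E[X_i X_j] = (u_i/u_ij0)(u_j/u_j0) + (u_j/u_ij0)(u_i/u_i0).

An enumeration oracle (ordered distractor prefixes, `K ≤ 8`) is the arbiter
of these expressions; the closed forms agree with it to better than 1e-10 on
random instances, which is how the algebra of the cross-moment was pinned
down.

**Posterior update and the relative-entropy identity.**  One incremental
step multiplies the prior by a likelihood `p(w|z) ∈ [0,1]` and renormalizes;
the normalizer is the word's marginal probability, whose negative log is the
step surprisal.  When the likelihood is 0/1-valued (structures determine the
word), the surprisal equals `KL(posterior ‖ prior)` exactly; a graded
likelihood breaks the identity.  Both sides are computed by direct summation
and compared in the tests.

## Linking functions

Four parametric families map surprisal to processing time (ms):
linear `α + βI` (with proportionality `α=0, β=1` as a special case),
exponential `c·e^I`, power `c·I^k`, and the retrieval-latency form
`F(e^I - 1)^f` obtained from the ACT-R latency formula `F e^{-fA}` via the
log-odds identity `log-odds(p) = -ln(e^I - 1)`.  With `f = 1` (the common
assumption, and our default) the latency form is the exponential family
shifted by `-F`.  Fitting is least squares: closed-form for linear and
exponential, Levenberg–Marquardt from a fixed grid of starts for power and
actr, so fits are deterministic given the data.  The power family's
proportionality constant is exposed as an explicit scale parameter `c`.

## Simulation

The without-replacement sampler has two distributionally identical
implementations: sequential renormalized draws (vectorized across runs) and
an exponential race in which item `i` fires at `E_i/u_i`, `E_i ~ Exp(1)`,
and the firing order is read off.  The race form makes the precedence
probability obvious and is the default in the all-targets experiment; the
two are tested for distributional agreement against the enumeration pmf.
Every stochastic operation takes an explicit seed; the all-targets
experiment spawns per-target child streams from one parent seed so results
do not depend on evaluation order.

The runtime-vs-surprisal experiment treats each item of a weight set in turn
as the target (rotation to index 0 preserves the other items' order) and
tabulates simulated against analytic moments.  The canonical configuration
is 1000 weights drawn from Pareto(1, 1) — heavy-tailed, as word-frequency
distributions are — normalized, with 500 runs per target; Pareto draws use
inverse-CDF sampling on a seeded uniform stream.  The tests and the
acceptance script run a reduced configuration (100 weights, 2000 runs per
target) that exhibits the same qualitative behavior — mean runtime strictly
increasing and superlinear in target surprisal, runtime variance rising and
then flattening in the top decile of the surprisal range — at a few seconds
of compute.  The variance cap on the quadratic-cost pairwise sum defaults to
K = 5000 with an explicit override.

## Synthetic reading-time data

The generator emulates the structure of a self-paced-reading corpus without
any text.  `n_items` abstract items receive surprisals from a right-skewed
distribution — by default lognormal with `σ = 1` and median 2 nats, so the
overwhelming majority of items have low surprisal with a heavy right tail;
a `pareto_derived` option reuses the surprisals of a normalized Pareto
weight set instead.  Every subject reads every item in order, and

    rt = link(I) + β_spill · I_prev + b_subj + m_subj · I + ε,
    ε ~ Normal(0, exp(ℓ(I))^2),

with `ℓ` either constant or linear in surprisal (the location-scale
structure), per-subject intercepts `b_subj ~ N(0, 30 ms)`, per-subject
slopes `m_subj` with SD equal to 10% of the linking function's secant slope
over the realized surprisal range, and a one-previous-word spillover effect
of 8 ms/nat.  Defaults: 40 subjects × 800 items, baseline 250 ms, slope
25 ms/nat for the linear link, noise SD 50 ms.  RTs are floored at 1 ms and
the floored count logged.  The generator is a pure function of its config.

What it does **not** emulate: word frequency/length covariates and their
interaction, non-Gaussian RT distributions (Gamma/inverse-Gaussian waiting
times), nonlinear per-subject deviations, multi-word spillover, and
autocorrelated residuals within a story.  Passing recovery tests therefore
shows the estimators work under the generator's assumptions, not that those
assumptions exhaust real reading data.

The degradation perturbation multiplies the surprisal of a seeded random
fraction of rows (default 30%) by a constant (default 2) while keeping the
reading times fixed, imitating an estimator that systematically
overestimates some words' surprisal.  Because low-RT rows land in the upper
surprisal range, the fitted linking function flattens at the top and fitted
superlinearity drops — the package's tests confirm the drop on paired seeds.
The default fraction and inflation are package choices exposed in the
configuration.

## Curve fitting

The location-scale fitter estimates the mean curve `μ(s)` and log-SD curve
`ℓ(s)` by an iterated two-stage penalized-spline scheme: (1) penalized
weighted least squares of RT on a cubic B-spline basis (6 basis functions by
default, knots at surprisal quantiles, second-order difference penalty,
weights `exp(-2ℓ)` normalized to mean 1 so the penalty scale is stable),
with optional subject fixed intercepts and a linear spillover term; (2)
penalized least squares of `log|residual|` on the same basis, de-biased by
`E[ln|Z|] = (ln 2 + ψ(1/2))/2` for standard normal `Z` (computed at
startup).  The mean-stage penalty is chosen by generalized cross-validation
on a fixed log-spaced grid; the scale stage reuses it (one fewer knob).
Iteration stops at a relative curve change below 1e-6 or 50 iterations;
non-convergence is flagged, not raised.  The low basis dimension
deliberately caps the wiggliness of the fitted curve so its two-interval
slopes are interpretable.

The linear control replaces both curves with straight lines, iterated the
same way a fixed 3 times.  Standard errors are CR1 cluster-robust by
subject: with by-subject intercept and slope variation in the data the
classical errors would be badly anticonservative for repeated-measures
reading data.  Subject adjustment is fixed intercepts; nonlinear per-subject
smooths are out of scope.  Disabling the scale stage gives the
constant-variance control, which on convex-link data agrees with the full
fitter on the sign of superlinearity.

This fitter deliberately replaces factor-smooth thin-plate GAM machinery
with a small, fully specified estimator: the fidelity target is qualitative
agreement (curve shape, slope signs, superlinearity sign), not
coefficient-level replication of any particular mixed-model fit.

## Superlinearity

For a curve (or scatter) over an x-range, split the observed range at its
midpoint (midpoint ties to the lower half), take the OLS slope in each half,
and report `slope_high - slope_low`.  Fitted curves are first evaluated on a
uniform 512-point grid per half so the statistic does not depend on the
density of the fitting data.  The statistic is invariant to adding an affine
function of x.  Positive values mean the curve bends upward; note a U-shaped
curve is "superlinear" by this definition — the statistic measures global
convexity, not monotonicity, which is why the direction of the effect is
established separately by the linear control's slope.  The full observed
range (not a trimmed quantile range) is split; this is exposed in the API by
operating on whatever points are passed in.  The companion trend regression
is weighted least squares of superlinearity on estimator quality (negative
log perplexity, so higher is better), with uniform weights by default.

## Numerical choices

- Surprisal is in nats everywhere; a nats↔bits helper exists but units are
  never mixed internally.
- Weights are stored at arbitrary scale; probabilities are formed on demand.
- Moment sums use `math.fsum` / numpy pairwise reductions; the variance
  cross-term is evaluated in 2048-column blocks.
- The enumeration oracle uses compensated float summation, not rational
  arithmetic; 1e-10 comparison tolerances are ample at `K ≤ 8`.
- Nonlinear linking fits multi-start from fixed grids (power:
  k ∈ {0.5..3}, actr: f ∈ {1..3}) to keep results deterministic.
- `log|residual|` is clipped at 1e-8 before logging; RTs are floored at
  1 ms with a logged count.
- Problem sizes in the test suite and acceptance script (100-item runtime
  experiment with 2000 runs per target, 10^5-run simulation checks,
  40×800-row recovery studies over 20 seeds) were chosen so the full
  qualitative behavior is exhibited while the whole suite runs in a couple
  of minutes on one CPU.

## Known limitations

- The variance formula's pairwise sum is O(K²); the default cap (K = 5000)
  is an explicit override away but the cost grows quadratically.
- GCV can undersmooth at small n; the low basis dimension bounds the damage.
- The exponential link over a heavy-tailed surprisal distribution produces
  astronomically large tail RTs; sign-level conclusions (positive
  superlinearity, positive log-SD slope) are robust to this, but magnitudes
  of the superlinearity statistic under exponential links are
  tail-dominated and should not be compared across datasets.
- The linear control's cluster-robust errors assume many subjects (40 by
  default); with very few clusters they are themselves anticonservative.
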