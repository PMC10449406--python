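# samplingcost

Runtime theory of sampling-based incremental processing, and the tools to
test its behavioral signature in reading-time data.

Words that are more surprising given their context take longer to read.
Most accounts assume reading time grows *linearly* in surprisal
`I = -ln p(word | context)` and say nothing about variance.  Algorithms
that integrate a word by repeatedly *sampling* candidate interpretations
from the prior make two sharper predictions: processing time should grow
**superlinearly** in surprisal, and its **variance should grow too**.  This
package implements that theory exactly and provides the statistical
machinery to look for its signature — for computational psycholinguists who
want closed forms, seeded simulations, and a transparent curve fitter
instead of a pile of one-off scripts.

## What's inside

- **Exact runtime theory.**  Guessing with replacement: the draw count is
  geometric, `E[M] = e^I`, `Var[M] = e^{2I} - e^I`.  Guessing *without*
  replacement over items with weights `u_0..u_K` (target indexed 0):
  `E[N] = 1 + Σ u_i/(u_i+u_0)`, with an exact variance built from the
  precedence probability `Pr(i before j) = u_i/(u_i+u_j)`.  A brute-force
  enumeration oracle validates both to 1e-10.
- **Seeded Monte-Carlo simulation** of both algorithms, plus the
  all-targets experiment over heavy-tailed (Pareto) weight sets that shows
  mean runtime rising superlinearly in surprisal and runtime variance
  rising then plateauing.
- **Linking functions**: linear `α+βI`, exponential `c·e^I`, power `c·I^k`,
  and the ACT-R retrieval-latency form `F(e^I-1)^f`, connected to surprisal
  via the log-odds identity `log-odds = -ln(e^I - 1)`; deterministic
  least-squares fitting of each family.
- **Synthetic self-paced-reading generator** with a known linking function,
  location-scale noise, by-subject effects and spillover — plus a
  surprisal-degradation perturbation that emulates systematically
  overestimated surprisals.
- **Location-scale curve fitter**: penalized-spline estimation of mean RT
  and log-SD of RT as smooth functions of surprisal, with a linear control
  model, and the two-interval **superlinearity** statistic.

## Worked example: runtime theory

```python
import samplingcost as sc

ws = sc.make_weightset([0.4, 0.3, 0.2, 0.1])   # target weight 0.4, 3 distractors
th = sc.wor_runtime_variance(ws)
wr = sc.geometric_runtime_moments(ws.target_probability)
sim = sc.simulate_wor(ws, 100_000, seed=1)
```

prints (via the fields of the returned summaries):

```
target surprisal (nats): 0.9163
with replacement:    mean 2.5     var 3.75
without replacement: mean 1.9619  var 0.916
simulated (n=100000): mean 1.9605  var 0.9174
```

The target's surprisal is `-ln 0.4 = 0.92` nats, so with replacement the
guesser needs `e^I = 2.5` draws on average.  Removing rejected hypotheses
can only help: the exact without-replacement mean is 1.9619 draws (its
distribution is supported on {1,…,4}), and a 100k-run simulation agrees to
within sampling error on both moments.

## Worked example: superlinearity in reading data

```python
data = sc.generate_rt_dataset(
    sc.GeneratorConfig(linking=sc.LinkingFunction.power(15.0, 2.0), seed=0)
)                                   # 40 subjects x 800 items, convex link
ctrl = sc.fit_linear_control(data)
fit  = sc.fit_location_scale(data)
sl   = sc.superlinearity_of_fit(fit)
```

```
linear-control slope: 88.94 +/- 7.85 ms/nat
log-SD slope:         0.2620 +/- 0.0069 per nat
superlinearity:       617.3 ms/nat (low 327.8, high 945.0)
```

The linear control confirms the overall effect is positive (RT and its
variability both increase with surprisal), and the smooth fit's upper-half
slope exceeds its lower-half slope by 617 ms/nat — the convexity the
sampling account predicts.  On linear-link data the same statistic
fluctuates around zero.

The same workflow is available from the shell:

```
samplingcost figure1 --items 1000 --runs 500 --seed 0 --outdir fig1/
samplingcost synth --seed 5 --out data.tsv
samplingcost fit --in data.tsv --out-prefix fit
samplingcost superlinearity --in fit.tsv --x-col grid --y-col mu
samplingcost demo --seed 0 --outdir demo/
```

## Layout

```
src/samplingcost/
  priors.py         weight/probability containers, Pareto weights, posterior update
  analytic.py       closed-form runtime moments, precedence, KL identity
  oracle.py         brute-force enumeration ground truth (K <= 8)
  simulator.py      seeded Monte-Carlo guessing + all-targets experiment
  linking.py        linking-function families and fitting
  synthetic.py      reading-time generator and surprisal degradation
  curvefit.py       location-scale penalized-spline fitter + linear control
  superlinearity.py two-interval statistic and quality-trend regression
  tables.py         TSV I/O
  pipeline.py       end-to-end demo pipeline
  cli.py            command-line interface
```

See `docs/methods.md` for the estimators, defaults, and their rationale.
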