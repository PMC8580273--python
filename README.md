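# fcrank

Bayesian comparison of the three classic models of life-course
epidemiology — **accumulation**, **sensitive periods** and **critical
period** — and decomposition of the sensitive model into the most
informative credible ranking of measurement occasions.

## Who this is for

Life-course studies relate repeated measures of an exposure (body weight,
adversity, smoking, ...) at occasions `t = 1..T` to a later health
outcome.  The standing question is *which temporal pattern* links exposure
to outcome: do all occasions matter equally (accumulation), does one
occasion dominate (critical period), or do several matter to different
degrees (sensitive periods)?  `fcrank` answers this with posterior
probabilities of the three hypotheses and, when the sensitive model wins,
with a credible partial ordering of the occasions by importance.

## The model and the two statistics

The linear coefficients on the exposure history are reparameterized as
`theta = delta * w`, giving the regression

    y_i = delta * sum_j x_ij w_j + eps_i,    eps_i ~ N(0, sigma)

where `w` lies on the T-part simplex (`w_j >= 0`, `sum_j w_j = 1`) and
captures each occasion's *relative* importance, while the scalar `delta`
is the total lifetime effect.  Priors: `w ~ Dirichlet(1)` (uniform on the
simplex), `delta ~ Cauchy(0, 2.5)`, `sigma ~ lognormal(1, 1)`; an
intercept and covariates with `Cauchy` priors are available for
observational analyses.

Two univariate summaries of the posterior `p(w | y)` do all the work:

1. **Range statistic** `phi = max(w) - min(w)`.  Thresholds
   `0 < a < b < 1` (default 0.15/0.85) carve `[0, 1]` into regions of
   practical equivalence: accumulation `[0, a]`, sensitive `(a, b)`,
   critical `[b, 1]`.  The posterior probability of each model is the
   fraction of MCMC draws of `phi` in its interval; a model is accepted
   when its probability exceeds 0.9 (Bayes factors against the prior ROPE
   probabilities are reported alongside).

2. **Finest credible rank (FCR)** `C_beta`.  Partial rankings such as
   `1,3|2` ("occasion 2 matters more than 1 and 3, which are not
   distinguished") have posterior probability equal to the fraction of
   draws satisfying their inequalities.  Starting from the most probable
   full ranking, the FCR algorithm greedily merges adjacent blocks —
   keeping the most probable coarsening at each step — and stops at the
   first ranking with probability `>= beta` (default 0.90).  The result is
   the most informative ordering statement the data support at that
   credibility.

Analyses are gated: the model comparison is only attempted when the 95%
credible interval for `delta` excludes zero.

## Worked example

```python
import fcrank as fc

truth = fc.GroundTruth.make("linear", T=3, delta_star=2.0)  # w* = (1,2,3)/6
data  = fc.simulate_dataset(truth, n=3000, seed=7)
draws = fc.fit(data)

print(fc.delta_interval(draws))          # 2.02 (1.97, 2.06)
rope = fc.rope_test(draws.weight_draws)
print(rope.probabilities, rope.decision)
res = fc.finest_credible_rank(draws.weight_draws, beta=0.9)
print(res.format_report())
```

prints (from `examples/03_sensitive_decomposition.py`):

```
delta: 2.02 (1.97, 2.06)
model probabilities: a=0.0000 s=1.0000 c=0.0000 -> sensitive
Ranking	Probability
1|2|3	1.000
1,2|3	1.000
1,2,3	1.000
q = 1.00 of true distinctions preserved; consistent with truth: True
```

The lifetime effect is estimated at 2.02 (truth: 2), every posterior draw
of `phi` falls in the sensitive interval, and the 90% FCR is the full
ranking `1|2|3`: at n = 3000 the data order all three occasions with
essentially certainty.  `q = r/r*` is the fraction of the true ordering's
distinctions the FCR retained.

More walk-throughs live in `examples/` (one script per capability), and
`fcrank --help` exposes the same workflow as a command line
(`simulate | fit | test | fcr | analyze | study`).

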