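# wmcap — working-memory capacity estimation

`wmcap` implements, end to end, the two standard routes to estimating
visual working-memory capacity *k*:

- **Compound-stimulus report (CSVI).** The number of correctly reported
  features at stimulus level *n* is modelled with the Bose-Einstein
  occupancy distribution: *r* indistinguishable units of attention fall
  uniformly over the weak compositions into *n* feature "boxes", and the
  score is the number of occupied boxes,
  `p(x) = C(n, n-x) C(r-1, x-1) / C(n+r-1, r)`.
  Long presentation is assumed to allow *k* attending acts (r = k²); brief
  presentations allow 1–3 acts (r = k, 2k, 3k). Capacity is estimated per
  participant by exhaustive integer maximum likelihood over k ∈ 1..9.
- **Change detection (VAT).** Cowan's per-set-size formula
  `k = N (p(H) + p(CR) − 1)`, and a hierarchical Bayesian three-parameter
  model with capacity *k*, attending probability *z* and guessing bias *g*
  (`p(hit) = z(m + (1−m)g) + (1−z)g`, `p(FA) = z(1−m)g + (1−z)g`,
  `m = min(k, N)/N`), fit across set sizes by an adaptive
  Metropolis-within-Gibbs sampler with Geweke convergence diagnostics and
  an optional fixed-*z* control analysis.

A synthetic-data module simulates both task designs (including presets for
the five study designs the package targets), and a pipeline layer rebuilds
the published expected-value table, correlates observed with expected
short/long ratios, compares estimates across tasks, and runs
simulate-then-fit recovery studies. The intended users are researchers in
working memory / psychometrics who want reproducible, tested
implementations of these estimators rather than one-off scripts.

## Worked example

Expected mean correct reports per trial for a capacity-7 participant
(`wmcap table1 --k 7`, abridged):

```
level  long  short_2acts  short_1act  short_3acts
    2  1.96         1.87        1.75         1.91
    5  4.62         3.89        3.18         4.20
    6  5.44         4.42        3.50         4.85
    7  6.24         4.90        3.77         5.44
```

Reading: a capacity-7 observer shown a 7-feature stimulus reports on
average 6.24 features with long presentation (r = 49 balls) but only 3.77
with a single brief attending act (r = 7); the short/long ratio falls with
level exactly as the occupancy model predicts.

Simulating a cohort and re-estimating capacity:

```python
import numpy as np
from wmcap import synthetic, csvi, vat

spec = synthetic.scenario_presets("exp1a", seed=9)   # 20 participants, 8 trials/level
trials, truth = synthetic.simulate_csvi_cohort(spec)
counts = csvi.counts_from_trials(trials, condition="long")
k_hat = {p: csvi.estimate_k(c, csvi.SATURATION).k_hat for p, c in counts.items()}

spec3 = synthetic.scenario_presets("exp3", seed=0)   # 24 participants, set sizes 3/6/8/10
vtrials, vtruth = synthetic.simulate_vat_cohort(spec3)
summary = vat.fit_mcmc(vat.counts_from_trials(vtrials, condition="short"))
print({p: round(v, 2) for p, v in summary.population_means().items()})
# {'k': 4.18, 'z': 0.96, 'g': 0.45}
print(round(summary.acceptance_rate, 2))
# 0.69
```

The fitted population means land on the generating population (k ≈ 4.4,
z ≈ 0.94, g ≈ 0.48) within posterior uncertainty, and the acceptance rate
sits in the healthy 0.65–0.75 band the adaptive proposals target.

The same flows are scriptable from the shell: `wmcap simulate`,
`wmcap fit-csvi`, `wmcap fit-vat [--fix-z 0.95]`, `wmcap compare
--null-diff 1`, and `wmcap recover --scenario exp3`.

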