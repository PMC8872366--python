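# wqsmix

Chemical-mixture epidemiology toolkit: sex-stratified **weighted quantile
sum (WQS) regression** with repeated-holdout validation, **g-computation**
counterfactuals on mixture and nutrition indices, and **exposure-reduction
scenario** analysis — the analysis pattern used to link a prenatal mixture
of 26 endocrine-disrupting chemicals (EDCs) and maternal nutrition to
children's IQ in pregnancy-cohort studies.

It is written for biostatisticians and environmental epidemiologists who
want that full pipeline as tested, scriptable Python rather than a one-off
analysis, and who need a synthetic cohort with known ground truth to
validate every stage (the motivating cohort data are access-restricted).

## The model

Chemicals are decile-scored (q_ij ∈ {0,…,9}, empirical full-sample cuts)
and combined into a single index with sex-specific weights on one simplex:

    WQS_i = Σ_j w[s(i), j] · q_ij ,   w ≥ 0,  Σ w = 1  (52 weights: 26 per sex)

The outcome model is the stratified interaction parameterization

    y = β0 + β1·WQS + β2·x + β12·x·WQS + φ′z + ε ,

with x = 1 for girls: β1 is the boys' slope and β1 + β12 the girls' slope.
Weights are estimated by simplex-constrained least squares (β1
sign-constrained, direction chosen a priori) averaged over bootstrap
resamples of a 40% training split; the frozen-weight index is then tested
by OLS on the 60% holdout; the whole procedure repeats over (by default)
100 random splits and the distribution of estimates is the result.  Mean
weights above the equi-weight guideline 1/52 ≈ 0.019 flag chemicals of
concern.  g-computation turns the fitted model into marginal "what if"
contrasts (e.g. index fixed one SD below its mean), and the scenario
module asks what class-wise exposure reductions would push subjects below
that target.  See `docs/methods.md` for assumptions and numerical details.

## Worked example

Simulate a cohort at the published summary statistics (n = 678, known
sparse truth with boys' slope −2.13), run a reduced repeated-holdout
analysis, and ask the two counterfactual questions:

```python
from wqsmix import (simulate_cohort, run_repeated_holdout, summarize_ensemble,
                    scale_metric, gcomp_marginal, compute_index)

cohort, quantiles = simulate_cohort(n=678, seed=1)
ensemble = run_repeated_holdout(cohort, quantiles, n_repeats=20, n_boot=50, seed=1)
summary = summarize_ensemble(ensemble)
print(summary.parameters.loc[["WQS", "WQS:Female"]].round(3))
```

```
            Estimate  Std. Error   2.5%  97.5%  Frac. negative
WQS           -1.866       1.067 -3.908 -0.327            1.00
WQS:Female     1.438       1.295 -0.876  3.216            0.15
```

The boys' slope is recovered near the generating −2.13 with every repeat
negative; the positive interaction pulls the girls' slope (β1 + β12 ≈ −0.4)
toward zero, as built into the truth.  Marginal counterfactual (index one
SD below its mean, weights frozen at the ensemble average):

```python
import numpy as np
from wqsmix import WeightSet

flat = np.mean([r.weights.flat for r in ensemble.repeats], axis=0)
ref = ensemble.repeats[0].weights
weights = WeightSet(flat.reshape(ref.weights.shape) / flat.sum(),
                    chemicals=ref.chemicals)
index = compute_index(quantiles.scores, weights, cohort.sex)
metric = scale_metric(index, name="WQSsc")
res = gcomp_marginal(metric, cohort.covariates, cohort.sex, cohort.outcome,
                     levels=(0.0, -1.0), n_boot=200, seed=1)
print({s: round(d, 2) for s, d in res.difference.items()})
print({s: (round(float(lo), 2), round(float(hi), 2))
       for s, (lo, hi) in res.ci_difference.items()})
```

```
{'boy': 2.02, 'girl': 0.55, 'overall': 1.3}
{'boy': (0.74, 3.0), 'girl': (-0.44, 1.54), 'overall': (0.51, 2.03)}
```

Boys gain ≈ 2 IQ points under the one-SD reduction counterfactual while
girls change little — the pattern encoded by the interaction truth.  The
same machinery runs from the shell:

```bash
wqsmix simulate --n 678 --seed 1 --out cohort/
printf 'n_repeats: 20\nn_boot: 50\n' > small.yaml
wqsmix all --config small.yaml --seed 1 --out run/   # full pipeline + report bundle
wqsmix report --out run/
```

(The package defaults — 100 repeats × 100 bootstraps with 3 optimizer
restarts — reproduce the reference analysis settings and take hours on one
core; the reduced config above gives the same qualitative picture in
minutes.)

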