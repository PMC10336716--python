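# voival

Value-of-information analysis for the **external validation** of clinical
risk prediction models.

When a previously developed risk model is validated on a finite sample from
a new population, its estimated clinical utility — the **net benefit** (NB)
of decision curve analysis — carries sampling uncertainty. A risk-neutral
decision maker should adopt whichever strategy has the highest *expected*
NB, but the finite sample means that choice can be wrong, and being wrong
costs clinical utility. `voival` quantifies that cost as the **expected
value of perfect information (EVPI)** for model validation, so that the
question "do we need more validation data?" gets an answer in the same
units as the decision curve itself.

## The quantities

At a risk threshold `z` (treat when predicted risk ≥ z), with outcome
`Y ∈ {0,1}` and predicted risk `π`:

- `NB_model = P(π ≥ z, Y=1) − P(π ≥ z, Y=0) · z/(1−z)`, estimated by the
  sample mean of `I(π_i ≥ z){Y_i − (1−Y_i) z/(1−z)}`;
- `NB_all = P0 − (1−P0) · z/(1−z)` for treating everyone (P0 = prevalence);
  treat-none has NB 0;
- `dNB = NB_model − max(0, NB_all)`, the model's incremental utility.

Bootstrap (ordinary, or Bayesian with flat-Dirichlet observation weights)
replicates of the pair `(NB_model, NB_all)` are read as draws from the
posterior of the true net benefits. Then

```
EVPI = E[ max(0, NB_model, NB_all) ] − max(0, E NB_model, E NB_all)
```

is the expected NB lost per decision because the truly best strategy is
uncertain. Alongside it the package reports `P(useful)` (posterior
probability the model strategy is truly the best), the relative EVPI, and
TP/FP population equivalents (`EVPI × N decisions`, or `× (1−z)/z` in
avoided false positives). An asymptotic alternative models the estimator
pair as bivariate normal with closed-form moments and evaluates the
expectation of `max(0, N1, N2)` as a bivariate-normal loss integral.

## Worked example

```python
from voival import (SimConfig, generate_sample, decision_curve,
                    evpi_bootstrap, scale_to_population)

# a 500-subject validation sample from the reference mechanism
# logit P(Y=1|X) = -1.55 + 0.77 X  (prevalence 20%, c-statistic 0.70),
# with the candidate model equal to the correct model
sample = generate_sample(SimConfig(n=500, seed=3))

curve = decision_curve(sample, [0.1, 0.2, 0.3])
print(curve.to_frame().round(4).to_string(index=False))

r = evpi_bootstrap(sample, z=0.3, B=10_000, scheme="bayesian", seed=1)
print(f"EVPI at z=0.3: {r.evpi:.6f}  p_useful={r.p_useful:.3f}  "
      f"winner={r.winner}  rEVPI={r.r_evpi:.3f}")
tp, fp = scale_to_population(r.evpi, 0.3, 10_000)
print(f"per 10,000 decisions: {tp:.1f} TP or {fp:.1f} FP equivalents")
```

prints

```
 threshold  nb_model  nb_all  nb_none
       0.1    0.1151  0.1067      0.0
       0.2    0.0405 -0.0050      0.0
       0.3    0.0134 -0.1486      0.0
EVPI at z=0.3: 0.000915  p_useful=0.851  winner=model  rEVPI=1.069
per 10,000 decisions: 9.2 TP or 21.4 FP equivalents
```

Reading: at z = 0.3 the model strategy has the highest expected NB
(0.0134 net true positives per decision, vs. treat-all at −0.1486 and
treat-none at 0), so with current information the model should be used. But
in 14.9% of posterior draws another strategy is truly better, and
eliminating that uncertainty would be worth 0.000915 NB units per decision
— equivalent to 9.2 extra true positives (or 21.4 avoided unnecessary
treatments) per 10,000 decisions. That is the expected yield of further
validation at this threshold.

The same analyses are available from the shell:

```
voival dca sample.csv --grid 0:0.3:0.05 -o curve.csv
voival evpi sample.csv --z 0.3 --method bayesian --B 10000 --seed 1 -o voi.csv
voival evpi sample.csv --z 0.3 --method asymptotic -o voi.json
voival scale --value 0.0005 --z 0.02 --n 800000
voival simulate --n-grid 250,500,1000,2000 -o experiment.csv
```

Each file-writing run also writes a `.manifest.json` (inputs, options,
seed, version) from which the output is exactly reproducible.

A logistic coefficient set can be applied to a covariate table to produce
the risks (`voival.load_gusto_model()` ships the published post-myocardial-
infarction 30-day mortality model as a ready-made example;
`LogisticModel.from_json` loads your own).

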