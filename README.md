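# triarm

Bayesian pre–post analysis of three-arm anxiety trials.

`triarm` implements the outcome analysis for a randomized design with a
control arm and two intervention arms (a single exposure session vs.
multiple sessions), measuring public-speaking anxiety before and after
treatment on bounded questionnaire scales. It is aimed at researchers who
want a fully scripted, reproducible version of this analysis — including a
synthetic-trial generator, so every stage can be validated end-to-end even
when the original participant-level data are unavailable.

## The model

Each outcome `y_i` (a post-treatment score) is tied to the linear predictor

```
eta_i = mu + alpha_j + beta * C_i + gamma_j * C_i  [+ beta_F * F_i]
```

where `j` indexes the arm (control, multiple, single) with the
reference-arm constraint `alpha_control = gamma_control = 0`, `C_i` is the
participant's matching pre score, and `F_i` an ordinal topic-familiarity
covariate (1..5) used for the SPIC and STAI outcomes. The STAI outcome has
no pre measurement, so its predictor reduces to `mu + alpha_j + beta_F F_i`.

Two likelihood families:

* **Robust ANCOVA** — `y_i ~ Student-t(nu, eta_i, sigma)` with identity
  link, for PRCA-24, SPIC (post and after) and STAI. Heavy tails absorb
  outliers; for `nu > ~30` the fit is indistinguishable from normal ANCOVA.
* **Beta regression with logit link** — for the bounded IAT score
  (range −2..2). Scores are squeezed into (0, 1), the mean is
  `mu_i = logistic(eta_i)`, and `y_i ~ Beta(phi mu_i, phi (1 − mu_i))`.

Priors are weakly informative: coefficients `~ normal(0, 100)`; the
positive parameters `sigma`, `nu`, `phi` have `Gamma(2, rate 0.1)` priors
(central 95% interval 2.4–55.7), `nu` truncated to `nu > 1`. Sampling uses
independent affine-invariant ensembles (emcee), 4 chains, with split-Rhat
gated at 1.01.

The headline derived quantity is the **probability of improvement** at a
conditioning anchor `x` of the pre-score scale (10% above the minimum, the
midpoint, or 10% below the maximum):

```
P(post mean > x | pre = x, data)    # "increase" scales
P(post mean < x | pre = x, data)    # PRCA-24, where lower = better
```

and the **odds of improvement** between two arms is the ratio of their
probabilities at the same anchor. Classical Cohen's d effect sizes on
change scores round out the descriptive layer.

## Worked example

```python
import triarm

cfg = triarm.reference_config()            # 15 / 14 / 16 participants per arm
dataset = triarm.generate_trial(cfg, seed=1)

model = triarm.BayesianOutcomeModel.from_dataset("postPRCA24", dataset)
results = model.fit(chains=4, iterations=1500, seed=2)
print(results.summary().round(3))
```

```
                  mean      sd    2.5%   97.5%   rhat
mu              16.420   9.563  -2.638  35.272  1.009
alpha_multiple  -7.983  13.007 -33.828  17.188  1.005
alpha_single     0.657  14.085 -27.339  28.672  1.002
beta             0.850   0.137   0.582   1.119  1.008
gamma_multiple   0.047   0.187  -0.313   0.414  1.005
gamma_single     0.009   0.199  -0.384   0.398  1.002
sigma            6.833   0.888   5.337   8.859  1.005
nu              24.051  14.306   5.639  59.547  1.004
```

The posterior mean slope for the control arm is `beta ≈ 0.85` (each point
of baseline communication apprehension carries over at slightly less than
one-for-one), and the interaction draws shift that slope for the treated
arms. Improvement probabilities condition on the anchors of the 24–120
scale (33.6 / 72 / 110.4):

```python
print(results.prob_improvement("single", 110.4))   # P(post < 110.4 | pre = 110.4)
# 0.394  -> on this synthetic trial, roughly even odds that a highly
#           anxious participant's modelled post score drops below baseline
```

(Exact numbers vary with the simulation seed; those shown are from the
seeds above.) The full grid — all five outcomes, all anchors, between-arm
odds, slope-exceedance probabilities and effect sizes — comes from the
pipeline:

```
triarm full --seed 1 --out run1/        # dataset + posteriors + reports
```

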