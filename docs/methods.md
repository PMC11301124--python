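# Methods

## Design and model

The package analyses a three-arm randomized pre–post trial of
public-speaking anxiety: a control arm (n=15), a multiple-session exposure
arm (n=14) and a single-session exposure arm (n=16). Four bounded
questionnaire scales are built in:

| scale  | bounds    | improvement | role |
|--------|-----------|-------------|------|
| IAT    | −2..2     | increase    | implicit fear of negative evaluation (pre/post) |
| PRCA24 | 24..120   | decrease    | communication apprehension (pre/post) |
| SPIC   | 15..105   | increase    | perceived competence (pre/post and after the test speech) |
| STAI   | 8..32     | increase    | state comfort, short form (post only) |

Each of the five outcomes (postIAT, postPRCA24, postSPIC, afterSPIC,
postSTAI) gets its own independent parameter block — no pooling across
outcomes — with linear predictor

    eta_i = mu + alpha_j + (beta + gamma_j) * C_i [+ beta_F * F_i],

`alpha_control = gamma_control = 0` structurally (the control arm is the
reference; the treated-arm parameters are contrasts against it, and the
structural zeros are not representable in the parameter containers, so
they cannot be set by accident). Familiarity `F_i` (ordinal 1..5, how well
the participant knows the speech topic) enters only the SPIC outcomes and
STAI; postSTAI has no pre covariate.

Likelihoods: Student-t location-scale `t(nu, eta, sigma)` for the four
score-scale outcomes (identity link), Beta with logit link for the bounded
IAT. The Student-t "scale" `sigma` is the SD only in the large-`nu`
(normal) limit; at finite `nu` the SD is `sigma * sqrt(nu/(nu-2))`. A
Gaussian likelihood (`likelihood="normal"`) exists as the explicit
large-`nu` limit, used for diagnostics.

The Beta parameterization is mean/precision: `y ~ Beta(phi*mu, phi*(1-mu))`
with `mu = logistic(eta)`. Responses and the pre covariate are mapped to
the open unit interval with the affine map followed by the
Smithson–Verkuilen compression `u' = (u(n-1) + 0.5)/n`, applied to every
score (not only boundary scores) so the transform stays continuous and
strictly monotone; `n` is the number of records in the fitted dataset.
Results on the mean scale are mapped back through the exact inverse, so
conditioning anchors are always expressed on the original −2..2 scale.

## Priors

* Coefficients (`mu`, `alpha_j`, `beta`, `gamma_j`, `beta_F`):
  normal(0, SD 100) — central 95% interval ±196.
* `sigma`, `nu`, `phi`: Gamma(shape 2, rate 0.1) — central 95% interval
  2.4–55.7. The `nu` prior is truncated to `nu > 1` (renormalized by the
  upper-tail mass), which reconciles the prior's support with the
  Student-t degrees-of-freedom constraint.

These are weakly informative on the scales involved; with trial-sized data
the posterior intervals of all identified parameters are several times
narrower than their priors. The exception is `nu`: with ~45 near-normal
records the degrees of freedom are weakly identified and their posterior
legitimately spans most of the prior. This is a property of the design,
not a convergence failure.

## Sampling

The sampler sits behind a minimal backend contract (vectorized log density
in unconstrained space in, draws out), so engines are interchangeable. The
default backend runs one independent affine-invariant ensemble (emcee) per
chain; `sigma`, `nu`, `phi` are sampled as `log sigma`, `log(nu-1)`,
`log phi` with the Jacobian in the target. Defaults: 4 chains × 3000
iterations (ensemble moves), first half discarded as warmup; the surviving
walker states (≥ 2·ndim + 2 walkers, ~16–20 for these models) are
flattened into each chain's draw set. Walkers start in a small ball around
a least-squares estimate (logit-scale least squares for the Beta model),
which removes most burn-in at these model sizes.

Convergence is certified with rank-normalized split-Rhat (arviz) per
parameter, gated at 1.01. A fit failing the gate is returned flagged
(`converged=False`, a `ConvergenceWarning`, and `raise_for_convergence()`);
the CLI exits nonzero. Seeds propagate through `numpy.random.SeedSequence`
spawning, one stream per chain, so a fixed seed and backend reproduce
draws bit-for-bit.

Because chains are walker-interleaved, naive autocorrelation-based ESS
estimates on the flattened draws are optimistic; where the test-suite needs
a Monte Carlo standard error it uses the spread of per-chain means instead.

A brute-force grid posterior (`triarm.grid`) serves as an independent
oracle for reduced models with at most three free parameters: the
unnormalized log posterior is evaluated on a tensor grid, normalized by the
trapezoid rule, and flagged if the boundary slices carry more than 0.1% of
the mass. It shares nothing with the sampler beyond the log density.

## Synthetic trials

The generator draws trials with exactly the structure the models assume:

* arm sizes 15/14/16 (total 45) in the reference configuration;
* pre scores: truncated normal within scale bounds — IAT 0 ± 0.6,
  PRCA-24 70 ± 15, SPIC 55 ± 14 (invented but plausible values; the
  source reports only change-score descriptives, not pre/post moments or
  their covariance, so the pre-score moments and the implicit pre–post
  correlation are the package's choices);
* familiarity: ordinal draw with probabilities (0.1, 0.2, 0.4, 0.2, 0.1),
  mode and median 3;
* Student-t outcomes: `post = eta + sigma * t(nu)`, clipped to bounds;
* IAT: Beta draw on the squeezed unit interval, mapped back to −2..2.

Reference truth blocks are loosely calibrated to the motivating trial's
published summaries: the SPIC/afterSPIC main effects and slope reductions
use the reported posterior means (e.g. multiple-arm main effect 47.78 with
slope change −0.67 on postSPIC; 68.06 and −1.02 on afterSPIC), and the
remaining blocks are set so arm-level change means sit near the published
descriptives while preserving the treated-arm slope-reduction signature on
PRCA-24. For any single linear truth these two published layers are
mutually in tension (the model-based anchor probabilities reflect
covariances the descriptives do not pin down), so the change means are
matched near the centre of the pre-score distribution and the control
arm's top-anchor behaviour is left unmatched.

What passing tests on these trials do show: the estimation machinery
recovers known truths, the derived probabilities behave correctly, and the
pipeline is deterministic. What they do not show: anything about the real
participants — the generator has no dropout, no session-by-session
dynamics in the multiple-session arm, independent outcomes given the
covariates, and exactly the fitted model's error structure.

Clipping Student-t draws at the scale bounds slightly distorts the
likelihood near the edges. Under the reference truths at large n roughly
0.5% of PRCA-24 draws clip, which measurably biases the high-pre arm's
slope; recovery and coverage tests therefore use an "interior"
configuration (smaller slope and effects, post means ≥ 3 SD inside the
bounds, clipping ~0%) so the data are genuinely generated under the fitted
model. Trial-scale analyses are unaffected at this clipping rate.

## Derived quantities

Conditioning anchors for a scale with bounds (xmin, xmax) and range d:
`xmin + 0.1 d`, `(xmin+xmax)/2`, `xmax − 0.1 d` — e.g. 33.6 / 72 / 110.4
for PRCA-24.

The improvement probability at anchor x is computed over the posterior of
the conditional mean (the linear predictor pushed through the link,
familiarity at its median 3), not the posterior predictive of a new
observation; the predictive variant (adding Student-t or Beta observation
noise per draw) is available behind `predictive=True`. Note the
mean-based probability at a truth exactly on the anchor is driven entirely
by the dataset's sampling noise — across replicate null datasets it is
nearly uniform on (0, 1) with expectation 1/2 — which is why the null
calibration test averages over replicate trials rather than asserting 0.5
for a single dataset.

Reported anchors follow each scale's improvement direction: PRCA-24
(decrease) at middle/highest, all "increase" scales at lowest/middle,
STAI unconditional. Odds between arms are plain probability ratios; a zero
denominator yields infinite odds rather than an error. Displayed odds are
rounded half-to-even — integers at ≥ 10, one decimal below — with the raw
ratio always retained.

Effect sizes: paired Cohen's d uses the change-score SD denominator (d_z),
the usual convention for pre–post designs; the average-SD variant (d_av)
is available behind an option and never silently mixed in. Between-arm d
on change scores uses the pooled SD with n−1 variances; no small-sample
(Hedges) correction. `cohen_d_from_summary` reconstructs the between-arm d
from group means, SEs and sizes and is exact for exact summaries;
2-decimal published SEs limit agreement with published d values to about
±0.03.

## Numerical choices and problem sizes

* Boundary squeeze denominator: the fitted dataset's record count.
* Grid oracle: trapezoid normalization; coverage flag at 0.1% edge mass;
  refinement on the test fixture changes marginal means by < 1e-3.
* Convergence gate 1.01 on split-Rhat; at least 2 chains and 10 draws per
  chain required for the statistic.
* Test-suite problem sizes: recovery fits use 500 participants per arm
  with shortened chains (300–500 iterations, 16 walkers); coverage uses 50
  replicates; null calibration averages 40 replicate trials at 60 per arm;
  oracle equivalence uses a 30-record fixture. These sizes give stable
  checks at interactive runtimes on a single CPU.
* Degenerate inputs: zero-range scales, out-of-bounds scores, unknown arm
  labels, zero change-score SDs and single-chain Rhat requests are all
  rejected with named errors; non-finite likelihood contributions report
  the offending record index.

## Known limitations

* The ensemble sampler is not NUTS; very high-dimensional or strongly
  multimodal extensions would need a different backend (the contract
  accepts any engine that maps a vectorized log density to draws).
* `nu` is prior-dominated at trial-sized n (see Priors).
* Published posterior summaries of the motivating trial cannot be
  reproduced numerically: the participant-level data are not public, and
  the original warmup/seed are unrecorded. Printed derived arithmetic
  (anchors, prior intervals, odds ratios of published probabilities)
  reproduces exactly.
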