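"""Bayesian ANCOVA-style outcome models for a three-arm pre-post trial.

For each anxiety outcome the mean is tied to a linear predictor

    eta_i = mu + alpha_j + beta * C_i + gamma_j * C_i  [+ beta_F * F_i]

where ``j`` indexes the arm (control / multiple / single) with the
reference-arm constraint ``alpha_control = gamma_control = 0``, ``C_i`` is
the participant's matching pre score and ``F_i`` the ordinal familiarity
covariate (used for the SPIC outcomes and STAI). The STAI outcome has no
pre covariate, so its predictor reduces to arm main effects plus
familiarity.

Two likelihood families are used:

* ``student_t`` — robust location-scale Student-t, ``y_i ~ t(nu, eta_i,
  sigma)`` with identity link; heavy tails absorb outliers and for
  ``nu >~ 30`` the fit is indistinguishable from a normal ANCOVA.
* ``beta_logit`` — for the bounded IAT score: responses (and the pre
  covariate) are squeezed into (0, 1), the mean follows a logit link
  ``mu_i = logistic(eta_i)``, and ``y_i ~ Beta(phi * mu_i, phi * (1 -
  mu_i))`` with precision ``phi``.

A ``normal`` family (identity link, Gaussian likelihood) is also available
as the large-``nu`` limit of the Student-t model, mainly for diagnostics.

Priors are weakly informative: all regression coefficients are
``normal(0, 100)``; the positive parameters ``sigma``, ``nu``, ``phi`` have
``Gamma(shape 2, rate 0.1)`` priors (95% interval 2.4-55.7), with the
``nu`` prior truncated to ``nu > 1`` where the Student-t variance exists as
a distribution.

The user-facing entry point is :class:`BayesianOutcomeModel` (construct
from a :class:`~triarm.data.TrialDataset`, call :meth:`fit`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit, gammaln

from .data import CONDITIONS, TrialDataset
from .scales import ScaleDefinition, normalize_bounded

__all__ = [
    "PriorSpec",
    "ModelSpec",
    "ModelParams",
    "builtin_spec",
    "all_builtin_specs",
    "linear_predictor",
    "likelihood_mean",
    "log_likelihood",
    "log_prior",
    "BayesianOutcomeModel",
]

_LIKELIHOODS = ("student_t", "beta_logit", "normal")


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors: coefficients ~ normal(0, coef_scale),
    positive parameters (sigma, nu, phi) ~ Gamma(shape, rate)."""

    coef_scale: float = 100.0
    positive_shape: float = 2.0
    positive_rate: float = 0.1

    def positive_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Central credible interval of the positive-parameter prior."""
        g = stats.gamma(self.positive_shape, scale=1.0 / self.positive_rate)
        a = (1.0 - level) / 2.0
        return (float(g.ppf(a)), float(g.ppf(1.0 - a)))

    def coef_interval(self, level: float = 0.95) -> tuple[float, float]:
        n = stats.norm(0.0, self.coef_scale)
        a = (1.0 - level) / 2.0
        return (float(n.ppf(a)), float(n.ppf(1.0 - a)))


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one outcome model.

    Parameters
    ----------
    outcome : str
        Outcome column (``postIAT``, ``postPRCA24``, ``postSPIC``,
        ``afterSPIC`` or ``postSTAI``).
    likelihood : {"student_t", "beta_logit", "normal"}
    covariate : str or None
        Matching pre-score column; None for STAI (no pre measurement).
    uses_familiarity : bool
        Whether the familiarity covariate enters the predictor.
    """

    outcome: str
    likelihood: str
    covariate: str | None
    uses_familiarity: bool
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self) -> None:
        if self.likelihood not in _LIKELIHOODS:
            raise ValueError(f"unknown likelihood {self.likelihood!r}")

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["mu", "alpha_multiple", "alpha_single"]
        if self.covariate is not None:
            names += ["beta", "gamma_multiple", "gamma_single"]
        if self.uses_familiarity:
            names += ["beta_fam"]
        if self.likelihood in ("student_t", "normal"):
            names += ["sigma"] + (["nu"] if self.likelihood == "student_t" else [])
        else:
            names += ["phi"]
        return tuple(names)

    @property
    def n_coef(self) -> int:
        """Number of regression coefficients (before sigma/nu/phi)."""
        n = 3
        if self.covariate is not None:
            n += 3
        if self.uses_familiarity:
            n += 1
        return n


_BUILTIN_SPECS = {
    "postIAT": ModelSpec("postIAT", "beta_logit", "preIAT", False),
    "postPRCA24": ModelSpec("postPRCA24", "student_t", "prePRCA24", False),
    "postSPIC": ModelSpec("postSPIC", "student_t", "preSPIC", True),
    "afterSPIC": ModelSpec("afterSPIC", "student_t", "preSPIC", True),
    "postSTAI": ModelSpec("postSTAI", "student_t", None, True),
}


def builtin_spec(outcome: str) -> ModelSpec:
    """The default model structure for one of the five trial outcomes."""
    try:
        return _BUILTIN_SPECS[outcome]
    except KeyError:
        raise KeyError(f"unknown outcome {outcome!r}; expected one of {list(_BUILTIN_SPECS)}")


def all_builtin_specs() -> dict[str, ModelSpec]:
    return dict(_BUILTIN_SPECS)


@dataclass(frozen=True)
class ModelParams:
    """A parameter point. Control-arm main effect and interaction are
    structural zeros — they are not fields and cannot be set."""

    mu: float
    alpha_multiple: float = 0.0
    alpha_single: float = 0.0
    beta: float | None = None
    gamma_multiple: float = 0.0
    gamma_single: float = 0.0
    beta_fam: float | None = None
    sigma: float | None = None
    nu: float | None = None
    phi: float | None = None

    def __post_init__(self) -> None:
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.nu is not None and self.nu <= 1:
            raise ValueError("nu must be > 1")
        if self.phi is not None and self.phi <= 0:
            raise ValueError("phi must be > 0")

    def alpha(self, condition: str) -> float:
        return {"control": 0.0, "multiple": self.alpha_multiple, "single": self.alpha_single}[
            condition
        ]

    def gamma(self, condition: str) -> float:
        return {"control": 0.0, "multiple": self.gamma_multiple, "single": self.gamma_single}[
            condition
        ]


def linear_predictor(
    params: ModelParams,
    condition: str,
    covariate_value: float | None = None,
    familiarity: float | None = None,
) -> float:
    """Evaluate eta = mu + alpha_j + (beta + gamma_j) * c [+ beta_F * f].

    ``covariate_value`` must be given iff the model has a pre covariate
    (``params.beta`` set); ``familiarity`` iff ``params.beta_fam`` is set.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    eta = params.mu + params.alpha(condition)
    if params.beta is not None:
        if covariate_value is None:
            raise ValueError("model has a pre covariate; covariate_value required")
        eta += (params.beta + params.gamma(condition)) * covariate_value
    elif covariate_value is not None:
        raise ValueError("model has no pre covariate; covariate_value not accepted")
    if params.beta_fam is not None:
        if familiarity is None:
            raise ValueError("model uses familiarity; familiarity value required")
        eta += params.beta_fam * familiarity
    return float(eta)


def likelihood_mean(spec: ModelSpec, eta):
    """Map the linear predictor to the outcome-scale mean: identity for
    Student-t/normal, inverse-logit for the Beta model."""
    eta = np.asarray(eta, dtype=float)
    if spec.likelihood == "beta_logit":
        out = expit(eta)
    else:
        out = eta
    return out if out.ndim else float(out)


def _student_t_logpdf(y, nu, mu, sigma):
    z = (y - mu) / sigma
    return (
        gammaln((nu + 1.0) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * np.log(nu * np.pi)
        - np.log(sigma)
        - (nu + 1.0) / 2.0 * np.log1p(z * z / nu)
    )


def _beta_logpdf(y, a, b):
    return gammaln(a + b) - gammaln(a) - gammaln(b) + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(
        -y
    )


class BayesianOutcomeModel:
    """One outcome's Bayesian regression model, built from trial data.

    Parameters
    ----------
    spec : ModelSpec
        Outcome, likelihood family, covariate structure and priors;
        :func:`builtin_spec` supplies the defaults for the five outcomes.
    dataset : TrialDataset
        Wide-format trial records.

    Examples
    --------
    >>> model = BayesianOutcomeModel.from_dataset("postPRCA24", dataset)
    >>> results = model.fit(seed=7)
    >>> results.summary()          # doctest: +SKIP
    """

    def __init__(self, spec: ModelSpec, dataset: TrialDataset):
        self.spec = spec
        self.dataset = dataset
        self.scale: ScaleDefinition = dataset.scale_for(spec.outcome)
        arrays = dataset.outcome_arrays(spec.outcome)
        self.nobs = len(arrays["y"])
        self.n_obs_squeeze = self.nobs  # Smithson-Verkuilen denominator

        y = arrays["y"]
        if spec.likelihood == "beta_logit":
            y = np.asarray(normalize_bounded(y, self.scale, self.n_obs_squeeze))
        self.endog = y

        cols = [np.ones(self.nobs)]
        cols.append((arrays["condition"] == "multiple").astype(float))
        cols.append((arrays["condition"] == "single").astype(float))
        if spec.covariate is not None:
            pre = arrays["pre"]
            if spec.likelihood == "beta_logit":
                pre = np.asarray(normalize_bounded(pre, self.scale, self.n_obs_squeeze))
            self.pre = pre
            cols.append(pre)
            cols.append(pre * cols[1])
            cols.append(pre * cols[2])
        if spec.uses_familiarity:
            cols.append(arrays["familiarity"])
        self.exog = np.column_stack(cols)
        self.param_names = spec.param_names

    # -- parameter vector <-> ModelParams ---------------------------------
    def params_to_vector(self, params: ModelParams) -> np.ndarray:
        vals = []
        for name in self.param_names:
            v = getattr(params, name)
            if v is None:
                raise ValueError(f"params missing {name!r} required by this model")
            vals.append(float(v))
        return np.array(vals)

    def vector_to_params(self, theta: np.ndarray) -> ModelParams:
        return ModelParams(**dict(zip(self.param_names, map(float, theta))))

    # -- densities ---------------------------------------------------------
    def loglike_per_record(self, theta: np.ndarray) -> np.ndarray:
        """Per-record log density at one constrained parameter vector."""
        theta = np.asarray(theta, dtype=float)
        k = self.spec.n_coef
        eta = self.exog @ theta[:k]
        if self.spec.likelihood == "student_t":
            sigma, nu = theta[k], theta[k + 1]
            return _student_t_logpdf(self.endog, nu, eta, sigma)
        if self.spec.likelihood == "normal":
            sigma = theta[k]
            z = (self.endog - eta) / sigma
            return -0.5 * z * z - np.log(sigma) - 0.5 * math.log(2.0 * math.pi)
        phi = theta[k]
        mu = expit(eta)
        return _beta_logpdf(self.endog, phi * mu, phi * (1.0 - mu))

    def loglike(self, theta: np.ndarray) -> float:
        """Total log likelihood; raises if any record contributes a
        non-finite density, naming the record index."""
        contrib = self.loglike_per_record(theta)
        if not np.all(np.isfinite(contrib)):
            bad = int(np.flatnonzero(~np.isfinite(contrib))[0])
            raise FloatingPointError(
                f"non-finite log-likelihood contribution at record index {bad}"
            )
        return float(contrib.sum())

    def logprior(self, theta: np.ndarray) -> float:
        """Log prior density at a constrained parameter vector."""
        theta = np.asarray(theta, dtype=float)
        k = self.spec.n_coef
        pri = self.spec.priors
        s = pri.coef_scale
        lp = float(
            -0.5 * np.sum((theta[:k] / s) ** 2)
            - k * (math.log(s) + 0.5 * math.log(2.0 * math.pi))
        )
        if self.spec.likelihood in ("student_t", "normal"):
            sigma = theta[k]
            if sigma <= 0:
                raise ValueError("sigma must be > 0")
            lp += float(self._gamma_logprior(np.asarray(sigma)))
            if self.spec.likelihood == "student_t":
                nu = theta[k + 1]
                if nu <= 1:
                    raise ValueError("nu must be > 1")
                # truncated to nu > 1: renormalize by the upper-tail mass
                lp += float(self._gamma_logprior(np.asarray(nu))) - self._log_nu_trunc()
        else:
            phi = theta[k]
            if phi <= 0:
                raise ValueError("phi must be > 0")
            lp += float(self._gamma_logprior(np.asarray(phi)))
        return lp

    def logpost(self, theta: np.ndarray) -> float:
        try:
            return self.loglike(theta) + self.logprior(theta)
        except (ValueError, FloatingPointError):
            return -np.inf

    # -- unconstrained parameterization for samplers -----------------------
    # sigma = exp(z), nu = 1 + exp(z), phi = exp(z); log-Jacobian = z.
    def constrain(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        theta = z.copy()
        k = self.spec.n_coef
        if self.spec.likelihood == "student_t":
            theta[:, k] = np.exp(z[:, k])
            theta[:, k + 1] = 1.0 + np.exp(z[:, k + 1])
        else:
            theta[:, k] = np.exp(z[:, k])
        return theta

    def unconstrain(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        z = theta.copy()
        k = self.spec.n_coef
        if self.spec.likelihood == "student_t":
            z[:, k] = np.log(theta[:, k])
            z[:, k + 1] = np.log(theta[:, k + 1] - 1.0)
        else:
            z[:, k] = np.log(theta[:, k])
        return z

    def logpost_unconstrained(self, z: np.ndarray) -> np.ndarray:
        """Vectorized log posterior in the unconstrained space; ``z`` has
        shape (walkers, ndim) or (ndim,). Returns one value per row."""
        z2 = np.atleast_2d(np.asarray(z, dtype=float))
        w, _ = z2.shape
        k = self.spec.n_coef
        pri = self.spec.priors
        coefs = z2[:, :k]  # (w, k)
        eta = self.exog @ coefs.T  # (n, w)
        y = self.endog[:, None]
        out = np.full(w, -np.inf)
        with np.errstate(over="ignore", invalid="ignore"):
            if self.spec.likelihood == "student_t":
                log_sigma, log_num1 = z2[:, k], z2[:, k + 1]
                sigma = np.exp(log_sigma)
                nu = 1.0 + np.exp(log_num1)
                ll = _student_t_logpdf(y, nu[None, :], eta, sigma[None, :]).sum(axis=0)
                lp = self._coef_logprior(coefs) + self._gamma_logprior(sigma) + log_sigma
                lp += self._gamma_logprior(nu) - self._log_nu_trunc() + log_num1
            elif self.spec.likelihood == "normal":
                log_sigma = z2[:, k]
                sigma = np.exp(log_sigma)
                zz = (y - eta) / sigma[None, :]
                ll = (-0.5 * zz * zz).sum(axis=0) - self.nobs * (
                    log_sigma + 0.5 * math.log(2.0 * math.pi)
                )
                lp = self._coef_logprior(coefs) + self._gamma_logprior(sigma) + log_sigma
            else:
                log_phi = z2[:, k]
                phi = np.exp(log_phi)
                mu = expit(eta)
                ll = _beta_logpdf(y, phi[None, :] * mu, phi[None, :] * (1.0 - mu)).sum(axis=0)
                lp = self._coef_logprior(coefs) + self._gamma_logprior(phi) + log_phi
            val = ll + lp
        finite = np.isfinite(val)
        out[finite] = val[finite]
        return out if np.asarray(z).ndim > 1 else float(out[0])

    def _coef_logprior(self, coefs: np.ndarray) -> np.ndarray:
        s = self.spec.priors.coef_scale
        k = coefs.shape[1]
        return -0.5 * (coefs / s) ** 2 @ np.ones(k) - k * (
            math.log(s) + 0.5 * math.log(2.0 * math.pi)
        )

    def _gamma_logprior(self, x: np.ndarray) -> np.ndarray:
        a, r = self.spec.priors.positive_shape, self.spec.priors.positive_rate
        return a * math.log(r) - gammaln(a) + (a - 1.0) * np.log(x) - r * x

    def _log_nu_trunc(self) -> float:
        if not hasattr(self, "_nu_trunc_cache"):
            pri = self.spec.priors
            gam = stats.gamma(pri.positive_shape, scale=1.0 / pri.positive_rate)
            self._nu_trunc_cache = float(np.log(gam.sf(1.0)))
        return self._nu_trunc_cache

    # -- rough point estimate for sampler initialization -------------------
    def start_vector(self) -> np.ndarray:
        """Least-squares start values (logit scale for the Beta model)."""
        y = self.endog
        if self.spec.likelihood == "beta_logit":
            y = np.log(y / (1.0 - y))
        coef, *_ = np.linalg.lstsq(self.exog, y, rcond=None)
        resid = y - self.exog @ coef
        s = float(np.std(resid, ddof=min(len(coef), len(y) - 1)))
        s = max(s, 1e-3)
        if self.spec.likelihood == "student_t":
            extras = [s, 10.0]
        elif self.spec.likelihood == "normal":
            extras = [s]
        else:
            extras = [10.0]
        return np.concatenate([coef, extras])

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        *,
        chains: int = 4,
        iterations: int = 3000,
        warmup: int | None = None,
        seed: int | None = None,
        backend=None,
        walkers: int | None = None,
    ):
        """Sample the posterior; returns an
        :class:`~triarm.results.OutcomeResults`.

        ``iterations`` counts sampler moves per chain, of which ``warmup``
        (default: half) are discarded. Reproducible for a fixed seed and
        backend. Convergence is gated on split-Rhat < 1.01; a failing fit
        is returned flagged (``results.converged`` False) with a warning,
        never silently.
        """
        from .inference import fit as _fit

        return _fit(
            self,
            chains=chains,
            iterations=iterations,
            warmup=warmup,
            seed=seed,
            backend=backend,
            walkers=walkers,
        )

    @classmethod
    def from_dataset(cls, outcome: str, dataset: TrialDataset) -> "BayesianOutcomeModel":
        """Build the default model for one of the five outcomes."""
        return cls(builtin_spec(outcome), dataset)


def log_likelihood(spec: ModelSpec, params: ModelParams, dataset: TrialDataset) -> float:
    """Total log likelihood of ``dataset`` under ``spec`` at ``params``."""
    model = BayesianOutcomeModel(spec, dataset)
    return model.loglike(model.params_to_vector(params))


def log_prior(spec: ModelSpec, params: ModelParams, dataset: TrialDataset | None = None) -> float:
    """Log prior density at ``params`` (normal(0,100) coefficients;
    Gamma(2, 0.1) for sigma/nu/phi, truncated to nu > 1)."""
    if dataset is None:
        # evaluate without data: build the vector in spec order directly
        vals = []
        for name in spec.param_names:
            v = getattr(params, name)
            if v is None:
                raise ValueError(f"params missing {name!r}")
            vals.append(float(v))
        theta = np.array(vals)
        return _logprior_for_spec(spec, theta)
    model = BayesianOutcomeModel(spec, dataset)
    return model.logprior(model.params_to_vector(params))


def _logprior_for_spec(spec: ModelSpec, theta: np.ndarray) -> float:
    k = spec.n_coef
    pri = spec.priors
    lp = float(stats.norm.logpdf(theta[:k], 0.0, pri.coef_scale).sum())
    gam = stats.gamma(pri.positive_shape, scale=1.0 / pri.positive_rate)
    for i, name in enumerate(spec.param_names[k:], start=k):
        x = theta[i]
        if name == "nu":
            if x <= 1:
                raise ValueError("nu must be > 1")
            lp += float(gam.logpdf(x)) - float(np.log(gam.sf(1.0)))
        else:
            if x <= 0:
                raise ValueError(f"{name} must be > 0")
            lp += float(gam.logpdf(x))
    return lp
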