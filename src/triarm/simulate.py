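"""Synthetic three-arm trial generator.

The raw participant data of the motivating study are not public, so every
downstream stage is exercised on synthetic trials drawn from the same
generative structure the models assume:

* pre scores: truncated normal within each scale's bounds;
* familiarity: ordinal draw on 1..5 (default mode at 3, the observed
  median);
* Student-t outcomes: post = linear predictor + sigma * t(nu) noise,
  clipped to the scale bounds (clipping is rare under the default
  configurations);
* the bounded IAT outcome: pre and post live on the squeezed unit
  interval; the mean follows a logit-linear predictor and the draw is
  Beta(phi*mu, phi*(1-mu)), mapped back to the -2..2 scale.

Truth blocks reuse :class:`~triarm.model.ModelParams`, so the generator and
the fitted models share one definition of the linear predictor and the
reference-arm constraint (control main effect and interaction are
structural zeros).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .data import CONDITIONS, OUTCOME_COLUMNS, TrialDataset
from .model import ModelParams, linear_predictor
from .scales import denormalize_bounded, get_scale, normalize_bounded

__all__ = [
    "PreScoreDist",
    "GeneratorConfig",
    "reference_config",
    "null_config",
    "generate_trial",
]


@dataclass(frozen=True)
class PreScoreDist:
    """Truncated-normal pre-score distribution within scale bounds."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("pre-score SD must be > 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to draw one synthetic trial.

    ``truths`` maps each outcome to a :class:`~triarm.model.ModelParams`
    block; the IAT block is on the logit scale of the squeezed unit
    interval (with ``phi``), the others on the raw score scale (with
    ``sigma`` and ``nu``). ``pre_dists`` maps pre columns to truncated
    normals; ``familiarity_probs`` is the distribution over 1..5.
    """

    n_per_arm: Mapping[str, int]
    truths: Mapping[str, ModelParams]
    pre_dists: Mapping[str, PreScoreDist]
    familiarity_probs: tuple[float, float, float, float, float] = (
        0.10,
        0.20,
        0.40,
        0.20,
        0.10,
    )

    def __post_init__(self) -> None:
        if set(self.n_per_arm) != set(CONDITIONS):
            raise ValueError(f"n_per_arm must have exactly the arms {CONDITIONS}")
        for arm, n in self.n_per_arm.items():
            if n < 2:
                raise ValueError(f"n_per_arm[{arm!r}] must be >= 2")
        if set(self.truths) != set(OUTCOME_COLUMNS):
            raise ValueError(f"truths must cover exactly the outcomes {list(OUTCOME_COLUMNS)}")
        for outcome, t in self.truths.items():
            if outcome == "postIAT":
                if t.phi is None or t.phi <= 0:
                    raise ValueError("postIAT truth requires phi > 0")
            else:
                if t.sigma is None or t.sigma <= 0:
                    raise ValueError(f"{outcome} truth requires sigma > 0")
                if t.nu is None or t.nu <= 1:
                    raise ValueError(f"{outcome} truth requires nu > 1")
        probs = np.asarray(self.familiarity_probs, dtype=float)
        if probs.shape != (5,) or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("familiarity_probs must be 5 non-negative values summing to 1")

    @property
    def total_n(self) -> int:
        return sum(self.n_per_arm.values())

    def with_truth(self, outcome: str, **changes) -> "GeneratorConfig":
        """Copy of the config with one outcome's truth block modified."""
        truths = dict(self.truths)
        truths[outcome] = replace(truths[outcome], **changes)
        return replace(self, truths=truths)

    def with_n_per_arm(self, n: int | Mapping[str, int]) -> "GeneratorConfig":
        if isinstance(n, int):
            n = {c: n for c in CONDITIONS}
        return replace(self, n_per_arm=dict(n))


def reference_config() -> GeneratorConfig:
    """Default study conditions: arm sizes 15 (control) / 14 (multiple) /
    16 (single), pre-score distributions and truth coefficients loosely
    matched to the motivating trial's descriptives and posterior means.
    """
    truths = {
        # logit scale of the squeezed [0,1] IAT; control slope near zero,
        # positive interactions for the treated arms
        "postIAT": ModelParams(
            mu=-0.10,
            alpha_multiple=-0.20,
            alpha_single=-0.30,
            beta=0.0,
            gamma_multiple=1.2,
            gamma_single=1.5,
            phi=10.0,
        ),
        # positive control slope; both treated arms have reduced slopes so
        # high-anxiety (high pre) participants improve, while change means
        # near the pre-score centre stay close to the observed descriptives
        "postPRCA24": ModelParams(
            mu=8.4,
            alpha_multiple=5.6,
            alpha_single=8.2,
            beta=0.95,
            gamma_multiple=-0.15,
            gamma_single=-0.11,
            sigma=8.0,
            nu=20.0,
        ),
        "postSPIC": ModelParams(
            mu=-10.2,
            alpha_multiple=47.78,
            alpha_single=26.29,
            beta=1.0,
            gamma_multiple=-0.67,
            gamma_single=-0.33,
            beta_fam=1.0,
            sigma=9.0,
            nu=20.0,
        ),
        "afterSPIC": ModelParams(
            mu=-16.2,
            alpha_multiple=68.06,
            alpha_single=51.42,
            beta=1.0,
            gamma_multiple=-1.02,
            gamma_single=-0.52,
            beta_fam=1.5,
            sigma=11.0,
            nu=20.0,
        ),
        "postSTAI": ModelParams(
            mu=19.7,
            alpha_multiple=0.1,
            alpha_single=2.6,
            beta_fam=0.3,
            sigma=4.5,
            nu=20.0,
        ),
    }
    pre_dists = {
        "preIAT": PreScoreDist(0.0, 0.6),
        "prePRCA24": PreScoreDist(70.0, 15.0),
        "preSPIC": PreScoreDist(55.0, 14.0),
    }
    return GeneratorConfig(
        n_per_arm={"control": 15, "multiple": 14, "single": 16},
        truths=truths,
        pre_dists=pre_dists,
    )


def null_config() -> GeneratorConfig:
    """No-effect baseline: all arm effects and interactions zero, unit
    pre->post slope, no familiarity effect, intercepts centred so the
    post-score mean matches the pre anchor (STAI at its scale midpoint).
    Used for calibration checks."""
    cfg = reference_config()
    truths = {
        # logit-scale intercept offsets the unit slope so the mean at the
        # midpoint covariate (u = 0.5) is exactly 0.5 (no systematic change)
        "postIAT": ModelParams(
            mu=-0.5,
            beta=1.0,
            phi=10.0,
        ),
        "postPRCA24": ModelParams(mu=0.0, beta=1.0, sigma=8.0, nu=20.0),
        "postSPIC": ModelParams(mu=0.0, beta=1.0, beta_fam=0.0, sigma=9.0, nu=20.0),
        "afterSPIC": ModelParams(mu=0.0, beta=1.0, beta_fam=0.0, sigma=11.0, nu=20.0),
        "postSTAI": ModelParams(mu=20.0, beta_fam=0.0, sigma=4.5, nu=20.0),
    }
    return replace(cfg, truths=truths)


def _truncnorm(rng: np.random.Generator, dist: PreScoreDist, lo: float, hi: float, size: int):
    a = (lo - dist.mean) / dist.sd
    b = (hi - dist.mean) / dist.sd
    return stats.truncnorm.rvs(a, b, loc=dist.mean, scale=dist.sd, size=size, random_state=rng)


def generate_trial(config: GeneratorConfig, seed: int | None = None) -> TrialDataset:
    """Draw one synthetic trial; identical seeds give identical datasets.

    Score draws respect their scale bounds: pre scores are truncated
    draws, Student-t post scores are clipped, and Beta draws are strictly
    interior before being mapped back to the raw scale.
    """
    rng = np.random.default_rng(seed)
    n_total = config.total_n

    conditions = np.repeat(
        [c for c in CONDITIONS], [config.n_per_arm[c] for c in CONDITIONS]
    )
    familiarity = rng.choice(
        np.arange(1, 6), size=n_total, p=np.asarray(config.familiarity_probs, dtype=float)
    )

    pre: dict[str, np.ndarray] = {}
    for pre_col, dist in config.pre_dists.items():
        scale = get_scale({"preIAT": "IAT", "prePRCA24": "PRCA24", "preSPIC": "SPIC"}[pre_col])
        pre[pre_col] = _truncnorm(rng, dist, scale.xmin, scale.xmax, n_total)

    frame = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:03d}" for i in range(n_total)],
            "condition": conditions,
            **{k: v for k, v in pre.items()},
            "familiarity": familiarity.astype(int),
        }
    )

    for outcome, (scale_name, pre_col) in OUTCOME_COLUMNS.items():
        scale = get_scale(scale_name)
        truth = config.truths[outcome]
        eta = np.empty(n_total)
        for i in range(n_total):
            c = None
            if pre_col is not None and truth.beta is not None:
                c = pre[pre_col][i]
                if outcome == "postIAT":
                    c = normalize_bounded(c, scale, n_total)
            f = float(familiarity[i]) if truth.beta_fam is not None else None
            eta[i] = linear_predictor(truth, conditions[i], c, f)
        if outcome == "postIAT":
            mu = 1.0 / (1.0 + np.exp(-eta))
            u = rng.beta(truth.phi * mu, truth.phi * (1.0 - mu))
            y = denormalize_bounded(u, scale, n_total)
        else:
            y = eta + truth.sigma * rng.standard_t(truth.nu, size=n_total)
        frame[outcome] = np.clip(y, scale.xmin, scale.xmax)

    col_order = [
        "participant_id",
        "condition",
        "preIAT",
        "postIAT",
        "prePRCA24",
        "postPRCA24",
        "preSPIC",
        "postSPIC",
        "afterSPIC",
        "postSTAI",
        "familiarity",
    ]
    return TrialDataset(frame[col_order].reset_index(drop=True))
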