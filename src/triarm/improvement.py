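"""Posterior probabilities of improvement, odds between arms, slopes.

The headline quantity is the posterior probability of improvement at a
conditioning anchor ``x`` of the pre-score scale:

    P(post mean > x | pre = x, data)   for "increase" scales,
    P(post mean < x | pre = x, data)   for "decrease" scales (PRCA-24),

computed over the posterior of the conditional mean (the linear predictor
pushed through the link), with familiarity held at its median of 3 where
the model uses it. The STAI outcome has no pre covariate, so its
probabilities are unconditional: P(mean > anchor).

The posterior-predictive variant — adding observation noise to each draw —
is available behind ``predictive=True`` but is off by default: the target
of inference is the modelled mean, not a single future participant.

Odds of improvement between two arms are plain ratios of their improvement
probabilities at the same anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data import CONDITIONS
from .model import likelihood_mean
from .results import OutcomeResults
from .scales import anchor_values, denormalize_bounded, normalize_bounded

__all__ = [
    "conditional_mu_draws",
    "prob_improvement",
    "odds_of_improvement",
    "display_odds",
    "slope_exceedance",
    "ImprovementReport",
    "build_report",
]

_ANCHOR_LABELS = ("lowest", "middle", "highest")

#: which anchors each outcome's improvement probability is reported at
_REPORTED_ANCHORS = {
    "postIAT": ("lowest", "middle"),
    "postPRCA24": ("middle", "highest"),
    "postSPIC": ("lowest", "middle"),
    "afterSPIC": ("lowest", "middle"),
    "postSTAI": ("lowest", "middle"),
}


def conditional_mu_draws(
    results: OutcomeResults,
    condition: str,
    pre_value: float | None = None,
    familiarity: float = 3.0,
    predictive: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Posterior draws of the outcome-scale conditional mean.

    For each posterior draw the linear predictor is evaluated at the given
    condition, pre score and familiarity, mapped through the link, and —
    for the Beta-modelled IAT — mapped back to the original score scale by
    the exact inverse of the normalization.

    ``pre_value`` is required iff the model has a pre covariate and must
    lie within the covariate's scale. With ``predictive=True`` the draws
    include observation noise (Student-t or Beta) instead of being the
    posterior of the mean.
    """
    model = results.model
    spec = model.spec
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if spec.covariate is None:
        if pre_value is not None:
            raise ValueError(f"{spec.outcome} has no pre covariate; pre_value not accepted")
    else:
        if pre_value is None:
            raise ValueError(f"{spec.outcome} requires a pre_value")
        if not model.scale.contains(pre_value):
            raise ValueError(
                f"pre_value {pre_value} outside scale bounds "
                f"[{model.scale.xmin}, {model.scale.xmax}]"
            )
    if spec.uses_familiarity and not (1.0 <= familiarity <= 5.0):
        raise ValueError("familiarity must lie in 1..5")

    flat = results.draws.flat()
    names = results.draws.param_names
    col = {n: flat[:, j] for j, n in enumerate(names)}

    eta = col["mu"].copy()
    if condition != "control":
        eta += col[f"alpha_{condition}"]
    if spec.covariate is not None:
        c = pre_value
        if spec.likelihood == "beta_logit":
            c = normalize_bounded(pre_value, model.scale, model.n_obs_squeeze)
        slope = col["beta"].copy()
        if condition != "control":
            slope += col[f"gamma_{condition}"]
        eta += slope * c
    if spec.uses_familiarity:
        eta += col["beta_fam"] * familiarity

    mu = likelihood_mean(spec, eta)

    if predictive:
        if rng is None:
            rng = np.random.default_rng()
        if spec.likelihood == "student_t":
            mu = mu + col["sigma"] * rng.standard_t(col["nu"])
        elif spec.likelihood == "normal":
            mu = mu + col["sigma"] * rng.standard_normal(len(mu))
        else:
            phi = col["phi"]
            mu = rng.beta(phi * mu, phi * (1.0 - mu))

    if spec.likelihood == "beta_logit":
        mu = denormalize_bounded(mu, model.scale, model.n_obs_squeeze)
    return np.asarray(mu)


def prob_improvement(mu_draws: np.ndarray, anchor: float, direction: str) -> float:
    """Fraction of draws strictly beyond ``anchor`` in the improvement
    direction ("increase" => above; "decrease" => below)."""
    mu_draws = np.asarray(mu_draws, dtype=float)
    if mu_draws.size == 0:
        raise ValueError("empty draw sample")
    if direction == "increase":
        return float(np.mean(mu_draws > anchor))
    if direction == "decrease":
        return float(np.mean(mu_draws < anchor))
    raise ValueError(f"unknown improvement direction {direction!r}")


def odds_of_improvement(p_a: float, p_b: float) -> float:
    """Ratio p_a / p_b of two improvement probabilities.

    A zero denominator yields ``inf`` (infinite odds), never an exception.
    """
    if not (0.0 <= p_a <= 1.0 and 0.0 <= p_b <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    if p_b == 0.0:
        return float("inf")
    return p_a / p_b


def display_odds(odds: float) -> str:
    """Round an odds ratio for display: integers at >= 10, one decimal
    below (banker's rounding); infinite odds shown as 'inf'."""
    if np.isinf(odds):
        return "inf"
    if odds >= 10.0:
        return f"{int(np.round(odds)):d}"
    return f"{np.round(odds, 1):.1f}"


def slope_exceedance(results: OutcomeResults, condition: str, threshold: float = 1.0) -> float:
    """Posterior probability that the arm's pre->post slope exceeds
    ``threshold``: P(beta + gamma_j > t), with gamma_control = 0."""
    if results.spec.covariate is None:
        raise ValueError(f"{results.outcome} has no pre covariate; no slope defined")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    slope = results.draws.get("beta").copy()
    if condition != "control":
        slope += results.draws.get(f"gamma_{condition}")
    return float(np.mean(slope > threshold))


@dataclass
class ImprovementReport:
    """Improvement probabilities, between-arm odds and slope probabilities
    for all fitted outcomes at the conditioning anchors.

    Attributes
    ----------
    probabilities : DataFrame
        Columns outcome, condition, anchor, anchor_value, direction,
        probability.
    odds : DataFrame
        Columns outcome, anchor, numerator, denominator, odds,
        odds_display (raw ratio always retained).
    slopes : DataFrame
        Columns outcome, condition, threshold, probability (covariate
        models only).
    familiarity : float
        Conditioning value of the familiarity covariate.
    """

    probabilities: pd.DataFrame
    odds: pd.DataFrame
    slopes: pd.DataFrame
    familiarity: float = 3.0

    def probability(self, outcome: str, condition: str, anchor: str) -> float:
        m = self.probabilities
        row = m[
            (m.outcome == outcome) & (m.condition == condition) & (m.anchor == anchor)
        ]
        if row.empty:
            raise KeyError(f"no probability for ({outcome}, {condition}, {anchor})")
        return float(row.probability.iloc[0])

    def to_csv(self, directory: str | Path, prefix: str = "improvement") -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, frame in [
            ("probabilities", self.probabilities),
            ("odds", self.odds),
            ("slopes", self.slopes),
        ]:
            p = directory / f"{prefix}_{name}.csv"
            frame.to_csv(p, index=False)
            paths.append(p)
        return paths

    def format_table(self) -> str:
        """Human-readable grid: one block per outcome, arms as rows and
        reported anchors as columns."""
        lines = []
        for outcome, grp in self.probabilities.groupby("outcome", sort=False):
            anchors = grp.drop_duplicates("anchor")
            header = "  ".join(
                f"{a.anchor}({a.anchor_value:g},{'<' if a.direction == 'decrease' else '>'})"
                for a in anchors.itertuples()
            )
            lines.append(f"{outcome}:  {header}")
            for cond in CONDITIONS:
                vals = grp[grp.condition == cond]
                cells = "  ".join(f"{v:.3f}" for v in vals.probability)
                lines.append(f"  {cond:<9s} {cells}")
        return "\n".join(lines)


def build_report(
    fits: Mapping[str, OutcomeResults],
    familiarity: float = 3.0,
    slope_thresholds: tuple[float, ...] = (0.0, 1.0),
) -> ImprovementReport:
    """Assemble the full improvement report from per-outcome fits.

    ``fits`` must contain all five outcomes (postIAT, postPRCA24, postSPIC,
    afterSPIC, postSTAI); a missing outcome is reported by name. Reported
    anchors follow each scale's improvement direction: PRCA-24 (decrease)
    at middle/highest, all others (increase) at lowest/middle, STAI
    unconditional.
    """
    missing = [o for o in _REPORTED_ANCHORS if o not in fits]
    if missing:
        raise KeyError(f"missing outcome fit(s): {missing}")

    prob_rows, odds_rows, slope_rows = [], [], []
    for outcome, anchor_labels in _REPORTED_ANCHORS.items():
        res = fits[outcome]
        scale = res.model.scale
        anchors = dict(zip(_ANCHOR_LABELS, anchor_values(scale)))
        direction = scale.improvement_direction
        for label in anchor_labels:
            x = anchors[label]
            probs = {}
            for cond in CONDITIONS:
                pre = None if res.spec.covariate is None else x
                mu = conditional_mu_draws(
                    res, cond, pre_value=pre, familiarity=familiarity
                )
                p = prob_improvement(mu, x, direction)
                probs[cond] = p
                prob_rows.append(
                    {
                        "outcome": outcome,
                        "condition": cond,
                        "anchor": label,
                        "anchor_value": x,
                        "direction": direction,
                        "probability": p,
                    }
                )
            for num, den in [
                ("multiple", "control"),
                ("single", "control"),
                ("single", "multiple"),
            ]:
                o = odds_of_improvement(probs[num], probs[den])
                odds_rows.append(
                    {
                        "outcome": outcome,
                        "anchor": label,
                        "numerator": num,
                        "denominator": den,
                        "odds": o,
                        "odds_display": display_odds(o),
                    }
                )
        if res.spec.covariate is not None:
            for t in slope_thresholds:
                for cond in CONDITIONS:
                    slope_rows.append(
                        {
                            "outcome": outcome,
                            "condition": cond,
                            "threshold": t,
                            "probability": slope_exceedance(res, cond, t),
                        }
                    )
    return ImprovementReport(
        probabilities=pd.DataFrame(prob_rows),
        odds=pd.DataFrame(odds_rows),
        slopes=pd.DataFrame(slope_rows),
        familiarity=familiarity,
    )
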