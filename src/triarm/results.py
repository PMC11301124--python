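"""Fit results: posterior summaries, convergence state, derived quantities."""

from __future__ import annotations

from functools import cached_property

import numpy as np
import pandas as pd

from .inference import PosteriorDraws
from .model import BayesianOutcomeModel

__all__ = ["OutcomeResults"]


class OutcomeResults:
    """Posterior of one outcome model.

    Wraps the model and its :class:`~triarm.inference.PosteriorDraws`;
    exposes the summary table, convergence diagnostics and the derived
    quantities of interest (conditional means at covariate anchors,
    improvement probabilities, slope-exceedance probabilities).
    """

    #: operational convergence gate on split-Rhat
    RHAT_GATE = 1.01

    def __init__(self, model: BayesianOutcomeModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    @property
    def spec(self):
        return self.model.spec

    @property
    def outcome(self) -> str:
        return self.model.spec.outcome

    @cached_property
    def rhat(self) -> dict[str, float]:
        return self.draws.rhat()

    @property
    def converged(self) -> bool:
        return all(v <= self.RHAT_GATE for v in self.rhat.values())

    def raise_for_convergence(self) -> None:
        if not self.converged:
            bad = {k: round(v, 4) for k, v in self.rhat.items() if v > self.RHAT_GATE}
            raise RuntimeError(
                f"fit of {self.outcome} failed the Rhat<{self.RHAT_GATE} gate: {bad}"
            )

    @cached_property
    def params_mean(self) -> dict[str, float]:
        flat = self.draws.flat()
        return {n: float(flat[:, j].mean()) for j, n in enumerate(self.draws.param_names)}

    @cached_property
    def params_sd(self) -> dict[str, float]:
        flat = self.draws.flat()
        return {n: float(flat[:, j].std(ddof=1)) for j, n in enumerate(self.draws.param_names)}

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        x = self.draws.get(name)
        a = (1.0 - level) / 2.0
        return (float(np.quantile(x, a)), float(np.quantile(x, 1.0 - a)))

    def summary(self) -> pd.DataFrame:
        """Per-parameter posterior mean, SD, 2.5%/97.5% quantiles, Rhat."""
        return self.draws.summary()

    # -- derived quantities (delegated to triarm.improvement) --------------
    def conditional_mean_draws(
        self,
        condition: str,
        pre_value: float | None = None,
        familiarity: float = 3.0,
        predictive: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        from .improvement import conditional_mu_draws

        return conditional_mu_draws(
            self,
            condition,
            pre_value=pre_value,
            familiarity=familiarity,
            predictive=predictive,
            rng=rng,
        )

    def prob_improvement(
        self, condition: str, anchor: float, familiarity: float = 3.0
    ) -> float:
        from .improvement import prob_improvement

        pre = None if self.spec.covariate is None else anchor
        mu = self.conditional_mean_draws(condition, pre_value=pre, familiarity=familiarity)
        return prob_improvement(mu, anchor, self.model.scale.improvement_direction)

    def slope_exceedance(self, condition: str, threshold: float = 1.0) -> float:
        from .improvement import slope_exceedance

        return slope_exceedance(self, condition, threshold)

    def __repr__(self) -> str:
        return (
            f"<OutcomeResults {self.outcome} ({self.spec.likelihood}), "
            f"{self.draws.n_chains} chains x {self.draws.n_draws} draws, "
            f"converged={self.converged}>"
        )
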