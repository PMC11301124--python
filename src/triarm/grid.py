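"""Brute-force grid posterior for reduced models.

An independent check on the MCMC machinery: restrict a model to at most
three free parameters (fixing the rest), evaluate the unnormalized log
posterior on a dense tensor grid, normalize by the trapezoid rule, and
read off marginal means and quantiles. Tractable only for tiny models, by
design — it shares no code path with the samplers beyond the log density.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .model import BayesianOutcomeModel

__all__ = ["GridPosterior", "grid_posterior"]

_EDGE_MASS_TOL = 1e-3


class GridCoverageWarning(UserWarning):
    pass


@dataclass
class GridPosterior:
    """Normalized posterior density on a tensor grid.

    ``density`` integrates to 1 over the grid by the trapezoid rule;
    ``free_names`` orders the grid axes.
    """

    free_names: tuple[str, ...]
    axes: tuple[np.ndarray, ...]
    density: np.ndarray
    fixed: dict[str, float]
    edge_mass: float

    @property
    def covered(self) -> bool:
        """Whether the grid captured essentially all posterior mass
        (boundary slices carry < 0.1% of it)."""
        return self.edge_mass < _EDGE_MASS_TOL

    def _axis(self, name: str) -> int:
        return self.free_names.index(name)

    def marginal(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(grid, density) of one parameter, other axes integrated out."""
        i = self._axis(name)
        dens = self.density
        for j in reversed(range(len(self.free_names))):
            if j != i:
                dens = np.trapezoid(dens, self.axes[j], axis=j)
        return self.axes[i], dens

    def marginal_mean(self, name: str) -> float:
        x, d = self.marginal(name)
        return float(np.trapezoid(x * d, x))

    def marginal_sd(self, name: str) -> float:
        x, d = self.marginal(name)
        m = np.trapezoid(x * d, x)
        return float(np.sqrt(np.trapezoid((x - m) ** 2 * d, x)))

    def marginal_quantile(self, name: str, q: float) -> float:
        x, d = self.marginal(name)
        cdf = np.concatenate([[0.0], np.cumsum(np.diff(x) * (d[1:] + d[:-1]) / 2.0)])
        cdf /= cdf[-1]
        return float(np.interp(q, cdf, x))


def grid_posterior(
    model: BayesianOutcomeModel,
    free: Mapping[str, np.ndarray],
    fixed: Mapping[str, float],
) -> GridPosterior:
    """Exhaustive posterior over <= 3 free parameters of a model.

    ``free`` maps parameter names to 1-d grids; ``fixed`` pins every other
    parameter of the model. A warning is issued (and ``covered`` set
    False) when the outermost grid slices hold more than 0.1% of the
    posterior mass, indicating the grid does not span the posterior.
    """
    free_names = tuple(free)
    if len(free_names) > 3:
        raise ValueError("grid oracle is restricted to at most 3 free parameters")
    expected = set(model.param_names)
    given = set(free_names) | set(fixed)
    if given != expected:
        raise ValueError(
            f"free+fixed must cover exactly the model parameters {sorted(expected)}; "
            f"got {sorted(given)}"
        )

    axes = tuple(np.asarray(free[n], dtype=float) for n in free_names)
    shape = tuple(len(a) for a in axes)
    logpost = np.empty(shape)
    template = {n: v for n, v in fixed.items()}
    for idx in itertools.product(*(range(s) for s in shape)):
        point = dict(template)
        for n, a, i in zip(free_names, axes, idx):
            point[n] = float(a[i])
        theta = np.array([point[n] for n in model.param_names])
        logpost[idx] = model.logpost(theta)

    logpost -= logpost.max()
    dens = np.exp(logpost)
    z = dens
    for j in reversed(range(len(axes))):
        z = np.trapezoid(z, axes[j], axis=j)
    dens = dens / z

    edge = 0.0
    for j in range(len(axes)):
        for which in (0, -1):
            sl = [slice(None)] * len(axes)
            sl[j] = which
            slice_dens = dens[tuple(sl)]
            step = abs(
                axes[j][1] - axes[j][0] if which == 0 else axes[j][-1] - axes[j][-2]
            )
            m = slice_dens
            remaining = [axes[k] for k in range(len(axes)) if k != j]
            for ax in reversed(remaining):
                m = np.trapezoid(m, ax, axis=-1)
            edge = max(edge, float(m) * step)

    gp = GridPosterior(free_names, axes, dens, dict(fixed), edge)
    if not gp.covered:
        warnings.warn(
            f"grid boundary slices carry {edge:.2e} posterior mass; widen the grid",
            GridCoverageWarning,
            stacklevel=2,
        )
    return gp
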