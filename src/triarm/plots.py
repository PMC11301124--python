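"""Density plots of the conditional posterior means, one panel per
outcome x anchor, arms overlaid (single / multiple / control)."""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .data import CONDITIONS
from .improvement import _REPORTED_ANCHORS, conditional_mu_draws
from .results import OutcomeResults
from .scales import anchor_values

__all__ = ["plot_conditional_posteriors"]

_ARM_COLORS = {"single": "tab:red", "multiple": "tab:green", "control": "tab:blue"}


def plot_conditional_posteriors(
    fits: Mapping[str, OutcomeResults], familiarity: float = 3.0
):
    """Overlaid posterior densities of the conditional means at each
    reported anchor; returns the matplotlib Figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    outcomes = [o for o in _REPORTED_ANCHORS if o in fits]
    ncols = max(len(_REPORTED_ANCHORS[o]) for o in outcomes)
    fig, axes = plt.subplots(
        len(outcomes), ncols, figsize=(4.0 * ncols, 2.4 * len(outcomes)), squeeze=False
    )
    labels = ("lowest", "middle", "highest")
    for r, outcome in enumerate(outcomes):
        res = fits[outcome]
        anchors = dict(zip(labels, anchor_values(res.model.scale)))
        for c, label in enumerate(_REPORTED_ANCHORS[outcome]):
            ax = axes[r][c]
            x = anchors[label]
            for cond in CONDITIONS:
                pre = None if res.spec.covariate is None else x
                mu = conditional_mu_draws(
                    res, cond, pre_value=pre, familiarity=familiarity
                )
                if np.std(mu) > 0:
                    kde = gaussian_kde(mu)
                    grid = np.linspace(mu.min(), mu.max(), 200)
                    ax.plot(grid, kde(grid), color=_ARM_COLORS[cond], label=cond)
                ax.axvline(x, color="gray", lw=0.8, ls="--")
            ax.set_title(f"{outcome} @ {label} ({x:g})", fontsize=9)
            if r == 0 and c == 0:
                ax.legend(fontsize=7)
        for c in range(len(_REPORTED_ANCHORS[outcome]), ncols):
            axes[r][c].set_visible(False)
    fig.tight_layout()
    return fig
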