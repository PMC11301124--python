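"""Classical effect sizes on pre-post change scores.

Descriptive layer alongside the Bayesian models: paired Cohen's d within
each arm (change-score mean over change-score SD, the d_z convention; the
average-SD variant d_av is available behind an option) and between-arm
Cohen's d on change scores with the pooled-SD denominator. The STAI
outcome has no pre measurement, so its "change" is the raw post score and
only between-arm comparisons are reported.
"""

from __future__ import annotations

import math
import numpy as np
import pandas as pd

from .data import CONDITIONS, OUTCOME_COLUMNS, TrialDataset

__all__ = [
    "cohen_d_paired",
    "cohen_d_between",
    "cohen_d_from_summary",
    "effect_size_table",
]


class DegenerateVarianceError(ValueError):
    """Zero change-score or pooled SD: the effect size is undefined."""


def cohen_d_paired(pre, post, denominator: str = "dz") -> float:
    """Paired Cohen's d for post - pre change.

    ``denominator="dz"`` (default) divides the mean change by the SD of the
    change scores; ``"dav"`` divides by the average of the pre and post
    SDs. Sample SDs use the n-1 denominator.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-d vectors of equal length")
    if len(pre) < 2:
        raise ValueError("need at least 2 pairs")
    diff = post - pre
    if denominator == "dz":
        s = float(np.std(diff, ddof=1))
    elif denominator == "dav":
        s = (float(np.std(pre, ddof=1)) + float(np.std(post, ddof=1))) / 2.0
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if s == 0.0:
        raise DegenerateVarianceError("zero change-score SD; paired d undefined")
    return float(np.mean(diff)) / s


def cohen_d_between(diff_a, diff_b) -> float:
    """Between-group Cohen's d on change scores with pooled SD."""
    a = np.asarray(diff_a, dtype=float)
    b = np.asarray(diff_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    if sp2 == 0.0:
        raise DegenerateVarianceError("zero pooled SD; between-group d undefined")
    return float((np.mean(a) - np.mean(b)) / math.sqrt(sp2))


def cohen_d_from_summary(
    mean_a: float, se_a: float, n_a: int, mean_b: float, se_b: float, n_b: int
) -> float:
    """Between-group Cohen's d reconstructed from group means, standard
    errors and sizes: s = se * sqrt(n) per group, then the pooled-SD d.

    Exact when the summaries are exact; summaries rounded for display
    (e.g. SEs at 2 decimals) propagate their rounding error into d.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    if n_a < 2 or n_b < 2:
        raise ValueError("group sizes must be >= 2")
    sa = se_a * math.sqrt(n_a)
    sb = se_b * math.sqrt(n_b)
    sp2 = ((n_a - 1) * sa**2 + (n_b - 1) * sb**2) / (n_a + n_b - 2)
    if sp2 == 0.0:
        raise DegenerateVarianceError("zero pooled SD")
    return (mean_a - mean_b) / math.sqrt(sp2)


def _change(dataset: TrialDataset, outcome: str, condition: str) -> np.ndarray:
    arm = dataset.arm(condition)
    _, pre_col = OUTCOME_COLUMNS[outcome]
    post = arm[outcome].to_numpy(dtype=float)
    if pre_col is None:
        return post
    return post - arm[pre_col].to_numpy(dtype=float)


def effect_size_table(dataset: TrialDataset, paired_denominator: str = "dz") -> pd.DataFrame:
    """Change-score descriptives and effect sizes per outcome.

    Returns one row per outcome with, for each arm, the change mean,
    its SE and the paired d (where a pre measure exists), plus the three
    pairwise between-arm d values on change scores.
    """
    rows = []
    pairs = [("single", "multiple"), ("single", "control"), ("multiple", "control")]
    for outcome, (_, pre_col) in OUTCOME_COLUMNS.items():
        row: dict[str, float | str] = {"outcome": outcome}
        for cond in CONDITIONS:
            ch = _change(dataset, outcome, cond)
            row[f"{cond}_change_mean"] = float(np.mean(ch))
            row[f"{cond}_change_se"] = float(np.std(ch, ddof=1) / math.sqrt(len(ch)))
            if pre_col is not None:
                arm = dataset.arm(cond)
                row[f"{cond}_paired_d"] = cohen_d_paired(
                    arm[pre_col], arm[outcome], denominator=paired_denominator
                )
            else:
                row[f"{cond}_paired_d"] = float("nan")
        for a, b in pairs:
            row[f"d_{a}_vs_{b}"] = cohen_d_between(
                _change(dataset, outcome, a), _change(dataset, outcome, b)
            )
        rows.append(row)
    return pd.DataFrame(rows)
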