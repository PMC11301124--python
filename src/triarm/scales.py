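"""Questionnaire scale definitions, conditioning anchors, and bounded-score
normalization.

The trial uses four psychometric instruments, each with hard bounds and a
direction in which change counts as improvement:

========  ==========  ==========  =====================================
Scale     Bounds      Improves    Meaning of a high score
========  ==========  ==========  =====================================
IAT       [-2, 2]     increase    automatic self/liked association
PRCA24    [24, 120]   decrease    communication apprehension (anxiety)
SPIC      [15, 105]   increase    perceived competence
STAI      [8, 32]     increase    state comfort (short form, comfort-coded)
========  ==========  ==========  =====================================

Conditioning anchors for the pre-score covariate are 10% of the range above
the minimum, the midpoint, and 10% of the range below the maximum.

Bounded outcomes modelled with a Beta likelihood must lie strictly inside
(0, 1); :func:`normalize_bounded` therefore combines an affine map to the
unit interval with the Smithson-Verkuilen compression
``u' = (u * (n - 1) + 0.5) / n``, which is strictly monotone and pulls
boundary scores into the open interval by an amount that shrinks with the
sample size ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import pandas as pd

__all__ = [
    "ScaleDefinition",
    "builtin_scales",
    "get_scale",
    "anchor_values",
    "normalize_bounded",
    "denormalize_bounded",
    "scale_registry_frame",
]

ImprovementDirection = Literal["increase", "decrease"]


@dataclass(frozen=True)
class ScaleDefinition:
    """A bounded questionnaire scale.

    Parameters
    ----------
    name : str
        Scale label, e.g. ``"PRCA24"``.
    xmin, xmax : float
        Hard bounds of the score. ``xmax`` must exceed ``xmin``.
    improvement_direction : {"increase", "decrease"}
        Direction of beneficial change for a participant.
    """

    name: str
    xmin: float
    xmax: float
    improvement_direction: ImprovementDirection

    def __post_init__(self) -> None:
        if not self.xmax > self.xmin:
            raise ValueError(
                f"scale {self.name!r}: xmax ({self.xmax}) must exceed xmin ({self.xmin})"
            )
        if self.improvement_direction not in ("increase", "decrease"):
            raise ValueError(
                f"scale {self.name!r}: unknown improvement direction "
                f"{self.improvement_direction!r}"
            )

    @property
    def range(self) -> float:
        return self.xmax - self.xmin

    def contains(self, y: float) -> bool:
        return self.xmin <= y <= self.xmax


_BUILTIN = (
    ScaleDefinition("IAT", -2.0, 2.0, "increase"),
    ScaleDefinition("PRCA24", 24.0, 120.0, "decrease"),
    ScaleDefinition("SPIC", 15.0, 105.0, "increase"),
    ScaleDefinition("STAI", 8.0, 32.0, "increase"),
)


def builtin_scales() -> list[ScaleDefinition]:
    """Return the four built-in scales (IAT, PRCA24, SPIC, STAI)."""
    return list(_BUILTIN)


def get_scale(name: str) -> ScaleDefinition:
    """Look up a built-in scale by name (case-insensitive)."""
    for s in _BUILTIN:
        if s.name.lower() == name.lower():
            return s
    raise KeyError(f"no built-in scale named {name!r}")


def anchor_values(scale: ScaleDefinition) -> tuple[float, float, float]:
    """Conditioning anchors (lowest, middle, highest) for a scale.

    With range ``d = xmax - xmin`` these are ``xmin + 0.1 d``,
    ``(xmin + xmax) / 2`` and ``xmax - 0.1 d``.

    Examples
    --------
    >>> anchor_values(get_scale("PRCA24"))
    (33.6, 72.0, 110.4)
    """
    d = scale.range
    if d <= 0:
        raise ValueError(f"degenerate scale {scale.name!r}: zero range")
    return (scale.xmin + 0.1 * d, (scale.xmin + scale.xmax) / 2.0, scale.xmax - 0.1 * d)


def normalize_bounded(y, scale: ScaleDefinition, n_obs: int | None = None):
    """Map a score into the open unit interval for a Beta likelihood.

    First the affine map ``u = (y - xmin) / (xmax - xmin)``, then, if
    ``n_obs`` is given, the boundary squeeze
    ``u' = (u * (n_obs - 1) + 0.5) / n_obs`` so that ``0 < u' < 1`` even for
    boundary scores. Accepts scalars or array-likes.
    """
    import numpy as np

    y = np.asarray(y, dtype=float)
    if np.any(y < scale.xmin) or np.any(y > scale.xmax):
        raise ValueError(
            f"score outside bounds [{scale.xmin}, {scale.xmax}] of scale {scale.name!r}"
        )
    u = (y - scale.xmin) / scale.range
    if n_obs is not None:
        if n_obs < 1:
            raise ValueError("n_obs must be >= 1")
        u = (u * (n_obs - 1) + 0.5) / n_obs
    return u if u.ndim else float(u)


def denormalize_bounded(u, scale: ScaleDefinition, n_obs: int | None = None):
    """Exact inverse of :func:`normalize_bounded`.

    Undoes the squeeze (if ``n_obs`` given), then the affine map. The result
    may fall marginally outside the bounds for ``u`` outside the squeezed
    image; callers that require bounded output should clip.
    """
    import numpy as np

    u = np.asarray(u, dtype=float)
    if n_obs is not None:
        if n_obs < 1:
            raise ValueError("n_obs must be >= 1")
        u = (u * n_obs - 0.5) / (n_obs - 1) if n_obs > 1 else u
    y = scale.xmin + u * scale.range
    return y if y.ndim else float(y)


def scale_registry_frame() -> pd.DataFrame:
    """The built-in scale registry as a DataFrame (exportable as CSV)."""
    return pd.DataFrame(
        [
            {
                "name": s.name,
                "xmin": s.xmin,
                "xmax": s.xmax,
                "improvement_direction": s.improvement_direction,
            }
            for s in _BUILTIN
        ]
    )
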