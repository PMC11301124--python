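"""Per-participant trial records: container, validation, CSV round-trip.

A trial dataset is wide-format, one row per participant, with columns

    participant_id, condition, preIAT, postIAT, prePRCA24, postPRCA24,
    preSPIC, postSPIC, afterSPIC, postSTAI, familiarity

``condition`` is one of ``control``, ``multiple``, ``single`` (control is the
reference arm). ``postSTAI`` has no paired pre measurement. ``familiarity``
is an ordinal covariate on 1..5 (prior familiarity with the speech topic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scales import ScaleDefinition, builtin_scales, get_scale

__all__ = ["CONDITIONS", "OUTCOME_COLUMNS", "TrialDataset", "read_dataset", "write_dataset"]

CONDITIONS = ("control", "multiple", "single")

#: outcome column -> (scale name, paired pre column or None)
OUTCOME_COLUMNS: dict[str, tuple[str, str | None]] = {
    "postIAT": ("IAT", "preIAT"),
    "postPRCA24": ("PRCA24", "prePRCA24"),
    "postSPIC": ("SPIC", "preSPIC"),
    "afterSPIC": ("SPIC", "preSPIC"),
    "postSTAI": ("STAI", None),
}

_SCORE_COLUMNS: dict[str, str] = {
    "preIAT": "IAT",
    "postIAT": "IAT",
    "prePRCA24": "PRCA24",
    "postPRCA24": "PRCA24",
    "preSPIC": "SPIC",
    "postSPIC": "SPIC",
    "afterSPIC": "SPIC",
    "postSTAI": "STAI",
}

REQUIRED_COLUMNS = ("participant_id", "condition", *_SCORE_COLUMNS, "familiarity")


class DatasetValidationError(ValueError):
    """Raised when trial records violate the schema; carries row indices."""


@dataclass
class TrialDataset:
    """Wide-format three-arm trial data.

    Parameters
    ----------
    frame : pandas.DataFrame
        One row per participant with the required columns.
    validate : bool
        Validate on construction (default True).
    """

    frame: pd.DataFrame
    validate: bool = True
    scales: dict[str, ScaleDefinition] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.scales:
            self.scales = {s.name: s for s in builtin_scales()}
        if self.validate:
            self._validate()

    def _validate(self) -> None:
        errors: list[str] = []
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DatasetValidationError(f"missing required column(s): {missing}")
        bad_cond = ~self.frame["condition"].isin(CONDITIONS)
        for idx in self.frame.index[bad_cond]:
            errors.append(
                f"row {idx}: unknown condition {self.frame.at[idx, 'condition']!r} "
                f"(expected one of {CONDITIONS})"
            )
        for col, scale_name in _SCORE_COLUMNS.items():
            scale = self.scales[scale_name]
            vals = pd.to_numeric(self.frame[col], errors="coerce")
            out = vals.notna() & ((vals < scale.xmin) | (vals > scale.xmax))
            for idx in self.frame.index[out]:
                errors.append(
                    f"row {idx}: {col}={vals[idx]} outside "
                    f"[{scale.xmin}, {scale.xmax}] for scale {scale_name}"
                )
        fam = pd.to_numeric(self.frame["familiarity"], errors="coerce")
        bad_fam = fam.isna() | (fam < 1) | (fam > 5) | (fam != fam.round())
        for idx in self.frame.index[bad_fam]:
            errors.append(f"row {idx}: familiarity={self.frame.at[idx, 'familiarity']!r} not in 1..5")
        if errors:
            raise DatasetValidationError("; ".join(errors))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_per_arm(self) -> dict[str, int]:
        counts = self.frame["condition"].value_counts()
        return {c: int(counts.get(c, 0)) for c in CONDITIONS}

    def arm(self, condition: str) -> pd.DataFrame:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return self.frame[self.frame["condition"] == condition]

    def outcome_arrays(self, outcome: str) -> dict[str, np.ndarray]:
        """Response, paired pre covariate (if any), condition and familiarity
        arrays for one outcome column."""
        if outcome not in OUTCOME_COLUMNS:
            raise KeyError(f"unknown outcome {outcome!r}")
        _, pre_col = OUTCOME_COLUMNS[outcome]
        out = {
            "y": self.frame[outcome].to_numpy(dtype=float),
            "condition": self.frame["condition"].to_numpy(),
            "familiarity": self.frame["familiarity"].to_numpy(dtype=float),
        }
        if pre_col is not None:
            out["pre"] = self.frame[pre_col].to_numpy(dtype=float)
        return out

    def scale_for(self, outcome: str) -> ScaleDefinition:
        return get_scale(OUTCOME_COLUMNS[outcome][0])


def write_dataset(dataset: TrialDataset, path: str | Path) -> None:
    """Write a trial dataset as UTF-8 CSV with header."""
    cols = [c for c in REQUIRED_COLUMNS if c in dataset.frame.columns]
    extra = [c for c in dataset.frame.columns if c not in cols]
    dataset.frame[cols + extra].to_csv(path, index=False)


def read_dataset(path: str | Path, validate: bool = True) -> TrialDataset:
    """Read a CSV trial dataset, validating schema and scale bounds.

    Raises
    ------
    DatasetValidationError
        Missing column, unknown condition label, or out-of-range score;
        the message names the offending row index.
    """
    frame = pd.read_csv(path)
    frame["condition"] = frame["condition"].astype(str)
    return TrialDataset(frame, validate=validate)
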