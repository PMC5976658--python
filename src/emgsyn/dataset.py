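"""Container for single-trial EMG activation data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns expected in a label table, in canonical order.
LABEL_COLUMNS = (
    "trial_id",
    "movement_id",
    "start_target",
    "start_bar",
    "start_height",
    "direction",
    "horizontal_direction",
    "vertical_direction",
    "end_bar",
    "end_height",
    "end_target",
)


@dataclass
class EMGDataset:
    """L single-trial activation matrices of shape T x M with task labels.

    Parameters
    ----------
    trials
        Array of shape (L, T, M); entries must be finite and >= 0.
    labels
        Per-trial label table aligned with ``trials`` (row l describes
        trial l).  Must contain at least ``trial_id`` and ``movement_id``.
    """

    trials: np.ndarray
    labels: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        if self.trials.ndim != 3:
            raise ValueError(
                f"trials must be a (L, T, M) array, got shape {self.trials.shape}"
            )
        if not np.all(np.isfinite(self.trials)):
            raise ValueError("trials contain non-finite entries")
        if np.any(self.trials < 0):
            raise ValueError("trials contain negative entries")
        if len(self.labels) != self.trials.shape[0]:
            raise ValueError(
                f"label table has {len(self.labels)} rows for "
                f"{self.trials.shape[0]} trials"
            )
        for col in ("trial_id", "movement_id"):
            if col not in self.labels.columns:
                raise ValueError(f"label table is missing column {col!r}")
        self.labels = self.labels.reset_index(drop=True)

    @property
    def L(self) -> int:
        return self.trials.shape[0]

    @property
    def T(self) -> int:
        return self.trials.shape[1]

    @property
    def M(self) -> int:
        return self.trials.shape[2]

    def label_values(self, parameter: str) -> np.ndarray:
        """Return the per-trial values of one task parameter."""
        if parameter not in self.labels.columns:
            raise KeyError(f"unknown task parameter {parameter!r}")
        return self.labels[parameter].to_numpy()
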