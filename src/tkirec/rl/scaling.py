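"""Feature standardization for the Q-network state space."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FeatureScaler:
    """Per-feature mean/sd fitted on the training table.

    Zero-variance columns are dropped (and recorded) rather than divided by
    zero; the training min/max per feature is kept so that inference on
    values far outside the training range can warn instead of failing.
    """

    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray
    feature_min: np.ndarray
    feature_max: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def transform(self, table: pd.DataFrame, warn_out_of_range: bool = False) -> np.ndarray:
        missing = [c for c in self.columns if c not in table.columns]
        if missing:
            raise ValueError(f"missing features: {', '.join(missing)}")
        x = table[self.columns].to_numpy(dtype=float)
        if warn_out_of_range:
            low = x < self.feature_min
            high = x > self.feature_max
            if low.any() or high.any():
                cols = [self.columns[j] for j in np.unique(np.nonzero(low | high)[1])]
                warnings.warn(
                    f"features outside the training range: {', '.join(cols)}; "
                    "Q-values are extrapolations",
                    stacklevel=2,
                )
        return (x - self.mean) / self.sd

    def transform_value(self, column: str, value: float) -> float:
        """Standardize a single raw value of one feature."""
        try:
            j = self.columns.index(column)
        except ValueError:
            raise ValueError(f"unknown feature {column!r}") from None
        return (float(value) - self.mean[j]) / self.sd[j]

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "feature_min": self.feature_min.tolist(),
            "feature_max": self.feature_max.tolist(),
            "dropped": list(self.dropped),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FeatureScaler":
        return cls(
            columns=list(payload["columns"]),
            mean=np.asarray(payload["mean"], dtype=float),
            sd=np.asarray(payload["sd"], dtype=float),
            feature_min=np.asarray(payload["feature_min"], dtype=float),
            feature_max=np.asarray(payload["feature_max"], dtype=float),
            dropped=list(payload["dropped"]),
        )


def standardize(table: pd.DataFrame) -> tuple[np.ndarray, FeatureScaler]:
    """Center and scale every column to mean 0, sd 1 over the table.

    Returns the standardized state matrix and the fitted scaler; columns with
    zero variance are dropped from the matrix and listed in
    ``scaler.dropped``.
    """
    x = table.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = [c for c, k in zip(table.columns, keep) if not k]
    columns = [c for c, k in zip(table.columns, keep) if k]
    x = x[:, keep]
    scaler = FeatureScaler(
        columns=columns,
        mean=x.mean(axis=0),
        sd=sd[keep],
        feature_min=x.min(axis=0),
        feature_max=x.max(axis=0),
        dropped=dropped,
    )
    return (x - scaler.mean) / scaler.sd, scaler
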