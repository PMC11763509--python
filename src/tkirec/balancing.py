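"""Class balancing by SMOTE and the stratified modelling split.

The one-year progression endpoint is imbalanced in TKI cohorts (roughly 60/40
toward early progression), so the minority class is oversampled with SMOTE:
each synthetic observation is drawn on the segment between a minority sample
and one of its k nearest minority neighbours,

    x_new = x_i + u * (x_nn - x_i),  u ~ Uniform(0, 1),

with neighbours found by Euclidean distance on standardized features.
Original rows pass through bit-identically; only the minority class gains
rows, exactly enough to equalize the class counts.  Binary (0/1) columns are
rounded back to the nearest level after interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    seed: int = 0
    target: str = "balance"
    #: Columns snapped back to the nearest level after interpolation; None
    #: infers all 0/1-valued columns, [] disables rounding entirely.
    categorical_columns: list[str] | None = None

    def validate(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target != "balance":
            raise ValueError(f"unsupported SMOTE target {self.target!r}")


def _binary_columns(features: pd.DataFrame) -> list[str]:
    out = []
    for col in features.columns:
        values = pd.unique(features[col].dropna())
        if len(values) <= 2 and set(np.asarray(values, dtype=float)) <= {0.0, 1.0}:
            out.append(col)
    return out


def smote_balance(
    features: pd.DataFrame,
    labels,
    cfg: SmoteConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Equalize binary class counts by synthesizing minority samples.

    Returns the balanced feature table (original rows first, unchanged),
    the balanced label series, and the number of synthetic rows created
    (= majority count - minority count).
    """
    cfg = cfg or SmoteConfig()
    cfg.validate()
    labels = pd.Series(np.asarray(labels), index=features.index, name="label")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"SMOTE requires exactly 2 classes, got {len(classes)}")

    minority, majority = classes[np.argmin(counts)], classes[np.argmax(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_synthetic = int(n_maj - n_min)
    if n_synthetic == 0:
        return features.copy(), labels.copy(), 0
    if n_min <= cfg.k_neighbors:
        raise ValueError(
            f"minority class has {n_min} samples, not more than k_neighbors="
            f"{cfg.k_neighbors}; lower k_neighbors"
        )

    x = features.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    minority_idx = np.flatnonzero(labels.to_numpy() == minority)
    z_min = z[minority_idx]

    nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(z_min)
    neighbors = nn.kneighbors(z_min, return_distance=False)[:, 1:]  # drop self

    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, len(minority_idx), size=n_synthetic)
    pick = rng.integers(0, cfg.k_neighbors, size=n_synthetic)
    u = rng.random(n_synthetic)

    x_min = x[minority_idx]
    x_base = x_min[base]
    x_nn = x_min[neighbors[base, pick]]
    synthetic = x_base + u[:, None] * (x_nn - x_base)

    synth_df = pd.DataFrame(synthetic, columns=features.columns)
    categorical = (
        cfg.categorical_columns if cfg.categorical_columns is not None else _binary_columns(features)
    )
    for col in categorical:
        levels = np.sort(pd.unique(features[col].dropna()).astype(float))
        nearest = np.abs(synth_df[col].to_numpy()[:, None] - levels[None, :]).argmin(axis=1)
        synth_df[col] = levels[nearest]
    synth_df.index = pd.RangeIndex(len(features), len(features) + n_synthetic)

    balanced = pd.concat([features, synth_df])
    balanced_labels = pd.concat(
        [labels, pd.Series([minority] * n_synthetic, index=synth_df.index, name="label")]
    )
    return balanced, balanced_labels, n_synthetic


def train_eval_split(
    table: pd.DataFrame,
    train_fraction: float,
    seed: int = 0,
    stratify_column: str | None = "progression_category",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/holdout split with |train| = round(f * n).

    The split is stratified by ``stratify_column`` when present, with
    per-stratum sizes set by largest remainder so the total training size is
    exactly the rounded target.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = len(table)
    target = int(np.floor(train_fraction * n + 0.5))
    rng = np.random.default_rng(seed)

    if stratify_column is None or stratify_column not in table.columns:
        order = rng.permutation(n)
        train_pos = np.sort(order[:target])
    else:
        groups = table.groupby(stratify_column, sort=True).indices
        quotas = {k: train_fraction * len(v) for k, v in groups.items()}
        floors = {k: int(np.floor(q)) for k, q in quotas.items()}
        shortfall = target - sum(floors.values())
        by_remainder = sorted(groups, key=lambda k: quotas[k] - floors[k], reverse=True)
        for k in by_remainder[:shortfall]:
            floors[k] += 1
        train_pos = []
        for k, idx in groups.items():
            take = min(floors[k], len(idx))
            if take == 0 or take == len(idx):
                warnings.warn(
                    f"stratum {k!r} too small to appear in both train and holdout",
                    stacklevel=2,
                )
            shuffled = rng.permutation(np.asarray(idx))
            train_pos.extend(shuffled[:take])
        train_pos = np.sort(np.asarray(train_pos, dtype=int))

    mask = np.zeros(n, dtype=bool)
    mask[train_pos] = True
    return table.iloc[mask.nonzero()[0]].copy(), table.iloc[(~mask).nonzero()[0]].copy()
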