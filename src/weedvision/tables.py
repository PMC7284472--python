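"""Labeled feature tables: the tabular hand-off between pipeline stages.

A :class:`FeatureTable` couples a feature matrix (one row per plant object)
with integer class labels (1 = rice, 2 = narrow-leaf weed, 3 = wide-leaf
weed) and optional metadata about which columns are informative (used by the
synthetic generator to provide ground truth for feature-selection tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLASS_NAMES = {1: "rice", 2: "narrow-leaf weed", 3: "wide-leaf weed"}
CLASS_LABELS = (1, 2, 3)


@dataclass
class FeatureTable:
    """Feature matrix plus labels.

    Parameters
    ----------
    features
        DataFrame, one row per object, one column per feature.
    labels
        Integer class labels aligned with ``features`` rows.
    informative
        Optional tuple of column indices that carry class signal
        (populated by the synthetic table generator).
    """

    features: pd.DataFrame
    labels: np.ndarray
    informative: tuple[int, ...] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.features):
            raise ValueError("labels and features length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.features)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def values(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    def subset(self, indices) -> "FeatureTable":
        """Restrict to the given feature columns (by position)."""
        idx = list(indices)
        return FeatureTable(self.features.iloc[:, idx].copy(), self.labels.copy())

    def to_csv(self, path) -> None:
        out = self.features.copy()
        out.insert(0, "label", self.labels)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError("feature CSV must contain a 'label' column")
        labels = df.pop("label").to_numpy(dtype=int)
        meta_cols = [c for c in ("object_id", "frame_id", "channel") if c in df.columns]
        meta = {c: df.pop(c).tolist() for c in meta_cols}
        return cls(df, labels, meta=meta)
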