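"""Left/right channel object matching and feature fusion.

Corresponding plant objects in a temporally paired left/right frame are
matched at object level: an optimal one-to-one assignment on centroid
distance after compensating the median horizontal disparity. Matched
objects' feature vectors are then combined entrywise by the arithmetic
mean (L + R) / 2 or the geometric mean sqrt(L * R).

The geometric mean is defined only for positive values, so for feature
columns that can go negative a persisted min-max shift to [1, 2] (fit on
the training pool) is applied before taking sqrt(L * R); see
:class:`PositivityShift`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .segmentation import PlantObject
from .tables import FeatureTable

FUSION_MODES = ("arithmetic", "geometric")


@dataclass
class ObjectMatch:
    left_index: int
    right_index: int
    centroid_offset: tuple[float, float]   # (d_row, d_col) = right - left
    cost: float


@dataclass
class MatchReport:
    matches: list[ObjectMatch]
    unmatched_left: list[int]
    unmatched_right: list[int]


def _assign(cl: np.ndarray, cr: np.ndarray, col_shift: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    shifted = cr.copy()
    shifted[:, 1] -= col_shift
    cost = np.linalg.norm(cl[:, None, :] - shifted[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    return rows, cols, cost


def match_objects(
    left: list[PlantObject],
    right: list[PlantObject],
    max_offset: float = 30.0,
) -> MatchReport:
    """One-to-one centroid matching with median-disparity compensation.

    A first assignment on raw centroid distance estimates the median
    column disparity; the assignment is re-solved after subtracting it,
    and pairs whose residual offset exceeds ``max_offset`` are dropped.
    """
    if not left or not right:
        return MatchReport([], list(range(len(left))), list(range(len(right))))
    cl = np.array([o.centroid for o in left], dtype=float)
    cr = np.array([o.centroid for o in right], dtype=float)
    rows, cols, _ = _assign(cl, cr, 0.0)
    med_disp = float(np.median(cr[cols, 1] - cl[rows, 1]))
    rows, cols, cost = _assign(cl, cr, med_disp)
    matches, used_l, used_r = [], set(), set()
    for li, ri in zip(rows, cols):
        residual = cost[li, ri]
        if residual > max_offset:
            continue
        offset = (float(cr[ri, 0] - cl[li, 0]), float(cr[ri, 1] - cl[li, 1]))
        matches.append(ObjectMatch(int(li), int(ri), offset, float(residual)))
        used_l.add(int(li))
        used_r.add(int(ri))
    return MatchReport(
        matches,
        [k for k in range(len(left)) if k not in used_l],
        [k for k in range(len(right)) if k not in used_r],
    )


@dataclass
class PositivityShift:
    """Per-column min-max shift to [1, 2], fit on a training pool."""

    lo: np.ndarray
    span: np.ndarray

    @classmethod
    def fit(cls, pool: np.ndarray) -> "PositivityShift":
        pool = np.asarray(pool, dtype=float)
        lo = pool.min(axis=0)
        span = pool.max(axis=0) - lo
        span[span <= 0] = 1.0
        return cls(lo, span)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return 1.0 + (np.asarray(x, dtype=float) - self.lo) / self.span

    def to_dict(self) -> dict:
        return {"lo": self.lo.tolist(), "span": self.span.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "PositivityShift":
        return cls(np.asarray(d["lo"], float), np.asarray(d["span"], float))


def fuse_features(
    left_vec: np.ndarray,
    right_vec: np.ndarray,
    mode: str,
    shift: PositivityShift | None = None,
) -> np.ndarray:
    """Entrywise arithmetic or geometric mean of two feature vectors.

    With a :class:`PositivityShift` both vectors are mapped to [1, 2]
    before either mean, so arithmetic >= geometric holds entrywise.
    Without one, the geometric mean is the sign-consistent
    sign * sqrt(|L * R|) for same-sign entries and falls back to the
    arithmetic mean for mixed-sign entries.
    """
    left_vec = np.asarray(left_vec, dtype=float)
    right_vec = np.asarray(right_vec, dtype=float)
    if left_vec.shape != right_vec.shape:
        raise ValueError("feature vectors must share one registry")
    if mode not in FUSION_MODES:
        raise ValueError(f"mode must be one of {FUSION_MODES}")
    if shift is not None:
        left_vec = shift.transform(left_vec)
        right_vec = shift.transform(right_vec)
    if mode == "arithmetic":
        return (left_vec + right_vec) / 2.0
    prod = left_vec * right_vec
    same_sign = prod >= 0
    sign = np.where(left_vec + right_vec >= 0, 1.0, -1.0)
    geo = sign * np.sqrt(np.abs(prod))
    return np.where(same_sign, geo, (left_vec + right_vec) / 2.0)


def fuse_tables(
    left: FeatureTable,
    right: FeatureTable,
    report: MatchReport,
    mode: str,
    shift: PositivityShift | None = None,
) -> FeatureTable:
    """Fuse matched rows of two aligned feature tables."""
    if left.feature_names != right.feature_names:
        raise ValueError("tables must share one registry")
    rows, labels = [], []
    for m in report.matches:
        lv = left.values[m.left_index]
        rv = right.values[m.right_index]
        rows.append(fuse_features(lv, rv, mode, shift))
        labels.append(left.labels[m.left_index])
    df = pd.DataFrame(np.array(rows).reshape(len(rows), left.n_features),
                      columns=left.feature_names)
    return FeatureTable(df, np.array(labels, dtype=int))
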