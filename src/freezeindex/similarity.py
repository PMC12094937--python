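"""Pairwise similarity of FI series and the leave-one-out range-IOU meta-comparison.

Different FI definitions hop their windows at different rates and live on
different scales, so series are first restricted to their common time span,
resampled to a common length by linear interpolation, and standardized to
zero mean and unit standard deviation.  Standardized series are compared by
mean absolute distance (MAD), Pearson correlation, and the coefficient of
determination R^2.

To judge whether one definition is an outlier among many, a leave-one-out
comparison groups the pair scores involving a test definition (set A)
against all remaining pair scores (set B) and measures the overlap of the
value *ranges* spanned by the two sets with a range-based
intersection-over-union: 1 means the ranges coincide, 0 means they are
disjoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import mean_absolute_error, r2_score

from .estimators import FISeries

__all__ = [
    "MetricSet",
    "SimilarityReport",
    "resample_linear",
    "standardize",
    "pairwise_metrics",
    "similarity_matrix",
    "range_iou",
    "leave_one_out_iou",
]

METRIC_NAMES = ("mad", "rho", "r2")


@dataclass(frozen=True)
class MetricSet:
    """Similarity scores of one pair of standardized FI series."""

    mad: float
    rho: float
    r2: float

    def as_dict(self) -> dict[str, float]:
        return {"mad": self.mad, "rho": self.rho, "r2": self.r2}


def resample_linear(
    series: FISeries,
    n_out: int,
    time_range: tuple[float, float] | None = None,
) -> FISeries:
    """Linearly interpolate a series onto ``n_out`` uniformly spaced times.

    NaN values are dropped before interpolation.  By default the output grid
    spans the series' own (non-NaN) time support; ``time_range`` restricts it
    to a sub-interval so series of different window widths can be compared on
    their overlap.
    """
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    keep = np.isfinite(series.values)
    if np.count_nonzero(keep) < 2:
        raise ValueError("series needs at least 2 non-NaN values to resample")
    t, v = series.times[keep], series.values[keep]
    if time_range is None:
        lo, hi = t[0], t[-1]
    else:
        lo, hi = time_range
        if not (t[0] <= lo < hi <= t[-1]):
            raise ValueError(
                f"time_range {time_range} not contained in series support [{t[0]}, {t[-1]}]"
            )
    grid = np.linspace(lo, hi, n_out)
    return FISeries(
        times=grid,
        values=np.interp(grid, t, v),
        method=series.method,
        config=series.config,
    )


def standardize(series: FISeries) -> FISeries:
    """Scale a series to zero mean and unit (population) standard deviation."""
    v = series.values
    sd = float(np.std(v))
    # guard against rounding: a constant series has sd at machine-epsilon scale
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, float(np.max(np.abs(v)))):
        raise ValueError("cannot standardize a constant (zero-variance) series")
    return FISeries(
        times=series.times,
        values=(v - np.mean(v)) / sd,
        method=series.method,
        config=series.config,
    )


def pairwise_metrics(a: FISeries, b: FISeries) -> MetricSet:
    """MAD, Pearson correlation, and R^2 between two equal-length series.

    Both inputs are expected standardized.  R^2 is asymmetric: series ``a``
    is the reference (``y_true``); callers pin the ordering.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    va, vb = a.values, b.values
    return MetricSet(
        mad=float(mean_absolute_error(va, vb)),
        rho=float(np.corrcoef(va, vb)[0, 1]),
        r2=float(r2_score(va, vb)),
    )


@dataclass(frozen=True)
class SimilarityReport:
    """All pairwise scores for a set of FI series plus IOU summaries.

    ``pairs`` maps each unordered label pair (ordered as in ``labels``, the
    first acting as the R^2 reference) to its :class:`MetricSet`.
    """

    labels: tuple[str, ...]
    pairs: dict[tuple[str, str], MetricSet]
    n_common: int

    def pair(self, label_i: str, label_j: str) -> MetricSet:
        if (label_i, label_j) in self.pairs:
            return self.pairs[(label_i, label_j)]
        return self.pairs[(label_j, label_i)]

    def metric_matrix(self, metric: str) -> pd.DataFrame:
        """Symmetric-layout DataFrame of one metric; self-comparison on the diagonal."""
        if metric not in METRIC_NAMES:
            raise ValueError(f"unknown metric {metric!r}")
        diag = 0.0 if metric == "mad" else 1.0
        mat = pd.DataFrame(diag, index=list(self.labels), columns=list(self.labels))
        for (i, j), scores in self.pairs.items():
            value = getattr(scores, metric)
            mat.loc[i, j] = value
            mat.loc[j, i] = value
        return mat

    def iou_summary(self) -> pd.DataFrame:
        """Leave-one-out range IOU of every label for every metric."""
        rows = {label: leave_one_out_iou(self, label) for label in self.labels}
        return pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "labels": list(self.labels),
            "n_common": self.n_common,
            "pairs": {f"{i}|{j}": m.as_dict() for (i, j), m in self.pairs.items()},
            "leave_one_out_iou": {
                label: leave_one_out_iou(self, label) for label in self.labels
            }
            if len(self.labels) >= 4
            else {},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def similarity_matrix(
    series_list: list[FISeries],
    labels: list[str] | None = None,
    n_common: int | None = None,
) -> SimilarityReport:
    """Pairwise comparison of ``>= 3`` FI series computed on the same input.

    All series are restricted to their overlapping time interval, resampled
    to ``n_common`` points (default: the length of the longest input, so no
    resolution is discarded), standardized, and scored for every unordered
    pair.  Within a pair the series listed first is the R^2 reference.
    """
    if len(series_list) < 3:
        raise ValueError("similarity_matrix requires at least 3 series")
    if labels is None:
        labels = [s.method for s in series_list]
    if len(labels) != len(series_list) or len(set(labels)) != len(labels):
        raise ValueError("labels must be unique and match the number of series")
    if n_common is None:
        n_common = max(len(s) for s in series_list)
    lo = max(s.times[np.isfinite(s.values)][0] for s in series_list)
    hi = min(s.times[np.isfinite(s.values)][-1] for s in series_list)
    if not lo < hi:
        raise ValueError("series have no overlapping time support")
    prepared = [
        standardize(resample_linear(s, n_common, time_range=(lo, hi)))
        for s in series_list
    ]
    pairs = {
        (labels[i], labels[j]): pairwise_metrics(prepared[i], prepared[j])
        for i, j in combinations(range(len(prepared)), 2)
    }
    return SimilarityReport(labels=tuple(labels), pairs=pairs, n_common=n_common)


def range_iou(a, b) -> float:
    """Intersection-over-union of the value ranges spanned by two score sets.

    The union is the hull ``max(max A, max B) - min(min A, min B)`` and the
    intersection is ``max(min(max A, max B) - max(min A, min B), 0)``.  When
    every value in both sets is identical the union degenerates to zero
    length; this is defined as perfect overlap (1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("range_iou requires at least 2 scores per set")
    union = max(a.max(), b.max()) - min(a.min(), b.min())
    if union == 0:
        return 1.0
    intersection = max(min(a.max(), b.max()) - max(a.min(), b.min()), 0.0)
    return float(intersection / union)


def leave_one_out_iou(report: SimilarityReport, test_label: str) -> dict[str, float]:
    """Range IOU of one definition's pair scores against all remaining pair scores.

    Set A holds every pair score involving ``test_label``; set B holds every
    pair score not involving it.  At least 4 labels are required so that B
    contains >= 2 pairs.  Returns one IOU per metric.
    """
    if test_label not in report.labels:
        raise ValueError(f"unknown label {test_label!r}")
    if len(report.labels) < 4:
        raise ValueError("leave-one-out IOU requires at least 4 labels")
    result = {}
    for metric in METRIC_NAMES:
        a = [getattr(m, metric) for pair, m in report.pairs.items() if test_label in pair]
        b = [getattr(m, metric) for pair, m in report.pairs.items() if test_label not in pair]
        result[metric] = range_iou(a, b)
    return result
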