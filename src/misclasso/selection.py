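"""Thresholded-Lasso variable selection and the evaluation metrics.

The thresholded estimator zeroes every slope below ``delta`` in absolute
value (the intercept is never thresholded); with a threshold inside the
right interval this recovers the true support exactly.  The three metrics
of the simulation study are:

* TD   — number of correctly selected relevant predictors,
* sep  — number of relevant predictors whose |coefficient| strictly
         exceeds every irrelevant predictor's |coefficient|,
* pred — fraction of correctly classified test objects.

``sep <= TD`` always: a separated predictor necessarily has a nonzero
coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np

from .data import Dataset
from .solvers import FitResult, predict_labels

__all__ = [
    "SelectionResult",
    "threshold_estimator",
    "true_discoveries",
    "separation_count",
    "prediction_accuracy",
]


@dataclass(frozen=True)
class SelectionResult:
    """Support selected by thresholding a Lasso fit."""

    selected: tuple
    delta: float
    coef_th: np.ndarray
    source_fit: FitResult


def threshold_estimator(fit: FitResult, delta: float) -> SelectionResult:
    """Zero all slopes with |b_j| < delta; copy the intercept unchanged."""
    if not delta > 0:
        raise ValueError("delta must be > 0")
    coef = fit.coef.copy()
    small = np.abs(coef[1:]) < delta
    coef[1:][small] = 0.0
    selected = tuple((np.flatnonzero(coef[1:]) + 1).tolist())
    return SelectionResult(selected=selected, delta=float(delta),
                           coef_th=coef, source_fit=fit)


def _support_of(obj: Union[FitResult, SelectionResult, Iterable[int]]) -> set:
    if isinstance(obj, FitResult):
        return set(obj.support.tolist())
    if isinstance(obj, SelectionResult):
        return set(obj.selected)
    return set(int(j) for j in obj)


def true_discoveries(selected_or_fit, true_T: Iterable[int]) -> int:
    """|support ∩ T| — the number of relevant predictors selected."""
    return len(_support_of(selected_or_fit) & set(int(j) for j in true_T))


def separation_count(fit: FitResult, true_T: Iterable[int]) -> int:
    """Number of relevant predictors whose |coefficient| strictly exceeds
    the largest irrelevant |coefficient| (taken as 0 when no irrelevant
    coefficient is nonzero)."""
    T = set(int(j) for j in true_T)
    slopes = fit.slopes
    irrelevant = [abs(slopes[j - 1]) for j in range(1, slopes.size + 1) if j not in T]
    M = max(irrelevant, default=0.0)
    return int(sum(abs(slopes[j - 1]) > M for j in T))


def prediction_accuracy(coef: np.ndarray, test: Dataset) -> float:
    """Fraction of test objects whose class is predicted correctly."""
    yhat = predict_labels(coef, test.X)
    return float(np.mean(yhat == test.y))
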