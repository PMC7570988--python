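"""Sadeh sleep/wake scoring of per-minute actigraphy counts.

Each minute is scored by the Sadeh regression over an 11-minute window
centered on it:

    PS = 7.601 - 0.065*AVG - 1.08*NAT - 0.056*SD - 0.703*LG

where AVG is the window mean of the activity counts, NAT the number of window
minutes with counts in [50, 100), SD the (population) standard deviation of
the 5 preceding minutes, and LG the natural log of the current minute's
counts + 1. The minute is scored *sleep* iff PS >= 0.

Record edges use clamped (truncated) windows over the available minutes; at
the very first minutes, SD is computed over however many preceding minutes
exist (0 when there are none). The regression constants are isolated in
``SADEH_COEFFS``/``NAT_BAND`` so deviating conventions are auditable and
replaceable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .indices import SleepIndexSet, sleep_wake_indices

__all__ = [
    "ActivitySeries",
    "SadehScorer",
    "sadeh_scores",
    "actigraphy_indices",
    "SADEH_COEFFS",
    "NAT_BAND",
]

#: Sadeh regression constants: intercept and weights for AVG, NAT, SD, LG.
SADEH_COEFFS = {
    "intercept": 7.601,
    "avg": -0.065,
    "nat": -1.08,
    "sd": -0.056,
    "lg": -0.703,
}

#: count range (inclusive low, exclusive high) defining "moderate activity"
NAT_BAND = (50.0, 100.0)

_HALF_WINDOW = 5  # minutes each side -> 11-minute centered window
_SD_LOOKBACK = 5  # preceding minutes entering the SD term


@dataclass(frozen=True)
class ActivitySeries:
    """Per-minute activity counts with an optional clock offset (minutes)."""

    counts: np.ndarray
    start_time_min: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float).ravel()
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ValueError("activity counts must be finite and non-negative")
        object.__setattr__(self, "counts", c)

    def __len__(self) -> int:
        return int(self.counts.size)


class SadehScorer(BaseEstimator):
    """Per-minute sleep/wake classifier over actigraphy counts.

    A stateless scikit-learn style estimator: ``fit`` is a no-op and
    ``predict(counts)`` returns a binary array (1 = sleep). ``decision_scores``
    exposes the raw PS values.
    """

    def __init__(self, threshold: float = 0.0) -> None:
        self.threshold = threshold

    def fit(self, X=None, y=None):
        return self

    def decision_scores(self, counts) -> np.ndarray:
        c = counts.counts if isinstance(counts, ActivitySeries) else np.asarray(
            counts, dtype=float
        ).ravel()
        if np.any(c < 0):
            raise ValueError("activity counts must be non-negative")
        n = c.size
        if n < 2 * _HALF_WINDOW + 1:
            raise ValueError(
                f"Sadeh scoring needs at least {2 * _HALF_WINDOW + 1} minutes, got {n}"
            )
        ps = np.empty(n)
        lo, hi = NAT_BAND
        for t in range(n):
            win = c[max(0, t - _HALF_WINDOW) : t + _HALF_WINDOW + 1]
            avg = win.mean()
            nat = int(np.sum((win >= lo) & (win < hi)))
            prev = c[max(0, t - _SD_LOOKBACK) : t]
            sd = float(prev.std()) if prev.size else 0.0
            lg = np.log(c[t] + 1.0)
            ps[t] = (
                SADEH_COEFFS["intercept"]
                + SADEH_COEFFS["avg"] * avg
                + SADEH_COEFFS["nat"] * nat
                + SADEH_COEFFS["sd"] * sd
                + SADEH_COEFFS["lg"] * lg
            )
        return ps

    def predict(self, counts) -> np.ndarray:
        """1 = sleep, 0 = wake, one value per input minute."""
        return (self.decision_scores(counts) >= self.threshold).astype(np.int8)


def sadeh_scores(series) -> np.ndarray:
    """Functional wrapper: per-minute sleep(1)/wake(0) scores."""
    return SadehScorer().predict(series)


def actigraphy_indices(series) -> SleepIndexSet:
    """Sadeh-score a series and derive SE/TST/SOL/WASO at 1-min steps."""
    return sleep_wake_indices(sadeh_scores(series), step_minutes=1.0)
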