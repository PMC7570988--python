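"""Hypnogram-derived sleep-quality indices.

RNR (REM-to-non-REM ratio, %) and SSI (stage-shift index, shifts per hour of
total sleep time) summarize hypnogram architecture; SE, TST, SOL and WASO are
computed from any binary sleep/wake sequence, so the same routine serves both
EEG hypnograms (30-s epochs, sleep = non-Wake) and actigraphy scores (1-min
steps).

Conventions (switchable where the defining formulas are ambiguous):

* RNR denominator is non-REM *sleep* (Light + Deep); Wake is excluded by
  default. The reported cohort values are only consistent with this reading
  (REM ≈ 58 min against TST − REM ≈ 256 min gives RNR ≈ 23%).
* SSI counts every adjacent-epoch label change over the whole record,
  including shifts into and out of Wake; the denominator is TST in hours.
* Sleep onset is the first sleep-scored step; no N-consecutive smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import nan

import numpy as np

from .exceptions import UndefinedIndexError
from .stages import Hypnogram, Stage

__all__ = ["SleepIndexSet", "rnr", "ssi", "sleep_wake_indices", "hypnogram_indices"]


@dataclass
class SleepIndexSet:
    """Bundle of sleep-quality indices.

    ``se`` is a fraction in [0, 1] (multiply by 100 to report %); durations
    are minutes; ``ssi`` is stage shifts per hour of total sleep time; ``rnr``
    is a percentage. Undefined entries are NaN.
    """

    se: float
    tst_min: float
    sol_min: float
    waso_min: float
    rem_min: float = nan
    deep_min: float = nan
    rnr: float = nan
    ssi: float = nan

    def as_dict(self) -> dict:
        return {
            "se": self.se,
            "tst_min": self.tst_min,
            "sol_min": self.sol_min,
            "waso_min": self.waso_min,
            "rem_min": self.rem_min,
            "deep_min": self.deep_min,
            "rnr": self.rnr,
            "ssi": self.ssi,
        }


def rnr(hyp: Hypnogram, include_wake: bool = False) -> float:
    """REM-to-non-REM ratio in percent.

    100 × REM minutes / non-REM sleep minutes (Light + Deep). With
    ``include_wake=True`` the denominator also counts Wake.
    """
    rem_min = hyp.minutes_in(Stage.REM)
    denom = hyp.minutes_in(Stage.LIGHT) + hyp.minutes_in(Stage.DEEP)
    if include_wake:
        denom += hyp.minutes_in(Stage.WAKE)
    if denom <= 0:
        raise UndefinedIndexError("RNR undefined: zero non-REM minutes")
    return 100.0 * rem_min / denom


def ssi(hyp: Hypnogram, within_sleep_only: bool = False) -> float:
    """Stage-shift index: label changes per hour of total sleep time.

    By default every adjacent-epoch change over the whole record counts,
    including shifts into/out of Wake. ``within_sleep_only=True`` counts only
    changes between two sleep stages (both epochs non-Wake).
    """
    tst_hours = (hyp.duration_minutes - hyp.minutes_in(Stage.WAKE)) / 60.0
    if tst_hours <= 0:
        raise UndefinedIndexError("SSI undefined: zero total sleep time")
    a, b = hyp.stages[:-1], hyp.stages[1:]
    changed = a != b
    if within_sleep_only:
        changed &= (a != int(Stage.WAKE)) & (b != int(Stage.WAKE))
    return float(np.sum(changed)) / tst_hours


def sleep_wake_indices(states, step_minutes: float) -> SleepIndexSet:
    """SE, TST, SOL and WASO from a binary sleep(1)/wake(0) sequence.

    SE = sleep steps / total steps; TST = sleep steps × step_minutes; SOL =
    minutes from record start to the first sleep step; WASO = wake minutes
    after the first sleep step. A record with no sleep at all returns SE=0,
    TST=0 and NaN for SOL/WASO (undefined).
    """
    if step_minutes <= 0:
        raise ValueError("step_minutes must be positive")
    raw = np.asarray(states, dtype=float).ravel()
    if raw.size == 0:
        raise ValueError("empty sleep/wake sequence")
    if not np.isin(raw, [0.0, 1.0]).all():
        raise ValueError("sleep/wake sequence must be binary (0=wake, 1=sleep)")
    s = raw.astype(np.int8)
    n_sleep = int(s.sum())
    se = n_sleep / s.size
    tst = n_sleep * step_minutes
    if n_sleep == 0:
        return SleepIndexSet(se=0.0, tst_min=0.0, sol_min=nan, waso_min=nan)
    onset = int(np.argmax(s))
    sol = onset * step_minutes
    waso = float(np.sum(s[onset:] == 0)) * step_minutes
    return SleepIndexSet(se=se, tst_min=tst, sol_min=sol, waso_min=waso)


def hypnogram_indices(
    hyp: Hypnogram,
    include_wake_in_rnr: bool = False,
    ssi_within_sleep_only: bool = False,
) -> SleepIndexSet:
    """All indices for one hypnogram (sleep = any non-Wake stage)."""
    base = sleep_wake_indices(hyp.sleep_wake(), step_minutes=hyp.epoch_seconds / 60.0)
    base.rem_min = hyp.minutes_in(Stage.REM)
    base.deep_min = hyp.minutes_in(Stage.DEEP)
    try:
        base.rnr = rnr(hyp, include_wake=include_wake_in_rnr)
    except UndefinedIndexError:
        base.rnr = nan
    try:
        base.ssi = ssi(hyp, within_sleep_only=ssi_within_sleep_only)
    except UndefinedIndexError:
        base.ssi = nan
    return base
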