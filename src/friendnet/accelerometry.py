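"""Accelerometer count processing: non-wear, intensity classes, summaries.

Waist-worn accelerometer counts recorded in 10-second epochs are reduced to
per-child mean daily minutes of MVPA and sedentary time:

* non-wear: maximal spans of zero counts totalling >= 60 min, allowing
  nonzero interruptions of up to 2 consecutive minutes, are excluded;
* intensity: worn epochs are classed sedentary / light / MVPA by child cut
  points (defaults: sedentary <= 100 counts per minute, moderate >= 2296
  cpm), thresholds rescaled to the epoch length;
* a valid day has >= 500 worn minutes; a child needs >= 3 valid days, else
  their summary means are left missing for downstream imputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import EpochSeries

__all__ = [
    "CutPoints",
    "DaySummary",
    "ChildActivitySummary",
    "detect_nonwear",
    "classify_epochs",
    "summarize_day",
    "summarize_child",
    "process_epochs",
    "EPOCHS_PER_MINUTE",
]

EPOCHS_PER_MINUTE = 6  # 10-s epochs
NONWEAR_MIN_SPAN_MIN = 60
NONWEAR_MAX_INTERRUPT_MIN = 2
VALID_DAY_MIN = 500
MIN_VALID_DAYS = 3

SEDENTARY, LIGHT, MVPA = 0, 1, 2


@dataclass(frozen=True)
class CutPoints:
    """Counts-per-minute intensity thresholds (child calibration defaults).

    Scaled to the 10-s epoch by /6: ceilings floored, floors ceiled, and
    class intervals closed at both the sedentary ceiling and the moderate
    floor (<= sed_cpm/6 is sedentary, >= ceil(moderate_cpm/6) is MVPA).
    """

    sedentary_cpm: float = 100.0
    moderate_cpm: float = 2296.0

    def per_epoch(self, epochs_per_minute: int = EPOCHS_PER_MINUTE) -> tuple[int, int]:
        if not self.sedentary_cpm < self.moderate_cpm:
            raise ValueError("cut points must satisfy sedentary < moderate")
        sed_ceiling = int(np.floor(self.sedentary_cpm / epochs_per_minute))
        mod_floor = int(np.ceil(self.moderate_cpm / epochs_per_minute))
        return sed_ceiling, mod_floor


@dataclass
class DaySummary:
    child_id: str
    day_id: int
    weekend: bool
    wear_minutes: float
    sedentary_minutes: float
    light_minutes: float
    mvpa_minutes: float
    valid: bool


@dataclass
class ChildActivitySummary:
    child_id: str
    n_valid_days: int
    n_valid_weekend_days: int
    mean_mvpa: float  # NaN when n_valid_days < 3
    mean_sedentary: float


def detect_nonwear(
    series: EpochSeries,
    min_span_min: int = NONWEAR_MIN_SPAN_MIN,
    max_interrupt_min: int = NONWEAR_MAX_INTERRUPT_MIN,
    epochs_per_minute: int = EPOCHS_PER_MINUTE,
) -> np.ndarray:
    """Per-epoch wear mask (True = worn).

    A non-wear window runs from a zero epoch to a zero epoch, may contain
    nonzero interruptions of at most ``max_interrupt_min`` consecutive
    minutes (a longer nonzero run terminates it), and must span at least
    ``min_span_min`` minutes in total; the whole span, interruptions
    included, is marked non-wear.
    """
    counts = np.asarray(series.counts)
    n = counts.size
    wear = np.ones(n, dtype=bool)
    if n == 0:
        return wear
    min_span = min_span_min * epochs_per_minute
    max_gap = max_interrupt_min * epochs_per_minute

    # run-length encode zero/nonzero
    is_zero = counts == 0
    change = np.flatnonzero(np.diff(is_zero.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    runs = [(bool(is_zero[s]), s, e) for s, e in zip(starts, ends)]

    i = 0
    while i < len(runs):
        zero, s, e = runs[i]
        if not zero:
            i += 1
            continue
        # absorb alternating (short nonzero, zero) pairs
        j = i
        while j + 2 < len(runs) and (runs[j + 1][2] - runs[j + 1][1]) <= max_gap:
            j += 2
        span_start, span_end = runs[i][1], runs[j][2]
        if span_end - span_start >= min_span:
            wear[span_start:span_end] = False
        i = j + 1
    return wear


def classify_epochs(counts: np.ndarray, cutpoints: CutPoints = CutPoints()) -> np.ndarray:
    """Assign each epoch an intensity class (0 sedentary, 1 light, 2 MVPA)."""
    sed_ceiling, mod_floor = cutpoints.per_epoch()
    counts = np.asarray(counts)
    classes = np.full(counts.shape, LIGHT, dtype=np.int8)
    classes[counts <= sed_ceiling] = SEDENTARY
    classes[counts >= mod_floor] = MVPA
    return classes


def summarize_day(
    series: EpochSeries, wear: np.ndarray, classes: np.ndarray, valid_min: float = VALID_DAY_MIN
) -> DaySummary:
    """Minutes per intensity band over worn epochs; valid iff wear >= 500 min."""
    counts = np.asarray(series.counts)
    if wear.shape != counts.shape or classes.shape != counts.shape:
        raise ValueError("wear mask and classes must align with the series")
    per_min = 1.0 / EPOCHS_PER_MINUTE
    wear_minutes = float(wear.sum()) * per_min
    sed = np.sum(wear & (classes == SEDENTARY)) * per_min
    light = np.sum(wear & (classes == LIGHT)) * per_min
    mvpa = np.sum(wear & (classes == MVPA)) * per_min
    return DaySummary(
        child_id=series.child_id,
        day_id=series.day_id,
        weekend=series.weekend,
        wear_minutes=wear_minutes,
        sedentary_minutes=float(sed),
        light_minutes=float(light),
        mvpa_minutes=float(mvpa),
        valid=bool(wear_minutes >= valid_min),
    )


def summarize_child(
    days: list[DaySummary], min_valid_days: int = MIN_VALID_DAYS
) -> ChildActivitySummary:
    """Mean daily MVPA / sedentary minutes over valid days only.

    With fewer than ``min_valid_days`` valid days the means are NaN — those
    children have their accelerometer measures multiply imputed downstream.
    """
    if not days:
        raise ValueError("need at least one day summary")
    child_id = days[0].child_id
    valid = [d for d in days if d.valid]
    n_valid = len(valid)
    n_wk = sum(1 for d in valid if d.weekend)
    if n_valid >= min_valid_days:
        mvpa = float(np.mean([d.mvpa_minutes for d in valid]))
        sed = float(np.mean([d.sedentary_minutes for d in valid]))
    else:
        mvpa = sed = float("nan")
    return ChildActivitySummary(
        child_id=child_id,
        n_valid_days=n_valid,
        n_valid_weekend_days=n_wk,
        mean_mvpa=mvpa,
        mean_sedentary=sed,
    )


def process_epochs(
    epochs: pd.DataFrame | list[EpochSeries], cutpoints: CutPoints = CutPoints()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full reduction: epoch table or series list -> (day_summaries, child_summaries).

    Accepts the epochs.csv schema (child_id, day_id, weekend, epoch_index,
    counts) or a list of :class:`EpochSeries`.
    """
    if isinstance(epochs, pd.DataFrame):
        series_list = [
            EpochSeries(
                child_id=str(cid),
                day_id=int(did),
                weekend=bool(grp["weekend"].iloc[0]),
                counts=grp.sort_values("epoch_index")["counts"].to_numpy(),
            )
            for (cid, did), grp in epochs.groupby(["child_id", "day_id"], sort=True)
        ]
    else:
        series_list = epochs

    day_rows = []
    by_child: dict[str, list[DaySummary]] = {}
    for es in series_list:
        wear = detect_nonwear(es)
        classes = classify_epochs(es.counts, cutpoints)
        ds = summarize_day(es, wear, classes)
        day_rows.append(vars(ds))
        by_child.setdefault(ds.child_id, []).append(ds)
    child_rows = [vars(summarize_child(days)) for days in by_child.values()]
    return pd.DataFrame(day_rows), pd.DataFrame(child_rows)
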