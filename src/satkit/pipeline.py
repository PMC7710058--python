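"""Anticipatory-licking analysis pipeline.

Implements the behavioral readout of sensory association training:

1. licks are debounced on a 100 ms grid (the sensor cannot resolve faster
   licking, capping measurable rates at 10 Hz);
2. each trial's licks are re-expressed relative to its (virtual) puff onset,
   removing the random-delay jitter;
3. anticipatory licks are counted in the 700-1000 ms post-onset window — the
   300 ms directly before scheduled water delivery — and converted to Hz;
4. trials are binned into 4-hour intervals; per bin, ``L_w`` is the mean
   anticipatory rate over stimulus trials, ``L_b`` over blank trials
   (zero-lick trials included), and performance = L_w - L_b;
5. the last 20% of trials give each animal its learning criterion
   (learned iff L_w > L_b over that subset).

The pipeline is deterministic: a given event log always yields the same
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BLANK_LIKE, STIM_REWARD
from .events import EventLog, TrialRecord

#: Anticipatory scoring window relative to (virtual) puff onset, ms,
#: half-open.  Water arrives at onset + 1000 ms, so this is the 300 ms
#: immediately preceding reward.
ANTICIPATORY_WINDOW_MS = (700, 1000)

SENSOR_PERIOD_MS = 100


@dataclass
class AlignedTrial:
    trial_id: int
    trial_type: str
    init_time_ms: int
    puff_onset_ms: int
    licks_rel_ms: np.ndarray
    anticipatory_count: int
    anticipatory_rate_hz: float


@dataclass
class AnimalResult:
    animal_id: str
    n_trials: int
    last20_L_w: float
    last20_L_b: float
    learned: bool
    participated: bool | None = None
    signed_rank_p: float | None = None

    @property
    def performance(self) -> float:
        return self.last20_L_w - self.last20_L_b


def debounce(licks_ms, period_ms: int = SENSOR_PERIOD_MS) -> np.ndarray:
    """Collapse licks to at most one per grid period.

    The grid is anchored at time 0 of the input's reference frame (trial
    onset for aligned licks) with half-open periods [k*period, (k+1)*period).
    The first lick in each occupied period is kept, preserving real times.
    """
    arr = np.asarray(licks_ms, dtype=np.int64)
    if arr.size == 0:
        return arr
    if np.any(np.diff(arr) < 0):
        raise ValueError("lick timestamps must be sorted")
    periods = np.floor_divide(arr, period_ms)
    first = np.ones(arr.size, dtype=bool)
    first[1:] = periods[1:] != periods[:-1]
    return arr[first]


def anticipatory_rate(
    licks_rel_ms,
    window_ms: tuple[int, int] = ANTICIPATORY_WINDOW_MS,
    period_ms: int = SENSOR_PERIOD_MS,
) -> tuple[int, float]:
    """Debounced lick count and rate (Hz) in the anticipatory window.

    ``licks_rel_ms`` are lick times relative to (virtual) puff onset; the
    debounce grid is therefore onset-anchored, so the default window spans
    exactly three grid periods and the measured rate cannot exceed 10 Hz.
    """
    lo, hi = window_ms
    deb = debounce(np.sort(np.asarray(licks_rel_ms, dtype=np.int64)), period_ms)
    count = int(np.sum((deb >= lo) & (deb < hi)))
    return count, count / ((hi - lo) / 1000.0)


def align_trials(log: EventLog) -> list[AlignedTrial]:
    """Segment the event stream into onset-aligned trials.

    Each lick is assigned to the trial whose half-open span
    [init_time, next init_time) contains it; licks before the first trial
    belong to none.  Lick times are re-expressed relative to the trial's
    (virtual) puff onset.
    """
    trials = log.trials()
    licks = np.asarray(log.licks(), dtype=np.int64)
    starts = np.array([tr.init_time_ms for tr in trials], dtype=np.int64)
    aligned: list[AlignedTrial] = []
    if starts.size:
        owner = np.searchsorted(starts, licks, side="right") - 1
    else:
        owner = np.empty(0, dtype=np.int64)
    for i, tr in enumerate(trials):
        rel = licks[owner == i] - tr.puff_onset_ms
        count, rate = anticipatory_rate(rel)
        aligned.append(
            AlignedTrial(
                trial_id=tr.trial_id,
                trial_type=tr.trial_type,
                init_time_ms=tr.init_time_ms,
                puff_onset_ms=tr.puff_onset_ms,
                licks_rel_ms=rel,
                anticipatory_count=count,
                anticipatory_rate_hz=rate,
            )
        )
    return aligned


def _mean_rates(trials: list[AlignedTrial]) -> tuple[float, float, int, int]:
    stim = [t.anticipatory_rate_hz for t in trials if t.trial_type == STIM_REWARD]
    blank = [t.anticipatory_rate_hz for t in trials if t.trial_type in BLANK_LIKE]
    l_w = float(np.mean(stim)) if stim else math.nan
    l_b = float(np.mean(blank)) if blank else math.nan
    return l_w, l_b, len(stim), len(blank)


def bin_summaries(
    trials: list[AlignedTrial],
    bin_hr: float = 4.0,
    origin_ms: int = 0,
) -> pd.DataFrame:
    """Bin trials into fixed intervals anchored at training onset.

    Returns one row per bin with L_w, L_b, performance = L_w - L_b, and
    trial counts.  Bins lacking a trial type carry NaN (an explicit missing
    value — zero is a meaningful lick rate), and performance is NaN whenever
    either side is missing.
    """
    bin_ms = bin_hr * 3_600_000
    rows = []
    if trials:
        idx = [(int((t.init_time_ms - origin_ms) // bin_ms)) for t in trials]
        n_bins = max(idx) + 1
        for b in range(n_bins):
            members = [t for t, i in zip(trials, idx) if i == b]
            l_w, l_b, n_s, n_b = _mean_rates(members)
            rows.append(
                {
                    "bin_index": b,
                    "bin_start_hr": b * bin_hr,
                    "L_w": l_w,
                    "L_b": l_b,
                    "performance": l_w - l_b,
                    "n_stim": n_s,
                    "n_blank": n_b,
                }
            )
    return pd.DataFrame(
        rows, columns=["bin_index", "bin_start_hr", "L_w", "L_b", "performance", "n_stim", "n_blank"]
    )


def last_fraction_result(
    trials: list[AlignedTrial],
    fraction: float = 0.2,
    animal_id: str = "sim",
    min_trials: int = 5,
) -> AnimalResult:
    """Learning criterion over the final fraction of initiated trials.

    Selects the last ceil(fraction * N) trials of the training phase (all
    types, in time order) and compares mean anticipatory rates; the animal
    is scored as having learned iff L_w > L_b on that subset.
    """
    n = len(trials)
    if n < min_trials:
        raise ValueError(f"need at least {min_trials} trials, got {n}")
    ordered = sorted(trials, key=lambda t: t.init_time_ms)
    k = math.ceil(fraction * n)
    subset = ordered[n - k:]
    l_w, l_b, _, _ = _mean_rates(subset)
    learned = bool(l_w > l_b) if not (math.isnan(l_w) or math.isnan(l_b)) else False
    return AnimalResult(
        animal_id=animal_id,
        n_trials=n,
        last20_L_w=l_w,
        last20_L_b=l_b,
        learned=learned,
    )


def participation(log: EventLog, criterion_window_hr: float = 4.0) -> tuple[bool, float]:
    """Whether the animal kept initiating trials, and its trials/day.

    An animal counts as a non-participant (dropout) if it initiated no
    trial during the final ``criterion_window_hr`` hours of the session.
    """
    trials = log.trials()
    duration_ms = log.config.duration_ms
    cutoff = duration_ms - criterion_window_hr * 3_600_000
    participated = any(tr.init_time_ms >= cutoff for tr in trials)
    days = duration_ms / (24 * 3_600_000)
    return participated, len(trials) / days


def trials_table(trials: list[AlignedTrial]) -> pd.DataFrame:
    """Tidy per-trial table for export."""
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "trial_type": [t.trial_type for t in trials],
            "init_time_ms": [t.init_time_ms for t in trials],
            "puff_onset_ms": [t.puff_onset_ms for t in trials],
            "anticipatory_count": [t.anticipatory_count for t in trials],
            "anticipatory_rate_hz": [t.anticipatory_rate_hz for t in trials],
        }
    )
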