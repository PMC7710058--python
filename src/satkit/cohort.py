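"""Cohort simulation and summary: many synthetic animals, one condition.

Ties the simulator, agent, pipeline, and statistics together: simulate one
event log per synthetic animal, score each with the lick pipeline, and
collect the per-animal results into a tidy cohort table (one row per
animal: last-20% L_w, L_b, performance, learned and participated flags)
ready for group statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .agent import AgentParams
from .config import SessionConfig
from .controller import run_session
from .events import EventLog
from .pipeline import (
    AnimalResult,
    align_trials,
    bin_summaries,
    last_fraction_result,
    participation,
)


def simulate_cohort(
    cfg: SessionConfig,
    agent: AgentParams,
    n_animals: int,
    seed: int,
    condition: str = "default",
) -> list[EventLog]:
    """Simulate one session per animal with independent child seeds."""
    root = np.random.SeedSequence(seed)
    logs = []
    for i, child in enumerate(root.spawn(n_animals)):
        logs.append(run_session(cfg, agent, child, animal_id=f"{condition}-{i:03d}"))
    return logs


def analyze_log(
    log: EventLog,
    fraction: float = 0.2,
    criterion_window_hr: float = 4.0,
) -> tuple[AnimalResult, pd.DataFrame]:
    """Score one animal: last-fraction result plus 4-hr bin summaries."""
    trials = align_trials(log)
    result = last_fraction_result(
        trials, fraction=fraction, animal_id=log.header.get("animal_id", "sim")
    )
    result.participated, _ = participation(log, criterion_window_hr)
    bins = bin_summaries(trials)
    return result, bins


def cohort_table(
    logs: list[EventLog],
    condition: str = "default",
    fraction: float = 0.2,
    criterion_window_hr: float = 4.0,
    min_trials: int = 5,
) -> pd.DataFrame:
    """One row per animal; animals with too few trials are marked
    non-participants with missing rates rather than dropped silently."""
    rows = []
    for log in logs:
        animal_id = log.header.get("animal_id", "sim")
        trials = align_trials(log)
        participated, per_day = participation(log, criterion_window_hr)
        if len(trials) < min_trials:
            rows.append(
                {
                    "animal_id": animal_id,
                    "condition": condition,
                    "last20_L_w": np.nan,
                    "last20_L_b": np.nan,
                    "performance": np.nan,
                    "learned": False,
                    "participated": participated,
                    "trials_per_day": per_day,
                }
            )
            continue
        res = last_fraction_result(trials, fraction=fraction, animal_id=animal_id)
        rows.append(
            {
                "animal_id": animal_id,
                "condition": condition,
                "last20_L_w": res.last20_L_w,
                "last20_L_b": res.last20_L_b,
                "performance": res.performance,
                "learned": res.learned,
                "participated": participated,
                "trials_per_day": per_day,
            }
        )
    return pd.DataFrame(rows)


def mean_performance_trace(logs: list[EventLog], bin_hr: float = 4.0) -> pd.DataFrame:
    """Cohort-mean binned performance (the learning-trajectory readout)."""
    frames = []
    for log in logs:
        bins = bin_summaries(align_trials(log), bin_hr=bin_hr)
        frames.append(bins.set_index("bin_index")["performance"])
    stacked = pd.concat(frames, axis=1)
    return pd.DataFrame(
        {
            "bin_index": stacked.index,
            "bin_start_hr": stacked.index * bin_hr,
            "mean_performance": stacked.mean(axis=1, skipna=True),
            "n_animals": stacked.notna().sum(axis=1),
        }
    ).reset_index(drop=True)
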