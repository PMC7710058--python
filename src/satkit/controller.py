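"""Discrete-event simulator of the homecage trial controller.

The controller accepts self-initiated nosepokes, assigns each accepted trial
a type (stimulus+reward vs blank, or unrewarded direction in discrimination
mode), draws the random pre-stimulus delay, schedules the actuation chain at
exact millisecond times, enforces the inter-trial lockout, and merges the
agent's sensor-grid-quantized lick stream into a single event log.

Blank trials run the same internal schedule as stimulus trials: they sample
a delay and define a *virtual* puff onset at init + delay, at which the sham
relay clicks (masking the solenoid's auditory cue) but nothing is delivered.
The virtual onset anchors lick alignment downstream and keeps trial pacing
identical across types.
"""

from __future__ import annotations

import math

import numpy as np

from .agent import (
    AgentParams,
    AgentState,
    anticipatory_rate,
    generate_licks,
    initiation_times,
    update_state,
)
from .config import (
    BLANK,
    STIM_REWARD,
    UNREWARDED_DIRECTION,
    SessionConfig,
)
from .events import Event, EventLog, make_header


def _as_rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sample_trial_type(cfg: SessionConfig, rng: int | np.random.Generator) -> str:
    """Draw one trial type: stim_reward with probability reward_probability,
    otherwise blank (detection/acclimation) or the unrewarded direction
    (discrimination).  Assignment is i.i.d. Bernoulli per trial."""
    rng = _as_rng(rng)
    if rng.random() < cfg.reward_probability:
        return STIM_REWARD
    return UNREWARDED_DIRECTION if cfg.mode == "discrimination" else BLANK


def sample_delay(cfg: SessionConfig, rng: int | np.random.Generator) -> int:
    """Uniform random pre-stimulus delay in [delay_min_ms, delay_max_ms], ms."""
    rng = _as_rng(rng)
    return int(rng.integers(cfg.delay_min_ms, cfg.delay_max_ms + 1))


def dispensed_volume(cfg: SessionConfig, n_rewarded_trials: int) -> float:
    """Total water volume (μL) dispensed over n rewarded trials.

    Default calibration: 75 ms valve opening x 0.2 μL/ms = 15 μL per reward.
    """
    if n_rewarded_trials < 0:
        raise ValueError("n_rewarded_trials must be >= 0")
    return n_rewarded_trials * cfg.water_duration_ms * cfg.dispense_rate_ul_per_ms


def run_session(
    cfg: SessionConfig,
    agent: AgentParams,
    seed: int | np.random.SeedSequence,
    animal_id: str = "sim",
) -> EventLog:
    """Simulate one full training (or acclimation) session.

    One root seed drives three independent child streams — trial-type
    assignment, delay sampling, and the agent (initiation, detection,
    licking, dropout) — so that e.g. changing the agent's lick parameters
    never perturbs the trial-type sequence.  Replaying the same seed,
    config, and agent yields a bit-identical log.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    type_ss, delay_ss, agent_ss = ss.spawn(3)
    rng_type = np.random.default_rng(type_ss)
    rng_delay = np.random.default_rng(delay_ss)
    rng_agent = np.random.default_rng(agent_ss)

    duration_ms = cfg.duration_ms
    period = cfg.sensor_period_ms
    pokes = initiation_times(agent, cfg, rng_agent)

    state = AgentState()
    events: list[Event] = []
    lick_times: list[np.ndarray] = []
    trial_id = 0
    next_allowed = 0

    for poke in pokes:
        if not state.active:
            break
        # the IR beam-break registers at the next sensor poll
        t = int(math.ceil(poke / period)) * period
        if t < next_allowed:
            continue  # still in lockout: poke rejected, no trial
        if t >= duration_ms:
            break

        trial_type = sample_trial_type(cfg, rng_type)
        delay = sample_delay(cfg, rng_delay)
        onset = t + delay
        has_puff = cfg.mode != "acclimation" and trial_type in (
            STIM_REWARD,
            UNREWARDED_DIRECTION,
        )
        rewarded = trial_type == STIM_REWARD
        detected = (
            has_puff
            and trial_type == STIM_REWARD
            and rng_agent.random() < agent.effective_detection_prob
        )

        events.append(
            Event(t, "nosepoke", trial_id, {"trial_type": trial_type, "delay_ms": delay})
        )
        if has_puff:
            payload = {}
            if cfg.mode == "discrimination":
                payload["direction_deg"] = (
                    cfg.rewarded_direction_deg
                    if trial_type == STIM_REWARD
                    else cfg.unrewarded_direction_deg
                )
            events.append(Event(onset, "puff_on", trial_id, payload))
            events.append(Event(onset + cfg.puff_duration_ms, "puff_off", trial_id, {}))
        else:
            events.append(Event(onset, "relay_click", trial_id, {}))

        water_on = None
        if rewarded:
            water_on = onset + cfg.water_offset_from_onset_ms
            events.append(Event(water_on, "water_on", trial_id, {}))
            events.append(Event(water_on + cfg.water_duration_ms, "water_off", trial_id, {}))

        trial_end = onset + cfg.effective_lockout_ms(rewarded)

        # --- agent licking over the trial span [init, trial end) ----------
        # anticipatory rate applies from (virtual) puff onset to the
        # scheduled reward time; consummatory licking follows water;
        # baseline licking covers the rest of the span.  Between trials the
        # animal is away from the port and emits no licks.
        if trial_type == STIM_REWARD and not detected:
            ant = agent.baseline_lick_rate_hz  # undetected puff: nothing to anticipate
        else:
            ant = anticipatory_rate(agent, state, trial_type)
        reward_time = onset + cfg.water_offset_from_onset_ms
        segments = [
            (float(t), float(onset), agent.baseline_lick_rate_hz),
            (float(onset), float(reward_time), ant),
        ]
        if rewarded:
            segments.append((float(reward_time), float(trial_end), agent.consummatory_rate_hz))
        else:
            segments.append((float(reward_time), float(trial_end), agent.baseline_lick_rate_hz))
        lick_times.append(generate_licks(segments, rng_agent, period))

        state = update_state(
            agent, state, detected=detected, rewarded=rewarded, rng=rng_agent
        )
        next_allowed = trial_end
        trial_id += 1

    # merge licks, de-duplicated on the sensor grid, and tag them with the
    # trial whose span [init, trial_end) contains them (-1 otherwise)
    if lick_times:
        all_licks = np.unique(np.concatenate(lick_times))
    else:
        all_licks = np.empty(0, dtype=np.int64)
    trial_spans = [
        (e.timestamp_ms, e.trial_id)
        for e in events
        if e.kind == "nosepoke"
    ]
    starts = np.array([s for s, _ in trial_spans], dtype=np.int64)
    for lt in all_licks:
        idx = int(np.searchsorted(starts, lt, side="right")) - 1
        tid = trial_spans[idx][1] if idx >= 0 else -1
        events.append(Event(int(lt), "lick", tid, {}))

    events.sort(key=Event.sort_key)
    header = make_header(
        cfg,
        seed=None if isinstance(seed, np.random.SeedSequence) else int(seed),
        animal_id=animal_id,
        conventions={
            "blank_virtual_onset": True,
            "last_fraction_scope": "full training phase, acclimation excluded",
        },
    )
    if isinstance(seed, np.random.SeedSequence):
        header["seed"] = seed.entropy if isinstance(seed.entropy, int) else None
    return EventLog(header=header, events=events)
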