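"""Parametric synthetic mouse: trial initiation, licking, and learning.

The agent is deliberately phenomenological.  It reproduces the behavioral
regularities the training system is designed to read out — a rising
anticipatory lick rate on stimulus trials, baseline licking on blanks, an
early-training novelty dip (blank > stimulus licking at onset), diurnal
modulation of trial initiation, intensity-dependent stimulus detection, and
intensity-dependent task dropout — without claiming any mechanistic
interpretation of the underlying learning rule.

Learning is an exponential-approach associative update: each detected,
rewarded pairing moves the association strength ``a`` toward 1 by
``learning_rate * (1 - a)``, so after ``n`` pairings ``a = 1 - (1 - lr)^n``.
The anticipatory rate on stimulus trials interpolates between the baseline
and asymptotic lick rates by ``a``, scaled by a novelty-suppression factor
that decays exponentially in trials experienced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .config import STIM_REWARD, SessionConfig

#: Default per-psi probability that a single air puff is detected.
DETECTION_BY_PSI = {2: 0.4, 6: 0.9, 9: 0.95}
#: Default per-psi per-trial hazard of permanent task dropout.
DROPOUT_BY_PSI = {2: 0.0, 6: 0.0, 9: 0.007}

#: Clock hour (0-24) at which the diurnal initiation rate peaks; mice are
#: nocturnal and the vivarium runs lights-on 07:00-19:00, so the peak sits
#: in the middle of the dark phase.
DIURNAL_PEAK_HOUR = 1.0


@dataclass(frozen=True)
class AgentParams:
    """Free parameters of the synthetic mouse."""

    baseline_lick_rate_hz: float = 1.0
    asymptote_hz: float = 8.0
    learning_rate: float = 0.01
    novelty_suppression: float = 0.5
    novelty_decay_trials: float = 100.0
    consummatory_rate_hz: float = 8.0
    init_rate_per_hr: float = 20.0
    diurnal_amplitude: float = 0.6
    detection_prob: float = 0.9
    dropout_hazard: float = 0.0
    whiskered: bool = True
    transfer_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "baseline_lick_rate_hz",
            "asymptote_hz",
            "learning_rate",
            "consummatory_rate_hz",
            "init_rate_per_hr",
            "novelty_decay_trials",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("detection_prob", "dropout_hazard", "novelty_suppression", "learning_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.diurnal_amplitude <= 1.0:
            raise ValueError("diurnal_amplitude must be in [0, 1]")

    @property
    def effective_detection_prob(self) -> float:
        """Detection probability; zero for a whiskerless (barbered) agent."""
        return self.detection_prob if self.whiskered else 0.0

    @classmethod
    def for_psi(cls, psi: int, **overrides) -> "AgentParams":
        """Agent defaults for a given air-puff intensity label (2, 6, 9 psi)."""
        if psi not in DETECTION_BY_PSI:
            raise ValueError(f"psi must be one of {sorted(DETECTION_BY_PSI)}, got {psi}")
        kwargs = {
            "detection_prob": DETECTION_BY_PSI[psi],
            "dropout_hazard": DROPOUT_BY_PSI[psi],
        }
        kwargs.update(overrides)
        return cls(**kwargs)

    def transferred(self, new_psi: int) -> "AgentParams":
        """Parameters after switching a trained agent to a new intensity.

        Perceptual transfer: a trained agent keeps its learned detection
        probability scaled by ``transfer_factor`` (1.0 = full transfer)
        instead of reverting to the naive detection level of ``new_psi``;
        the dropout hazard follows the new intensity.
        """
        return replace(
            self,
            detection_prob=min(1.0, self.detection_prob * self.transfer_factor),
            dropout_hazard=DROPOUT_BY_PSI[new_psi],
        )


@dataclass(frozen=True)
class AgentState:
    association_strength: float = 0.0
    trials_experienced: int = 0
    active: bool = True


def anticipatory_rate(params: AgentParams, state: AgentState, trial_type: str) -> float:
    """Anticipatory lick rate (Hz) during the pre-reward window of a trial.

    Stimulus trials express the learned rate, suppressed early in training
    by stimulus novelty; blank and unrewarded-direction trials lick at
    baseline.  With ``novelty_suppression > 0`` and no learning yet, the
    stimulus rate sits *below* baseline, producing the negative early
    performance dip seen at training onset.
    """
    if trial_type != STIM_REWARD:
        return params.baseline_lick_rate_hz
    learned = params.baseline_lick_rate_hz + state.association_strength * (
        params.asymptote_hz - params.baseline_lick_rate_hz
    )
    if params.novelty_decay_trials > 0:
        decay = math.exp(-state.trials_experienced / params.novelty_decay_trials)
    else:
        decay = 0.0
    return learned * (1.0 - params.novelty_suppression * decay)


def update_state(
    params: AgentParams,
    state: AgentState,
    *,
    detected: bool,
    rewarded: bool,
    rng: np.random.Generator,
) -> AgentState:
    """Advance the agent by one initiated trial.

    Association strength grows only on detected AND rewarded trials;
    the trial counter always increments; dropout is sampled once per trial.
    """
    strength = state.association_strength
    if detected and rewarded:
        strength = strength + params.learning_rate * (1.0 - strength)
    active = state.active and not (
        params.dropout_hazard > 0 and rng.random() < params.dropout_hazard
    )
    return AgentState(
        association_strength=strength,
        trials_experienced=state.trials_experienced + 1,
        active=active,
    )


def generate_licks(
    segments: Sequence[tuple[float, float, float]],
    rng: np.random.Generator,
    sensor_period_ms: int = 100,
) -> np.ndarray:
    """Emit lick timestamps from a piecewise-constant rate profile.

    ``segments`` is a sequence of ``(start_ms, end_ms, rate_hz)``.  Licks are
    drawn as an inhomogeneous Poisson process (homogeneous within each
    segment), then quantized to the sensor polling grid: each lick is
    stamped at the first poll tick at or after it occurs (the sensor cannot
    report a lick before it happens), and licks sharing a tick collapse to
    one, mirroring the capacitive sensor's 100 ms update.
    Returns sorted, de-duplicated integer timestamps.
    """
    times: list[np.ndarray] = []
    for start, end, rate in segments:
        if rate < 0:
            raise ValueError("lick rates must be >= 0")
        span_ms = end - start
        if span_ms <= 0 or rate == 0:
            continue
        n = rng.poisson(rate * span_ms / 1000.0)
        if n:
            times.append(start + rng.random(n) * span_ms)
    if not times:
        return np.empty(0, dtype=np.int64)
    raw = np.concatenate(times)
    quantized = np.ceil(raw / sensor_period_ms).astype(np.int64) * sensor_period_ms
    return np.unique(quantized)


def diurnal_rate_per_hr(params: AgentParams, clock_hour: float) -> float:
    """Trial-initiation rate (per hour) at a given clock hour."""
    phase = 2.0 * math.pi * (clock_hour - DIURNAL_PEAK_HOUR) / 24.0
    return params.init_rate_per_hr * (1.0 + params.diurnal_amplitude * math.cos(phase))


def initiation_times(
    params: AgentParams,
    cfg: SessionConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Proposed nosepoke times (ms) over the session.

    An inhomogeneous Poisson process with sinusoidal diurnal modulation
    peaking in the dark phase, sampled by thinning.  These are *proposals*:
    the controller rejects pokes during the trial lockout, and the session
    loop stops consuming them permanently once dropout fires.
    """
    duration_ms = cfg.duration_ms
    lam_max_per_ms = params.init_rate_per_hr * (1.0 + params.diurnal_amplitude) / 3.6e6
    if lam_max_per_ms == 0:
        return np.empty(0, dtype=np.float64)
    n = rng.poisson(lam_max_per_ms * duration_ms)
    t = np.sort(rng.random(n) * duration_ms)
    clock = (cfg.onset_clock_hours + t / 3.6e6) % 24.0
    phase = 2.0 * np.pi * (clock - DIURNAL_PEAK_HOUR) / 24.0
    rate = params.init_rate_per_hr * (1.0 + params.diurnal_amplitude * np.cos(phase))
    keep = rng.random(n) * (params.init_rate_per_hr * (1.0 + params.diurnal_amplitude)) < rate
    return t[keep]
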