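"""Session configuration: the training paradigm as data.

A :class:`SessionConfig` captures every timing and contingency parameter of
the homecage trial controller — reward probability, the random pre-stimulus
delay range, actuation durations, the trial lockout, and the sensor polling
period.  Defaults reproduce the standard detection-mode paradigm: a
self-initiated trial draws a 200–800 ms delay, delivers a 500 ms air puff,
waits 500 ms, opens the water valve for 75 ms (~15 μL), and enforces a 2 s
lockout from puff onset before the next trial can begin.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

MODES = ("acclimation", "detection", "discrimination")

#: Trial-type labels emitted by the controller.
STIM_REWARD = "stim_reward"
BLANK = "blank"
UNREWARDED_DIRECTION = "unrewarded_direction"

#: Trial types scored against the rewarded type in the analysis pipeline.
BLANK_LIKE = frozenset({BLANK, UNREWARDED_DIRECTION})


class ConfigError(ValueError):
    """Raised for an invalid or inconsistent session configuration."""


@dataclass(frozen=True)
class SessionConfig:
    """Controller timing and contingency parameters (all times in ms)."""

    reward_probability: float = 0.8
    mode: str = "detection"
    delay_min_ms: int = 200
    delay_max_ms: int = 800
    puff_duration_ms: int = 500
    puff_to_water_gap_ms: int = 500
    water_duration_ms: int = 75
    post_water_break_ms: int = 925
    lockout_from_puff_onset_ms: int = 2000
    sensor_period_ms: int = 100
    dispense_rate_ul_per_ms: float = 0.2
    stimulus_intensity_psi: int = 6
    rewarded_direction_deg: float | None = None
    unrewarded_direction_deg: float | None = None
    session_duration_hr: float = 48.0
    training_onset_clock: str = "12:00"

    def __post_init__(self) -> None:
        if not 0.0 <= self.reward_probability <= 1.0:
            raise ConfigError(
                f"reward_probability must be in [0, 1], got {self.reward_probability}"
            )
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.delay_min_ms > self.delay_max_ms:
            raise ConfigError("delay_min_ms must be <= delay_max_ms")
        if self.delay_min_ms < 0:
            raise ConfigError("delays must be non-negative")
        for name in (
            "puff_duration_ms",
            "puff_to_water_gap_ms",
            "water_duration_ms",
            "post_water_break_ms",
            "lockout_from_puff_onset_ms",
            "sensor_period_ms",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.dispense_rate_ul_per_ms <= 0:
            raise ConfigError("dispense_rate_ul_per_ms must be > 0")
        if self.session_duration_hr <= 0:
            raise ConfigError("session_duration_hr must be > 0")
        if self.mode == "discrimination" and (
            self.rewarded_direction_deg is None or self.unrewarded_direction_deg is None
        ):
            raise ConfigError(
                "discrimination mode requires rewarded_direction_deg and "
                "unrewarded_direction_deg"
            )
        hh_mm = self.training_onset_clock.split(":")
        if len(hh_mm) != 2 or not all(p.isdigit() for p in hh_mm):
            raise ConfigError("training_onset_clock must look like 'HH:MM'")

    # -- derived timings -------------------------------------------------

    @property
    def water_offset_from_onset_ms(self) -> int:
        """Water valve opening time relative to (virtual) puff onset."""
        return self.puff_duration_ms + self.puff_to_water_gap_ms

    @property
    def rewarded_refractory_ms(self) -> int:
        """Full actuation chain after puff onset on a rewarded trial."""
        return (
            self.puff_duration_ms
            + self.puff_to_water_gap_ms
            + self.water_duration_ms
            + self.post_water_break_ms
        )

    def effective_lockout_ms(self, rewarded: bool) -> int:
        """Time after puff onset before the next trial may be initiated.

        The controller enforces the maximum of the nominal lockout and, on
        rewarded trials, the actuation chain plus the post-water break.
        With the default timings both equal 2000 ms.
        """
        if rewarded:
            return max(self.lockout_from_puff_onset_ms, self.rewarded_refractory_ms)
        return self.lockout_from_puff_onset_ms

    @property
    def onset_clock_hours(self) -> float:
        hh, mm = self.training_onset_clock.split(":")
        return int(hh) + int(mm) / 60.0

    @property
    def duration_ms(self) -> int:
        return int(round(self.session_duration_hr * 3_600_000))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SessionConfig":
        return cls(**d)


def _coerce(raw: str, typ: Any) -> Any:
    raw = raw.strip()
    if raw.lower() in {"none", ""}:
        return None
    if typ is bool or raw.lower() in {"true", "false"}:
        return raw.lower() == "true"
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        pass
    return raw


def parse_flat_config(path: str | Path) -> dict[str, Any]:
    """Parse a flat ``key = value`` config file.

    Lines starting with ``#`` are comments.  Keys prefixed ``agent.`` belong
    to the synthetic-agent block; all others mirror :class:`SessionConfig`
    fields.  Unknown keys are hard errors so typos cannot silently fall back
    to defaults.
    """
    out: dict[str, Any] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, raw = stripped.partition("=")
        out[key.strip()] = _coerce(raw, None)
    return out


def load_config(path: str | Path) -> tuple[SessionConfig, dict[str, Any]]:
    """Load a flat config file into a SessionConfig plus agent overrides."""
    flat = parse_flat_config(path)
    session_keys = {f.name for f in dataclasses.fields(SessionConfig)}
    cfg_kwargs: dict[str, Any] = {}
    agent_kwargs: dict[str, Any] = {}
    for key, value in flat.items():
        if key.startswith("agent."):
            agent_kwargs[key[len("agent."):]] = value
        elif key in session_keys:
            cfg_kwargs[key] = value
        else:
            raise ConfigError(f"unknown config key {key!r}")
    return SessionConfig(**cfg_kwargs), agent_kwargs
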