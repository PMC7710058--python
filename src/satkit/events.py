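"""Event logs: the controller's on-disk record of a training session.

Format: a single JSON header line (config snapshot, seed, animal id, schema
version, conventions) followed by one tab-separated record per event::

    timestamp_ms<TAB>event_kind<TAB>trial_id<TAB>payload_json

Timestamps are integer milliseconds since session start.  Sensor events
(``nosepoke``, ``lick``) are quantized to the controller's polling grid;
actuation events (``puff_on/off``, ``water_on/off``, ``relay_click``) are at
exact milliseconds.  ``trial_id`` is -1 for licks recorded between trials.
Blank trials carry a ``relay_click`` (the sham relay that masks auditory
cues) and no puff or water events.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .config import (
    BLANK,
    STIM_REWARD,
    UNREWARDED_DIRECTION,
    SessionConfig,
)

SCHEMA_VERSION = 1

EVENT_KINDS = (
    "nosepoke",
    "puff_on",
    "puff_off",
    "water_on",
    "water_off",
    "relay_click",
    "lick",
)

# tie-break order for events sharing a timestamp
_KIND_ORDER = {k: i for i, k in enumerate(EVENT_KINDS)}


class LogFormatError(ValueError):
    """Malformed event-log file (carries the offending line number)."""


class LogInvariantError(ValueError):
    """Structurally valid log that violates a controller invariant."""


@dataclass(frozen=True)
class Event:
    timestamp_ms: int
    kind: str
    trial_id: int
    payload: dict = field(default_factory=dict)

    def sort_key(self) -> tuple[int, int, int]:
        return (self.timestamp_ms, _KIND_ORDER[self.kind], self.trial_id)


@dataclass(frozen=True)
class TrialRecord:
    """Per-trial segmentation of the event stream.

    ``puff_onset_ms`` is the real puff onset on stimulus trials and the
    *virtual* onset (init + random delay, marked by the sham relay click) on
    blank trials; lick alignment uses it identically for both.
    """

    trial_id: int
    init_time_ms: int
    trial_type: str
    random_delay_ms: int
    puff_onset_ms: int
    water_onset_ms: int | None = None
    direction_deg: float | None = None


@dataclass
class EventLog:
    header: dict
    events: list[Event]

    @property
    def config(self) -> SessionConfig:
        return SessionConfig.from_dict(self.header["config"])

    def licks(self) -> list[int]:
        return [e.timestamp_ms for e in self.events if e.kind == "lick"]

    def trials(self) -> list[TrialRecord]:
        """Reconstruct per-trial records from the event stream."""
        by_trial: dict[int, dict[str, Event]] = {}
        for ev in self.events:
            if ev.trial_id < 0 or ev.kind == "lick":
                continue
            by_trial.setdefault(ev.trial_id, {})[ev.kind] = ev
        records = []
        for trial_id in sorted(by_trial):
            evs = by_trial[trial_id]
            if "nosepoke" not in evs:
                raise LogInvariantError(f"trial {trial_id} has no nosepoke event")
            poke = evs["nosepoke"]
            trial_type = poke.payload["trial_type"]
            delay = int(poke.payload["delay_ms"])
            if "puff_on" in evs:
                onset = evs["puff_on"].timestamp_ms
                direction = evs["puff_on"].payload.get("direction_deg")
            elif "relay_click" in evs:
                onset = evs["relay_click"].timestamp_ms
                direction = None
            else:
                raise LogInvariantError(
                    f"trial {trial_id} has neither puff_on nor relay_click"
                )
            water = evs["water_on"].timestamp_ms if "water_on" in evs else None
            records.append(
                TrialRecord(
                    trial_id=trial_id,
                    init_time_ms=poke.timestamp_ms,
                    trial_type=trial_type,
                    random_delay_ms=delay,
                    puff_onset_ms=onset,
                    water_onset_ms=water,
                    direction_deg=direction,
                )
            )
        return records

    def validate(self) -> None:
        """Check the event-stream invariants; raise LogInvariantError if broken."""
        cfg = self.config
        prev_t = None
        for ev in self.events:
            if ev.kind not in EVENT_KINDS:
                raise LogInvariantError(f"unknown event kind {ev.kind!r}")
            if prev_t is not None and ev.timestamp_ms < prev_t:
                raise LogInvariantError("timestamps are not non-decreasing")
            prev_t = ev.timestamp_ms

        # paired actuations
        for on_kind, off_kind, dur in (
            ("puff_on", "puff_off", cfg.puff_duration_ms),
            ("water_on", "water_off", cfg.water_duration_ms),
        ):
            ons = {e.trial_id: e for e in self.events if e.kind == on_kind}
            offs = {e.trial_id: e for e in self.events if e.kind == off_kind}
            if set(ons) != set(offs):
                raise LogInvariantError(f"unmatched {on_kind}/{off_kind} events")
            for tid, on in ons.items():
                if offs[tid].timestamp_ms - on.timestamp_ms != dur:
                    raise LogInvariantError(
                        f"trial {tid}: {on_kind} duration != {dur} ms"
                    )

        trials = self.trials()
        for tr in trials:
            if tr.puff_onset_ms != tr.init_time_ms + tr.random_delay_ms:
                raise LogInvariantError(
                    f"trial {tr.trial_id}: onset != init + delay"
                )
            if tr.trial_type == STIM_REWARD and cfg.mode != "acclimation":
                expected = tr.puff_onset_ms + cfg.water_offset_from_onset_ms
                if tr.water_onset_ms != expected:
                    raise LogInvariantError(
                        f"trial {tr.trial_id}: water onset != puff onset + "
                        f"{cfg.water_offset_from_onset_ms} ms"
                    )
            if tr.trial_type in (BLANK, UNREWARDED_DIRECTION) and tr.water_onset_ms is not None:
                raise LogInvariantError(
                    f"trial {tr.trial_id}: unrewarded trial has water"
                )
        blank_ids = {tr.trial_id for tr in trials if tr.trial_type == BLANK}
        for ev in self.events:
            if ev.trial_id in blank_ids and ev.kind in ("puff_on", "puff_off", "water_on", "water_off"):
                raise LogInvariantError(
                    f"blank trial {ev.trial_id} contains a {ev.kind} event"
                )
        onsets = [tr.puff_onset_ms for tr in trials]
        for a, b in zip(onsets, onsets[1:]):
            if b - a < cfg.lockout_from_puff_onset_ms:
                raise LogInvariantError(
                    f"consecutive puff onsets {a} and {b} violate the "
                    f"{cfg.lockout_from_puff_onset_ms} ms lockout"
                )


def make_header(
    cfg: SessionConfig,
    seed: int | None,
    animal_id: str,
    conventions: dict | None = None,
) -> dict:
    return {
        "schema": SCHEMA_VERSION,
        "animal_id": animal_id,
        "seed": seed,
        "config": cfg.to_dict(),
        "conventions": dict(conventions or {"blank_virtual_onset": True}),
    }


def write_log(log: EventLog, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(json.dumps(log.header, sort_keys=True) + "\n")
        for ev in log.events:
            fh.write(
                f"{ev.timestamp_ms}\t{ev.kind}\t{ev.trial_id}\t"
                f"{json.dumps(ev.payload, sort_keys=True)}\n"
            )


def read_log(path: str | Path) -> EventLog:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.strip():
            raise LogFormatError(f"{path}:1: empty or missing header line")
        try:
            header = json.loads(first)
        except json.JSONDecodeError as exc:
            raise LogFormatError(f"{path}:1: invalid JSON header: {exc}") from exc
        if not isinstance(header, dict) or "config" not in header:
            raise LogFormatError(f"{path}:1: header missing 'config'")
        events = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise LogFormatError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            ts, kind, trial_id, payload = parts
            try:
                ev = Event(int(ts), kind, int(trial_id), json.loads(payload))
            except (ValueError, json.JSONDecodeError) as exc:
                raise LogFormatError(f"{path}:{lineno}: {exc}") from exc
            if kind not in EVENT_KINDS:
                raise LogFormatError(f"{path}:{lineno}: unknown event kind {kind!r}")
            events.append(ev)
    return EventLog(header=header, events=events)
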