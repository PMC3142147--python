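"""Pulse delivery, safety timing, session logging and replay.

The stimulator is abstracted behind a three-method contract (set
intensity, arm, trigger); :class:`MockStimulator` implements it in
memory and the genuine serial protocol is a documented extension point.
A :class:`PulseSequencer` wraps a device and refuses any pulse requested
before the configured minimum inter-pulse interval has elapsed — the
safety gate every session runner goes through.

Session runners bind a staircase to a responder (a simulated observer,
or the interactive keyboard responder from the CLI), pace the pulses on
a clock (a virtual clock by default, so simulations do not sleep), and
produce a :class:`SessionLog`: the procedure name, a config snapshot,
the trial records and the result block. Logs round-trip through
CSV + JSON and can be replayed: feeding the logged responses back
through the logged configuration must reproduce the logged intensity
sequence and result exactly, otherwise the log is corrupt or was written
by an incompatible version.

Default pacing: a 2.5 s minimum inter-pulse interval plus typical
response latency yields an average stimulation rate of about 0.36 Hz
over a 30-trial run; the slow mode (6 s) runs at about 0.16 Hz.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np

from .errors import ConfigError, ReplayDivergenceError, SafetyIntervalError, StateError
from .mobs import MobsConfig, MobsResult, init_mobs, mobs_estimate, mobs_next, mobs_update
from .observer import SimulatedObserver
from .psi import (
    PsiConfig,
    StaircaseResult,
    init_psi,
    next_intensity,
    posterior_entropy,
    update_posterior,
    _result_from_state,
)
from .records import TrialRecord

__all__ = [
    "PulseDevice",
    "MockStimulator",
    "PulseSequencer",
    "VirtualClock",
    "SessionLog",
    "run_rept_session",
    "run_mobs_session",
    "replay_session",
    "DEFAULT_MIN_INTERVAL",
    "SLOW_MIN_INTERVAL",
]

DEFAULT_MIN_INTERVAL = 2.5  # seconds; ~0.36 Hz with response latency
SLOW_MIN_INTERVAL = 6.0  # seconds; ~0.16 Hz slow mode
DEFAULT_RESPONSE_LATENCY = 0.4  # seconds a simulated participant takes to answer


class PulseDevice(Protocol):
    """Minimal stimulator contract: set intensity, arm, trigger."""

    def set_intensity(self, percent: int) -> None: ...

    def arm(self) -> None: ...

    def trigger(self) -> None: ...


@dataclass
class MockStimulator:
    """In-memory stand-in for the stimulator; records every pulse event."""

    armed: bool = False
    intensity: int | None = None
    pulses: list[int] = field(default_factory=list)

    def set_intensity(self, percent: int) -> None:
        if not (1 <= int(percent) <= 100):
            raise ConfigError(f"intensity {percent} outside 1–100 %MSO")
        self.intensity = int(percent)

    def arm(self) -> None:
        self.armed = True

    def trigger(self) -> None:
        if not self.armed:
            raise StateError("device not armed")
        if self.intensity is None:
            raise StateError("intensity not set")
        self.pulses.append(self.intensity)


class VirtualClock:
    """A monotone clock whose time is advanced explicitly (no sleeping)."""

    def __init__(self, start: float = 0.0):
        self.t = float(start)

    def __call__(self) -> float:
        return self.t

    def advance(self, dt: float) -> None:
        if dt < 0:
            raise ConfigError("cannot advance a monotone clock backwards")
        self.t += dt


class PulseSequencer:
    """Safety gate in front of a pulse device.

    Refuses (raises, and leaves the device untouched) any pulse
    requested before ``min_interval`` seconds have elapsed since the
    previous delivered pulse.
    """

    def __init__(
        self,
        device: PulseDevice,
        *,
        min_interval: float = DEFAULT_MIN_INTERVAL,
        clock=None,
    ):
        if min_interval < 0:
            raise ConfigError("minimum inter-pulse interval must be >= 0")
        self.device = device
        self.min_interval = float(min_interval)
        self.clock = clock if clock is not None else VirtualClock()
        self._last_pulse: float | None = None
        self.pulse_times: list[float] = []

    def ready_at(self) -> float:
        if self._last_pulse is None:
            return self.clock()
        return self._last_pulse + self.min_interval

    def deliver(self, intensity: int) -> float:
        """Set intensity, arm and trigger one pulse; returns its timestamp."""
        now = self.clock()
        if self._last_pulse is not None and now - self._last_pulse < self.min_interval:
            raise SafetyIntervalError(
                f"pulse requested {now - self._last_pulse:.3f}s after the previous "
                f"one; minimum interval is {self.min_interval}s"
            )
        self.device.set_intensity(int(intensity))
        self.device.arm()
        self.device.trigger()
        self._last_pulse = now
        self.pulse_times.append(now)
        return now


@dataclass
class SessionLog:
    """One persisted thresholding session."""

    procedure: str  # "REPT" or "MOBS"
    config: dict
    observer: dict | str  # observer spec, or "interactive"
    trials: tuple[TrialRecord, ...]
    result: dict
    entropies: tuple[float, ...] = ()
    min_interval: float = DEFAULT_MIN_INTERVAL

    def to_json(self) -> str:
        return json.dumps(
            {
                "procedure": self.procedure,
                "config": self.config,
                "observer": self.observer,
                "min_interval": self.min_interval,
                "trials": [t.to_dict() for t in self.trials],
                "entropies": list(self.entropies),
                "result": self.result,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SessionLog":
        d = json.loads(text)
        return cls(
            procedure=d["procedure"],
            config=d["config"],
            observer=d["observer"],
            trials=tuple(TrialRecord(**t) for t in d["trials"]),
            result=d["result"],
            entropies=tuple(d.get("entropies", ())),
            min_interval=d.get("min_interval", DEFAULT_MIN_INTERVAL),
        )

    def write(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write <prefix>.csv (trial table) and <prefix>.json (full log)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        csv_path = prefix.with_suffix(".csv")
        json_path = prefix.with_suffix(".json")
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["trial", "intensity", "response", "timestamp", "entropy"])
            for i, t in enumerate(self.trials):
                entropy = self.entropies[i] if i < len(self.entropies) else ""
                writer.writerow(
                    [t.trial_index, t.intensity, t.response, t.timestamp, entropy]
                )
        json_path.write_text(self.to_json())
        return csv_path, json_path

    @classmethod
    def read(cls, prefix: str | Path) -> "SessionLog":
        return cls.from_json(Path(prefix).with_suffix(".json").read_text())


def run_rept_session(
    responder,
    *,
    config: PsiConfig | None = None,
    observer_spec: dict | str = "interactive",
    device: PulseDevice | None = None,
    min_interval: float = DEFAULT_MIN_INTERVAL,
    response_latency: float = DEFAULT_RESPONSE_LATENCY,
    clock: VirtualClock | None = None,
) -> SessionLog:
    """Run a paced, logged Psi staircase session.

    Every pulse goes through the safety sequencer; trial timestamps are
    the pulse times on the session clock (virtual by default, so
    simulated sessions complete instantly while preserving realistic
    timing in the log).
    """
    config = config or PsiConfig()
    if not config.integer_intensities:
        raise ConfigError("hardware sessions require integer %MSO intensities")
    clock = clock or VirtualClock()
    sequencer = PulseSequencer(
        device or MockStimulator(), min_interval=min_interval, clock=clock
    )
    state = init_psi(config)
    trials: list[TrialRecord] = []
    entropies: list[float] = []
    while not state.complete:
        x = next_intensity(state)
        intensity = int(round(x))
        wait = sequencer.ready_at() - clock()
        if wait > 0:
            clock.advance(wait)
        stamp = sequencer.deliver(intensity)
        response = int(bool(responder(intensity)))
        clock.advance(response_latency)
        # participant-paced delivery: the next pulse is requested a full
        # interval after the response, so the pulse-to-pulse gap is
        # interval + latency (~0.36 Hz default, ~0.16 Hz slow mode)
        clock.advance(min_interval)
        state = update_posterior(state, x, response)
        entropies.append(posterior_entropy(state))
        rec = state.history[-1]
        trials.append(
            TrialRecord(rec.trial_index, rec.intensity, rec.response, stamp)
        )
    result = _result_from_state(state, tuple(entropies))
    return SessionLog(
        procedure="REPT",
        config=config.to_dict(),
        observer=observer_spec,
        trials=tuple(trials),
        result=result.to_dict(),
        entropies=tuple(entropies),
        min_interval=min_interval,
    )


def run_mobs_session(
    responder,
    *,
    config: MobsConfig | None = None,
    observer_spec: dict | str = "interactive",
    device: PulseDevice | None = None,
    min_interval: float = DEFAULT_MIN_INTERVAL,
    response_latency: float = DEFAULT_RESPONSE_LATENCY,
    clock: VirtualClock | None = None,
) -> SessionLog:
    """Run a paced, logged MOBS session (same schema as REPT sessions)."""
    config = config or MobsConfig()
    clock = clock or VirtualClock()
    sequencer = PulseSequencer(
        device or MockStimulator(), min_interval=min_interval, clock=clock
    )
    state = init_mobs(config)
    trials: list[TrialRecord] = []
    while not state.terminated:
        intensity = mobs_next(state)
        wait = sequencer.ready_at() - clock()
        if wait > 0:
            clock.advance(wait)
        stamp = sequencer.deliver(intensity)
        response = int(bool(responder(intensity)))
        clock.advance(response_latency)
        clock.advance(min_interval)  # participant-paced, as in REPT sessions
        state = mobs_update(state, response)
        rec = state.history[-1]
        trials.append(
            TrialRecord(rec.trial_index, rec.intensity, rec.response, stamp)
        )
    result = MobsResult(
        threshold=float(mobs_estimate(state)),
        n_trials=state.trial_count,
        n_reversals=state.reversal_count,
        history=state.history,
    )
    return SessionLog(
        procedure="MOBS",
        config=config.to_dict(),
        observer=observer_spec,
        trials=tuple(trials),
        result=result.to_dict(),
        min_interval=min_interval,
    )


def replay_session(log: SessionLog):
    """Re-run the logged procedure on the logged responses and verify it.

    Returns the recomputed result (a :class:`StaircaseResult` for REPT, a
    :class:`MobsResult` for MOBS).

    Raises
    ------
    ReplayDivergenceError
        If the recomputed intensity sequence or threshold differs from
        the log — a corrupted or version-mismatched log.
    """
    responses = iter([t.response for t in log.trials])
    logged_x = [t.intensity for t in log.trials]
    if log.procedure == "REPT":
        config = PsiConfig.from_dict(log.config)
        state = init_psi(config)
        entropies = []
        replayed_x = []
        for r in responses:
            x = next_intensity(state)
            replayed_x.append(float(int(round(x)) if config.integer_intensities else x))
            state = update_posterior(state, x, r)
            entropies.append(posterior_entropy(state))
        result = _result_from_state(state, tuple(entropies))
        recomputed_threshold = result.threshold
    elif log.procedure == "MOBS":
        config = MobsConfig.from_dict(log.config)
        state = init_mobs(config)
        replayed_x = []
        for r in responses:
            if state.terminated:
                raise ReplayDivergenceError("log has trials past MOBS termination")
            replayed_x.append(float(mobs_next(state)))
            state = mobs_update(state, r)
        if not state.terminated:
            raise ReplayDivergenceError("logged responses do not reach termination")
        result = MobsResult(
            threshold=float(mobs_estimate(state)),
            n_trials=state.trial_count,
            n_reversals=state.reversal_count,
            history=state.history,
        )
        recomputed_threshold = result.threshold
    else:
        raise ConfigError(f"cannot replay procedure {log.procedure!r}")

    if replayed_x != [float(x) for x in logged_x]:
        raise ReplayDivergenceError(
            "replayed intensity sequence diverges from the logged one"
        )
    if not np.isclose(recomputed_threshold, log.result["threshold"], atol=1e-9):
        raise ReplayDivergenceError("replayed threshold diverges from the logged one")
    return result
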