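"""Modified binary search (MOBS) staircase.

A bisection-style comparator procedure: the intensity under test is the
midpoint of the tops of two boundary stacks (initialised to the full
1–100 %MSO range). A "seen" response pushes the tested intensity as a
new upper boundary, "not seen" pushes it as a new lower boundary. After
two consecutive identical responses the opposite stack retreats (pops)
one level, so a run of lucky or unlucky responses cannot permanently
pinch the bracket. The run terminates after six response reversals
(changes from seen to unseen or vice versa) and the threshold estimate
is the midpoint pending at termination — the ~50% detection point the
bisection converges on.

The original field implementations circulate as spreadsheets and differ
in small details; this module implements the two-stack variant as cited
in the adaptive-procedures literature, not a bit-for-bit copy of any one
sheet. Midpoints are rounded half-up to the integer intensities the
stimulator accepts, and a hard cap (default 100 trials) guarantees
termination against pathological responders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import AbortedSessionError, ConfigError, StateError
from .records import TrialRecord

__all__ = [
    "MobsConfig",
    "MobsState",
    "MobsResult",
    "init_mobs",
    "mobs_next",
    "mobs_update",
    "mobs_estimate",
    "run_mobs",
]


@dataclass(frozen=True)
class MobsConfig:
    lower: int = 1
    upper: int = 100
    n_reversals: int = 6
    max_trials: int = 100

    def __post_init__(self) -> None:
        if not (self.lower < self.upper):
            raise ConfigError("lower bound must be below upper bound")
        if self.n_reversals < 1 or self.max_trials < 1:
            raise ConfigError("n_reversals and max_trials must be positive")

    def to_dict(self) -> dict:
        return {
            "lower": self.lower,
            "upper": self.upper,
            "n_reversals": self.n_reversals,
            "max_trials": self.max_trials,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MobsConfig":
        return cls(**d)


def _midpoint(lower: int, upper: int) -> int:
    # round half up: stimulators accept integer percent
    return math.floor((lower + upper) / 2 + 0.5)


@dataclass(frozen=True)
class MobsState:
    """Boundary stacks, reversal counter and trial history."""

    config: MobsConfig
    upper_stack: tuple[int, ...]
    lower_stack: tuple[int, ...]
    reversal_count: int = 0
    last_response: int | None = None
    consecutive_same: int = 0
    history: tuple[TrialRecord, ...] = ()
    terminated: bool = False

    @property
    def trial_count(self) -> int:
        return len(self.history)

    @property
    def current(self) -> int:
        return _midpoint(self.lower_stack[-1], self.upper_stack[-1])


def init_mobs(config: MobsConfig | None = None) -> MobsState:
    config = config or MobsConfig()
    return MobsState(
        config=config,
        upper_stack=(config.upper,),
        lower_stack=(config.lower,),
    )


def mobs_next(state: MobsState) -> int:
    """Integer midpoint of the current boundary-stack tops."""
    if state.terminated:
        raise StateError("MOBS staircase already terminated")
    return state.current


def mobs_update(state: MobsState, response: int) -> MobsState:
    """Advance the staircase by one trial outcome.

    Seen pushes the tested intensity as a new upper boundary; not-seen
    pushes it as a new lower boundary. A response repeating the previous
    one retreats the opposite stack by one level (never below its base
    element). The first response can never count as a reversal.
    """
    if state.terminated:
        raise StateError("MOBS staircase already terminated")
    if response not in (0, 1):
        raise ConfigError("response must be binary")
    x = state.current
    reversal = state.last_response is not None and response != state.last_response
    same = 1 if state.last_response is None or reversal else state.consecutive_same + 1

    upper, lower = state.upper_stack, state.lower_stack
    if response:
        upper = upper + (x,)
        if same >= 2 and len(lower) > 1:
            lower = lower[:-1]
    else:
        lower = lower + (x,)
        if same >= 2 and len(upper) > 1:
            upper = upper[:-1]
    if not lower[-1] < upper[-1]:
        # bracket collapsed to a single integer: retreat the freshly
        # pushed boundary so a pending midpoint always exists
        if response:
            upper = upper[:-1] if len(upper) > 1 else upper
        else:
            lower = lower[:-1] if len(lower) > 1 else lower

    reversal_count = state.reversal_count + int(reversal)
    record = TrialRecord(
        trial_index=state.trial_count + 1,
        intensity=float(x),
        response=int(response),
        timestamp=float(state.trial_count + 1),
    )
    terminated = (
        reversal_count >= state.config.n_reversals
        or state.trial_count + 1 >= state.config.max_trials
    )
    return replace(
        state,
        upper_stack=upper,
        lower_stack=lower,
        reversal_count=reversal_count,
        last_response=int(response),
        consecutive_same=same,
        history=state.history + (record,),
        terminated=terminated,
    )


def mobs_estimate(state: MobsState) -> int:
    """Threshold estimate: the midpoint pending at termination."""
    if not state.terminated:
        raise StateError("MOBS staircase has not terminated")
    return state.current


@dataclass(frozen=True)
class MobsResult:
    threshold: float
    n_trials: int
    n_reversals: int
    history: tuple[TrialRecord, ...]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_trials": self.n_trials,
            "n_reversals": self.n_reversals,
        }


def run_mobs(responder, config: MobsConfig | None = None) -> MobsResult:
    """Run MOBS to termination against a responder callable."""
    state = init_mobs(config)
    while not state.terminated:
        x = mobs_next(state)
        try:
            response = int(bool(responder(x)))
        except Exception as exc:
            raise AbortedSessionError(
                f"responder failed on trial {state.trial_count + 1}: {exc!r}",
                history=state.history,
            ) from exc
        state = mobs_update(state, response)
    return MobsResult(
        threshold=float(mobs_estimate(state)),
        n_trials=state.trial_count,
        n_reversals=state.reversal_count,
        history=state.history,
    )
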