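"""Trial-level records shared by every staircase procedure."""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class TrialRecord:
    """One delivered pulse and the observer's binary report.

    ``intensity`` is in the stimulus units of the running procedure —
    integer percent of maximum stimulator output for TMS sessions,
    contrast for the 2AFC validation observer. The session layer, which
    always works in %MSO, enforces the integer [1, 100] range; the record
    itself is unit-agnostic.

    ``timestamp`` is seconds from session start. Library-level runs that
    do not simulate pulse pacing use the 1-based trial index as a
    monotone stand-in.
    """

    trial_index: int
    intensity: float
    response: int
    timestamp: float

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise ValueError("trial_index is 1-based")
        if self.response not in (0, 1):
            raise ValueError("response must be binary (0 = not seen, 1 = seen)")

    def to_dict(self) -> dict:
        return asdict(self)
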