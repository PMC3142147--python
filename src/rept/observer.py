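"""Simulated observers: Bernoulli phosphene detectors for hardware-free testing.

A simulated observer stands in for a human participant: given a stimulus
intensity it reports "seen" with probability given by its own
lapse-corrected Weibull psychometric function. Yes/no observers use a
zero guess rate (participants are instructed to respond "no" when
unsure); the 2AFC validation observer uses gamma = 0.5.

Responses are drawn from a per-observer seeded generator, so an
identical seed and stimulus sequence always reproduces the identical
response stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .psychometric import WeibullParams, detect_prob, threshold_at_accuracy

__all__ = ["SimulatedObserver", "sample_observer_panel"]


@dataclass
class SimulatedObserver:
    """A stochastic yes/no (or 2AFC) detector with known true parameters."""

    params: WeibullParams
    seed: int
    mode: str = "yes_no"
    _rng: np.random.Generator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.mode not in ("yes_no", "2afc"):
            raise ConfigError(f"unknown observer mode {self.mode!r}")
        if self.mode == "2afc" and self.params.gamma != 0.5:
            raise ConfigError("a 2AFC observer must have gamma = 0.5")
        self.reset()

    def reset(self) -> None:
        """Rewind the response stream to the start (re-seed the generator)."""
        self._rng = np.random.default_rng(self.seed)

    def respond(self, x) -> int:
        """Bernoulli response at intensity x: 1 = seen / correct, 0 otherwise."""
        return int(self._rng.random() < detect_prob(x, self.params))

    __call__ = respond

    @property
    def threshold_60(self) -> float:
        """The observer's true 60% lapse-corrected detection point."""
        return threshold_at_accuracy(0.60, self.params)

    def to_dict(self) -> dict:
        return {"params": self.params.to_dict(), "seed": self.seed, "mode": self.mode}

    @classmethod
    def from_dict(cls, d: dict) -> "SimulatedObserver":
        return cls(
            params=WeibullParams.from_dict(d["params"]),
            seed=int(d["seed"]),
            mode=d.get("mode", "yes_no"),
        )


def sample_observer_panel(
    n: int,
    *,
    alpha_range: tuple[float, float] = (40.0, 80.0),
    beta_range: tuple[float, float] = (4.0, 16.0),
    gamma: float = 0.0,
    lapse: float = 0.04,
    seed: int = 0,
) -> list[SimulatedObserver]:
    """Draw a reproducible panel of simulated yes/no observers.

    Position parameters are uniform over ``alpha_range`` (% of maximum
    stimulator output), slopes log-uniform over ``beta_range``; the
    defaults bracket plausible human phosphene psychometric functions.
    """
    if n < 1:
        raise ConfigError("panel size must be >= 1")
    if not (alpha_range[0] < alpha_range[1]) or not (0 < beta_range[0] < beta_range[1]):
        raise ConfigError("parameter ranges must be non-empty")
    rng = np.random.default_rng(seed)
    panel = []
    for _ in range(n):
        alpha = float(rng.uniform(*alpha_range))
        beta = float(np.exp(rng.uniform(np.log(beta_range[0]), np.log(beta_range[1]))))
        obs_seed = int(rng.integers(0, 2**31 - 1))
        panel.append(
            SimulatedObserver(
                params=WeibullParams(alpha, beta, gamma, lapse), seed=obs_seed
            )
        )
    return panel
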