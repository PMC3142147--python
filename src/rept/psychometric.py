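"""Weibull psychometric function with guess- and lapse-rate asymptotes.

The detection model used throughout the package is the four-parameter
Weibull

    psi(x) = gamma + (1 - gamma - lapse) * (1 - exp(-(x / alpha) ** beta))

where ``alpha`` is the position parameter (the stimulus at which the
lapse-free, guess-free curve reaches 1 - 1/e ~ 63% detection), ``beta``
the slope, ``gamma`` the lower asymptote (false-alarm / guess rate; 0 for
yes/no phosphene detection, 0.5 for 2AFC) and ``lapse`` the lapse rate
that compresses the upper asymptote to 1 - lapse.

Stimulus units are arbitrary but must be positive: percent of maximum
stimulator output for TMS phosphene work, contrast for the 2AFC
validation observer.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import ParameterError, UnattainableAccuracyError

__all__ = ["WeibullParams", "detect_prob", "threshold_at_accuracy", "to_decibels"]


@dataclass(frozen=True)
class WeibullParams:
    """Parameters of the lapse-corrected Weibull psychometric function.

    Attributes
    ----------
    alpha:
        Position parameter, same units as the stimulus; > 0.
    beta:
        Slope, dimensionless; > 0.
    gamma:
        Lower asymptote (guess / false-alarm rate) in [0, 1).
    lapse:
        Lapse rate in [0, 1); together with gamma must leave a
        non-degenerate dynamic range, gamma + lapse < 1.
    """

    alpha: float
    beta: float
    gamma: float = 0.0
    lapse: float = 0.04

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ParameterError(f"alpha must be > 0, got {self.alpha}")
        if not (self.beta > 0):
            raise ParameterError(f"beta must be > 0, got {self.beta}")
        if not (0.0 <= self.gamma < 1.0):
            raise ParameterError(f"gamma must be in [0, 1), got {self.gamma}")
        if not (0.0 <= self.lapse < 1.0):
            raise ParameterError(f"lapse must be in [0, 1), got {self.lapse}")
        if not (self.gamma + self.lapse < 1.0):
            raise ParameterError(
                f"gamma + lapse must be < 1, got {self.gamma + self.lapse}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "WeibullParams":
        return cls(**d)


def detect_prob(x, params: WeibullParams):
    """Detection probability psi(x) of the lapse-corrected Weibull.

    Parameters
    ----------
    x:
        Stimulus intensity (scalar or array), >= 0.
    params:
        Validated :class:`WeibullParams`.

    Returns
    -------
    Probability in [gamma, 1 - lapse], same shape as ``x``; strictly
    increasing in x for x > 0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ParameterError("stimulus intensity must be >= 0")
    span = 1.0 - params.gamma - params.lapse
    p = params.gamma - span * np.expm1(-((x / params.alpha) ** params.beta))
    return p if p.ndim else float(p)


def threshold_at_accuracy(p_target: float, params: WeibullParams) -> float:
    """Invert the psychometric function: stimulus at which psi(x) = p_target.

    Closed form: x = alpha * (-log(1 - q)) ** (1/beta) with
    q = (p_target - gamma) / (1 - gamma - lapse).

    Raises
    ------
    UnattainableAccuracyError
        If ``p_target`` is not strictly inside (gamma, 1 - lapse).
    """
    lo, hi = params.gamma, 1.0 - params.lapse
    if not (lo < p_target < hi):
        raise UnattainableAccuracyError(
            f"target accuracy {p_target} outside attainable open interval "
            f"({lo}, {hi})"
        )
    q = (p_target - params.gamma) / (1.0 - params.gamma - params.lapse)
    return float(params.alpha * (-np.log1p(-q)) ** (1.0 / params.beta))


def to_decibels(x, reference):
    """Express an intensity relative to a reference in decibels, 20*log10(x/ref)."""
    x = np.asarray(x, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if np.any(x <= 0) or np.any(reference <= 0):
        raise ParameterError("decibel conversion requires strictly positive inputs")
    out = 20.0 * np.log10(x / reference)
    return out if out.ndim else float(out)
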