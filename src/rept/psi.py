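"""The Psi Bayesian adaptive staircase.

The staircase maintains a discrete posterior over candidate Weibull
position/slope pairs (alpha, beta). On every trial it evaluates, for each
admissible stimulus intensity, the expected Shannon entropy of the
posterior after a hypothetical trial at that intensity — the average of
the entropies of the two Bayes-updated posteriors, weighted by the
predictive probabilities of "seen" and "not seen" — and delivers the
intensity that minimises it. After a fixed number of trials (30 by
default) the threshold is read out from the posterior-mean parameters at
the 60% lapse-corrected accuracy point.

The staircase itself is fully deterministic: given the same configuration
and the same response sequence it reproduces the same intensity sequence
and the same estimate. Only simulated observers consume random seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import xlogy

from .errors import AbortedSessionError, ConfigError, StateError
from .psychometric import WeibullParams, detect_prob, threshold_at_accuracy
from .records import TrialRecord

__all__ = [
    "PsiConfig",
    "PsiGrid",
    "PsiState",
    "StaircaseResult",
    "init_psi",
    "posterior_entropy",
    "expected_entropy",
    "next_intensity",
    "update_posterior",
    "run_rept",
]


def _default_alpha_grid() -> np.ndarray:
    return np.arange(1.0, 101.0)


def _default_beta_grid() -> np.ndarray:
    return np.geomspace(0.5, 20.0, 10)


def _default_x_grid() -> np.ndarray:
    return np.arange(1.0, 101.0)


@dataclass(frozen=True)
class PsiConfig:
    """Configuration of the staircase grids and readout.

    Defaults target yes/no phosphene detection on the integer 1–100 %MSO
    axis: alpha candidates 1..100 step 1, ten log-spaced slope candidates
    in [0.5, 20], guess rate 0, lapse rate fixed at 0.04, 30 trials, and
    a 60% lapse-corrected threshold readout.

    ``log_domain_estimate`` switches the alpha point estimate from the
    linear marginal posterior mean to the geometric (log-domain) mean,
    the natural choice when the alpha grid is log-spaced as in the 2AFC
    contrast-detection configuration.
    """

    alpha_values: np.ndarray = field(default_factory=_default_alpha_grid)
    beta_values: np.ndarray = field(default_factory=_default_beta_grid)
    x_values: np.ndarray = field(default_factory=_default_x_grid)
    gamma: float = 0.0
    lapse: float = 0.04
    max_trials: int = 30
    target_accuracy: float = 0.60
    integer_intensities: bool = True
    log_domain_estimate: bool = False

    @classmethod
    def two_afc_validation(cls) -> "PsiConfig":
        """Configuration for the 2AFC contrast-detection precision study.

        Log-spaced contrast axes spanning 40 dB (contrast 0.01 to 1), a
        0.5 guess rate and a small (2%) lapse rate; thresholds are
        estimated in the log domain, matching how staircase precision is
        conventionally quoted in dB.
        """
        return cls(
            alpha_values=np.geomspace(0.01, 1.0, 41),
            beta_values=np.geomspace(1.0, 16.0, 10),
            x_values=np.geomspace(0.01, 1.0, 41),
            gamma=0.5,
            lapse=0.02,
            target_accuracy=0.75,
            integer_intensities=False,
            log_domain_estimate=True,
        )

    def to_dict(self) -> dict:
        return {
            "alpha_values": np.asarray(self.alpha_values).tolist(),
            "beta_values": np.asarray(self.beta_values).tolist(),
            "x_values": np.asarray(self.x_values).tolist(),
            "gamma": self.gamma,
            "lapse": self.lapse,
            "max_trials": self.max_trials,
            "target_accuracy": self.target_accuracy,
            "integer_intensities": self.integer_intensities,
            "log_domain_estimate": self.log_domain_estimate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PsiConfig":
        d = dict(d)
        for key in ("alpha_values", "beta_values", "x_values"):
            if key in d:
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


def _check_axis(name: str, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ConfigError(f"{name} must be a non-empty 1-d axis")
    if values.size > 1 and not np.all(np.diff(values) > 0):
        raise ConfigError(f"{name} must be strictly increasing")
    return values


@dataclass(frozen=True)
class PsiGrid:
    """Candidate parameter/stimulus axes plus the precomputed likelihood table.

    ``likelihood`` has shape (n_alpha * n_beta, n_x) with alpha the slow
    axis, and holds P(seen | alpha, beta, x) for the configured gamma and
    lapse.
    """

    alpha_values: np.ndarray
    beta_values: np.ndarray
    x_values: np.ndarray
    likelihood: np.ndarray

    @classmethod
    def from_config(cls, config: PsiConfig) -> "PsiGrid":
        alphas = _check_axis("alpha_values", config.alpha_values)
        betas = _check_axis("beta_values", config.beta_values)
        xs = _check_axis("x_values", config.x_values)
        span = 1.0 - config.gamma - config.lapse
        if span <= 0:
            raise ConfigError("gamma + lapse must be < 1")
        a = alphas[:, None, None]
        b = betas[None, :, None]
        x = xs[None, None, :]
        table = config.gamma - span * np.expm1(-((x / a) ** b))
        # Keep likelihoods inside the open interval so Bayes updates can
        # never annihilate the posterior.
        tiny = 1e-12
        table = np.clip(table, tiny, 1.0 - tiny)
        return cls(alphas, betas, xs, table.reshape(alphas.size * betas.size, xs.size))

    @property
    def n_alpha(self) -> int:
        return self.alpha_values.size

    @property
    def n_beta(self) -> int:
        return self.beta_values.size


@dataclass(frozen=True)
class PsiState:
    """Posterior over (alpha, beta) plus trial history."""

    config: PsiConfig
    grid: PsiGrid
    posterior: np.ndarray  # flat, shape (n_alpha * n_beta,), sums to 1
    history: tuple[TrialRecord, ...] = ()

    @property
    def trial_count(self) -> int:
        return len(self.history)

    @property
    def complete(self) -> bool:
        return self.trial_count >= self.config.max_trials


@dataclass(frozen=True)
class StaircaseResult:
    """Outcome of a completed (or replayed) Psi run."""

    threshold: float
    alpha_estimate: float
    beta_estimate: float
    threshold_50: float | None
    n_trials: int
    history: tuple[TrialRecord, ...]
    entropies: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "alpha_estimate": self.alpha_estimate,
            "beta_estimate": self.beta_estimate,
            "threshold_50": self.threshold_50,
            "n_trials": self.n_trials,
        }


def init_psi(config: PsiConfig | None = None) -> PsiState:
    """Build the initial state: uniform prior over the (alpha, beta) grid."""
    config = config or PsiConfig()
    grid = PsiGrid.from_config(config)
    n = grid.n_alpha * grid.n_beta
    return PsiState(config=config, grid=grid, posterior=np.full(n, 1.0 / n))


def posterior_entropy(state: PsiState) -> float:
    """Shannon entropy (nats) of the current posterior."""
    p = state.posterior
    return float(-xlogy(p, p).sum())


def _expected_entropies(state: PsiState) -> np.ndarray:
    """Expected posterior entropy after one trial, for every candidate x."""
    p = state.posterior
    L = state.grid.likelihood
    joint_seen = p[:, None] * L
    joint_miss = p[:, None] * (1.0 - L)
    p_seen = joint_seen.sum(axis=0)
    p_miss = joint_miss.sum(axis=0)
    post_seen = joint_seen / p_seen
    post_miss = joint_miss / p_miss
    h_seen = -xlogy(post_seen, post_seen).sum(axis=0)
    h_miss = -xlogy(post_miss, post_miss).sum(axis=0)
    return p_seen * h_seen + p_miss * h_miss


def _x_index(grid: PsiGrid, x) -> int:
    idx = np.searchsorted(grid.x_values, x)
    if idx >= grid.x_values.size or not math.isclose(
        grid.x_values[idx], float(x), rel_tol=1e-12, abs_tol=1e-12
    ):
        raise ConfigError(f"stimulus {x} is not on the configured intensity grid")
    return int(idx)


def expected_entropy(state: PsiState, x) -> float:
    """Outcome-averaged posterior entropy of a hypothetical trial at x (nats)."""
    return float(_expected_entropies(state)[_x_index(state.grid, x)])


def next_intensity(state: PsiState) -> float:
    """The entropy-minimising stimulus for the next trial.

    Deterministic given the state; ties are broken in favour of the
    lowest intensity (argmin takes the first of equal minima on the
    ascending x axis) to minimise participant discomfort.
    """
    if state.complete:
        raise StateError("staircase already complete")
    x = float(state.grid.x_values[int(np.argmin(_expected_entropies(state)))])
    return x


def update_posterior(state: PsiState, x, response: int) -> PsiState:
    """Bayes-update the posterior with the outcome of a trial at x."""
    if state.complete:
        raise StateError("staircase already complete")
    if response not in (0, 1):
        raise ConfigError("response must be binary")
    idx = _x_index(state.grid, x)
    like = state.grid.likelihood[:, idx]
    if not response:
        like = 1.0 - like
    post = state.posterior * like
    total = post.sum()
    if not (total > 0) or not np.isfinite(total):
        raise ArithmeticError("posterior annihilated by a zero-likelihood update")
    record = TrialRecord(
        trial_index=state.trial_count + 1,
        intensity=float(x),
        response=int(response),
        timestamp=float(state.trial_count + 1),
    )
    return replace(state, posterior=post / total, history=state.history + (record,))


def _marginal_means(state: PsiState) -> tuple[float, float]:
    post = state.posterior.reshape(state.grid.n_alpha, state.grid.n_beta)
    p_alpha = post.sum(axis=1)
    p_beta = post.sum(axis=0)
    if state.config.log_domain_estimate:
        alpha = float(np.exp(np.dot(p_alpha, np.log(state.grid.alpha_values))))
        beta = float(np.exp(np.dot(p_beta, np.log(state.grid.beta_values))))
    else:
        alpha = float(np.dot(p_alpha, state.grid.alpha_values))
        beta = float(np.dot(p_beta, state.grid.beta_values))
    return alpha, beta


def _result_from_state(state: PsiState, entropies: tuple[float, ...]) -> StaircaseResult:
    config = state.config
    alpha, beta = _marginal_means(state)
    params = WeibullParams(alpha, beta, config.gamma, config.lapse)
    threshold = threshold_at_accuracy(config.target_accuracy, params)
    lo = float(state.grid.x_values[0])
    hi = float(state.grid.x_values[-1])
    threshold = min(max(threshold, lo), hi)
    try:
        threshold_50 = threshold_at_accuracy(0.50, params)
    except Exception:
        threshold_50 = None  # 50% unattainable, e.g. gamma = 0.5 in 2AFC
    return StaircaseResult(
        threshold=threshold,
        alpha_estimate=alpha,
        beta_estimate=beta,
        threshold_50=threshold_50,
        n_trials=state.trial_count,
        history=state.history,
        entropies=entropies,
    )


def run_rept(responder, config: PsiConfig | None = None) -> StaircaseResult:
    """Run a complete Psi staircase against a responder.

    ``responder`` is any callable mapping a stimulus intensity to a
    binary response (1 = seen). Exactly ``config.max_trials``
    select-deliver-update cycles are executed; the reported threshold is
    the lapse-corrected ``target_accuracy`` (default 60%) point of the
    posterior-mean psychometric function, and the 50% point is reported
    post hoc alongside it.

    Raises
    ------
    AbortedSessionError
        If the responder raises; the partial history is attached.
    """
    state = init_psi(config)
    entropies: list[float] = []
    while not state.complete:
        x = next_intensity(state)
        stimulus = int(round(x)) if state.config.integer_intensities else x
        try:
            response = int(bool(responder(stimulus)))
        except Exception as exc:  # responder failure → abort with partial history
            raise AbortedSessionError(
                f"responder failed on trial {state.trial_count + 1}: {exc!r}",
                history=state.history,
            ) from exc
        state = update_posterior(state, x, response)
        entropies.append(posterior_entropy(state))
    return _result_from_state(state, tuple(entropies))
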