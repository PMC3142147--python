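"""Method of constant stimuli (MOCS): design, ML Weibull fit, bootstrap errors.

MOCS is the slow, accurate comparator used as proxy ground truth: a small
set of fixed intensities, centred on a pilot threshold estimate, each
presented 20–30 times in random order. The per-level detection counts
are fitted with a lapse-corrected cumulative Weibull by maximising the
binomial log-likelihood

    LL(alpha, beta) = sum_i [ k_i log psi(x_i) + (n_i - k_i) log(1 - psi(x_i)) ]

with the guess rate fixed at 0 and the lapse rate at 0.04, consistent
with the adaptive procedure. Thresholds are read out at 60% and 50%
accuracy, and their standard errors come from a parametric bootstrap
(simulate from the fitted curve at the same design, refit, take the SD
of the refitted thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import ConfigError, DesignError, FitError
from .psychometric import WeibullParams, detect_prob, threshold_at_accuracy

__all__ = [
    "MocsDesign",
    "MocsDataset",
    "MocsFit",
    "BootstrapSE",
    "design_mocs",
    "run_mocs",
    "fit_weibull_ml",
    "bootstrap_threshold_se",
]


@dataclass(frozen=True)
class MocsDesign:
    """Fixed intensity levels, repetitions, and the seeded presentation order."""

    levels: np.ndarray
    reps_per_level: int
    presentation_order: np.ndarray
    seed: int

    @property
    def n_trials(self) -> int:
        return int(self.levels.size * self.reps_per_level)


def design_mocs(
    pilot_threshold: float,
    *,
    n_levels: int = 7,
    spacing: float = 5.0,
    reps_per_level: int = 25,
    seed: int = 0,
    bounds: tuple[float, float] = (1.0, 100.0),
) -> MocsDesign:
    """Build a constant-stimuli design centred on a pilot threshold.

    Seven integer levels (default) at 5 %MSO spacing span a symmetric
    window around the pilot estimate — wide enough to cover near-0% to
    near-100% expected detection for typical phosphene slopes. A window
    that would overhang the admissible [1, 100] range is shifted inside
    it, keeping all levels distinct and strictly increasing.
    """
    lo, hi = bounds
    if not (lo <= pilot_threshold <= hi):
        raise DesignError(f"pilot threshold {pilot_threshold} outside [{lo}, {hi}]")
    if n_levels < 2 or spacing <= 0 or reps_per_level < 1:
        raise ConfigError("need >= 2 levels, positive spacing and repetitions")
    half = (n_levels - 1) / 2.0
    levels = pilot_threshold + spacing * (np.arange(n_levels) - half)
    # shift the window inside the admissible range rather than clipping
    # element-wise, which would collapse duplicate boundary levels
    if levels[-1] > hi:
        levels = levels - (levels[-1] - hi)
    if levels[0] < lo:
        levels = levels + (lo - levels[0])
    levels = np.round(levels)
    if levels[-1] > hi or np.unique(levels).size < min(n_levels, 6):
        raise DesignError("design window degenerate after fitting into bounds")
    levels = np.unique(levels)
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.repeat(levels, reps_per_level))
    return MocsDesign(
        levels=levels,
        reps_per_level=reps_per_level,
        presentation_order=order,
        seed=seed,
    )


@dataclass(frozen=True)
class MocsDataset:
    """Per-level presentation and detection counts."""

    levels: np.ndarray
    presented: np.ndarray
    seen: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.levels) == len(self.presented) == len(self.seen)):
            raise ConfigError("levels, presented and seen must align")
        if np.any(self.seen < 0) or np.any(self.seen > self.presented):
            raise ConfigError("need 0 <= seen <= presented at every level")

    @property
    def proportions(self) -> np.ndarray:
        return self.seen / self.presented


def run_mocs(responder, design: MocsDesign) -> MocsDataset:
    """Present the design's randomised trial sequence and tally responses."""
    seen = {float(level): 0 for level in design.levels}
    presented = {float(level): 0 for level in design.levels}
    for x in design.presentation_order:
        presented[float(x)] += 1
        seen[float(x)] += int(bool(responder(x)))
    levels = np.asarray(design.levels, dtype=float)
    return MocsDataset(
        levels=levels,
        presented=np.array([presented[float(v)] for v in levels]),
        seen=np.array([seen[float(v)] for v in levels]),
    )


@dataclass(frozen=True)
class MocsFit:
    params: WeibullParams
    log_likelihood: float
    threshold_60: float
    threshold_50: float


@dataclass(frozen=True)
class BootstrapSE:
    se_60: float
    se_50: float
    n_boot: int
    n_failed: int


def _neg_log_likelihood(
    log_params: np.ndarray, data: MocsDataset, gamma: float, lapse: float
) -> float:
    alpha, beta = np.exp(log_params)
    psi = detect_prob(data.levels, WeibullParams(alpha, beta, gamma, lapse))
    psi = np.clip(psi, 1e-300, 1.0 - 1e-12)
    ll = data.seen * np.log(psi) + (data.presented - data.seen) * np.log1p(-psi)
    return -float(ll.sum())


def fit_weibull_ml(
    data: MocsDataset,
    *,
    gamma: float = 0.0,
    lapse: float = 0.04,
    n_starts: int = 5,
) -> MocsFit:
    """Maximum-likelihood Weibull fit with fixed asymptotes.

    Derivative-free simplex optimisation in (log alpha, log beta) from
    multiple starts spread across the sampled intensity range guards
    against the likelihood's flat shoulders.

    Raises
    ------
    FitError
        On non-identifiable data (all seen or none seen), which pins the
        threshold outside the sampled range.
    """
    if data.levels.size < 2 or data.presented.sum() < 2:
        raise FitError("need at least two sampled levels with presentations")
    total_seen = int(data.seen.sum())
    if total_seen == 0 or total_seen == int(data.presented.sum()):
        raise FitError("responses identical at every level: threshold not identifiable")
    alpha_starts = np.linspace(data.levels[0], data.levels[-1], n_starts)
    alpha_starts = np.clip(alpha_starts, 1e-6, None)
    best = None
    for a0 in alpha_starts:
        for b0 in (2.0, 8.0):
            res = minimize(
                _neg_log_likelihood,
                x0=np.log([a0, b0]),
                args=(data, gamma, lapse),
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
    alpha, beta = np.exp(best.x)
    params = WeibullParams(float(alpha), float(beta), gamma, lapse)
    return MocsFit(
        params=params,
        log_likelihood=-float(best.fun),
        threshold_60=threshold_at_accuracy(0.60, params),
        threshold_50=threshold_at_accuracy(0.50, params),
    )


def bootstrap_threshold_se(
    fit: MocsFit, design: MocsDesign, n_boot: int = 400, *, seed: int = 0
) -> BootstrapSE:
    """Parametric-bootstrap standard errors of the 60% and 50% thresholds.

    Simulates ``n_boot`` datasets from the fitted curve at the design's
    levels and counts, refits each, and returns the SD of the refitted
    thresholds. More than 20% failed refits marks the fit unstable.
    """
    if n_boot < 1:
        raise ConfigError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    levels = np.asarray(design.levels, dtype=float)
    n = np.full(levels.size, design.reps_per_level)
    p = detect_prob(levels, fit.params)
    t60, t50, failed = [], [], 0
    for _ in range(n_boot):
        k = rng.binomial(n, p)
        try:
            refit = fit_weibull_ml(
                MocsDataset(levels=levels, presented=n, seen=k),
                gamma=fit.params.gamma,
                lapse=fit.params.lapse,
            )
        except FitError:
            failed += 1
            continue
        t60.append(refit.threshold_60)
        t50.append(refit.threshold_50)
    if failed > 0.2 * n_boot:
        raise FitError(f"{failed}/{n_boot} bootstrap refits failed: unstable fit")
    ddof = 1 if len(t60) > 1 else 0
    return BootstrapSE(
        se_60=float(np.std(t60, ddof=ddof)),
        se_50=float(np.std(t50, ddof=ddof)),
        n_boot=n_boot,
        n_failed=failed,
    )
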