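"""In-silico comparison of the adaptive procedures against ground truth.

For each simulated observer on a panel, run four Psi (REPT) staircases,
four MOBS staircases and one constant-stimuli (MOCS) session, then score:

* accuracy — absolute difference between the mean of the four staircase
  thresholds and the truth (both the observer's analytic 60% point,
  available in silico, and the MOCS fit, the proxy truth a human study
  must settle for);
* reliability — the standard deviation over the four repeated runs;
* cost — trial counts (Psi is fixed at 30; MOBS varies run to run).

All randomness is seeded, so a report is a deterministic function of the
panel and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ReptError
from .mobs import MobsConfig, run_mobs
from .mocs import design_mocs, fit_weibull_ml, run_mocs
from .observer import SimulatedObserver
from .psi import PsiConfig, run_rept

__all__ = ["ComparisonReport", "run_comparison"]


@dataclass(frozen=True)
class ComparisonReport:
    per_observer: pd.DataFrame
    summary: dict
    excluded: tuple[tuple[int, str], ...] = ()

    def to_json_dict(self) -> dict:
        return {
            "summary": self.summary,
            "excluded": [list(e) for e in self.excluded],
            "per_observer": self.per_observer.to_dict(orient="records"),
        }


def run_comparison(
    panel: list[SimulatedObserver],
    *,
    runs_per_procedure: int = 4,
    psi_config: PsiConfig | None = None,
    mobs_config: MobsConfig | None = None,
    mocs_reps: int = 25,
    seed: int = 0,
) -> ComparisonReport:
    """Score REPT vs MOBS against true and MOCS thresholds on a panel.

    Each observer's response stream is re-seeded per run from a
    reproducible spawn of ``seed``, so repeated staircases see
    independent noise while the whole report stays deterministic.
    """
    if not panel:
        raise ReptError("panel must be non-empty")
    psi_config = psi_config or PsiConfig()
    mobs_config = mobs_config or MobsConfig()
    rng = np.random.default_rng(seed)
    rows = []
    excluded: list[tuple[int, str]] = []
    for i, obs in enumerate(panel):
        try:
            true60 = obs.threshold_60
            rept_thresholds, rept_trials = [], []
            for _ in range(runs_per_procedure):
                runner = SimulatedObserver(
                    params=obs.params,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    mode=obs.mode,
                )
                res = run_rept(runner, psi_config)
                rept_thresholds.append(res.threshold)
                rept_trials.append(res.n_trials)
            mobs_thresholds, mobs_trials = [], []
            for _ in range(runs_per_procedure):
                runner = SimulatedObserver(
                    params=obs.params,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    mode=obs.mode,
                )
                res = run_mobs(runner, mobs_config)
                mobs_thresholds.append(res.threshold)
                mobs_trials.append(res.n_trials)
            pilot = float(np.mean(rept_thresholds))
            design = design_mocs(
                pilot, reps_per_level=mocs_reps, seed=int(rng.integers(0, 2**31 - 1))
            )
            runner = SimulatedObserver(
                params=obs.params, seed=int(rng.integers(0, 2**31 - 1)), mode=obs.mode
            )
            mocs_fit = fit_weibull_ml(run_mocs(runner, design))
        except ReptError as exc:
            excluded.append((i, str(exc)))
            continue
        rept_mean = float(np.mean(rept_thresholds))
        mobs_mean = float(np.mean(mobs_thresholds))
        rows.append(
            {
                "observer": i,
                "true_threshold_60": true60,
                "rept_mean": rept_mean,
                "mobs_mean": mobs_mean,
                "mocs_threshold_60": mocs_fit.threshold_60,
                "mocs_threshold_50": mocs_fit.threshold_50,
                "rept_abs_error": abs(rept_mean - true60),
                "mobs_abs_error": abs(mobs_mean - true60),
                "rept_abs_error_vs_mocs": abs(rept_mean - mocs_fit.threshold_60),
                "mobs_abs_error_vs_mocs": abs(mobs_mean - mocs_fit.threshold_60),
                "rept_sd": float(np.std(rept_thresholds, ddof=1)),
                "mobs_sd": float(np.std(mobs_thresholds, ddof=1)),
                "rept_trials_mean": float(np.mean(rept_trials)),
                "mobs_trials_mean": float(np.mean(mobs_trials)),
                "mobs_trials_sd": float(np.std(mobs_trials, ddof=1)),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ReptError("every observer was excluded; nothing to summarise")
    summary = {
        "n_observers": int(len(df)),
        "rept_mean_abs_error": float(df["rept_abs_error"].mean()),
        "mobs_mean_abs_error": float(df["mobs_abs_error"].mean()),
        "rept_mean_abs_error_vs_mocs": float(df["rept_abs_error_vs_mocs"].mean()),
        "mobs_mean_abs_error_vs_mocs": float(df["mobs_abs_error_vs_mocs"].mean()),
        "rept_mean_sd": float(df["rept_sd"].mean()),
        "mobs_mean_sd": float(df["mobs_sd"].mean()),
        "rept_mean_trials": float(df["rept_trials_mean"].mean()),
        "mobs_mean_trials": float(df["mobs_trials_mean"].mean()),
    }
    return ComparisonReport(per_observer=df, summary=summary, excluded=tuple(excluded))
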