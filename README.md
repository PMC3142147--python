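# rept — rapid estimation of phosphene thresholds

Calibrating transcranial magnetic stimulation (TMS) over visual cortex
requires the **phosphene threshold (PT)**: the stimulation intensity, in
percent of the stimulator's maximum output (%MSO), that elicits illusory
flashes of light on a criterion proportion of trials. This package
implements a hardware-free version of an automatic PT procedure built on
the **Ψ Bayesian adaptive staircase**, together with the two classic
comparators it is usually judged against:

* **Ψ staircase** (`rept.psi`) — maintains a discrete posterior
  p(α, β) over Weibull psychometric functions
  ψ(x) = γ + (1 − γ − λ)(1 − e^{−(x/α)^β}),
  picks each stimulus to minimise the one-step-ahead expected Shannon
  entropy of the posterior, always finishes in 30 trials, and reports the
  lapse-corrected 60%-accuracy threshold (plus a post-hoc 50% point).
* **MOBS** (`rept.mobs`) — the modified binary search: two boundary
  stacks, midpoint testing, retreat on repeated responses, termination
  after six response reversals.
* **MOCS** (`rept.mocs`) — the method of constant stimuli used as proxy
  ground truth: seven fixed levels presented 20–30 times each in random
  order, maximum-likelihood Weibull fit, parametric-bootstrap threshold
  errors.

Because no stimulator or participant is required, every procedure runs
against **simulated observers** (`rept.observer`): Bernoulli detectors
with known Weibull parameters, yes/no (γ = 0) or 2AFC (γ = 0.5). The
session layer (`rept.session`) adds the pulse-delivery contract with a
mock stimulator, a safety gate enforcing the minimum inter-pulse
interval, CSV/JSON session logs and bit-for-bit replay. The validation
module (`rept.validation`) reruns the whole comparison study in silico.

Intended users: TMS/psychophysics researchers who want a transparent,
testable reference implementation of these procedures, and anyone
studying adaptive threshold estimation.

## Worked example

```python
from rept import SimulatedObserver, WeibullParams, run_rept

observer = SimulatedObserver(WeibullParams(alpha=60, beta=10, gamma=0, lapse=0.04),
                             seed=1)
result = run_rept(observer)
print(f"trials: {result.n_trials}")
print(f"threshold (60% accuracy): {result.threshold:.2f} %MSO")
print(f"post-hoc 50% threshold:  {result.threshold_50:.2f} %MSO")
```

prints

```
trials: 30
threshold (60% accuracy): 62.19 %MSO
post-hoc 50% threshold:  61.15 %MSO
```

The observer's true 60% detection point is 59.88 %MSO; a single 30-trial
staircase typically lands within ±3 %MSO of it. The same run from the
shell, with a paced, logged session:

```sh
rept run --alpha 60 --beta 10 --seed 1 --out session
rept replay session                 # verifies the log reproduces itself
rept mobs run --alpha 60 --beta 10 --seed 2 --out mobs_session
rept mocs run --pilot 60 --alpha 60 --beta 10 --seed 3 --out mocs.csv
rept mocs fit --data mocs.csv
rept validate panel --n 10 --seed 0 --out report
```

`rept validate panel` compares the procedures over a panel of simulated
observers: four Ψ staircases and four MOBS runs per observer scored
against the observer's analytic 60% point and against the MOCS fit, with
per-run SDs and trial counts. The Ψ staircase is consistently the more
accurate and more repeatable of the two adaptive procedures.

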