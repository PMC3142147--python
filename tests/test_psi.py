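"""Psi staircase: Bayes updates, entropy bookkeeping, brute-force oracles."""

import math

import numpy as np
import pytest

from rept import (
    PsiConfig,
    SimulatedObserver,
    WeibullParams,
    detect_prob,
    expected_entropy,
    init_psi,
    next_intensity,
    posterior_entropy,
    run_rept,
    update_posterior,
)
from rept.errors import AbortedSessionError, ConfigError, StateError

from conftest import step_responder


def brute_force_expected_entropy(state, x):
    """Naive double-loop oracle for the expected posterior entropy at x."""
    xs = list(state.grid.x_values)
    idx = xs.index(float(x))
    post = list(state.posterior)
    total = 0.0
    for outcome in (0, 1):
        joint = []
        for i, p in enumerate(post):
            like = state.grid.likelihood[i, idx]
            joint.append(p * (like if outcome else 1.0 - like))
        p_outcome = sum(joint)
        h = 0.0
        for j in joint:
            q = j / p_outcome
            if q > 0:
                h -= q * math.log(q)
        total += p_outcome * h
    return total


class TestInit:
    def test_uniform_prior(self, small_psi_config):
        state = init_psi(small_psi_config)
        n = small_psi_config.alpha_values.size * small_psi_config.beta_values.size
        assert state.posterior.shape == (n,)
        assert np.allclose(state.posterior, 1.0 / n)
        assert state.posterior.sum() == pytest.approx(1.0, abs=1e-12)

    def test_likelihood_table_matches_detect_prob(self, small_psi_config):
        state = init_psi(small_psi_config)
        grid = state.grid
        for ia, ib, ix in [(0, 0, 0), (2, 3, 4), (4, 4, 6)]:
            expected = detect_prob(
                grid.x_values[ix],
                WeibullParams(
                    grid.alpha_values[ia],
                    grid.beta_values[ib],
                    small_psi_config.gamma,
                    small_psi_config.lapse,
                ),
            )
            assert grid.likelihood[ia * grid.n_beta + ib, ix] == pytest.approx(
                expected, abs=1e-9
            )

    @pytest.mark.parametrize(
        "bad_axis",
        [np.array([]), np.array([3.0, 2.0, 1.0]), np.array([1.0, 1.0, 2.0])],
    )
    def test_malformed_axes_rejected(self, bad_axis):
        with pytest.raises(ConfigError):
            init_psi(PsiConfig(alpha_values=bad_axis))


class TestExpectedEntropy:
    def test_matches_brute_force_oracle(self, small_psi_config):
        state = init_psi(small_psi_config)
        # sharpen the posterior a little first so the check is not trivial
        state = update_posterior(state, 60.0, 1)
        state = update_posterior(state, 40.0, 0)
        for x in state.grid.x_values:
            assert expected_entropy(state, x) == pytest.approx(
                brute_force_expected_entropy(state, x), abs=1e-12
            )

    def test_matches_oracle_on_random_posteriors_larger_grid(self):
        config = PsiConfig(
            alpha_values=np.linspace(20.0, 90.0, 10),
            beta_values=np.geomspace(1.0, 18.0, 10),
            x_values=np.linspace(5.0, 100.0, 20),
        )
        state = init_psi(config)
        rng = np.random.default_rng(11)
        post = rng.dirichlet(np.ones(state.posterior.size))
        state = type(state)(
            config=state.config, grid=state.grid, posterior=post, history=()
        )
        for x in state.grid.x_values[::4]:
            assert expected_entropy(state, x) == pytest.approx(
                brute_force_expected_entropy(state, x), abs=1e-12
            )

    def test_degenerate_posterior_has_zero_expected_entropy(self, small_psi_config):
        state = init_psi(small_psi_config)
        post = np.zeros_like(state.posterior)
        post[7] = 1.0
        state = type(state)(
            config=state.config, grid=state.grid, posterior=post, history=()
        )
        for x in state.grid.x_values:
            assert expected_entropy(state, x) == pytest.approx(0.0, abs=1e-12)

    def test_never_exceeds_current_entropy(self, small_psi_config):
        # conditioning cannot increase expected entropy
        rng = np.random.default_rng(5)
        state = init_psi(small_psi_config)
        for _ in range(5):
            post = rng.dirichlet(np.ones(state.posterior.size))
            state = type(state)(
                config=state.config, grid=state.grid, posterior=post, history=()
            )
            h_now = posterior_entropy(state)
            for x in state.grid.x_values:
                assert expected_entropy(state, x) <= h_now + 1e-12

    def test_off_grid_stimulus_rejected(self, small_psi_config):
        state = init_psi(small_psi_config)
        with pytest.raises(ConfigError):
            expected_entropy(state, 33.3)


class TestNextIntensity:
    def test_equals_exhaustive_argmin(self, small_psi_config):
        state = init_psi(small_psi_config)
        state = update_posterior(state, 50.0, 1)
        brute = [
            brute_force_expected_entropy(state, x) for x in state.grid.x_values
        ]
        assert next_intensity(state) == state.grid.x_values[int(np.argmin(brute))]

    def test_tie_broken_toward_lowest_intensity(self, small_psi_config):
        # a degenerate posterior makes every candidate an exact tie at 0
        state = init_psi(small_psi_config)
        post = np.zeros_like(state.posterior)
        post[0] = 1.0
        state = type(state)(
            config=state.config, grid=state.grid, posterior=post, history=()
        )
        assert next_intensity(state) == state.grid.x_values[0]

    def test_default_grid_returns_integer_percent(self):
        state = init_psi(PsiConfig())
        x = next_intensity(state)
        assert x == int(x) and 1 <= x <= 100

    def test_complete_staircase_rejected(self, small_psi_config):
        state = init_psi(small_psi_config)
        for _ in range(small_psi_config.max_trials):
            state = update_posterior(state, 50.0, 1)
        with pytest.raises(StateError):
            next_intensity(state)


class TestUpdatePosterior:
    def test_normalized_after_every_update(self, small_psi_config):
        state = init_psi(small_psi_config)
        responses = [1, 0, 1, 1, 0, 0, 1, 0]
        for r in responses:
            state = update_posterior(state, next_intensity(state), r)
            assert state.posterior.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(state.posterior >= 0)
        assert state.trial_count == len(responses)

    def test_updates_commute(self, small_psi_config):
        state = init_psi(small_psi_config)
        a = update_posterior(update_posterior(state, 60.0, 1), 60.0, 0)
        b = update_posterior(update_posterior(state, 60.0, 0), 60.0, 1)
        assert np.allclose(a.posterior, b.posterior, atol=1e-12)

    def test_matches_hand_computed_two_node_update(self):
        # pencil-and-paper Bayes step on a two-candidate grid
        config = PsiConfig(
            alpha_values=np.array([50.0, 70.0]),
            beta_values=np.array([5.0]),
            x_values=np.array([60.0]),
        )
        state = init_psi(config)
        state = update_posterior(state, 60.0, 1)
        psi50 = 0.96 * (1 - math.exp(-((60.0 / 50.0) ** 5)))
        psi70 = 0.96 * (1 - math.exp(-((60.0 / 70.0) ** 5)))
        expected = np.array([0.5 * psi50, 0.5 * psi70])
        expected /= expected.sum()
        assert np.allclose(state.posterior, expected, atol=1e-12)


class TestRunRept:
    def test_default_run_takes_exactly_30_trials(self, typical_observer):
        result = run_rept(typical_observer)
        assert result.n_trials == 30
        assert len(result.history) == 30

    def test_deterministic_given_responses(self, small_psi_config):
        responder = step_responder(57.0)
        r1 = run_rept(responder, small_psi_config)
        r2 = run_rept(responder, small_psi_config)
        assert [t.intensity for t in r1.history] == [t.intensity for t in r2.history]
        assert r1.threshold == r2.threshold

    def test_never_seen_drives_estimate_to_grid_top(self):
        result = run_rept(lambda x: 0)
        assert result.alpha_estimate > 90.0
        assert result.threshold > 90.0

    def test_entropy_descends_in_expectation(self):
        # averaged over simulated runs, posterior entropy falls with trials
        rng = np.random.default_rng(9)
        traces = []
        for _ in range(40):
            obs = SimulatedObserver(
                WeibullParams(60.0, 10.0, 0.0, 0.04),
                seed=int(rng.integers(2**31 - 1)),
            )
            traces.append(run_rept(obs).entropies)
        mean_trace = np.mean(traces, axis=0)
        assert np.all(np.diff(mean_trace) <= 1e-9)

    def test_parameter_recovery_on_simulated_panel(self):
        from rept import sample_observer_panel

        errors = []
        for obs in sample_observer_panel(30, seed=42):
            result = run_rept(obs)
            errors.append(abs(result.threshold - obs.threshold_60))
        assert np.median(errors) <= 3.0

    def test_responder_failure_aborts_with_partial_history(self):
        calls = []

        def flaky(x):
            calls.append(x)
            if len(calls) == 4:
                raise RuntimeError("keyboard unplugged")
            return 1

        with pytest.raises(AbortedSessionError) as err:
            run_rept(flaky)
        assert len(err.value.history) == 3
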