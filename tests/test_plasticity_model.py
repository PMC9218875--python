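"""TD circuit model: value, RPE, eligibility, weights, action selection."""

import math

import numpy as np
import pytest

from creditseq.plasticity_model import (
    PlasticityParams,
    compute_rpe,
    compute_value,
    integrate_trial,
    reward_kernel,
    run_plasticity_session,
    select_action,
    update_eligibility,
    update_weights,
)
from creditseq.synthetic_data import SequenceProfile, generate_sequence_trial
from creditseq.task_engine import TaskConfig


@pytest.fixture()
def params():
    return PlasticityParams()


class TestComputeValue:
    def test_zero_weights_give_zero_value(self):
        f = np.random.default_rng(0).random(10)
        assert compute_value(np.zeros(10), f, 5) == (0.0, 0.0, 0.0)

    def test_single_neuron_arithmetic(self):
        w = np.array([2.0, 0.0])
        f = np.array([0.5, 0.3])
        v_l, v_r, v = compute_value(w, f, 1)
        assert (v_l, v_r, v) == (1.0, 0.0, 1.0)

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(1)
        w, f = rng.random(8), rng.random(8)
        _, _, v1 = compute_value(w, f, 4)
        _, _, v2 = compute_value(2 * w, f, 4)
        assert v2 == pytest.approx(2 * v1)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            compute_value(np.zeros(3), np.zeros(4), 2)


class TestComputeRpe:
    def test_zero_value_zero_reward(self, params):
        assert compute_rpe(0.0, 0.0, 0.0, params) == 0.0

    def test_constant_value_decays_at_discount_rate(self, params):
        # V == 1, r = 0: delta = (gamma - 1)/Delta = (e^(-1/70) - 1)/0.01
        expected = (math.exp(-0.01 / 0.7) - 1.0) / 0.01
        assert compute_rpe(1.0, 1.0, 0.0, params) == pytest.approx(expected)
        assert expected == pytest.approx(-1.418, abs=1e-3)

    def test_reward_passes_through_when_value_is_zero(self, params):
        assert compute_rpe(0.0, 0.0, 3.25, params) == 3.25


class TestEligibility:
    def test_stays_zero_without_input(self, params):
        assert np.all(update_eligibility(np.zeros(4), np.zeros(4), params) == 0.0)

    def test_two_step_recursion(self, params):
        e = update_eligibility(np.zeros(1), np.ones(1), params)
        assert e[0] == pytest.approx(0.01)
        e = update_eligibility(e, np.zeros(1), params)
        assert e[0] == pytest.approx(0.01 * math.exp(-0.0125), rel=1e-9)
        assert e[0] == pytest.approx(0.009876, abs=1e-6)

    def test_pure_exponential_decay(self, params):
        e = np.array([1.0])
        for _ in range(80):  # 0.8 s = one time constant
            e = update_eligibility(e, np.zeros(1), params)
        assert e[0] == pytest.approx(math.exp(-1.0), rel=1e-9)


class TestWeightUpdate:
    def test_zero_rpe_leaves_weights(self):
        w_hat, w = update_weights(np.array([0.3]), 0.0, np.array([1.0]), 0.009, 0.01)
        assert w_hat[0] == 0.3 and w[0] == 0.3

    def test_forward_euler_arithmetic(self):
        w_hat, w = update_weights(np.array([0.1]), 10.0, np.array([1.0]), 0.009, 0.01)
        assert w[0] == pytest.approx(0.1009)

    def test_dale_clipping_exposes_zero(self):
        w_hat, w = update_weights(np.array([-0.05]), 0.0, np.array([0.0]), 0.009, 0.01)
        assert w_hat[0] == -0.05 and w[0] == 0.0


class TestRewardKernel:
    def test_unrewarded_trial_is_silent(self, params):
        t = np.arange(0, 3, 0.01)
        r, _ = reward_kernel(0, t, params, np.random.default_rng(0))
        assert np.all(r == 0.0)

    def test_peak_is_gaussian_density_maximum(self, params):
        t = np.arange(0, 3, 0.01)
        r, mu = reward_kernel(1, t, params, np.random.default_rng(0))
        assert r.max() == pytest.approx(1 / (0.3 * math.sqrt(2 * math.pi)), rel=1e-3)
        assert r.max() == pytest.approx(1.330, abs=2e-3)
        assert t[np.argmax(r)] == pytest.approx(mu, abs=0.011)

    def test_truncation_before_onset(self, params):
        t = np.arange(0, 3, 0.01)
        r, mu = reward_kernel(1, t, params, np.random.default_rng(1))
        assert np.all(r[t < mu - 0.2] == 0.0)
        assert np.any(r[t >= mu - 0.2] > 0.0)

    def test_mass_equals_truncated_gaussian_mass(self, params):
        from scipy.stats import norm

        t = np.arange(-0.5, 3.5, 0.01)
        masses = [
            np.trapezoid(reward_kernel(1, t, params, np.random.default_rng(s))[0], t)
            for s in range(20)
        ]
        assert np.mean(masses) == pytest.approx(1 - norm.cdf(-0.2 / 0.3), abs=0.01)


class TestSelectAction:
    def test_zero_weights_give_even_odds(self, params):
        choice, d_l, d_r, p_left = select_action(
            np.zeros(20), np.arange(5), 10 + np.arange(5), None, params, np.random.default_rng(0)
        )
        assert (d_l, d_r) == (0.0, 0.0)
        assert p_left == 0.5

    def test_stay_bias_closed_form(self, params):
        _, _, _, p_left = select_action(
            np.zeros(20), np.arange(5), 10 + np.arange(5), "left", params,
            np.random.default_rng(0),
        )
        assert p_left == pytest.approx(1 / (1 + math.exp(-0.15)))
        assert p_left == pytest.approx(0.537, abs=1e-3)

    def test_large_gain_is_greedy(self):
        params = PlasticityParams(beta_value=1e9)
        w = np.zeros(20)
        w[:5] = 1.0  # left onset neurons carry all the weight
        rng = np.random.default_rng(0)
        p_lefts = [
            select_action(w, np.arange(5), 10 + np.arange(5), None, params, rng)[3]
            for _ in range(20)
        ]
        assert min(p_lefts) > 0.999

    def test_probe_is_nonnegative_truncated_normal(self, params):
        # the decision variables inherit nonnegativity from the probe
        w = np.ones(20)
        rng = np.random.default_rng(0)
        for _ in range(50):
            _, d_l, d_r, _ = select_action(
                w, np.arange(5), 10 + np.arange(5), None, params, rng
            )
            assert d_l >= 0 and d_r >= 0


class TestIntegrateTrial:
    def _small_inputs(self, seed=0, n=6, t_len=60):
        rng = np.random.default_rng(seed)
        f = rng.random((n, t_len))
        r = np.zeros(t_len)
        r[40:50] = 1.0
        return f, r

    def test_matches_stepwise_reference_implementation(self):
        """The compiled loop must agree exactly with the op-level composition."""
        params = PlasticityParams()
        f, r = self._small_inputs()
        w = np.zeros(6)
        w_hat = np.zeros(6)
        out = integrate_trial(f.copy(), r.copy(), w, w_hat, 3, 5, params)

        # independent reference using the documented elementary operations
        w_ref = np.zeros(6)
        e = np.zeros(6)
        vals = np.zeros(f.shape[1])
        deltas = np.zeros(f.shape[1])
        for t in range(5, f.shape[1]):
            v_l, v_r, v = compute_value(w_ref, f[:, t], 3)
            v_del = vals[t - 1] if t - 1 >= 5 else 0.0
            d = compute_rpe(v, v_del, r[t], params)
            vals[t] = v
            deltas[t] = d
            e = update_eligibility(e, f[:, t], params)
            w_ref = np.maximum(w_ref + params.alpha * d * e * params.dt, 0.0)
        assert np.allclose(out["value"], vals, atol=1e-12)
        assert np.allclose(out["delta"], deltas, atol=1e-10)
        assert np.allclose(w, w_ref, atol=1e-14)

    def test_unclipped_accumulator_variant_retains_negative_drive(self):
        params = PlasticityParams(retain_unclipped_accumulator=True)
        f, _ = self._small_inputs()
        r = np.zeros(f.shape[1])  # persistent negative RPE from decaying value
        w = np.ones(6) * 1e-4
        w_hat = w.copy()
        integrate_trial(f, r - 0.5, w, w_hat, 3, 0, params)
        assert w_hat.min() < 0.0
        assert w.min() == 0.0

    def test_rpe_integral_conserves_reward_mass_on_surprise(self):
        # zero weights stay zero (nothing to learn without eligibility x RPE
        # overlap before reward), so integral(delta) = integral(r)
        params = PlasticityParams()
        prof = SequenceProfile(n_per_side=30)
        rng = np.random.default_rng(0)
        act = generate_sequence_trial("left", prof, rng)
        t = act.t_grid
        r, mu = reward_kernel(1, t, params, rng)
        w = np.zeros(60)
        w_hat = np.zeros(60)
        i_start = int(np.searchsorted(t, -2.5))
        out = integrate_trial(act.rates * 0.0, r, w, w_hat, 30, i_start, params)
        int_delta = out["delta"].sum() * params.dt
        int_r = r.sum() * params.dt
        assert int_delta == pytest.approx(int_r, rel=0.05)


class TestRunSession:
    def test_alpha_zero_freezes_weights_and_choice_statistics(self):
        params = PlasticityParams(alpha=0.0)
        prof = SequenceProfile(n_per_side=20)
        rng = np.random.default_rng(0)
        session, hist = run_plasticity_session(prof, TaskConfig(), params, 300, rng)
        assert np.all(hist.weights == 0.0)
        # stay-biased coin flips: overall stay probability 0.537, choice ~ 50/50
        c = session.choices()
        stay = np.mean(c[1:] == c[:-1])
        assert abs(np.mean(c == 1) - 0.5) < 0.1
        assert stay == pytest.approx(1 / (1 + math.exp(-0.15)), abs=0.06)

    def test_seeded_runs_are_bit_reproducible(self):
        prof = SequenceProfile(n_per_side=15)
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(3)
            session, hist = run_plasticity_session(prof, TaskConfig(), PlasticityParams(), 60, rng)
            outs.append((session.choices(), hist.weights, hist.da_feedback))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])
        assert np.array_equal(outs[0][2], outs[1][2])

    def test_weights_remain_nonnegative_throughout(self):
        prof = SequenceProfile(n_per_side=15)
        rng = np.random.default_rng(0)
        _, hist = run_plasticity_session(
            prof, TaskConfig(), PlasticityParams(), 200, rng, snapshot_every=20
        )
        assert hist.weight_snapshots.min() >= 0.0

    def test_current_trial_choice_blind_to_stimulation(self):
        # the probe readout precedes the stimulation window, so the
        # stimulated-trial choice distribution matches unstimulated trials
        prof = SequenceProfile(n_per_side=20)
        rng = np.random.default_rng(1)
        session, _ = run_plasticity_session(
            prof, TaskConfig(), PlasticityParams(), 2000, rng, stim_fraction_of_trials=0.5
        )
        c = session.choices()
        s = session.stimulated()
        p_right_stim = np.mean(c[s] == 1)
        p_right_unstim = np.mean(c[~s] == 1)
        assert abs(p_right_stim - p_right_unstim) < 0.07
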