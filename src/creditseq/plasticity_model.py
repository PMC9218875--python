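"""Synaptic-plasticity TD circuit model driven by choice-selective sequences.

The model learns the value of each lever using dopamine-gated plasticity of
cortex-to-striatum synapses. Value is a weighted sum of the choice-selective
temporal basis functions f_i(t) (one striatal neuron per input neuron):

    V_L(t) = sum_i w_i^L f_i^L(t),  V_R(t) = sum_i w_i^R f_i^R(t),
    V(t) = V_L(t) + V_R(t)

The reward prediction error is carried by dopamine neurons receiving a reward
input, a discounted value input and a delayed, sign-inverted value input
through an inhibitory interneuron with delay Delta:

    delta(t) = r(t) + (gamma V(t) - V(t - Delta)) / Delta,
    gamma = exp(-Delta / tau)

Each synapse carries an exponentially decaying eligibility trace
E_i <- exp(-dt/tau_e) E_i + f_i(t) dt, and weights integrate
dw_i/dt = alpha delta(t) E_i(t) with forward Euler; the exposed weights are
clipped at zero (Dale constraint) while the unclipped accumulator is retained.

Action selection reads out the summed activity of the earliest-firing
("onset") striatal neurons of each side during a 50 ms noisy probe just
before the sequence starts, and passes the two decision variables through a
softmax with a stay-with-previous-choice bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from numba import njit
from scipy.stats import truncnorm

from .synthetic_data import SequenceProfile, generate_sequence_trial
from .task_engine import BlockSchedule, SessionRecord, TaskConfig, TrialRecord


@dataclass(frozen=True)
class PlasticityParams:
    tau_discount: float = 0.7  # value discounting timescale tau (s)
    delta: float = 0.01  # interneuron pathway delay Delta (s)
    dt: float = 0.01
    tau_e: float = 0.8  # eligibility decay (s)
    alpha: float = 0.009  # learning rate, per (spikes/s)
    beta_value: float = 7000.0  # softmax gain on the decision variables
    beta_stay: float = 0.15  # stay-with-previous-choice bias
    probe_duration: float = 0.05  # s
    probe_mean: float = 0.05  # probe input mean rate (fraction of unit peak)
    probe_sd_coeff: float = 0.0025  # probe sd = probe_sd_coeff / dt (taken literally)
    n_probe: Optional[int] = None  # onset neurons per side; None -> 18.5% rule
    reward_mu_range: tuple = (0.2, 1.2)  # peak-reward time, uniform (s post press)
    reward_sigma: float = 0.3  # reward kernel width (s)
    t_start_mean: float = -2.5  # update onset ~ N(mean, sd), s relative to press
    t_start_sd: float = 0.2
    t_end: float = 3.0  # updates stop here (s post press)
    # If True, integrate an unclipped accumulator and expose w = max(0, w_hat).
    # Default False: the Dale clip applies to the integration state itself,
    # which avoids a hysteretic ratchet (weights stuck deep below zero) that
    # slows reversals far beyond the behaviour the model is meant to capture.
    retain_unclipped_accumulator: bool = False

    def __post_init__(self) -> None:
        for name in ("tau_discount", "delta", "dt", "tau_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.delta < self.dt:
            raise ValueError("delta must be at least one time step")

    @property
    def gamma(self) -> float:
        return math.exp(-self.delta / self.tau_discount)

    @property
    def probe_sd(self) -> float:
        return self.probe_sd_coeff / self.dt

    def n_probe_for(self, n_per_side: int) -> int:
        # the earliest ~18.5% of peak times per side (17 of 92 recorded units)
        if self.n_probe is not None:
            return self.n_probe
        return max(1, round(n_per_side * 17 / 92))


@dataclass
class PlasticityHistory:
    """Per-trial record of the circuit's internal variables."""

    d_left: np.ndarray
    d_right: np.ndarray
    p_left: np.ndarray
    da_feedback: np.ndarray  # mean delta 0.2-1.2 s after outcome feedback
    mu_r: np.ndarray
    t_start: np.ndarray
    weights: np.ndarray  # final exposed weights
    weights_unclipped: np.ndarray
    weight_snapshots: Optional[np.ndarray] = None  # (n_snapshots, n_neurons)
    snapshot_trials: Optional[np.ndarray] = None
    delta_traces: Optional[list] = None
    value_traces: Optional[list] = None
    t_grid: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# elementary operations (unit-testable forms of the update equations)


def compute_value(weights: np.ndarray, activity_sample: np.ndarray, n_left: int) -> tuple:
    """(V_L, V_R, V) for one time sample; neurons ordered left block then right."""
    if weights.shape != activity_sample.shape:
        raise ValueError("weights and activity must align by neuron")
    v_l = float(weights[:n_left] @ activity_sample[:n_left])
    v_r = float(weights[n_left:] @ activity_sample[n_left:])
    return v_l, v_r, v_l + v_r


def compute_rpe(v_now: float, v_delayed: float, r_now: float, params: PlasticityParams) -> float:
    """delta(t) = r(t) + (gamma V(t) - V(t-Delta)) / Delta."""
    return r_now + (params.gamma * v_now - v_delayed) / params.delta


def update_eligibility(e: np.ndarray, f_now: np.ndarray, params: PlasticityParams) -> np.ndarray:
    return math.exp(-params.dt / params.tau_e) * e + f_now * params.dt


def update_weights(
    w_hat: np.ndarray, delta: float, e: np.ndarray, alpha: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-Euler step on the unclipped accumulator; exposed w = max(0, w_hat)."""
    w_hat = w_hat + alpha * delta * e * dt
    return w_hat, np.maximum(w_hat, 0.0)


def reward_kernel(
    outcome: int,
    t_grid: np.ndarray,
    params: PlasticityParams,
    rng: np.random.Generator,
    mu_r: Optional[float] = None,
) -> tuple[np.ndarray, float]:
    """Truncated-Gaussian reward input r(t); returns (r, mu_r).

    The kernel is the Gaussian density N(mu_r, sigma_r) scaled by the outcome
    and zeroed for t < mu_r - 0.2 s; no renormalisation is applied, so the
    integrated reward on a rewarded trial equals the truncated mass (~0.75).
    """
    lo, hi = params.reward_mu_range
    if mu_r is None:
        mu_r = float(rng.uniform(lo, hi))
    sig = params.reward_sigma
    r = outcome * np.exp(-0.5 * ((t_grid - mu_r) / sig) ** 2) / (sig * math.sqrt(2 * math.pi))
    r[t_grid < mu_r - 0.2] = 0.0
    return r, mu_r


def select_action(
    weights: np.ndarray,
    onset_left: np.ndarray,
    onset_right: np.ndarray,
    prev_choice: Optional[str],
    params: PlasticityParams,
    rng: np.random.Generator,
) -> tuple[str, float, float, float]:
    """Probe-based probabilistic readout of the relative action values.

    A 50 ms truncated-normal noise probe drives the onset neurons of each
    side; the decision variables are the probe-averaged weighted sums, and the
    choice is a softmax of beta_value * d plus the stay bias.
    Returns (choice, d_left, d_right, p_left).
    """
    n_steps = max(1, int(round(params.probe_duration / params.dt)))
    a = (0.0 - params.probe_mean) / params.probe_sd  # truncation at zero
    size = (n_steps, len(onset_left) + len(onset_right))
    probe = truncnorm.rvs(
        a, np.inf, loc=params.probe_mean, scale=params.probe_sd, size=size, random_state=rng
    )
    n_l = len(onset_left)
    d_left = float(np.mean(probe[:, :n_l] @ weights[onset_left]))
    d_right = float(np.mean(probe[:, n_l:] @ weights[onset_right]))
    b_l = params.beta_value * d_left + (params.beta_stay if prev_choice == "left" else 0.0)
    b_r = params.beta_value * d_right + (params.beta_stay if prev_choice == "right" else 0.0)
    m = max(b_l, b_r)
    p_left = math.exp(b_l - m) / (math.exp(b_l - m) + math.exp(b_r - m))
    choice = "left" if rng.random() < p_left else "right"
    return choice, d_left, d_right, p_left


# ---------------------------------------------------------------------------
# within-trial TD integration (compiled inner loop)


@njit(cache=False)
def _td_trial(
    f, r, w, w_hat, e, i_start, n_left, gamma, delta_s, delay_steps, dt, decay_e, alpha, retain
):
    n, T = f.shape
    delta = np.zeros(T)
    value = np.zeros(T)
    v_left = np.zeros(T)
    v_right = np.zeros(T)
    for t in range(i_start, T):
        vl = 0.0
        vr = 0.0
        for i in range(n_left):
            vl += w[i] * f[i, t]
        for i in range(n_left, n):
            vr += w[i] * f[i, t]
        v = vl + vr
        td = t - delay_steps
        vd = value[td] if td >= i_start else 0.0
        d = r[t] + (gamma * v - vd) / delta_s
        delta[t] = d
        value[t] = v
        v_left[t] = vl
        v_right[t] = vr
        a_eff = alpha * d * dt
        if retain:
            # hidden accumulator integrates unclipped; exposed weight clipped
            for i in range(n):
                e[i] = decay_e * e[i] + f[i, t] * dt
                w_hat[i] += a_eff * e[i]
                w[i] = w_hat[i] if w_hat[i] > 0.0 else 0.0
        else:
            # the clipped weight itself is the integration state
            for i in range(n):
                e[i] = decay_e * e[i] + f[i, t] * dt
                wn = w[i] + a_eff * e[i]
                w[i] = wn if wn > 0.0 else 0.0
                w_hat[i] = w[i]
    return delta, value, v_left, v_right


def integrate_trial(
    f: np.ndarray,
    r: np.ndarray,
    w: np.ndarray,
    w_hat: np.ndarray,
    n_left: int,
    i_start: int,
    params: PlasticityParams,
) -> dict:
    """Run one trial's TD integration in place on (w, w_hat).

    The eligibility trace is reset to zero at trial start; updates run from
    ``i_start`` to the end of the grid. Returns the delta/value traces.
    """
    e = np.zeros(len(w))
    delay_steps = max(1, int(round(params.delta / params.dt)))
    delta, value, v_l, v_r = _td_trial(
        np.ascontiguousarray(f),
        np.ascontiguousarray(r),
        w,
        w_hat,
        e,
        i_start,
        n_left,
        params.gamma,
        params.delta,
        delay_steps,
        params.dt,
        math.exp(-params.dt / params.tau_e),
        params.alpha,
        params.retain_unclipped_accumulator,
    )
    return {"delta": delta, "value": value, "v_left": v_l, "v_right": v_r, "eligibility": e}


# ---------------------------------------------------------------------------
# full session


def run_plasticity_session(
    input_source: Union[SequenceProfile, str],
    task: TaskConfig,
    params: PlasticityParams,
    n_trials: int,
    rng: np.random.Generator,
    stim_fraction_of_trials: float = 0.0,
    stim_neuron_fraction: float = 0.7,
    store_traces: bool = False,
    snapshot_every: Optional[int] = None,
    seed: Optional[int] = None,
) -> tuple[SessionRecord, PlasticityHistory]:
    """Simulate the full circuit over ``n_trials`` of the reversal task.

    Per trial: select the action from the probe readout; play the chosen
    side's sequence (or clamped activity on a stimulation trial); integrate
    value, RPE, eligibility and weights from a random start time
    ~N(t_start_mean, t_start_sd) to ``t_end``; draw the outcome by the task's
    block rules. Weights carry across trials, eligibility does not.
    """
    from .synthetic_data import make_profile_preset

    profile = make_profile_preset(input_source) if isinstance(input_source, str) else input_source
    if abs(profile.dt - params.dt) > 1e-12:
        raise ValueError("profile and params must share dt")

    t_grid = profile.t_grid
    n_side = profile.n_per_side
    n_total = 2 * n_side
    n_probe = params.n_probe_for(n_side)
    onset_left = np.arange(n_probe)
    onset_right = n_side + np.arange(n_probe)

    schedule = BlockSchedule(task, rng)
    w = np.zeros(n_total)
    w_hat = np.zeros(n_total)

    d_left = np.zeros(n_trials)
    d_right = np.zeros(n_trials)
    p_left_arr = np.zeros(n_trials)
    da = np.zeros(n_trials)
    mu_arr = np.zeros(n_trials)
    ts_arr = np.zeros(n_trials)
    trials: list[TrialRecord] = []
    delta_traces = [] if store_traces else None
    value_traces = [] if store_traces else None
    snaps = [] if snapshot_every else None
    snap_at = [] if snapshot_every else None

    prev_choice: Optional[str] = None
    for i in range(n_trials):
        schedule.maybe_reverse_pre_trial()
        choice, dl, dr, pl = select_action(w, onset_left, onset_right, prev_choice, params, rng)
        outcome = schedule.draw_outcome(choice)
        block = schedule.block
        schedule.advance_post_trial(outcome)

        stimulated = rng.random() < stim_fraction_of_trials
        t_start = float(
            np.clip(rng.normal(params.t_start_mean, params.t_start_sd), t_grid[0], -1.0)
        )
        i_start = int(np.searchsorted(t_grid, t_start))

        activity = generate_sequence_trial(choice, profile, rng)
        f = activity.rates
        r, mu_r = reward_kernel(outcome, t_grid, params, rng)
        t_cs = mu_r - 0.2  # outcome feedback (CS) leads the reward peak
        if stimulated:
            # clamp a random subset to 0.2 from the simulated nose poke until
            # 2 s after reward presentation (CS reference on unrewarded trials)
            selected = rng.random(n_total) < stim_neuron_fraction
            window = (t_grid >= t_start) & (t_grid <= min(params.t_end, t_cs + 2.0))
            f = f.copy()
            f[np.ix_(selected, window)] = 0.2

        out = integrate_trial(f, r, w, w_hat, n_side, i_start, params)

        fb = (t_grid >= t_cs + 0.2) & (t_grid <= t_cs + 1.2)
        da[i] = float(out["delta"][fb].mean())
        d_left[i], d_right[i], p_left_arr[i] = dl, dr, pl
        mu_arr[i], ts_arr[i] = mu_r, t_start
        ev = {
            "nose_poke": t_start,
            "levers_out": t_start / 2.0,
            "lever_press": 0.0,
            "cs": t_cs,
        }
        if outcome:
            ev["reward_consumption"] = t_cs + 0.5
        trials.append(
            TrialRecord(
                index=i,
                choice=choice,
                outcome=outcome,
                block=block,
                stimulated=bool(stimulated),
                event_times=ev,
            )
        )
        if store_traces:
            delta_traces.append(out["delta"])
            value_traces.append(out["value"])
        if snapshot_every and (i % snapshot_every == 0 or i == n_trials - 1):
            snaps.append(w.copy())
            snap_at.append(i)
        prev_choice = choice

    history = PlasticityHistory(
        d_left=d_left,
        d_right=d_right,
        p_left=p_left_arr,
        da_feedback=da,
        mu_r=mu_arr,
        t_start=ts_arr,
        weights=w,
        weights_unclipped=w_hat,
        weight_snapshots=np.array(snaps) if snaps else None,
        snapshot_trials=np.array(snap_at) if snap_at else None,
        delta_traces=delta_traces,
        value_traces=value_traces,
        t_grid=t_grid,
    )
    session = SessionRecord(trials=trials, config=task, seed=seed)
    return session, history
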