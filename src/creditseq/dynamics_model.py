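"""Actor-critic recurrent-network model of reversal learning without plasticity.

Two LSTM networks are trained slowly with advantage actor-critic (A2C) and
then frozen; at test time, reversal learning happens purely through the
networks' recurrent dynamics. The critic receives the choice-selective
sequential input f(t) and the previous step's reward and reads out a value
V(t); dopamine carries the RPE delta(t) = r + gamma V(t) - V(t - dt) to the
actor, which also receives an efference copy of the previous action and a
one-hot temporal context, and emits a 3-way policy (left / right / do
nothing).

Trial grammar: each trial spans ``steps_per_trial`` = 42 steps of dt = 0.1 s
(40 sequence steps covering -2..+2 s around the lever press plus a decision
registration step and an end-of-trial step whose discount is 0). A left or
right press is meaningful only on the first step of a trial; acting at any
other step, or choosing 'do nothing' on the first step, is penalised with
reward -1. Episodes are ``trials_per_episode`` trials with hidden states
reset at episode start.

The LSTM forward/backward passes are written directly in NumPy (batched over
episodes) and verified against finite differences; training uses RMSprop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .task_engine import BlockSchedule, SessionRecord, TaskConfig, TrialRecord

N_ACTIONS = 3  # left, right, do nothing
ACTION_NAMES = ("left", "right", "none")


@dataclass(frozen=True)
class DynamicsConfig:
    n_units: int = 128
    n_input_neurons: int = 306  # critic sequence input (split evenly by side)
    trials_per_episode: int = 15
    steps_per_trial: int = 42
    dt: float = 0.1
    tau_discount: float = 2.5  # per-step gamma = exp(-dt/tau) ~ 0.96
    beta_v: float = 0.05
    beta_e: float = 0.05
    learning_rate: float = 0.001
    rho: float = 0.9  # RMSprop decay
    eps: float = 1e-7
    n_episodes: int = 62000
    batch_size: int = 1
    penalty: float = -1.0
    press_step: int = 21  # lever press lands 2 s into the 40 sequence steps
    reward_mu_range: tuple = (0.2, 1.2)
    reward_sigma: float = 0.3
    # training-task block hazard (per-trial reversal probability); see the
    # module docs for why reversals must be unpredictable during training
    train_hazard: float = 0.1
    input_amplitude: float = 1.0
    input_jitter_sd: float = 0.1
    input_amp_noise_sd: float = 0.3
    input_selectivity: float = 0.1
    bump_width: float = 0.36  # effective (smoothed) bump sd, s
    discount_immediate: bool = True  # the immediate reward is also discounted by gamma_t

    @property
    def gamma(self) -> float:
        return math.exp(-self.dt / self.tau_discount)

    @property
    def episode_steps(self) -> int:
        return self.trials_per_episode * self.steps_per_trial

    @property
    def actor_input_dim(self) -> int:
        return N_ACTIONS + self.steps_per_trial + 1  # prev action, context, RPE

    @property
    def critic_input_dim(self) -> int:
        return self.n_input_neurons + 1  # sequence + previous reward

    @classmethod
    def desk(cls, **overrides) -> "DynamicsConfig":
        """Scaled-down configuration for single-CPU experiments.

        Shorter trials (1.6 s, press 0.8 s in), 10-trial episodes, 24 units
        and ~10^4 episodes in minibatches of 12; the entropy weight and
        learning rate are raised to suit the smaller network and budget.
        """
        base = dict(
            n_units=24,
            n_input_neurons=40,
            trials_per_episode=10,
            steps_per_trial=16,
            press_step=8,
            reward_mu_range=(0.2, 0.5),
            reward_sigma=0.2,
            beta_e=0.15,
            learning_rate=0.003,
            n_episodes=10000,
            batch_size=12,
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# LSTM primitives (gate order: forget phi, input i, output o, candidate c)


@dataclass
class LSTMWeights:
    w: np.ndarray  # (4H, D) input weights
    u: np.ndarray  # (4H, H) recurrent weights
    b: np.ndarray  # (4H,)

    @classmethod
    def init(cls, n_units: int, n_in: int, rng: np.random.Generator) -> "LSTMWeights":
        # Keras-LSTM-style initialization: Glorot-uniform input weights,
        # orthogonal recurrent weights (per gate block), zero biases except a
        # unit forget-gate bias, which is what lets an untrained network hold
        # information across the trial
        limit = math.sqrt(6.0 / (n_in + n_units))
        w = rng.uniform(-limit, limit, size=(4 * n_units, n_in))
        u = np.vstack([_orthogonal((n_units, n_units), rng) for _ in range(4)])
        b = np.zeros(4 * n_units)
        b[:n_units] = 1.0  # forget gate block
        return cls(w=w, u=u, b=b)


def _orthogonal(shape: tuple, rng: np.random.Generator) -> np.ndarray:
    rows, cols = shape
    a = rng.normal(size=(max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q[:rows, :cols] if rows >= cols else q.T[:rows, :cols]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # exp underflow for very negative arguments harmlessly rounds to 0
    with np.errstate(over="ignore", under="ignore"):
        out = np.exp(np.minimum(-x, 700.0))
    out += 1.0
    np.reciprocal(out, out=out)
    return out


def lstm_step(state: tuple, x: np.ndarray, weights: LSTMWeights) -> tuple:
    """One LSTM step; ``state`` is (h, c), each (B, H); ``x`` is (B, D).

    Returns (h', c', cache) with the gate activations cached for backprop.
    """
    h, c = state
    if x.shape[1] != weights.w.shape[1]:
        raise ValueError("input dimension mismatch")
    hh = weights.u.shape[1]
    z = x @ weights.w.T + h @ weights.u.T + weights.b
    gates = _sigmoid(z[:, : 3 * hh])
    phi = gates[:, :hh]
    gi = gates[:, hh : 2 * hh]
    go = gates[:, 2 * hh :]
    gc = np.tanh(z[:, 3 * hh :])
    c_new = phi * c + gi * gc
    tc = np.tanh(c_new)
    h_new = go * tc
    cache = (x, h, c, phi, gi, go, gc, tc)
    return h_new, c_new, cache


def lstm_backward(
    dh: np.ndarray,
    dc: np.ndarray,
    cache: tuple,
    weights: LSTMWeights,
    grads: dict,
) -> tuple:
    """Backward through one LSTM step.

    ``dh``/``dc`` are the gradients flowing into h(t), c(t); returns
    (dh_prev, dc_prev, dx) and accumulates parameter gradients in ``grads``
    (keys w, u, b).
    """
    x, h_prev, c_prev, phi, gi, go, gc, tc = cache
    dgo = dh * tc
    dcc = dc + dh * go * (1.0 - tc * tc)
    dc_prev = dcc * phi
    dz = np.concatenate(
        [
            dcc * c_prev * phi * (1.0 - phi),
            dcc * gc * gi * (1.0 - gi),
            dgo * go * (1.0 - go),
            dcc * gi * (1.0 - gc * gc),
        ],
        axis=1,
    )
    grads["w"] += dz.T @ x
    grads["u"] += dz.T @ h_prev
    grads["b"] += dz.sum(axis=0)
    dh_prev = dz @ weights.u
    dx = dz @ weights.w
    return dh_prev, dc_prev, dx


# ---------------------------------------------------------------------------
# returns and RPE


def compute_rpe_dyn(v_now: float, v_prev: float, r_now: float, gamma: float) -> float:
    """delta = r + gamma V(t) - V(t - dt); V_prev = 0 on the first step."""
    return r_now + gamma * v_now - v_prev


def kstep_return(
    rewards: np.ndarray, gammas: np.ndarray, terminal_value: float, discount_immediate: bool = True
) -> float:
    """Discounted k-step bootstrapped return for the first of k steps.

    ``rewards`` has length k, ``gammas`` length k+1 (gamma_t .. gamma_{t+k}).
    In the default form the immediate reward is itself discounted by gamma_t:
    R_t = sum_i r_{t+i} prod_{j<=i} gamma_{t+j} + V prod_{j<=k} gamma_{t+j};
    ``discount_immediate=False`` gives the conventional form with r_t
    undiscounted.
    """
    rewards = np.asarray(rewards, dtype=float)
    gammas = np.asarray(gammas, dtype=float)
    k = len(rewards)
    if len(gammas) != k + 1:
        raise ValueError("need k+1 gammas for k rewards")
    total = 0.0
    prod = 1.0
    for i in range(k):
        if discount_immediate:
            prod *= gammas[i]
            total += rewards[i] * prod
        else:
            total += rewards[i] * prod
            prod *= gammas[i]
    prod *= gammas[k] if discount_immediate else 1.0
    return float(total + terminal_value * prod)


def _returns_backward(rewards: np.ndarray, gammas: np.ndarray, discount_immediate: bool) -> np.ndarray:
    """Per-step returns over an episode, vectorised over the batch axis.

    rewards, gammas: (T, B). Recursion R_t = gamma_t (r_t + R_{t+1}) in the
    default form, R_t = r_t + gamma_t R_{t+1} conventionally; R after the
    final step is 0 (every episode ends on a gamma = 0 trial-end step).
    """
    t_len, b = rewards.shape
    out = np.zeros((t_len, b))
    nxt = np.zeros(b)
    for t in range(t_len - 1, -1, -1):
        if discount_immediate:
            nxt = gammas[t] * (rewards[t] + nxt)
        else:
            nxt = rewards[t] + gammas[t] * nxt
        out[t] = nxt
    return out


# ---------------------------------------------------------------------------
# agent


@dataclass
class DynamicsAgent:
    config: DynamicsConfig
    critic: LSTMWeights
    actor: LSTMWeights
    w_v: np.ndarray  # (H,)
    b_v: float
    w_pi: np.ndarray  # (3, H)
    b_pi: np.ndarray  # (3,)

    @classmethod
    def init(cls, config: DynamicsConfig, rng: np.random.Generator) -> "DynamicsAgent":
        h = config.n_units
        critic = LSTMWeights.init(h, config.critic_input_dim, rng)
        actor = LSTMWeights.init(h, config.actor_input_dim, rng)
        limit = math.sqrt(6.0 / (h + 1))
        w_v = rng.uniform(-limit, limit, size=h)
        limit = math.sqrt(6.0 / (h + N_ACTIONS))
        w_pi = rng.uniform(-limit, limit, size=(N_ACTIONS, h))
        return cls(config, critic, actor, w_v, 0.0, w_pi, np.zeros(N_ACTIONS))

    def parameters(self) -> dict:
        return {
            "c.w": self.critic.w,
            "c.u": self.critic.u,
            "c.b": self.critic.b,
            "a.w": self.actor.w,
            "a.u": self.actor.u,
            "a.b": self.actor.b,
            "w_v": self.w_v,
            "w_pi": self.w_pi,
            "b_pi": self.b_pi,
        }

    @property
    def choice_readout(self) -> np.ndarray:
        """Left-minus-right policy readout direction in actor state space."""
        return self.w_pi[0] - self.w_pi[1]


# ---------------------------------------------------------------------------
# task inputs


def _trial_sequence(
    choice_idx: int, cfg: DynamicsConfig, rng: np.random.Generator, persistent: bool
) -> np.ndarray:
    """Critic input (n_input_neurons, steps_per_trial) for one trial."""
    n = cfg.n_input_neurons
    s = cfg.steps_per_trial
    f = np.zeros((n, s))
    if choice_idx == 2:  # do nothing: zeros for the rest of the trial
        return f
    half = n // 2
    chosen = slice(0, half) if choice_idx == 0 else slice(half, n)
    other = slice(half, n) if choice_idx == 0 else slice(0, half)
    if persistent:
        f[chosen, 1:] = cfg.input_amplitude
        return f
    t = -2.0 + cfg.dt * np.arange(s - 2)  # sequence occupies steps 1..S-2
    peaks = np.linspace(-2.0, 2.0 - cfg.dt, half)
    for sl, gain in ((chosen, 1.0), (other, cfg.input_selectivity)):
        mu = peaks + rng.normal(0.0, cfg.input_jitter_sd, half)
        amp = np.clip(1.0 + rng.normal(0.0, cfg.input_amp_noise_sd, half), 0.0, None)
        z = (t[None, :] - mu[:, None]) / cfg.bump_width
        f[sl, 1 : s - 1] = gain * cfg.input_amplitude * amp[:, None] * np.exp(-0.5 * z * z)
    return f


def _trial_reward_profile(
    outcome: int, cfg: DynamicsConfig, rng: np.random.Generator
) -> np.ndarray:
    """Reward input r(t) over the trial (truncated Gaussian at the peak time)."""
    s = cfg.steps_per_trial
    mu = rng.uniform(*cfg.reward_mu_range)
    sig = cfg.reward_sigma
    tt = cfg.dt * (np.arange(s) - cfg.press_step)  # time relative to press
    r = outcome * np.exp(-0.5 * ((tt - mu) / sig) ** 2) / (sig * math.sqrt(2 * math.pi))
    r[tt < mu - 0.2] = 0.0
    r[0] = 0.0
    return r


class _EpisodeBatch:
    """Vectorised environment state for a batch of independent episodes."""

    def __init__(
        self,
        cfg: DynamicsConfig,
        task: TaskConfig,
        batch: int,
        rng: np.random.Generator,
        persistent: bool = False,
        stim_fraction: float = 0.0,
        fixed_block_length: Optional[int] = None,
    ):
        self.cfg = cfg
        self.rng = rng
        self.persistent = persistent
        self.stim_fraction = stim_fraction
        self.fixed_block_length = fixed_block_length
        self.schedules = [BlockSchedule(task, rng) for _ in range(batch)]
        self.batch = batch
        self.f = np.zeros((batch, cfg.n_input_neurons, cfg.steps_per_trial))
        self.r_profile = np.zeros((batch, cfg.steps_per_trial))
        self.outcomes = np.zeros(batch, dtype=int)
        self.stimulated = np.zeros(batch, dtype=bool)
        self.blocks = [s.block for s in self.schedules]
        self.trial_count = 0

    def begin_trial(self, choices: np.ndarray) -> None:
        """Resolve outcomes and build the trial's inputs from step-0 choices."""
        cfg = self.cfg
        for b, sched in enumerate(self.schedules):
            if self.fixed_block_length is None:
                sched.maybe_reverse_pre_trial()
            elif self.trial_count > 0 and self.trial_count % self.fixed_block_length == 0:
                sched._flip()
            ci = int(choices[b])
            self.blocks[b] = sched.block
            if ci == 2:
                self.outcomes[b] = 0
            else:
                self.outcomes[b] = sched.draw_outcome(ACTION_NAMES[ci])
                sched.advance_post_trial(self.outcomes[b])
            self.f[b] = _trial_sequence(ci, cfg, self.rng, self.persistent)
            self.stimulated[b] = self.rng.random() < self.stim_fraction
            if self.stimulated[b]:
                sel = self.rng.random(cfg.n_input_neurons) < 0.7
                self.f[b, sel, :] = 0.15
            self.r_profile[b] = _trial_reward_profile(self.outcomes[b], cfg, self.rng)
        self.trial_count += 1


# ---------------------------------------------------------------------------
# rollout (shared by training and frozen-weight testing)


def run_episode(
    agent: DynamicsAgent,
    env: _EpisodeBatch,
    rng: np.random.Generator,
    cache: bool = False,
    greedy: bool = False,
):
    """Roll one batched episode; returns a trajectory dict.

    Per step: the critic sees [f(t), r(t-1)] and emits V(t); the RPE input to
    the actor is delta(t) = r(t-1) + gamma V(t) - V(t-1); the actor sees
    [one-hot a(t-1), temporal context, delta(t)] and samples an action.
    Choosing left/right on a trial's first step triggers that trial's
    sequence and reward profile; wrong-time actions are penalised.
    """
    cfg = agent.config
    b = env.batch
    h = cfg.n_units
    s_trial = cfg.steps_per_trial
    t_total = cfg.trials_per_episode * s_trial
    hc = np.zeros((b, h))
    cc = np.zeros((b, h))
    ha = np.zeros((b, h))
    ca = np.zeros((b, h))
    v_prev = np.zeros(b)
    r_prev = np.zeros(b)
    prev_action = np.full(b, 2, dtype=int)  # "do nothing" before the episode

    traj = {
        "rewards": np.zeros((t_total, b)),
        "gammas": np.zeros((t_total, b)),
        "values": np.zeros((t_total, b)),
        "actions": np.zeros((t_total, b), dtype=int),
        "pis": np.zeros((t_total, b, N_ACTIONS)),
        "rpe": np.zeros((t_total, b)),
        "caches_c": [] if cache else None,
        "caches_a": [] if cache else None,
        "actor_h": np.zeros((t_total, b, h)),
        "trial_outcome": np.zeros((cfg.trials_per_episode, b), dtype=int),
        "trial_choice": np.zeros((cfg.trials_per_episode, b), dtype=int),
        "trial_block": [],
        "trial_stim": np.zeros((cfg.trials_per_episode, b), dtype=bool),
    }

    for t in range(t_total):
        tau = t % s_trial
        trial = t // s_trial
        if tau == 0:
            # decision step: critic input carries no sequence yet
            x_seq = np.zeros((b, cfg.n_input_neurons))
        else:
            x_seq = env.f[:, :, tau]
        x_c = np.concatenate([x_seq, r_prev[:, None]], axis=1)
        hc, cc, cache_c = lstm_step((hc, cc), x_c, agent.critic)
        v = hc @ agent.w_v + agent.b_v
        rpe = r_prev + cfg.gamma * v - v_prev

        x_a = np.zeros((b, cfg.actor_input_dim))
        x_a[np.arange(b), prev_action] = 1.0
        x_a[:, N_ACTIONS + tau] = 1.0
        x_a[:, -1] = rpe
        ha, ca, cache_a = lstm_step((ha, ca), x_a, agent.actor)
        logits = ha @ agent.w_pi.T + agent.b_pi
        logits -= logits.max(axis=1, keepdims=True)
        pi = np.exp(logits)
        pi /= pi.sum(axis=1, keepdims=True)
        if greedy:
            actions = pi.argmax(axis=1)
        else:
            u = rng.random(b)
            actions = (pi.cumsum(axis=1) < u[:, None]).sum(axis=1)
            np.clip(actions, 0, N_ACTIONS - 1, out=actions)

        if tau == 0:
            env.begin_trial(actions)
            traj["trial_choice"][trial] = actions
            traj["trial_outcome"][trial] = env.outcomes
            traj["trial_block"].append(list(env.blocks))
            traj["trial_stim"][trial] = env.stimulated
            penalty = np.where(actions == 2, cfg.penalty, 0.0)
        else:
            penalty = np.where(actions != 2, cfg.penalty, 0.0)
        r_now = env.r_profile[:, tau] + penalty

        traj["rewards"][t] = r_now
        traj["gammas"][t] = 0.0 if tau == s_trial - 1 else cfg.gamma
        traj["values"][t] = v
        traj["actions"][t] = actions
        traj["pis"][t] = pi
        traj["rpe"][t] = rpe
        traj["actor_h"][t] = ha
        if cache:
            traj["caches_c"].append(cache_c)
            traj["caches_a"].append(cache_a)

        v_prev = v
        r_prev = r_now
        prev_action = actions
    return traj


# ---------------------------------------------------------------------------
# A2C update


def a2c_gradients(agent: DynamicsAgent, traj: dict) -> tuple[dict, dict]:
    """Episode-batch A2C gradients for all parameters.

    Critic: d/dtheta_v of beta_v/2 sum (V_t - R_t)^2 with the k-step return
    R_t treated as a constant target. Actor: policy-gradient term
    -(log pi(a_t)) * advantage plus the entropy bonus -beta_e H. The RPE
    input to the actor and the efference copy are treated as external inputs
    (no gradient flows from the actor into the critic).
    Returns (grads, stats).
    """
    cfg = agent.config
    t_total, b = traj["rewards"].shape
    returns = _returns_backward(traj["rewards"], traj["gammas"], cfg.discount_immediate)
    adv = returns - traj["values"]

    grads = {
        "c.w": np.zeros_like(agent.critic.w),
        "c.u": np.zeros_like(agent.critic.u),
        "c.b": np.zeros_like(agent.critic.b),
        "a.w": np.zeros_like(agent.actor.w),
        "a.u": np.zeros_like(agent.actor.u),
        "a.b": np.zeros_like(agent.actor.b),
        "w_v": np.zeros_like(agent.w_v),
        "b_v": 0.0,
        "w_pi": np.zeros_like(agent.w_pi),
        "b_pi": np.zeros_like(agent.b_pi),
    }
    gc = {"w": grads["c.w"], "u": grads["c.u"], "b": grads["c.b"]}
    ga = {"w": grads["a.w"], "u": grads["a.u"], "b": grads["a.b"]}

    dh_c = np.zeros((b, cfg.n_units))
    dc_c = np.zeros((b, cfg.n_units))
    dh_a = np.zeros((b, cfg.n_units))
    dc_a = np.zeros((b, cfg.n_units))
    inv_b = 1.0 / b
    for t in range(t_total - 1, -1, -1):
        # critic value loss
        dv = cfg.beta_v * (traj["values"][t] - returns[t]) * inv_b  # (B,)
        _, _, _, _, _, go_c, _, tc_c = traj["caches_c"][t]
        h_c = go_c * tc_c  # h(t) rebuilt from the cached gate activations
        grads["w_v"] += dv @ h_c
        grads["b_v"] += float(dv.sum())
        dh_c += dv[:, None] * agent.w_v[None, :]
        dh_c, dc_c, _ = lstm_backward(dh_c, dc_c, traj["caches_c"][t], agent.critic, gc)

        # actor policy loss
        pi = traj["pis"][t]
        a_t = traj["actions"][t]
        one_hot = np.zeros_like(pi)
        one_hot[np.arange(b), a_t] = 1.0
        logpi = np.log(np.clip(pi, 1e-12, None))
        ent = -(pi * logpi).sum(axis=1, keepdims=True)
        dlogits = adv[t][:, None] * (pi - one_hot) + cfg.beta_e * pi * (logpi + ent)
        dlogits *= inv_b
        xa, ha_prev, ca_prev, phi, gi, go, gcand, tc = traj["caches_a"][t]
        h_a = go * tc
        grads["w_pi"] += dlogits.T @ h_a
        grads["b_pi"] += dlogits.sum(axis=0)
        dh_a += dlogits @ agent.w_pi
        dh_a, dc_a, _ = lstm_backward(dh_a, dc_a, traj["caches_a"][t], agent.actor, ga)

    stats = {
        "mean_return": float(returns[0].mean()),
        "mean_adv": float(adv.mean()),
        "entropy": float(
            -(traj["pis"] * np.log(np.clip(traj["pis"], 1e-12, None))).sum(axis=2).mean()
        ),
    }
    return grads, stats


def episode_loss(agent: DynamicsAgent, traj: dict) -> float:
    """Scalar A2C loss for a *fixed* trajectory (teacher-forced re-run).

    Re-runs both LSTMs on the trajectory's recorded inputs and actions with
    the agent's current parameters, holding the return targets, advantages
    and actor inputs fixed; used by the finite-difference gradient checks.
    """
    cfg = agent.config
    t_total, b = traj["rewards"].shape
    returns = _returns_backward(traj["rewards"], traj["gammas"], cfg.discount_immediate)
    adv = returns - traj["values"]
    hc = np.zeros((b, cfg.n_units))
    cc = np.zeros((b, cfg.n_units))
    ha = np.zeros((b, cfg.n_units))
    ca = np.zeros((b, cfg.n_units))
    loss = 0.0
    for t in range(t_total):
        x_c = traj["caches_c"][t][0]
        hc, cc, _ = lstm_step((hc, cc), x_c, agent.critic)
        v = hc @ agent.w_v + agent.b_v
        loss += 0.5 * cfg.beta_v * float(((v - returns[t]) ** 2).sum()) / b
        x_a = traj["caches_a"][t][0]
        ha, ca, _ = lstm_step((ha, ca), x_a, agent.actor)
        logits = ha @ agent.w_pi.T + agent.b_pi
        logits = logits - logits.max(axis=1, keepdims=True)
        pi = np.exp(logits)
        pi /= pi.sum(axis=1, keepdims=True)
        logpi = np.log(np.clip(pi, 1e-12, None))
        a_t = traj["actions"][t]
        ent = -(pi * logpi).sum(axis=1)
        loss += float((-logpi[np.arange(b), a_t] * adv[t] - cfg.beta_e * ent).sum()) / b
    return loss


class RMSProp:
    def __init__(self, params: dict, lr: float, rho: float, eps: float):
        self.cache = {k: np.zeros_like(v) if isinstance(v, np.ndarray) else 0.0 for k, v in params.items()}
        self.lr, self.rho, self.eps = lr, rho, eps

    def step(self, params: dict, grads: dict) -> None:
        for k, p in params.items():
            g = grads[k]
            self.cache[k] = self.rho * self.cache[k] + (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(self.cache[k]) + self.eps)


# ---------------------------------------------------------------------------
# training / testing


def train_dynamics_model(
    config: DynamicsConfig,
    rng: np.random.Generator,
    task: Optional[TaskConfig] = None,
    persistent_input: bool = False,
    progress_every: int = 0,
) -> tuple[DynamicsAgent, np.ndarray]:
    """Train the actor-critic with A2C; returns (agent, learning curve).

    Training uses unpredictable block reversals (per-trial hazard
    ``config.train_hazard``) so the agent cannot count rewards to anticipate
    reversals. The learning curve holds the mean non-penalty reward rate
    (fraction of rewarded lever presses) per training iteration.
    """
    if task is None:
        task = TaskConfig(variant="per_trial_hazard", hazard=config.train_hazard)
    agent = DynamicsAgent.init(config, rng)
    params = {**agent.parameters(), "b_v": None}  # b_v handled separately (scalar)
    params.pop("b_v")
    opt = RMSProp(params, config.learning_rate, config.rho, config.eps)
    bv_cache = 0.0
    n_iter = max(1, config.n_episodes // config.batch_size)
    curve = np.zeros(n_iter)
    for it in range(n_iter):
        env = _EpisodeBatch(config, task, config.batch_size, rng, persistent=persistent_input)
        traj = run_episode(agent, env, rng, cache=True)
        grads, stats = a2c_gradients(agent, traj)
        if not all(np.all(np.isfinite(g)) for g in grads.values() if isinstance(g, np.ndarray)):
            raise FloatingPointError(f"non-finite gradient at iteration {it}: {stats}")
        opt.step(params, grads)
        bv_cache = opt.rho * bv_cache + (1 - opt.rho) * grads["b_v"] ** 2
        agent.b_v -= opt.lr * grads["b_v"] / (math.sqrt(bv_cache) + opt.eps)
        pressed = traj["trial_choice"] != 2
        curve[it] = traj["trial_outcome"][pressed].mean() if pressed.any() else 0.0
        if progress_every and it % progress_every == 0:
            print(f"iter {it}: reward {curve[it]:.3f} entropy {stats['entropy']:.3f}")
    return agent, curve


def test_dynamics_model(
    agent: DynamicsAgent,
    task: Optional[TaskConfig] = None,
    n_episodes: int = 4,
    episode_trials: int = 300,
    rng: Optional[np.random.Generator] = None,
    stim_fraction: float = 0.0,
    fixed_block_length: Optional[int] = None,
) -> tuple[list, list]:
    """Frozen-weight testing; behaviour arises from recurrent dynamics alone.

    Returns (sessions, extras) where extras carry the per-trial post-press
    RPE average and the actor's decision-step activity for geometry analyses.
    """
    if task is None:
        task = TaskConfig()  # the mice's reward-counted 70/10 task
    rng = np.random.default_rng() if rng is None else rng
    cfg = replace(agent.config, trials_per_episode=episode_trials)
    test_agent = replace(agent, config=cfg)
    sessions = []
    extras = []
    for _ in range(n_episodes):
        env = _EpisodeBatch(
            cfg, task, 1, rng, stim_fraction=stim_fraction, fixed_block_length=fixed_block_length
        )
        traj = run_episode(test_agent, env, rng, cache=False)
        s = cfg.steps_per_trial
        post = traj["rpe"].reshape(episode_trials, s)[:, cfg.press_step :]
        h0 = traj["actor_h"].reshape(episode_trials, s, 1, cfg.n_units)[:, 0, 0, :]
        trials = []
        for i in range(episode_trials):
            ci = int(traj["trial_choice"][i, 0])
            trials.append(
                TrialRecord(
                    index=i,
                    choice=ACTION_NAMES[ci],
                    outcome=int(traj["trial_outcome"][i, 0]) if ci != 2 else 0,
                    block=traj["trial_block"][i][0],
                    stimulated=bool(traj["trial_stim"][i, 0]),
                    event_times={},
                )
            )
        sessions.append(SessionRecord(trials=trials, config=task))
        extras.append(
            {
                "rpe_post_press": post.mean(axis=1),
                "actor_h_decision": h0,
                "rpe_full": traj["rpe"].reshape(episode_trials, s),
            }
        )
    return sessions, extras


# ---------------------------------------------------------------------------
# actor geometry


@dataclass
class ActorGeometry:
    explained_variance_ratio: np.ndarray
    readout_cosines: np.ndarray  # |cos| between readout vector and each PC
    pc1_regression: dict  # keys choice, rpe, interaction -> (n_back,) coefs
    n_trials: int


def actor_geometry_analysis(
    agent: DynamicsAgent,
    rng: np.random.Generator,
    n_episodes: int = 4,
    episode_trials: int = 300,
    block_length: int = 30,
    n_back: int = 7,
    n_components: int = 3,
) -> ActorGeometry:
    """PCA of decision-step actor activity and its behavioural regression.

    Runs frozen-weight sessions with blocks fixed at ``block_length`` trials,
    extracts principal components of the actor output at the decision step,
    the |cosine| between the choice readout vector and each component, and a
    linear regression of PC1 on the previous ``n_back`` trials' choice,
    post-press RPE and choice x RPE interaction.
    """
    from sklearn.decomposition import PCA
    import statsmodels.api as sm

    sessions, extras = test_dynamics_model(
        agent,
        task=TaskConfig(),
        n_episodes=n_episodes,
        episode_trials=episode_trials,
        rng=rng,
        fixed_block_length=block_length,
    )
    h = np.vstack([e["actor_h_decision"] for e in extras])
    if np.allclose(h.var(axis=0).sum(), 0.0):
        raise ValueError("degenerate actor activity variance")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(h)
    read = agent.choice_readout
    read = read / np.linalg.norm(read)
    cosines = np.abs(pca.components_ @ read)

    # PC1 history regression, per session then pooled
    ys, xs = [], []
    offset = 0
    for sess, e in zip(sessions, extras):
        c = sess.choices().astype(float)  # +1 right, -1 left, 0 none
        rpe = e["rpe_post_press"]
        pc1 = scores[offset : offset + len(c), 0]
        offset += len(c)
        for i in range(n_back, len(c)):
            lags_c = c[i - n_back : i][::-1]
            lags_r = rpe[i - n_back : i][::-1]
            xs.append(np.concatenate([lags_c, lags_r, lags_c * lags_r]))
            ys.append(pc1[i])
    design = sm.add_constant(np.asarray(xs))
    fit = sm.OLS(np.asarray(ys), design).fit()
    coefs = np.asarray(fit.params[1:])
    return ActorGeometry(
        explained_variance_ratio=pca.explained_variance_ratio_,
        readout_cosines=cosines,
        pc1_regression={
            "choice": coefs[:n_back],
            "rpe": coefs[n_back : 2 * n_back],
            "interaction": coefs[2 * n_back :],
        },
        n_trials=len(ys),
    )
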