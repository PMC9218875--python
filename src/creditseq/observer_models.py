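"""Ideal-observer (model-based) and Q-learning (model-free) agents.

Both agents play the reversal task trial by trial and expose a scalar reward
prediction error RPE = r(t) - expectation for the chosen lever, where the
expectation is the Bayesian one-step-ahead reward prediction (observer) or
the incremental action value (Q-learner). Their signature difference appears
on the second trial after a block reversal when the agent switches levers:
the observer *infers* the new contingency from the first trial's outcome,
so its trial-2 RPE for the newly chosen (unexperienced) lever is already
small, while the Q-learner must experience that lever to update it.

The observer knows the block transition matrix T (per-trial hazard) and the
reward matrix R (state x choice). Its belief over {left_high, right_high} is
updated recursively:

    posterior_j  propto  R_jk^r (1-R_jk)^(1-r) * sum_m T_mj prior_m

and its one-step-ahead expected reward for choice l is
rho_l = sum_i R_il sum_j T_ji belief_j.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .task_engine import BlockSchedule, SessionRecord, TaskConfig, TrialRecord

STATES = ("left_high", "right_high")
CHOICES = ("left", "right")


def _transition_matrix(hazard: float) -> np.ndarray:
    return np.array([[1 - hazard, hazard], [hazard, 1 - hazard]])


def _reward_matrix(p_high: float, p_low: float) -> np.ndarray:
    # rows: states (left_high, right_high); columns: choices (left, right)
    return np.array([[p_high, p_low], [p_low, p_high]])


@dataclass(frozen=True)
class ObserverConfig:
    transition: np.ndarray = field(default_factory=lambda: _transition_matrix(0.05))
    reward: np.ndarray = field(default_factory=lambda: _reward_matrix(0.7, 0.1))

    def __post_init__(self) -> None:
        t = np.asarray(self.transition)
        r = np.asarray(self.reward)
        if t.shape != (2, 2) or not np.allclose(t.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if r.shape != (2, 2) or np.any((r < 0) | (r > 1)):
            raise ValueError("reward entries must be probabilities")

    @classmethod
    def bromberg(cls, hazard: float = 0.05) -> "ObserverConfig":
        """100/0 reward contingencies with per-trial reversal hazard."""
        return cls(_transition_matrix(hazard), _reward_matrix(1.0, 0.0))

    @classmethod
    def ours(cls, hazard: float = 0.05) -> "ObserverConfig":
        """70/10 contingencies with per-trial reversal hazard."""
        return cls(_transition_matrix(hazard), _reward_matrix(0.7, 0.1))


@dataclass
class QState:
    q_left: float = 0.0
    q_right: float = 0.0
    alpha: float = 0.612
    beta_value: float = 0.99
    beta_stay: float = 0.95


def observer_update(
    belief: np.ndarray, choice: str, reward: int, config: ObserverConfig
) -> np.ndarray:
    """Posterior over block states after observing (choice, reward)."""
    belief = np.asarray(belief, dtype=float)
    if belief.min() < 0 or not np.isclose(belief.sum(), 1.0):
        raise ValueError("belief must be a probability vector")
    k = CHOICES.index(choice)
    prior_pred = config.transition.T @ belief  # P(s_t = j | history up to t-1)
    lik = np.where(reward, config.reward[:, k], 1.0 - config.reward[:, k])
    post = lik * prior_pred
    z = post.sum()
    if z <= 0.0:
        # impossible observation under a deterministic reward matrix: all
        # mass goes to the complementary state
        out = np.zeros(2)
        out[1 - int(np.argmax(prior_pred))] = 1.0
        return out
    return post / z


def observer_expected_reward(belief: np.ndarray, choice: str, config: ObserverConfig) -> float:
    """One-step-ahead expected reward rho for ``choice`` given the belief."""
    l = CHOICES.index(choice)
    pred = config.transition.T @ np.asarray(belief, dtype=float)
    return float(config.reward[:, l] @ pred)


def q_step(q: QState, choice: str, reward: int) -> QState:
    """Incremental update of the chosen action's value; the other is untouched."""
    if choice == "left":
        return QState(
            q.q_left + q.alpha * (reward - q.q_left), q.q_right, q.alpha, q.beta_value, q.beta_stay
        )
    return QState(
        q.q_left, q.q_right + q.alpha * (reward - q.q_right), q.alpha, q.beta_value, q.beta_stay
    )


def softmax_policy(
    value_left: float,
    value_right: float,
    prev_choice: Optional[str],
    beta_value: float,
    beta_stay: float,
) -> tuple[float, float]:
    """(P(left), P(right)) from values plus the stay-with-previous bias."""
    b_l = beta_value * value_left + (beta_stay if prev_choice == "left" else 0.0)
    b_r = beta_value * value_right + (beta_stay if prev_choice == "right" else 0.0)
    m = max(b_l, b_r)
    e_l, e_r = np.exp(b_l - m), np.exp(b_r - m)
    return float(e_l / (e_l + e_r)), float(e_r / (e_l + e_r))


@dataclass
class AgentRun:
    session: SessionRecord
    rpe: np.ndarray  # per-trial RPE of the agent
    expectation: np.ndarray  # rho_chosen or Q_chosen per trial
    belief_trace: Optional[np.ndarray] = None  # observer: P(left_high) per trial


def run_agent(
    agent: str,
    task: TaskConfig,
    n_trials: int,
    rng: np.random.Generator,
    observer_config: Optional[ObserverConfig] = None,
    q_params: Optional[QState] = None,
) -> AgentRun:
    """Simulate an agent ("observer" or "q") on the task.

    Both use the same softmax action rule (on rho for the observer, on Q for
    the Q-learner) with the fitted beta_value=0.99, beta_stay=0.95, so the
    RPE comparison between them conditions on comparable stochastic choices.
    """
    if agent not in ("observer", "q"):
        raise ValueError("agent must be 'observer' or 'q'")
    q = q_params or QState()
    if observer_config is None:
        observer_config = ObserverConfig(
            _transition_matrix(task.hazard), _reward_matrix(task.p_high, task.p_low)
        )
    schedule = BlockSchedule(task, rng)
    belief = np.array([0.5, 0.5])
    prev: Optional[str] = None
    trials = []
    rpes = np.zeros(n_trials)
    exps = np.zeros(n_trials)
    btr = np.zeros(n_trials)
    for i in range(n_trials):
        schedule.maybe_reverse_pre_trial()
        if agent == "observer":
            v_l = observer_expected_reward(belief, "left", observer_config)
            v_r = observer_expected_reward(belief, "right", observer_config)
        else:
            v_l, v_r = q.q_left, q.q_right
        p_l, _ = softmax_policy(v_l, v_r, prev, q.beta_value, q.beta_stay)
        choice = "left" if rng.random() < p_l else "right"
        outcome = schedule.draw_outcome(choice)
        block = schedule.block
        schedule.advance_post_trial(outcome)
        expectation = v_l if choice == "left" else v_r
        rpes[i] = outcome - expectation
        exps[i] = expectation
        btr[i] = belief[0]
        if agent == "observer":
            belief = observer_update(belief, choice, outcome, observer_config)
        else:
            q = q_step(q, choice, outcome)
        trials.append(
            TrialRecord(index=i, choice=choice, outcome=outcome, block=block, event_times={})
        )
        prev = choice
    session = SessionRecord(trials=trials, config=task)
    return AgentRun(
        session=session,
        rpe=rpes,
        expectation=exps,
        belief_trace=btr if agent == "observer" else None,
    )


def rpe_trace(run: AgentRun) -> np.ndarray:
    """Per-trial RPE = r(t) - expectation for the chosen action."""
    return run.rpe


def reversal_rpe_comparison(runs: dict, min_trials: int = 2) -> pd.DataFrame:
    """Mean RPE on the first trial of a block and on switch second trials.

    ``runs`` maps agent name -> AgentRun. A qualifying second trial is one
    whose choice differs from the first trial of the block (so its
    action-outcome contingency has not been experienced in the new block).
    Rewarded-only means are reported alongside, since the model-based
    signature is the reduced *positive* surprise on inferred-good levers.
    """
    rows = []
    for name, run in runs.items():
        c = run.session.choices()
        rev = run.session.reversal_trials()
        t1 = [r for r in rev if r + 1 < len(c)]
        t2 = [r + 1 for r in t1 if c[r + 1] != c[r]]
        rpe = run.rpe
        o = run.session.outcomes()

        def mstat(idx, rewarded_only=False):
            idx = np.asarray(idx, dtype=int)
            if rewarded_only and len(idx):
                idx = idx[o[idx] == 1]
            return float(rpe[idx].mean()) if len(idx) else float("nan")

        rows.append(
            {
                "agent": name,
                "rpe_trial1": mstat(t1),
                "rpe_trial2_switch": mstat(t2),
                "rpe_trial1_rewarded": mstat(t1, True),
                "rpe_trial2_switch_rewarded": mstat(t2, True),
                "n_trial1": len(t1),
                "n_trial2_switch": len(t2),
            }
        )
    return pd.DataFrame(rows)
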