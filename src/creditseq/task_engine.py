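"""Probabilistic reversal learning task: block structure, reward draws, summaries.

The task is a two-lever bandit. On every trial one lever is the
high-probability ("block") lever and the other the low-probability lever
(defaults 70% / 10%). The identity of the high lever reverses without any cue.
Three reversal rules are supported:

``reward_counted``
    The rule used for the mice and the plasticity model: the block ends
    ``rewards_to_reversal`` rewarded trials plus a geometric number of
    additional trials (success probability ``geometric_p``) into the block.
``geometric_only``
    Block length is a pure geometric draw (used to train the dynamics model,
    where reward counting would make reversals predictable).
``per_trial_hazard``
    The block flips i.i.d. with probability ``hazard`` on each trial (the
    task variant used for the ideal-observer / Q-learning comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional

import numpy as np
import pandas as pd

Choice = Literal["left", "right", "none"]
Block = Literal["left_high", "right_high"]

#: canonical within-trial event order, times in seconds relative to lever press
EVENT_ORDER = ("nose_poke", "levers_out", "lever_press", "cs", "reward_consumption")


class InvalidConfigError(ValueError):
    """Raised for task/model configurations that violate their invariants."""


@dataclass(frozen=True)
class TaskConfig:
    p_high: float = 0.7
    p_low: float = 0.1
    rewards_to_reversal: int = 10
    geometric_p: float = 0.4
    variant: str = "reward_counted"
    hazard: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_low < self.p_high <= 1.0):
            raise InvalidConfigError(
                f"require 0 <= p_low < p_high <= 1, got ({self.p_low}, {self.p_high})"
            )
        if not (0.0 < self.geometric_p <= 1.0):
            raise InvalidConfigError(f"geometric_p must be in (0, 1], got {self.geometric_p}")
        if self.rewards_to_reversal < 1:
            raise InvalidConfigError("rewards_to_reversal must be >= 1")
        if self.variant not in ("reward_counted", "geometric_only", "per_trial_hazard"):
            raise InvalidConfigError(f"unknown task variant {self.variant!r}")
        if not (0.0 <= self.hazard <= 1.0):
            raise InvalidConfigError("hazard must be a probability")


@dataclass
class TrialRecord:
    index: int
    choice: Choice
    outcome: int
    block: Block
    stimulated: bool = False
    event_times: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.choice == "none" and self.outcome != 0:
            raise ValueError("abandoned trials cannot be rewarded")


@dataclass
class SessionRecord:
    trials: list
    config: TaskConfig
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.trials)

    # -- array views ------------------------------------------------------
    def choices(self) -> np.ndarray:
        """Signed choices: +1 right, -1 left, 0 abandoned."""
        m = {"right": 1, "left": -1, "none": 0}
        return np.array([m[t.choice] for t in self.trials], dtype=int)

    def outcomes(self) -> np.ndarray:
        return np.array([t.outcome for t in self.trials], dtype=int)

    def blocks(self) -> np.ndarray:
        """Signed blocks: +1 right_high, -1 left_high."""
        return np.array([1 if t.block == "right_high" else -1 for t in self.trials], dtype=int)

    def stimulated(self) -> np.ndarray:
        return np.array([t.stimulated for t in self.trials], dtype=bool)

    def reward_rate(self) -> float:
        return float(self.outcomes().mean())

    def reversal_trials(self) -> np.ndarray:
        """Indices of the first trial of each new block (excluding trial 0)."""
        b = self.blocks()
        return np.nonzero(b[1:] != b[:-1])[0] + 1

    def mean_block_length(self) -> float:
        """Mean trial count between consecutive reversals (completed blocks only)."""
        rev = self.reversal_trials()
        if len(rev) < 2:
            return float("nan")
        return float(np.diff(rev).mean())

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            row = {
                "trial": t.index,
                "choice": t.choice,
                "outcome": t.outcome,
                "block": t.block,
                "stimulated": int(t.stimulated),
            }
            for ev in EVENT_ORDER:
                row[f"t_{ev}"] = t.event_times.get(ev, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sampling primitives


def sample_block_extension(p: float, rng: np.random.Generator) -> int:
    """Geometric draw P(k) = (1-p)^(k-1) p with support k >= 1.

    This is the random block extension after the reward criterion is met; the
    support starting at 1 means a reversal can never land on the same trial as
    the final counted reward.
    """
    if not (0.0 < p <= 1.0):
        raise InvalidConfigError(f"geometric success probability must be in (0, 1], got {p}")
    return int(rng.geometric(p))


def chance_reward_rate(config: TaskConfig) -> float:
    """Long-run reward rate of a choice-blind (uniform random) policy."""
    return (config.p_high + config.p_low) / 2.0


def draw_event_times(rng: np.random.Generator, rewarded: bool) -> dict:
    """Within-trial event times (s, relative to lever press).

    Nose-poke -> levers-out delay is uniform on a 0.1 s grid over 0-1 s and
    press -> CS is uniform over 0-1 s, mirroring the task's programmed jitter.
    The levers-out -> press latency is drawn uniform 0-1 s.
    """
    lp_delay = rng.uniform(0.0, 1.0)  # levers out -> press
    np_delay = rng.integers(0, 11) * 0.1  # nose poke -> levers out, 0.1 s grid
    cs = rng.uniform(0.0, 1.0)
    times = {
        "lever_press": 0.0,
        "levers_out": -lp_delay,
        "nose_poke": -lp_delay - np_delay,
        "cs": cs,
    }
    if rewarded:
        times["reward_consumption"] = cs + rng.uniform(0.2, 0.8)
    return times


class BlockSchedule:
    """Stateful block-reversal bookkeeping shared by all session runners."""

    def __init__(self, config: TaskConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.block: Block = "left_high" if rng.random() < 0.5 else "right_high"
        self._reset_block_state()

    def _reset_block_state(self) -> None:
        self._rewards = 0
        self._countdown: Optional[int] = None
        if self.config.variant == "geometric_only":
            self._countdown = sample_block_extension(self.config.geometric_p, self.rng)

    def maybe_reverse_pre_trial(self) -> None:
        """per_trial_hazard flips the block state i.i.d. before each trial."""
        if self.config.variant == "per_trial_hazard" and self.rng.random() < self.config.hazard:
            self._flip()

    def draw_outcome(self, choice: Choice) -> int:
        if choice == "none":
            return 0
        matching = (choice == "left") == (self.block == "left_high")
        p = self.config.p_high if matching else self.config.p_low
        return int(self.rng.random() < p)

    def advance_post_trial(self, outcome: int) -> None:
        """Update reversal counters after a completed trial."""
        cfg = self.config
        if cfg.variant == "per_trial_hazard":
            return
        if cfg.variant == "geometric_only":
            self._countdown -= 1
            if self._countdown == 0:
                self._flip()
            return
        # reward_counted: count rewards; once the criterion is met, start the
        # geometric countdown on the trials that follow.
        if self._countdown is None:
            self._rewards += outcome
            if self._rewards >= cfg.rewards_to_reversal:
                self._countdown = sample_block_extension(cfg.geometric_p, self.rng)
        else:
            self._countdown -= 1
            if self._countdown == 0:
                self._flip()

    def _flip(self) -> None:
        self.block = "right_high" if self.block == "left_high" else "left_high"
        self._reset_block_state()


def run_session(
    policy: Callable[[TrialRecord | None], Choice],
    config: TaskConfig,
    n_trials: int,
    rng: np.random.Generator,
    seed: Optional[int] = None,
    event_times: bool = True,
) -> SessionRecord:
    """Run ``n_trials`` of the task under ``policy``.

    ``policy`` receives the previous :class:`TrialRecord` (None on the first
    trial) and the current block label, and returns "left", "right" or "none".
    Passing the block allows oracle policies used for calibration checks; a
    behaving agent should ignore it.
    """
    if n_trials < 1:
        raise InvalidConfigError("n_trials must be >= 1")
    schedule = BlockSchedule(config, rng)
    trials: list[TrialRecord] = []
    prev: Optional[TrialRecord] = None
    for i in range(n_trials):
        schedule.maybe_reverse_pre_trial()
        choice = policy(prev, schedule.block)
        outcome = schedule.draw_outcome(choice)
        rec = TrialRecord(
            index=i,
            choice=choice,
            outcome=outcome,
            block=schedule.block,
            event_times=draw_event_times(rng, bool(outcome)) if event_times else {},
        )
        if choice != "none":
            schedule.advance_post_trial(outcome)
        trials.append(rec)
        prev = rec
    return SessionRecord(trials=trials, config=config, seed=seed)


# ---------------------------------------------------------------------------
# behavioral summaries


def stay_probability(session: SessionRecord, split_by: str = "outcome") -> pd.DataFrame:
    """Probability of repeating the previous lever choice.

    Stratified by the previous trial's outcome; with
    ``split_by="outcome×stimulation"`` additionally by whether the previous or
    the current trial was stimulated. Trials following an abandoned trial are
    excluded; an empty stratum yields NaN.
    """
    c = session.choices()
    o = session.outcomes()
    s = session.stimulated()
    if np.count_nonzero(c != 0) < 2:
        raise ValueError("need at least two non-abandoned trials")
    valid = (c[1:] != 0) & (c[:-1] != 0)
    stay = (c[1:] == c[:-1])[valid]
    prev_rew = o[:-1][valid].astype(bool)
    prev_stim = s[:-1][valid]
    curr_stim = s[1:][valid]

    def frac(mask: np.ndarray) -> float:
        return float(stay[mask].mean()) if mask.any() else float("nan")

    rows = []
    if split_by == "outcome":
        for label, m in (("rewarded", prev_rew), ("unrewarded", ~prev_rew)):
            rows.append({"prev_outcome": label, "stay_prob": frac(m), "n": int(m.sum())})
    elif split_by in ("outcome×stimulation", "outcome x stimulation"):
        for label, m in (("rewarded", prev_rew), ("unrewarded", ~prev_rew)):
            for align, stim in (("previous", prev_stim), ("current", curr_stim)):
                for flag in (False, True):
                    mm = m & (stim == flag)
                    rows.append(
                        {
                            "prev_outcome": label,
                            "stim_alignment": align,
                            "stimulated": flag,
                            "stay_prob": frac(mm),
                            "n": int(mm.sum()),
                        }
                    )
    else:
        raise ValueError(f"unknown split_by {split_by!r}")
    return pd.DataFrame(rows)


def reversal_aligned_choice_prob(session: SessionRecord, window: int = 10) -> pd.DataFrame:
    """P(choose left) and P(choose right) at lags around block reversals.

    Averaged separately for left_high->right_high and right_high->left_high
    reversals. Lags run -window..+window with lag 0 the first trial of the new
    block; strata with no data give NaN.
    """
    rev = session.reversal_trials()
    if len(rev) == 0:
        raise ValueError("session contains no reversal")
    c = session.choices()
    b = session.blocks()
    lags = np.arange(-window, window + 1)
    rows = []
    for direction, sign in (("left_to_right", 1), ("right_to_left", -1)):
        rev_d = [r for r in rev if b[r] == sign]
        for lag in lags:
            vals = []
            for r in rev_d:
                i = r + lag
                if 0 <= i < len(c) and c[i] != 0:
                    vals.append(c[i])
            p_right = float(np.mean(np.array(vals) == 1)) if vals else float("nan")
            p_left = float(np.mean(np.array(vals) == -1)) if vals else float("nan")
            rows.append(
                {
                    "direction": direction,
                    "lag": int(lag),
                    "p_left": p_left,
                    "p_right": p_right,
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)


def choice_prob_new_high(session: SessionRecord, window: int = 10) -> pd.Series:
    """P(choose the newly high lever) per lag around reversals, both directions pooled."""
    df = reversal_aligned_choice_prob(session, window)
    out = {}
    for lag in sorted(df["lag"].unique()):
        sub = df[df["lag"] == lag]
        num = 0.0
        n = 0
        for _, row in sub.iterrows():
            p_new = row["p_right"] if row["direction"] == "left_to_right" else row["p_left"]
            if row["n"] > 0 and np.isfinite(p_new):
                num += p_new * row["n"]
                n += row["n"]
        out[lag] = num / n if n else float("nan")
    return pd.Series(out, name="p_new_high")


# convenience policies ------------------------------------------------------


def uniform_random_policy(rng: np.random.Generator) -> Callable:
    def policy(prev, block):
        return "left" if rng.random() < 0.5 else "right"

    return policy


def oracle_policy() -> Callable:
    """Always press the current block's high-probability lever."""

    def policy(prev, block):
        return "left" if block == "left_high" else "right"

    return policy


def win_stay_lose_shift_policy(rng: np.random.Generator) -> Callable:
    def policy(prev, block):
        if prev is None or prev.choice == "none":
            return "left" if rng.random() < 0.5 else "right"
        if prev.outcome == 1:
            return prev.choice
        return "right" if prev.choice == "left" else "left"

    return policy
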