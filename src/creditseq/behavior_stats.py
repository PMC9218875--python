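"""History-based regressions of choice and dopamine activity.

Choice regressions model the log-odds of a right press on trial i from the
signed identities of previously rewarded and unrewarded choices:

    logit P(right_i) = b0 + sum_j bR_j R(i-j) + sum_j bU_j U(i-j)

with R(i-j) = +1 / -1 for a rewarded right / left press j trials back (0 if
unrewarded) and U defined analogously for unrewarded presses. The stimulation
variant adds stimulation main effects L(i-j) and reward x stimulation /
unreward x stimulation interactions.

The dopamine regression predicts the trial's feedback-window dopamine
(window-averaged RPE, 0.2-1.2 s after feedback) from the current and previous
five outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm

from .task_engine import SessionRecord


@dataclass
class ChoiceRegressionResult:
    n_back: int
    intercept: float
    beta_rewarded: np.ndarray  # bR_j, j = 1..n_back
    beta_unrewarded: np.ndarray
    beta_stim: Optional[np.ndarray] = None  # bL_j
    beta_stim_rewarded: Optional[np.ndarray] = None  # bLR_j
    beta_stim_unrewarded: Optional[np.ndarray] = None  # bLU_j
    se: Optional[np.ndarray] = None  # SEs in design-column order
    ridge_fallback: bool = False

    @property
    def combined_rewarded(self) -> np.ndarray:
        """bR + bLR: influence of a rewarded choice when that trial was stimulated."""
        if self.beta_stim_rewarded is None:
            raise ValueError("no stimulation terms in this fit")
        return self.beta_rewarded + self.beta_stim_rewarded

    @property
    def combined_unrewarded(self) -> np.ndarray:
        if self.beta_stim_unrewarded is None:
            raise ValueError("no stimulation terms in this fit")
        return self.beta_unrewarded + self.beta_stim_unrewarded


@dataclass
class DAHistoryResult:
    coefficients: np.ndarray  # beta_j, j = 0 (current) .. n_back
    intercept: float
    se: np.ndarray
    window: tuple = (0.2, 1.2)


def _signed_history(session: SessionRecord) -> tuple:
    """Completed-trial arrays (abandoned trials dropped before lagging)."""
    c = session.choices()
    keep = c != 0
    c = c[keep]
    o = session.outcomes()[keep]
    s = session.stimulated()[keep].astype(float)
    rewarded = np.where(o == 1, c, 0)  # +1 rewarded right, -1 rewarded left
    unrewarded = np.where(o == 0, c, 0)
    return c, o, s, rewarded, unrewarded


def _lagged(x: np.ndarray, n_back: int) -> np.ndarray:
    """Columns x(i-1) .. x(i-n_back) for rows i = n_back .. len(x)-1."""
    return np.column_stack([x[n_back - j : len(x) - j] for j in range(1, n_back + 1)])


def _fit_logit(y: np.ndarray, x: np.ndarray) -> tuple:
    """Logit fit with a minimal-ridge fallback under separation/non-convergence."""
    design = sm.add_constant(x, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        if np.all(np.isfinite(fit.params)) and fit.mle_retvals.get("converged", True):
            return fit.params, fit.bse, False
    except Exception:
        pass
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1e6, max_iter=2000)
    clf.fit(x, y)
    params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    return params, np.full(design.shape[1], np.nan), True


def choice_history_regression(session: SessionRecord, n_back: int = 5) -> ChoiceRegressionResult:
    """Logistic regression of current choice on the previous ``n_back`` trials."""
    c, o, s, rew, unr = _signed_history(session)
    if len(c) < n_back + 10:
        raise ValueError(f"need at least {n_back + 10} completed trials")
    y = (c[n_back:] == 1).astype(float)
    x = np.hstack([_lagged(rew, n_back), _lagged(unr, n_back)])
    params, bse, ridge = _fit_logit(y, x)
    return ChoiceRegressionResult(
        n_back=n_back,
        intercept=float(params[0]),
        beta_rewarded=params[1 : n_back + 1],
        beta_unrewarded=params[n_back + 1 : 2 * n_back + 1],
        se=bse,
        ridge_fallback=ridge,
    )


def stim_choice_regression(session: SessionRecord, n_back: int = 5) -> ChoiceRegressionResult:
    """Choice regression with stimulation main effects and interactions."""
    c, o, s, rew, unr = _signed_history(session)
    if s.sum() == 0:
        raise ValueError("session contains no stimulated trials; interactions undefined")
    if len(c) < n_back + 10:
        raise ValueError(f"need at least {n_back + 10} completed trials")
    y = (c[n_back:] == 1).astype(float)
    x = np.hstack(
        [
            _lagged(rew, n_back),
            _lagged(unr, n_back),
            _lagged(s * rew, n_back),
            _lagged(s * unr, n_back),
            _lagged(s, n_back),
        ]
    )
    params, bse, ridge = _fit_logit(y, x)
    k = n_back
    return ChoiceRegressionResult(
        n_back=n_back,
        intercept=float(params[0]),
        beta_rewarded=params[1 : k + 1],
        beta_unrewarded=params[k + 1 : 2 * k + 1],
        beta_stim_rewarded=params[2 * k + 1 : 3 * k + 1],
        beta_stim_unrewarded=params[3 * k + 1 : 4 * k + 1],
        beta_stim=params[4 * k + 1 : 5 * k + 1],
        se=bse,
        ridge_fallback=ridge,
    )


def dopamine_history_regression(
    rpe_by_trial: np.ndarray,
    outcomes: np.ndarray,
    n_back: int = 5,
) -> DAHistoryResult:
    """Linear regression of feedback-window dopamine on outcome history.

    ``rpe_by_trial`` is the per-trial feedback-window average of the RPE
    (dopamine) signal; ``outcomes`` the binary reward history. Coefficient j
    is the effect of the outcome j trials back (j=0 is the current trial).
    """
    rpe_by_trial = np.asarray(rpe_by_trial, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if rpe_by_trial.shape != outcomes.shape:
        raise ValueError("rpe_by_trial and outcomes must align")
    if len(outcomes) < n_back + 10:
        raise ValueError(f"need at least {n_back + 10} trials")
    y = rpe_by_trial[n_back:]
    cols = [outcomes[n_back:]] + [
        outcomes[n_back - j : len(outcomes) - j] for j in range(1, n_back + 1)
    ]
    design = sm.add_constant(np.column_stack(cols), has_constant="add")
    fit = sm.OLS(y, design).fit()
    return DAHistoryResult(
        coefficients=np.asarray(fit.params[1:]),
        intercept=float(fit.params[0]),
        se=np.asarray(fit.bse[1:]),
    )
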