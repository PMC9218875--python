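"""Population decoding of choice and outcome, with sequence-type weighting.

Choices (and outcomes) are strongly autocorrelated across neighbouring
trials, so an unweighted decoder can appear to read out the current trial
while actually exploiting activity locked to the previous or next one. Each
trial is therefore classified by its previous-current-future label triplet
(8 "sequence types") and given weight 1/frequency(type), which equalises the
triplet distribution seen by the logistic decoder.

The time-course decoder first removes behavioural timing variability with a
piecewise-linear warp: the 2 s before the nose poke and the 3 s after the
next trial's nose poke pass through unwarped, while the nose-poke-to-press
and press-to-next-nose-poke epochs are linearly rescaled to their across-
trial median durations. Separate weighted logistic decoders are then fit on
0.5 s bins of the warped traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import ttest_1samp
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold


@dataclass(frozen=True)
class DecoderSpec:
    ensemble_size: int = 10
    n_resamples: int = 100
    cv_folds: int = 5
    activity_window: tuple = (-2.0, 6.0)
    threshold: float = 0.5
    ridge: float = 1e-6  # minimal l2 for numerical stability under separation

    def __post_init__(self) -> None:
        if not (1 <= self.ensemble_size):
            raise ValueError("ensemble_size must be >= 1")


@dataclass(frozen=True)
class WarpSpec:
    pre_window: float = 2.0  # s before nose poke, pass-through
    post_window: float = 3.0  # s after next nose poke, pass-through
    bin_size: float = 0.5
    dt: float = 0.1


def sequence_type_weights(labels: np.ndarray, kind: str = "press") -> np.ndarray:
    """Inverse-frequency weights over previous-current-future label triplets.

    ``labels`` is the per-trial binary label sequence (choice side or
    outcome). The first and last trials cannot be classified and get weight
    0. Both the press and outcome variants use their 8 respective triplets;
    the arithmetic is identical.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 trials to form triplets")
    trip = np.stack([labels[:-2], labels[1:-1], labels[2:]], axis=1)
    # encode triplet as int
    uniq, inverse, counts = np.unique(
        trip.astype(int) @ np.array([4, 2, 1]), return_inverse=True, return_counts=True
    )
    w = np.zeros(n)
    w[1:-1] = 1.0 / counts[inverse]
    return w


def decode_labels(
    features: np.ndarray,
    labels: np.ndarray,
    spec: DecoderSpec,
    rng: np.random.Generator,
    weights: Optional[np.ndarray] = None,
) -> float:
    """Cross-validated accuracy of weighted logistic decoding.

    ``features`` is (n_trials, n_neurons) of window-averaged activity. For
    each of ``n_resamples`` random ensembles of ``ensemble_size`` neurons, a
    weighted logistic regression is fit per CV fold and held-out predictions
    are thresholded at 0.5; the mean accuracy over ensembles x folds is
    returned.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_trials, n_neurons = features.shape
    if n_neurons < spec.ensemble_size:
        raise ValueError("fewer neurons than ensemble_size")
    if weights is None:
        weights = sequence_type_weights(labels)
    usable = weights > 0
    x_all = features[usable]
    y_all = labels[usable]
    w_all = weights[usable]
    accs = []
    clf = LogisticRegression(C=1.0 / spec.ridge, max_iter=1000)
    for _ in range(spec.n_resamples):
        ens = rng.choice(n_neurons, size=spec.ensemble_size, replace=False)
        x = x_all[:, ens]
        kf = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=int(rng.integers(2**31)))
        for train, test in kf.split(x):
            if len(np.unique(y_all[train])) < 2:
                continue
            clf.fit(x[train], y_all[train], sample_weight=w_all[train])
            p = clf.predict_proba(x[test])[:, 1]
            accs.append(np.mean((p >= spec.threshold).astype(int) == y_all[test]))
    return float(np.mean(accs))


def trial_features(
    traces: np.ndarray, t_grid: np.ndarray, window: tuple = (-2.0, 6.0)
) -> np.ndarray:
    """Mean activity per trial over a peri-press window.

    ``traces`` is (n_trials, n_neurons, n_time) on the common ``t_grid``.
    """
    mask = (t_grid >= window[0]) & (t_grid <= window[1])
    return traces[:, :, mask].mean(axis=2)


# ---------------------------------------------------------------------------
# piecewise-linear trial time warping


def _median_epochs(event_times: Sequence[dict]) -> tuple:
    d2 = np.median([ev["lever_press"] - ev["nose_poke"] for ev in event_times])
    d3 = np.median([ev["next_nose_poke"] - ev["lever_press"] for ev in event_times])
    return float(d2), float(d3)


def warp_time_map(
    ev: dict, median_ii: float, median_iii: float, spec: WarpSpec
) -> tuple[np.ndarray, np.ndarray]:
    """(adjusted grid, source times) for one trial.

    Epochs: (i) pre_window before the nose poke, unwarped; (ii) nose poke to
    press, rescaled to ``median_ii``; (iii) press to the next trial's nose
    poke, rescaled to ``median_iii``; (iv) post_window after the next nose
    poke, unwarped. The map is continuous and strictly increasing.
    """
    t_np, t_lp, t_np1 = ev["nose_poke"], ev["lever_press"], ev["next_nose_poke"]
    if not (t_np < t_lp < t_np1):
        raise ValueError("event times must be strictly increasing (nose poke < press < next)")
    dt = spec.dt
    total = spec.pre_window + median_ii + median_iii + spec.post_window
    u = np.arange(0.0, total + dt / 2, dt)  # adjusted time from warped-trial start
    src = np.empty_like(u)
    b1 = spec.pre_window
    b2 = b1 + median_ii
    b3 = b2 + median_iii
    seg1 = u < b1
    seg2 = (u >= b1) & (u < b2)
    seg3 = (u >= b2) & (u < b3)
    seg4 = u >= b3
    src[seg1] = t_np - spec.pre_window + u[seg1]
    src[seg2] = t_np + (u[seg2] - b1) * (t_lp - t_np) / median_ii
    src[seg3] = t_lp + (u[seg3] - b2) * (t_np1 - t_lp) / median_iii
    src[seg4] = t_np1 + (u[seg4] - b3)
    return u, src


def time_warp_trials(
    traces: np.ndarray,
    trace_t: np.ndarray,
    event_times: Sequence[dict],
    spec: WarpSpec = WarpSpec(),
) -> tuple[np.ndarray, np.ndarray, list]:
    """Warp per-trial traces onto the common adjusted-time grid.

    ``traces`` is (n_trials, n_neurons, n_time) sampled at ``trace_t``
    (absolute or trial-relative seconds, matching the per-trial event dicts,
    each with keys nose_poke, lever_press, next_nose_poke). Trials with
    non-monotone anchors are dropped and their indices returned.
    Returns (warped (n_kept, n_neurons, n_adjusted), adjusted grid, dropped).
    """
    median_ii, median_iii = _median_epochs(event_times)
    warped = []
    dropped = []
    u_grid = None
    for i, ev in enumerate(event_times):
        try:
            u, src = warp_time_map(ev, median_ii, median_iii, spec)
        except ValueError:
            dropped.append(i)
            continue
        u_grid = u
        w = np.empty((traces.shape[1], len(u)))
        for j in range(traces.shape[1]):
            w[j] = np.interp(src, trace_t, traces[i, j])
        warped.append(w)
    if not warped:
        raise ValueError("no trial survived warping")
    return np.stack(warped), u_grid, dropped


def timecourse_decoding(
    warped: np.ndarray,
    u_grid: np.ndarray,
    labels: np.ndarray,
    lag: int,
    spec: DecoderSpec,
    rng: np.random.Generator,
    warp_spec: WarpSpec = WarpSpec(),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin decoding accuracy of the label at ``lag`` trials.

    ``lag`` 0 decodes the current trial's label, -1 the previous, +1 the
    next. The sequence-type weights are always computed from the label
    sequence itself, then aligned to the lag. Returns (bin centers, accuracy).
    """
    if lag not in (-2, -1, 0, 1):
        raise ValueError("supported lags are -2, -1, 0, +1")
    n_trials = warped.shape[0]
    base_w = sequence_type_weights(labels)
    # align label at requested lag to each trial's activity
    idx = np.arange(n_trials) + lag
    ok = (idx >= 0) & (idx < n_trials)
    y = np.asarray(labels)[idx[ok]]
    w = base_w[idx[ok]]
    act = warped[ok]
    edges = np.arange(u_grid[0], u_grid[-1] + 1e-9, warp_spec.bin_size)
    centers = []
    accs = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (u_grid >= lo) & (u_grid < hi)
        if not m.any():
            continue
        feats = act[:, :, m].mean(axis=2)
        accs.append(decode_labels(feats, y, spec, rng, weights=w))
        centers.append((lo + hi) / 2)
    return np.asarray(centers), np.asarray(accs)


def above_chance_ttest(session_accuracies: np.ndarray, chance: float = 0.5) -> tuple:
    """Two-tailed one-sample t test of per-session accuracies against chance."""
    res = ttest_1samp(np.asarray(session_accuracies), chance)
    return float(res.statistic), float(res.pvalue)
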