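"""Synthetic choice-selective sequential population activity.

Real recordings of corticostriatal (PL-NAc style) populations show
choice-selective *sequences*: neurons preferring one lever fire in a reliable
temporal order tiling the interval from before the lever press through the
outcome. This module generates single-trial stand-ins for such activity so
that every downstream stage (encoding model, decoders, both circuit models)
is testable without recorded data.

Each model neuron carries a Gaussian temporal bump of unit nominal peak at a
fixed preferred time; on each trial the chosen side's neurons emit their bumps
(with per-trial peak jitter and multiplicative amplitude noise), the unchosen
side emits the same shape scaled by ``selectivity``, and the population is
smoothed with a 0.2 s Gaussian. Because a Gaussian bump convolved with a
Gaussian kernel is again Gaussian (sigma added in quadrature, peak scaled by
the sigma ratio), the smoothing is applied analytically; the result is
bit-identical to explicit convolution on the continuous profile.

Presets:

``pl_like``    consistent sequences, high selectivity (cortex-like input)
``mth_like``   inconsistent sequences, weak selectivity (thalamus-like input)
``early_only`` all peaks in the first 0.5 s of the sequence (control in which
               only decision-time neurons carry input)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .task_engine import InvalidConfigError, SessionRecord

NATIVE_RATE_HZ = 10.0  # imaging frame rate emulated by event-locked traces


@dataclass(frozen=True)
class SequenceProfile:
    n_per_side: int = 184
    span: tuple = (-2.0, 3.0)  # peak times tiled over this window (s, press at 0)
    bump_width: float = 0.3  # sd of the underlying Gaussian bump (s)
    # Nominal bump peak; unit peak is the normalized-rate convention shared
    # by the probe ("5% of peak" = 0.05) and stimulation (0.2, 0.15)
    # constants. It also keeps the TD value loop in its stable regime (the
    # loop gain alpha * sum_i f_i E_i scales with amplitude^2); see the
    # methods note.
    amplitude: float = 1.0
    selectivity: float = 0.1  # unchosen-side amplitude ratio; 0 = fully selective
    peak_jitter_sd: float = 0.1  # per-trial, per-neuron peak-time jitter (s)
    amplitude_noise_sd: float = 0.7  # multiplicative amplitude noise, sd
    background_noise_sd: float = 0.05  # additive rate noise floor (rectified), rate units
    # Fraction of trials on which a neuron fires at its assigned sequence
    # position; otherwise its bump lands uniformly in the span. Distinguishes
    # timing blur (jitter around a reliable position) from genuine pattern
    # unreliability, the defining weakness of thalamus-like input.
    pattern_reliability: float = 1.0
    smoothing_sd: float = 0.2  # Gaussian smoothing kernel sd (s)
    dt: float = 0.01
    t_min: float = -3.5  # grid start (s, covers the earliest trial starts)
    t_max: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.selectivity <= 1.0):
            raise InvalidConfigError("selectivity must lie in [0, 1]")
        if self.dt <= 0:
            raise InvalidConfigError("dt must be positive")
        if self.span[1] <= self.span[0]:
            raise InvalidConfigError("span must be increasing")

    @property
    def t_grid(self) -> np.ndarray:
        n = int(round((self.t_max - self.t_min) / self.dt)) + 1
        return self.t_min + self.dt * np.arange(n)

    def peak_times(self) -> np.ndarray:
        """Configured peak times for one side, strictly increasing."""
        return np.linspace(self.span[0], self.span[1], self.n_per_side)

    @property
    def effective_width(self) -> float:
        return math.hypot(self.bump_width, self.smoothing_sd)

    @property
    def peak_gain(self) -> float:
        """Peak amplitude after smoothing a unit-peak bump."""
        return self.bump_width / self.effective_width


@dataclass
class PopulationActivity:
    """Per-trial neuron x time rates with side labels and peak-time metadata."""

    rates: np.ndarray  # (n_neurons, n_time), nonnegative
    side_labels: np.ndarray  # (n_neurons,) of "left"/"right"
    peak_times: np.ndarray  # (n_neurons,) configured peak times (s)
    dt: float
    t0: float  # time of first sample relative to lever press (s)

    def __post_init__(self) -> None:
        if self.rates.ndim != 2 or self.rates.shape[0] != len(self.side_labels):
            raise ValueError("rates must be (n_neurons, n_time) matching side_labels")

    @property
    def t_grid(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.rates.shape[1])

    def side_mask(self, side: str) -> np.ndarray:
        return self.side_labels == side


@dataclass(frozen=True)
class GroundTruthKernels:
    """Generative truth for encoding-model validation.

    ``kernels`` maps event name -> 81-sample kernel on that event's window
    (-2..6 s for actions, 0..8 s for stimuli at 10 Hz); ``noise_sd`` is the
    i.i.d. Gaussian noise added to each generated trace.
    """

    kernels: dict
    noise_sd: float = 0.1
    window_starts: dict = field(default_factory=dict)  # event -> window start (s)


# ---------------------------------------------------------------------------
# presets


def make_profile_preset(name: str) -> SequenceProfile:
    base = SequenceProfile()
    if name == "pl_like":
        return base
    if name == "mth_like":
        return replace(
            base,
            selectivity=0.5,
            peak_jitter_sd=0.2,
            background_noise_sd=0.2,
            pattern_reliability=0.5,
        )
    if name == "early_only":
        # all peaks within the first 0.5 s of the sequence; the sequence onset
        # (mean trial start) is -2.5 s relative to press
        return replace(base, span=(-2.5, -2.0))
    raise InvalidConfigError(f"unknown profile preset {name!r}")


# ---------------------------------------------------------------------------
# single-trial generation


def generate_sequence_trial(
    side: str,
    profile: SequenceProfile,
    rng: np.random.Generator,
) -> PopulationActivity:
    """One trial of population activity given the chosen ``side``.

    Chosen-side neurons emit unit-nominal-peak Gaussian bumps at their tiled
    peak times (jittered per trial); the unchosen side emits the same shape
    scaled by ``selectivity``. Smoothing with the 0.2 s kernel is applied
    analytically (see module docstring). Rates are clipped at zero.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    p = profile
    n = p.n_per_side
    peaks_one = p.peak_times()
    peaks = np.concatenate([peaks_one, peaks_one])  # left block then right block
    sides = np.array(["left"] * n + ["right"] * n)

    jitter = rng.normal(0.0, p.peak_jitter_sd, size=2 * n) if p.peak_jitter_sd > 0 else 0.0
    amp = np.ones(2 * n)
    if p.amplitude_noise_sd > 0:
        amp = np.clip(1.0 + rng.normal(0.0, p.amplitude_noise_sd, size=2 * n), 0.0, None)
    amp = amp * np.where(sides == side, 1.0, p.selectivity) * p.amplitude

    t = p.t_grid
    mu = peaks + jitter
    if p.pattern_reliability < 1.0:
        stray = rng.random(2 * n) >= p.pattern_reliability
        mu = np.where(stray, rng.uniform(p.span[0], p.span[1], size=2 * n), mu)
    sigma = p.effective_width
    # (2n, T) Gaussian bumps, peak gain folds in the smoothing attenuation
    z = (t[None, :] - mu[:, None]) / sigma
    rates = (amp * p.peak_gain)[:, None] * np.exp(-0.5 * z * z)
    if p.background_noise_sd > 0:
        rates = rates + _band_limited_noise(
            rng, rates.shape, p.background_noise_sd, p.smoothing_sd, p.dt
        )
    np.clip(rates, 0.0, None, out=rates)
    return PopulationActivity(rates=rates, side_labels=sides, peak_times=peaks, dt=p.dt, t0=p.t_min)


def _band_limited_noise(
    rng: np.random.Generator,
    shape: tuple,
    sd: float,
    corr_time: float,
    dt: float,
) -> np.ndarray:
    """Additive background noise correlated on the smoothing timescale.

    White noise smoothed with the 0.2 s kernel is, to good approximation,
    noise drawn on a 0.2 s grid and linearly interpolated; the latter is used
    because it is far cheaper inside the per-trial simulation loop. ``sd`` is
    the noise sd on the coarse grid.
    """
    n_rows, n_t = shape
    step = max(1, int(round(corr_time / dt)))
    n_coarse = n_t // step + 2
    coarse = rng.normal(0.0, sd, size=(n_rows, n_coarse))
    pos = np.arange(n_t) / step
    idx = pos.astype(int)
    frac = pos - idx
    return coarse[:, idx] * (1.0 - frac) + coarse[:, idx + 1] * frac


def apply_stimulation(
    activity: PopulationActivity,
    mode: str,
    fraction: float = 0.7,
    rng: Optional[np.random.Generator] = None,
    t_on: Optional[float] = None,
    t_off: Optional[float] = None,
) -> PopulationActivity:
    """Optogenetic-like perturbation of a random subset of neurons.

    ``plasticity`` mode clamps selected neurons (both sides pooled) to a
    constant 0.2 from ``t_on`` (simulated nose poke) to ``t_off`` (2 s after
    reward presentation); ``dynamics`` mode clamps them to 0.15 for the whole
    trial. Unselected neurons are untouched.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    if mode not in ("plasticity", "dynamics"):
        raise ValueError(f"unknown stimulation mode {mode!r}")
    rng = np.random.default_rng() if rng is None else rng
    n = activity.rates.shape[0]
    selected = rng.random(n) < fraction
    rates = activity.rates.copy()
    if mode == "dynamics":
        rates[selected, :] = 0.15
    else:
        t = activity.t_grid
        lo = t[0] if t_on is None else t_on
        hi = t[-1] if t_off is None else t_off
        window = (t >= lo) & (t <= hi)
        rates[np.ix_(selected, window)] = 0.2
    return PopulationActivity(
        rates=rates,
        side_labels=activity.side_labels,
        peak_times=activity.peak_times,
        dt=activity.dt,
        t0=activity.t0,
    )


# ---------------------------------------------------------------------------
# sequence consistency (split-half peak-time correlation)


class SequenceConsistency(NamedTuple):
    r_squared: float
    n_excluded: int


def sequence_consistency(
    trials: Sequence[PopulationActivity],
    rng: np.random.Generator,
    silence_threshold: float = 1e-9,
) -> SequenceConsistency:
    """Split-half consistency of the population's temporal order.

    Trials are split into random halves; each neuron's peak time of the
    trial-averaged activity is computed per half and the squared Pearson
    correlation between halves is returned. Neurons silent (max activity below
    ``silence_threshold``) in either half are excluded and counted.
    """
    if len(trials) < 20:
        raise ValueError("need at least 20 trials for a split-half estimate")
    stack = np.stack([a.rates for a in trials])  # (n_trials, n_neurons, T)
    t = trials[0].t_grid
    idx = rng.permutation(len(trials))
    half_a, half_b = idx[: len(idx) // 2], idx[len(idx) // 2 :]
    mean_a = stack[half_a].mean(axis=0)
    mean_b = stack[half_b].mean(axis=0)
    alive = (mean_a.max(axis=1) > silence_threshold) & (mean_b.max(axis=1) > silence_threshold)
    n_excluded = int((~alive).sum())
    pk_a = t[np.argmax(mean_a[alive], axis=1)]
    pk_b = t[np.argmax(mean_b[alive], axis=1)]
    r = np.corrcoef(pk_a, pk_b)[0, 1]
    return SequenceConsistency(float(r * r), n_excluded)


# ---------------------------------------------------------------------------
# event-locked fluorescence with known ground-truth kernels

ACTION_EVENTS = ("nose_poke", "ipsi_press", "contra_press", "reward_consumption")
STIMULUS_EVENTS = ("levers_out", "cs_plus", "cs_minus")
KERNEL_LEN = 81


def default_window_start(event: str) -> float:
    """Kernel window start relative to the event: -2 s for actions, 0 for stimuli."""
    return -2.0 if event in ACTION_EVENTS or event in ("all_press",) else 0.0


def press_only_truth(amplitude: float = 1.0, noise_sd: float = 0.1) -> GroundTruthKernels:
    """Ground truth responding only to lever presses (encoding-model control)."""
    tt = np.linspace(-2.0, 6.0, KERNEL_LEN)
    bump = amplitude * np.exp(-0.5 * ((tt - 0.3) / 0.4) ** 2)
    kernels = {"ipsi_press": bump.copy(), "contra_press": bump.copy()}
    return GroundTruthKernels(kernels=kernels, noise_sd=noise_sd)


def session_event_streams(
    session: SessionRecord,
    rate_hz: float = NATIVE_RATE_HZ,
    iti_gap: float = 3.0,
) -> tuple[dict, int, np.ndarray]:
    """Binary event trains for one session on a common 10 Hz timeline.

    Lever-press choice is coded by side: right presses map to ``ipsi_press``
    and left presses to ``contra_press`` (the ipsilateral convention of a
    right-hemisphere recording). Returns (event trains, n_samples, absolute
    press times in seconds).
    """
    dt = 1.0 / rate_hz
    press_abs = []
    t_cursor = 5.0
    for trial in session.trials:
        ev = trial.event_times
        if not ev:
            raise ValueError(f"trial {trial.index} has no event times")
        press_abs.append(t_cursor - min(ev.values()))  # keep all events in-session
        t_end = t_cursor - min(ev.values()) + max(ev.values())
        t_cursor = t_end + iti_gap
    press_abs = np.asarray(press_abs)
    total_t = t_cursor + 10.0
    n_samples = int(round(total_t * rate_hz))
    names = (
        "nose_poke",
        "levers_out",
        "ipsi_press",
        "contra_press",
        "cs_plus",
        "cs_minus",
        "reward_consumption",
    )
    trains = {k: np.zeros(n_samples) for k in names}
    for trial, t_press in zip(session.trials, press_abs):
        ev = trial.event_times
        if trial.choice == "none":
            continue

        def put(name: str, t_rel: float) -> None:
            i = int(round((t_press + t_rel) * rate_hz))
            if 0 <= i < n_samples:
                trains[name][i] = 1.0

        put("nose_poke", ev["nose_poke"])
        put("levers_out", ev["levers_out"])
        put("ipsi_press" if trial.choice == "right" else "contra_press", 0.0)
        put("cs_plus" if trial.outcome else "cs_minus", ev["cs"])
        if trial.outcome and "reward_consumption" in ev:
            put("reward_consumption", ev["reward_consumption"])
    return trains, n_samples, press_abs


def generate_event_stream_session(
    session: SessionRecord,
    truth: GroundTruthKernels,
    n_neurons: int,
    rng: np.random.Generator,
    rate_hz: float = NATIVE_RATE_HZ,
) -> tuple[np.ndarray, dict]:
    """Z-scored 10 Hz traces generated from known event kernels.

    Each neuron's trace is the sum over the truth's events of the kernel
    convolved with the binary event train, plus i.i.d. Gaussian noise, then
    z-scored by session mean/sd. Returns (traces (n_neurons, T), event trains).
    """
    trains, n_samples, _ = session_event_streams(session, rate_hz)
    clean = np.zeros(n_samples)
    for event, kernel in truth.kernels.items():
        if event not in trains:
            raise ValueError(f"truth kernel references unknown event {event!r}")
        start = truth.window_starts.get(event, default_window_start(event))
        offset = int(round(start * rate_hz))
        conv = np.convolve(trains[event], kernel)[:n_samples]
        shifted = np.zeros(n_samples)
        if offset >= 0:
            shifted[offset:] = conv[: n_samples - offset] if offset else conv
        else:
            shifted[:offset] = conv[-offset:]
        clean += shifted
    traces = np.empty((n_neurons, n_samples))
    for i in range(n_neurons):
        tr = clean + (rng.normal(0.0, truth.noise_sd, n_samples) if truth.noise_sd > 0 else 0.0)
        sd = tr.std()
        traces[i] = (tr - tr.mean()) / sd if sd > 0 else tr - tr.mean()
    return traces, trains
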