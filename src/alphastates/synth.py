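"""Synthetic data with recoverable ground truth.

Emulates the structure of a parcellated MEG detection-task study: a
Markov chain of transient network states, each state expressed as
narrowband alpha oscillations (state-specific peak frequency, ~1 Hz
linewidth) on a set of parcels over a 1/f background; a blocked trial
schedule with an exact present/absent balance; and behavioral responses
drawn from a probit signal-detection model in which stimulus presence,
network alpha power and network on/off status jointly determine the
report.

Every generator takes an explicit seed (or ``numpy`` Generator) and the
ground truth (state path, per-trial covariates, coefficient vector,
random effects) is returned alongside the data so downstream inference
can be scored against it.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import norm

from .io import ParcelTimeSeries

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_state_sequence",
    "simulate_parcel_timeseries",
    "simulate_trials",
    "simulate_responses",
    "draw_subject_effects",
    "simulate_dataset",
]

#: Probit-scale coefficient vector (b0..b7) used by default: a mildly
#: conservative observer (c ~ 0.2) at threshold sensitivity (d' = 1.5),
#: whose sensitivity drops with network alpha power, more so when the
#: network is active.
DEFAULT_BETA = (-0.95, 1.5, 0.0, 0.0, 0.0, -0.3, 0.0, -0.2)


def _default_amp_map(n_parcels: int, n_states: int) -> np.ndarray:
    """Disjoint parcel blocks per state, unit oscillation amplitude."""
    amp = np.zeros((n_parcels, n_states))
    for p in range(n_parcels):
        amp[p, p % n_states] = 1.0
    return amp


def _sticky_transmat(n_states: int, stay: float = 0.96) -> np.ndarray:
    if n_states == 1:
        return np.ones((1, 1))
    off = (1.0 - stay) / (n_states - 1)
    tm = np.full((n_states, n_states), off)
    np.fill_diagonal(tm, stay)
    return tm


@dataclasses.dataclass
class SimConfig:
    """Study-scale generator configuration.

    Defaults mirror the emulated study: 52 parcels at 250 Hz, 8 network
    states with alpha peaks spread over 9.8-11 Hz, 32 subjects, 8 blocks
    of 80 main trials with exactly half grating-present, and block-level
    priming conditions (conservative/liberal) that enter behavior only
    through the subject:condition random effects.
    """

    n_parcels: int = 52
    fs: float = 250.0
    n_states: int = 8
    transmat: np.ndarray | None = None
    initial: np.ndarray | None = None
    state_peak_freq: np.ndarray | None = None  # Hz, one per state
    state_amp_map: np.ndarray | None = None  # parcels x states, a.u.
    aperiodic_exponent: float = 1.0
    noise_sd: float = 1.0
    # oscillation linewidth controls: the instantaneous frequency drifts
    # as an Ornstein-Uhlenbeck process, giving ~1.2 Hz FWHM at defaults
    freq_drift_rate: float = 1.0  # 1/s mean reversion of the drift
    freq_drift_sd: float = 0.5  # Hz, stationary SD of the drift
    am_depth: float = 0.2  # slow amplitude modulation depth
    n_subjects: int = 32
    n_blocks: int = 8
    n_main_trials_per_block: int = 80
    priming_labels: tuple[str, ...] | None = None  # per block
    signal_fraction: float = 0.5  # S=1 fraction among main trials
    trial_spacing_s: float = 2.0
    edge_buffer_s: float = 2.0
    beta_true: tuple[float, ...] = DEFAULT_BETA
    subject_re_sd: tuple[float, float] = (0.3, 0.3)
    subject_re_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        K = self.n_states
        if self.transmat is None:
            self.transmat = _sticky_transmat(K)
        self.transmat = np.asarray(self.transmat, float)
        if self.initial is None:
            self.initial = np.full(K, 1.0 / K)
        self.initial = np.asarray(self.initial, float)
        if self.state_peak_freq is None:
            self.state_peak_freq = (
                np.linspace(9.8, 11.0, K) if K > 1 else np.array([10.0])
            )
        self.state_peak_freq = np.asarray(self.state_peak_freq, float)
        if self.state_amp_map is None:
            self.state_amp_map = _default_amp_map(self.n_parcels, K)
        self.state_amp_map = np.asarray(self.state_amp_map, float)
        if self.priming_labels is None:
            self.priming_labels = tuple(
                ("conservative" if b % 2 == 0 else "liberal")
                for b in range(self.n_blocks)
            )
        _check_stochastic(self.transmat, "transmat")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-12):
            raise ValueError("initial distribution must sum to 1")
        if np.any(self.state_amp_map < 0):
            raise ValueError("oscillation amplitudes must be non-negative")
        if self.fs <= 2.0 * self.state_peak_freq.max():
            raise ValueError(
                "sampling rate must exceed twice the highest state peak "
                f"frequency ({self.state_peak_freq.max():g} Hz)"
            )
        if self.n_main_trials_per_block % 2:
            raise ValueError("n_main_trials_per_block must be even")
        if len(self.beta_true) != 8:
            raise ValueError("beta_true must have 8 entries (b0..b7)")
        if len(self.priming_labels) != self.n_blocks:
            raise ValueError("need one priming label per block")


@dataclasses.dataclass
class GroundTruth:
    """Everything downstream recovery is scored against."""

    state_paths: dict  # subject -> per-sample state index
    trial_table: pd.DataFrame  # subject, condition, block, onset_sample, S, Y
    beta_true: np.ndarray
    subject_effects: pd.DataFrame  # subject, condition, u0, u1
    P: np.ndarray | None = None  # generative per-trial power covariate
    A: np.ndarray | None = None  # generative per-trial activation


def _check_stochastic(mat: np.ndarray, name: str, atol: float = 1e-12) -> None:
    mat = np.asarray(mat, float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square")
    if np.any(mat < 0):
        raise ValueError(f"{name} has negative entries")
    sums = mat.sum(axis=1)
    bad = np.flatnonzero(~np.isclose(sums, 1.0, atol=atol))
    if bad.size:
        raise ValueError(
            f"{name} row {bad[0]} sums to {sums[bad[0]]:.12g}, not 1"
        )


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_state_sequence(
    transmat: np.ndarray,
    initial: np.ndarray,
    n_samples: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample a Markov state path of length ``n_samples``.

    Parameters
    ----------
    transmat
        K x K row-stochastic transition matrix.
    initial
        Length-K initial state distribution.
    n_samples
        Number of samples to draw.
    seed
        Integer seed or ``numpy`` Generator; the path is reproducible
        given the seed.
    """
    transmat = np.asarray(transmat, float)
    initial = np.asarray(initial, float)
    _check_stochastic(transmat, "transmat")
    if not np.isclose(initial.sum(), 1.0, atol=1e-12) or np.any(initial < 0):
        raise ValueError("initial distribution must be a probability vector")
    rng = _rng(seed)
    K = transmat.shape[0]
    path = np.empty(n_samples, dtype=np.int64)
    # inverse-CDF sampling against precomputed row CDFs
    cdf = np.cumsum(transmat, axis=1)
    u = rng.random(n_samples)
    path[0] = np.searchsorted(np.cumsum(initial), u[0], side="right")
    path[0] = min(path[0], K - 1)
    for t in range(1, n_samples):
        path[t] = np.searchsorted(cdf[path[t - 1]], u[t], side="right")
        if path[t] == K:  # guard against cumulative rounding
            path[t] = K - 1
    return path


def one_over_f_noise(
    n_samples: int, exponent: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """White noise spectrally shaped to power ~ 1/f**exponent, given SD."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * gain, n=n_samples)
    shaped -= shaped.mean()
    s = shaped.std()
    return shaped * (sd / s) if s > 0 else shaped


def _ou_process(
    n_samples: int, dt: float, rate: float, stat_sd: float, rng
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path (exact discretization)."""
    a = np.exp(-rate * dt)
    innov_sd = stat_sd * np.sqrt(1.0 - a * a)
    eps = rng.standard_normal(n_samples) * innov_sd
    eps[0] = rng.normal(0.0, stat_sd)
    # exact discretization is an AR(1); run it as a recursive filter
    return lfilter([1.0], [1.0, -a], eps)


def _narrowband_oscillation(
    n_samples: int, fs: float, freq: float, cfg: SimConfig, rng
) -> np.ndarray:
    """Unit-amplitude oscillation with slowly drifting phase and AM.

    The phase drift is the integral of an Ornstein-Uhlenbeck
    instantaneous-frequency deviation, which broadens the spectral
    line to a controllable width (~1.2 Hz FWHM at the defaults); a
    pure sinusoid would be a delta line and unfittable.
    """
    dt = 1.0 / fs
    t = np.arange(n_samples) * dt
    drift_hz = _ou_process(
        n_samples, dt, cfg.freq_drift_rate, cfg.freq_drift_sd, rng
    )
    phase = 2.0 * np.pi * np.cumsum(drift_hz) * dt
    env = 1.0 + cfg.am_depth * _ou_process(n_samples, dt, 1.0, 1.0, rng)
    env = np.clip(env, 0.0, None)
    return env * np.sin(2.0 * np.pi * freq * t + phase)


def simulate_parcel_timeseries(
    path: np.ndarray, cfg: SimConfig, seed: int | np.random.Generator = 0
) -> ParcelTimeSeries:
    """Render a state path into parcel signals.

    Each parcel is the sum over states of
    ``1[path == k] * amp[p, k] * oscillation_k(t)`` plus an independent
    1/f background of SD ``noise_sd``; parcels are mean-centered after
    generation.
    """
    path = np.asarray(path)
    n = path.size
    if n < cfg.fs:
        raise ValueError("state path must cover at least one second")
    if cfg.state_peak_freq.max() >= cfg.fs / 2:
        raise ValueError("state peak frequency at or above Nyquist")
    rng = _rng(seed)
    K = cfg.n_states
    osc = np.stack(
        [
            _narrowband_oscillation(n, cfg.fs, cfg.state_peak_freq[k], cfg, rng)
            for k in range(K)
        ]
    )
    onoff = np.stack([(path == k).astype(float) for k in range(K)])
    gated = osc * onoff  # states x samples
    data = cfg.state_amp_map @ gated
    for p in range(cfg.n_parcels):
        data[p] += one_over_f_noise(n, cfg.aperiodic_exponent, cfg.noise_sd, rng)
    data -= data.mean(axis=1, keepdims=True)
    return ParcelTimeSeries(data=data, fs=cfg.fs)


def required_samples(cfg: SimConfig) -> int:
    """Samples needed for one subject's full blocked trial schedule."""
    spacing = int(round(cfg.trial_spacing_s * cfg.fs))
    buffer = int(round(cfg.edge_buffer_s * cfg.fs))
    n_trials = cfg.n_blocks * cfg.n_main_trials_per_block
    return 2 * buffer + n_trials * spacing


def simulate_trials(
    cfg: SimConfig,
    seed: int | np.random.Generator = 0,
    n_samples: int | None = None,
) -> pd.DataFrame:
    """Blocked trial schedule (no responses yet) for the whole cohort.

    Within every block exactly ``signal_fraction`` of the main trials
    are grating-present (S=1), positions permuted by the seed; the block
    condition is its priming label.  Onsets sit on a fixed grid with
    ``trial_spacing_s`` spacing so analysis windows never straddle
    neighboring trials.
    """
    rng = _rng(seed)
    need = required_samples(cfg)
    if n_samples is not None and n_samples < need:
        raise ValueError(
            f"recording too short for the trial schedule: need {need} "
            f"samples, got {n_samples}"
        )
    spacing = int(round(cfg.trial_spacing_s * cfg.fs))
    buffer = int(round(cfg.edge_buffer_s * cfg.fs))
    n_sig = int(round(cfg.signal_fraction * cfg.n_main_trials_per_block))
    rows = []
    for s in range(cfg.n_subjects):
        subject = f"s{s:02d}"
        i_trial = 0
        for b in range(cfg.n_blocks):
            S = np.zeros(cfg.n_main_trials_per_block, dtype=int)
            S[:n_sig] = 1
            S = rng.permutation(S)
            for j in range(cfg.n_main_trials_per_block):
                rows.append(
                    {
                        "subject": subject,
                        "condition": cfg.priming_labels[b],
                        "block": b,
                        "onset_sample": buffer + i_trial * spacing,
                        "S": int(S[j]),
                    }
                )
                i_trial += 1
    return pd.DataFrame(rows)


def draw_subject_effects(
    cfg: SimConfig, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Random intercept/S-slope per subject:condition cell.

    Bivariate normal with SDs ``subject_re_sd`` and correlation
    ``subject_re_corr`` (diagonal by default).
    """
    rng = _rng(seed)
    sd0, sd1 = cfg.subject_re_sd
    rho = cfg.subject_re_corr
    cov = np.array(
        [[sd0**2, rho * sd0 * sd1], [rho * sd0 * sd1, sd1**2]]
    )
    rows = []
    conditions = sorted(set(cfg.priming_labels))
    for s in range(cfg.n_subjects):
        for cond in conditions:
            u = rng.multivariate_normal(np.zeros(2), cov)
            rows.append(
                {"subject": f"s{s:02d}", "condition": cond, "u0": u[0], "u1": u[1]}
            )
    return pd.DataFrame(rows)


def simulate_responses(
    trials: pd.DataFrame,
    P: np.ndarray,
    A: np.ndarray,
    beta_true: Sequence[float],
    subject_effects: pd.DataFrame | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Bernoulli "present" reports from the probit SDT model.

    The linear predictor per trial is
    ``(b0+u0) + (b1+u1) S + b2 P + b3 A + b4 P A + b5 S P + b6 S A +
    b7 S P A`` with (u0, u1) the subject:condition random effects, and
    ``Y ~ Bernoulli(Phi(eta))``.
    """
    beta = np.asarray(beta_true, float)
    if beta.size != 8:
        raise ValueError("beta_true must have 8 entries (b0..b7)")
    P = np.asarray(P, float)
    A = np.asarray(A, float)
    S = trials["S"].to_numpy(float)
    n = len(trials)
    if P.shape != (n,) or A.shape != (n,):
        raise ValueError("P and A must be per-trial vectors")
    u0 = np.zeros(n)
    u1 = np.zeros(n)
    if subject_effects is not None:
        eff = subject_effects.set_index(["subject", "condition"])
        keys = list(zip(trials["subject"], trials["condition"]))
        u = eff.loc[keys]
        u0 = u["u0"].to_numpy()
        u1 = u["u1"].to_numpy()
    eta = (
        beta[0]
        + u0
        + (beta[1] + u1) * S
        + beta[2] * P
        + beta[3] * A
        + beta[4] * P * A
        + beta[5] * S * P
        + beta[6] * S * A
        + beta[7] * S * P * A
    )
    rng = _rng(seed)
    return (rng.random(n) < norm.cdf(eta)).astype(int)


def _window_mask(n: int, center: int, half: int) -> slice:
    return slice(max(0, center - half), min(n, center + half + 1))


def simulate_dataset(
    cfg: SimConfig,
    seed: int | np.random.Generator = 0,
    coupling_state: int = 0,
    coupling_time_s: float = -0.2,
    make_recordings: bool = True,
):
    """Full cohort: recordings, schedule, and Eq.-style behavior.

    The behavioral covariates are the *generative* network power and
    activation of ``coupling_state`` in the 500-ms window centered at
    ``coupling_time_s`` relative to each onset: P is the log mean squared
    gated oscillation over that state's parcels, z-scored per subject;
    A is the any-on indicator of the true path.  Downstream estimators
    that measure power from the rendered signals should therefore
    recover the configured coefficient effects at (and, through window
    overlap, near) the coupling time.

    Returns
    -------
    recordings : dict[str, ParcelTimeSeries] (empty if not requested)
    truth : GroundTruth
    """
    rng = _rng(seed)
    n_samples = required_samples(cfg)
    trials = simulate_trials(cfg, rng, n_samples)
    effects = draw_subject_effects(cfg, rng)
    half = int(round(0.25 * cfg.fs))
    c_off = int(round(coupling_time_s * cfg.fs))
    state_parcels = np.flatnonzero(cfg.state_amp_map[:, coupling_state] > 0)

    recordings: dict[str, ParcelTimeSeries] = {}
    state_paths: dict[str, np.ndarray] = {}
    P_raw = np.empty(len(trials))
    A = np.empty(len(trials), dtype=int)
    for subject, idx in trials.groupby("subject", sort=True).groups.items():
        path = simulate_state_sequence(cfg.transmat, cfg.initial, n_samples, rng)
        state_paths[subject] = path
        onsets = trials.loc[idx, "onset_sample"].to_numpy()
        if make_recordings:
            recordings[subject] = simulate_parcel_timeseries(path, cfg, rng)
            sig = recordings[subject].data[state_parcels]
            gated = sig  # rendered parcels of the coupling state
        else:
            # analytic gate: oscillation energy proxy without rendering
            gated = (path == coupling_state).astype(float)[None, :]
        for row, onset in zip(idx, onsets):
            win = _window_mask(n_samples, onset + c_off, half)
            A[row] = int(np.any(path[win] == coupling_state))
            P_raw[row] = np.mean(gated[:, win] ** 2)
    # log then z-score within subject, matching the analysis convention
    P = np.log(np.maximum(P_raw, 1e-300))
    for subject, idx in trials.groupby("subject", sort=True).groups.items():
        v = P[idx]
        sd = v.std()
        P[idx] = (v - v.mean()) / sd if sd > 0 else 0.0
    Y = simulate_responses(trials, P, A, cfg.beta_true, effects, rng)
    trials = trials.assign(Y=Y)
    truth = GroundTruth(
        state_paths=state_paths,
        trial_table=trials,
        beta_true=np.asarray(cfg.beta_true, float),
        subject_effects=effects,
        P=P,
        A=A,
    )
    return recordings, truth
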