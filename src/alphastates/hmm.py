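"""Time-delay embedded hidden Markov model (TDE-HMM).

A K-state HMM with zero-mean multivariate Gaussian emissions over a
time-delay embedded signal space: each sample is augmented with lagged
copies of every parcel, so the state covariances encode spectral
content and the states become transient spatio-spectral networks.

Estimation is maximum-likelihood EM (scaled forward-backward E-step,
closed-form M-step) with multiple seeded restarts; the restart with the
highest log-likelihood is kept, playing the role that lowest free
energy plays for variational fits of the same generative model.

Usage follows the Model/Results convention::

    model = TDEHMM(ts, n_states=8, n_lags=15)
    res = model.fit(n_restarts=10, seed=0)
    res.gammas, res.viterbi, res.transmat
    print(res.summary())
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import linear_sum_assignment

from .io import ParcelTimeSeries

__all__ = [
    "EmbeddedData",
    "HMMParams",
    "TDEHMM",
    "TDEHMMResults",
    "embed",
    "forward_backward",
    "viterbi",
    "epoch_state_timecourses",
    "match_state_labels",
]


@dataclasses.dataclass
class EmbeddedData:
    """Lag-embedded data matrix plus bookkeeping.

    ``X`` holds one row per *valid* sample (those with all lags inside
    the recording); ``valid`` marks the original samples those rows came
    from, so downstream state time courses can be re-aligned.
    """

    X: np.ndarray  # valid samples x (n_parcels * n_lags)
    valid: np.ndarray  # boolean over original samples
    lags: np.ndarray  # in samples, symmetric about 0
    lags_ms: np.ndarray
    n_samples: int
    n_parcels: int


@dataclasses.dataclass
class HMMParams:
    """Fitted HMM parameters (emission means are fixed at zero)."""

    n_states: int
    transmat: np.ndarray
    initial: np.ndarray
    covariances: np.ndarray  # K x d x d, symmetric positive definite
    loglik: float = np.nan


def embed(
    ts: ParcelTimeSeries | np.ndarray,
    n_lags: int,
    fs: float | None = None,
    standardize: bool = True,
) -> EmbeddedData:
    """Time-delay embed a parcels-x-samples recording.

    Row t concatenates, for each lag in the symmetric lag set, all
    parcels at ``t + lag``.  ``n_lags`` must be odd so the set is
    symmetric about zero; with 15 lags at 250 Hz the maximum lag is
    7 samples = 28 ms.  Each parcel is z-scored first by default so the
    zero-mean Gaussian observation model is well posed.
    """
    if isinstance(ts, ParcelTimeSeries):
        data, fs = ts.data, ts.fs
    else:
        data = np.asarray(ts, float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    if n_lags < 1 or n_lags % 2 == 0:
        raise ValueError("n_lags must be odd (symmetric lag set) and >= 1")
    n_parcels, n_samples = data.shape
    if n_samples <= n_lags:
        raise ValueError("recording shorter than the lag window")
    if standardize:
        mu = data.mean(axis=1, keepdims=True)
        sd = data.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        data = (data - mu) / sd
    half = (n_lags - 1) // 2
    lags = np.arange(-half, half + 1)
    valid = np.zeros(n_samples, dtype=bool)
    valid[half : n_samples - half] = True
    t_idx = np.flatnonzero(valid)
    cols = [data[:, t_idx + lag].T for lag in lags]  # each: T_valid x P
    X = np.concatenate(cols, axis=1)
    return EmbeddedData(
        X=X,
        valid=valid,
        lags=lags,
        lags_ms=lags * 1000.0 / fs,
        n_samples=n_samples,
        n_parcels=n_parcels,
    )


# ---------------------------------------------------------------------------
# core recursions


def _state_loglik(X: np.ndarray, covariances: np.ndarray) -> np.ndarray:
    """Per-sample, per-state zero-mean Gaussian log density (T x K)."""
    T, d = X.shape
    K = covariances.shape[0]
    out = np.empty((T, K))
    for k in range(K):
        try:
            L = np.linalg.cholesky(covariances[k])
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"state {k} covariance is not positive definite"
            ) from err
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        z = solve_triangular(L, X.T, lower=True)  # d x T
        maha = np.sum(z * z, axis=0)
        out[:, k] = -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)
    return out


def _scaled_forward_backward(log_b, transmat, initial):
    """Scaled forward-backward.

    Returns exact posteriors ``gamma`` (T x K), pairwise-transition
    expectations summed over time (K x K), and the data log-likelihood.
    Emission likelihoods are rescaled per sample before exponentiation;
    the scaling cancels in the posteriors and is added back to the
    log-likelihood.
    """
    T, K = log_b.shape
    shift = log_b.max(axis=1)
    b = np.exp(log_b - shift[:, None])
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = initial * b[0]
    c[0] = a.sum()
    if c[0] == 0:
        raise FloatingPointError("impossible sample at t=0 (zero likelihood)")
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ transmat) * b[t]
        c[t] = a.sum()
        if c[t] == 0:
            raise FloatingPointError(
                f"impossible sample at t={t} (zero likelihood)"
            )
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (transmat @ (b[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    # xi summed over t, vectorized from stored alpha/beta
    w = (b[1:] * beta[1:]) / c[1:, None]  # (T-1) x K
    xi_sum = (alpha[:-1].T @ w) * transmat
    loglik = float(np.sum(np.log(c)) + shift.sum())
    return gamma, xi_sum, loglik


def _viterbi_path(log_b, transmat, initial) -> np.ndarray:
    """Most probable path; ties broken toward the lower state index."""
    T, K = log_b.shape
    with np.errstate(divide="ignore"):
        logA = np.log(transmat)
        logpi = np.log(initial)
    delta = logpi + log_b[0]
    psi = np.empty((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + logA  # prev x next
        psi[t] = np.argmax(cand, axis=0)  # first max -> lower index
        delta = cand[psi[t], np.arange(K)] + log_b[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def _as_embedded(embedded) -> tuple[np.ndarray, EmbeddedData | None]:
    if isinstance(embedded, EmbeddedData):
        return embedded.X, embedded
    return np.asarray(embedded, float), None


def forward_backward(params: HMMParams, embedded) -> np.ndarray:
    """Exact per-sample state posteriors (gammas) under fixed parameters."""
    X, _ = _as_embedded(embedded)
    log_b = _state_loglik(X, params.covariances)
    gamma, _, _ = _scaled_forward_backward(log_b, params.transmat, params.initial)
    return gamma


def viterbi(params: HMMParams, embedded) -> np.ndarray:
    """Joint-probability-maximizing hard state path."""
    X, _ = _as_embedded(embedded)
    log_b = _state_loglik(X, params.covariances)
    return _viterbi_path(log_b, params.transmat, params.initial)


# ---------------------------------------------------------------------------
# model / results


class TDEHMM:
    """TDE-HMM model bound to one (possibly concatenated) recording.

    Parameters
    ----------
    ts
        ``ParcelTimeSeries`` or parcels-x-samples array (then ``fs`` is
        required).
    n_states
        Number of hidden states K.
    n_lags
        Odd number of embedding lags; ``n_lags=1`` disables embedding.
    pca
        Optional rank for a PCA projection of the embedded space
        (default off: the embedded dimension is small in the intended
        simulations).
    """

    def __init__(
        self,
        ts,
        n_states: int = 8,
        n_lags: int = 15,
        fs: float | None = None,
        standardize: bool = True,
        pca: int | None = None,
    ):
        if n_states < 1:
            raise ValueError("n_states must be >= 1")
        self.n_states = n_states
        self.n_lags = n_lags
        self.embedded = embed(ts, n_lags, fs=fs, standardize=standardize)
        X = self.embedded.X
        self._pca_components = None
        if pca is not None:
            Xc = X - X.mean(axis=0)
            _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
            self._pca_components = Vt[:pca]
            X = Xc @ self._pca_components.T
        self.X = X
        if self.X.shape[0] < 10 * n_states:
            raise ValueError("need at least 10*K embedded samples")

    # -- EM -------------------------------------------------------------

    def _m_step(self, gamma, xi_sum, reg_scale):
        K = self.n_states
        X = self.X
        occ = gamma.sum(axis=0)
        covs = np.empty((K, X.shape[1], X.shape[1]))
        for k in range(K):
            w = gamma[:, k]
            covs[k] = (X.T * w) @ X / occ[k]
            covs[k] += reg_scale * np.mean(np.diag(covs[k])) * np.eye(X.shape[1])
        if K == 1:
            transmat = np.ones((1, 1))
        else:
            transmat = xi_sum / xi_sum.sum(axis=1, keepdims=True)
        initial = gamma[0] / gamma[0].sum()
        return transmat, initial, covs

    def _run_em(self, rng, max_iter, tol, reg_scale):
        T = self.X.shape[0]
        K = self.n_states
        gamma = rng.random((T, K)) + 0.1
        gamma /= gamma.sum(axis=1, keepdims=True)
        # initial pseudo-counts for transitions: mildly sticky
        xi_sum = np.full((K, K), 1.0) + 10.0 * np.eye(K)
        transmat, initial, covs = self._m_step(gamma, xi_sum, reg_scale)
        loglik_hist = []
        for _ in range(max_iter):
            log_b = _state_loglik(self.X, covs)
            gamma, xi_sum, loglik = _scaled_forward_backward(
                log_b, transmat, initial
            )
            loglik_hist.append(loglik)
            transmat, initial, covs = self._m_step(gamma, xi_sum, reg_scale)
            if len(loglik_hist) > 1 and (
                loglik_hist[-1] - loglik_hist[-2] < tol * abs(loglik_hist[-2])
            ):
                break
        log_b = _state_loglik(self.X, covs)
        gamma, _, loglik = _scaled_forward_backward(log_b, transmat, initial)
        loglik_hist.append(loglik)
        params = HMMParams(K, transmat, initial, covs, loglik)
        return params, gamma, log_b, loglik_hist

    def fit(
        self,
        n_restarts: int = 10,
        max_iter: int = 100,
        tol: float = 1e-6,
        seed: int = 0,
        reg_scale: float = 1e-6,
    ) -> "TDEHMMResults":
        """Run EM from ``n_restarts`` seeded initializations.

        The restart with the highest final log-likelihood wins.  A
        restart whose covariances collapse (non-PD after the epsilon*I
        regularization) is abandoned with a warning; if every restart
        collapses an error is raised.
        """
        ss = np.random.SeedSequence(seed)
        best = None
        restart_logliks = []
        for child in ss.spawn(max(n_restarts, 1)):
            rng = np.random.default_rng(child)
            try:
                params, gamma, log_b, hist = self._run_em(
                    rng, max_iter, tol, reg_scale
                )
            except (np.linalg.LinAlgError, FloatingPointError) as err:
                warnings.warn(f"EM restart abandoned: {err}")
                restart_logliks.append(float("nan"))
                continue
            restart_logliks.append(hist[-1])
            if best is None or hist[-1] > best[0]:
                best = (hist[-1], params, gamma, log_b, hist)
        if best is None:
            raise RuntimeError("all EM restarts failed (covariance collapse)")
        _, params, gamma, log_b, hist = best
        vpath = _viterbi_path(log_b, params.transmat, params.initial)
        return TDEHMMResults(
            model=self,
            params=params,
            gammas_valid=gamma,
            viterbi_valid=vpath,
            loglik_history=hist,
            restart_logliks=restart_logliks,
        )


class TDEHMMResults:
    """Fitted TDE-HMM: parameters plus per-sample state inference.

    ``gammas`` and ``viterbi`` cover every original sample; the edge
    samples invalidated by the embedding are imputed from the nearest
    valid sample so downstream trial alignment stays simple.
    """

    def __init__(
        self, model, params, gammas_valid, viterbi_valid, loglik_history,
        restart_logliks,
    ):
        self.model = model
        self.params = params
        self.loglik_history = list(loglik_history)
        self.restart_logliks = list(restart_logliks)
        emb = model.embedded
        self.gammas = _expand_to_samples(gammas_valid, emb.valid)
        self.viterbi = _expand_to_samples(
            viterbi_valid[:, None], emb.valid
        )[:, 0].astype(np.int64)

    @property
    def n_states(self) -> int:
        return self.params.n_states

    @property
    def transmat(self) -> np.ndarray:
        return self.params.transmat

    @property
    def loglik(self) -> float:
        return self.params.loglik

    @property
    def fractional_occupancy(self) -> np.ndarray:
        return self.gammas.mean(axis=0)

    def summary(self) -> str:
        lines = [
            "TDE-HMM fit",
            f"  states: {self.n_states}   lags: {self.model.n_lags} "
            f"(max |lag| {np.abs(self.model.embedded.lags_ms).max():.0f} ms)",
            f"  log-likelihood: {self.loglik:.2f} "
            f"({sum(np.isfinite(self.restart_logliks))} successful restarts)",
            f"  fractional occupancy: "
            + " ".join(f"{o:.3f}" for o in self.fractional_occupancy),
            f"  transmat diagonal:    "
            + " ".join(f"{d:.3f}" for d in np.diag(self.transmat)),
        ]
        return "\n".join(lines)

    def model_card(self) -> dict:
        return {
            "n_states": self.n_states,
            "n_lags": self.model.n_lags,
            "loglik": self.loglik,
            "restart_logliks": self.restart_logliks,
            "fractional_occupancy": self.fractional_occupancy.tolist(),
        }


def _expand_to_samples(values_valid, valid_mask):
    """Spread valid-sample rows back to full length, edge-imputing."""
    n = valid_mask.size
    out = np.empty((n, values_valid.shape[1]), dtype=values_valid.dtype)
    idx_valid = np.flatnonzero(valid_mask)
    nearest = np.clip(
        np.searchsorted(idx_valid, np.arange(n)), 0, idx_valid.size - 1
    )
    # searchsorted gives the next valid index; for trailing edges clip
    # already maps to the last valid sample, which is the nearest one.
    out[:] = values_valid[nearest]
    return out


def epoch_state_timecourses(
    gammas: np.ndarray,
    onsets: np.ndarray,
    fs: float,
    window_s: tuple[float, float] = (-1.0, 1.0),
    baseline_s: float = 0.1,
):
    """Trial-locked evoked state probabilities.

    Epochs the state posteriors around each onset, averages over
    trials, and subtracts the mean of the pre-stimulus baseline window
    (the ``baseline_s`` seconds immediately before onset) per state.
    Out-of-bounds epochs are dropped and counted.

    Returns a dict with ``times`` (s, relative to onset), ``epochs``
    (kept trials x states x times), ``evoked`` (states x times,
    baseline-corrected trial average) and ``n_dropped``.
    """
    gammas = np.asarray(gammas, float)
    onsets = np.asarray(onsets, int)
    n_samples, K = gammas.shape
    i0 = int(round(window_s[0] * fs))
    i1 = int(round(window_s[1] * fs))
    if i1 <= i0:
        raise ValueError("window end must exceed window start")
    rel = np.arange(i0, i1 + 1)
    times = rel / fs
    keep, epochs = [], []
    for onset in onsets:
        lo, hi = onset + i0, onset + i1
        if lo < 0 or hi >= n_samples:
            continue
        keep.append(onset)
        epochs.append(gammas[lo : hi + 1].T)  # K x times
    n_dropped = onsets.size - len(keep)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} out-of-bounds epochs")
    if not epochs:
        raise ValueError("no epochs fall inside the recording")
    epochs = np.stack(epochs)
    evoked = epochs.mean(axis=0)
    base = (times >= -baseline_s) & (times < 0)
    if base.any():
        evoked = evoked - evoked[:, base].mean(axis=1, keepdims=True)
    return {
        "times": times,
        "epochs": epochs,
        "evoked": evoked,
        "n_dropped": n_dropped,
    }


def match_state_labels(gammas_a: np.ndarray, gammas_b: np.ndarray) -> np.ndarray:
    """Permutation aligning states of B to A by maximal total correlation.

    Hungarian assignment on the pairwise gamma correlation matrix;
    returns ``perm`` such that state ``perm[k]`` of B corresponds to
    state ``k`` of A.
    """
    Ka = gammas_a.shape[1]
    corr = np.corrcoef(gammas_a.T, gammas_b.T)[:Ka, Ka:]
    corr = np.nan_to_num(corr)
    _, cols = linear_sum_assignment(-corr)
    return cols
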