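"""Cluster-based permutation inference over time courses.

Contiguous runs of supra-threshold statistics are summed into cluster
masses and compared against the permutation distribution of the
maximal cluster mass, which controls the family-wise error over
timepoints without parametric assumptions about temporal dependence.
Three permutation schemes are provided: within-subject shuffling of
the trial-wise neural covariates for the GLMM coefficient time
courses, condition-label flips for evoked state responses, and
epoch-vs-zeros swaps for baseline tests (both of the latter reduce to
per-subject sign flips of a difference series).

Monte-Carlo p-values use the add-one rule, p = (1 + #{null >=
observed}) / (1 + n_perm), so p is never exactly zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from .glmm import CONTRASTS, ProbitSDTGLMM, _batched_probit_fit, _design_matrix

__all__ = [
    "Cluster",
    "ClusterResult",
    "find_clusters",
    "permute_glmm",
    "permute_evoked",
]


@dataclasses.dataclass
class Cluster:
    start: int  # first supra-threshold index
    stop: int  # one past the last (python slice convention)
    mass: float  # sum of the statistic over the run


@dataclasses.dataclass
class ClusterResult:
    clusters: list  # of Cluster
    pvalues: np.ndarray  # one per cluster
    null_max_mass: np.ndarray  # permutation distribution
    n_perm: int
    seed: int
    stat: np.ndarray | None = None  # observed statistic series
    stat_p: np.ndarray | None = None  # per-timepoint uncorrected p

    def significant(self, alpha: float = 0.05):
        return [
            c for c, p in zip(self.clusters, self.pvalues) if p <= alpha
        ]


def _runs(mask: np.ndarray):
    """Start/stop pairs of maximal True runs."""
    idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    return list(zip(idx[::2], idx[1::2]))


def _clusters_from_mask(mask, stat):
    return [Cluster(a, b, float(stat[a:b].sum())) for a, b in _runs(mask)]


def find_clusters(stat, threshold: float, tail: str = "greater"):
    """Maximal contiguous runs of supra-threshold statistics.

    Strictly greater than ``threshold`` (a value equal to the
    threshold is excluded).  ``tail="two"`` returns positive runs
    (stat > threshold) and negative runs (stat < -threshold)
    separately, with signed masses.
    """
    stat = np.asarray(stat, float)
    if not np.all(np.isfinite(stat)):
        raise ValueError("statistic series must be finite")
    out = _clusters_from_mask(stat > threshold, stat)
    if tail == "two":
        out += _clusters_from_mask(stat < -threshold, stat)
        out.sort(key=lambda c: c.start)
    elif tail != "greater":
        raise ValueError("tail must be 'greater' or 'two'")
    return out


def _mc_pvalues(clusters, null_max: np.ndarray) -> np.ndarray:
    return np.array(
        [
            (1.0 + np.sum(null_max >= abs(c.mass))) / (1.0 + null_max.size)
            for c in clusters
        ]
    )


# ---------------------------------------------------------------------------
# GLMM coefficient time courses


def _contrast_series(beta, cov, contrasts, df):
    """Per-timepoint F and p for each contrast from batched fits."""
    out = {}
    for name, c in contrasts.items():
        est = beta @ c
        var = np.einsum("p,tpq,q->t", c, cov, c)
        F = est**2 / np.maximum(var, 1e-300)
        out[name] = (F, f_dist.sf(F, 1, df))
    return out


def _fit_series(y, S, P, A, groups, method, contrasts):
    """Contrast F/p series over timepoints; P, A are trials x T."""
    T = P.shape[1]
    if method == "fixed":
        Xs = np.stack(
            [_design_matrix(S, P[:, j], A[:, j]) for j in range(T)]
        )
        beta, cov = _batched_probit_fit(Xs, y)
        return _contrast_series(beta, cov, contrasts, y.size - Xs.shape[2])
    out = {name: (np.empty(T), np.empty(T)) for name in contrasts}
    for j in range(T):
        fit = ProbitSDTGLMM(y, S, P[:, j], A[:, j], groups).fit(method=method)
        for name, c in contrasts.items():
            _, _, F, p = fit.contrast(c)
            out[name][0][j] = F
            out[name][1][j] = p
    return out


def permute_glmm(
    trials: pd.DataFrame,
    netpower,
    contrasts=None,
    n_perm: int = 400,
    seed: int = 0,
    cluster_alpha: float = 0.05,
    method: str = "fixed",
):
    """Cluster permutation test on GLMM contrast time courses.

    The observed per-timepoint F series for each SDT contrast is
    thresholded at uncorrected p < ``cluster_alpha`` and clustered;
    each permutation shuffles whole per-trial (P, A) covariate rows
    across trials *within subject* (jointly, preserving the P-A
    pairing), refits every timepoint, and records the maximal cluster
    mass.  ``method`` selects the per-timepoint estimator, used
    identically for observed and permuted data.

    Returns ``{contrast_name: ClusterResult}``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    contrasts = dict(contrasts or CONTRASTS)
    sub = trials.iloc[netpower.trial_index]
    subjects = sub["subject"].to_numpy()
    if pd.Series(subjects).value_counts().min() < 2:
        raise ValueError("need at least 2 trials per subject to permute")
    groups = (
        sub["subject"].astype(str) + ":" + sub["condition"].astype(str)
    ).to_numpy()
    y = sub["Y"].to_numpy(float)
    S = sub["S"].to_numpy(float)
    P, A = netpower.P, netpower.A

    observed = _fit_series(y, S, P, A, groups, method, contrasts)
    obs_clusters = {
        name: _clusters_from_mask(pv < cluster_alpha, F)
        for name, (F, pv) in observed.items()
    }

    rng = np.random.default_rng(seed)
    subj_idx = [np.flatnonzero(subjects == s) for s in np.unique(subjects)]
    null = {name: np.zeros(n_perm) for name in contrasts}
    perms = np.tile(np.arange(y.size), (n_perm, 1))
    for b in range(n_perm):
        for idx in subj_idx:
            perms[b, idx] = rng.permutation(idx)
    if method == "fixed":
        # batch permutations x timepoints into joint vectorized fits
        T = P.shape[1]
        df_resid = y.size - 8
        chunk = max(1, 4096 // max(T * (y.size // 256), 1))
        for lo in range(0, n_perm, chunk):
            pc = perms[lo : lo + chunk]
            c = pc.shape[0]
            Pp = np.swapaxes(P[pc], 1, 2)  # c x T x n
            Ap = np.swapaxes(A[pc], 1, 2)
            ones = np.broadcast_to(np.ones_like(S), (c, T, y.size))
            Sb = np.broadcast_to(S, (c, T, y.size))
            Xs = np.stack(
                [ones, Sb, Pp, Ap, Pp * Ap, Sb * Pp, Sb * Ap, Sb * Pp * Ap],
                axis=-1,
            ).reshape(c * T, y.size, 8)
            beta, cov = _batched_probit_fit(Xs, y)
            for name, cvec in contrasts.items():
                est = (beta @ cvec).reshape(c, T)
                var = np.einsum("p,tpq,q->t", cvec, cov, cvec).reshape(c, T)
                F = est**2 / np.maximum(var, 1e-300)
                pv = f_dist.sf(F, 1, df_resid)
                for i in range(c):
                    clu = _clusters_from_mask(pv[i] < cluster_alpha, F[i])
                    null[name][lo + i] = max(
                        (abs(x.mass) for x in clu), default=0.0
                    )
    else:
        for b in range(n_perm):
            series = _fit_series(
                y, S, P[perms[b]], A[perms[b]], groups, method, contrasts
            )
            for name, (F, pv) in series.items():
                clu = _clusters_from_mask(pv < cluster_alpha, F)
                null[name][b] = max((abs(c.mass) for c in clu), default=0.0)

    out = {}
    for name in contrasts:
        F, pv = observed[name]
        cl = obs_clusters[name]
        out[name] = ClusterResult(
            clusters=cl,
            pvalues=_mc_pvalues(cl, null[name]),
            null_max_mass=null[name],
            n_perm=n_perm,
            seed=seed,
            stat=F,
            stat_p=pv,
        )
    return out


# ---------------------------------------------------------------------------
# evoked state responses


def permute_evoked(
    epochs: np.ndarray,
    mode: str = "baseline",
    n_perm: int = 1000,
    seed: int = 0,
    cluster_alpha: float = 0.05,
) -> ClusterResult:
    """Cluster permutation test on subject-level evoked time courses.

    ``mode="condition"`` takes ``epochs`` as subjects x 2 x time and
    tests the condition difference (label flips within subject);
    ``mode="baseline"`` takes subjects x time, already
    baseline-corrected, and tests against zero (each permutation swaps
    a random subset of subjects' epochs with flat-zero series).  Both
    schemes amount to per-subject sign flips of a difference series,
    tested with two-tailed paired t statistics and signed clusters.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    epochs = np.asarray(epochs, float)
    if mode == "condition":
        if epochs.ndim != 3 or epochs.shape[1] != 2:
            raise ValueError("condition mode expects subjects x 2 x time")
        diff = epochs[:, 0] - epochs[:, 1]
    elif mode == "baseline":
        if epochs.ndim != 2:
            raise ValueError("baseline mode expects subjects x time")
        diff = epochs
    else:
        raise ValueError("mode must be 'condition' or 'baseline'")
    n_subj = diff.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    df = n_subj - 1
    tcrit = t_dist.isf(cluster_alpha / 2.0, df)

    def t_series(d):
        sd = d.std(axis=0, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        return d.mean(axis=0) / (sd / np.sqrt(n_subj))

    tobs = t_series(diff)
    clusters = find_clusters(tobs, tcrit, tail="two")
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    null = np.zeros(n_perm)
    for b in range(n_perm):
        tb = t_series(diff * signs[b][:, None])
        cl = find_clusters(tb, tcrit, tail="two")
        null[b] = max((abs(c.mass) for c in cl), default=0.0)
    return ClusterResult(
        clusters=clusters,
        pvalues=_mc_pvalues(clusters, null),
        null_max_mass=null,
        n_perm=n_perm,
        seed=seed,
        stat=tobs,
        stat_p=2.0 * t_dist.sf(np.abs(tobs), df),
    )
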