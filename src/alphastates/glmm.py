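"""Probit mixed model linking neural covariates to detection reports.

The model is, in Wilkinson notation,

    Y ~ 1 + S*P*A + (1 + S | subject:condition)

with a probit link: the report probability is Phi of a full factorial
of stimulus presence S, standardized network alpha power P and network
activation A (eight fixed effects b0..b7), plus a random intercept and
S-slope per subject-by-condition cell.  Because the probit of the
hit/false-alarm rates are linear in the same coefficients, fitted
coefficients translate exactly into signal-detection language:

    d'            = b1 + b5 P + b6 A + b7 P A
    c             = -(b0 + b1/2) - (b2 + b5/2) P - (b3 + b6/2) A
                    - (b4 + b7/2) P A

so b5 (state off) and b5+b7 (state on) are the power modulations of
sensitivity, and -(b2+b5/2) / -(b2+b5/2+b4+b7/2) those of criterion.

Estimation maximizes the Laplace approximation to the marginal
likelihood: an inner penalized Newton solve for the fixed effects and
the spherical random effects jointly, and an outer derivative-free
search over the three free elements of the random-effect Cholesky
factor.  A plain probit GLM with cluster-robust covariance is both the
``method="fixed"`` estimator and the documented fallback when the
mixed fit does not converge.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr, ndtr
from scipy.stats import f as f_dist

__all__ = [
    "ProbitSDTGLMM",
    "ProbitSDTGLMMResults",
    "derive_sdt_betas",
    "beta_timecourse",
    "TERM_NAMES",
    "CONTRASTS",
]

TERM_NAMES = ("Intercept", "S", "P", "A", "P:A", "S:P", "S:A", "S:P:A")

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _mills(eta: np.ndarray) -> np.ndarray:
    """phi(eta)/Phi(eta), computed in the log domain for stability."""
    return np.exp(-0.5 * eta**2 - _LOG_SQRT_2PI - log_ndtr(eta))


def _probit_derivs(y: np.ndarray, eta: np.ndarray):
    """Log-likelihood, score and observed information w.r.t. eta."""
    ll = np.where(y == 1, log_ndtr(eta), log_ndtr(-eta)).sum()
    lam_p = _mills(eta)
    lam_m = _mills(-eta)
    s = np.where(y == 1, lam_p, -lam_m)
    h = np.where(y == 1, lam_p * (eta + lam_p), lam_m * (lam_m - eta))
    return ll, s, np.maximum(h, 1e-12)


def _design_matrix(S, P, A):
    S = np.asarray(S, float)
    P = np.asarray(P, float)
    A = np.asarray(A, float)
    one = np.ones_like(S)
    return np.column_stack([one, S, P, A, P * A, S * P, S * A, S * P * A])


@dataclasses.dataclass
class ProbitSDTGLMMResults:
    """Estimates on the full 8-term parameterization.

    Omitted (inestimable) terms carry NaN in ``params``/``bse`` and are
    listed in ``omitted``.  ``fvalues`` are per-term Wald F statistics
    (squared z, 1 numerator df) with p-values from F(1, df_resid).
    """

    params: np.ndarray  # length 8
    cov_params: np.ndarray  # 8 x 8
    re_cov: np.ndarray | None  # 2 x 2 random-effect covariance
    loglik: float
    converged: bool
    method: str
    nobs: int
    n_groups: int
    omitted: tuple[str, ...] = ()
    random_effects: np.ndarray | None = None  # groups x 2 (BLUP-style modes)
    group_labels: tuple | () = ()

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def df_resid(self) -> int:
        return self.nobs - int(np.sum(np.isfinite(self.params)))

    @property
    def fvalues(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return (self.params / self.bse) ** 2

    @property
    def pvalues(self) -> np.ndarray:
        return f_dist.sf(self.fvalues, 1, self.df_resid)

    def contrast(self, c: np.ndarray):
        """Estimate, SE, F and p of a linear contrast c'beta."""
        c = np.asarray(c, float)
        used = c != 0
        if np.any(~np.isfinite(self.params[used])):
            return np.nan, np.nan, np.nan, np.nan
        est = float(c[used] @ self.params[used])
        var = float(c[used] @ self.cov_params[np.ix_(used, used)] @ c[used])
        se = np.sqrt(var)
        F = est**2 / var if var > 0 else np.nan
        return est, se, F, float(f_dist.sf(F, 1, self.df_resid))

    def summary(self) -> str:
        lines = [
            "Probit SDT mixed model"
            if self.method == "laplace"
            else "Probit SDT model (fixed effects, cluster-robust)",
            f"  formula: Y ~ 1 + S*P*A + (1 + S | subject:condition)",
            f"  nobs: {self.nobs}   groups: {self.n_groups}   "
            f"loglik: {self.loglik:.2f}   converged: {self.converged}",
            f"  {'term':<10}{'coef':>10}{'se':>10}{'F':>10}{'p':>12}",
        ]
        for i, name in enumerate(TERM_NAMES):
            if name in self.omitted:
                lines.append(f"  {name:<10}{'--- omitted (inestimable)':>30}")
                continue
            lines.append(
                f"  {name:<10}{self.params[i]:>10.4f}{self.bse[i]:>10.4f}"
                f"{self.fvalues[i]:>10.2f}{self.pvalues[i]:>12.3g}"
            )
        if self.re_cov is not None:
            sd = np.sqrt(np.diag(self.re_cov))
            lines.append(
                f"  random effects (subject:condition): sd(1)={sd[0]:.3f} "
                f"sd(S)={sd[1]:.3f}"
            )
        lines.append("  SDT contrasts:")
        for _, row in derive_sdt_betas(self).iterrows():
            lines.append(
                f"  {row['term']:<22}{row['estimate']:>10.4f}"
                f"{row['se']:>10.4f}{row['F']:>10.2f}{row['p']:>12.3g}"
            )
        return "\n".join(lines)


class ProbitSDTGLMM:
    """Probit SDT model bound to one timepoint's trial data.

    Parameters
    ----------
    y, S, A : binary per-trial arrays
    P : per-trial standardized log power
    groups : per-trial subject:condition labels (the random-effect
        grouping); pass ``None`` for a purely fixed-effects model.
    """

    def __init__(self, y, S, P, A, groups=None):
        self.y = np.asarray(y, float)
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("Y must be binary")
        S = np.asarray(S, float)
        A = np.asarray(A, float)
        P = np.asarray(P, float)
        if not np.isin(S, (0, 1)).all() or not np.isin(A, (0, 1)).all():
            raise ValueError("S and A must be binary")
        if not np.all(np.isfinite(P)):
            raise ValueError("P must be finite")
        self.S, self.P, self.A = S, P, A
        X = _design_matrix(S, P, A)
        # rank-deficiency rule: a constant A (or P) makes its terms
        # inestimable -> fit the reduced factorial and flag the rest
        keep = np.ones(8, dtype=bool)
        if np.ptp(A) == 0:
            keep &= ~np.isin(np.arange(8), [3, 4, 6, 7])
        if np.ptp(P) == 0:
            keep &= ~np.isin(np.arange(8), [2, 4, 5, 7])
        self.keep = keep
        self.omitted = tuple(np.array(TERM_NAMES)[~keep])
        self.X = X[:, keep]
        if groups is None:
            self.group_codes = None
            self.group_labels = ()
        else:
            codes, labels = pd.factorize(np.asarray(groups), sort=True)
            self.group_codes = codes
            self.group_labels = tuple(labels)
            if len(labels) < 2:
                warnings.warn(
                    "fewer than 2 grouping cells; random effects are weakly "
                    "identified"
                )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, p_col="P", a_col="A"):
        """Build from a trial table with subject/condition/S/Y columns."""
        groups = (
            df["subject"].astype(str) + ":" + df["condition"].astype(str)
        ).to_numpy()
        return cls(
            df["Y"].to_numpy(),
            df["S"].to_numpy(),
            df[p_col].to_numpy(),
            df[a_col].to_numpy(),
            groups,
        )

    # -- fixed-effects estimator (also the fallback) --------------------

    def _fit_fixed(self, max_iter=100, tol=1e-10):
        X, y = self.X, self.y
        beta = np.zeros(X.shape[1])
        converged = False
        ll = -np.inf
        for _ in range(max_iter):
            eta = X @ beta
            ll_new, s, h = _probit_derivs(y, eta)
            grad = X.T @ s
            H = (X.T * h) @ X
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                break
            beta_new = beta + step
            if np.max(np.abs(step)) < tol:
                beta = beta_new
                ll = ll_new
                converged = True
                break
            beta = beta_new
            ll = ll_new
        eta = X @ beta
        ll, s, h = _probit_derivs(y, eta)
        H = (X.T * h) @ X
        try:
            bread = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            bread = np.linalg.pinv(H)
        if self.group_codes is not None:
            # cluster-robust sandwich over grouping cells
            scores = X * s[:, None]
            G = self.group_codes.max() + 1
            meat = np.zeros((X.shape[1], X.shape[1]))
            for g in range(G):
                sg = scores[self.group_codes == g].sum(axis=0)
                meat += np.outer(sg, sg)
            cov = bread @ meat @ bread
        else:
            cov = bread
        return beta, cov, ll, converged

    # -- Laplace machinery ----------------------------------------------

    def _pirls(self, L, coef0=None, max_iter=60, tol=1e-9):
        """Penalized Newton solve for (beta, u) at fixed Cholesky L."""
        X, y, g = self.X, self.y, self.group_codes
        n, p = X.shape
        G = g.max() + 1
        Z = np.column_stack([np.ones(n), self.S])
        ZL = Z @ L  # n x 2
        B = np.zeros((n, 2 * G))
        rows = np.arange(n)
        B[rows, 2 * g] = ZL[:, 0]
        B[rows, 2 * g + 1] = ZL[:, 1]
        C = np.hstack([X, B])
        pen = np.r_[np.zeros(p), np.ones(2 * G)]
        coef = np.zeros(p + 2 * G) if coef0 is None else coef0.copy()

        def pll(cf):
            eta = C @ cf
            ll = np.where(y == 1, log_ndtr(eta), log_ndtr(-eta)).sum()
            return ll - 0.5 * np.sum(pen * cf**2)

        cur = pll(coef)
        ok = False
        for _ in range(max_iter):
            eta = C @ coef
            _, s, h = _probit_derivs(y, eta)
            grad = C.T @ s - pen * coef
            H = (C.T * h) @ C
            H[np.diag_indices_from(H)] += pen
            step = np.linalg.solve(H, grad)
            t = 1.0
            for _ in range(30):
                new = coef + t * step
                val = pll(new)
                if val >= cur - 1e-12:
                    break
                t *= 0.5
            coef, cur = new, val
            if np.max(np.abs(t * step)) < tol:
                ok = True
                break
        eta = C @ coef
        ll_data, s, h = _probit_derivs(y, eta)
        return coef, C, pen, ll_data, h, ok

    def _laplace_dev(self, L, coef0=None):
        coef, C, pen, ll_data, h, ok = self._pirls(L, coef0)
        g = self.group_codes
        G = g.max() + 1
        u = coef[self.X.shape[1]:]
        # per-group Z'WZ (2x2), then logdet(I + L' Z'WZ L)
        w = h
        sw = np.bincount(g, weights=w, minlength=G)
        swS = np.bincount(g, weights=w * self.S, minlength=G)
        swSS = np.bincount(g, weights=w * self.S**2, minlength=G)
        logdet = 0.0
        for i in range(G):
            M = L.T @ np.array([[sw[i], swS[i]], [swS[i], swSS[i]]]) @ L
            M[np.diag_indices_from(M)] += 1.0
            sign, ld = np.linalg.slogdet(M)
            logdet += ld
        lap = ll_data - 0.5 * np.sum(u**2) - 0.5 * logdet
        return -2.0 * lap, coef, ok

    def fit(
        self,
        method: str = "laplace",
        theta0=(0.3, 0.0, 0.3),
        outer_maxiter: int = 80,
    ) -> ProbitSDTGLMMResults:
        """Fit the model.

        ``method="laplace"`` (default) estimates the mixed model;
        ``method="fixed"`` fits the plain probit GLM with
        cluster-robust covariance.  A failed mixed fit falls back to
        the fixed estimator with ``converged=False`` rather than
        raising.
        """
        if method not in ("laplace", "fixed"):
            raise ValueError("method must be 'laplace' or 'fixed'")
        if method == "fixed" or self.group_codes is None:
            beta, cov, ll, converged = self._fit_fixed()
            return self._package(
                beta, cov, None, ll, converged, "fixed", None
            )

        state = {"coef": None}

        def objective(theta):
            L = np.array([[theta[0], 0.0], [theta[1], theta[2]]])
            try:
                dev, coef, ok = self._laplace_dev(L, state["coef"])
            except np.linalg.LinAlgError:
                return np.inf
            state["coef"] = coef
            return dev if np.isfinite(dev) else np.inf

        try:
            res = optimize.minimize(
                objective,
                x0=np.asarray(theta0, float),
                method="Nelder-Mead",
                bounds=[(0.0, None), (None, None), (0.0, None)],
                options={
                    "maxiter": outer_maxiter,
                    "fatol": 1e-3,
                    "xatol": 2e-3,
                },
            )
            theta = res.x
            L = np.array([[theta[0], 0.0], [theta[1], theta[2]]])
            coef, C, pen, ll_data, h, inner_ok = self._pirls(L, state["coef"])
        except np.linalg.LinAlgError:
            res = None
            inner_ok = False
        if res is None or not np.isfinite(res.fun) or not inner_ok:
            warnings.warn(
                "mixed probit fit failed to converge; returning "
                "fixed-effects fallback"
            )
            beta, cov, ll, _ = self._fit_fixed()
            return self._package(beta, cov, None, ll, False, "laplace", None)
        p = self.X.shape[1]
        H = (C.T * h) @ C
        H[np.diag_indices_from(H)] += pen
        try:
            cov_joint = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov_joint = np.linalg.pinv(H)
        beta = coef[:p]
        cov = cov_joint[:p, :p]
        re_cov = L @ L.T
        u = coef[p:].reshape(-1, 2) @ L.T  # modes on the original scale
        loglik = -0.5 * res.fun
        converged = bool(res.success) and inner_ok
        return self._package(
            beta, cov, re_cov, loglik, converged, "laplace", u
        )

    def _package(self, beta, cov, re_cov, ll, converged, method, u):
        params = np.full(8, np.nan)
        cov_full = np.full((8, 8), np.nan)
        idx = np.flatnonzero(self.keep)
        params[idx] = beta
        cov_full[np.ix_(idx, idx)] = cov
        G = 0 if self.group_codes is None else self.group_codes.max() + 1
        return ProbitSDTGLMMResults(
            params=params,
            cov_params=cov_full,
            re_cov=re_cov,
            loglik=float(ll),
            converged=bool(converged),
            method=method,
            nobs=self.y.size,
            n_groups=int(G),
            omitted=self.omitted,
            random_effects=u,
            group_labels=self.group_labels,
        )


#: Contrast vectors over (b0..b7) mapping fits to SDT modulations.
#: Signs follow the standard convention: positive criterion contrasts
#: would mean more conservative with increasing power; the interaction
#: contrast for c is reported as (b4 + b7/2), the amount by which the
#: *negative* criterion slope differs between state on and off.
CONTRASTS = {
    "d_prime_A0": np.array([0, 0, 0, 0, 0, 1, 0, 0], float),
    "d_prime_A1": np.array([0, 0, 0, 0, 0, 1, 0, 1], float),
    "d_prime_interaction": np.array([0, 0, 0, 0, 0, 0, 0, 1], float),
    "criterion_A0": np.array([0, 0, -1, 0, 0, -0.5, 0, 0], float),
    "criterion_A1": np.array([0, 0, -1, 0, -1, -0.5, 0, -0.5], float),
    "criterion_interaction": np.array([0, 0, 0, 0, 1, 0, 0, 0.5], float),
}


def derive_sdt_betas(fit: ProbitSDTGLMMResults) -> pd.DataFrame:
    """Power-modulation contrasts of sensitivity and criterion.

    Exact linear contrasts of the fitted coefficients: the d' slope in
    power is b5 when the state is off and b5+b7 when on (difference
    b7); the criterion slope is -(b2+b5/2) off and -(b2+b5/2+b4+b7/2)
    on (difference reported as b4+b7/2).  SEs come from c' Cov c;
    contrasts touching omitted terms are returned as NaN.
    """
    rows = []
    for name, c in CONTRASTS.items():
        est, se, F, p = fit.contrast(c)
        rows.append(
            {"term": name, "estimate": est, "se": se, "F": F, "p": p}
        )
    return pd.DataFrame(rows)


def _batched_probit_fit(
    Xs: np.ndarray, y: np.ndarray, max_iter: int = 15, tol: float = 1e-7
):
    """Vectorized probit Newton fits across stacked design matrices.

    ``Xs`` is problems x trials x params with a shared response; this
    is the throughput path for permutation testing, where thousands of
    per-timepoint refits are needed.  Problems drop out of the
    iteration as they converge (separated problems are capped by
    ``max_iter`` with clipped linear predictors).  Returns per-problem
    coefficients and (non-robust) covariance.
    """
    T, n, p = Xs.shape
    beta = np.zeros((T, p))
    ridge = 1e-8 * n
    eye = np.eye(p)
    active = np.arange(T)
    for _ in range(max_iter):
        Xa = Xs[active]
        eta = np.einsum("tnp,tp->tn", Xa, beta[active])
        np.clip(eta, -8.0, 8.0, out=eta)
        lam_p = _mills(eta)
        lam_m = _mills(-eta)
        s = np.where(y[None, :] == 1, lam_p, -lam_m)
        h = np.where(y[None, :] == 1, lam_p * (eta + lam_p),
                     lam_m * (lam_m - eta))
        h = np.maximum(h, 1e-12)
        grad = np.einsum("tnp,tn->tp", Xa, s)
        H = np.einsum("tnp,tn,tnq->tpq", Xa, h, Xa) + ridge * eye
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        beta[active] += step
        moving = np.abs(step).max(axis=1) >= tol
        active = active[moving]
        if active.size == 0:
            break
    eta = np.einsum("tnp,tp->tn", Xs, beta)
    np.clip(eta, -8.0, 8.0, out=eta)
    lam_p = _mills(eta)
    lam_m = _mills(-eta)
    h = np.maximum(
        np.where(y[None, :] == 1, lam_p * (eta + lam_p),
                 lam_m * (lam_m - eta)),
        1e-12,
    )
    H = np.einsum("tnp,tn,tnq->tpq", Xs, h, Xs) + ridge * eye
    cov = np.linalg.inv(H)
    return beta, cov


def beta_timecourse(
    trials: pd.DataFrame,
    netpower,
    state: int | str = 0,
    method: str = "laplace",
) -> pd.DataFrame:
    """Fit the probit SDT model independently at every timepoint.

    ``netpower`` is a ``NetworkPower`` with standardized P; the two
    priming conditions are pooled into one model per timepoint,
    condition entering only through the subject:condition grouping.
    Returns a long-format table (state, time_s, term, estimate, se, F,
    p, converged) holding both the raw coefficients and the derived
    SDT contrasts; non-converged timepoints are flagged and retained.
    """
    sub = trials.iloc[netpower.trial_index]
    groups = (
        sub["subject"].astype(str) + ":" + sub["condition"].astype(str)
    ).to_numpy()
    y = sub["Y"].to_numpy()
    S = sub["S"].to_numpy()
    rows = []
    for j, t in enumerate(netpower.times):
        model = ProbitSDTGLMM(y, S, netpower.P[:, j], netpower.A[:, j], groups)
        fit = model.fit(method=method)
        for i, name in enumerate(TERM_NAMES):
            rows.append(
                {
                    "state": state,
                    "time_s": float(t),
                    "term": name,
                    "estimate": fit.params[i],
                    "se": fit.bse[i],
                    "F": fit.fvalues[i],
                    "p": fit.pvalues[i],
                    "converged": fit.converged,
                }
            )
        for _, r in derive_sdt_betas(fit).iterrows():
            rows.append(
                {
                    "state": state,
                    "time_s": float(t),
                    "term": r["term"],
                    "estimate": r["estimate"],
                    "se": r["se"],
                    "F": r["F"],
                    "p": r["p"],
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)
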