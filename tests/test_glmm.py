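"""Probit SDT mixed model: estimator correctness against an external
mixed-model oracle, coefficient recovery, contrast algebra, and the
reduced-model rules."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from alphastates.glmm import (
    CONTRASTS,
    ProbitSDTGLMM,
    TERM_NAMES,
    _batched_probit_fit,
    _design_matrix,
    beta_timecourse,
    derive_sdt_betas,
)
from tests.conftest import simulate_factorial_trials

# Reference fit of the seed-42 factorial dataset (12 cells x 400
# trials) by lme4::glmer with family=binomial("probit") and formula
# Y ~ 1 + S*P*A + (1+S|grp): fixed effects, their SEs, and the
# random-effect (co)variances.  Frozen from an independent run.
LME4_FIXEF = {
    "Intercept": (-0.51276, 0.07938),
    "S": (1.31664, 0.09902),
    "P": (-0.22920, 0.03815),
    "A": (0.31339, 0.05337),
    "P:A": (0.13249, 0.05398),
    "S:P": (-0.22086, 0.05980),
    "S:A": (0.06852, 0.08765),
    "S:P:A": (-0.34184, 0.08905),
}
LME4_RE = {"var_int": 0.05823, "var_s": 0.07672, "cov": -0.02227}


@pytest.fixture(scope="module")
def oracle_data():
    df, beta = simulate_factorial_trials(
        seed=42,
        n_groups=12,
        n_per=400,
        beta=[-0.5, 1.2, -0.2, 0.3, 0.1, -0.3, 0.15, -0.2],
        re_sd=0.35,
    )
    return df


class TestLaplaceAgainstLme4:
    def test_fixed_effects_match(self, oracle_data):
        d = oracle_data
        fit = ProbitSDTGLMM(d.Y, d.S, d.P, d.A, d.grp).fit()
        assert fit.converged
        for i, name in enumerate(TERM_NAMES):
            est, se = LME4_FIXEF[name]
            assert fit.params[i] == pytest.approx(est, abs=0.01)
            assert fit.bse[i] == pytest.approx(se, rel=0.05)

    def test_random_effect_covariance_matches(self, oracle_data):
        d = oracle_data
        fit = ProbitSDTGLMM(d.Y, d.S, d.P, d.A, d.grp).fit()
        assert fit.re_cov[0, 0] == pytest.approx(LME4_RE["var_int"], abs=0.01)
        assert fit.re_cov[1, 1] == pytest.approx(LME4_RE["var_s"], abs=0.01)
        assert fit.re_cov[0, 1] == pytest.approx(LME4_RE["cov"], abs=0.01)


class TestRecovery:
    def test_pure_stimulus_effect_recovered(self):
        df, _ = simulate_factorial_trials(
            seed=11, n_groups=4, n_per=5000,
            beta=[0, 1, 0, 0, 0, 0, 0, 0], re_sd=0.0,
        )
        fit = ProbitSDTGLMM(df.Y, df.S, df.P, df.A).fit(method="fixed")
        assert abs(fit.params[1] - 1.0) <= 3 * fit.bse[1]
        for i in (0, 2, 3, 4, 5, 6, 7):
            assert abs(fit.params[i]) <= 3 * fit.bse[i]

    def test_full_beta_vector_recovered_mixed(self):
        beta = [0, 1.5, -0.1, 0.2, 0, -0.3, 0, -0.2]
        df, _ = simulate_factorial_trials(
            seed=5, n_groups=16, n_per=640, beta=beta, re_sd=0.3
        )
        fit = ProbitSDTGLMM(df.Y, df.S, df.P, df.A, df.grp).fit()
        assert fit.converged
        for i in range(8):
            assert abs(fit.params[i] - beta[i]) <= 3 * fit.bse[i]


class TestReducedModels:
    def test_constant_activation_omits_a_terms(self):
        rng = np.random.default_rng(0)
        n = 2000
        S = rng.integers(0, 2, n)
        P = rng.standard_normal(n)
        Y = (rng.random(n) < norm.cdf(0.5 * S)).astype(int)
        fit = ProbitSDTGLMM(Y, S, P, np.zeros(n)).fit(method="fixed")
        assert set(fit.omitted) == {"A", "P:A", "S:A", "S:P:A"}
        assert np.isnan(fit.params[3])
        assert np.isfinite(fit.params[1])
        con = derive_sdt_betas(fit).set_index("term")
        assert np.isnan(con.loc["d_prime_A1", "estimate"])
        assert np.isfinite(con.loc["d_prime_A0", "estimate"])

    def test_constant_power_omits_p_terms(self):
        rng = np.random.default_rng(1)
        n = 2000
        S = rng.integers(0, 2, n)
        A = rng.integers(0, 2, n)
        Y = (rng.random(n) < norm.cdf(0.5 * S)).astype(int)
        fit = ProbitSDTGLMM(Y, S, np.zeros(n), A).fit(method="fixed")
        assert set(fit.omitted) == {"P", "P:A", "S:P", "S:P:A"}


class TestContrastAlgebra:
    def test_zero_betas_give_zero_contrasts(self):
        df, _ = simulate_factorial_trials(
            seed=2, n_groups=2, n_per=4000, beta=np.zeros(8), re_sd=0.0
        )
        fit = ProbitSDTGLMM(df.Y, df.S, df.P, df.A).fit(method="fixed")
        con = derive_sdt_betas(fit).set_index("term")
        for term in CONTRASTS:
            assert abs(con.loc[term, "estimate"]) <= 3 * con.loc[term, "se"]

    def test_criterion_from_power_main_effect(self):
        # with only b2 nonzero, both criterion slopes equal -b2
        params = np.array([0, 0, 0.1, 0, 0, 0, 0, 0])
        assert CONTRASTS["criterion_A0"] @ params == pytest.approx(-0.1)
        assert CONTRASTS["criterion_A1"] @ params == pytest.approx(-0.1)

    def test_dprime_slopes_from_b5_b7(self):
        params = np.array([0, 0, 0, 0, 0, -0.2, 0, 0.1])
        assert CONTRASTS["d_prime_A0"] @ params == pytest.approx(-0.2)
        assert CONTRASTS["d_prime_A1"] @ params == pytest.approx(-0.1)
        assert CONTRASTS["d_prime_interaction"] @ params == pytest.approx(0.1)

    def test_recoding_a_reproduces_on_contrasts_exactly(self):
        df, _ = simulate_factorial_trials(seed=3, n_groups=4, n_per=3000,
                                          re_sd=0.0)
        fit = ProbitSDTGLMM(df.Y, df.S, df.P, df.A).fit(method="fixed")
        refit = ProbitSDTGLMM(df.Y, df.S, df.P, 1 - df.A).fit(method="fixed")
        con = derive_sdt_betas(fit).set_index("term")
        rcon = derive_sdt_betas(refit).set_index("term")
        for orig, recoded in [
            ("d_prime_A1", "d_prime_A0"),
            ("criterion_A1", "criterion_A0"),
        ]:
            assert con.loc[orig, "estimate"] == pytest.approx(
                rcon.loc[recoded, "estimate"], abs=1e-6
            )
            assert con.loc[orig, "se"] == pytest.approx(
                rcon.loc[recoded, "se"], abs=1e-6
            )

    def test_recoding_a_consistent_under_mixed_fit(self, oracle_data):
        d = oracle_data
        fit = ProbitSDTGLMM(d.Y, d.S, d.P, d.A, d.grp).fit()
        refit = ProbitSDTGLMM(d.Y, d.S, d.P, 1 - d.A, d.grp).fit()
        con = derive_sdt_betas(fit).set_index("term")
        rcon = derive_sdt_betas(refit).set_index("term")
        assert con.loc["d_prime_A1", "estimate"] == pytest.approx(
            rcon.loc["d_prime_A0", "estimate"], abs=1e-3
        )

    def test_median_split_dprime_sign_matches_beta(self):
        # descriptive/model consistency on dichotomized power
        from alphastates.sdt import sdt_measures

        agree = 0
        n_seeds = 10
        for seed in range(n_seeds):
            df, _ = simulate_factorial_trials(
                seed=100 + seed, n_groups=1, n_per=10_000,
                beta=[0, 1.2, 0, 0, 0, -0.25, 0, 0], re_sd=0.0,
            )
            A = np.zeros(len(df))
            fit = ProbitSDTGLMM(df.Y, df.S, df.P, A).fit(method="fixed")
            hi = df.P > df.P.median()

            def dp(sub):
                S, Y = sub.S.to_numpy(), sub.Y.to_numpy()
                return sdt_measures(
                    int(Y[S == 1].sum()), int((1 - Y[S == 1]).sum()),
                    int(Y[S == 0].sum()), int((1 - Y[S == 0]).sum()),
                ).d_prime

            split_diff = dp(df[hi]) - dp(df[~hi])
            agree += np.sign(split_diff) == np.sign(fit.params[5])
        assert agree >= int(0.95 * n_seeds)


class TestBatchedFits:
    def test_batched_matches_single_fit(self):
        df, _ = simulate_factorial_trials(seed=8, n_groups=2, n_per=1000,
                                          re_sd=0.0)
        X = _design_matrix(df.S, df.P, df.A)
        rng = np.random.default_rng(0)
        P2 = rng.standard_normal(len(df))
        X2 = _design_matrix(df.S, P2, df.A)
        beta, cov = _batched_probit_fit(
            np.stack([X, X2]), df.Y.to_numpy(float)
        )
        single = ProbitSDTGLMM(df.Y, df.S, df.P, df.A).fit(method="fixed")
        assert np.allclose(beta[0], single.params, atol=1e-6)

    def test_timecourse_long_format(self):
        from alphastates.power import NetworkPower

        df, _ = simulate_factorial_trials(seed=9, n_groups=4, n_per=100,
                                          re_sd=0.0)
        df = df.rename(columns={"grp": "subject"})
        df["condition"] = "c"
        T = 3
        rng = np.random.default_rng(1)
        npow = NetworkPower(
            P=rng.standard_normal((len(df), T)),
            A=rng.integers(0, 2, (len(df), T)).astype(float),
            times=np.array([-0.1, -0.06, -0.02]),
            trial_index=np.arange(len(df)),
        )
        out = beta_timecourse(df, npow, state=0, method="fixed")
        assert set(out["term"]) == set(TERM_NAMES) | set(CONTRASTS)
        assert len(out) == T * (len(TERM_NAMES) + len(CONTRASTS))
        assert out["converged"].all()


def test_summary_mentions_formula_and_contrasts(oracle_data):
    d = oracle_data.iloc[:2000]
    fit = ProbitSDTGLMM(d.Y, d.S, d.P, d.A, d.grp).fit(method="fixed")
    text = fit.summary()
    assert "Y ~ 1 + S*P*A" in text
    assert "d_prime_A1" in text
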