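import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def simulate_factorial_trials(seed, n_groups=12, n_per=400, beta=None,
                              re_sd=0.3):
    """Balanced factorial probit data with subject-cell random effects.

    Independent S/P/A covariates per trial; used wherever a test needs
    model-correct data without the full neural generator.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(
        beta if beta is not None else [-0.5, 1.2, -0.2, 0.3, 0.1, -0.3, 0.15, -0.2],
        float,
    )
    frames = []
    for g in range(n_groups):
        u0, u1 = rng.normal(0, re_sd, 2) if re_sd > 0 else (0.0, 0.0)
        S = rng.integers(0, 2, n_per)
        P = rng.standard_normal(n_per)
        A = rng.integers(0, 2, n_per)
        eta = (
            beta[0] + u0 + (beta[1] + u1) * S + beta[2] * P + beta[3] * A
            + beta[4] * P * A + beta[5] * S * P + beta[6] * S * A
            + beta[7] * S * P * A
        )
        Y = (rng.random(n_per) < norm.cdf(eta)).astype(int)
        frames.append(
            pd.DataFrame({"grp": f"g{g:02d}", "Y": Y, "S": S, "P": P, "A": A})
        )
    return pd.concat(frames, ignore_index=True), beta


@pytest.fixture(scope="session")
def factorial_data():
    return simulate_factorial_trials(seed=7)
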