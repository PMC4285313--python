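import numpy as np
import pytest

from errkit import Dataset, NaiveFit, RCModelFit, make_scenario

# Published example used across tests: a naive log OR of -0.193 (SE 0.070)
# and a classical-RC corrected value of -0.286, implying a repeat-regression
# slope of 0.193/0.286.
NAIVE_BETA = -0.193
NAIVE_SE = 0.070
RC_BETA = -0.286
LAM_STAR = NAIVE_BETA / RC_BETA


def naive_fit_from(beta: float, se: float, n: int = 1527) -> NaiveFit:
    """A NaiveFit carrying just the scalar summaries (for arithmetic tests)."""
    return NaiveFit(beta_star=np.array([beta]), se_star=np.array([se]),
                    params=np.array([0.0, beta]),
                    cov=np.diag([0.0, se**2]),
                    exposure_names=["w1"], n=n, converged=True)


def rc_fit_from(lam: float, var_lam: float = 0.0,
                var_w1_given_z: float = 1.0) -> RCModelFit:
    return RCModelFit(mu=0.0, lam=lam, delta=np.array([]), resid_var=0.0,
                      var_lam=var_lam, n_repeat=400,
                      var_w1_given_z=var_w1_given_z)


@pytest.fixture(scope="session")
def classical_ds() -> Dataset:
    """Classical error, sigma_X = sigma_eps = 1 (RDR 0.5), beta = 0.3."""
    return make_scenario("classical_recovery", seed=20260928, n=20000)


@pytest.fixture(scope="session")
def small_classical_ds() -> Dataset:
    return make_scenario("classical_recovery", seed=42, n=4000)


@pytest.fixture(scope="session")
def differential_ds() -> Dataset:
    """Cases' measurements shifted by 0.5 * sigma_X."""
    return make_scenario("differential_shift", seed=777, n=20000)


@pytest.fixture(scope="session")
def lognormal_ds() -> Dataset:
    return make_scenario("lognormal_heteroscedastic", seed=99, n=20000)


@pytest.fixture()
def noerror_ds(small_classical_ds) -> Dataset:
    """W1 = W2 = X exactly: every correction must be the identity."""
    df = small_classical_ds.df.copy()
    df["w1"] = df["x"]
    df["w2"] = df["x"]
    return Dataset(df)
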