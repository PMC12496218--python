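import numpy as np
import pytest
from hypothesis import settings

import wtpmxl as w
from wtpmxl.data_model import PartyMeta

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


def two_party_true_params(lam_shift: float = 10.0) -> w.TrueParameters:
    """Compact ground truth: full six-attribute design, one non-baseline
    party (B) shifting every WTP mean by ``lam_shift`` EUR, an income
    loading on the landscape block, independent random components."""
    coef = ["asc_sq", "forest", "river", "agriculture", "connectivity",
            "carnivores", "herbivores"]
    cov_names = ["income", "voting[B]"]
    mu = np.array([95.0, 20.0, 28.0, 15.0, 50.0, 60.0, 45.0])
    lam = np.zeros((7, 2))
    lam[:, 1] = lam_shift
    lam[1:5, 0] = 6.0
    sds = np.array([40.0, 15.0, 15.0, 12.0, 20.0, 25.0, 20.0, 0.4])
    return w.TrueParameters(coef, cov_names, mu, lam, float(np.log(0.03)),
                            np.array([0.1, 0.0]), np.diag(sds))


def two_party_config(n_respondents: int, seed: int, n_tasks: int = 6,
                     true_params: w.TrueParameters | None = None
                     ) -> w.SimulationConfig:
    parties = [PartyMeta("A", "XX", 4.0, 4.0, 0.6),
               PartyMeta("B", "XX", 6.0, 6.0, 0.4)]
    return w.SimulationConfig(
        n_respondents=n_respondents,
        design=w.default_design(n_tasks=n_tasks),
        parties=parties,
        regions={"r1": 1.0},
        true_params=true_params if true_params is not None
                    else two_party_true_params(),
        seed=seed,
        covariate_columns=["income", "voting"],
    )


@pytest.fixture(scope="session")
def default_fixture():
    """Small bundle from the full default generator (six parties, four
    regions, correlated random components)."""
    cfg = w.default_config(n_respondents=60, seed=5, n_tasks=6)
    return w.make_fixture(cfg)


@pytest.fixture(scope="session")
def two_party_fixture():
    cfg = two_party_config(n_respondents=200, seed=17)
    return w.make_fixture(cfg)


@pytest.fixture(scope="session")
def fitted_mxl(two_party_fixture):
    """A converged mixed logit fit (diagonal covariance, reduced draws)
    with both variance matrices, shared across post-estimation tests."""
    data, cov, _ = two_party_fixture
    spec = w.ModelSpec(covariates=("income", "voting"), n_draws=100,
                       structure="diagonal")
    return w.fit_mxl(data, cov, spec, seed=3)


@pytest.fixture(scope="session")
def mnl_fixture():
    """Data simulated with no heterogeneity at all (Omega = 0, no covariate
    loadings): the exact multinomial-logit world."""
    tp = two_party_true_params(lam_shift=0.0)
    tp0 = w.TrueParameters(tp.coef_names, tp.cov_names, tp.mu,
                           np.zeros_like(tp.lam), tp.pi,
                           np.zeros_like(tp.gamma),
                           np.zeros_like(tp.omega_chol))
    cfg = two_party_config(n_respondents=1500, seed=29, true_params=tp0)
    return w.make_fixture(cfg)


@pytest.fixture(scope="session")
def fitted_mnl(mnl_fixture):
    data, cov, _ = mnl_fixture
    spec = w.ModelSpec(covariates=("income",))
    return w.fit_mnl(data, cov, spec)
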