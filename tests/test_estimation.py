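"""Likelihood core: utilities, probabilities, gradients, fits, Wald tests."""

import numpy as np
import pytest

import wtpmxl as w
from wtpmxl.data_model import SchemaError
from wtpmxl.estimation import _Layout, _core, _prepare, DrawSet

from conftest import two_party_config, two_party_true_params


# -- systematic utility and choice probability ------------------------------

@pytest.mark.parametrize("x,cost,beta,alpha,expected", [
    (np.zeros(3), 50.0, np.zeros(3), 1.0, -50.0),        # cost only
    (np.array([1.0, 0, 0]), 0.0, np.array([3.0, 0, 0]), 2.0, 6.0),  # SQ row
    (np.array([0, np.log(2), 1.0]), 20.0,
     np.array([0.0, 10.0, 5.0]), 0.5, 0.5 * (10 * np.log(2) + 5 - 20)),
])
def test_systematic_utility_hand_values(x, cost, beta, alpha, expected):
    assert w.systematic_utility(x, cost, beta, alpha) == pytest.approx(expected)


def test_systematic_utility_homogeneous_in_alpha():
    x = np.array([0, np.log(3), 2.0])
    beta = np.array([5.0, -2.0, 1.0])
    v1 = w.systematic_utility(x, 30.0, beta, 1.3)
    v2 = w.systematic_utility(x, 30.0, beta, 2.6)
    assert v2 == pytest.approx(2 * v1)


def test_choice_probability_closed_forms():
    assert np.allclose(w.choice_probability([0.0, 0.0, 0.0]), 1 / 3)
    assert np.allclose(w.choice_probability([np.log(2), 0.0]), [2 / 3, 1 / 3])


def test_choice_probability_overflow_safe():
    p = w.choice_probability([1000.0, 0.0])
    assert np.isfinite(p).all()
    assert p[0] == pytest.approx(1.0)
    assert p.sum() == pytest.approx(1.0)


def test_choice_probability_empty_rejected():
    with pytest.raises(ValueError):
        w.choice_probability([])


# -- simulated likelihood ---------------------------------------------------

def _random_params(md, layout, seed=0):
    rng = np.random.default_rng(seed)
    k, p = layout.k, layout.p
    chol = np.tril(rng.normal(0, 4, (k + 1, k + 1)))
    chol[k, :] = rng.normal(0, 0.15, k + 1)
    return w.ParameterSet(md.coef_names, md.cov_names,
                          rng.normal(0, 20, k), rng.normal(0, 5, (k, p)),
                          -3.3, rng.normal(0, 0.1, p), chol)


def test_gradient_matches_finite_differences(two_party_fixture):
    data, cov, _ = two_party_fixture
    spec = w.ModelSpec(covariates=("income", "voting"), structure="full")
    md = _prepare(data, cov, spec)
    layout = _Layout(md.coef_names, md.cov_names, "full", False)
    ps = _random_params(md, layout)
    theta = layout.pack(ps)
    u = DrawSet.generate(md.n, layout.k + 1, 16, 5).u
    ll, g = _core(theta, layout, md, u)
    rng = np.random.default_rng(1)
    for i in rng.choice(len(theta), size=25, replace=False):
        h = 1e-5 * (1 + abs(theta[i]))
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        lp, _ = _core(tp, layout, md, u, want_grad=False)
        lm, _ = _core(tm, layout, md, u, want_grad=False)
        fd = (lp - lm) / (2 * h)
        assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)


def test_mnl_collapse_is_exact(two_party_fixture):
    """With Omega = 0 and no covariates the simulated likelihood equals the
    analytic multinomial-logit likelihood for any draw set."""
    data, _, tp = two_party_fixture
    k = len(tp.coef_names)
    ps = w.ParameterSet(tp.coef_names, [], tp.mu, np.zeros((k, 0)), tp.pi,
                        np.zeros(0), np.zeros((k + 1, k + 1)))
    for n_draws, seed in [(8, 1), (64, 2)]:
        draws = w.DrawSet.generate(data.n_respondents, k + 1, n_draws, seed)
        ll_sim, _ = w.simulated_loglik(ps, data, None, draws)
        arr = data.to_arrays()
        v = np.exp(tp.pi) * (np.einsum("ntak,k->nta", arr.x, tp.mu) - arr.cost)
        v -= v.max(axis=2, keepdims=True)
        p = np.exp(v)
        p /= p.sum(axis=2, keepdims=True)
        ll_an = float(np.log(np.take_along_axis(
            p, arr.chosen[..., None], axis=2)).sum())
        assert ll_sim == pytest.approx(ll_an, abs=1e-9)


def test_currency_rescaling_invariance(two_party_fixture):
    """Measuring cost in half-EUR doubles the WTP-scale parameters, shifts
    pi by -log 2, and leaves the likelihood unchanged."""
    data, cov, _ = two_party_fixture
    spec = w.ModelSpec(covariates=("income", "voting"), structure="full")
    md = _prepare(data, cov, spec)
    layout = _Layout(md.coef_names, md.cov_names, "full", False)
    ps = _random_params(md, layout, seed=3)
    draws = w.DrawSet.generate(data.n_respondents, layout.k + 1, 32, 9)
    ll1, _ = w.simulated_loglik(ps, data, cov, draws)

    t2 = data.table.copy()
    t2["cost_eur"] = 2.0 * t2["cost_eur"]
    data2 = w.ChoiceDataset(t2, data.design)
    k = layout.k
    chol2 = ps.chol.copy()
    chol2[:k, :] *= 2.0
    ps2 = w.ParameterSet(ps.coef_names, ps.cov_names, 2 * ps.mu, 2 * ps.lam,
                         ps.pi - np.log(2), ps.gamma, chol2)
    ll2, _ = w.simulated_loglik(ps2, data2, cov, draws)
    assert ll2 == pytest.approx(ll1, rel=1e-12)


def test_draw_count_stability(two_party_fixture):
    """Doubling the draw count moves the simulated loglik by less than the
    spread implied by re-seeding at the lower count."""
    data, cov, _ = two_party_fixture
    spec = w.ModelSpec(covariates=("income", "voting"), structure="diagonal")
    md = _prepare(data, cov, spec)
    layout = _Layout(md.coef_names, md.cov_names, "diagonal", False)
    ps = _random_params(md, layout, seed=5)
    lls = []
    for seed in range(5):
        dr = w.DrawSet.generate(data.n_respondents, layout.k + 1, 128, seed)
        lls.append(w.simulated_loglik(ps, data, cov, dr,
                                      structure="diagonal")[0])
    dr2 = w.DrawSet.generate(data.n_respondents, layout.k + 1, 256, 101)
    ll2, _ = w.simulated_loglik(ps, data, cov, dr2, structure="diagonal")
    spread = np.ptp(lls)
    assert abs(ll2 - np.mean(lls)) < max(spread, 1e-6)


def test_drawset_deterministic_and_blocked():
    d1 = DrawSet.generate(10, 3, 16, 7)
    d2 = DrawSet.generate(10, 3, 16, 7)
    assert np.array_equal(d1.u, d2.u)
    # distinct blocks per respondent
    assert not np.array_equal(d1.u[0], d1.u[1])
    assert np.isfinite(d1.u).all()


# -- fitting ----------------------------------------------------------------

def test_mnl_recovers_truth_within_three_se(mnl_fixture):
    data, cov, tp = mnl_fixture
    res = w.fit_mnl(data, cov, w.ModelSpec(covariates=("income",)))
    assert res.converged
    se = res.se("sandwich")
    for j, c in enumerate(tp.coef_names):
        i = res.index(f"mu[{c}]")
        assert abs(res.theta[i] - tp.mu[j]) < 3 * se[i]
    i = res.index("pi")
    assert abs(res.theta[i] - tp.pi) < 3 * se[i]


def test_mnl_optimum_beats_truth(mnl_fixture):
    data, cov, tp = mnl_fixture
    res = w.fit_mnl(data, cov, w.ModelSpec(covariates=("income",)))
    k = len(tp.coef_names)
    x, names, _ = cov.encode(["income"])
    ps_true = w.ParameterSet(tp.coef_names, names, tp.mu,
                             np.zeros((k, 1)), tp.pi, np.zeros(1),
                             np.zeros((k + 1, k + 1)))
    draws = w.DrawSet.zeros(data.n_respondents, k + 1)
    ll_true, _ = w.simulated_loglik(ps_true, data, cov, draws,
                                    structure="none")
    assert res.loglik >= ll_true - 1e-8


def test_null_data_has_symmetric_loglik():
    """With every coefficient at zero, choices are uniform: the fitted
    preference-scale coefficients vanish and the loglik per task is log 1/3."""
    tp = two_party_true_params()
    tp0 = w.TrueParameters(tp.coef_names, tp.cov_names, np.zeros(7),
                           np.zeros_like(tp.lam), -20.0,
                           np.zeros_like(tp.gamma),
                           np.zeros_like(tp.omega_chol))
    cfg = two_party_config(800, seed=31, true_params=tp0)
    data, cov, _ = w.make_fixture(cfg)
    res = w.fit_mnl(data)
    n_tasks = 800 * 6
    assert res.loglik / n_tasks == pytest.approx(np.log(1 / 3), rel=5e-3)
    # WTP-space mu is a ratio of two vanishing quantities; the identified
    # preference-scale products alpha*mu must be near zero
    pref = np.exp(res.params.pi) * res.params.mu
    # ~3 standard errors at 4800 uniform tasks
    assert np.max(np.abs(pref)) < 0.1
    assert np.exp(res.params.pi) < 0.05


def test_mxl_loglik_nests_mnl(two_party_fixture, fitted_mxl):
    data, cov, _ = two_party_fixture
    mnl = w.fit_mnl(data, cov, w.ModelSpec(covariates=("income", "voting")),
                    compute_vcov=False)
    assert fitted_mxl.loglik >= mnl.loglik - 1e-6


def test_mxl_with_zero_structure_matches_mnl(two_party_fixture):
    data, cov, _ = two_party_fixture
    spec = w.ModelSpec(covariates=("income",), structure="none")
    mxl = w.fit_mxl(data, cov, spec, seed=1, compute_vcov=False)
    mnl = w.fit_mnl(data, cov, w.ModelSpec(covariates=("income",)),
                    compute_vcov=False)
    assert mxl.loglik == pytest.approx(mnl.loglik, abs=1e-5)
    assert np.allclose(mxl.theta, mnl.theta, atol=2e-4)


def test_constant_attribute_not_identified():
    cfg = two_party_config(30, seed=33)
    data, cov, _ = w.make_fixture(cfg)
    t = data.table.copy()
    t["herbivores"] = 1.5
    with pytest.raises(SchemaError, match="herbivores"):
        w.fit_mnl(w.ChoiceDataset(t, data.design))


def test_result_roundtrip(tmp_path, fitted_mxl):
    fitted_mxl.save(tmp_path / "r.yaml")
    back = w.EstimationResult.load(tmp_path / "r.yaml")
    assert back.loglik == pytest.approx(fitted_mxl.loglik)
    assert np.allclose(back.theta, fitted_mxl.theta)
    assert back.param_names == fitted_mxl.param_names
    assert np.allclose(back.vcov("sandwich"), fitted_mxl.vcov("sandwich"))


# -- Wald test --------------------------------------------------------------

def test_wald_single_coefficient_is_squared_z(fitted_mnl):
    name = "lam[river|income]"
    i = fitted_mnl.index(name)
    se = fitted_mnl.se("sandwich")[i]
    stat, df, p = w.wald_test(fitted_mnl, [name])
    assert df == 1
    assert stat == pytest.approx((fitted_mnl.theta[i] / se) ** 2, rel=1e-10)


def test_wald_invariant_to_subset_order(fitted_mnl):
    names = [f"lam[{c}|income]" for c in ("forest", "river", "carnivores")]
    s1, _, p1 = w.wald_test(fitted_mnl, names)
    s2, _, p2 = w.wald_test(fitted_mnl, names[::-1])
    assert s1 == pytest.approx(s2, rel=1e-10)
    assert p1 == pytest.approx(p2, rel=1e-8)


def test_wald_rejects_duplicates(fitted_mnl):
    with pytest.raises(ValueError, match="duplicate"):
        w.wald_test(fitted_mnl, ["pi", "pi"])


def test_independent_money_layout_zeroes_cross_covariance(two_party_fixture):
    """The independence switch removes the eta-zeta covariance parameters:
    the fitted Omega keeps a money variance but no money-WTP covariance."""
    data, cov, _ = two_party_fixture
    md = _prepare(data, cov, w.ModelSpec(covariates=("income",)))
    full = _Layout(md.coef_names, md.cov_names, "full", False)
    indep = _Layout(md.coef_names, md.cov_names, "full", True)
    k = full.k
    assert full.n_params - indep.n_params == k
    ps = _random_params(md, indep, seed=11)
    theta = indep.pack(ps)
    back = indep.unpack(theta)
    assert np.all(back.chol[k, :k] == 0)
    assert back.omega[k, :k] == pytest.approx(0)
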