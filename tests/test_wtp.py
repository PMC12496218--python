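"""WTP transformations, party tables, status-quo metrics, map dimensions."""

import numpy as np
import pandas as pd
import pytest

import wtpmxl as w
from wtpmxl.data_model import PartyMeta
from wtpmxl.estimation import EstimationResult, ParameterSet
from wtpmxl.wtp import dimension_means, party_summary

from conftest import two_party_true_params


# -- scalar transformations -------------------------------------------------

@pytest.mark.parametrize("beta", [-12.5, 0.0, 27.62, 50.64])
def test_marginal_wtp_at_level_one_is_beta(beta):
    assert w.marginal_wtp_log(beta, 1) == beta


def test_marginal_and_discrete_modes():
    assert w.marginal_wtp_log(10.0, 2) == pytest.approx(5.0)
    assert w.marginal_wtp_log(10.0, 2, mode="discrete") == pytest.approx(
        10.0 * (np.log(3) - np.log(2)))
    with pytest.raises(ValueError):
        w.marginal_wtp_log(10.0, 0)


@pytest.mark.parametrize("per_level,code,expected", [
    (48.41, 3, 145.23),    # both herbivores
    (80.30, 2, 160.60),    # both carnivores
    (48.41, 2, 96.82),     # bison
    (41.60, 2, 83.20),     # bison, second sample
    (123.0, 0, 0.0),       # species absent
])
def test_linear_attribute_wtp_arithmetic(per_level, code, expected):
    assert w.linear_attribute_wtp(per_level, code) == pytest.approx(
        expected, abs=1e-9)


# -- status-quo share -------------------------------------------------------

def test_sq_share_matches_brute_force_and_row_order(default_fixture):
    data, cov, _ = default_fixture
    overall, per_party = w.sq_share(data, cov)
    t = data.table
    brute = t[(t.is_sq == 1) & (t.chosen == 1)].shape[0] / (
        t.shape[0] / data.design.n_alternatives)
    assert overall == pytest.approx(brute)
    shuffled = w.ChoiceDataset(
        t.sample(frac=1.0, random_state=0), data.design)
    overall2, per2 = w.sq_share(shuffled, cov)
    assert overall2 == pytest.approx(overall)
    pd.testing.assert_series_equal(per_party.sort_index(), per2.sort_index())


def test_sq_share_saturated():
    cfg = w.default_config(n_respondents=20, seed=2, n_tasks=3)
    data, _, _ = w.make_fixture(cfg)
    t = data.table.copy()
    t["chosen"] = t["is_sq"]
    overall, _ = w.sq_share(w.ChoiceDataset(t, data.design))
    assert overall == 1.0


def test_sq_share_missing_party_is_nan(default_fixture):
    data, cov, _ = default_fixture
    _, per_party = w.sq_share(data, cov, parties=["PiS", "NoSuchParty"])
    assert np.isnan(per_party["NoSuchParty"])
    assert np.isfinite(per_party["PiS"])


# -- party WTP table --------------------------------------------------------

def test_party_table_baseline_shift_is_zero(fitted_mxl):
    table = w.party_wtp_table(fitted_mxl)
    base = table[table.is_baseline]
    assert (base.party == "A").all()
    assert (base["shift"] == 0).all()
    assert base["shift_se"].isna().all()
    assert ((table.ci_low <= table.wtp) & (table.wtp <= table.ci_high)).all()


def test_party_table_shift_se_equals_lambda_se(fitted_mxl):
    table = w.party_wtp_table(fitted_mxl)
    se = fitted_mxl.se("sandwich")
    for attr in fitted_mxl.params.coef_names:
        j = fitted_mxl.index(f"lam[{attr}|voting[B]]")
        row = table[(table.party == "B") & (table.attribute == attr)]
        assert row["shift_se"].iloc[0] == pytest.approx(se[j])
        assert row["shift"].iloc[0] == pytest.approx(fitted_mxl.theta[j])


def test_party_table_recovers_true_shift(fitted_mxl):
    """The generating process moved party B's WTP means by +10 EUR; each
    estimated shift should sit within three standard errors of that."""
    truth = two_party_true_params()
    table = w.party_wtp_table(fitted_mxl)
    b = table[table.party == "B"]
    for _, row in b.iterrows():
        j = truth.coef_names.index(row.attribute)
        assert abs(row["shift"] - truth.lam[j, 1]) < 3 * row["shift_se"]


def test_party_table_unknown_party_rejected(fitted_mxl):
    with pytest.raises(ValueError, match="absent"):
        w.party_wtp_table(fitted_mxl,
                          parties=[PartyMeta("Z", "XX", 1, 1, 1.0)])


def test_log_attribute_next_level_column(fitted_mxl):
    table = w.party_wtp_table(fitted_mxl)
    r = table[(table.party == "A") & (table.attribute == "river")].iloc[0]
    assert r.wtp_next_level == pytest.approx(r.wtp * np.log(2))
    h = table[(table.party == "A") & (table.attribute == "herbivores")].iloc[0]
    assert np.isnan(h.wtp_next_level)


# -- predicted SQ probability ----------------------------------------------

def _manual_result(mu, pi, cov_names=(), baseline_party=None, groups=None):
    coef = ["asc_sq", "forest", "river", "agriculture", "connectivity",
            "carnivores", "herbivores"]
    k = len(coef)
    p = len(cov_names)
    ps = ParameterSet(coef, list(cov_names), mu, np.zeros((k, p)), pi,
                      np.zeros(p), np.zeros((k + 1, k + 1)))
    return EstimationResult(
        params=ps, param_names=[], theta=np.zeros(1), loglik=0.0,
        grad_norm=0.0, converged=True, n_draws=1, seed=0, structure="none",
        n_respondents=0, n_iter=0, groups=groups or {},
        baseline_party=baseline_party)


def test_predicted_sq_symmetric_model_is_one_third(default_fixture):
    data, _, _ = default_fixture
    res = _manual_result(np.zeros(7), -30.0)  # alpha ~ 0: cost carries no utility
    overall, _ = w.predicted_sq_probability(res, data, None)
    assert overall == pytest.approx(1 / 3, abs=1e-9)


def test_predicted_sq_dominated_is_zero(default_fixture):
    data, _, _ = default_fixture
    mu = np.zeros(7)
    mu[0] = -5000.0
    res = _manual_result(mu, np.log(0.03))
    overall, _ = w.predicted_sq_probability(res, data, None)
    assert overall < 1e-6


def test_predicted_sq_consistent_with_empirical(fitted_mxl, two_party_fixture):
    """On data simulated from (nearly) the fitted model, the simulated SQ
    probability tracks the empirical share."""
    data, cov, _ = two_party_fixture
    emp, _ = w.sq_share(data, cov)
    pred, per_party = w.predicted_sq_probability(fitted_mxl, data, cov,
                                                 n_draws=200, seed=4)
    assert abs(pred - emp) < 0.03
    assert per_party.between(0, 1).all()


# -- dimensions and summary -------------------------------------------------

def test_dimension_means_arithmetic():
    rows = []
    vals = {"forest": 10.0, "river": 20.0, "agriculture": 30.0,
            "connectivity": 44.0, "carnivores": 50.0, "herbivores": 70.0,
            "asc_sq": 5.0}
    for attr, v in vals.items():
        rows.append({"party": "A", "attribute": attr, "wtp": v})
    out = dimension_means(pd.DataFrame(rows))
    assert out.landscape_wtp.iloc[0] == pytest.approx(20.0)
    assert out.connectivity_wtp.iloc[0] == pytest.approx(44.0)
    assert out.animal_wtp.iloc[0] == pytest.approx(60.0)


def test_dimension_means_missing_attribute():
    rows = [{"party": "A", "attribute": "forest", "wtp": 1.0}]
    with pytest.raises(ValueError, match="missing"):
        dimension_means(pd.DataFrame(rows))


def test_party_summary_includes_coordinates(fitted_mxl, two_party_fixture):
    data, cov, _ = two_party_fixture
    parties = [PartyMeta("A", "XX", 4.0, 4.0, 0.6),
               PartyMeta("B", "XX", 6.0, 6.0, 0.4)]
    out = party_summary(fitted_mxl, data, cov, parties)
    assert set(out.party) == {"A", "B"}
    assert {"landscape_wtp", "connectivity_wtp", "animal_wtp", "sq_share",
            "econ_lr", "eu_position"} <= set(out.columns)
    assert out.sq_share.between(0, 1).all()


def test_party_map_plot_written(tmp_path, fitted_mxl, two_party_fixture):
    data, cov, _ = two_party_fixture
    parties = [PartyMeta("A", "XX", 4.0, 4.0, 0.6),
               PartyMeta("B", "XX", 6.0, 6.0, 0.4)]
    summary = party_summary(fitted_mxl, data, cov, parties)
    from wtpmxl.wtp import plot_party_map
    out = plot_party_map(summary, tmp_path / "map.png")
    assert (tmp_path / "map.png").stat().st_size > 0
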