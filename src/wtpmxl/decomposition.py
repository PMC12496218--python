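"""Variance decomposition of preference heterogeneity.

For each random WTP coefficient beta_j = mu_j + lambda_j X + zeta_j, the
between-respondent variance splits into an observed part var(lambda_j X)
(computed across the sample) and an unobserved part Omega_jj.  The observed
part is further attributed to covariate groups: a group's raw contribution
is the sample variance of its fitted linear combination (so a categorical
block such as voting counts the covariance among its own dummies), and
relative contributions are normalized to sum to 100% per attribute.  Joint
Wald tests mark whether each group's loadings are distinguishable from zero.

The money-utility coefficient alpha = exp(pi + gamma'X + eta) is decomposed
the same way on its natural log scale (gamma, Omega_eta), never translated
to EUR.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import CovariateMatrix
from .estimation import EstimationResult, wald_test
from .wtp import significance_stars

__all__ = [
    "DecompositionTable",
    "explained_share",
    "covariate_contribution",
    "group_wald_significance",
    "build_table",
]

COST_ROW = "cost_log_scale"
MEAN_ROW = "mean_non_monetary"


def _encode_for(result: EstimationResult, covariates: CovariateMatrix):
    cols = list(result.groups.keys())
    x, names, groups = covariates.encode(cols)
    if names != list(result.params.cov_names):
        raise ValueError(
            "covariate encoding does not match the fitted model "
            f"({names} vs {list(result.params.cov_names)})")
    return x, groups


def _loadings(result: EstimationResult, attribute: str) -> np.ndarray:
    """The attribute's covariate loadings: a row of Lambda, or gamma for the
    log-scale money coefficient."""
    ps = result.params
    if attribute == COST_ROW:
        return ps.gamma
    if attribute not in ps.coef_names:
        raise KeyError(f"no random coefficient for attribute {attribute!r}")
    return ps.lam[ps.coef_names.index(attribute)]


def _residual_variance(result: EstimationResult, attribute: str) -> float:
    omega = result.params.omega
    k = len(result.params.coef_names)
    if attribute == COST_ROW:
        return float(omega[k, k])
    return float(omega[result.params.coef_names.index(attribute),
                       result.params.coef_names.index(attribute)])


def explained_share(
    result: EstimationResult,
    covariates: CovariateMatrix,
    attribute: str,
) -> float:
    """Percentage of the attribute's total WTP variance explained by the
    covariates: 100 * var(lambda_j X) / (var(lambda_j X) + Omega_jj)."""
    x, _ = _encode_for(result, covariates)
    lam = _loadings(result, attribute)
    v_obs = float(np.var(x @ lam, ddof=1)) if x.shape[1] else 0.0
    v_res = _residual_variance(result, attribute)
    total = v_obs + v_res
    if total <= 0:
        return float("nan")
    return 100.0 * v_obs / total


def covariate_contribution(
    result: EstimationResult,
    covariates: CovariateMatrix,
    attribute: str,
    group: Sequence[int] | str,
    groups: Mapping[str, Sequence[int]] | None = None,
) -> float:
    """Relative contribution (%) of one covariate group to the attribute's
    explained heterogeneity, normalized so the groups sum to 100."""
    x, fitted_groups = _encode_for(result, covariates)
    if groups is None:
        groups = fitted_groups
    if isinstance(group, str):
        group = groups[group]
    _check_partition(groups.values(), x.shape[1])
    lam = _loadings(result, attribute)
    raws = {name: _raw_contribution(x, lam, idx) for name, idx in groups.items()}
    denom = sum(raws.values())
    if denom <= 0:
        return float("nan")
    target = _raw_contribution(x, lam, group)
    return 100.0 * target / denom


def _raw_contribution(x: np.ndarray, lam: np.ndarray, idx: Sequence[int]) -> float:
    idx = list(idx)
    if not idx:
        raise ValueError("empty covariate group")
    return float(np.var(x[:, idx] @ lam[idx], ddof=1))


def _check_partition(index_sets, p: int) -> None:
    seen: list[int] = []
    for s in index_sets:
        seen.extend(s)
    if len(seen) != len(set(seen)):
        raise ValueError("covariate groups overlap")
    if set(seen) != set(range(p)):
        raise ValueError("covariate groups do not partition the covariate set")


def _group_param_names(result: EstimationResult, attribute: str,
                       group_cols: Sequence[str]) -> list[str]:
    if attribute == COST_ROW:
        return [f"gamma[{c}]" for c in group_cols]
    return [f"lam[{attribute}|{c}]" for c in group_cols]


def group_wald_significance(
    result: EstimationResult,
    attribute: str,
    group: str,
    vcov_kind: str = "sandwich",
) -> str:
    """Joint significance marker ('', '*', '**', '***') for one covariate
    group's loadings on one attribute."""
    cov_names = list(result.params.cov_names)
    idx = result.groups[group]
    cols = [cov_names[i] for i in idx]
    names = _group_param_names(result, attribute, cols)
    _, _, p = wald_test(result, names, kind=vcov_kind)
    return significance_stars(p)


@dataclass
class DecompositionTable:
    """The decomposition grid: attributes (plus the log-scale cost row and
    the mean over the six non-monetary attributes) by covariate groups.

    ``contributions`` holds relative contributions in percent (rows sum to
    100), ``significance`` the joint Wald markers (its ``Sum`` column tests
    all of an attribute's loadings jointly), ``explained_share`` the percent
    of total variance explained, and ``unnormalized`` the raw per-group
    share of *total* (explained + residual) variance, which does not sum to
    100 across groups.
    """

    contributions: pd.DataFrame
    significance: pd.DataFrame
    explained_share: pd.Series
    unnormalized: pd.DataFrame

    @property
    def row_sums(self) -> pd.Series:
        return self.contributions.sum(axis=1).rename("sum")

    def formatted(self) -> pd.DataFrame:
        out = pd.DataFrame(index=self.contributions.index)
        for g in self.contributions.columns:
            out[g] = (self.contributions[g].map(lambda v: f"{v:.3f}")
                      + self.significance[g])
        sum_sig = (self.significance["Sum"] if "Sum" in self.significance
                   else "")
        out["Sum"] = self.row_sums.map(lambda v: f"{v:.3f}") + sum_sig
        return out

    def to_csv(self, path: str | Path) -> None:
        t = self.contributions.copy()
        t["sum"] = self.row_sums
        t["explained_share_pct"] = self.explained_share
        for g in self.contributions.columns:
            t[f"sig_{g}"] = self.significance[g]
        if "Sum" in self.significance:
            t["sig_joint"] = self.significance["Sum"]
        t.to_csv(path, index_label="attribute")


def build_table(
    result: EstimationResult,
    covariates: CovariateMatrix,
    groups: Mapping[str, Sequence[int]] | None = None,
    include_cost: bool = True,
    vcov_kind: str = "sandwich",
) -> DecompositionTable:
    """Assemble the full decomposition table for a fitted model.

    ``groups`` maps group names to covariate-column indices and must
    partition the encoded covariate set; by default each model covariate
    (with its dummies) is its own group.  Wald markers are skipped when no
    variance matrix is available.
    """
    x, fitted_groups = _encode_for(result, covariates)
    if groups is None:
        groups = fitted_groups
    _check_partition(groups.values(), x.shape[1])
    cov_names = list(result.params.cov_names)
    coef_names = list(result.params.coef_names)
    attrs = list(coef_names) + ([COST_ROW] if include_cost else [])
    non_monetary = [c for c in coef_names if c != "asc_sq"]

    have_vcov = (result.vcov_sandwich is not None
                 or result.vcov_hessian is not None)
    contrib = pd.DataFrame(index=attrs, columns=list(groups), dtype=float)
    unnorm = pd.DataFrame(index=attrs, columns=list(groups), dtype=float)
    sig = pd.DataFrame("", index=attrs + [MEAN_ROW],
                       columns=list(groups) + ["Sum"], dtype=object)
    shares = pd.Series(index=attrs, dtype=float, name="explained_share")

    for attr in attrs:
        lam = _loadings(result, attr)
        raws = {g: _raw_contribution(x, lam, idx) for g, idx in groups.items()}
        denom = sum(raws.values())
        v_res = _residual_variance(result, attr)
        total = denom + v_res
        for g in groups:
            contrib.loc[attr, g] = (100.0 * raws[g] / denom
                                    if denom > 0 else np.nan)
            unnorm.loc[attr, g] = (100.0 * raws[g] / total
                                   if total > 0 else np.nan)
        shares[attr] = 100.0 * denom / total if total > 0 else np.nan
        if have_vcov:
            all_cols: list[str] = []
            for g, idx in groups.items():
                cols = [cov_names[i] for i in idx]
                names = _group_param_names(result, attr, cols)
                _, _, p = wald_test(result, names, kind=vcov_kind)
                sig.loc[attr, g] = significance_stars(p)
                all_cols.extend(names)
            _, _, p = wald_test(result, all_cols, kind=vcov_kind)
            sig.loc[attr, "Sum"] = significance_stars(p)

    mean_row = contrib.loc[non_monetary].mean(axis=0)
    contrib.loc[MEAN_ROW] = mean_row
    unnorm.loc[MEAN_ROW] = unnorm.loc[non_monetary].mean(axis=0)
    shares[MEAN_ROW] = shares[non_monetary].mean()
    if have_vcov:
        for g, idx in groups.items():
            cols = [cov_names[i] for i in idx]
            names = [n for attr in non_monetary
                     for n in _group_param_names(result, attr, cols)]
            _, _, p = wald_test(result, names, kind=vcov_kind)
            sig.loc[MEAN_ROW, g] = significance_stars(p)
        names = [f"lam[{attr}|{c}]" for attr in non_monetary for c in cov_names]
        _, _, p = wald_test(result, names, kind=vcov_kind)
        sig.loc[MEAN_ROW, "Sum"] = significance_stars(p)

    return DecompositionTable(contributions=contrib, significance=sig,
                              explained_share=shares, unnormalized=unnorm)
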