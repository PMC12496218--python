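"""Post-estimation willingness-to-pay analysis.

Turns a fitted WTP-space mixed logit into the study's derived outputs:
per-party WTP tables (baseline party carries the mean, other parties a
shift), WTP transformations for log-coded and linear-in-levels attributes,
status-quo shares (empirical and model-predicted), and the party-level
summary dimensions used for the two-axis political map.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import ChoiceDataset, CovariateMatrix, PartyMeta
from .estimation import DrawSet, EstimationResult, _prepare, ModelSpec

__all__ = [
    "marginal_wtp_log",
    "linear_attribute_wtp",
    "party_wtp_table",
    "sq_share",
    "predicted_sq_probability",
    "dimension_means",
    "party_summary",
]

LANDSCAPE_ATTRIBUTES = ("forest", "river", "agriculture")
ANIMAL_ATTRIBUTES = ("carnivores", "herbivores")


def significance_stars(p: float) -> str:
    """Two-sided significance markers at the 10/5/1% levels."""
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.1 else ""


def marginal_wtp_log(beta: float, level: float, mode: str = "marginal") -> float:
    """WTP implied by a log-coded attribute coefficient at level code L.

    ``marginal`` mode returns beta / L, the marginal WTP per unit of the
    underlying code at level L (equal to beta itself at L = 1, the status
    quo, where it measures the first improvement).  ``discrete`` mode
    returns beta * (log(L+1) - log(L)), the value of moving up one level.
    """
    if level < 1:
        raise ValueError(f"level code must be >= 1, got {level}")
    if mode == "marginal":
        return float(beta / level)
    if mode == "discrete":
        return float(beta * (np.log(level + 1) - np.log(level)))
    raise ValueError(f"unknown mode {mode!r}")


def linear_attribute_wtp(per_level_wtp: float, level_code: int) -> float:
    """WTP for a linear-in-levels animal attribute: per-level value times
    the level code (e.g., both herbivores = 3 x the per-level WTP)."""
    if level_code < 0:
        raise ValueError("level code must be nonnegative")
    return float(per_level_wtp * level_code)


def _attr_names(result: EstimationResult) -> list[str]:
    return [c for c in result.params.coef_names]


def _party_dummies(result: EstimationResult) -> list[str]:
    return [c for c in result.params.cov_names if c.startswith("voting[")]


def party_wtp_table(
    result: EstimationResult,
    parties: Sequence[PartyMeta] | None = None,
    vcov_kind: str = "sandwich",
) -> pd.DataFrame:
    """Per-(party, attribute) mean WTP with the baseline-shift decomposition.

    The baseline party's row carries the estimated mean mu_j; every other
    party carries mu_j + lambda_j,party with a delta-method standard error.
    The ``wtp_next_level`` column reports, for log-coded attributes, the
    discrete value of the first improvement above the status quo.
    """
    dummies = _party_dummies(result)
    if result.baseline_party is None or not dummies:
        raise ValueError("voting covariate absent from the fitted model")
    if parties is not None:
        known = {d[len("voting["):-1] for d in dummies} | {result.baseline_party}
        for p in parties:
            if p.party not in known:
                raise ValueError(f"party {p.party!r} absent from model covariates")
        order = [p.party for p in parties]
    else:
        order = [result.baseline_party] + sorted(
            d[len("voting["):-1] for d in dummies)
    vcov = result.vcov(vcov_kind)
    rows = []
    log_attrs = {"forest", "river", "agriculture", "connectivity"}
    for party in order:
        is_base = party == result.baseline_party
        for attr in _attr_names(result):
            i = result.index(f"mu[{attr}]")
            if is_base:
                est = result.theta[i]
                var = vcov[i, i]
                shift, shift_se = 0.0, np.nan
            else:
                j = result.index(f"lam[{attr}|voting[{party}]]")
                est = result.theta[i] + result.theta[j]
                var = vcov[i, i] + vcov[j, j] + 2 * vcov[i, j]
                shift = result.theta[j]
                shift_se = float(np.sqrt(max(vcov[j, j], 0)))
            se = float(np.sqrt(max(var, 0)))
            z = est / se if se > 0 else np.inf
            p = 2 * norm.sf(abs(z))
            rows.append({
                "party": party, "attribute": attr, "is_baseline": is_base,
                "wtp": float(est), "se": se,
                "ci_low": float(est - 1.96 * se),
                "ci_high": float(est + 1.96 * se),
                "sig": significance_stars(p),
                "shift": float(shift), "shift_se": shift_se,
                "wtp_next_level": float(est * np.log(2.0))
                                  if attr in log_attrs else np.nan,
            })
    return pd.DataFrame(rows)


def sq_share(
    data: ChoiceDataset,
    covariates: CovariateMatrix | None = None,
    parties: Sequence[str] | None = None,
) -> tuple[float, pd.Series | None]:
    """Share of tasks in which the status quo was chosen.

    Returns (overall share, per-party shares) — the latter None when no
    covariates are supplied.  A party with no respondents is reported as
    missing (NaN), never as zero.
    """
    t = data.table
    sq_chosen = t.loc[(t["is_sq"] == 1), ["respondent_id", "task", "chosen"]]
    n_tasks = t.groupby(["respondent_id", "task"]).ngroups
    overall = float(sq_chosen["chosen"].sum() / n_tasks)
    if covariates is None:
        return overall, None
    covariates.check_matches(data)
    voting = covariates.table.set_index("respondent_id")["voting"]
    per_resp = sq_chosen.groupby("respondent_id")["chosen"].agg(["sum", "count"])
    per_resp["party"] = voting.reindex(per_resp.index)
    g = per_resp.groupby("party")
    shares = g["sum"].sum() / g["count"].sum()
    if parties is not None:
        shares = shares.reindex(list(parties))
    return overall, shares.rename("sq_share")


def predicted_sq_probability(
    result: EstimationResult,
    data: ChoiceDataset,
    covariates: CovariateMatrix | None,
    n_draws: int = 500,
    seed: int = 0,
) -> tuple[float, pd.Series | None]:
    """Model-implied probability of choosing the status quo, averaged over
    tasks and simulation draws, overall and by party."""
    spec = ModelSpec(covariates=tuple(result.groups.keys()),
                     n_draws=max(1, n_draws), structure=result.structure)
    md = _prepare(data, covariates, spec)
    ps = result.params
    k = len(ps.coef_names)
    if result.structure == "none" or not np.any(ps.chol):
        draws = DrawSet.zeros(md.n, k + 1)
    else:
        draws = DrawSet.generate(md.n, k + 1, n_draws, seed)
    u = draws.u
    mean_beta = ps.mu[None, :] + md.xcov @ ps.lam.T
    s0 = ps.pi + md.xcov @ ps.gamma
    T, A = md.n_tasks, md.n_alts
    n = md.n
    p_sq = np.empty(n)
    chunk = max(1, int(6_000_000 / max(1, u.shape[1] * T * A)))
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        uc = u[lo:hi]
        beta = mean_beta[lo:hi, None, :] + uc[:, :, :k] @ ps.chol[:k, :k].T
        a = np.exp(np.clip(s0[lo:hi, None] + uc @ ps.chol[k, :], -60, 60))
        v = a[:, :, None] * (np.matmul(beta, md.x[lo:hi].transpose(0, 2, 1))
                             - md.cost[lo:hi, None, :])
        vt = v.reshape(hi - lo, -1, T, A)
        e = np.exp(vt - vt.max(axis=3, keepdims=True))
        prob = e / e.sum(axis=3, keepdims=True)
        # status quo is alternative 0
        p_sq[lo:hi] = prob[..., 0].mean(axis=(1, 2))
    overall = float(p_sq.mean())
    if covariates is None:
        return overall, None
    voting = covariates.table.set_index("respondent_id")["voting"]
    s = pd.Series(p_sq, index=md_respondent_ids(md, data)).groupby(
        voting.reindex(md_respondent_ids(md, data))).mean()
    return overall, s.rename("predicted_sq_probability")


def md_respondent_ids(md, data: ChoiceDataset) -> np.ndarray:
    return np.sort(data.respondent_ids)


def dimension_means(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a party WTP table into the three political-map dimensions:
    landscape (mean of forest, river, agriculture), connectivity, and large
    animals (mean of carnivores, herbivores)."""
    need = set(LANDSCAPE_ATTRIBUTES) | {"connectivity"} | set(ANIMAL_ATTRIBUTES)
    have = set(table["attribute"])
    missing = need - have
    if missing:
        raise ValueError(f"WTP table missing attribute rows: {sorted(missing)}")
    wide = table.pivot(index="party", columns="attribute", values="wtp")
    out = pd.DataFrame({
        "landscape_wtp": wide[list(LANDSCAPE_ATTRIBUTES)].mean(axis=1),
        "connectivity_wtp": wide["connectivity"],
        "animal_wtp": wide[list(ANIMAL_ATTRIBUTES)].mean(axis=1),
    })
    return out.reset_index()


def plot_party_map(summary: pd.DataFrame, path, dimension: str = "sq_share"):
    """Scatter the parties on the (economic left-right, EU position) plane,
    sized/colored by one summary dimension; writes an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not {"econ_lr", "eu_position"} <= set(summary.columns):
        raise ValueError("summary lacks party map coordinates")
    fig, ax = plt.subplots(figsize=(6, 5))
    vals = summary[dimension].to_numpy(float)
    sc = ax.scatter(summary["econ_lr"], summary["eu_position"], c=vals,
                    s=400 * summary.get("share", pd.Series(0.2, index=summary.index)),
                    cmap="viridis")
    for _, row in summary.iterrows():
        ax.annotate(row["party"], (row["econ_lr"], row["eu_position"]),
                    textcoords="offset points", xytext=(6, 6))
    ax.set_xlabel("economic left-right")
    ax.set_ylabel("EU integration: against-in favor")
    fig.colorbar(sc, ax=ax, label=dimension)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def party_summary(
    result: EstimationResult,
    data: ChoiceDataset,
    covariates: CovariateMatrix,
    parties: Sequence[PartyMeta] | None = None,
) -> pd.DataFrame:
    """The full political-map summary: per party the empirical SQ share and
    the three WTP dimensions, joined with map coordinates when supplied."""
    table = party_wtp_table(result, parties)
    dims = dimension_means(table)
    _, shares = sq_share(data, covariates, parties=list(dims["party"]))
    out = dims.merge(shares.reset_index().rename(columns={"party": "party"}),
                     on="party", how="left")
    if parties is not None:
        meta = pd.DataFrame([{"party": p.party, "econ_lr": p.econ_lr,
                              "eu_position": p.eu_position, "share": p.share}
                             for p in parties])
        out = out.merge(meta, on="party", how="left")
    return out
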