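"""Synthetic choice-experiment data with the estimator's exact generative
structure.

The generator mirrors the hierarchical model the estimator assumes: each
respondent n owns a WTP vector beta_n = mu + Lambda X_n + zeta_n and a
money-utility scale alpha_n = exp(pi + gamma'X_n + eta_n), with
(zeta_n, eta_n) jointly multivariate normal with covariance Omega.  Choices
are multinomial-logit draws over V = alpha_n (beta_n'x - cost).

Defaults emulate the Oder Delta rewilding survey's structure: 12 cards per
respondent, two program alternatives plus a status quo, six rewilding
attributes plus an annual tax, respondents affiliated with one of six
parties at realistic shares (largest party is the covariate baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    choice_columns,
    ChoiceDataset,
    CovariateMatrix,
    DesignSpec,
    PartyMeta,
    default_design,
)

__all__ = [
    "TrueParameters",
    "SimulationConfig",
    "default_parties",
    "default_true_parameters",
    "default_config",
    "sample_covariates",
    "make_choice_template",
    "draw_individual_coefficients",
    "simulate_choices",
    "make_fixture",
]


@dataclass
class TrueParameters:
    """Ground-truth generative parameters.

    ``mu`` is ordered as [asc_sq, forest, river, agriculture, connectivity,
    carnivores, herbivores] (EUR); ``lam`` is (K, p) over ``cov_names``;
    ``pi``/``gamma`` govern log marginal utility of money; ``omega_chol`` is
    the lower-triangular Cholesky factor of the joint (K+1)-dimensional
    covariance of (zeta, eta).
    """

    coef_names: list[str]
    cov_names: list[str]
    mu: np.ndarray
    lam: np.ndarray
    pi: float
    gamma: np.ndarray
    omega_chol: np.ndarray

    def __post_init__(self) -> None:
        k, p = len(self.coef_names), len(self.cov_names)
        self.mu = np.asarray(self.mu, float).reshape(k)
        self.lam = np.asarray(self.lam, float).reshape(k, p)
        self.gamma = np.asarray(self.gamma, float).reshape(p)
        self.omega_chol = np.asarray(self.omega_chol, float).reshape(k + 1, k + 1)
        if np.any(np.triu(self.omega_chol, 1) != 0):
            raise ValueError("omega_chol must be lower triangular")
        if np.any(np.diag(self.omega_chol) < 0):
            raise ValueError("omega_chol diagonal must be nonnegative")

    @property
    def omega(self) -> np.ndarray:
        return self.omega_chol @ self.omega_chol.T

    def to_dict(self) -> dict:
        return {
            "coef_names": list(self.coef_names),
            "cov_names": list(self.cov_names),
            "mu": self.mu.tolist(),
            "lam": self.lam.tolist(),
            "pi": float(self.pi),
            "gamma": self.gamma.tolist(),
            "omega_chol": self.omega_chol.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueParameters":
        return cls(
            coef_names=list(d["coef_names"]), cov_names=list(d["cov_names"]),
            mu=np.asarray(d["mu"]), lam=np.asarray(d["lam"]),
            pi=float(d["pi"]), gamma=np.asarray(d["gamma"]),
            omega_chol=np.asarray(d["omega_chol"]),
        )


@dataclass
class SimulationConfig:
    """Everything needed to generate one synthetic study."""

    n_respondents: int
    design: DesignSpec
    parties: list[PartyMeta]
    regions: dict[str, float]
    true_params: TrueParameters
    seed: int
    covariate_columns: list[str] = field(default_factory=lambda: [
        "log_distance", "age", "male", "city_size", "income", "education",
        "voting", "region",
    ])

    def __post_init__(self) -> None:
        PartyMeta.validate_shares(self.parties)
        if abs(sum(self.regions.values()) - 1.0) > 1e-9:
            raise ValueError("region shares must sum to 1")
        if self.n_respondents < 1:
            raise ValueError("need at least one respondent")


def default_parties() -> list[PartyMeta]:
    """Six parties with Poland-2022-like support shares and two-axis map
    coordinates (economic left-right, EU integration; 0-10 scales)."""
    return [
        PartyMeta("PiS", "PL", 4.0, 3.0, 0.35),
        PartyMeta("KO", "PL", 6.0, 8.5, 0.28),
        PartyMeta("P2050", "PL", 5.5, 7.5, 0.12),
        PartyMeta("NL", "PL", 2.5, 8.0, 0.09),
        PartyMeta("KONF", "PL", 8.5, 1.5, 0.09),
        PartyMeta("PSL", "PL", 5.0, 6.5, 0.07),
    ]


def _default_cov_names(parties: list[PartyMeta], regions: dict[str, float]) -> list[str]:
    base_party = max(parties, key=lambda p: p.share).party
    base_region = max(regions, key=regions.get)
    names = ["log_distance", "age", "male", "city_size", "income", "education"]
    names += [f"voting[{p.party}]" for p in sorted(parties, key=lambda q: q.party)
              if p.party != base_party]
    names += [f"region[{r}]" for r in sorted(regions) if r != base_region]
    return names


def default_true_parameters(
    parties: list[PartyMeta] | None = None,
    regions: dict[str, float] | None = None,
) -> TrueParameters:
    """Generative defaults chosen to echo the study's headline magnitudes:
    mean WTPs of tens of EUR per attribute (highest for connectivity and the
    large animals), party/region loadings dominating the explained
    heterogeneity, substantial unexplained spread, and a status-quo share in
    the low double digits driven by a positive SQ inertia constant."""
    parties = parties if parties is not None else default_parties()
    regions = regions if regions is not None else {
        "north": 0.4, "south": 0.3, "east": 0.2, "west": 0.1}
    coef_names = ["asc_sq", "forest", "river", "agriculture",
                  "connectivity", "carnivores", "herbivores"]
    cov_names = _default_cov_names(parties, regions)
    k, p = len(coef_names), len(cov_names)
    mu = np.array([95.0, 20.0, 28.0, 15.0, 50.0, 60.0, 45.0])

    lam = np.zeros((k, p))
    col = {c: i for i, c in enumerate(cov_names)}
    party_shift = {"KO": 12.0, "NL": 10.0, "P2050": 4.0, "KONF": -8.0, "PSL": -4.0}
    for party, shift in party_shift.items():
        j = col.get(f"voting[{party}]")
        if j is not None:
            lam[1:, j] = shift                       # all six attributes
            lam[0, j] = {"KONF": 25.0, "KO": -15.0, "NL": -12.0}.get(party, 0.0)
    region_shift = {"south": 8.0, "east": -8.0, "west": 5.0}
    for region, shift in region_shift.items():
        j = col.get(f"region[{region}]")
        if j is not None:
            lam[1:5, j] = shift                      # landscape block
    lam[1:5, col["income"]] = 6.0
    lam[:, col["log_distance"]] = -5.0
    lam[5:7, col["age"]] = -4.0

    # joint covariance of (zeta, eta): moderate correlation inside the
    # landscape block, independent animal and money components
    sds = np.array([45.0, 18.0, 18.0, 15.0, 22.0, 30.0, 25.0, 0.5])
    corr = np.eye(k + 1)
    for i in range(1, 5):
        for j in range(1, 5):
            if i != j:
                corr[i, j] = 0.3
    omega = np.outer(sds, sds) * corr
    omega_chol = np.linalg.cholesky(omega)

    gamma = np.zeros(p)
    gamma[col["income"]] = 0.10
    return TrueParameters(coef_names, cov_names, mu, lam,
                          float(np.log(0.03)), gamma, omega_chol)


def default_config(n_respondents: int = 1000, seed: int = 0,
                   n_tasks: int = 12) -> SimulationConfig:
    parties = default_parties()
    regions = {"north": 0.4, "south": 0.3, "east": 0.2, "west": 0.1}
    return SimulationConfig(
        n_respondents=n_respondents,
        design=default_design(n_tasks=n_tasks),
        parties=parties,
        regions=regions,
        true_params=default_true_parameters(parties, regions),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_covariates(config: SimulationConfig) -> CovariateMatrix:
    """Draw respondent covariates: standardized continuous variables,
    ordinal city size / education, and party / region labels at the
    configured shares.  Deterministic under the config seed."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    n = config.n_respondents
    party_names = [p.party for p in config.parties]
    party_probs = np.array([p.share for p in config.parties])
    if np.any(party_probs < 0) or np.any(party_probs > 1):
        raise ValueError("party shares must lie in [0, 1]")
    region_names = list(config.regions)
    region_probs = np.array([config.regions[r] for r in region_names])
    t = pd.DataFrame({
        "respondent_id": np.arange(n),
        "log_distance": rng.standard_normal(n),
        "age": rng.standard_normal(n),
        "male": rng.binomial(1, 0.49, n).astype(float),
        "city_size": rng.choice(np.arange(1, 6), n,
                                p=[0.25, 0.25, 0.2, 0.15, 0.15]).astype(float),
        "income": rng.standard_normal(n),
        "education": rng.choice(np.arange(1, 5), n,
                                p=[0.15, 0.35, 0.3, 0.2]).astype(float),
        "voting": rng.choice(party_names, n, p=party_probs),
        "region": rng.choice(region_names, n, p=region_probs),
    })
    base_party = max(config.parties, key=lambda p: p.share).party
    base_region = max(config.regions, key=config.regions.get)
    return CovariateMatrix(t, baseline_party=base_party, baseline_region=base_region,
                           party_levels=tuple(party_names),
                           region_levels=tuple(region_names))


def make_choice_template(config: SimulationConfig) -> ChoiceDataset:
    """Choice cards with attribute levels drawn uniformly per program
    alternative (status quo fixed at its lowest-level/zero-cost profile);
    chosen flags are all zero until :func:`simulate_choices` fills them."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])
    design = config.design
    n, T, A = config.n_respondents, design.n_tasks_per_respondent, design.n_alternatives
    n_prog = design.n_program_alternatives
    rows = n * T * A
    rid = np.repeat(np.arange(n), T * A)
    task = np.tile(np.repeat(np.arange(T), A), n)
    alt = np.tile(np.arange(A), n * T)
    is_sq = (alt == 0).astype(int) if design.has_status_quo else np.zeros(rows, int)
    t = pd.DataFrame({"respondent_id": rid, "task": task, "alt": alt,
                      "is_sq": is_sq})
    prog = is_sq == 0 if design.has_status_quo else np.ones(rows, bool)
    n_prog_rows = int(prog.sum())
    for a in design.non_cost_attributes:
        codes = np.asarray(a.level_codes, float)
        vals = np.zeros(rows)
        draw = codes[rng.integers(0, len(codes), n_prog_rows)]
        vals[prog] = np.log(draw) if a.kind == "log_level" else draw
        t[a.name] = vals
    cost = np.zeros(rows)
    cost[prog] = rng.choice(np.asarray(design.cost_levels, float), n_prog_rows)
    t["cost_eur"] = cost
    t["chosen"] = 0
    return ChoiceDataset(t[choice_columns(design)], design)


def draw_individual_coefficients(
    covariates: CovariateMatrix,
    params: TrueParameters,
    seed: int,
) -> pd.DataFrame:
    """Draw (beta_n, alpha_n) for each respondent from the hierarchical model.

    Returns a frame keyed by respondent_id with one column per WTP
    coefficient plus ``alpha``; alpha is strictly positive by construction.
    """
    x, names, _ = covariates.encode()
    want = list(params.cov_names)
    if names != want:
        # tolerate column-order differences but not content differences
        idx = []
        for c in want:
            if c not in names:
                raise ValueError(f"covariate {c!r} required by TrueParameters "
                                 "is absent from the encoded matrix")
            idx.append(names.index(c))
        x = x[:, idx]
    rng = np.random.default_rng(seed)
    n, k = len(x), len(params.coef_names)
    z = rng.standard_normal((n, k + 1)) @ params.omega_chol.T
    beta = params.mu[None, :] + x @ params.lam.T + z[:, :k]
    alpha = np.exp(params.pi + x @ params.gamma + z[:, k])
    out = pd.DataFrame(beta, columns=params.coef_names)
    out.insert(0, "respondent_id",
               np.sort(covariates.respondent_ids))
    out["alpha"] = alpha
    return out


def simulate_choices(
    template: ChoiceDataset,
    coefficients: pd.DataFrame,
    seed: int,
) -> ChoiceDataset:
    """Fill chosen flags by sampling each task from the logit probabilities
    implied by V = alpha_n (beta_n'x - cost)."""
    arrays = template.to_arrays()
    coef = coefficients.set_index("respondent_id").loc[arrays.respondent_ids]
    beta = coef[arrays.coef_names].to_numpy()          # (N, K)
    alpha = coef["alpha"].to_numpy()                   # (N,)
    net = np.einsum("ntak,nk->nta", arrays.x, beta) - arrays.cost
    v = alpha[:, None, None] * net
    if not np.all(np.isfinite(v)):
        n_bad = int((~np.isfinite(v)).any(axis=(1, 2)).sum())
        raise FloatingPointError(
            f"non-finite utilities for {n_bad} respondents "
            f"(max |alpha| = {np.abs(alpha).max():.3g}); "
            "check the scale of the money-utility parameters"
        )
    v = v - v.max(axis=2, keepdims=True)
    p = np.exp(v)
    p /= p.sum(axis=2, keepdims=True)
    rng = np.random.default_rng(seed)
    cum = p.cumsum(axis=2)
    u = rng.random(cum.shape[:2])[..., None]
    choice = (u > cum).sum(axis=2)                     # (N, T) indices
    t = template.table.copy()
    t = t.sort_values(["respondent_id", "task", "alt"], kind="stable")
    n, T, A = p.shape[0], p.shape[1], p.shape[2]
    flat = np.zeros((n, T, A), int)
    np.put_along_axis(flat, choice[..., None], 1, axis=2)
    t["chosen"] = flat.reshape(-1)
    ds = ChoiceDataset(t[choice_columns(template.design)], template.design)
    ds.validate()
    return ds


def make_fixture(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
) -> tuple[ChoiceDataset, CovariateMatrix, TrueParameters]:
    """End-to-end bundle: covariates, cards, coefficients, choices.

    With ``out_dir`` set, writes ``choices.csv``, ``covariates.csv`` and a
    ``manifest.yaml`` recording the seed and the true parameters.
    """
    cov = sample_covariates(config)
    template = make_choice_template(config)
    coef_seed, choice_seed = (
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(config.seed).spawn(3)[2].spawn(2)
    )
    coefs = draw_individual_coefficients(cov, config.true_params, coef_seed)
    data = simulate_choices(template, coefs, choice_seed)
    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            data.table[choice_columns(config.design)].to_csv(out / "choices.csv", index=False)
            cov.table.to_csv(out / "covariates.csv", index=False)
            manifest = {
                "seed": int(config.seed),
                "n_respondents": int(config.n_respondents),
                "n_tasks": int(config.design.n_tasks_per_respondent),
                "baseline_party": cov.baseline_party,
                "baseline_region": cov.baseline_region,
                "true_params": config.true_params.to_dict(),
            }
            (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
        except OSError as e:
            raise OSError(f"cannot write fixture bundle under {out}: {e}") from e
    return data, cov, config.true_params
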