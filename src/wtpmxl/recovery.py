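"""Parameter-recovery and test-size simulation studies.

These are the package's estimator-validation experiments: simulate data from
known parameters, re-estimate, and summarize bias and Monte Carlo spread
(recovery study), or simulate under a zero restriction and measure the Wald
test's empirical rejection rate (size study).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import AttributeSpec, DesignSpec, PartyMeta, default_design
from .estimation import ModelSpec, fit_mnl, fit_mxl, wald_test
from .synthetic import SimulationConfig, TrueParameters, make_fixture

__all__ = [
    "recovery_true_parameters",
    "recovery_config",
    "run_recovery_study",
    "run_wald_size_study",
]


def _child_seed(base_seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([base_seed, *key]).generate_state(1)[0]
               % (2**31))


def recovery_true_parameters() -> TrueParameters:
    """Ground truth for the recovery study: the full six-attribute design,
    one non-baseline party carrying EUR-scale WTP shifts, and independent
    random components (diagonal Omega) so every variance is identified from
    a moderate fixture."""
    coef = ["asc_sq", "forest", "river", "agriculture", "connectivity",
            "carnivores", "herbivores"]
    mu = np.array([95.0, 20.0, 28.0, 15.0, 50.0, 60.0, 45.0])
    lam = np.array([[20.0], [10.0], [-8.0], [12.0], [15.0], [-10.0], [8.0]])
    sds = np.array([40.0, 15.0, 15.0, 12.0, 20.0, 25.0, 20.0, 0.4])
    return TrueParameters(coef, ["voting[B]"], mu, lam,
                          float(np.log(0.03)), np.array([0.15]),
                          np.diag(sds))


def recovery_config(n_respondents: int = 1000, seed: int = 0) -> SimulationConfig:
    parties = [PartyMeta("A", "XX", 4.0, 4.0, 0.6),
               PartyMeta("B", "XX", 6.0, 6.0, 0.4)]
    return SimulationConfig(
        n_respondents=n_respondents,
        design=default_design(n_tasks=12),
        parties=parties,
        regions={"r1": 1.0},
        true_params=recovery_true_parameters(),
        seed=seed,
        covariate_columns=["voting"],
    )


def run_recovery_study(
    n_seeds: int = 20,
    n_respondents: int = 1000,
    n_draws: int = 500,
    base_seed: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulate-and-refit ``n_seeds`` independent studies and summarize.

    Returns one row per parameter with the truth, the mean estimate across
    seeds, the relative bias of the mean, and the Monte Carlo standard error
    of the mean.  Random-component variances are compared on the Omega
    (variance) scale.
    """
    truth = recovery_true_parameters()
    k = len(truth.coef_names)
    spec = ModelSpec(covariates=("voting",), n_draws=n_draws,
                     structure="diagonal")
    rows = []
    for s in range(n_seeds):
        cfg = recovery_config(n_respondents, seed=_child_seed(base_seed, 0, s))
        data, cov, _ = make_fixture(cfg)
        res = fit_mxl(data, cov, spec, seed=_child_seed(base_seed, 1, s),
                      compute_vcov=False)
        est = {}
        for j, c in enumerate(truth.coef_names):
            est[f"mu[{c}]"] = res.params.mu[j]
            est[f"lam[{c}|voting[B]]"] = res.params.lam[j, 0]
            est[f"omega[{c}]"] = res.params.omega[j, j]
        est["pi"] = res.params.pi
        est["gamma[voting[B]]"] = res.params.gamma[0]
        est["omega[log_alpha]"] = res.params.omega[k, k]
        est["_converged"] = res.converged
        rows.append(est)
        if progress:
            print(f"  recovery replicate {s + 1}/{n_seeds} done "
                  f"(loglik {res.loglik:.1f})")
    reps = pd.DataFrame(rows)

    true_vals = {}
    for j, c in enumerate(truth.coef_names):
        true_vals[f"mu[{c}]"] = truth.mu[j]
        true_vals[f"lam[{c}|voting[B]]"] = truth.lam[j, 0]
        true_vals[f"omega[{c}]"] = truth.omega[j, j]
    true_vals["pi"] = truth.pi
    true_vals["gamma[voting[B]]"] = truth.gamma[0]
    true_vals["omega[log_alpha]"] = truth.omega[k, k]

    out = []
    for name, tv in true_vals.items():
        vals = reps[name].to_numpy()
        mean = vals.mean()
        mc_se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
        out.append({
            "parameter": name,
            "truth": tv,
            "mean_estimate": mean,
            "rel_bias": (mean - tv) / tv if tv != 0 else np.nan,
            "mc_se": mc_se,
            "z_bias": (mean - tv) / mc_se if mc_se and np.isfinite(mc_se)
                      and mc_se > 0 else np.nan,
            "n_converged": int(reps["_converged"].sum()),
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Wald size study
# ---------------------------------------------------------------------------

def _size_study_design() -> DesignSpec:
    attrs = (
        AttributeSpec("river", "log_level",
                      ("level 1", "level 2", "level 3", "level 4"),
                      (1, 2, 3, 4)),
        AttributeSpec("carnivores", "linear_count",
                      ("none", "just lynx", "just wolf", "both"),
                      (0, 1, 1, 2)),
        AttributeSpec("cost_eur", "cost"),
    )
    return DesignSpec(attributes=attrs, n_tasks_per_respondent=8)


def _size_study_truth(lam_scale: float = 0.0) -> TrueParameters:
    """Two-attribute multinomial-logit truth; the single covariate ('income')
    loads on the WTP means with strength ``lam_scale`` (0 under the null)."""
    coef = ["asc_sq", "river", "carnivores"]
    mu = np.array([40.0, 30.0, 50.0])
    lam = lam_scale * np.array([[1.0], [1.0], [1.0]])
    k = len(coef)
    return TrueParameters(coef, ["income"], mu, lam, float(np.log(0.03)),
                          np.array([0.0]), np.zeros((k + 1, k + 1)))


def run_wald_size_study(
    n_replicates: int = 500,
    n_respondents: int = 250,
    base_seed: int = 0,
    level: float = 0.05,
    lam_scale: float = 0.0,
    vcov_kind: str = "sandwich",
    attribute: str = "river",
    progress: bool = False,
) -> dict:
    """Empirical rejection rate of the group Wald test on a covariate's
    loading when the data are simulated with that loading at ``lam_scale``
    (0 gives the test's size, > 0 its power).

    Each replicate simulates a compact multinomial-logit study (no random
    components, so each fit is fast and exact), fits it, and applies the
    same per-attribute group test the decomposition table uses: the
    'income' loading on ``attribute``.
    """
    design = _size_study_design()
    truth = _size_study_truth(lam_scale)
    parties = [PartyMeta("A", "XX", 5.0, 5.0, 1.0)]
    spec = ModelSpec(covariates=("income",))
    reject = 0
    pvals = []
    for r in range(n_replicates):
        cfg = SimulationConfig(
            n_respondents=n_respondents, design=design, parties=parties,
            regions={"r1": 1.0}, true_params=truth,
            seed=_child_seed(base_seed, 2, r), covariate_columns=["income"])
        data, cov, _ = make_fixture(cfg)
        res = fit_mnl(data, cov, spec)
        _, _, p = wald_test(res, [f"lam[{attribute}|income]"], kind=vcov_kind)
        pvals.append(p)
        reject += p < level
        if progress and (r + 1) % 100 == 0:
            print(f"  wald replicate {r + 1}/{n_replicates}")
    rate = reject / n_replicates
    half = 1.96 * np.sqrt(level * (1 - level) / n_replicates)
    return {"rejection_rate": rate, "n_replicates": n_replicates,
            "level": level, "binomial_ci": (level - half, level + half),
            "pvalues": np.asarray(pvals)}
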