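"""Decompose preference heterogeneity into observed and unobserved parts.

For each WTP coefficient the between-respondent variance splits into the
part explained by respondent covariates (income and party here) and the
residual random-component variance; the explained part is then attributed
to covariate groups, normalized to 100% per attribute, with joint Wald
significance markers.
"""

import numpy as np

import wtpmxl as w
from wtpmxl.data_model import PartyMeta
from wtpmxl.decomposition import build_table

parties = [PartyMeta("A", "XX", 4.0, 4.0, 0.6),
           PartyMeta("B", "XX", 6.0, 6.0, 0.4)]
coef = ["asc_sq", "forest", "river", "agriculture", "connectivity",
        "carnivores", "herbivores"]
mu = np.array([95.0, 20.0, 28.0, 15.0, 50.0, 60.0, 45.0])
lam = np.zeros((7, 2))
lam[:, 1] = 12.0      # party B shifts every attribute
lam[1:5, 0] = 6.0     # income loads on the landscape block
sds = np.array([40.0, 15.0, 15.0, 12.0, 20.0, 25.0, 20.0, 0.4])
truth = w.TrueParameters(coef, ["income", "voting[B]"], mu, lam,
                         float(np.log(0.03)), np.array([0.1, 0.0]),
                         np.diag(sds))
cfg = w.SimulationConfig(
    n_respondents=300, design=w.default_design(n_tasks=8),
    parties=parties, regions={"r1": 1.0}, true_params=truth, seed=19,
    covariate_columns=["income", "voting"])
data, cov, _ = w.make_fixture(cfg)
spec = w.ModelSpec(covariates=("income", "voting"), n_draws=100,
                   structure="diagonal")
result = w.fit_mxl(data, cov, spec, seed=3)

table = build_table(result, cov)
print("relative covariate contributions to explained heterogeneity (%),")
print("with joint Wald significance markers (rows sum to 100):")
print(table.formatted().to_string())
print("\nshare of total WTP variance explained by covariates (%):")
print(table.explained_share.round(1).to_string())
print("\nIncome was simulated to matter only for the landscape block and")
print("party only as a uniform shift: the table attributes the explained")
print("variance accordingly, while the residual variance keeps the")
print("explained shares modest.")
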