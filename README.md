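# wtpmxl

Willingness-to-pay-space mixed logit for stated-preference choice
experiments on landscape rewilding — simulation, maximum simulated
likelihood estimation, and preference-heterogeneity decomposition.

## The problem

Discrete choice experiments ask survey respondents to choose repeatedly
between policy programs described by attributes and an annual cost, or a
zero-cost status quo.  In the rewilding setting the attributes are four
landscape gradients (forest, river, agriculture, connectivity), the
presence of large carnivores (lynx/wolf) and herbivores (elk/bison), and a
tax in EUR/year.  The scientific questions are (i) what people are willing
to pay for each intervention, (ii) how strongly willingness to pay (WTP)
varies across people, and (iii) how much of that variation observable
characteristics — especially political affiliation — can explain.

`wtpmxl` is aimed at choice modellers and environmental economists who
want a reproducible, testable pipeline for this class of analysis: a
generative simulator with exactly the estimator's assumed structure, the
estimator itself, and the derived party-level outputs.

## The model

Utility of alternative *i* in task *t* for respondent *n*:

    U_itn = alpha_n ( beta_n' x_itn - Cost_itn ) + e_itn,  e ~ Gumbel

where `x` stacks an SQ dummy, the log-coded landscape levels and the
linear animal codes.  Since cost enters with coefficient `alpha_n`
(marginal utility of money, confounded with scale), every component of
`beta_n` is measured directly in EUR.  Respondent heterogeneity is
hierarchical,

    beta_n  = mu + Lambda X_n + zeta_n,
    alpha_n = exp(pi + gamma' X_n + eta_n),
    (zeta_n, eta_n) ~ N(0, Omega),

with `X_n` the respondent covariates (party and region as baseline-omitted
dummies).  The likelihood integral over `(zeta, eta)` is simulated with
scrambled Sobol draws (2000 by default) and maximized by quasi-Newton
iteration with fully analytic gradients; `Omega` is estimated through its
Cholesky factor.  See `docs/methods.md` for the complete account.

## Worked example

`examples/03_party_wtp_tables.py` simulates a two-party study (300
respondents, 6 cards each; party B's true WTPs sit 10 EUR above party A's
on every attribute), fits the mixed logit at 100 draws and prints the
per-party WTP table:

```
party    attribute  is_baseline    wtp    se  ci_low  ci_high sig  shift  shift_se  wtp_next_level
    A       asc_sq         True  98.39 12.76   73.38   123.41 ***   0.00       NaN             NaN
    A        river         True  28.90  4.43   20.22    37.57 ***   0.00       NaN           20.03
    A connectivity         True  46.90  5.36   36.39    57.41 ***   0.00       NaN           32.51
    ...
    B connectivity        False  63.52  6.41   50.96    76.07 ***  16.62      8.32           44.03
    B   herbivores        False  62.24  5.32   51.81    72.68 ***  14.70      6.47             NaN
```

Rows for the baseline party A carry the estimated mean WTP `mu` (EUR per
year); rows for party B carry `mu + lambda_B` with the estimated shift and
its standard error alongside — here the true +10 EUR shifts are recovered
within sampling error.  For log-coded attributes `wtp` is the value at the
lowest level (equal to the coefficient), and `wtp_next_level` the discrete
value of the first improvement.  The same script prints the political-map
summary (landscape / connectivity / animal WTP dimensions and the
status-quo share per party) and the scalar transformations:

```
connectivity WTP at the lowest level (= the coefficient itself): 46.90 EUR
value of the first improvement (level 1 -> 2): 32.51 EUR
herbivores are linear in levels: per-level 47.55 EUR, both species (code 3) 142.64 EUR
```

The other examples cover simulation (`01`), estimation against known truth
(`02`) and the heterogeneity decomposition with Wald markers (`04`).

## Command line

The same pipeline is scriptable from the shell:

```sh
wtpmxl simulate -c config.yaml -o study/
wtpmxl fit --choices study/choices.csv --covariates study/covariates.csv \
       -c config.yaml -o study/result.yaml
wtpmxl report --result study/result.yaml --choices study/choices.csv \
       --covariates study/covariates.csv -c config.yaml -o study/report/
wtpmxl recover -o study/recovery/          # simulation studies
```

Every run writes a manifest with the config hash, seed and package
version; exit codes are 0 / 1 / 2 for ok / user error / non-convergence.

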