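"""Panel mixed logit in willingness-to-pay space, estimated by maximum
simulated likelihood.

Model
-----
Utility of alternative i in task t for respondent n:

    U_itn = V_itn + e_itn,   V_itn = alpha_n * (beta_n' x_itn - Cost_itn)

with x the encoded attribute vector (SQ dummy first) so that beta_n is in
EUR, and e Gumbel.  Heterogeneity is hierarchical:

    beta_n  = mu + Lambda X_n + zeta_n
    alpha_n = exp(pi + gamma' X_n + eta_n),  (zeta_n, eta_n) ~ N(0, Omega)

Omega spans all K+1 random dimensions jointly and is parameterized through
its lower-triangular Cholesky factor, so the fitted covariance is positive
semidefinite by construction.  The likelihood integral over (zeta, eta) has
no closed form; it is simulated per respondent as the average over a fixed
block of scrambled-Sobol standard-normal draws of the product over tasks of
logit choice probabilities.  The simulated log likelihood and its exact
analytic gradient (including the Cholesky block) are maximized with a
quasi-Newton optimizer from multinomial-logit starting values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import optimize
from scipy.special import ndtri
from scipy.stats import chi2, qmc

from .data_model import ChoiceArrays, ChoiceDataset, CovariateMatrix, SchemaError

__all__ = [
    "ModelSpec",
    "ParameterSet",
    "DrawSet",
    "EstimationResult",
    "systematic_utility",
    "choice_probability",
    "simulated_loglik",
    "fit_mnl",
    "fit_mxl",
    "wald_test",
]

_EXP_CLIP = 60.0  # cap on log alpha_n; far outside any plausible estimate
_CHUNK_TARGET = 600_000  # elements per (chunk, draws, task*alt) work array; small enough to stay cache/allocator friendly


# ---------------------------------------------------------------------------
# specifications and parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """What to estimate and how.

    ``covariates`` are columns of the respondent table entering both the WTP
    means (through Lambda) and log money utility (through gamma); voting and
    region expand to baseline-omitted dummies.  ``structure`` controls the
    random-component covariance: "full" (free Cholesky, default),
    "diagonal" (independent random coefficients) or "none" (Omega = 0, the
    multinomial-logit special case).  ``independent_money`` zeroes the
    covariance between eta and the WTP block while keeping its variance.
    Cost never carries a WTP-space random coefficient: it is the numeraire.
    """

    covariates: tuple[str, ...] = ("log_distance", "age", "male", "city_size",
                                   "income", "education", "voting", "region")
    n_draws: int = 2000
    structure: str = "full"
    independent_money: bool = False
    gtol: float = 1e-5
    maxiter: int = 1000

    def __post_init__(self) -> None:
        if self.structure not in {"full", "diagonal", "none"}:
            raise ValueError(f"unknown covariance structure {self.structure!r}")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass
class ParameterSet:
    """A complete point in parameter space (estimated or true)."""

    coef_names: list[str]
    cov_names: list[str]
    mu: np.ndarray          # (K,) EUR
    lam: np.ndarray         # (K, p) EUR per covariate unit
    pi: float               # location of log marginal utility of money
    gamma: np.ndarray       # (p,)
    chol: np.ndarray        # (K+1, K+1) lower triangular, Omega = chol chol'

    def __post_init__(self) -> None:
        k, p = len(self.coef_names), len(self.cov_names)
        self.mu = np.asarray(self.mu, float).reshape(k)
        self.lam = np.asarray(self.lam, float).reshape(k, p)
        self.gamma = np.asarray(self.gamma, float).reshape(p)
        self.chol = np.asarray(self.chol, float).reshape(k + 1, k + 1)

    @property
    def omega(self) -> np.ndarray:
        return self.chol @ self.chol.T

    def to_dict(self) -> dict:
        return {"coef_names": list(self.coef_names),
                "cov_names": list(self.cov_names),
                "mu": self.mu.tolist(), "lam": self.lam.tolist(),
                "pi": float(self.pi), "gamma": self.gamma.tolist(),
                "chol": self.chol.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(list(d["coef_names"]), list(d["cov_names"]),
                   np.asarray(d["mu"]), np.asarray(d["lam"]), float(d["pi"]),
                   np.asarray(d["gamma"]), np.asarray(d["chol"]))


@dataclass
class _Layout:
    """Flat parameterization of the free parameters for the optimizer."""

    coef_names: list[str]
    cov_names: list[str]
    structure: str
    independent_money: bool

    def __post_init__(self) -> None:
        k = len(self.coef_names)
        d = k + 1
        if self.structure == "full":
            idx = [(a, b) for a in range(d) for b in range(a + 1)]
            if self.independent_money:
                idx = [(a, b) for a, b in idx if not (a == d - 1 and b < d - 1)]
        elif self.structure == "diagonal":
            idx = [(a, a) for a in range(d)]
        else:
            idx = []
        self.chol_idx = idx

    @property
    def k(self) -> int:
        return len(self.coef_names)

    @property
    def p(self) -> int:
        return len(self.cov_names)

    @property
    def n_params(self) -> int:
        return self.k + self.k * self.p + 1 + self.p + len(self.chol_idx)

    def names(self) -> list[str]:
        out = [f"mu[{c}]" for c in self.coef_names]
        out += [f"lam[{c}|{v}]" for c in self.coef_names for v in self.cov_names]
        out += ["pi"]
        out += [f"gamma[{v}]" for v in self.cov_names]
        out += [f"chol[{a},{b}]" for a, b in self.chol_idx]
        return out

    def scales(self) -> np.ndarray:
        """Characteristic magnitudes used to condition the optimizer:
        EUR-dimension parameters live on a ~25 EUR scale, the log-money
        block on a unit scale."""
        k = self.k
        s = [25.0] * k + [25.0] * (k * self.p) + [1.0] + [1.0] * self.p
        s += [25.0 if a < k else 1.0 for a, _ in self.chol_idx]
        return np.asarray(s)

    def pack(self, ps: ParameterSet) -> np.ndarray:
        parts = [ps.mu, ps.lam.ravel(), [ps.pi], ps.gamma,
                 [ps.chol[a, b] for a, b in self.chol_idx]]
        return np.concatenate([np.atleast_1d(np.asarray(p, float)) for p in parts])

    def unpack(self, theta: np.ndarray) -> ParameterSet:
        k, p = self.k, self.p
        i = 0
        mu = theta[i:i + k]; i += k
        lam = theta[i:i + k * p].reshape(k, p); i += k * p
        pi = float(theta[i]); i += 1
        gamma = theta[i:i + p]; i += p
        chol = np.zeros((k + 1, k + 1))
        for (a, b), v in zip(self.chol_idx, theta[i:]):
            chol[a, b] = v
        return ParameterSet(self.coef_names, self.cov_names, mu, lam, pi,
                            gamma, chol)


@dataclass
class DrawSet:
    """Per-respondent standard-normal deviates from a scrambled Sobol
    sequence.  Respondent n consumes rows [n*R, (n+1)*R) of the sequence;
    the block is generated once and held fixed across all objective
    evaluations of an estimation run."""

    u: np.ndarray            # (N, R, K+1)
    scramble_seed: int

    @property
    def n_draws(self) -> int:
        return self.u.shape[1]

    @property
    def dimension(self) -> int:
        return self.u.shape[2]

    @classmethod
    def generate(cls, n_respondents: int, dimension: int, n_draws: int,
                 scramble_seed: int) -> "DrawSet":
        total = n_respondents * n_draws
        m = max(1, int(np.ceil(np.log2(total))))
        sob = qmc.Sobol(d=dimension, scramble=True, seed=scramble_seed)
        pts = sob.random_base2(m)[:total]
        eps = np.finfo(float).tiny
        u = ndtri(np.clip(pts, eps, 1 - 1e-15))
        return cls(u.reshape(n_respondents, n_draws, dimension),
                   scramble_seed=scramble_seed)

    @classmethod
    def zeros(cls, n_respondents: int, dimension: int) -> "DrawSet":
        """Single all-zero draw: collapses the mixture to its mean (the
        multinomial-logit special case when Omega = 0)."""
        return cls(np.zeros((n_respondents, 1, dimension)), scramble_seed=0)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def systematic_utility(attributes: np.ndarray, cost: float,
                       beta: np.ndarray, alpha: float) -> float:
    """V = alpha * (beta' x - cost) for one alternative."""
    attributes = np.asarray(attributes, float)
    beta = np.asarray(beta, float)
    v = alpha * (attributes @ beta - cost)
    if not np.isfinite(v):
        raise FloatingPointError("non-finite systematic utility")
    return float(v)


def choice_probability(utilities: np.ndarray) -> np.ndarray:
    """Multinomial-logit (softmax) probabilities, overflow-safe."""
    v = np.asarray(utilities, float)
    if v.size == 0:
        raise ValueError("empty utility vector")
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("non-finite utilities")
    e = np.exp(v - v.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

@dataclass
class _ModelData:
    x: np.ndarray          # (N, T*A, K)
    cost: np.ndarray       # (N, T*A)
    chosen_flat: np.ndarray  # (N, T) indices into the flattened T*A axis
    xcov: np.ndarray       # (N, p)
    coef_names: list[str]
    cov_names: list[str]
    groups: dict[str, list[int]]
    n_tasks: int
    n_alts: int

    @property
    def n(self) -> int:
        return self.x.shape[0]


def _prepare(data: ChoiceDataset, covariates: CovariateMatrix | None,
             spec: ModelSpec) -> _ModelData:
    arrays: ChoiceArrays = data.to_arrays()
    n, T, A, k = arrays.x.shape
    # identification screen: an attribute constant within every task carries
    # no choice information
    for j, name in enumerate(arrays.coef_names):
        if np.ptp(arrays.x[..., j], axis=2).max() == 0:
            raise SchemaError(
                f"attribute {name!r} is constant across alternatives in every "
                "task; its coefficient is not identified")
    if np.ptp(arrays.cost, axis=2).max() == 0:
        raise SchemaError("cost is constant across alternatives in every task; "
                          "the money-utility scale is not identified")
    if covariates is not None and len(spec.covariates):
        covariates.check_matches(data)
        xcov, cov_names, groups = covariates.encode(list(spec.covariates))
    else:
        xcov = np.empty((n, 0))
        cov_names, groups = [], {}
    chosen_flat = arrays.chosen + np.arange(T)[None, :] * A
    return _ModelData(
        x=arrays.x.reshape(n, T * A, k),
        cost=arrays.cost.reshape(n, T * A),
        chosen_flat=chosen_flat,
        xcov=xcov, coef_names=arrays.coef_names, cov_names=cov_names,
        groups=groups, n_tasks=T, n_alts=A)


# ---------------------------------------------------------------------------
# simulated likelihood and analytic gradient
# ---------------------------------------------------------------------------

def _core(theta: np.ndarray, layout: _Layout, md: _ModelData, u: np.ndarray,
          want_grad: bool = True, per_respondent: bool = False):
    """Simulated log likelihood and its gradient.

    With ``per_respondent`` returns (loglik_n, scores) with scores (N, P);
    otherwise (loglik, grad).  The gradient is exact for the simulated
    objective (draws held fixed), including the Cholesky block.
    """
    ps = layout.unpack(theta)
    k, p = layout.k, layout.p
    n, TA, _ = md.x.shape
    T, A = md.n_tasks, md.n_alts
    R = u.shape[1]
    c_beta = ps.chol[:k, :k]           # zeta depends on the first k coords
    c_eta = ps.chol[k, :]              # eta on all k+1

    mean_beta = ps.mu[None, :] + md.xcov @ ps.lam.T       # (N, K)
    s0 = ps.pi + md.xcov @ ps.gamma                        # (N,)

    ll_n = np.empty(n)
    if want_grad:
        gmu = np.zeros(k)
        glam = np.zeros((k, p))
        gpi = 0.0
        ggam = np.zeros(p)
        gchol = np.zeros((k + 1, k + 1))
    if per_respondent:
        scores = np.empty((n, layout.n_params))

    chunk = max(1, int(_CHUNK_TARGET / max(1, R * TA)))
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        c = hi - lo
        uc = u[lo:hi]                                       # (c, R, K+1)
        zeta = uc[:, :, :k] @ c_beta.T                      # (c, R, K)
        eta = uc @ c_eta                                    # (c, R)
        beta = mean_beta[lo:hi, None, :] + zeta
        s = np.clip(s0[lo:hi, None] + eta, -_EXP_CLIP, _EXP_CLIP)
        a = np.exp(s)                                       # (c, R)
        net = np.matmul(beta, md.x[lo:hi].transpose(0, 2, 1))  # (c, R, TA)
        net -= md.cost[lo:hi, None, :]
        v = a[:, :, None] * net
        del net
        vt = v.reshape(c, R, T, A)
        vmax = vt.max(axis=3, keepdims=True)
        e = np.exp(vt - vmax)
        ssum = e.sum(axis=3)                                # (c, R, T)
        v_chosen = np.take_along_axis(
            v, md.chosen_flat[lo:hi, None, :], axis=2)      # (c, R, T)
        logp = (v_chosen - vmax[..., 0] - np.log(ssum)).sum(axis=2)  # (c, R)
        m = logp.max(axis=1, keepdims=True)
        w = np.exp(logp - m)
        wsum = w.sum(axis=1)
        ll_n[lo:hi] = m[:, 0] + np.log(wsum) - np.log(R)
        if not (want_grad or per_respondent):
            continue
        w = w / wsum[:, None]                               # (c, R) softmax

        prob = (e / ssum[..., None]).reshape(c, R, TA)
        # residual y - p on the flattened task*alt axis
        np.negative(prob, out=prob)
        resid = prob
        idx = md.chosen_flat[lo:hi, None, :]
        np.put_along_axis(resid, idx,
                          np.take_along_axis(resid, idx, axis=2) + 1.0, axis=2)
        g_beta = a[:, :, None] * np.matmul(resid, md.x[lo:hi])   # (c, R, K)
        g_s = np.einsum("nrx,nrx->nr", resid, v)                 # (c, R)
        del resid, v, e

        wb = np.einsum("nr,nrk->nk", w, g_beta)             # (c, K)
        ws = np.einsum("nr,nr->n", w, g_s)                  # (c,)
        gd = np.concatenate([g_beta, g_s[..., None]], axis=2)  # (c, R, K+1)
        gd *= w[:, :, None]
        if per_respondent:
            gc_n = np.einsum("nra,nrb->nab", gd, uc)        # (c, K+1, K+1)
            sc = np.empty((c, layout.n_params))
            i = 0
            sc[:, i:i + k] = wb; i += k
            sc[:, i:i + k * p] = (wb[:, :, None] * md.xcov[lo:hi, None, :]
                                  ).reshape(c, k * p); i += k * p
            sc[:, i] = ws; i += 1
            sc[:, i:i + p] = ws[:, None] * md.xcov[lo:hi]; i += p
            for j, (ai, bi) in enumerate(layout.chol_idx):
                sc[:, i + j] = gc_n[:, ai, bi]
            scores[lo:hi] = sc
            if want_grad:
                gc = gc_n.sum(axis=0)
        elif want_grad:
            gc = np.tensordot(gd, uc, axes=([0, 1], [0, 1]))  # (K+1, K+1)
        if want_grad:
            gmu += wb.sum(axis=0)
            glam += wb.T @ md.xcov[lo:hi]
            gpi += ws.sum()
            ggam += ws @ md.xcov[lo:hi]
            gchol += gc

    if per_respondent:
        return ll_n, scores
    ll = float(ll_n.sum())
    if not want_grad:
        return ll, None
    grad = np.concatenate([
        gmu, glam.ravel(), [gpi], ggam,
        [gchol[a, b] for a, b in layout.chol_idx]])
    return ll, grad


def simulated_loglik(
    params: ParameterSet,
    data: ChoiceDataset,
    covariates: CovariateMatrix | None,
    draws: DrawSet,
    structure: str = "full",
    independent_money: bool = False,
) -> tuple[float, np.ndarray]:
    """Simulated log likelihood at ``params`` and its gradient with respect
    to the flat free-parameter vector implied by ``structure``."""
    base_cols: list[str] = []
    for name in params.cov_names:
        col = name.split("[", 1)[0] if name.startswith(("voting[", "region[")) \
            else name
        if col not in base_cols:
            base_cols.append(col)
    spec = ModelSpec(covariates=tuple(base_cols), n_draws=draws.n_draws,
                     structure=structure, independent_money=independent_money)
    md = _prepare(data, covariates, spec)
    if md.cov_names != list(params.cov_names):
        raise ValueError(
            f"covariate encoding mismatch: data gives {md.cov_names}, "
            f"params expect {list(params.cov_names)}")
    layout = _Layout(md.coef_names, md.cov_names, structure, independent_money)
    if draws.dimension != layout.k + 1:
        raise ValueError(
            f"draws have dimension {draws.dimension}, need {layout.k + 1}")
    theta = layout.pack(params)
    ll, grad = _core(theta, layout, md, draws.u)
    return ll, grad


# ---------------------------------------------------------------------------
# estimation results
# ---------------------------------------------------------------------------

@dataclass
class EstimationResult:
    """Converged parameters plus everything needed for inference and
    reproduction."""

    params: ParameterSet
    param_names: list[str]
    theta: np.ndarray
    loglik: float
    grad_norm: float
    converged: bool
    n_draws: int
    seed: int | None
    structure: str
    n_respondents: int
    n_iter: int
    message: str = ""
    vcov_hessian: np.ndarray | None = None
    vcov_sandwich: np.ndarray | None = None
    groups: dict[str, list[int]] = field(default_factory=dict)
    baseline_party: str | None = None
    baseline_region: str | None = None

    def index(self, name: str) -> int:
        return self.param_names.index(name)

    def vcov(self, kind: str = "sandwich") -> np.ndarray:
        v = self.vcov_sandwich if kind == "sandwich" else self.vcov_hessian
        if v is None:
            v = self.vcov_hessian if self.vcov_hessian is not None else self.vcov_sandwich
        if v is None:
            raise ValueError("no variance matrix was computed for this result")
        return v

    def se(self, kind: str = "sandwich") -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov(kind)), 0, None))

    def to_dict(self) -> dict:
        d = {
            "params": self.params.to_dict(),
            "param_names": list(self.param_names),
            "theta": self.theta.tolist(),
            "loglik": float(self.loglik),
            "grad_norm": float(self.grad_norm),
            "converged": bool(self.converged),
            "n_draws": int(self.n_draws),
            "seed": None if self.seed is None else int(self.seed),
            "structure": self.structure,
            "n_respondents": int(self.n_respondents),
            "n_iter": int(self.n_iter),
            "message": self.message,
            "groups": {g: list(ix) for g, ix in self.groups.items()},
            "baseline_party": self.baseline_party,
            "baseline_region": self.baseline_region,
        }
        for key in ("vcov_hessian", "vcov_sandwich"):
            v = getattr(self, key)
            d[key] = None if v is None else np.asarray(v).tolist()
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "EstimationResult":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            params=ParameterSet.from_dict(d["params"]),
            param_names=list(d["param_names"]),
            theta=np.asarray(d["theta"]),
            loglik=float(d["loglik"]), grad_norm=float(d["grad_norm"]),
            converged=bool(d["converged"]), n_draws=int(d["n_draws"]),
            seed=d["seed"], structure=d["structure"],
            n_respondents=int(d["n_respondents"]), n_iter=int(d["n_iter"]),
            message=d.get("message", ""),
            vcov_hessian=None if d["vcov_hessian"] is None else np.asarray(d["vcov_hessian"]),
            vcov_sandwich=None if d["vcov_sandwich"] is None else np.asarray(d["vcov_sandwich"]),
            groups={g: list(ix) for g, ix in d.get("groups", {}).items()},
            baseline_party=d.get("baseline_party"),
            baseline_region=d.get("baseline_region"),
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _mnl_preference_space(md: _ModelData) -> tuple[np.ndarray, float]:
    """Preference-space MNL (pooled, no covariates) used for starting
    values: V = b'x - exp(c) cost.  The cost coefficient is parameterized
    on the log scale because the WTP-space model requires a positive
    marginal utility of money; data with no (or perverse) cost signal push
    exp(c) toward the zero boundary instead of leaving the model's
    parameter space.  Returns (b, exp(c))."""
    n, TA, k = md.x.shape
    T, A = md.n_tasks, md.n_alts

    def nll(par):
        b, c = par[:-1], par[-1]
        bc = np.exp(np.clip(c, -_EXP_CLIP, _EXP_CLIP))
        v = (md.x @ b - bc * md.cost).reshape(n, T, A)
        vmax = v.max(axis=2, keepdims=True)
        e = np.exp(v - vmax)
        ssum = e.sum(axis=2)
        vch = np.take_along_axis(
            v.reshape(n, TA), md.chosen_flat, axis=1)
        ll = (vch - vmax[..., 0] - np.log(ssum)).sum()
        prob = (e / ssum[..., None]).reshape(n, TA)
        np.negative(prob, out=prob)
        np.put_along_axis(prob, md.chosen_flat,
                          np.take_along_axis(prob, md.chosen_flat, axis=1) + 1.0,
                          axis=1)
        grad_b = np.einsum("nx,nxk->k", prob, md.x)
        grad_c = -bc * float(np.einsum("nx,nx->", prob, md.cost))
        return -ll, -np.concatenate([grad_b, [grad_c]])

    x0 = np.zeros(k + 1)
    x0[-1] = np.log(0.01)
    res = optimize.minimize(nll, x0, jac=True, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 500})
    b, bc = res.x[:-1], float(np.exp(res.x[-1]))
    if bc < 1e-8:
        warnings.warn(
            "marginal utility of money is at the zero boundary; the cost "
            "attribute carries essentially no signal in these choices")
    return b, bc


def _optimize(theta0: np.ndarray, layout: _Layout, md: _ModelData,
              u: np.ndarray, gtol: float, maxiter: int):
    scale = layout.scales()

    def fun(y):
        ll, grad = _core(y * scale, layout, md, u)
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(y)
        return -ll, -grad * scale

    res = optimize.minimize(
        fun, theta0 / scale, jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-11,
                 "maxcor": 30})
    theta = res.x * scale
    ll, grad = _core(theta, layout, md, u)
    return theta, ll, grad, res


def _hessian(theta: np.ndarray, layout: _Layout, md: _ModelData,
             u: np.ndarray) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    P = len(theta)
    H = np.empty((P, P))
    for i in range(P):
        h = 1e-4 * (1.0 + abs(theta[i]))
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        _, gp = _core(tp, layout, md, u)
        _, gm = _core(tm, layout, md, u)
        H[i] = (gp - gm) / (2 * h)
    return (H + H.T) / 2


def _vcovs(theta, layout, md, u):
    H = _hessian(theta, layout, md, u)
    neg_h = -H
    try:
        v_hess = np.linalg.inv(neg_h)
    except np.linalg.LinAlgError:
        warnings.warn("singular Hessian; using pseudo-inverse")
        v_hess = np.linalg.pinv(neg_h)
    _, scores = _core(theta, layout, md, u, want_grad=False, per_respondent=True)
    bread = v_hess
    meat = scores.T @ scores
    v_sand = bread @ meat @ bread
    return v_hess, (v_sand + v_sand.T) / 2


def _build_result(theta, layout, md, ll, grad, res, spec, seed, cov,
                  compute_vcov, u) -> EstimationResult:
    v_hess = v_sand = None
    if compute_vcov:
        v_hess, v_sand = _vcovs(theta, layout, md, u)
    return EstimationResult(
        params=layout.unpack(theta),
        param_names=layout.names(),
        theta=theta,
        loglik=ll,
        grad_norm=float(np.abs(grad).max()),
        converged=bool(res.success),
        n_draws=u.shape[1],
        seed=seed,
        structure=layout.structure,
        n_respondents=md.n,
        n_iter=int(res.nit),
        message=str(res.message),
        vcov_hessian=v_hess,
        vcov_sandwich=v_sand,
        groups=md.groups,
        baseline_party=None if cov is None else cov.baseline_party,
        baseline_region=None if cov is None else cov.baseline_region,
    )


def fit_mnl(
    data: ChoiceDataset,
    covariates: CovariateMatrix | None = None,
    spec: ModelSpec | None = None,
    compute_vcov: bool = True,
) -> EstimationResult:
    """Multinomial logit in WTP space: the Omega = 0 special case.

    Fitted in two stages: a concave pooled preference-space logit pins down
    (mu, pi) starting values exactly up to reparameterization; a quasi-Newton
    pass then adds the covariate shifts (Lambda, gamma) if requested.
    """
    spec = spec if spec is not None else ModelSpec(covariates=())
    spec = replace(spec, structure="none")
    md = _prepare(data, covariates, spec)
    b, bc = _mnl_preference_space(md)
    layout = _Layout(md.coef_names, md.cov_names, "none", False)
    k, p = layout.k, layout.p
    ps0 = ParameterSet(md.coef_names, md.cov_names, b / bc, np.zeros((k, p)),
                       float(np.log(bc)), np.zeros(p),
                       np.zeros((k + 1, k + 1)))
    theta0 = layout.pack(ps0)
    u = DrawSet.zeros(md.n, k + 1).u
    theta, ll, grad, res = _optimize(theta0, layout, md, u, spec.gtol,
                                     spec.maxiter)
    return _build_result(theta, layout, md, ll, grad, res, spec, None,
                         covariates, compute_vcov, u)


def fit_mxl(
    data: ChoiceDataset,
    covariates: CovariateMatrix | None,
    spec: ModelSpec,
    seed: int,
    compute_vcov: bool = True,
    start: ParameterSet | None = None,
) -> EstimationResult:
    """Maximum simulated likelihood fit of the WTP-space mixed logit.

    Draws are scrambled Sobol, fixed for the whole run and seeded by
    ``seed``; starting values come from :func:`fit_mnl` with the Cholesky
    factor initialized to a small positive diagonal.
    """
    md = _prepare(data, covariates, spec)
    layout = _Layout(md.coef_names, md.cov_names, spec.structure,
                     spec.independent_money)
    k = layout.k
    if start is None:
        mnl = fit_mnl(data, covariates,
                      ModelSpec(covariates=spec.covariates, gtol=spec.gtol),
                      compute_vcov=False)
        chol0 = np.zeros((k + 1, k + 1))
        if spec.structure != "none":
            d0 = 0.25 * (np.abs(mnl.params.mu) + 5.0)
            chol0[:k, :k] = np.diag(d0)
            chol0[k, k] = 0.3
        start = ParameterSet(md.coef_names, md.cov_names, mnl.params.mu,
                             mnl.params.lam, mnl.params.pi, mnl.params.gamma,
                             chol0)
    theta0 = layout.pack(start)
    if spec.structure == "none":
        draws = DrawSet.zeros(md.n, k + 1)
    else:
        draws = DrawSet.generate(md.n, k + 1, spec.n_draws, seed)
    theta, ll, grad, res = _optimize(theta0, layout, md, draws.u, spec.gtol,
                                     spec.maxiter)
    out = _build_result(theta, layout, md, ll, grad, res, spec, seed,
                        covariates, compute_vcov, draws.u)
    if not out.converged:
        warnings.warn(f"MSL optimizer did not report convergence: {out.message}")
    return out


def wald_test(
    result: EstimationResult,
    coefficient_subset: Sequence[int] | Sequence[str],
    kind: str = "sandwich",
) -> tuple[float, int, float]:
    """Joint zero-restriction Wald test on a block of estimated parameters.

    Returns (statistic, degrees of freedom, p-value) from the chi-square
    reference distribution, using the respondent-clustered sandwich variance
    by default.
    """
    idx = [result.index(c) if isinstance(c, str) else int(c)
           for c in coefficient_subset]
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate entries in coefficient subset")
    est = result.theta[idx]
    sub = result.vcov(kind)[np.ix_(idx, idx)]
    try:
        sol = np.linalg.solve(sub, est)
    except np.linalg.LinAlgError:
        warnings.warn("singular sub-variance matrix in Wald test; "
                      "using pseudo-inverse")
        sol = np.linalg.pinv(sub) @ est
    stat = float(est @ sol)
    df = len(idx)
    return stat, df, float(chi2.sf(stat, df))
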