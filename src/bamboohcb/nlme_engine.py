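"""Two-level nonlinear mixed-effects estimation for HCB models.

The model for culm k in plot j of block i is

    hcb_ijk = g(h_ijk, x_ijk) + xi_ijk,
    x_ijk   = sum_t (beta_t + u_t,i + u_t,ij) * cov_t,ijk,

where g is a shape-parameter-free form link (the logistic h/(1+exp(x))
in practice), block-level effects u_i ~ N(0, Psi_b) are jointly normal
across the parameters they perturb, plot-level effects u_ij ~ N(0,
Psi_p) are independent of them, and residuals are independent
heteroscedastic normals Var(xi) = sigma^2 * w(h)^2 with w a variance
function of total height (within-plot correlation fixed to identity).

Estimation follows the alternating scheme of Lindstrom & Bates:

  (a) penalized nonlinear least squares in (beta, u) given the variance
      parameters — conditional modes of the random effects fall out as a
      by-product;
  (b) a linear mixed-effects step on the first-order expansion of the
      model about the current (beta, u), updating Psi_b, Psi_p, sigma^2
      and the variance-function parameters by maximum likelihood.

The LME-step likelihood profiles beta and sigma^2 analytically and
optimizes only the relative log-Cholesky-parametrized covariances and
the variance-function parameters; per-block covariance algebra uses the
Woodbury identity, so one likelihood evaluation is O(n * q^2) with q the
number of random effects per block (~10 for the bamboo design).  The
reported log-likelihood is the linearization-based marginal ML
log-likelihood, the lineage of estimate that R's nlme produces.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import least_squares, minimize

from .model_forms import FitStatistics, ModelForm, design_matrix, fit_ols, fit_statistics
from .stand_data import Dataset, dataset_to_frame

__all__ = [
    "RandomEffectsSpec",
    "VarianceFunction",
    "ResidualModel",
    "NlmeFit",
    "fit_nlme",
    "marginal_loglik",
    "select_random_effects_structure",
    "compare_variance_functions",
]

_LEVELS = ("block", "plot")
_LOGDIAG_LB = -13.0  # lower bound on relative log-Cholesky diagonals (variance floor)
_BOUNDARY_LOGDIAG = -9.0


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Placement of random effects: term name -> subset of {block, plot}.

    The structure selected for the bamboo model is
    ``{"1": {"block"}, "dbh": {"block", "plot"}}`` — a block-level
    intercept perturbation and a DBH-slope perturbation at both levels.
    """

    placements: Mapping[str, frozenset]

    def __init__(self, placements: Mapping[str, Iterable[str]]):
        norm = {}
        for name, levels in placements.items():
            levels = frozenset(levels)
            if not levels or not levels <= set(_LEVELS):
                raise ValueError(f"invalid levels {set(levels)} for parameter {name!r}")
            norm[name] = levels
        if not norm:
            raise ValueError("at least one random-effect placement required")
        object.__setattr__(self, "placements", norm)

    def params_at(self, level: str, form: ModelForm) -> tuple[str, ...]:
        """Terms carrying a random effect at ``level``, in term order."""
        missing = set(self.placements) - set(form.terms)
        if missing:
            raise ValueError(f"random-effect parameters {sorted(missing)} not in form terms")
        return tuple(t for t in form.terms if level in self.placements.get(t, ()))

    def describe(self) -> str:
        return "; ".join(f"{t}->{'+'.join(sorted(ls))}" for t, ls in self.placements.items())


DEFAULT_RE_STRUCTURE = RandomEffectsSpec({"1": {"block"}, "dbh": {"block", "plot"}})


@dataclass
class VarianceFunction:
    """Residual variance as a function of total height h.

    kind            Var(xi) / sigma^2          free params
    none            1                           -
    exponential     exp(2 * gamma * h)          gamma
    power           h^(2 * gamma)               gamma
    constant_power  (gamma1 + h^gamma2)^2       gamma1, gamma2
    """

    kind: str = "none"
    params: tuple[float, ...] = ()
    covariate: str = "h"

    _N_PARAMS = {"none": 0, "exponential": 1, "power": 1, "constant_power": 2}
    _STARTS = {"none": (), "exponential": (0.0,), "power": (0.0,), "constant_power": (1.0, 0.5)}

    def __post_init__(self) -> None:
        if self.kind not in self._N_PARAMS:
            raise ValueError(f"unknown variance-function kind {self.kind!r}")
        if not self.params:
            self.params = self._STARTS[self.kind]
        self.params = tuple(float(p) for p in self.params)
        if len(self.params) != self._N_PARAMS[self.kind]:
            raise ValueError(f"{self.kind} needs {self._N_PARAMS[self.kind]} params")

    @property
    def n_free(self) -> int:
        return self._N_PARAMS[self.kind]

    def weights(self, h: np.ndarray, params: Optional[Sequence[float]] = None) -> np.ndarray:
        """Standard-deviation multiplier w(h) > 0 (Var = sigma^2 w^2)."""
        p = self.params if params is None else tuple(params)
        if self.kind == "none":
            return np.ones_like(h)
        if self.kind == "exponential":
            return np.exp(np.clip(p[0] * h, -40.0, 40.0))
        if self.kind == "power":
            return np.exp(np.clip(p[0] * np.log(h), -40.0, 40.0))
        w = np.abs(p[0] + np.exp(np.clip(p[1] * np.log(h), -40.0, 40.0)))
        return w

    @classmethod
    def none(cls) -> "VarianceFunction":
        return cls("none")

    @classmethod
    def exponential(cls, gamma: float = 0.0) -> "VarianceFunction":
        return cls("exponential", (gamma,))

    @classmethod
    def power(cls, gamma: float = 0.0) -> "VarianceFunction":
        return cls("power", (gamma,))

    @classmethod
    def constant_power(cls, gamma1: float = 1.0, gamma2: float = 0.5) -> "VarianceFunction":
        return cls("constant_power", (gamma1, gamma2))


@dataclass
class ResidualModel:
    """Residual scale variance plus variance function (identity correlation)."""

    sigma2: float
    varfun: VarianceFunction

    def sd(self, h: np.ndarray) -> np.ndarray:
        return math.sqrt(self.sigma2) * self.varfun.weights(np.asarray(h, dtype=float))


# ---------------------------------------------------------------------------
# internal data layout


class _ModelData:
    """Arrays sorted by (block, plot) with grouping indices."""

    def __init__(self, ds: Dataset | pd.DataFrame, form: ModelForm, re_spec: RandomEffectsSpec):
        if form.has_shape:
            raise NotImplementedError(
                f"the mixed-effects engine supports shape-free forms only, not {form.designation}"
            )
        df = dataset_to_frame(ds) if isinstance(ds, Dataset) else ds.copy()
        df = df[df["hcb"].notna()].reset_index(drop=True)
        if df.empty:
            raise ValueError("no culms with observed hcb")
        df["_plotkey"] = df["block"].astype(str) + "\x1f" + df["plot"].astype(str)
        df = df.sort_values(["block", "_plotkey"], kind="stable").reset_index(drop=True)

        self.form = form
        self.re_spec = re_spec
        self.df = df
        self.y = df["hcb"].to_numpy(dtype=float)
        self.h = df["h"].to_numpy(dtype=float)
        self.X = design_matrix(form, df)
        self.n = len(df)

        self.blocks = list(dict.fromkeys(df["block"]))
        self.plots = list(dict.fromkeys(df["_plotkey"]))
        bcode = {b: i for i, b in enumerate(self.blocks)}
        pcode = {p: j for j, p in enumerate(self.plots)}
        self.block_codes = df["block"].map(bcode).to_numpy()
        self.plot_codes = df["_plotkey"].map(pcode).to_numpy()
        self.n_blocks = len(self.blocks)
        self.n_plots = len(self.plots)
        self.plot_block = np.array([bcode[p.split("\x1f")[0]] for p in self.plots])
        self.plot_ids = [p.split("\x1f")[1] for p in self.plots]

        # contiguous slices (data sorted)
        self.block_slices = [np.flatnonzero(self.block_codes == i) for i in range(self.n_blocks)]
        self.plot_slices = [np.flatnonzero(self.plot_codes == j) for j in range(self.n_plots)]
        self.block_plots = [np.flatnonzero(self.plot_block == i) for i in range(self.n_blocks)]

        bp = re_spec.params_at("block", form)
        pp = re_spec.params_at("plot", form)
        self.block_terms, self.plot_terms = bp, pp
        self.qb, self.qp = len(bp), len(pp)
        tcol = {t: k for k, t in enumerate(form.terms)}
        self.Xb = self.X[:, [tcol[t] for t in bp]] if bp else np.zeros((self.n, 0))
        self.Xp = self.X[:, [tcol[t] for t in pp]] if pp else np.zeros((self.n, 0))

    def linear_predictor(self, beta, ub, up):
        x = self.X @ beta
        if self.qb:
            x = x + np.sum(self.Xb * ub[self.block_codes], axis=1)
        if self.qp:
            x = x + np.sum(self.Xp * up[self.plot_codes], axis=1)
        return x


# --- log-Cholesky packing ---------------------------------------------------


def _n_chol(q: int) -> int:
    return q * (q + 1) // 2


def _unpack_chol(theta: np.ndarray, q: int) -> np.ndarray:
    """Lower-triangular factor from log-Cholesky parameters."""
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            L[i, j] = math.exp(theta[k]) if i == j else theta[k]
            k += 1
    return L

def _pack_chol(L: np.ndarray) -> np.ndarray:
    q = L.shape[0]
    out = []
    for i in range(q):
        for j in range(i + 1):
            out.append(math.log(max(L[i, i], 1e-12)) if i == j else L[i, j])
    return np.array(out)


def _psi_chol(psi: np.ndarray) -> np.ndarray:
    q = psi.shape[0]
    if q == 0:
        return np.zeros((0, 0))
    jitter = 1e-12 * max(np.trace(psi) / q, 1e-12)
    return np.linalg.cholesky(psi + jitter * np.eye(q))


# ---------------------------------------------------------------------------
# profiled marginal log-likelihood of the linearized model


def _lme_profiled(theta, md: _ModelData, w_resp, Xt, Zbt, Zpt, return_full=False):
    """Profiled ML log-likelihood of w ~ N(Xt b, s2 [W + Z D Z']).

    theta packs [logchol(Db), logchol(Dp), varfun params] with D the
    covariances relative to sigma^2 and W = diag(varfun weights^2).
    Returns -ll (for minimization) or, with ``return_full``, the tuple
    (ll, beta_hat, sigma2_hat, psi_b, psi_p, varfun_params).
    """
    qb, qp = md.qb, md.qp
    nb, np_ = _n_chol(qb), _n_chol(qp)
    Lb = _unpack_chol(theta[:nb], qb)
    Lp = _unpack_chol(theta[nb:nb + np_], qp)
    vf_params = tuple(theta[nb + np_:])
    w = _vf_weights(md, vf_params)
    if w is None:
        # finite penalty keeps finite-difference gradients usable
        return (1e12 if not return_full else (-np.inf, None, None, None, None, vf_params))
    w2 = w * w

    p = Xt.shape[1]
    XtMX = np.zeros((p, p))
    XtMw = np.zeros(p)
    wMw = 0.0
    logdet = 0.0
    for i in range(md.n_blocks):
        rows = md.block_slices[i]
        ni = rows.size
        ki = qb + md.block_plots[i].size * qp
        A = np.zeros((ni, ki))
        if qb:
            A[:, :qb] = Zbt[rows] @ Lb
        if qp:
            # map plot code -> local column group within this block
            local = {pj: c for c, pj in enumerate(md.block_plots[i])}
            pc = md.plot_codes[rows]
            for pj, c in local.items():
                sel = pc == pj
                A[sel, qb + c * qp: qb + (c + 1) * qp] = Zpt[rows][sel] @ Lp
        wv = w2[rows]
        B = np.column_stack([Xt[rows], w_resp[rows]])
        Bw = B / wv[:, None]
        logdet += float(np.sum(np.log(wv)))
        if ki:
            Aw = A / wv[:, None]
            S = np.eye(ki) + A.T @ Aw
            cS, lower = cho_factor(S, lower=True)
            logdet += 2.0 * float(np.sum(np.log(np.diag(cS))))
            AtB = A.T @ Bw
            Bw = Bw - Aw @ cho_solve((cS, lower), AtB)
        G = B.T @ Bw  # (p+1) x (p+1): [X'M⁻¹X, X'M⁻¹w; ., w'M⁻¹w]
        XtMX += G[:p, :p]
        XtMw += G[:p, p]
        wMw += G[p, p]

    try:
        cX = cho_factor(XtMX + 1e-10 * np.eye(p))
        beta = cho_solve(cX, XtMw)
    except np.linalg.LinAlgError:
        return 1e12 if not return_full else (-np.inf, None, None, None, None, vf_params)
    rss = wMw - 2.0 * beta @ XtMw + beta @ XtMX @ beta
    rss = max(rss, 1e-300)
    n = md.n
    sigma2 = rss / n
    ll = -0.5 * (n * (math.log(2 * math.pi) + 1.0 + math.log(sigma2)) + logdet)
    if not return_full:
        return -ll
    psi_b = sigma2 * (Lb @ Lb.T)
    psi_p = sigma2 * (Lp @ Lp.T)
    return ll, beta, sigma2, psi_b, psi_p, vf_params


def _vf_weights(md: _ModelData, vf_params):
    w = md.varfun.weights(md.h, vf_params) if vf_params or md.varfun.kind != "none" \
        else np.ones_like(md.h)
    if not np.all(np.isfinite(w)) or np.any(w < 1e-8):
        return None
    return w


# ---------------------------------------------------------------------------
# penalized nonlinear least squares (conditional step)


def _pnls(md: _ModelData, beta0, ub0, up0, Lb, Lp, vf_weights, max_nfev=400):
    """Minimize sum((y-f)^2/w^2) + u' D^-1 u over (beta, u); returns modes."""
    p = md.X.shape[1]
    qb, qp = md.qb, md.qp
    nB, nP = md.n_blocks, md.n_plots
    n = md.n
    inv_w = 1.0 / vf_weights

    # penalty factors: rows Lb^-1 u_i (whitened effects)
    Lb_inv = solve_triangular(Lb, np.eye(qb), lower=True) if qb else np.zeros((0, 0))
    Lp_inv = solve_triangular(Lp, np.eye(qp), lower=True) if qp else np.zeros((0, 0))

    def split(z):
        beta = z[:p]
        ub = z[p:p + nB * qb].reshape(nB, qb) if qb else np.zeros((nB, 0))
        up = z[p + nB * qb:].reshape(nP, qp) if qp else np.zeros((nP, 0))
        return beta, ub, up

    def resid(z):
        beta, ub, up = split(z)
        x = md.linear_predictor(beta, ub, up)
        r = (md.y - md.form.value(md.h, x)) * inv_w
        pen = []
        if qb:
            pen.append((ub @ Lb_inv.T).ravel())
        if qp:
            pen.append((up @ Lp_inv.T).ravel())
        return np.concatenate([r] + pen) if pen else r

    def jac(z):
        beta, ub, up = split(z)
        x = md.linear_predictor(beta, ub, up)
        dv = md.form.dvalue_dx(md.h, x) * inv_w  # d(resid)/dx = -dv
        m = n + nB * qb + nP * qp
        J = np.zeros((m, z.size))
        J[:n, :p] = -dv[:, None] * md.X
        rows = np.arange(n)
        for t in range(qb):
            J[rows, p + md.block_codes * qb + t] = -dv * md.Xb[:, t]
        off = p + nB * qb
        for t in range(qp):
            J[rows, off + md.plot_codes * qp + t] = -dv * md.Xp[:, t]
        r0 = n
        for i in range(nB):
            J[r0 + i * qb: r0 + (i + 1) * qb, p + i * qb: p + (i + 1) * qb] = Lb_inv
        r0 = n + nB * qb
        for j in range(nP):
            J[r0 + j * qp: r0 + (j + 1) * qp, off + j * qp: off + (j + 1) * qp] = Lp_inv
        return J

    z0 = np.concatenate([beta0, ub0.ravel(), up0.ravel()])
    sol = least_squares(resid, z0, jac=jac, method="trf", max_nfev=max_nfev,
                        xtol=1e-10, ftol=1e-10, gtol=1e-10)
    beta, ub, up = split(sol.x)
    return beta, ub, up, sol


# ---------------------------------------------------------------------------
# public fit containers


@dataclass
class NlmeFit:
    """A converged (or boundary) two-level NLME fit."""

    form: ModelForm
    re_spec: RandomEffectsSpec
    beta: np.ndarray
    psi_block: np.ndarray
    psi_plot: np.ndarray
    residual: ResidualModel
    ll: float
    aic: float
    converged: bool
    boundary: bool
    n_obs: int
    n_blocks: int
    n_plots: int
    n_outer: int
    u_block: dict[str, np.ndarray] = field(default_factory=dict)
    u_plot: dict[str, np.ndarray] = field(default_factory=dict)
    stats: Optional[FitStatistics] = None

    @property
    def block_terms(self) -> tuple[str, ...]:
        return self.re_spec.params_at("block", self.form)

    @property
    def plot_terms(self) -> tuple[str, ...]:
        return self.re_spec.params_at("plot", self.form)

    @property
    def var_plot(self) -> float:
        return float(self.psi_plot[0, 0]) if self.psi_plot.size else 0.0

    @property
    def sigma2(self) -> float:
        return self.residual.sigma2

    @property
    def n_varcov_params(self) -> int:
        # covariance entries + sigma^2 + variance-function params
        return _n_chol(self.psi_block.shape[0]) + _n_chol(self.psi_plot.shape[0]) \
            + 1 + self.residual.varfun.n_free

    def to_dict(self) -> dict:
        return {
            "form": {"designation": self.form.designation,
                     "terms": list(self.form.terms),
                     "beta": [float(b) for b in self.beta]},
            "random_effects": {t: sorted(ls) for t, ls in self.re_spec.placements.items()},
            "psi_block": self.psi_block.tolist(),
            "psi_plot": self.psi_plot.tolist(),
            "sigma2": self.residual.sigma2,
            "variance_function": {"kind": self.residual.varfun.kind,
                                  "params": list(self.residual.varfun.params)},
            "ll": self.ll, "aic": self.aic,
            "converged": bool(self.converged), "boundary": bool(self.boundary),
            "n_obs": self.n_obs, "n_blocks": self.n_blocks, "n_plots": self.n_plots,
            "n_outer": self.n_outer,
            "u_block": {k: v.tolist() for k, v in self.u_block.items()},
            "u_plot": {k: v.tolist() for k, v in self.u_plot.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: Mapping) -> "NlmeFit":
        form = ModelForm(d["form"]["designation"], tuple(d["form"]["terms"]),
                         np.asarray(d["form"]["beta"], dtype=float))
        varfun = VarianceFunction(d["variance_function"]["kind"],
                                  tuple(d["variance_function"]["params"]))
        return cls(
            form=form,
            re_spec=RandomEffectsSpec({t: set(ls) for t, ls in d["random_effects"].items()}),
            beta=np.asarray(d["form"]["beta"], dtype=float),
            psi_block=np.asarray(d["psi_block"], dtype=float),
            psi_plot=np.asarray(d["psi_plot"], dtype=float),
            residual=ResidualModel(sigma2=float(d["sigma2"]), varfun=varfun),
            ll=float(d["ll"]), aic=float(d["aic"]),
            converged=bool(d["converged"]), boundary=bool(d["boundary"]),
            n_obs=int(d["n_obs"]), n_blocks=int(d["n_blocks"]), n_plots=int(d["n_plots"]),
            n_outer=int(d["n_outer"]),
            u_block={k: np.asarray(v, dtype=float) for k, v in d["u_block"].items()},
            u_plot={k: np.asarray(v, dtype=float) for k, v in d["u_plot"].items()},
        )

    @classmethod
    def from_json(cls, path) -> "NlmeFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def summary(self) -> str:
        lines = [
            f"Two-level NLME fit: {self.form.designation} on terms {self.form.terms}",
            f"  observations: {self.n_obs}  blocks: {self.n_blocks}  plots: {self.n_plots}",
            f"  random effects: {self.re_spec.describe()}",
            "  fixed effects: " + ", ".join(
                f"{t}={b:.5g}" for t, b in zip(self.form.terms, self.beta)),
            f"  Psi_block:\n{np.array2string(self.psi_block, precision=4)}",
            f"  Psi_plot:\n{np.array2string(self.psi_plot, precision=4)}",
            f"  sigma2: {self.residual.sigma2:.5g}  variance function: "
            f"{self.residual.varfun.kind} {self.residual.varfun.params}",
            f"  logLik: {self.ll:.2f}  AIC: {self.aic:.2f}  converged: {self.converged}"
            + ("  (boundary)" if self.boundary else ""),
        ]
        return "\n".join(lines)


class NlmeConvergenceError(RuntimeError):
    """Raised when the alternating algorithm fails to make progress."""


# ---------------------------------------------------------------------------
# main driver


def fit_nlme(
    ds: Dataset | pd.DataFrame,
    form: ModelForm,
    re_spec: RandomEffectsSpec = DEFAULT_RE_STRUCTURE,
    varfun: Optional[VarianceFunction] = None,
    start: Optional[np.ndarray] = None,
    max_outer: int = 200,
    tol: float = 1e-6,
) -> NlmeFit:
    """Fit the two-level NLME model by the alternating ML scheme.

    ``start`` optionally provides fixed-effect starting values; by
    default an ordinary nonlinear least-squares fit supplies them.
    Returns an :class:`NlmeFit` with conditional modes of the random
    effects, the linearized marginal log-likelihood and AIC.
    """
    varfun = varfun or VarianceFunction.none()
    md = _ModelData(ds, form, re_spec)
    md.varfun = varfun

    # starting values
    if start is None:
        ols = fit_ols(md.df, replace(form, beta=None))
        beta = ols.form.beta.copy()
    else:
        beta = np.asarray(start, dtype=float).copy()
    ub = np.zeros((md.n_blocks, md.qb))
    up = np.zeros((md.n_plots, md.qp))

    nb, np_ = _n_chol(md.qb), _n_chol(md.qp)
    theta = np.concatenate([
        _pack_chol(np.exp(-2.0) * np.eye(md.qb)),
        _pack_chol(np.exp(-2.0) * np.eye(md.qp)),
        np.asarray(varfun._STARTS[varfun.kind], dtype=float),
    ]) if (nb + np_ + varfun.n_free) else np.zeros(0)

    bounds = []
    k = 0
    for q in (md.qb, md.qp):
        for i in range(q):
            for j in range(i + 1):
                bounds.append((_LOGDIAG_LB, 8.0) if i == j else (-60.0, 60.0))
                k += 1
    vf_bounds = {"none": [], "exponential": [(-1.5, 1.5)], "power": [(-8.0, 8.0)],
                 "constant_power": [(-50.0, 50.0), (-8.0, 8.0)]}
    bounds += vf_bounds[varfun.kind]

    prev = None
    converged = False
    ll = -np.inf
    est = None
    sol_info = None
    for outer in range(1, max_outer + 1):
        Lb = _unpack_chol(theta[:nb], md.qb)
        Lp = _unpack_chol(theta[nb:nb + np_], md.qp)
        vf_params = tuple(theta[nb + np_:])
        wts = _vf_weights(md, vf_params)
        if wts is None:
            raise NlmeConvergenceError("variance-function weights degenerate")

        # (a) PNLS: conditional modes and fixed effects
        beta, ub, up, sol = _pnls(md, beta, ub, up, Lb, Lp, wts)
        sol_info = sol

        # (b) LME step on the linearization about (beta, ub, up)
        x = md.linear_predictor(beta, ub, up)
        dv = md.form.dvalue_dx(md.h, x)
        Xt = dv[:, None] * md.X
        Zbt = dv[:, None] * md.Xb if md.qb else md.Xb
        Zpt = dv[:, None] * md.Xp if md.qp else md.Xp
        f0 = md.form.value(md.h, x)
        w_resp = md.y - f0 + Xt @ beta
        if md.qb:
            w_resp = w_resp + np.sum(Zbt * ub[md.block_codes], axis=1)
        if md.qp:
            w_resp = w_resp + np.sum(Zpt * up[md.plot_codes], axis=1)

        res = minimize(_lme_profiled, theta, args=(md, w_resp, Xt, Zbt, Zpt),
                       method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9})
        theta = res.x
        out = _lme_profiled(theta, md, w_resp, Xt, Zbt, Zpt, return_full=True)
        ll, beta_lme, sigma2, psi_b, psi_p, vf_params = out
        if beta_lme is None:
            raise NlmeConvergenceError("LME step produced a singular system")
        est = (sigma2, psi_b, psi_p, vf_params)

        cur = np.concatenate([beta, theta, [math.log(sigma2)]])
        if prev is not None:
            delta = np.max(np.abs(cur - prev) / (np.abs(prev) + 1e-3))
            # parameter stability, or an objective plateau (the parameters
            # can chatter harmlessly when a variance sits on its boundary)
            if delta < tol or abs(ll - prev_ll) < 1e-7 * (1.0 + abs(ll)):
                converged = True
                break
        prev = cur
        prev_ll = ll
    else:
        outer = max_outer

    sigma2, psi_b, psi_p, vf_params = est
    # final conditional modes at the converged variance parameters
    Lb = _unpack_chol(theta[:nb], md.qb)
    Lp = _unpack_chol(theta[nb:nb + np_], md.qp)
    wts = _vf_weights(md, vf_params)
    beta, ub, up, _ = _pnls(md, beta, ub, up, Lb, Lp, wts)

    boundary = bool(np.any(_diag_entries(theta, md.qb, md.qp) <= _BOUNDARY_LOGDIAG))
    fitted_form = replace(form, beta=beta.copy())
    varfun_fit = VarianceFunction(varfun.kind, vf_params) if varfun.n_free else varfun
    n_theta = nb + np_ + 1 + varfun.n_free
    aic = -2.0 * ll + 2.0 * (len(beta) + n_theta)

    x = md.linear_predictor(beta, ub, up)
    pred = md.form.value(md.h, x)
    stats = fit_statistics(md.y, pred)

    fit = NlmeFit(
        form=fitted_form, re_spec=re_spec, beta=beta,
        psi_block=psi_b, psi_plot=psi_p,
        residual=ResidualModel(sigma2=sigma2, varfun=varfun_fit),
        ll=float(ll), aic=float(aic), converged=converged, boundary=boundary,
        n_obs=md.n, n_blocks=md.n_blocks, n_plots=md.n_plots, n_outer=outer,
        u_block={b: ub[i].copy() for i, b in enumerate(md.blocks)},
        u_plot={md.plot_ids[j]: up[j].copy() for j in range(md.n_plots)},
        stats=stats,
    )
    if not converged:
        warnings.warn(
            f"fit_nlme: no convergence within {max_outer} outer iterations "
            f"(last relative change above {tol})", stacklevel=2)
    return fit


def _diag_entries(theta, qb, qp):
    vals = []
    k = 0
    for q in (qb, qp):
        for i in range(q):
            for j in range(i + 1):
                if i == j:
                    vals.append(theta[k])
                k += 1
    return np.array(vals) if vals else np.array([0.0])


# ---------------------------------------------------------------------------
# likelihood evaluation at given parameters (oracle hook, structure selection)


def marginal_loglik(
    ds: Dataset | pd.DataFrame,
    form: ModelForm,
    re_spec: RandomEffectsSpec,
    beta: np.ndarray,
    psi_block: np.ndarray,
    psi_plot: np.ndarray,
    sigma2: float,
    varfun: Optional[VarianceFunction] = None,
) -> float:
    """Linearization-based marginal log-likelihood at fixed parameters.

    Conditional modes of the random effects are found by penalized NLS
    at the supplied variance components; the marginal density is then
    evaluated for the model linearized about those modes.  This is the
    same approximation the fitting algorithm maximizes, exposed so it
    can be compared against exact numerical integration on toy data.
    """
    varfun = varfun or VarianceFunction.none()
    md = _ModelData(ds, form, re_spec)
    md.varfun = varfun
    beta = np.asarray(beta, dtype=float)
    psi_block = np.atleast_2d(np.asarray(psi_block, dtype=float))
    psi_plot = np.atleast_2d(np.asarray(psi_plot, dtype=float))
    wts = _vf_weights(md, varfun.params if varfun.n_free else ())
    if wts is None:
        raise ValueError("degenerate variance-function weights")

    # conditional modes with beta held fixed: relative D = Psi / sigma2
    Lb = _psi_chol(psi_block / sigma2) if md.qb else np.zeros((0, 0))
    Lp = _psi_chol(psi_plot / sigma2) if md.qp else np.zeros((0, 0))
    ub = np.zeros((md.n_blocks, md.qb))
    up = np.zeros((md.n_plots, md.qp))
    # freeze beta by treating it as offset: run PNLS with fixed beta via tiny wrapper
    beta_fix = beta

    p = 0  # no free fixed effects; optimize u only
    from scipy.optimize import least_squares as _ls

    qb, qp = md.qb, md.qp
    Lb_inv = solve_triangular(Lb, np.eye(qb), lower=True) if qb else np.zeros((0, 0))
    Lp_inv = solve_triangular(Lp, np.eye(qp), lower=True) if qp else np.zeros((0, 0))
    inv_w = 1.0 / wts

    def split(z):
        ub = z[:md.n_blocks * qb].reshape(md.n_blocks, qb) if qb else np.zeros((md.n_blocks, 0))
        up = z[md.n_blocks * qb:].reshape(md.n_plots, qp) if qp else np.zeros((md.n_plots, 0))
        return ub, up

    def resid(z):
        ub, up = split(z)
        x = md.linear_predictor(beta_fix, ub, up)
        r = (md.y - md.form.value(md.h, x)) * inv_w
        pen = []
        if qb:
            pen.append((ub @ Lb_inv.T).ravel())
        if qp:
            pen.append((up @ Lp_inv.T).ravel())
        return np.concatenate([r] + pen) if pen else r

    z0 = np.zeros(md.n_blocks * qb + md.n_plots * qp)
    sol = _ls(resid, z0, method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    ub, up = split(sol.x)

    # linearize about the modes and evaluate the Gaussian marginal
    x = md.linear_predictor(beta_fix, ub, up)
    dv = md.form.dvalue_dx(md.h, x)
    Zbt = dv[:, None] * md.Xb if qb else md.Xb
    Zpt = dv[:, None] * md.Xp if qp else md.Xp
    r = md.y - md.form.value(md.h, x)
    if qb:
        r = r + np.sum(Zbt * ub[md.block_codes], axis=1)
    if qp:
        r = r + np.sum(Zpt * up[md.plot_codes], axis=1)

    LbA = _psi_chol(psi_block) if qb else np.zeros((0, 0))
    LpA = _psi_chol(psi_plot) if qp else np.zeros((0, 0))
    w2 = sigma2 * wts * wts
    ll = 0.0
    for i in range(md.n_blocks):
        rows = md.block_slices[i]
        ni = rows.size
        ki = qb + md.block_plots[i].size * qp
        A = np.zeros((ni, ki))
        if qb:
            A[:, :qb] = Zbt[rows] @ LbA
        if qp:
            local = {pj: c for c, pj in enumerate(md.block_plots[i])}
            pc = md.plot_codes[rows]
            for pj, c in local.items():
                sel = pc == pj
                A[sel, qb + c * qp: qb + (c + 1) * qp] = Zpt[rows][sel] @ LpA
        wv = w2[rows]
        ri = r[rows]
        logdet = float(np.sum(np.log(wv)))
        rw = ri / wv
        quad = float(ri @ rw)
        if ki:
            Aw = A / wv[:, None]
            S = np.eye(ki) + A.T @ Aw
            cS, lower = cho_factor(S, lower=True)
            logdet += 2.0 * float(np.sum(np.log(np.diag(cS))))
            At_rw = A.T @ rw
            quad -= float(At_rw @ cho_solve((cS, lower), At_rw))
        ll += -0.5 * (ni * math.log(2 * math.pi) + logdet + quad)
    return float(ll)


# ---------------------------------------------------------------------------
# structure / variance-function selection harnesses


def select_random_effects_structure(
    ds: Dataset | pd.DataFrame,
    form: ModelForm,
    candidates: Sequence[RandomEffectsSpec],
    varfun: Optional[VarianceFunction] = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit every candidate placement; rank by AIC (ties by LL).

    Failed candidates are recorded with the error message and excluded
    from ranking.  The minimum-AIC row is flagged ``best``.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate structure")
    rows = []
    fits = []
    for spec in candidates:
        try:
            fit = fit_nlme(ds, form, spec, varfun=varfun, **fit_kwargs)
            rows.append({"structure": spec.describe(), "aic": fit.aic, "ll": fit.ll,
                         "converged": fit.converged, "boundary": fit.boundary, "error": ""})
            fits.append(fit)
        except Exception as exc:  # noqa: BLE001
            rows.append({"structure": spec.describe(), "aic": np.nan, "ll": np.nan,
                         "converged": False, "boundary": False, "error": str(exc)})
            fits.append(None)
    table = pd.DataFrame(rows)
    table["best"] = False
    ok = table["aic"].notna()
    if ok.any():
        table.loc[table.loc[ok, "aic"].idxmin(), "best"] = True
    return table


def compare_variance_functions(
    ds: Dataset | pd.DataFrame,
    form: ModelForm,
    re_spec: RandomEffectsSpec = DEFAULT_RE_STRUCTURE,
    varfuns: Optional[Mapping[str, VarianceFunction]] = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """AIC/LL table over residual variance functions; min-AIC row flagged."""
    if varfuns is None:
        varfuns = {
            "none": VarianceFunction.none(),
            "exponential": VarianceFunction.exponential(),
            "power": VarianceFunction.power(),
            "constant_power": VarianceFunction.constant_power(),
        }
    rows = []
    fits = []
    for name, vf in varfuns.items():
        try:
            fit = fit_nlme(ds, form, re_spec, varfun=vf, **fit_kwargs)
            rows.append({"variance_function": name, "aic": fit.aic, "ll": fit.ll,
                         "params": tuple(fit.residual.varfun.params),
                         "converged": fit.converged, "error": ""})
            fits.append(fit)
        except Exception as exc:  # noqa: BLE001
            rows.append({"variance_function": name, "aic": np.nan, "ll": np.nan,
                         "params": (), "converged": False, "error": str(exc)})
            fits.append(None)
    table = pd.DataFrame(rows)
    table["best"] = False
    ok = table["aic"].notna()
    if ok.any():
        table.loc[table.loc[ok, "aic"].idxmin(), "best"] = True
    return table
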