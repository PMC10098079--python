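"""Candidate height-to-crown-base model forms and fixed-effects fitting.

Six classical HCB forms (M1..M6) plus the extended logistic form M3ext
are supported.  All share a linear predictor x = sum_t beta_t * cov_t
over a user-chosen term list (intercept term "1", then culm/plot
covariates such as dbh, bal, cd, rd ...), wrapped in a form-specific
nonlinear link scaled by total height h:

    M1    hcb = h * (1 - exp(x))                exponential
    M2    hcb = h * (1 - exp(x)^2)              exponential (= M1 with 2x)
    M3    hcb = h / (1 + exp(x))                logistic, range (0, h)
    M4    hcb = h * (1 + c*exp(x))^(-1/m)       generalized logistic
    M5    hcb = h * (1 - c*exp(x_W))            exponential, W-powered terms
    M6    hcb = h * (a + exp(x))                exponential with offset
    M3ext alias of M3 with terms (1, dbh, bal, cd)

M3/M3ext predictions always lie strictly in (0, h), which is the reason
the logistic family wins on bounded crown-base data.  Fixed-effects
fitting is iterative nonlinear least squares (trust-region reflective);
fit quality is summarised by mean difference (MD), R2, RMSE and the two
total-relative-error conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .stand_data import CulmRecord, Dataset, PlotRecord, dataset_to_frame

__all__ = [
    "ModelForm",
    "FitStatistics",
    "FitResult",
    "m3",
    "m3ext",
    "candidate_forms",
    "predict",
    "predict_frame",
    "design_matrix",
    "fit_ols",
    "fit_statistics",
    "compare_models",
]

_SHAPE_DEFAULTS = {
    "M1": (), "M2": (), "M3": (), "M3ext": (),
    "M4": ("c", "m"), "M5": ("c", "W"), "M6": ("a",),
}


@dataclass
class ModelForm:
    """A candidate HCB form: designation, term list, coefficients.

    ``terms`` are covariate names for the linear predictor; "1" denotes
    the intercept.  ``shape`` holds the extra nonlinear parameters of
    M4-M6 (c, m, W, a).  ``beta`` is None until fitted or set.
    """

    designation: str
    terms: tuple[str, ...] = ("1", "dbh", "bal")
    beta: Optional[np.ndarray] = None
    shape: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.designation not in _SHAPE_DEFAULTS:
            raise ValueError(f"unknown form designation {self.designation!r}")
        for name in _SHAPE_DEFAULTS[self.designation]:
            self.shape.setdefault(name, 1.0)
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float)
            if self.beta.size != len(self.terms):
                raise ValueError(
                    f"{self.designation}: {len(self.terms)} terms but beta has {self.beta.size}"
                )

    @property
    def shape_names(self) -> tuple[str, ...]:
        return _SHAPE_DEFAULTS[self.designation]

    @property
    def n_params(self) -> int:
        return len(self.terms) + len(self.shape_names)

    @property
    def has_shape(self) -> bool:
        return bool(self.shape_names)

    # -- the nonlinear link g(h, x) and its x-derivative -----------------
    def value(self, h: np.ndarray, x: np.ndarray) -> np.ndarray:
        d = self.designation
        ex = np.exp(x)
        if d == "M1":
            return h * (1.0 - ex)
        if d == "M2":
            return h * (1.0 - ex ** 2)
        if d in ("M3", "M3ext"):
            return h / (1.0 + ex)
        if d == "M4":
            c, m = self.shape["c"], self.shape["m"]
            return h * (1.0 + c * ex) ** (-1.0 / m)
        if d == "M5":
            return h * (1.0 - self.shape["c"] * ex)
        if d == "M6":
            return h * (self.shape["a"] + ex)
        raise AssertionError(d)

    def dvalue_dx(self, h: np.ndarray, x: np.ndarray) -> np.ndarray:
        """d value / d x — the chain-rule factor for gradients in x."""
        d = self.designation
        ex = np.exp(x)
        if d == "M1":
            return -h * ex
        if d == "M2":
            return -2.0 * h * ex ** 2
        if d in ("M3", "M3ext"):
            return -h * ex / (1.0 + ex) ** 2
        if d == "M4":
            c, m = self.shape["c"], self.shape["m"]
            return -(c / m) * h * ex * (1.0 + c * ex) ** (-1.0 / m - 1.0)
        if d == "M5":
            return -h * self.shape["c"] * ex
        if d == "M6":
            return h * ex
        raise AssertionError(d)


def m3(terms: Sequence[str] = ("1", "dbh", "bal"), beta=None) -> ModelForm:
    """Three-parameter logistic HCB form."""
    return ModelForm("M3", tuple(terms), beta)


def m3ext(beta=None) -> ModelForm:
    """Extended logistic form with terms (1, dbh, bal, cd)."""
    return ModelForm("M3ext", ("1", "dbh", "bal", "cd"), beta)


def candidate_forms(terms: Sequence[str] = ("1", "dbh", "bal")) -> list[ModelForm]:
    """The six screening candidates M1..M6 on a common term list."""
    return [ModelForm(d, tuple(terms)) for d in ("M1", "M2", "M3", "M4", "M5", "M6")]


# ---------------------------------------------------------------------------
# design matrix / prediction


def _covariate_column(df: pd.DataFrame, name: str) -> np.ndarray:
    if name == "1":
        return np.ones(len(df))
    if name not in df.columns or df[name].isna().any():
        raise KeyError(f"covariate {name!r} missing (or has missing values)")
    return df[name].to_numpy(dtype=float)


def design_matrix(form: ModelForm, df: pd.DataFrame) -> np.ndarray:
    """n x p matrix of linear-predictor covariates in term order."""
    cols = []
    for t in form.terms:
        col = _covariate_column(df, t)
        if form.designation == "M5" and t != "1":
            col = np.sign(col) * np.abs(col) ** form.shape["W"]
        cols.append(col)
    return np.column_stack(cols)


def predict_frame(
    form: ModelForm,
    df: pd.DataFrame,
    offsets: Optional[np.ndarray] = None,
    beta: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Vectorized prediction over a culm-level frame.

    ``offsets`` is an optional n x p matrix of per-observation additive
    random-effect values for each linear-predictor coefficient.
    """
    b = form.beta if beta is None else np.asarray(beta, dtype=float)
    if b is None:
        raise ValueError(f"{form.designation}: parameters not set")
    X = design_matrix(form, df)
    coef = np.broadcast_to(b, X.shape).copy()
    if offsets is not None:
        coef = coef + offsets
    x = np.sum(X * coef, axis=1)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite linear predictor")
    h = _covariate_column(df, "h")
    return form.value(h, x)


def predict(
    form: ModelForm,
    culm: CulmRecord,
    plot: Optional[PlotRecord] = None,
    offsets: Optional[Mapping[str, float]] = None,
) -> float:
    """Predict HCB (m) for a single culm record.

    ``offsets`` maps term names to additive random-effect values on the
    corresponding coefficient.
    """
    row = {"dbh": culm.dbh, "h": culm.h, "bal": culm.bal, "rd": culm.rd,
           "age_du": culm.age_du, "cw": culm.cw}
    if plot is not None:
        row.update({"cd": plot.cd, "qmd": plot.qmd, "ba": plot.ba,
                    "n_per_ha": plot.n_per_ha})
    df = pd.DataFrame([row])
    off = None
    if offsets:
        off = np.array([[offsets.get(t, 0.0) for t in form.terms]])
    return float(predict_frame(form, df, offsets=off)[0])


# ---------------------------------------------------------------------------
# fit statistics


@dataclass(frozen=True)
class FitStatistics:
    """Goodness-of-fit summary for predicted vs observed HCB.

    ``tre_abs`` is the absolute-error total relative error
    100 * sum|e| / sum(pred); ``tre_sq`` is the squared-error convention
    100 * sum(e^2) / sum(pred^2).  Both are reported because both appear
    in the crown-base literature with the same name.
    """

    md: float
    r2: float
    rmse: float
    tre_sq: float
    tre_abs: float
    n: int
    ll: Optional[float] = None
    aic: Optional[float] = None


def fit_statistics(obs, pred, n_params: Optional[int] = None) -> FitStatistics:
    """MD / R2 / RMSE / TRE for observation and prediction vectors (m)."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 1:
        raise ValueError("obs and pred must be equal-length 1-D vectors")
    e = obs - pred
    sum_pred = pred.sum()
    if sum_pred <= 0:
        raise ValueError("sum of predictions <= 0: TRE undefined")
    n = obs.size
    sse = float(e @ e)
    sst = float(((obs - obs.mean()) ** 2).sum())
    ll = aic = None
    if n_params is not None:
        sigma2 = max(sse / n, 1e-300)
        ll = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
        aic = -2.0 * ll + 2.0 * (n_params + 1)  # + residual variance
    return FitStatistics(
        md=float(e.mean()),
        r2=1.0 - sse / sst if sst > 0 else float("nan"),
        rmse=math.sqrt(sse / n),
        tre_sq=100.0 * sse / float(pred @ pred),
        tre_abs=100.0 * float(np.abs(e).sum()) / sum_pred,
        n=n,
        ll=ll,
        aic=aic,
    )


# ---------------------------------------------------------------------------
# nonlinear least squares


@dataclass
class FitResult:
    form: ModelForm
    stats: FitStatistics
    converged: bool
    n_iter: int
    message: str = ""


def default_start(form: ModelForm, df: pd.DataFrame) -> np.ndarray:
    """Centroid start: intercept places the link at (mean H, mean HCB)."""
    hbar = df["h"].mean()
    cbar = df["hcb"].mean()
    beta = np.zeros(len(form.terms))
    ratio = max(hbar / cbar - 1.0, 1e-6)
    d = form.designation
    if d in ("M3", "M3ext", "M4"):
        b1 = math.log(ratio)
    elif d in ("M1", "M5"):
        b1 = math.log(max(1.0 - cbar / hbar, 1e-6))
    elif d == "M2":
        b1 = 0.5 * math.log(max(1.0 - cbar / hbar, 1e-6))
    else:  # M6
        b1 = math.log(max(cbar / hbar, 1e-6))
    try:
        i1 = form.terms.index("1")
    except ValueError:
        i1 = 0
    beta[i1] = b1
    return beta


def fit_ols(
    ds: Dataset | pd.DataFrame,
    form: ModelForm,
    start: Optional[np.ndarray] = None,
    max_iter: int = 200,
) -> FitResult:
    """Fit a form by iterative nonlinear least squares on all culms with HCB.

    Returns the fitted form (a copy with ``beta``/``shape`` set) and the
    training-data fit statistics, with a Gaussian log-likelihood and AIC.
    """
    df = dataset_to_frame(ds) if isinstance(ds, Dataset) else ds
    df = df[df["hcb"].notna()]
    y = df["hcb"].to_numpy(dtype=float)
    if len(df) <= form.n_params:
        raise ValueError("need more observations than parameters")

    p = len(form.terms)
    shape_names = form.shape_names
    if start is None:
        start = default_start(form, df)
    start = np.asarray(start, dtype=float)
    if start.size == p:
        start = np.concatenate([start, [form.shape[s] for s in shape_names]])

    work = replace(form, beta=None, shape=dict(form.shape))

    def unpack(theta):
        work.beta = theta[:p]
        for name, v in zip(shape_names, theta[p:]):
            work.shape[name] = v
        return work

    def resid(theta):
        return y - predict_frame(unpack(theta), df)

    sol = least_squares(resid, start, method="trf", max_nfev=max_iter * (p + len(shape_names) + 1))
    fitted = replace(form, beta=sol.x[:p].copy(),
                     shape={n: v for n, v in zip(shape_names, sol.x[p:])})
    if np.linalg.matrix_rank(sol.jac) < sol.x.size:
        # singular Jacobian at the optimum: parameters not jointly identified
        fitted_ok = False
    else:
        fitted_ok = sol.status > 0
    pred = predict_frame(fitted, df)
    stats = fit_statistics(y, pred, n_params=form.n_params)
    return FitResult(form=fitted, stats=stats, converged=fitted_ok,
                     n_iter=sol.nfev, message=sol.message)


# ---------------------------------------------------------------------------
# model comparison / predictor screening


def compare_models(
    ds: Dataset | pd.DataFrame,
    forms: Iterable[ModelForm],
    criteria: Sequence[str] = ("rmse", "r2", "tre", "md", "aic"),
    rmse_tie_decimals: int = 4,
) -> pd.DataFrame:
    """Fit each form and tabulate fit statistics with per-criterion ranks.

    Screening convention: among forms tied on RMSE (to
    ``rmse_tie_decimals`` places) the one with fewest parameters is
    flagged in the ``selected`` column — parsimony breaks statistical
    ties.  Failed fits are retained as rows with ``converged=False`` and
    excluded from ranking.
    """
    forms = list(forms)
    if len(forms) < 2:
        raise ValueError("need at least two forms to compare")
    rows = []
    for f in forms:
        label = f.designation if f.designation != "M3" or f.terms == ("1", "dbh", "bal") \
            else f"M3[{','.join(f.terms)}]"
        try:
            res = fit_ols(ds, f)
            rows.append({"form": label, "n_params": f.n_params, "converged": res.converged,
                         "md": res.stats.md, "rmse": res.stats.rmse, "r2": res.stats.r2,
                         "tre_sq": res.stats.tre_sq, "tre_abs": res.stats.tre_abs,
                         "aic": res.stats.aic, "ll": res.stats.ll, "error": ""})
        except Exception as exc:  # noqa: BLE001 — per-row failure is data, not control flow
            rows.append({"form": label, "n_params": f.n_params, "converged": False,
                         "md": np.nan, "rmse": np.nan, "r2": np.nan, "tre_sq": np.nan,
                         "tre_abs": np.nan, "aic": np.nan, "ll": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows)
    ok = table["converged"] & table["rmse"].notna()
    crit_cols = {"md": ("md", True), "rmse": ("rmse", False), "tre": ("tre_sq", False),
                 "r2": ("r2", True), "aic": ("aic", False)}
    for crit in criteria:
        col, maximize = crit_cols[crit]
        vals = table.loc[ok, col]
        if crit == "md":
            vals = vals.abs()
            ranks = vals.rank(method="min")
        else:
            ranks = (-vals).rank(method="min") if maximize else vals.rank(method="min")
        table[f"rank_{crit}"] = np.nan
        table.loc[ok, f"rank_{crit}"] = ranks
    table["selected"] = False
    if ok.any():
        rounded = table.loc[ok, "rmse"].round(rmse_tie_decimals)
        best_group = table.loc[ok][rounded == rounded.min()]
        pick = best_group.sort_values(["n_params", "rmse"]).index[0]
        table.loc[pick, "selected"] = True
    return table
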