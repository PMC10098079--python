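"""Seeded generator of nested moso-bamboo stand datasets.

Emulates the study design behind the model: 5 blocks carrying 38 plots
of 400 m2, per-culm DBH from a truncated normal, total height H from a
power allometry on DBH calibrated to the published marginal moments, and
plot canopy density uniform on its observed range.  HCB is generated
from the fitted two-level logistic model treated as a stochastic truth:

    hcb = h / (1 + exp(x)) + xi,
    x   = (b1 + u1_i) + (b2 + u2_i + u2_ij) * dbh + b3 * bal + b4 * cd,

with block effects (u1_i, u2_i) bivariate normal, plot effects u2_ij
normal, and heteroscedastic residuals xi ~ N(0, sigma^2 * exp(2*gamma*h)).
The residual scale is anchored by the standard deviation at the mean
height (``sd_at_mean_h``) rather than by a raw sigma, so the implied
noise level is explicit in metres.

Every routine is deterministic given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.optimize import brentq

from .stand_data import CulmRecord, Dataset, PlotRecord, derive_covariates

__all__ = [
    "SyntheticConfig",
    "GenerationInfo",
    "generate_dataset",
    "generate_calibration_truth",
    "calibrate_h_allometry",
    "truth_fit",
]

DEFAULT_SEED = 20230330


@dataclass
class SyntheticConfig:
    """Generative parameters for a synthetic bamboo stand.

    Defaults reproduce the study conditions: 38 plots of 20 x 20 m in 5
    blocks, ~1374 measured culms, DBH ~ TN(10.38, 1.57; [5.0, 15.6]) cm,
    H with mean 12.16 m / sd 2.01 m on [5, 17.9], CD ~ U[0.4, 0.87], and
    the published fixed effects and variance components as truth.
    """

    n_blocks: int = 5
    plot_allocation: tuple[int, ...] = (8, 8, 8, 7, 7)
    plot_area_m2: float = 400.0
    # stand density descriptor, culms/ha (truncated normal)
    density_mean: float = 2783.0
    density_sd: float = 853.0
    density_bounds: tuple[float, float] = (1150.0, 3750.0)
    #: fraction of standing culms that enter the measured dataset; the
    #: default yields ~36 culms/plot (~1374 total) at the default density
    measured_fraction: float = 0.343
    # per-culm DBH law, cm
    dbh_mean: float = 10.38
    dbh_sd: float = 1.57
    dbh_bounds: tuple[float, float] = (5.0, 15.6)
    # H marginal targets, m (allometry is calibrated to these)
    h_mean: float = 12.16
    h_sd: float = 2.01
    h_bounds: tuple[float, float] = (5.0, 17.9)
    h_dbh_corr: float = 0.6
    # plot canopy density
    cd_bounds: tuple[float, float] = (0.4, 0.87)
    # truth: fixed effects on (1, dbh, bal, cd)
    true_beta: tuple[float, ...] = (0.8407, -0.07922, -0.0020, -0.3440)
    # block-level covariance of (u1, u2): variances + correlation
    psi_block_var: tuple[float, float] = (1.17e-02, 5.84e-05)
    psi_block_corr: float = -0.529
    var_plot: float = 2.13e-04
    # residual: sd at mean height (m) under Var = sigma^2 exp(2 gamma h)
    resid_sd_at_mean_h: float = math.sqrt(1.3017)
    resid_gamma: float = -0.0179
    hcb_clamp: tuple[float, float] = (0.05, 0.98)  # fractions of h
    seed: int = DEFAULT_SEED

    def psi_block(self) -> np.ndarray:
        v1, v2 = self.psi_block_var
        cov = self.psi_block_corr * math.sqrt(v1 * v2)
        return np.array([[v1, cov], [cov, v2]])

    def resid_sigma(self) -> float:
        """Residual scale sigma implied by the sd anchored at mean height."""
        return self.resid_sd_at_mean_h / math.exp(self.resid_gamma * self.h_mean)

    def validate(self) -> None:
        if len(self.plot_allocation) != self.n_blocks:
            raise ValueError("plot_allocation length must equal n_blocks")
        if min(self.plot_allocation) < 1:
            raise ValueError("every block needs at least one plot")
        for lo, hi in (self.dbh_bounds, self.h_bounds, self.cd_bounds,
                       self.density_bounds, self.hcb_clamp):
            if not lo < hi:
                raise ValueError(f"bounds must be ordered, got ({lo}, {hi})")
        if any(v < 0 for v in self.psi_block_var) or self.var_plot < 0:
            raise ValueError("variances must be >= 0")
        if not -1 < self.psi_block_corr < 1:
            raise ValueError("block correlation must lie in (-1, 1)")
        expected = self.density_bounds[0] * self.plot_area_m2 / 10000.0 * self.measured_fraction
        if expected < 1:
            raise ValueError("config implies < 1 measured culm per plot")

    # -- YAML round-trip for the CLI -------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)


@dataclass(frozen=True)
class GenerationInfo:
    """Bookkeeping from one generator run."""

    n_culms: int
    n_clamped_low: int
    n_clamped_high: int
    allometry_a: float
    allometry_b: float
    allometry_sd: float

    @property
    def clamp_rate(self) -> float:
        return (self.n_clamped_low + self.n_clamped_high) / max(self.n_culms, 1)


def _truncnorm(mean: float, sd: float, bounds: tuple[float, float]):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def calibrate_h_allometry(cfg: SyntheticConfig) -> tuple[float, float, float]:
    """Solve the power allometry h = a * dbh**b + eps for (a, b, sd_eps).

    Matches the configured H mean, sd and H-DBH correlation against the
    truncated-normal DBH law (moments by quadrature, no sampling): the
    coefficient of variation of a*dbh**b is increasing in b, so b solves
    cv(dbh**b) = rho * sd_h / mean_h by bisection, a rescales to the mean,
    and the residual sd supplies the remaining variance.
    """
    d = _truncnorm(cfg.dbh_mean, cfg.dbh_sd, cfg.dbh_bounds)
    rho = cfg.h_dbh_corr

    def cv_gap(b: float) -> float:
        m1 = d.expect(lambda t: t ** b)
        m2 = d.expect(lambda t: t ** (2 * b))
        cv = math.sqrt(max(m2 - m1 * m1, 0.0)) / m1
        return cv - rho * cfg.h_sd / cfg.h_mean

    b = brentq(cv_gap, 0.02, 4.0, xtol=1e-10)
    a = cfg.h_mean / d.expect(lambda t: t ** b)
    sd_eps = cfg.h_sd * math.sqrt(max(1.0 - rho * rho, 0.0))
    return a, b, sd_eps


def _generate(cfg: SyntheticConfig, seed: Optional[int]):
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    a_allo, b_allo, sd_eps = calibrate_h_allometry(cfg)
    dbh_law = _truncnorm(cfg.dbh_mean, cfg.dbh_sd, cfg.dbh_bounds)
    dens_law = _truncnorm(cfg.density_mean, cfg.density_sd, cfg.density_bounds)
    area_ha = cfg.plot_area_m2 / 10000.0

    psi = cfg.psi_block()
    chol = np.linalg.cholesky(psi + 1e-300 * np.eye(2)) if psi.any() else np.zeros((2, 2))

    blocks, plots, culms = [], [], []
    truth_rows = []
    plot_effect: dict[str, float] = {}
    block_effect: dict[str, tuple[float, float]] = {}
    for i in range(cfg.n_blocks):
        bid = f"B{i + 1}"
        blocks.append(bid)
        u1, u2 = chol @ rng.standard_normal(2)
        block_effect[bid] = (u1, u2)
        truth_rows.append({"level": "block", "block": bid, "plot": None,
                           "u_1": u1, "u_dbh": u2})
        for j in range(cfg.plot_allocation[i]):
            pid = f"{bid}-P{j + 1:02d}"
            density = float(dens_law.ppf(rng.uniform()))
            n_meas = max(1, round(density * area_ha * cfg.measured_fraction))
            cd = rng.uniform(*cfg.cd_bounds)
            plots.append(PlotRecord(plot_id=pid, block_id=bid,
                                    area_m2=cfg.plot_area_m2, cd=cd,
                                    site={"density_total_per_ha": density}))
            u2ij = math.sqrt(cfg.var_plot) * rng.standard_normal() if cfg.var_plot > 0 else 0.0
            plot_effect[pid] = u2ij
            truth_rows.append({"level": "plot", "block": bid, "plot": pid,
                               "u_1": 0.0, "u_dbh": u2ij})
            dbh = dbh_law.ppf(rng.uniform(size=n_meas))
            h = np.clip(a_allo * dbh ** b_allo + sd_eps * rng.standard_normal(n_meas),
                        *cfg.h_bounds)
            for k in range(n_meas):
                culms.append(CulmRecord(block_id=bid, plot_id=pid,
                                        culm_id=f"{pid}-C{k + 1:03d}",
                                        dbh=float(dbh[k]), h=float(h[k])))

    ds = derive_covariates(Dataset(blocks=blocks, plots=plots, culms=culms))

    b1, b2, b3, b4 = cfg.true_beta
    sigma = cfg.resid_sigma()
    cd_of = {p.plot_id: p.cd for p in ds.plots}
    n_lo = n_hi = 0
    for c in ds.culms:
        u1, u2b = block_effect[c.block_id]
        u2p = plot_effect[c.plot_id]
        x = (b1 + u1) + (b2 + u2b + u2p) * c.dbh + b3 * c.bal + b4 * cd_of[c.plot_id]
        mean = c.h / (1.0 + math.exp(x))
        xi = sigma * math.exp(cfg.resid_gamma * c.h) * rng.standard_normal()
        hcb = mean + xi
        lo, hi = cfg.hcb_clamp[0] * c.h, cfg.hcb_clamp[1] * c.h
        if hcb < lo:
            hcb, n_lo = lo, n_lo + 1
        elif hcb > hi:
            hcb, n_hi = hi, n_hi + 1
        c.hcb = hcb

    info = GenerationInfo(n_culms=len(ds.culms), n_clamped_low=n_lo,
                          n_clamped_high=n_hi, allometry_a=a_allo,
                          allometry_b=b_allo, allometry_sd=sd_eps)
    truth = pd.DataFrame(truth_rows)
    return ds, truth, info


def generate_dataset(
    cfg: SyntheticConfig,
    seed: Optional[int] = None,
    with_info: bool = False,
):
    """Generate one synthetic stand (Dataset with covariates derived).

    ``seed`` overrides ``cfg.seed``.  With ``with_info`` the generator's
    bookkeeping (clamp counts, calibrated allometry) is returned too.
    """
    ds, _, info = _generate(cfg, seed)
    return (ds, info) if with_info else ds


def generate_calibration_truth(
    cfg: SyntheticConfig,
    seed: Optional[int] = None,
) -> tuple[Dataset, pd.DataFrame]:
    """Generate a stand together with its realized latent random effects.

    The truth table has one row per block (columns ``u_1``, ``u_dbh``:
    intercept and DBH-slope block effects) and one per plot (``u_dbh``:
    the plot-level DBH-slope effect), for recovery experiments.
    """
    ds, truth, _ = _generate(cfg, seed)
    return ds, truth


def truth_fit(cfg: SyntheticConfig):
    """The generating model packaged as a fitted-model object.

    Useful as a known-truth stand-in wherever an :class:`NlmeFit` is
    expected (calibration experiments, oracle comparisons) without the
    Monte-Carlo error of an actual refit.
    """
    from .nlme_engine import (DEFAULT_RE_STRUCTURE, NlmeFit, ResidualModel,
                              VarianceFunction)
    from .model_forms import m3ext

    beta = np.asarray(cfg.true_beta, dtype=float)
    n_plots = sum(cfg.plot_allocation)
    return NlmeFit(
        form=m3ext(beta), re_spec=DEFAULT_RE_STRUCTURE, beta=beta,
        psi_block=cfg.psi_block(), psi_plot=np.array([[cfg.var_plot]]),
        residual=ResidualModel(sigma2=cfg.resid_sigma() ** 2,
                               varfun=VarianceFunction.exponential(cfg.resid_gamma)),
        ll=float("nan"), aic=float("nan"), converged=True, boundary=False,
        n_obs=0, n_blocks=cfg.n_blocks, n_plots=n_plots, n_outer=0,
    )
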