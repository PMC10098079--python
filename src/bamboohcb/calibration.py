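"""EBLUP response calibration (model localization) of a fitted NLME model.

A fitted two-level model predicts a new culm's HCB either from fixed
effects alone (the mean response) or, when a few culms of the target
plot have measured HCB, with block/plot random effects estimated from
that subsample by empirical best linear unbiased prediction:

    u_hat = Psi Z' (R + Z Psi Z')^{-1} [y - f(beta, u*) + Z u*],

where Z holds the partial derivatives of the model with respect to each
random effect, Psi is the prior covariance assembled block-diagonally
from the block-level covariance and the plot-level variance, and R is
the residual covariance from the fitted variance function evaluated at
the subsample heights.  Because the right-hand side references the
current estimate u*, the equation is iterated from u* = 0 to its fixed
point (a one-step mode is available for comparability with the
single-pass convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model_forms import ModelForm, design_matrix, predict_frame
from .nlme_engine import NlmeFit
from .stand_data import CulmRecord, Dataset, PlotRecord, dataset_to_frame

__all__ = [
    "CalibrationSample",
    "RandomEffectEstimates",
    "estimate_random_effects",
    "predict_mean_response",
    "predict_calibrated",
]


@dataclass
class CalibrationSample:
    """A per-plot calibration subsample: culms with observed HCB.

    The study protocol draws 1-8 culms per plot; any positive count is
    accepted (a full-plot sample is the saturated case).
    """

    plot: PlotRecord
    culms: Sequence[CulmRecord]

    def __post_init__(self) -> None:
        if not self.culms:
            raise ValueError("calibration sample must contain at least one culm")
        for c in self.culms:
            if c.plot_id != self.plot.plot_id or c.block_id != self.plot.block_id:
                raise ValueError(
                    f"culm {c.culm_id} does not belong to plot {self.plot.plot_id}")
            if c.hcb is None or not (0 < c.hcb < c.h):
                raise ValueError(f"culm {c.culm_id}: calibration requires hcb in (0, h)")

    @property
    def m(self) -> int:
        return len(self.culms)

    def frame(self) -> pd.DataFrame:
        rows = []
        for c in self.culms:
            rows.append({"block": c.block_id, "plot": c.plot_id, "culm": c.culm_id,
                         "dbh": c.dbh, "h": c.h, "hcb": c.hcb, "bal": c.bal,
                         "rd": c.rd, "cd": self.plot.cd})
        return pd.DataFrame(rows)


@dataclass
class RandomEffectEstimates:
    """EBLUP random-effect estimates keyed by block and plot id.

    ``block_effects[b][t]`` is the estimated additive perturbation of
    coefficient ``t`` shared by block ``b``; ``plot_effects[p][t]``
    likewise at plot level.
    """

    block_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    plot_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    n_iter: int = 0
    converged: bool = True
    sample_sizes: dict[str, int] = field(default_factory=dict)
    strategy: str = ""

    def offsets_for(self, form: ModelForm, df: pd.DataFrame) -> np.ndarray:
        """n x p additive offsets on the linear-predictor coefficients.

        Culms in plots without estimates fall back to block-level
        effects only; culms in unknown blocks get zero (mean response).
        """
        off = np.zeros((len(df), len(form.terms)))
        blocks = df["block"].astype(str).to_numpy()
        plots = df["plot"].astype(str).to_numpy()
        for k, t in enumerate(form.terms):
            col = np.zeros(len(df))
            for b, eff in self.block_effects.items():
                col[blocks == b] += eff.get(t, 0.0)
            for p, eff in self.plot_effects.items():
                col[plots == p] += eff.get(t, 0.0)
            off[:, k] = col
        return off


def _zero_effects_like(fit: NlmeFit, samples: Sequence[CalibrationSample]) -> RandomEffectEstimates:
    est = RandomEffectEstimates()
    for s in samples:
        est.block_effects.setdefault(s.plot.block_id, {t: 0.0 for t in fit.block_terms})
        est.plot_effects[s.plot.plot_id] = {t: 0.0 for t in fit.plot_terms}
        est.sample_sizes[s.plot.plot_id] = s.m
    return est


def estimate_random_effects(
    fit: NlmeFit,
    sample: CalibrationSample | Sequence[CalibrationSample],
    one_step: bool = False,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> RandomEffectEstimates:
    """Estimate block and plot random effects jointly from a subsample.

    A single :class:`CalibrationSample` calibrates one plot (its block
    effects are predicted from the same culms, q = block + plot effects).
    A sequence of samples from plots of the same block is stacked: the
    block effect is shared, each plot gets its own plot-level effect.

    Iterates the EBLUP fixed-point equation from u* = 0, recomputing the
    derivative matrix Z and the adjusted residual at the current
    estimate each pass; ``one_step`` stops after the first pass.
    """
    samples = [sample] if isinstance(sample, CalibrationSample) else list(sample)
    if not samples:
        raise ValueError("no calibration samples")
    block_ids = {s.plot.block_id for s in samples}
    if len(block_ids) > 1:
        raise ValueError(
            "stacked calibration samples must share one block; calibrate blocks separately")
    block_id = block_ids.pop()

    form = fit.form
    bterms, pterms = fit.block_terms, fit.plot_terms
    qb, qp = len(bterms), len(pterms)
    J = len(samples)
    q = qb + J * qp

    df = pd.concat([s.frame() for s in samples], ignore_index=True)
    y = df["hcb"].to_numpy(dtype=float)
    h = df["h"].to_numpy(dtype=float)
    X = design_matrix(form, df)
    tcol = {t: k for k, t in enumerate(form.terms)}
    Cb = X[:, [tcol[t] for t in bterms]] if qb else np.zeros((len(df), 0))
    Cp = X[:, [tcol[t] for t in pterms]] if qp else np.zeros((len(df), 0))
    plot_of_row = np.concatenate([[j] * s.m for j, s in enumerate(samples)])

    # prior covariance, block-diagonal: block effects then per-plot effects
    Psi = np.zeros((q, q))
    if qb:
        Psi[:qb, :qb] = fit.psi_block
    for j in range(J):
        sl = slice(qb + j * qp, qb + (j + 1) * qp)
        Psi[sl, sl] = fit.psi_plot
    R = np.diag(fit.residual.sd(h) ** 2)

    beta = fit.beta

    def model_at(u):
        off = np.zeros_like(X)
        for k, t in enumerate(bterms):
            off[:, tcol[t]] += u[k]
        for j in range(J):
            rows = plot_of_row == j
            for k, t in enumerate(pterms):
                off[rows, tcol[t]] += u[qb + j * qp + k]
        x = np.sum(X * (beta + off), axis=1)
        f = form.value(h, x)
        dv = form.dvalue_dx(h, x)
        Z = np.zeros((len(df), q))
        if qb:
            Z[:, :qb] = dv[:, None] * Cb
        for j in range(J):
            rows = plot_of_row == j
            Z[rows, qb + j * qp: qb + (j + 1) * qp] = (dv[:, None] * Cp)[rows]
        return f, Z

    u = np.zeros(q)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        f, Z = model_at(u)
        e = y - f + Z @ u
        M = R + Z @ Psi @ Z.T
        try:
            sol = np.linalg.solve(M, e)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular EBLUP system for block {block_id}: {exc}") from exc
        u_new = Psi @ Z.T @ sol
        delta = np.max(np.abs(u_new - u)) if q else 0.0
        u = u_new
        if one_step or delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EBLUP iteration did not converge within {max_iter} passes",
                      stacklevel=2)

    est = RandomEffectEstimates(n_iter=it, converged=converged)
    est.block_effects[block_id] = {t: float(u[k]) for k, t in enumerate(bterms)}
    for j, s in enumerate(samples):
        est.plot_effects[s.plot.plot_id] = {
            t: float(u[qb + j * qp + k]) for k, t in enumerate(pterms)}
        est.sample_sizes[s.plot.plot_id] = s.m
    return est


def predict_mean_response(fit: NlmeFit, data: Dataset | pd.DataFrame) -> np.ndarray:
    """Fixed-effects-only prediction (all random effects zero), metres."""
    df = dataset_to_frame(data) if isinstance(data, Dataset) else data
    return predict_frame(fit.form, df)


def predict_calibrated(
    fit: NlmeFit,
    effects: Optional[RandomEffectEstimates],
    data: Dataset | pd.DataFrame,
) -> np.ndarray:
    """Prediction with estimated random-effect offsets applied.

    Culms whose plot has no estimate use block-level effects only;
    culms in unknown blocks fall back to the mean response.
    """
    df = dataset_to_frame(data) if isinstance(data, Dataset) else data
    if effects is None:
        return predict_mean_response(fit, df)
    return predict_frame(fit.form, df, offsets=effects.offsets_for(fit.form, df))
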