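"""Sampling-strategy evaluation and leave-one-plot-out cross-validation.

The calibration experiment asks the applied question: if a field crew
can measure HCB on only m culms per plot (m = 1..8), which culms should
they pick, and how much prediction accuracy does calibration buy over
the fixed-effects mean response?  Four selection strategies are
compared — random, largest-DBH, closest-to-average-DBH and
smallest-DBH — with the random strategy replicated and averaged.

Model validation removes one plot at a time, refits the model on the
remaining plots, and pools predictions for the held-out plots ("LOOCV"
at plot level, matching the grouped data structure).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import (CalibrationSample, RandomEffectEstimates,
                          estimate_random_effects, predict_calibrated,
                          predict_mean_response)
from .model_forms import FitStatistics, ModelForm, fit_statistics
from .nlme_engine import NlmeFit, RandomEffectsSpec, VarianceFunction, fit_nlme
from .stand_data import CulmRecord, Dataset

__all__ = [
    "STRATEGIES",
    "StrategyResult",
    "LoocvResult",
    "select_culms",
    "run_strategy_experiment",
    "loocv",
    "plot_strategy_results",
]

STRATEGIES = ("random", "largest_dbh", "average_dbh", "smallest_dbh")
_DETERMINISTIC = {"largest_dbh", "average_dbh", "smallest_dbh"}


def select_culms(
    culms: Sequence[CulmRecord],
    strategy: str,
    m: int,
    rng: Optional[np.random.Generator] = None,
) -> list[CulmRecord]:
    """Select m culms from a plot under a sampling strategy.

    Deterministic strategies order by DBH (ties broken by culm id);
    ``average_dbh`` ranks by distance to the arithmetic plot mean DBH.
    """
    if m < 1 or m > len(culms):
        raise ValueError(f"cannot select {m} culms from a plot of {len(culms)}")
    if strategy == "random":
        if rng is None:
            raise ValueError("random strategy needs an rng")
        idx = rng.choice(len(culms), size=m, replace=False)
        return [culms[i] for i in sorted(idx)]
    if strategy == "largest_dbh":
        ranked = sorted(culms, key=lambda c: (-c.dbh, c.culm_id))
    elif strategy == "smallest_dbh":
        ranked = sorted(culms, key=lambda c: (c.dbh, c.culm_id))
    elif strategy == "average_dbh":
        mean_dbh = sum(c.dbh for c in culms) / len(culms)
        ranked = sorted(culms, key=lambda c: (abs(c.dbh - mean_dbh), c.culm_id))
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return ranked[:m]


@dataclass(frozen=True)
class StrategyResult:
    """Averaged calibration performance for one (strategy, m) cell."""

    strategy: str
    m: int
    mean_rmse: float
    mean_tre_abs: float
    mean_tre_sq: float
    baseline_rmse: float
    baseline_tre_abs: float
    reduction_rmse_pct: float
    reduction_tre_pct: float
    n_reps: int
    rmse_mc_se: float
    n_culms_evaluated: int


def _pooled_errors(fit, ds, samples_by_plot, eval_df):
    """Calibrate each plot independently and pool calibrated predictions."""
    preds = np.empty(len(eval_df))
    preds[:] = np.nan
    plots = eval_df["plot"].to_numpy()
    for plot_id, sample in samples_by_plot.items():
        eff = estimate_random_effects(fit, sample)
        rows = plots == plot_id
        preds[rows] = predict_calibrated(fit, eff, eval_df.loc[rows])
    return preds


def run_strategy_experiment(
    ds: Dataset | pd.DataFrame,
    fit: NlmeFit,
    strategies: Sequence[str] = STRATEGIES,
    m_range: Iterable[int] = range(1, 9),
    reps: int = 100,
    seed: int = 20230330,
    include_calibration_culms: bool = True,
) -> pd.DataFrame:
    """Run the strategy x sample-size calibration experiment.

    For each (strategy, m, replicate): per plot, select m culms, estimate
    that plot's random effects by EBLUP, predict HCB for all its culms
    (optionally excluding the m calibration culms), pool across plots and
    compute RMSE and both TRE conventions; replicate averages and the
    reduction versus the mean response on the identical evaluation set
    are reported.  Deterministic strategies run once.  Plots with fewer
    than m culms are excluded (with a warning) from both the calibrated
    and the baseline pool.
    """
    from .stand_data import dataset_to_frame
    if isinstance(ds, Dataset):
        dataset = ds
    else:
        raise TypeError("run_strategy_experiment needs a Dataset (plot structure required)")
    rng = np.random.default_rng(seed)
    m_range = list(m_range)

    plot_culms = {p.plot_id: [c for c in dataset.culms_of_plot(p.block_id, p.plot_id)
                              if c.hcb is not None]
                  for p in dataset.plots}
    plot_rec = {p.plot_id: p for p in dataset.plots}
    full_df = dataset_to_frame(dataset)
    full_df = full_df[full_df["hcb"].notna()].reset_index(drop=True)

    results = []
    for strategy in strategies:
        if strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {strategy!r}")
        n_reps = 1 if strategy in _DETERMINISTIC else reps
        for m in m_range:
            usable = [pid for pid, cs in plot_culms.items() if len(cs) >= m]
            dropped = sorted(set(plot_culms) - set(usable))
            if dropped:
                warnings.warn(f"m={m}: plots {dropped} have fewer than {m} culms; excluded",
                              stacklevel=2)
            rep_rmse, rep_tre_abs, rep_tre_sq = [], [], []
            eval_df_first = None
            for _ in range(n_reps):
                samples = {}
                eval_parts = []
                for pid in usable:
                    culms = plot_culms[pid]
                    chosen = select_culms(culms, strategy, m, rng)
                    samples[pid] = CalibrationSample(plot=plot_rec[pid], culms=chosen)
                    part = full_df[full_df["plot"] == pid]
                    if not include_calibration_culms:
                        chosen_ids = {c.culm_id for c in chosen}
                        part = part[~part["culm"].isin(chosen_ids)]
                    eval_parts.append(part)
                eval_df = pd.concat(eval_parts, ignore_index=True)
                preds = _pooled_errors(fit, dataset, samples, eval_df)
                obs = eval_df["hcb"].to_numpy(dtype=float)
                st = fit_statistics(obs, preds)
                rep_rmse.append(st.rmse)
                rep_tre_abs.append(st.tre_abs)
                rep_tre_sq.append(st.tre_sq)
                if eval_df_first is None:
                    eval_df_first = eval_df
            # baseline on the identical evaluation set (strategy-independent
            # when calibration culms are included)
            base_pred = predict_mean_response(fit, eval_df_first)
            base = fit_statistics(eval_df_first["hcb"].to_numpy(dtype=float), base_pred)
            mean_rmse = float(np.mean(rep_rmse))
            mean_tre_abs = float(np.mean(rep_tre_abs))
            mc_se = float(np.std(rep_rmse, ddof=1) / math.sqrt(n_reps)) if n_reps > 1 else 0.0
            results.append(StrategyResult(
                strategy=strategy, m=m,
                mean_rmse=mean_rmse,
                mean_tre_abs=mean_tre_abs,
                mean_tre_sq=float(np.mean(rep_tre_sq)),
                baseline_rmse=base.rmse,
                baseline_tre_abs=base.tre_abs,
                reduction_rmse_pct=100.0 * (base.rmse - mean_rmse) / base.rmse,
                reduction_tre_pct=100.0 * (base.tre_abs - mean_tre_abs) / base.tre_abs,
                n_reps=n_reps, rmse_mc_se=mc_se,
                n_culms_evaluated=len(eval_df_first),
            ))
    return pd.DataFrame([r.__dict__ for r in results])


@dataclass
class LoocvResult:
    """Per-fold and pooled statistics of leave-one-plot-out validation."""

    per_plot: pd.DataFrame
    pooled: FitStatistics
    n_folds: int
    n_failed: int


def loocv(
    ds: Dataset,
    form: ModelForm,
    re_spec: RandomEffectsSpec,
    varfun: Optional[VarianceFunction] = None,
    mode: str = "mean_response",
    **fit_kwargs,
) -> LoocvResult:
    """Leave-one-plot-out cross-validation of the NLME model.

    Each fold drops one plot, refits on the remainder, and predicts the
    held-out plot.  ``mean_response`` predicts with fixed effects only
    (the held-out plot's effect is unobservable); ``block_calibrated``
    additionally applies the block effects estimated from that block's
    retained plots (the fold fit's conditional modes).  Folds whose
    refit fails are skipped and counted.
    """
    if mode not in ("mean_response", "block_calibrated"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(ds.plots) < 3:
        raise ValueError("LOOCV needs at least 3 plots")
    from .stand_data import dataset_to_frame

    rows, obs_all, pred_all = [], [], []
    n_failed = 0
    for held in ds.plots:
        train_culms = [c for c in ds.culms if c.plot_id != held.plot_id]
        test_culms = [c for c in ds.culms
                      if c.plot_id == held.plot_id and c.hcb is not None]
        if not test_culms:
            continue
        train = Dataset(blocks=list(ds.blocks),
                        plots=[p for p in ds.plots if p.plot_id != held.plot_id],
                        culms=train_culms)
        try:
            fit = fit_nlme(train, form, re_spec, varfun=varfun, **fit_kwargs)
        except Exception as exc:  # noqa: BLE001 — a failed fold is reported, not fatal
            warnings.warn(f"fold {held.plot_id}: refit failed ({exc}); skipped",
                          stacklevel=2)
            n_failed += 1
            continue
        test = Dataset(blocks=list(ds.blocks), plots=[held], culms=test_culms)
        test_df = dataset_to_frame(test)
        if mode == "mean_response":
            pred = predict_mean_response(fit, test_df)
        else:
            eff = RandomEffectEstimates(
                block_effects={held.block_id: {
                    t: float(v) for t, v in zip(fit.block_terms,
                                                fit.u_block.get(held.block_id,
                                                                np.zeros(len(fit.block_terms))))}})
            pred = predict_calibrated(fit, eff, test_df)
        y = test_df["hcb"].to_numpy(dtype=float)
        st = fit_statistics(y, pred)
        rows.append({"plot": held.plot_id, "block": held.block_id, "n": st.n,
                     "md": st.md, "rmse": st.rmse, "r2": st.r2,
                     "tre_abs": st.tre_abs, "tre_sq": st.tre_sq})
        obs_all.append(y)
        pred_all.append(pred)
    if not obs_all:
        raise RuntimeError("all LOOCV folds failed")
    pooled = fit_statistics(np.concatenate(obs_all), np.concatenate(pred_all))
    return LoocvResult(per_plot=pd.DataFrame(rows), pooled=pooled,
                       n_folds=len(rows), n_failed=n_failed)


def plot_strategy_results(table: pd.DataFrame, path=None):
    """Line chart of mean RMSE and TRE against calibration sample size m,
    one line per strategy, with the mean-response baseline dashed."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9.0, 3.6), sharex=True)
    for ax, col, base_col, label in (
            (axes[0], "mean_rmse", "baseline_rmse", "RMSE (m)"),
            (axes[1], "mean_tre_abs", "baseline_tre_abs", "TRE (%)")):
        for strategy, g in table.groupby("strategy"):
            g = g.sort_values("m")
            ax.plot(g["m"], g[col], marker="o", ms=3, label=strategy)
        base = table.sort_values("m").groupby("m")[base_col].mean()
        ax.plot(base.index, base.to_numpy(), "k--", lw=1, label="mean response")
        ax.set_xlabel("calibration sample size m")
        ax.set_ylabel(label)
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
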