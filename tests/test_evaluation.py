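"""Sampling-strategy experiment and leave-one-plot-out validation."""

import numpy as np
import pytest

from bamboohcb import (SyntheticConfig, VarianceFunction, generate_dataset,
                       loocv, m3ext, run_strategy_experiment, select_culms,
                       truth_fit)
from bamboohcb.nlme_engine import DEFAULT_RE_STRUCTURE
from bamboohcb.stand_data import CulmRecord


def _culms(dbhs):
    return [CulmRecord("A", "P", f"c{k}", dbh=float(d), h=10.0, hcb=5.0)
            for k, d in enumerate(dbhs)]


def test_select_culms_strategies_deterministic():
    culms = _culms([8.0, 12.0, 10.0, 11.0, 9.0])
    assert [c.dbh for c in select_culms(culms, "largest_dbh", 2)] == [12.0, 11.0]
    assert [c.dbh for c in select_culms(culms, "smallest_dbh", 2)] == [8.0, 9.0]
    # plot mean dbh = 10.0 -> closest first, ties by culm id
    assert [c.dbh for c in select_culms(culms, "average_dbh", 3)] == [10.0, 11.0, 9.0]
    rng = np.random.default_rng(0)
    picked = select_culms(culms, "random", 3, rng)
    assert len({c.culm_id for c in picked}) == 3
    with pytest.raises(ValueError):
        select_culms(culms, "random", 6, rng)
    with pytest.raises(ValueError):
        select_culms(culms, "median_dbh", 2)


@pytest.fixture(scope="module")
def stand_and_fit():
    cfg = SyntheticConfig()
    return generate_dataset(cfg, seed=101), truth_fit(cfg)


def test_strategy_experiment_monotone_and_beats_baseline(stand_and_fit):
    """Mean RMSE of random calibration is non-increasing in m (up to MC
    noise) and random/largest/average all beat the mean response at m = 4."""
    ds, fit = stand_and_fit
    tab = run_strategy_experiment(ds, fit, m_range=range(1, 9), reps=12, seed=5)
    rand = tab[tab["strategy"] == "random"].sort_values("m")
    rmse = rand["mean_rmse"].to_numpy()
    slack = 3 * rand["rmse_mc_se"].to_numpy()[1:]
    assert np.all(np.diff(rmse) <= slack)          # no significant increase
    assert rmse[-1] < rmse[0]                      # and a real overall decrease
    at4 = tab[tab["m"] == 4].set_index("strategy")
    for s in ("random", "largest_dbh", "average_dbh"):
        assert at4.loc[s, "mean_rmse"] < at4.loc[s, "baseline_rmse"]
        assert at4.loc[s, "reduction_rmse_pct"] > 0
    # deterministic strategies run once
    assert (tab[tab["strategy"] != "random"]["n_reps"] == 1).all()


def test_strategy_experiment_reproducible(stand_and_fit):
    ds, fit = stand_and_fit
    a = run_strategy_experiment(ds, fit, strategies=("random",),
                                m_range=[2, 4], reps=5, seed=9)
    b = run_strategy_experiment(ds, fit, strategies=("random",),
                                m_range=[2, 4], reps=5, seed=9)
    assert a.equals(b)
    c = run_strategy_experiment(ds, fit, strategies=("random",),
                                m_range=[2, 4], reps=5, seed=10)
    assert not np.allclose(a["mean_rmse"], c["mean_rmse"])


def test_saturated_noiseless_calibration_recovers_exactly():
    """With zero residual variance and the full plot in the sample, the
    calibrated model reproduces observed HCB almost exactly."""
    cfg = SyntheticConfig(n_blocks=2, plot_allocation=(2, 2),
                          measured_fraction=0.08,
                          resid_sd_at_mean_h=1e-6)
    ds = generate_dataset(cfg, seed=23)
    fit = truth_fit(cfg)
    m_full = min(len(ds.culms_of_plot(p.block_id, p.plot_id)) for p in ds.plots)
    tab = run_strategy_experiment(ds, fit, strategies=("largest_dbh",),
                                  m_range=[m_full], reps=1, seed=1)
    assert tab["mean_rmse"].iloc[0] < 1e-3
    assert tab["baseline_rmse"].iloc[0] > tab["mean_rmse"].iloc[0]


def test_strategy_baseline_uses_identical_evaluation_set(stand_and_fit):
    ds, fit = stand_and_fit
    tab = run_strategy_experiment(ds, fit, strategies=("largest_dbh",),
                                  m_range=[3], reps=1, seed=2,
                                  include_calibration_culms=False)
    row = tab.iloc[0]
    n_expected = ds.n_culms - 3 * len(ds.plots)
    assert row["n_culms_evaluated"] == n_expected
    assert row["reduction_rmse_pct"] == pytest.approx(
        100 * (row["baseline_rmse"] - row["mean_rmse"]) / row["baseline_rmse"])


@pytest.fixture(scope="module")
def loocv_stand():
    cfg = SyntheticConfig(n_blocks=2, plot_allocation=(3, 3),
                          measured_fraction=0.1)
    return cfg, generate_dataset(cfg, seed=77)


def test_loocv_folds_and_optimism(loocv_stand):
    """One fold per plot; pooled held-out RMSE is no better than the
    in-sample RMSE of the full-data fit."""
    cfg, ds = loocv_stand
    from bamboohcb import fit_nlme
    res = loocv(ds, m3ext(), DEFAULT_RE_STRUCTURE)
    assert res.n_folds == len(ds.plots)
    assert res.n_failed == 0
    assert set(res.per_plot["plot"]) == {p.plot_id for p in ds.plots}
    full = fit_nlme(ds, m3ext(), DEFAULT_RE_STRUCTURE)
    assert res.pooled.rmse >= full.stats.rmse - 1e-6


def test_loocv_zero_noise_predicts_held_out_plots(loocv_stand):
    cfg, _ = loocv_stand
    quiet = SyntheticConfig(n_blocks=2, plot_allocation=(3, 3),
                            measured_fraction=0.1,
                            psi_block_var=(0.0, 0.0), psi_block_corr=0.0,
                            var_plot=0.0, resid_sd_at_mean_h=1e-7)
    ds = generate_dataset(quiet, seed=78)
    res = loocv(ds, m3ext(), DEFAULT_RE_STRUCTURE)
    assert res.pooled.rmse < 1e-3


def test_loocv_block_calibrated_mode(loocv_stand):
    cfg, ds = loocv_stand
    res = loocv(ds, m3ext(), DEFAULT_RE_STRUCTURE, mode="block_calibrated")
    assert res.n_folds == len(ds.plots)
    assert np.isfinite(res.pooled.rmse)


def test_loocv_requires_three_plots():
    cfg = SyntheticConfig(n_blocks=1, plot_allocation=(2,), measured_fraction=0.1)
    ds = generate_dataset(cfg, seed=1)
    with pytest.raises(ValueError, match="3 plots"):
        loocv(ds, m3ext(), DEFAULT_RE_STRUCTURE)


def test_plot_helper_writes_figure(tmp_path, stand_and_fit):
    from bamboohcb.evaluation import plot_strategy_results
    ds, fit = stand_and_fit
    tab = run_strategy_experiment(ds, fit, strategies=("largest_dbh",),
                                  m_range=[1, 2], reps=1, seed=1)
    out = tmp_path / "strategies.png"
    plot_strategy_results(tab, out)
    assert out.stat().st_size > 0
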