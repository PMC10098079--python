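"""EBLUP calibration: fixed points, shrinkage, linear-model oracle."""

import math

import numpy as np
import pytest

from bamboohcb import (CalibrationSample, CulmRecord, PlotRecord,
                       RandomEffectEstimates, SyntheticConfig,
                       dataset_to_frame, estimate_random_effects,
                       generate_calibration_truth, predict_calibrated,
                       predict_mean_response, truth_fit)
from bamboohcb.nlme_engine import ResidualModel, VarianceFunction

from conftest import make_noise_free_dataset


REPORTED_BETA = (0.8407, -0.07922, -0.0020, -0.3440)


def _sample(ds, plot_id, m):
    plot = next(p for p in ds.plots if p.plot_id == plot_id)
    culms = ds.culms_of_plot(plot.block_id, plot_id)[:m]
    return CalibrationSample(plot=plot, culms=culms)


def test_mean_response_at_stand_mean_covariates():
    fit = truth_fit(SyntheticConfig())
    import pandas as pd
    df = pd.DataFrame([{"block": "A", "plot": "P", "dbh": 10.38, "h": 12.16,
                        "bal": 23.44, "cd": 0.65}])
    assert predict_mean_response(fit, df)[0] == pytest.approx(6.842, abs=5e-4)


def test_zero_residuals_give_zero_effects():
    """Observed HCB exactly at the mean response is the u = 0 fixed point."""
    fit = truth_fit(SyntheticConfig())
    ds = make_noise_free_dataset(REPORTED_BETA, n=6, seed=1)
    eff = estimate_random_effects(fit, CalibrationSample(plot=ds.plots[0],
                                                         culms=ds.culms))
    for d in (*eff.block_effects.values(), *eff.plot_effects.values()):
        for v in d.values():
            assert abs(v) < 1e-10


def test_prior_shrinkage_limit():
    """Scaling the prior covariance to zero drives the estimates to zero
    monotonically in norm."""
    cfg = SyntheticConfig()
    ds, _ = generate_calibration_truth(cfg, seed=13)
    base = truth_fit(cfg)
    norms = []
    for eps in (1.0, 1e-1, 1e-2, 1e-3, 1e-4):
        fit = truth_fit(cfg)
        fit.psi_block = base.psi_block * eps
        fit.psi_plot = base.psi_plot * eps
        eff = estimate_random_effects(fit, _sample(ds, ds.plots[0].plot_id, 6))
        u = [v for d in (*eff.block_effects.values(), *eff.plot_effects.values())
             for v in d.values()]
        norms.append(np.linalg.norm(u))
    assert all(a >= b for a, b in zip(norms, norms[1:]))
    assert norms[-1] < 1e-4 * norms[0] * 10


def test_iterated_eblup_equals_closed_form_blup_on_linear_toy():
    """When the model is replaced by its tangent plane the fixed point is
    the closed-form linear BLUP  Psi Z' (R + Z Psi Z')^{-1} e, reached in
    one step and exactly."""
    rng = np.random.default_rng(8)
    cfg = SyntheticConfig()
    fit = truth_fit(cfg)
    # a linear "form": hcb = x (identity link), achieved by a stub
    class LinearForm:
        designation = "M3ext"
        terms = ("1", "dbh", "bal", "cd")
        beta = np.asarray(cfg.true_beta)
        has_shape = False
        def value(self, h, x):
            return x
        def dvalue_dx(self, h, x):
            return np.ones_like(x)
    fit.form = LinearForm()
    fit.beta = np.asarray(cfg.true_beta)

    plot = PlotRecord("P1", "A", cd=0.6)
    culms = []
    for k in range(4):
        d = float(rng.uniform(7, 13))
        culms.append(CulmRecord("A", "P1", f"c{k}", dbh=d, h=10.0,
                                hcb=float(rng.uniform(1, 5)), bal=float(rng.uniform(0, 8)),
                                rd=1.0))
    sample = CalibrationSample(plot=plot, culms=culms)
    eff = estimate_random_effects(fit, sample)
    one = estimate_random_effects(fit, sample, one_step=True)

    # closed-form BLUP with Z = raw covariate columns (identity link)
    X = np.array([[1.0, c.dbh, c.bal, 0.6] for c in culms])
    y = np.array([c.hcb for c in culms])
    e = y - X @ fit.beta
    Z = np.column_stack([X[:, 0], X[:, 1], X[:, 1]])  # u1, u2_block, u2_plot
    Psi = np.zeros((3, 3))
    Psi[:2, :2] = fit.psi_block
    Psi[2, 2] = fit.psi_plot[0, 0]
    R = np.diag(fit.residual.sd(np.full(4, 10.0)) ** 2)
    u = Psi @ Z.T @ np.linalg.solve(R + Z @ Psi @ Z.T, e)

    got = np.array([eff.block_effects["A"]["1"], eff.block_effects["A"]["dbh"],
                    eff.plot_effects["P1"]["dbh"]])
    got1 = np.array([one.block_effects["A"]["1"], one.block_effects["A"]["dbh"],
                     one.plot_effects["P1"]["dbh"]])
    assert np.max(np.abs(got - u)) < 1e-10
    assert np.max(np.abs(got1 - u)) < 1e-10
    # linearity: doubling the residuals doubles the estimates (one-step mode)
    for c in culms:
        c.hcb = float(c.hcb + e[culms.index(c)])  # y' = y + e  =>  e' = 2e
    two = estimate_random_effects(fit, CalibrationSample(plot=plot, culms=culms),
                                  one_step=True)
    got2 = np.array([two.block_effects["A"]["1"], two.block_effects["A"]["dbh"],
                     two.plot_effects["P1"]["dbh"]])
    assert np.max(np.abs(got2 - 2 * u)) < 1e-10


def test_zero_effects_prediction_equals_mean_response():
    cfg = SyntheticConfig()
    ds, _ = generate_calibration_truth(cfg, seed=3)
    fit = truth_fit(cfg)
    df = dataset_to_frame(ds)
    zero = RandomEffectEstimates(
        block_effects={b: {"1": 0.0, "dbh": 0.0} for b in ds.blocks},
        plot_effects={p.plot_id: {"dbh": 0.0} for p in ds.plots})
    assert np.allclose(predict_calibrated(fit, zero, df),
                       predict_mean_response(fit, df))
    # and culms outside any calibrated block also fall back to mean response
    only_b1 = RandomEffectEstimates(block_effects={"B1": {"1": 0.5}})
    pred = predict_calibrated(fit, only_b1, df)
    outside = df["block"] != "B1"
    assert np.allclose(pred[outside], predict_mean_response(fit, df[outside]))
    assert not np.allclose(pred[~outside], predict_mean_response(fit, df[~outside]))


def test_eblup_shrinkage_and_unbiasedness_across_plots():
    """Across many plots: estimates average ~0, their variance stays below
    the prior variance, and they correlate positively with the truth."""
    cfg = SyntheticConfig()
    ds, truth = generate_calibration_truth(cfg, seed=17)
    fit = truth_fit(cfg)
    est_plot, true_plot = [], []
    for p in ds.plots:
        eff = estimate_random_effects(fit, _sample(ds, p.plot_id, 8))
        est_plot.append(eff.plot_effects[p.plot_id]["dbh"])
        row = truth[(truth["level"] == "plot") & (truth["plot"] == p.plot_id)]
        true_plot.append(float(row["u_dbh"].iloc[0]))
    est_plot, true_plot = np.array(est_plot), np.array(true_plot)
    n = len(est_plot)
    assert abs(est_plot.mean()) < 3 * math.sqrt(cfg.var_plot / n)
    assert est_plot.var() <= cfg.var_plot
    assert np.corrcoef(est_plot, true_plot)[0, 1] > 0.0


def test_stacked_samples_share_block_effect():
    cfg = SyntheticConfig()
    ds, _ = generate_calibration_truth(cfg, seed=19)
    fit = truth_fit(cfg)
    b1_plots = [p for p in ds.plots if p.block_id == "B1"][:3]
    samples = [_sample(ds, p.plot_id, 4) for p in b1_plots]
    eff = estimate_random_effects(fit, samples)
    assert set(eff.block_effects) == {"B1"}
    assert set(eff.plot_effects) == {p.plot_id for p in b1_plots}
    with pytest.raises(ValueError, match="share one block"):
        other = next(p for p in ds.plots if p.block_id == "B2")
        estimate_random_effects(fit, samples + [_sample(ds, other.plot_id, 4)])
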