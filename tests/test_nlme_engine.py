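"""Two-level NLME engine: degenerate limits, oracle agreement, selection."""

import math

import numpy as np
import pandas as pd
import pytest

from bamboohcb import (Dataset, CulmRecord, PlotRecord, SyntheticConfig,
                       VarianceFunction, compare_variance_functions,
                       dataset_to_frame, derive_covariates, fit_nlme, fit_ols,
                       generate_dataset, m3ext, marginal_loglik,
                       select_random_effects_structure)
from bamboohcb.nlme_engine import DEFAULT_RE_STRUCTURE, NlmeFit, RandomEffectsSpec

from oracles import quadrature_loglik, tiny_mixed_instance


def test_loglik_matches_quadrature_oracle():
    """The engine's linearized marginal log-likelihood agrees with exact
    numerical integration over all three random effects on a 12-culm toy."""
    ds, beta, psi_b, var_plot, sigma2, gamma = tiny_mixed_instance()
    ll_eng = marginal_loglik(ds, m3ext(beta), DEFAULT_RE_STRUCTURE, beta,
                             psi_b, np.array([[var_plot]]), sigma2,
                             VarianceFunction.exponential(gamma))
    ll_exact = quadrature_loglik(ds, beta, psi_b, var_plot, sigma2, gamma)
    assert abs(ll_eng - ll_exact) < 0.1


def test_zero_variance_hierarchy_collapses_to_ols():
    """Data generated without any group effects: the NLME fixed effects
    match nonlinear least squares and the variance estimates hit zero."""
    cfg = SyntheticConfig(n_blocks=3, plot_allocation=(3, 3, 3),
                          measured_fraction=0.14,
                          psi_block_var=(0.0, 0.0), psi_block_corr=0.0,
                          var_plot=0.0, resid_sd_at_mean_h=0.5, resid_gamma=0.0)
    ds = generate_dataset(cfg, seed=7)
    ols = fit_ols(ds, m3ext())
    fit = fit_nlme(ds, m3ext(), DEFAULT_RE_STRUCTURE)
    assert np.max(np.abs(fit.beta - ols.form.beta)) < 1e-4
    assert fit.boundary  # variances pinned at the lower bound
    assert np.all(np.diag(fit.psi_block) < 1e-4)
    assert fit.var_plot < 1e-5
    assert fit.stats.rmse == pytest.approx(ols.stats.rmse, abs=1e-4)


def test_marginal_ll_dominates_pinned_variances(small_stand):
    """ML over the variance components can only improve on the nested
    zero-variance (pure NLS) model."""
    fit = fit_nlme(small_stand, m3ext(), DEFAULT_RE_STRUCTURE)
    ols = fit_ols(small_stand, m3ext())
    df = dataset_to_frame(small_stand)
    n = int(df["hcb"].notna().sum())
    sigma2_ols = (ols.stats.rmse ** 2)
    ll_pinned = marginal_loglik(small_stand, ols.form, DEFAULT_RE_STRUCTURE,
                                ols.form.beta, np.eye(2) * 1e-12,
                                np.array([[1e-12]]), sigma2_ols,
                                VarianceFunction.none())
    assert fit.ll >= ll_pinned - 1e-6


def test_aic_bookkeeping_one_extra_variance_parameter(small_stand):
    """AIC = -2 LL + 2 k with k counting fixed effects and all
    variance-covariance parameters; one extra parameter costs exactly 2."""
    f0 = fit_nlme(small_stand, m3ext(), DEFAULT_RE_STRUCTURE,
                  varfun=VarianceFunction.none())
    f1 = fit_nlme(small_stand, m3ext(), DEFAULT_RE_STRUCTURE,
                  varfun=VarianceFunction.exponential())
    for f in (f0, f1):
        k = len(f.beta) + f.n_varcov_params
        assert f.aic == pytest.approx(-2.0 * f.ll + 2.0 * k, abs=1e-8)
    assert f1.n_varcov_params == f0.n_varcov_params + 1
    assert (f1.aic - f0.aic) == pytest.approx(-2.0 * (f1.ll - f0.ll) + 2.0, abs=1e-8)


def test_structure_selection_recovers_generating_placement():
    cfg = SyntheticConfig(measured_fraction=0.17)
    ds = generate_dataset(cfg, seed=31)
    cands = [DEFAULT_RE_STRUCTURE,
             RandomEffectsSpec({"1": {"plot"}}),
             RandomEffectsSpec({"bal": {"block"}}),
             RandomEffectsSpec({"1": {"block"}, "dbh": {"block"}})]
    table = select_random_effects_structure(ds, m3ext(), cands)
    assert table.loc[table["best"], "structure"].iloc[0] == DEFAULT_RE_STRUCTURE.describe()
    assert table["aic"].notna().all() and table["ll"].notna().all()


def test_structure_selection_single_candidate(small_stand):
    table = select_random_effects_structure(small_stand, m3ext(),
                                            [DEFAULT_RE_STRUCTURE])
    assert table["best"].iloc[0]


def test_variance_function_selection_generative_match():
    """Strongly height-dependent residual noise: the exponential variance
    function attains the best AIC; on truly homoscedastic residuals the
    unweighted model stays within 2 AIC of every competitor."""
    het = SyntheticConfig(measured_fraction=0.17, resid_gamma=-0.08,
                          resid_sd_at_mean_h=1.141)
    tab = compare_variance_functions(generate_dataset(het, seed=21), m3ext())
    tab = tab.set_index("variance_function")
    assert tab.loc["exponential", "best"]
    assert tab.loc["none", "aic"] > tab.loc["exponential", "aic"] + 10

    hom = SyntheticConfig(measured_fraction=0.17, resid_gamma=0.0,
                          resid_sd_at_mean_h=0.5,
                          psi_block_var=(0.0, 0.0), psi_block_corr=0.0,
                          var_plot=0.0)
    tab0 = compare_variance_functions(generate_dataset(hom, seed=22), m3ext())
    best_aic = tab0["aic"].min()
    assert tab0.set_index("variance_function").loc["none", "aic"] <= best_aic + 2.0


def test_fitted_variance_function_whitens_residuals():
    """Standardized residuals from the fitted exponential variance function
    show no height trend on data generated under that variance model."""
    cfg = SyntheticConfig(measured_fraction=0.17, resid_gamma=-0.08,
                          resid_sd_at_mean_h=1.141)
    ds = generate_dataset(cfg, seed=40)
    fit = fit_nlme(ds, m3ext(), DEFAULT_RE_STRUCTURE,
                   varfun=VarianceFunction.exponential())
    df = dataset_to_frame(ds)
    from bamboohcb.calibration import RandomEffectEstimates, predict_calibrated
    eff = RandomEffectEstimates(
        block_effects={b: dict(zip(fit.block_terms, v)) for b, v in fit.u_block.items()},
        plot_effects={p: dict(zip(fit.plot_terms, v)) for p, v in fit.u_plot.items()})
    resid = df["hcb"].to_numpy(float) - predict_calibrated(fit, eff, df)
    z = resid / fit.residual.sd(df["h"].to_numpy(float))
    corr = np.corrcoef(np.abs(z), df["h"].to_numpy(float))[0, 1]
    assert abs(corr) < 0.12


def test_fit_report_json_round_trip(tmp_path, small_stand):
    fit = fit_nlme(small_stand, m3ext(), DEFAULT_RE_STRUCTURE,
                   varfun=VarianceFunction.exponential())
    path = tmp_path / "fit.json"
    fit.to_json(path)
    back = NlmeFit.from_json(path)
    assert np.allclose(back.beta, fit.beta)
    assert np.allclose(back.psi_block, fit.psi_block)
    assert back.residual.varfun.kind == "exponential"
    assert back.ll == pytest.approx(fit.ll)
    for b in fit.u_block:
        assert np.allclose(back.u_block[b], fit.u_block[b])
    assert "logLik" in back.summary()


def test_shape_parameter_forms_rejected(small_stand):
    from bamboohcb.model_forms import ModelForm
    with pytest.raises(NotImplementedError):
        fit_nlme(small_stand, ModelForm("M4", ("1", "dbh", "bal")),
                 DEFAULT_RE_STRUCTURE)
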