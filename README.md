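# bamboohcb

Two-level nonlinear mixed-effects modelling of **height to crown base
(HCB)** for moso bamboo (*Phyllostachys edulis*) stands — candidate model
screening, hierarchical random-effects estimation with residual variance
functions, EBLUP response calibration under alternative field sampling
strategies, plot-level cross-validation, and a seeded synthetic stand
generator.

## The problem

HCB — the height from the ground to the first living branch of a culm —
drives crown-ratio, stem-utilization and carbon accounting calculations,
but is slow and costly to measure in dense bamboo stands. A predictive
model lets a crew measure DBH and total height (cheap) and infer HCB.
Bamboo inventory data are nested (culms within 20 × 20 m sample plots
within blocks), so ordinary least squares understates uncertainty and
misses stand-to-stand differences; a mixed-effects model with random
effects at both grouping levels addresses this, and a handful of locally
measured culms can *localize* the model to a new plot.

## The model

For culm *k* in plot *j* of block *i*:

```
HCB_ijk = H_ijk / (1 + exp(x_ijk)) + ξ_ijk
x_ijk   = (β₁ + μ₁ᵢ) + (β₂ + μ₂ᵢ + μ₂ᵢⱼ)·DBH_ijk + β₃·BAL_ijk + β₄·CD_ij
```

* `H` total height (m), `DBH` diameter at breast height (cm),
  `BAL` basal area of larger culms in the plot (m² ha⁻¹, a one-sided
  competition index), `CD` plot canopy density (0–1].
* Block effects `(μ₁ᵢ, μ₂ᵢ) ~ N(0, Ψ_b)` (correlated), plot effects
  `μ₂ᵢⱼ ~ N(0, σ²_plot)`.
* Heteroscedastic residuals `Var(ξ) = σ²·exp(2γH)` (exponential variance
  function; power and constant-plus-power alternatives are provided).

The logistic link keeps predictions strictly inside (0, H). Estimation is
maximum likelihood via the Lindstrom–Bates alternating algorithm
(penalized nonlinear least squares for `(β, μ)`; a profiled linear
mixed-effects step for the variance parameters). Random effects for a new
plot are predicted from m measured culms by iterated EBLUP,

```
û = Ψ̂ Zᵀ (R̂ + Z Ψ̂ Zᵀ)⁻¹ [y − f(β̂, u*) + Z u*],
```

iterated to its fixed point in `u*`, with `Z` the matrix of partial
derivatives of the model with respect to each random effect.

## Worked example

No stand inventory ships with the package; the synthetic generator
reproduces the design it is calibrated to (5 blocks, 38 plots of 400 m²,
~1 370 culms, DBH ≈ 10.4 ± 1.6 cm, H ≈ 12.2 ± 2.0 m) and draws HCB from
the two-level model above.

```python
import numpy as np
import bamboohcb as bb

cfg = bb.SyntheticConfig()                      # study-design defaults
ds  = bb.generate_dataset(cfg, seed=7)          # 1411 culms, 38 plots, 5 blocks

fit = bb.fit_nlme(ds, bb.m3ext(), bb.DEFAULT_RE_STRUCTURE,
                  varfun=bb.VarianceFunction.exponential())
print(fit.summary())
```

```
Two-level NLME fit: M3ext on terms ('1', 'dbh', 'bal', 'cd')
  observations: 1411  blocks: 5  plots: 38
  random effects: 1->block; dbh->block+plot
  fixed effects: 1=0.91949, dbh=-0.078676, bal=-0.00094748, cd=-0.4443
  ...
  sigma2: 1.5572  variance function: exponential (-0.008744059400673,)
  logLik: -2204.32  AIC: 4428.64  converged: True  (boundary)
```

The refit recovers the generating fixed effects (0.8407, −0.07922,
−0.0020, −0.3440) up to the sampling noise of a 5-block design.
Calibrating one plot from four randomly chosen culms and comparing with
the fixed-effects-only "mean response":

```python
p = ds.plots[0]
culms = ds.culms_of_plot(p.block_id, p.plot_id)
rng = np.random.default_rng(1)
pick = [culms[i] for i in rng.choice(len(culms), 4, replace=False)]
eff = bb.estimate_random_effects(fit, bb.CalibrationSample(plot=p, culms=pick))

tab = bb.run_strategy_experiment(ds, fit, reps=30, seed=42)
print(tab[tab.m == 4][["strategy", "mean_rmse", "baseline_rmse",
                       "reduction_rmse_pct"]])
```

```
    strategy  m  mean_rmse  baseline_rmse  reduction_rmse_pct
      random  4   1.170488        1.23763            5.424998
 largest_dbh  4   1.144622        1.23763            7.514988
 average_dbh  4   1.168505        1.23763            5.585221
smallest_dbh  4   1.198552        1.23763            3.157496
```

Four measured culms per plot already cut the pooled prediction RMSE by
several percent relative to the mean response, with the smallest-DBH
strategy consistently the weakest — the qualitative pattern that
motivates calibrating with a few random culms in practice. (The
improvement on this synthetic stand is smaller than on real stands,
whose block/plot effects are stronger relative to residual noise.)

The same stages are scriptable from a shell:

```
bamboohcb simulate --seed 7 --out stand.csv
bamboohcb fit --data stand.csv --out fit.json
bamboohcb evaluate-strategies --data stand.csv --fit fit.json --reps 100 --out strategies.csv
bamboohcb loocv --data stand.csv --out loocv.json
```

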