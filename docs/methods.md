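# Methods

## Model

Height to crown base of culm *k* in plot *j* of block *i* is modelled as

    hcb = h / (1 + exp(x)) + ξ,
    x   = (β₁ + μ₁ᵢ) + (β₂ + μ₂ᵢ + μ₂ᵢⱼ)·dbh + β₃·bal + β₄·cd.

The logistic link bounds predictions in (0, h), which matches the
physical constraint that a living crown base sits between the ground and
the tip. Six classical HCB forms (exponential and logistic families,
`M1`–`M6`) are implemented for screening; the three-parameter logistic
(`M3`) extended with canopy density (`M3ext`) is the working model. Two
of the printed screening forms are ambiguous as commonly typeset; we fix
one reading and keep it stable: `M2` is `h(1 − exp(x)²) = h(1 − exp(2x))`
(which explains why `M1` and `M2` tie exactly after rescaling β), and
`M4`'s exponent is read as `h(1 + c·exp(x))^(−1/m)` so that its range is
(0, h). `M5` applies its power parameter `W` to each non-intercept
covariate; `M6` is `h(a + exp(x))`. Shape-parameter forms are available
for nonlinear least squares only; the mixed-effects engine requires a
form whose only parameters are linear-predictor coefficients.

Random-effect placement is configurable per coefficient and level
(`RandomEffectsSpec`); the default places the intercept at block level
and the DBH slope at block and plot level, the structure that wins the
AIC comparison on data of this design. Block effects are jointly normal
with full covariance Ψ_b; plot effects are independent with covariance
Ψ_p (scalar in the default structure). Residuals are independent
(within-plot correlation is fixed to the identity) with variance
σ²·w(h)², where the variance function w is one of

    none             w = 1
    exponential      w = exp(γh)
    power            w = h^γ
    constant_power   w = |γ₁ + h^γ₂|

## Estimation

`fit_nlme` maximizes the marginal ML likelihood by the Lindstrom–Bates
alternation:

1. **PNLS step.** With variance parameters fixed, minimize
   Σ (y − f)²/w² + Σ uᵀD⁻¹u over (β, u), where D are the covariances
   relative to σ². The penalty rows are whitened by the inverse Cholesky
   factors, the Jacobian is analytic, and the solution's u are the
   conditional modes.
2. **LME step.** Linearize f about the current (β, u) and maximize the
   marginal likelihood of the resulting linear mixed model over the
   variance parameters. β and σ² are profiled out analytically; the
   remaining parameters (log-Cholesky factors of the relative
   covariances plus the variance-function parameters) are optimized by
   L-BFGS-B with finite-difference gradients. Per-block covariance
   algebra uses the Woodbury identity — `M = W + (ZL)(ZL)ᵀ` with `W`
   diagonal and `ZL` of rank q_block + n_plots·q_plot — so one
   likelihood evaluation is O(n·q²).

The outer loop stops when the maximum relative parameter change falls
below 1e−6 or the log-likelihood is flat to 1e−7 relative (parameters
can chatter harmlessly when a variance sits on its boundary), with a cap
of 200 outer iterations. Log-Cholesky diagonals are bounded below at
e⁻¹³ relative scale; estimates at that floor are flagged `boundary`,
which is the expected outcome when a true variance is zero. The reported
log-likelihood is the linearization-based marginal ML value — the same
approximation the algorithm maximizes — and on a 12-observation instance
it agrees with exact Gauss–Hermite integration over all three random
effects to better than 0.01 (the test suite carries that oracle). AIC
counts fixed effects, all covariance entries, σ² and the
variance-function parameters; the count is part of the fit report so
comparisons are self-consistent.

REML, crossed random effects, more than two grouping levels and
non-identity within-plot correlation are out of scope.

## Calibration (EBLUP)

`estimate_random_effects` iterates

    û = Ψ̂ Zᵀ (R̂ + Z Ψ̂ Zᵀ)⁻¹ [y − f(β̂, u*) + Z u*]

from u* = 0, recomputing Z (analytic partials of the logistic model with
respect to each random effect) and the adjusted residual at the current
u* each pass, until ‖Δu‖∞ < 1e−8 (at most 50 passes); a one-step mode
reproduces the single-pass convention. R̂ evaluates the fitted variance
function at the subsample heights. When one plot is calibrated, its
block's two effects and its plot effect are predicted jointly (q = 3)
from the same subsample; samples from several plots of one block can be
stacked so the block effect is shared. Predictions fall back to
block-level effects for uncalibrated plots and to the fixed-effects mean
response outside calibrated blocks.

The sampling-strategy experiment draws m = 1..8 culms per plot under
four strategies (random, largest DBH, closest-to-plot-mean DBH, smallest
DBH), calibrates each plot, and pools errors over all culms of each
plot. Including the m calibration culms in the evaluation set is the
default (a flag restricts evaluation to the unmeasured culms); the mean
response baseline is always computed on the identical evaluation set.
The random strategy is replicated (default 100×) and averaged with its
Monte-Carlo standard error reported; the deterministic strategies run
once. Cross-validation is leave-one-*plot*-out: each fold refits the
model without one plot and predicts it by mean response (default) or
with the fold's block-level conditional modes (`block_calibrated`).

## Synthetic stand generator

The generator emulates an intensively measured moso-bamboo inventory: 5
blocks carrying (8, 8, 8, 7, 7) plots of 400 m²; per-plot stand density
from a truncated normal (mean 2 783, sd 853, bounds 1 150–3 750
culms ha⁻¹) kept as a plot descriptor; per-culm DBH from a truncated
normal (10.38, 1.57; [5.0, 15.6]) cm; total height from a power
allometry h = a·dbh^b + ε whose (a, b, sd_ε) are solved by quadrature so
the H marginal hits mean 12.16 m, sd 2.01 m and an H–DBH correlation of
0.6 (configurable — the joint law is not observable from marginal
summaries); canopy density uniform on [0.4, 0.87] per plot. HCB is drawn
from the two-level model with fixed effects (0.8407, −0.07922, −0.0020,
−0.3440), block covariance diag(1.17e−2, 5.84e−5) with correlation
−0.529, plot variance 2.13e−4, and exponential residual variance with
γ = −0.0179 anchored so the residual sd at mean height is √1.3017 ≈
1.14 m (anchoring by the sd at a reference height keeps the noise level
in interpretable units regardless of γ). Generated HCB is clamped to
(0.05h, 0.98h); clamp events are counted and stay below 1 % under the
defaults.

Known departures from real inventories, and hence limits on what passing
tests demonstrate:

* Only ~34 % of standing culms enter the measured dataset
  (`measured_fraction`), giving ~36 culms per plot (~1 370 total) —
  matching measured-stand sizes — while BA/BAL are derived from the
  measured culms with the plain per-hectare expansion 10000/area. Real
  full-stand BAL magnitudes are therefore ~3× larger than the synthetic
  ones; since the BAL coefficient is −0.0020, the effect on mean HCB is
  ≈0.04 on the x-scale (≈0.1 m) and is absorbed in the stochastic
  tolerances of the consistency checks.
* Covariate laws are common across blocks; block differences are carried
  entirely by the random effects. No spatial culm placement, no
  on-year/off-year age dynamics, and plot canopy density is independent
  of stand density.
* Because the generator's block/plot variances are the (small) reported
  ones, calibration gains on synthetic stands (~2–8 % RMSE reduction)
  are smaller than on field data where group effects are stronger; the
  tests assert ordering and monotonicity, not field-scale gain.

Everything is deterministic given (config, seed); the default seed is
20230330.

## Problem sizes and numerical choices

The consistency experiments use 30 replicate stands for the generator
means and 100 simulate-and-refit replicates for fixed-effect recovery
(each refit takes ~1 s at full stand scale; 100 replicates put the
Monte-Carlo standard error of each mean — ≈0.026 for the intercept,
≈0.002 for the DBH slope, ≈0.021 for the CD coefficient — comfortably
below the precision at which those estimates are meaningfully compared).
The test suite uses scaled-down stands (6–9 plots) wherever a property
does not depend on stand size. Starting values: nonlinear least squares
supplies β (intercept started at log(H̄/HCB̄ − 1), the data centroid);
relative covariance factors start at e⁻²; variance-function parameters
start at their homoscedastic values. Ties in the deterministic sampling
strategies break by culm id; model-comparison ties on RMSE (4 decimals)
resolve toward fewer parameters.
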