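# Methods

## The model

`coversad` treats the species abundance distribution (SAD) of one vegetation
plot as a continuous probability distribution over cover, the proportion of
ground a species occupies. Field protocols record cover on an ordinal class
scale, so each observation is interval-censored: a species is known only to
lie in the class interval (L_i, U_i]. The likelihood of a candidate
distribution with parameters θ is therefore binned,

    L(θ) = Σ_i  n_i · ln P_i(θ),      P_i(θ) = F(U_i | θ) − F(L_i | θ),

where n_i is the number of species in class i, C the number of classes, and
F the model CDF. No renormalisation is applied at full cover: Σ P_i =
F(1) − F(0) may fall below 1, so the reported log-likelihood is that of the
plain CDF differences. A truncated-renormalised mode
(`class_probabilities(..., truncate=True)`, `FitOptions(truncate=True)`) is
available for sensitivity analysis.

Candidate models and parameterisations (all on the proportion scale):

| model       | parameters                | CDF                              | k |
|-------------|---------------------------|----------------------------------|---|
| exponential | rate β > 0                | 1 − e^(−βx)                      | 1 |
| gamma       | shape α, rate β           | regularised Γ(α, βx)             | 2 |
| lognormal   | meanlog μ, sdlog σ        | Φ((ln x − μ)/σ)                  | 2 |
| Pareto      | shape α (scale x_m fixed) | 1 − (x_m/x)^α for x ≥ x_m        | 1 |
| Weibull     | shape φ, scale λ          | 1 − exp(−(x/λ)^φ)                | 2 |

The Weibull shape φ is ecologically interpretable: low φ means an excess of
highly abundant species, φ > 1 puts the distribution's mode above the lowest
abundance class; λ expresses the spread of abundances. Gamma(α=1) and
Weibull(φ=1) both collapse to the exponential, which the test suite exploits
as exact nesting identities.

**Pareto scale.** The interval-censored ML estimate of x_m sits on the
boundary of the lowest occupied class, so by default x_m is fixed — at the
lower limit of the lowest occupied class, or at the first positive breakpoint
when class 1 (lower limit 0) is occupied — leaving the shape as the single
free parameter (k = 1). When class 1 is occupied this places x_m at the upper
limit of that class, the occupied class below the support gets zero mass, and
the fit is reported as failed (−∞ log-likelihood): a Pareto SAD genuinely
cannot describe a community with species below its scale parameter. Joint
estimation (`get_model("pareto")`, k = 2) is available.

## Cover scales

The canonical internal scale is the proportion [0, 1]; percent input is
divided by 100 at the I/O boundary. The built-in Londo scale uses the percent
breakpoints 0, 1, 3, 5, 10, 15, 25, 35, 45, 55, 65, 75, 85, 95, 100 — fourteen
classes. Class intervals are half-open right-closed, (L_i, U_i]: a cover
exactly on a breakpoint belongs to the lower class. This convention is a
package choice (any fixed convention works; it only matters that binning and
probability mass use the same one — both use the right-closed rule). Custom
scales register from YAML/JSON (`load_scales`), with optional symbolic class
labels for datasets recorded with codes rather than breakpoints. When covers
arrive as class indices or labels they are replaced by class midpoints
(L_i + U_i)/2, the conventional best estimate of censored cover.

## Fitting

Optimisation runs on log-transformed parameters (the lognormal meanlog stays
linear), Nelder–Mead simplex with objective tolerance 1e−8 followed by a BFGS
polish, 3 jittered restarts (σ = 0.5 on the log scale, seeded; best result
kept). Starting values are moment matches on count-weighted class midpoints:
exponential β₀ = 1/mean; gamma by mean/variance matching; lognormal moments of
log-midpoints; Weibull φ₀ = 1, λ₀ = mean; Pareto by a Hill-type estimator.

During optimisation P_i is floored at 1e−300 inside the logarithm only, so
the search can leave regions where an occupied class has zero mass; reported
log-likelihoods are recomputed without the floor (−∞ stays −∞ and the fit is
flagged). Standard errors come from the inverse of a central-difference
Hessian of the negative log-likelihood at the optimum; a non-positive-definite
Hessian yields NaN SEs, flagged unavailable. A plot with a single occupied
class is reported `converged=False` (the supremum is attained only in a
parameter limit). Parameters drifting more than 20 log-units from the start
are likewise flagged divergent.

## Model selection and goodness of fit

Models are ranked by AICc = −2L + 2k + 2k(k+1)/(n − k − 1) with n the plot's
species richness S; all models with ΔAICc ≤ 2 (inclusive) of the minimum form
the equally-plausible set. When n − k − 1 ≤ 0 (e.g. two-parameter models on
S ≤ 3) the criterion is undefined and the model is reported "not assessable"
rather than ranked. The correction is the scientifically decisive term on
species-poor plots: at equal log-likelihood an extra parameter costs 3.21
ΔAICc units at S = 10 and 12 units at S = 4, against a flat 2 under
uncorrected AIC — so a two-parameter model needs a log-likelihood advantage
greater than 6 to beat a one-parameter one at S = 4.

The χ² goodness-of-fit statistic compares observed counts with expected
S·P_i. Adjacent classes are pooled right-to-left until every pooled expected
count reaches 1 (configurable; 5 is the common stricter choice) because
sparse upper cover classes otherwise explode the statistic; df =
(#pooled classes) − 1 − k, floored at 1, with p from the upper tail. Both the
pooling threshold and the df convention are documented package choices, not
claims about how any particular study computed its tests; p > 0.05 is read as
adequate fit.

## Gradient analysis

`fit_transect` bins and compares every plot independently; per-plot failures
are logged and recorded, never fatal. `selection_tally` counts, per elevation
belt and model, the plots where the model is plausible (cell ≤ plots per
belt) plus grand totals and plausible fractions. `richness_cover_summary`
gives per-belt mean/min/max of richness and recorded total cover.

`parameter_trend` smooths per-plot parameter estimates against elevation with
a locally weighted linear regression: tri-cube kernel, span 0.75 of the
plots, 100-point uniform grid, observation weights ∝ 1/SE normalised to mean
one (making the curve invariant to uniform SE rescaling). Plots without
usable SEs, and plots whose relative weight falls below 1e−6 (numerically
absent), are excluded and reported. Pointwise SEs use the WLS sandwich
σ̂²·[A⁻¹ XᵀW²X A⁻¹]₀₀ with a local residual variance carrying an
effective-sample-size df correction. At least 5 usable plots are required.
This smoother was written in-package because no installed library offers
loess with observation weights and pointwise SEs.

## Synthetic data

The generator emulates the target study design: belts every 100 m from 2,000
to 4,500 m (26 belts), three 100 m² plots per belt and one at the top (76
plots); per-plot richness declining linearly from 46 species at 2,000 m to 5
at 4,500 m (rounded, floored at 1); covers drawn i.i.d. from a chosen model
and censored into Londo classes. The default cover model is exponential with
rate 1/(mean per-species cover), where mean cover = (total vegetation
cover)/richness and total cover declines linearly from 80% to 5% along the
gradient — the printed endpoint trends of the study system. Draws outside
(0, 1] are rejected and redrawn (the truncation fraction is reported, since
the fitting likelihood is untruncated); acceptance below 1e−3 is an error.
Plot-level streams spawn from one integer seed, so transects are reproducible
and plots mutually independent.

What the generator does *not* emulate: shared species identities across
plots, spatial autocorrelation, observer error in class assignment, and the
multi-layer vegetation that lets real total cover approach or exceed 100%.
Passing recovery/selection tests therefore show the estimator and selection
machinery are correct under the stated sampling model, not that any
particular field dataset satisfies that model.

## Problem sizes and numerical choices in the test suite

Recovery tests use 200 seeded replicates per model per sample size
S ∈ {50, 200, 1000}; selection sanity uses 100 replicates at S = 10; χ²
calibration uses 1000 replicates at S = 100, with the rejection band
[0.01, 0.12] wide because parameters are estimated from the data being
tested. One-parameter fits are validated against a twice-refined exhaustive
grid search (200-point log-spaced grid) within 1e−4 log-likelihood. All
stochastic tests enumerate explicit integer seeds; no global RNG state is
mutated anywhere.

## Known limitations

- Discrete SADs (log-series, Poisson-lognormal), mixtures and zero-inflation
  are out of scope; so are Bayesian estimation and profile-likelihood
  intervals.
- The lognormal parameter report is scale-dependent (proportion vs percent
  cover shifts μ by ln 100); AICc rankings are scale-invariant. Parameters
  are always reported on the proportion scale.
- χ² calibration is approximate for heavily pooled tables; the pooling map is
  returned so users can inspect it.
- The loess SE is a pointwise plug-in estimate, not a simultaneous band.
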