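# coversad

Species abundance distributions (SADs) from interval-censored cover-class
vegetation data.

Plant ecologists rarely count individuals; they estimate each species' cover
— the proportion of ground it occupies — and record it on an ordinal class
scale such as the Londo scale. A species' abundance is then known only up to
its class interval (L_i, U_i]. `coversad` fits continuous abundance
distributions directly to such data by maximising the binned log-likelihood

    L(θ) = Σ_i n_i ln P_i ,   P_i = F(U_i | θ) − F(L_i | θ) ,

where n_i is the number of species in cover class i and F the candidate
model's CDF. Five candidate models are built in — exponential(β),
gamma(α, β), lognormal(μ, σ), Pareto(α; x_m) and Weibull(φ, λ) — and are
ranked per plot by small-sample-corrected AIC,

    AICc = −2L + 2k + 2k(k+1)/(n − k − 1),   n = species richness S,

with every model within ΔAICc ≤ 2 of the minimum treated as equally
plausible, plus a pooled χ² goodness-of-fit test. On species-poor plots the
AICc correction is decisive: at equal likelihood an extra parameter costs
3.21 ΔAICc units at S = 10 and 12 units at S = 4, which is why parsimonious
one-parameter models win where richness collapses. Transect utilities tally
model selections per elevation belt, summarise richness and cover, and smooth
fitted parameters (e.g. the ecologically interpretable Weibull shape φ)
against elevation with an inverse-SE-weighted loess. A synthetic-data
generator reproduces the targeted study design (26 belts of 100 m from
2,000–4,500 m, 3 plots per belt, 1 at the top, richness declining 46 → 5) so
the whole pipeline is testable with known truth.

Audience: vegetation and community ecologists working with relevé/plot tables
recorded on cover-class scales.

## Worked example

```python
from coversad import simulate_community, compare_models

# a 40-species community with Weibull-distributed covers, Londo-censored
sample = simulate_community("weibull", [1.6, 0.08], S=40, seed=42)
cmp = compare_models(sample.counts)
for m, fit in cmp.fits.items():
    print(m, fit.loglik, fit.aicc, cmp.delta_aicc[m], cmp.plausible[m])
```

prints (columns: log-likelihood, k, AICc, ΔAICc, in the plausible set):

```
model          loglik  k     AICc   dAICc  plausible
exponential    -67.22  1   136.55   17.09  False
gamma          -58.11  2   120.55    1.09  True
lognormal      -57.57  2   119.46    0.00  True
pareto         -77.96  1   158.02   38.56  False
weibull        -59.12  2   122.56    3.10  False
Weibull shape: 1.80 +/- 0.23
GOF chi2 = 4.18, df = 2, p = 0.12
```

The flexible two-parameter models absorb the extra-parameter penalty at
S = 40 and beat the exponential by ~17 AICc units; lognormal and gamma are
equally plausible (ΔAICc ≤ 2) while this draw's Weibull fit narrowly misses
the set. The fitted Weibull shape 1.80 ± 0.23 is consistent with the
generating value 1.6, and the χ² test (p = 0.12 > 0.05) shows no significant
lack of fit.

The same pipeline runs from the shell:

```sh
coversad simulate --seed 1 --out plots.csv
coversad transect plots.csv --cover-kind proportion --out results/
```

writing a per-plot × per-model fit report, a per-belt selection tally and
smoothed Weibull parameter trends.

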