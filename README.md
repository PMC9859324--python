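# oxylife

Bayesian spatial analysis of the association between ambient oxygen
concentration and regional life expectancy.

At high altitude the partial pressure of oxygen falls below ~140 mmHg and
chronic hypoxia becomes physiologically relevant; whether that shows up in
population life expectancy is an ecological question: one outcome and one
exposure per spatial unit (province or municipality), confounded by wealth,
health-care provision, education and climate, and spatially autocorrelated.
`oxylife` is a reusable pipeline for exactly this kind of region-level
analysis, for epidemiologists and biostatisticians working with
administrative data (or, out of the box, with its own realistic synthetic
data).

## The model

For regions i = 1..n with life expectancy Y_i and covariates x_i
(oxygen partial pressure in mmHg — derived as pressure(kPa) × 0.2093 ×
7.5 — plus GDP per capita, health technicians per 1000, education years and
meteorology):

    Y_i = α + x_i'β + u_i + v_i        v_i ~ N(0, σ_v²)

with u either dropped (IID model) or given an intrinsic CAR / GMRF prior
with precision τ_u (D − W) built from inverse great-circle-distance weights
between region centroids (conditional mean Σ_j w_ij u_j / w_i+, conditional
variance σ_u²/w_i+). Coefficients carry hierarchical Gaussian priors whose
precisions, like τ_u and τ_v, get Gamma hyperpriors (Gamma(1, 0.1) and
Gamma(1, 0.05) respectively). The posterior is sampled by a blocked Gibbs
sampler written here from scratch (all full conditionals are conjugate).

Around the model sits the full analysis: a 140 mmHg hypoxia dichotomy with
exact Mann–Whitney comparisons; Pearson-correlation screening with a DIC
tie-break (|r| > 0.7 drops the higher-DIC twin) and backward stepwise DIC
selection; a Global Moran's I permutation gate (Freedman–Lane, on
fixed-effects residuals) that chooses CAR vs IID; DIC and adjusted R² for
model assessment; and Ward hierarchical clustering of regions by their
cause-of-death YLL profiles with ANOVA/Kruskal–Wallis routing and
Bonferroni-corrected pairwise tests. See `docs/methods.md` for details and
numerical choices.

## Worked example

Generate a synthetic 34-region dataset with known truth (oxygen effect
0.15 y/mmHg, GDP 0.877 y/SD, health technicians 0.752, spatial field
σ_u = 1, noise σ_v = 0.5) and fit with automatic model choice:

```bash
oxylife simulate --out-dir demo --seed 7
oxylife fit --regions demo/regions.csv --model auto --seed 7 \
    --n-iter 4000 --n-burnin 1000 --n-chains 2
```

prints (abridged):

```
Moran I=0.115 p=0.0001 -> car
                               mean       sd     q2.5    q97.5    rhat
alpha                       52.9943   2.7200  47.5664  58.2317  1.0250
beta[oxygen]                 0.1354   0.0165   0.1040   0.1690  1.0189
beta[gdp_per_capita]         0.7129   0.2132   0.3172   1.1413  1.0037
beta[health_tech_per_1000]   0.6538   0.1699   0.3177   0.9831  1.0191
precision_v                 20.2206  18.9427   0.8361  68.6005  1.0309
precision_u                  2.4510   7.0744   0.5848  17.8970  1.0307
...
DIC=13.87 p_D=1.74 adjR2(fixed)=0.780 adjR2(full)=0.995
```

The Moran gate detects the planted spatial field (p = 0.0001 < 0.05) and
selects the CAR model; the posterior mean for the oxygen slope, 0.135
(95% BCI 0.104–0.169), covers the generating value 0.15, as do the GDP and
health-technician intervals (truth 0.877 and 0.752); each extra mmHg of
ambient oxygen is associated with ~0.14 additional years of life
expectancy in this replicate. `oxylife run --config config.yaml` drives the
whole pipeline (descriptives → screening → gate → fit → clustering) and
writes a reproducible JSON report plus CSV/Newick artifacts;
`oxylife compare-groups`, `screen`, `moran`, `cluster` expose single
stages.

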