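# nestpattern

Spatial inference for ground-nesting bird nest distributions. The package
asks whether the nests of a breeding population — here motivated by Ruffs
(*Calidris pugnax*), a lekking wader of coastal meadows — are placed at
random across the suitable breeding habitat, or are spatially associated
with social and environmental features: other nests, lek display sites, the
meadow edge (a predation proxy) and the shoreline (a flooding proxy).

It is written for quantitative ecologists who have nest coordinates from
one or more seasons, lek centres with yearly activity, shore/edge
polylines, and (optionally) vegetation-index rasters, all in one projected
metric CRS.

## Methods implemented

**Suitable breeding area.** Index values (NDVI greenness; SAR backscatter,
dB) are extracted at nest locations per date, averaged per year, and pooled
across years; the 5th–95th percentile envelope of the pooled per-nest means
defines the "suitable" index range. Yearly masks are thresholded from
yearly mean rasters, compared via an overlap fraction, averaged per index
across years, and the union across indices gives the final polygon used for
null simulation.

**ANN randomization tests.** For each year, the average nearest-neighbour
distance (ANN) of the observed nests to each feature is compared with the
ANNs of *N* = 1000 complete-spatial-randomness (CSR) distributions of the
same size simulated inside the suitable area. With *N*₊ simulations whose
ANN exceeds the observed one, significance is the folded Monte-Carlo pseudo
p-value

&nbsp;&nbsp;&nbsp;&nbsp;*p*ₚₛₑᵤ𝒹ₒ = min(*N*₊ + 1, *N* + 1 − *N*₊) / (*N* + 1),

and per-year values are combined across seasons with Stouffer's sum-of-z
test, *Z* = Σᵢ Φ⁻¹(1 − pᵢ)/√k.

**Use-availability GLMM.** A Bayesian binomial GLMM with logit link
contrasts each observed distribution with its CSR replicates: the response
is observed-vs-simulated, the predictors are the z-scored distribution-mean
distances to the four features, and year is a random intercept,
logit P(observed) = α + u_year + **x**ᵀ**β**, u_year ~ N(0, σ_year).
Posteriors are sampled by ensemble MCMC (emcee) with arviz diagnostics; an
effect is "clear" when its 95% credible interval excludes 0, and a fit is
flagged non-converged when any R̂ ≥ 1.10. A Pearson/VIF collinearity screen
runs alongside.

A seeded synthetic-data module generates landscapes (a suitable band
between roughly parallel shore and edge polylines, leks with yearly
activity) and nest processes with known structure (log-linear attraction or
repulsion per metre of feature distance; Thomas clustering), so the whole
chain is testable end to end with known ground truth.

## Worked example

Generate a five-season synthetic dataset with nest clustering (Thomas,
σ = 30 m) and lek attraction (−0.01 per m), then run the full analysis:

```sh
nestpattern synth --outdir data --seed 2 --thomas-sigma 30 --beta-lek -0.01
cat > run.yaml <<EOF
nests: data/nests.csv
leks: data/leks.csv
features: data/features.geojson
outdir: results
n_replicates: 1000
seed: 11
EOF
nestpattern run-all --config run.yaml
```

or equivalently in Python:

```python
from nestpattern import AnnRandomizationTest, UseAvailabilityGLMM
from nestpattern.synthetic import (LandscapeConfig, NestProcessConfig,
                                   ThomasConfig, generate_dataset)

ds = generate_dataset(LandscapeConfig(seed=1),
                      NestProcessConfig(beta_lek=-0.01,
                                        clustering=ThomasConfig(8, 30.0), seed=2))
ann = AnnRandomizationTest(ds.nests_by_year, ds.features,
                           n_replicates=200, seed=5).fit()
print(ann.combined_summary())
glmm = UseAvailabilityGLMM.from_patterns(ds.nests_by_year, ann.model.ensemble,
                                         ds.features).fit()
print(glmm.summary().round(3))
```

The combined table prints:

```
  feature                method    combined_p         z
0   nests              stouffer  4.117293e-09  5.763585
1   nests  stouffer_directional  8.234587e-09 -5.763585
2    leks              stouffer  4.117293e-09  5.763585
3    leks  stouffer_directional  8.234587e-09 -5.763585
4    edge              stouffer  1.146581e-02  2.274572
5    edge  stouffer_directional  2.713981e-01  1.099849
6   shore              stouffer  1.463503e-03  2.975302
7   shore  stouffer_directional  1.481063e-02 -2.436977
```

Every yearly observed nest-to-nest and nest-to-lek ANN sits below all 200
simulated ANNs (pseudo p = 1/201 each year), so the combined p-values for
the two social features hit the Stouffer combination of five folded-minimum
values, with negative direction-aware z: the generator's clustering and lek
attraction are detected as attraction. The edge/shore folded combinations
are mildly small, but their direction-aware variants are inconsistent
across years — folded p-values accumulate evidence from both tails, which
is why the directional method is reported alongside. The GLMM summary on
the same ensemble prints

```
              mean     sd  cri_2.5%  cri_97.5%       ess   rhat  clear
intercept  -12.621  2.519   -18.061     -8.234  3390.722  1.039    NaN
beta_nests  -3.690  1.705    -7.364     -0.697  3268.456  1.032   True
beta_leks   -1.949  1.753    -5.767      1.038  2901.646  1.032  False
beta_edge   -0.056  1.282    -2.612      2.415  4368.436  1.028  False
beta_shore   0.004  1.303    -2.482      2.600  2840.707  1.032  False
sigma_year   1.746  1.309     0.091      4.993  2638.245  1.039    NaN
```

i.e. per one SD shorter mean nest-to-nest distance the log-odds of a
distribution being the observed one rise by ≈ 3.7 (the only clear effect),
the lek effect is negative but its CrI brushes zero, and the edge/shore
effects centre on zero — matching the generating process, which had
clustering and lek attraction but no edge/shore effect.

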