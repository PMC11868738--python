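# Methods

## The question and the inferential design

Given yearly sets of nest coordinates inside a delimited suitable breeding
area, the package tests whether the nests deviate from complete spatial
randomness (CSR) with respect to four spatial features — other nests of the
same year, the lek centres active that year, the meadow-edge polyline and
the shoreline polyline — and then estimates the relative weight of those
features in one multivariate model. The null model is deliberately simple:
conditioned on the observed per-year count, nests are i.i.d. uniform over
the suitable polygon. Everything the analysis concludes is relative to that
null; inhomogeneous or covariate-weighted availability is out of scope.

All coordinates are planar metres in a single projected CRS. The package
never reprojects; analyses of this kind operate on one site of a few
hundred hectares, where geodesic effects are irrelevant.

## Suitable breeding area from index rasters

The suitable area is calibrated from the nests themselves: per-date index
values (NDVI, unitless; SAR backscatter, dB) are extracted at each nest's
raster cell, averaged per year per nest (missing dates skipped), pooled
across years, and the envelope between the 5th and 95th percentile of the
pooled per-nest means defines the suitable range per index. Cells of a
year's mean raster within the range (inclusive at both bounds) are
suitable; nodata cells are never suitable. Yearly masks are summarised by
an overlap fraction, the per-index mask comes from thresholding the
across-year mean raster, and the final area is the union of the per-index
masks, polygonised cell-by-cell with exact area conservation.

Numerical conventions, each logged in the output metadata:

* percentiles use linear interpolation between order statistics
  (Hyndman–Fan type 7, numpy's default) — the convention matters at these
  small per-nest sample sizes;
* the between-year overlap fraction is intersection / min(area, area) by
  default, with Jaccard (intersection/union) selectable and both reported:
  the min-denominator convention reads "1" as "the smaller mask is nested
  in the larger", which is the natural reading of a between-year agreement
  check, but neither convention is privileged;
* rasters are square-cell single-band grids in the plain-text ESRI ASCII
  dialect; satellite retrieval, atmospheric correction, radar calibration
  and the like are upstream of this package.

## ANN randomization tests

The statistic per year and feature is the average nearest-neighbour
distance (ANN): for the nest feature, the mean over nests of the distance
to the nearest other nest in the same distribution (first degree, no edge
correction); for leks, the mean distance to the nearest lek centre active
that year; for the polyline features, the mean shortest distance to the
line. Each observed statistic is ranked within `n_replicates` seeded CSR
replicates of the same size, and

    p_pseudo = min(N_greater + 1, N + 1 - N_greater) / (N + 1)

with N_greater counting replicates with a *strictly* greater ANN — exact
ties, a measure-zero event with continuous coordinates, count as not
greater. This folded (two-tail-minimum) construction has floor 1/(N+1),
attained only at ranks 0 and N, and rejects at rate ≈ 2α under the null for
small α; the test suite verifies both the exact formula and the calibration
by simulation.

Per-year values are combined across seasons with Stouffer's sum-of-z
method, zᵢ = Φ⁻¹(1 − pᵢ), Z = Σzᵢ/√k. Feeding the folded p-values to a
one-sided combination is a procedural quirk inherited from the analysis
this package operationalises: a folded p carries no direction, so a "small
combined p" can mix years in which the observed ANN was unusually small
with years in which it was unusually large. Both variants are therefore
reported side by side — the folded combination under method tag
`stouffer`, and a direction-aware combination (`stouffer_directional`)
whose z-scores are signed by the observed ANN against the simulated median
and whose combined value is the two-sided normal tail. Neither is asserted
to be "the" correct combination; readers should prefer the directional one
when the direction of deviation matters.

CSR replicates are drawn by rejection sampling from the region's bounding
box (batch sizes adapt to the acceptance rate; a pathologically thin region
exhausts the iteration budget with an error naming the acceptance rate).
Every replicate's random stream derives from a counter-based substream of
the master seed keyed by (year, replicate index), so ensembles are
bit-reproducible, order-independent, and one year's patterns are unaffected
by another year's data. The same ensemble feeds every feature's test and
the GLMM design — deliberately, so the univariate and multivariate stages
see the same availability sample.

## Use-availability GLMM

Unit of analysis: one row per nest distribution — the observed pattern plus
each CSR replicate, per year. The four predictors are the
within-distribution ANN and the distribution means of the three feature
distances; the response is observed (1) vs simulated (0); year is a random
intercept. The row structure could equally be defined per nest (each point
carrying its own distances); that variant is implemented behind
`unit="nest"`, but the distribution level is the default because the
predictors are defined as per-distribution summaries. The 1 : N class
imbalance per year is the essence of the use-availability contrast and is
left unweighted.

Predictors are z-scored pooled across all rows (n−1 SD), so effects are
per-SD log-odds. Priors are weakly informative on that scale: Normal(0, 5)
for the intercept and slopes, half-Normal(2.5) for σ_year. A Pearson
correlation screen (overall and per year, with two-sided p-values) and
variance inflation factors (VIF_j = 1/(1−R²_j)) are computed on the same
table before fitting.

Sampling is ensemble MCMC (emcee): the year offsets are non-centred
(u = σz, z ~ N(0,1)) and σ_year is sampled on the log scale with the
Jacobian term, which removes the worst of the funnel. A mixture of
differential-evolution moves (80% DEMove, 20% DESnookerMove) replaces the
default stretch move; on this correlated 11-dimensional posterior the
stretch move mixes far too slowly. Several independent ensembles (default
4) of 32 walkers are run from jittered neutral starts (intercept at the
empirical base-rate logit); after discarding warmup, every walker of every
ensemble is treated as a chain for rank-normalised split R̂ and ESS
(arviz). Defaults are 2000 warmup + 2000 retained draws per walker —
longer than a gradient-based sampler would need, because ensemble moves
produce strongly autocorrelated chains; with these settings R̂ stays well
below the 1.10 convergence rule. Non-convergence is flagged on the results
object (and fails the CLI unless `--allow-nonconverged`), never silent.
Equal-tailed 95% credible intervals summarise each parameter; an effect is
"clear" when its interval excludes zero.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analysis assumes,
not the remote-sensing pipeline. A landscape is a suitable band between a
wavy shoreline near y = 0 and a meadow-edge polyline whose height profile
varies slowly along x (default band 3000 m × ~1000 m, ≈ 300 ha). The width
variation (default ±45%) is deliberate: with perfectly parallel boundaries
the distribution-mean distances to edge and shore are complements of a
constant and the GLMM design would be singular (VIF ≈ 50); with the
default profile their correlation lands near −0.65 and all VIFs stay below
2, the regime reported for the motivating field site. Eight leks are
placed uniformly in the interior (buffered off the boundaries); two are
active in every season and the rest are drawn so the yearly active counts
default to 6/8/4/4/6. Yearly nest counts default to 64/56/28/54/44
(2018–2022), the seasonal counts of the motivating study, 246 nests in
total.

Nest processes: a log-linear inhomogeneous intensity
λ(s) ∝ exp(β_lek·d_lek + β_edge·d_edge + β_shore·d_shore) (β in 1/m;
negative β_lek attracts) sampled by thinning against an intensity maximum
estimated on a 4096-point probe with 0.5 nats of headroom; and Thomas
clustering, with parents drawn from that same intensity and offspring
displaced by an isotropic Gaussian (σ in m), escapes resampled so the
yearly count is exact. With all β = 0 and no clustering the process is
exactly the CSR sampler. Ground truth is serialised next to the data. The
default "structured study" settings used in tests and in the acceptance
script — Thomas σ = 30 m with 8 parents, β_lek = −0.01/m — give ANN
reductions and lek attraction that are unambiguous at tens of nests per
year without collapsing the pattern to points.

A toy raster generator supports the suitability stage: two index layers
("ndvi"-like, "sar"-like) that differ inside vs. outside the band with
smooth spatial trends and per-date noise. It is a synthetic stand-in with
known percentile structure; it makes no attempt at radiometric realism, so
passing mask tests says the mask arithmetic is right, not that real
satellite products would behave this way.

There is also a distribution-level case-control generator with known
logistic truth: per year it builds N+1 CSR candidate distributions,
standardises their predictors, and picks the "observed" one with
probability ∝ exp(Σβz). Because the use-availability likelihood with one
case per stratum approximates conditional logistic sampling, a fit on such
data recovers β — this is the parameter-recovery oracle for the GLMM.

Passing tests on these generators demonstrates internal correctness and
statistical calibration under the stated processes. They do not capture
GPS error, nest detection effort, within-season settlement dynamics, or
habitat heterogeneity beyond the suitable/unsuitable dichotomy.

## Problem sizes and seeds

The test suite runs the calibration check at 200 datasets × 200 replicates
of 30 points, the power check at 20 runs of the five-season design with 200
replicates per year, and the recovery check at 20 fits with 2 ensembles ×
(1200 warmup + 800 draws) — sizes chosen so each check's Monte-Carlo error
is small against the band it asserts while the whole suite stays
interactive. The acceptance script uses the full 1000 replicates per year
and default sampler settings. Every random quantity anywhere derives from
an explicit seed; nothing is seeded from the clock.

## Known limitations

* The CSR null ignores observation effort and within-year settlement order;
  a nest placed early changes the "availability" seen by later nests in
  ways no conditionally-uniform null can express.
* Folded pseudo p-values in a one-sided combination conflate tails (see
  above); the directional variant is a pragmatic repair, not a replacement
  derived from first principles.
* The GLMM's year random intercept is weakly identified with five groups;
  its posterior leans on the half-Normal prior, and σ_year's credible
  interval should be read accordingly.
* VIFs and correlations are computed on a design dominated by simulated
  rows, so they describe the availability geometry more than the observed
  nests.
* Ensemble MCMC trades gradient information for robustness; fits are
  slower per effective sample than NUTS would be, and very high-dimensional
  extensions (many years, nest-level rows with interactions) would warrant
  a gradient-based sampler.
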