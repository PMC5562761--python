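# Methods

## Domain model

A slope is a grid of contiguous fixed-width elevational bands (default
250 m), band `i` covering the half-open interval
`[base + i·w, base + (i+1)·w)` with midpoint `base + (i + 0.5)·w`.  The two
default grids are `south` (1250–3650 m, 10 bands) and `north` (1000–3700 m,
11 bands); their band starts overlap at 1250–3500 m, giving 10 matched
cross-slope pairs.  Grids need at least two bands; a species' elevational
records are snapped to the bands containing them, with the domain top snapped
to the last band.

**Range interpolation.**  A species observed at bands `{b_1, …}` is assumed
present at every band of `[min(b), max(b)]` — gaps in banded survey data are
treated as detection failures rather than true absences.  Interpolation is
idempotent and never shrinks occupancy; every incidence-matrix column is
therefore one contiguous run, and range size is `n × w` metres for `n`
occupied bands.  Duplicate records collapse to presence/absence.

**Range-size groups.**  Species strictly above the median range size form the
larger-ranged group; species at or below it the smaller-ranged group.  Ties
go to the smaller-ranged set so "above the median" holds strictly (a `tie`
flag reverses this), and the split is recomputed within each slope by default
(`global_split` pools both slopes first).  With odd species counts or ties
the halves are unequal; that is accepted rather than forcing a 50/50 split.

## Mid-domain-effect null model

Each Monte-Carlo replicate draws `S` range sizes — with replacement from the
empirical size pool by default, or each observed size exactly once in
no-replacement mode — and places each range's start uniformly on
`{0, …, B − r}` (hard boundaries at both ends).  Defaults: 50,000 replicates;
simulation limits are the 2.5th/97.5th percentiles of per-band replicate
richness with nearest-rank interpolation (configurable through the
`np.quantile` method name).  A single integer seed drives one generator, so
results are bit-reproducible.  Range-size resampling (not midpoint
resampling) is the default because the size pool is the empirical quantity
the analysis conditions on; no-replacement mode exists because the exact
expectation

    E[richness_j] = Σ_s [min(j, B − r_s) − max(0, j − r_s + 1) + 1] / (B − r_s + 1)

assumes each size used once, and it is the oracle the simulator is tested
against (agreement within 3 Monte-Carlo standard errors per band at 50,000
replicates; per-replicate occupancy is conserved exactly by construction).
Goodness of fit is the OLS regression of observed on predicted richness
(r², slope, intercept, two-sided p for the slope); a constant prediction is
an error rather than r² = 0.

## Multi-model inference

Response and the five predictors are z-scored (sample sd, ddof = 1) so
coefficients are standardized betas; the intercept is retained (≈ 0 after
centring).  For each of the `2^p − 1` subsets an OLS fit gives
`AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n − k − 1)` with `k` = coefficients +
intercept + error variance.  RSS below 1e-12 is clamped to 1e-12 so noiseless
fits stay finite (with the side effect that among perfectly fitting models
the smallest `k` wins, which is the desired parsimony order).  The largest
model must satisfy `n > k + 1`, so five predictors need at least nine bands.
Rank-deficient subsets are fitted by pseudo-inverse, flagged `collinear`, and
kept in the set with a warning.

Akaike weights, impact factors (summed weights of models containing a
predictor; "important" at ≥ 0.80) and model-averaged coefficients follow the
standard information-theoretic recipe.  Averaging is *natural* (conditional
on inclusion, weights renormalised); full-model averaging with zeros for
absent predictors is available behind a flag since either convention is
defensible.  Unconditional standard errors use Buckland's combination
`Σ w'_i sqrt(se_i² + (β_i − β̄)²)`.  No p-values are attached to multi-model
output; with ~10 spatially autocorrelated bands they would be unreliable, so
p-values appear only in the single-fit polynomial and observed-vs-null
regressions.

**Polynomial selection.**  Orders 1–3 on centred elevation, chosen by AICc
with `k = order + 2`; orders violating `n > k + 1` are dropped from the
candidate set (at n = 6 the cubic is infeasible).  At least six points are
required.

## Beta diversity

Sorensen dissimilarity `S = (b + c)/(2a + b + c)` is undefined when either
assemblage is empty; adjacent-band comparisons touching an empty band are
reported as missing (NaN) rather than zero.  Cross-slope turnover pairs bands
with identical start elevations and reports the standardized regression slope
of dissimilarity on elevation, which for a simple regression equals the
Pearson correlation; it is `None` when dissimilarity is constant.  Whittaker's
`W = s/α − 1` uses mean per-site richness for α when a site table is
available, else mean per-band richness (a documented fallback that inflates α
relative to site-level sampling).  The Mantel statistic is the Pearson
correlation of upper-triangle entries; rows and columns of the second matrix
are permuted jointly, and `p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1)` — never
exactly zero — one-tailed for positive association by default because
distance decay is a directional hypothesis (two-sided available).  Geographic
distances are user-supplied; synthetic runs use band-midpoint separation as
the distance surrogate.

## Covariates

AMT is linear in altitude per slope (north `−0.0049·alt + 17.9` °C, south
`−0.0037·alt + 14.5` °C), evaluated at band midpoints since the per-band
altitude convention is otherwise unspecified.  Note the between-slope paired
t-test on *modelled* AMT is then deterministic in sign (two affine functions
of the same midpoints), so it cannot reproduce a paired test computed from
measured temperatures; the t-test utilities are intended for the measured
covariates (AMP, EVI, area).  Zero-variance differences are flagged
`degenerate` with `t = ±inf` (or `t = 0, p = 1` when the vectors are
identical).

## Synthetic data

The generator emulates the two-slope survey design: 30-species pool, 29
southern and 18 northern species with 17 shared; Oriental/Palaearctic labels
drawn with log-odds of Oriental declining 1.5 per sd of range-midpoint
elevation around a 60% baseline (so the Oriental fraction falls with
elevation); 3 sites per band with detection probability 0.7 — roughly the
study's ~28–29 sites per slope and plateaued accumulation curves.  Observed
band sets keep the range endpoints and drop interior bands with probability
0.2, so interpolation has gaps to fill.

Scenarios differ only in range placement: `mde_null` places starts uniformly
(the null model's own generative process); `monotonic_decline` anchors range
low ends at the base with an exponential start bias of decay scale 0.5 bands —
strong anchoring matters, because uniform sizes anchored at the base give an
expected richness proportional to `B − j` (linear, temperature-like), whereas
weak anchoring yields a convex left-shifted curve that the MDE predictor can
absorb; `hump` biases range midpoints toward the domain centre (Gaussian
weight, sd B/6).  Range sizes are uniform on `1..B` by default (spanning one
band to the whole domain), with empirical-pool and truncated-geometric
alternatives.  Covariates: AMT exactly from the lapse models; AMP declines
900→400 mm and EVI 0.55→0.20 up the gradient; area is hump-shaped
(Gaussian bump, one interior maximum); all but AMT carry multiplicative
noise of relative sd 0.05 (0 gives deterministic functions of elevation).

What the generator does *not* emulate: abundance and trapping dynamics,
spatial autocorrelation between neighbouring bands beyond range contiguity,
realm-dependent range sizes, and real covariate collinearity structure.
Passing tests therefore demonstrate that the machinery recovers known
generative processes, not that any particular field system obeys them.

## Pipeline

`run_analysis` executes ingest → interpolation → MDE → inference → beta
diversity for both slopes and the three species groups (beta diversity and
realm composition on all species only, matching the scope of a
composition-independent group split), writes per-stage CSVs and a
`report.json`, and derives every stage seed from the master seed via
`SeedSequence([seed, crc32(stage_tag)])`, so identical inputs and seed give a
byte-identical report.  Stage failures raise `PipelineError` naming the stage
and offending input.  Floats in the report are rounded to 10 significant
decimals purely to keep the JSON stable across platforms.

## Problem sizes in the test suite

Unit tests run reduced replicate counts (25–120) for simulation properties;
the acceptance-style checks use the full sizes the analyses are defined at —
50,000 MDE replicates, 200 impact-recovery replicates, 100 null-recovery
datasets, 1000 Mantel permutations — which complete in seconds thanks to the
vectorised difference-array simulator (each replicate costs O(S + B)).

## Known limitations

* The MDE simulator assumes hard boundaries at both domain ends; soft or
  one-sided boundary variants are out of scope.
* Model-averaged SEs follow one published convention; other software may
  print slightly different SEs for the same fits.
* The Mantel test permutes one matrix's labels; partial Mantel and
  autocorrelation-corrected variants are not provided.
* Beta-diversity partitioning into nestedness and turnover components is not
  implemented.
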