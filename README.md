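# elevdiv

Analysis toolkit for elevational diversity gradients on banded mountain
slopes: species-range interpolation, a mid-domain-effect (MDE) null model,
AICc multi-model inference over environmental and geometric predictors, and
beta-diversity statistics, with a synthetic-data generator that emulates a
two-slope small-mammal survey so every stage can be exercised and tested
without field data.

## The scientific problem

Montane surveys record each species in a set of 250-m elevational bands.
Three questions recur:

1. **Is the richness pattern just geometry?**  When ranges are shuffled at
   random between the domain's hard boundaries (valley floor and summit),
   overlap piles up mid-domain — the mid-domain effect.  The null model keeps
   each species' range size `r` (in bands), draws sizes with replacement from
   the empirical pool, places each range's start uniformly on the feasible
   positions `{0, …, B − r}` of a `B`-band domain, and repeats 50,000 times to
   get a per-band expected richness with 2.5–97.5% simulation limits.  An
   exact expectation,

   `E[richness at band j] = Σ_s (# feasible placements of r_s covering j) / (B − r_s + 1)`,

   serves as the simulator's oracle.  Observed richness is regressed on the
   null prediction; the r² measures how much geometry alone explains.

2. **Which factors drive richness?**  All `2^p − 1 = 31` OLS subsets of five
   standardized per-band predictors (MDE prediction, annual mean temperature
   AMT, annual mean precipitation AMP, vegetation index EVI, band area) are
   ranked by `AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)` and weighted by
   `w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2)`.  A predictor's **impact factor** is
   the summed weight of the models containing it (important when ≥ 0.80), and
   coefficients are model-averaged over those models.

3. **How does composition turn over?**  Sorensen dissimilarity
   `S = (b + c)/(2a + b + c)` between band pairs (adjacent, all pairs, and
   cross-slope pairs matched on elevation), Whittaker's `W = s/α − 1` at the
   whole-gradient scale, and one-tailed Mantel permutation tests of distance
   decay of similarity.

AMT comes from slope-specific lapse models (north: `−0.0049·alt + 17.9` °C;
south: `−0.0037·alt + 14.5` °C) evaluated at band midpoints; AMP, EVI and
area are user-supplied (or synthetic) inputs.

## Worked example

`examples/01_mde_null_model.py` generates 30 species whose ranges truly
follow the null on an 11-band slope (1000–3700 m) and fits the null model:

```
band mid (m):     1125   1375   1625   1875   2125   2375   2625   2875   3125   3375   3625
observed:            6     13     16     17     19     18     18     23     18     14     10
null mean:        7.93  13.41  16.17  18.51  19.81  20.33  19.82  18.50  16.17  13.40   7.94
exact (oracle):   7.93  13.40  16.17  18.50  19.83  20.33  19.83  18.50  16.17  13.40   7.93

observed ~ predicted: r2 = 0.804, p = 0.0002
```

The 50,000-replicate mean matches the closed-form expectation to two
decimals, and because these ranges were placed at random the null explains
~80% of the observed variance.  `examples/02_multi_model_inference.py` runs
the 31-model comparison on a temperature-driven declining gradient:

```
31 OLS models fitted; best subset: amt
predictor  impact  important  averaged beta
      amt   0.800        yes         +0.923
      evi   0.242         no         +0.636
      mde   0.178         no         +0.088
```

AMT is flagged important (impact ≥ 0.80) and carries a standardized
coefficient near 1, while the geometric null prediction is discounted —
the inference recovers the process that generated the data.  The other
examples cover beta diversity and the full pipeline.

## Command line

```sh
elevdiv simulate --scenario mde_null --seed 1 --out data/
elevdiv mde   --ranges data/ranges.csv --slope north --sims 50000 --seed 42
elevdiv infer --ranges data/ranges.csv --covariates data/covariates.csv --slope south
elevdiv beta  --ranges data/ranges.csv --slope south --distance data/dist_south.csv --perms 1000 --seed 7
elevdiv run   --config run.yaml        # full pipeline -> CSVs + report.json
```

Exit codes: 0 success, 1 user error, 2 internal error.

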