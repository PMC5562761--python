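"""All-subsets AICc inference: which factors drive a richness gradient?

Builds a synthetic slope whose richness declines monotonically (temperature-
like forcing), then fits all 31 subsets of five standardized predictors (null
MDE prediction, AMT, AMP, EVI, band area) and ranks the predictors by their
impact factor: the summed Akaike weights of the models containing each one.
"""

import elevdiv as ed

grids = {"south": ed.build_grid("south", 1250, 3650, 250)}
cfg = ed.ScenarioConfig(
    scenario="monotonic_decline", n_species={"south": 29}, seed=2
)
ranges = ed.generate_ranges(cfg, grids)["south"]
inc = ed.build_incidence(grids["south"], ranges)
obs = ed.richness(inc)

cov = ed.generate_covariates(grids, cfg)
null = ed.simulate_mde(inc.range_sizes_bands(), grids["south"], ed.MDEConfig(n_sims=50_000, seed=2))

models = ed.all_subsets(
    obs,
    {
        "mde": null.predicted_mean,
        "amt": cov["amt_c"].to_numpy(),
        "amp": cov["amp_mm"].to_numpy(),
        "evi": cov["evi"].to_numpy(),
        "area": cov["area_km2"].to_numpy(),
    },
)

print(f"{len(models.fits)} OLS models fitted; best subset: {'+'.join(models.best.predictor_subset)}")
print(f"best-model AICc = {models.best.aicc:.2f}, Akaike weights sum = {models.weights.sum():.6f}\n")
print("predictor  impact  important  averaged beta")
for name, impact in sorted(models.impact_factors.items(), key=lambda kv: -kv[1]):
    flag = "yes" if models.important[name] else "no"
    print(f"{name:>9}  {impact:6.3f}  {flag:>9}  {models.averaged_betas[name]:+13.3f}")
print(
    "\nAn impact factor >= 0.80 marks a predictor as important. Under a\n"
    "declining gradient, temperature-correlated predictors carry the weight;\n"
    "under a true mid-domain hump the MDE prediction would dominate instead."
)
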