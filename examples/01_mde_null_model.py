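"""Mid-domain-effect null model on one synthetic slope.

Generates 30 species whose ranges are placed uniformly between the domain's
hard boundaries, then asks whether the Monte-Carlo null model explains the
resulting richness curve.
"""

import numpy as np

import elevdiv as ed

grid = ed.build_grid("north", 1000, 3700, 250)
cfg = ed.ScenarioConfig(scenario="mde_null", n_species={"north": 30}, seed=1)
ranges = ed.generate_ranges(cfg, {"north": grid})["north"]

inc = ed.build_incidence(grid, ranges)
observed = ed.richness(inc)
null = ed.simulate_mde(inc.range_sizes_bands(), grid, ed.MDEConfig(n_sims=50_000, seed=1))
fit = ed.fit_observed_vs_predicted(observed, null.predicted_mean)
exact = ed.analytic_mde_expectation(inc.range_sizes_bands(), grid)

print("band mid (m):  ", " ".join(f"{m:6.0f}" for m in grid.midpoints))
print("observed:      ", " ".join(f"{c:6d}" for c in observed.counts))
print("null mean:     ", " ".join(f"{m:6.2f}" for m in null.predicted_mean))
print("exact (oracle):", " ".join(f"{m:6.2f}" for m in exact))
print(f"\nobserved ~ predicted: r2 = {fit.r_squared:.3f}, p = {fit.p_value:.4f}")
print(
    "The null richness humps toward mid-elevations; because these ranges were\n"
    "truly placed at random, the null explains most of the observed variation."
)
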