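import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import elevdiv as ed

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def grids():
    return ed.default_grids()


@pytest.fixture(scope="session")
def south_grid(grids):
    return grids["south"]


@pytest.fixture(scope="session")
def north_grid(grids):
    return grids["north"]


@pytest.fixture()
def toy_incidence():
    """3 bands, 3 species with intervals [0,1], [1,2], [2,2]."""
    grid = ed.build_grid("toy", 0, 750, 250)
    ranges = [
        ed.SpeciesRange("s1", "toy", frozenset({0, 1}), "Oriental"),
        ed.SpeciesRange("s2", "toy", frozenset({1, 2}), "Oriental"),
        ed.SpeciesRange("s3", "toy", frozenset({2}), "Palaearctic"),
    ]
    return ed.build_incidence(grid, ranges)


@pytest.fixture(scope="session")
def synthetic_run(tmp_path_factory):
    """A small but complete synthetic scenario plus pipeline outputs."""
    out = tmp_path_factory.mktemp("synth_run")
    cfg = ed.ScenarioConfig(seed=11)
    paths = ed.write_scenario(cfg, out / "data")
    rc = ed.RunConfig(
        ranges_path=str(paths["ranges"]),
        covariates_path=str(paths["covariates"]),
        sites_path=str(paths["sites"]),
        distance_paths={
            "south": str(paths["dist_south"]),
            "north": str(paths["dist_north"]),
        },
        grids=ed.default_grids(),
        out_dir=str(out / "run"),
        n_sims=2000,
        n_perm=199,
        seed=11,
    )
    report = ed.run_analysis(rc)
    return {"config": rc, "paths": paths, "report": report, "out": out}
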