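import numpy as np
import pytest

from foragerep import SimulationConfig, simulate_population
from foragerep.config import PipelineConfig
from foragerep.pipeline import run_pipeline


def small_sim_config(**overrides) -> SimulationConfig:
    """A reduced population (12 individuals, ~1-2 day trips over patches
    30-50 km out) that exercises every pipeline stage quickly."""
    kw = dict(n_individuals=12, trips_per_individual=(3, 5), seed=7,
              log_duration_mean=float(np.log(30.0)),
              patch_distance_mean_km=40.0, patch_distance_sd_km=8.0)
    kw.update(overrides)
    return SimulationConfig(**kw)


@pytest.fixture(scope="session")
def small_pop():
    cfg = small_sim_config()
    gps, depth, morph, truth = simulate_population(cfg)
    return {"cfg": cfg, "gps": gps, "depth": depth, "morph": morph, "truth": truth}


@pytest.fixture(scope="session")
def pipeline_result(small_pop):
    pc = PipelineConfig(n_permutations=100, n_bootstrap=100, seed=3)
    return run_pipeline(pc, gps=small_pop["gps"], depth=small_pop["depth"],
                        morph=small_pop["morph"])
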