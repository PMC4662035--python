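import pytest

from poolscreen.benchmark import run_pipeline
from poolscreen.simulate import (
    ReadSimConfig,
    amplicons_from_reference,
    assign_indexes,
    build_layout,
    build_toy_reference,
    simulate_population,
)


@pytest.fixture(scope="session")
def toy_reference():
    return build_toy_reference(2, 300, seed=7)


@pytest.fixture(scope="session")
def small_world():
    """A 32-plant simulated world with noiseless reads, shared across tests."""
    reference = build_toy_reference(1, 300, seed=11)
    population = simulate_population(
        reference, 32, per_round_density=2e-3, seed=12,
        n_background_polymorphisms=3)
    layout = assign_indexes(build_layout(32, plant_ids=population.plant_ids))
    amplicons = amplicons_from_reference(reference)
    read_config = ReadSimConfig(mean_depth_per_pool=6400.0, error_rate=0.0,
                                seed=13)
    return {
        "reference": reference,
        "population": population,
        "layout": layout,
        "amplicons": amplicons,
        "read_config": read_config,
    }


@pytest.fixture(scope="session")
def small_pipeline(small_world):
    result = run_pipeline(
        small_world["reference"], small_world["amplicons"],
        small_world["population"], small_world["layout"],
        small_world["read_config"])
    return {**small_world, "result": result}
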