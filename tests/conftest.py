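import numpy as np
import pytest

from npamyloid.mc import SimulationConfig, desk_preset, init_system


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Two chains in a roomy box: the sparse limit."""
    return SimulationConfig(box_length=20.0, n_chains=2,
                            n_production_steps=1000, n_analysis_steps=100,
                            seed=5)


@pytest.fixture(scope="session")
def small_np_config() -> SimulationConfig:
    """Small but interacting system with nanoparticles of two sizes."""
    cfg = desk_preset(n_chains=40, box_length=14.0,
                      n_production_steps=20_000, n_analysis_steps=4_000,
                      seed=9)
    from npamyloid.mc import NanoparticleSpec
    nps = [NanoparticleSpec(diameter=3.0) for _ in range(3)]
    nps += [NanoparticleSpec(diameter=2.0) for _ in range(2)]
    return cfg.model_copy(update={"nanoparticles": nps})


@pytest.fixture()
def small_np_state(small_np_config):
    return init_system(small_np_config, seed=4)
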