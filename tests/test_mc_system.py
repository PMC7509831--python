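"""System initialization, invariants, determinism and limiting behavior."""

import numpy as np
import pytest

from npamyloid.errors import PackingError
from npamyloid.mc import (NanoparticleSpec, SimulationConfig, desk_preset,
                          init_system, run_simulation)


def test_init_satisfies_all_invariants(small_np_state):
    small_np_state.validate()


def test_init_is_deterministic(small_np_config):
    a = init_system(small_np_config, seed=3)
    b = init_system(small_np_config, seed=3)
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.np_centers, b.np_centers)
    assert a.bond_pairs() == b.bond_pairs()
    c = init_system(small_np_config, seed=4)
    assert not np.array_equal(a.positions, c.positions)


def test_sparse_limit_two_chains(tiny_config):
    state = init_system(tiny_config, seed=1)
    assert state.chain_positions.shape == (2, 8, 3)
    assert len(state.bond_pairs()) <= 2
    state.validate()


def test_oversized_nanoparticle_rejected_by_config():
    with pytest.raises(ValueError, match="box_length"):
        SimulationConfig(box_length=10.0, n_chains=5,
                         n_production_steps=100, n_analysis_steps=10,
                         nanoparticles=[NanoparticleSpec(diameter=9.0)])


def test_overpacked_system_reports_density_too_high():
    cfg = SimulationConfig(box_length=6.0, n_chains=60,
                           n_production_steps=100, n_analysis_steps=10)
    with pytest.raises(PackingError, match="density too high"):
        init_system(cfg, seed=0)


def test_noninteracting_limit_gives_unit_clusters():
    """eps_hb = 0 and no adsorption: no bonds ever form, every chain is its
    own aggregate."""
    cfg = desk_preset(n_chains=25, box_length=12.0, eps_hb=0.0,
                      n_production_steps=20_000, n_analysis_steps=5_000,
                      seed=6)
    rep = run_simulation(cfg, 0)
    assert rep.mean_chains_per_aggregate == 1.0
    assert all((s == 1).all() for s in rep.cluster_sizes)


def test_aggregation_occurs_at_strong_coupling():
    cfg = desk_preset(n_chains=40, box_length=12.0,
                      n_production_steps=30_000, n_analysis_steps=5_000,
                      seed=12)
    rep = run_simulation(cfg, 0)
    assert rep.mean_chains_per_aggregate > 1.0


def test_run_is_deterministic(small_np_config):
    cfg = small_np_config
    a = run_simulation(cfg, 0)
    b = run_simulation(cfg, 0)
    assert a.mean_chains_per_aggregate == b.mean_chains_per_aggregate
    assert a.final_energy == b.final_energy
    assert a.n_accepted == b.n_accepted
    c = run_simulation(cfg, 1)
    assert c.seed == cfg.seed + 1


def test_energy_bookkeeping_never_drifts(small_np_config):
    cfg = small_np_config.model_copy(update={"n_production_steps": 20_000,
                                             "n_analysis_steps": 2_000})
    rep = run_simulation(cfg, 0, check_energy=True)
    assert rep.max_energy_drift < 1e-8


def test_cluster_sizes_partition_the_chains(small_np_config):
    rep = run_simulation(small_np_config, 0)
    for sizes in rep.cluster_sizes:
        assert sizes.sum() == small_np_config.n_chains
        assert (sizes >= 1).all()
    assert 1.0 <= rep.mean_chains_per_aggregate <= small_np_config.n_chains


def test_final_state_invariants_after_run(small_np_config):
    rep, state = run_simulation(small_np_config, 0, return_state=True)
    state.validate()
    assert state.energy == pytest.approx(state.recompute_energy(), abs=1e-8)


def test_surface_area_matching_rules():
    import math

    from npamyloid.errors import DataError
    from npamyloid.mc import matched_np_counts, size_sweep

    # area of exactly one particle of diameter d gives a count of one
    assert matched_np_counts([3.0], math.pi * 9.0) == [1]
    # a diameter whose count rounds to zero is a budget error, raised
    # before any simulation runs
    base = desk_preset(n_chains=10, box_length=40.0,
                       n_production_steps=100, n_analysis_steps=10)
    with pytest.raises(DataError, match="budget too small"):
        size_sweep([2.0, 15.0], math.pi * 4.0, base)


def test_move_weights_must_sum_to_one():
    with pytest.raises(ValueError, match="sum to 1"):
        SimulationConfig(box_length=20.0, n_chains=5,
                         n_production_steps=100, n_analysis_steps=10,
                         move_weights=(0.5, 0.5, 0.5, 0.5))
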