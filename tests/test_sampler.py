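import math

import numpy as np
import pytest

from confspace.distributions import make_continuous
from confspace.sampler import (ProtocolConfig, gaussian_on_grid, init_state,
                               optimize_structure, run_iteration,
                               run_protocol, run_free, subtract_conformer,
                               target_function, _structure_seed)
from confspace.structure import Conformer
from confspace.synthetic import make_benchmark, simulate_distributions

from conftest import discrete_gaussian


# ------------------------------------------------------------- config

def test_default_protocol_bookkeeping():
    cfg = ProtocolConfig()
    assert cfg.n_iterations == 250
    assert cfg.n_calculated == 100
    assert cfg.n_selected == 10
    assert cfg.ensemble_size == 2500
    assert cfg.subtraction_area == 1.0 / 2500
    assert cfg.sigma_sub == 2.5
    assert cfg.A == 10.0
    assert cfg.c == 0.75


def test_selected_cannot_exceed_calculated():
    with pytest.raises(ValueError):
        ProtocolConfig(n_calculated=5, n_selected=6)


def test_gaussian_on_grid_area():
    grid = np.arange(0.0, 100.0, 0.1)
    g = gaussian_on_grid(grid, 50.0, 2.5, 1.0 / 2500)
    assert abs(np.trapezoid(g, grid) - 1.0 / 2500) < 1e-9


# ---------------------------------------------------------- init_state

def test_init_state_copies_originals():
    cont = make_continuous(discrete_gaussian(step=0.1))
    cfg = ProtocolConfig(n_iterations=2, n_calculated=2, n_selected=1)
    state = init_state({"p": cont}, cfg)
    w = state.working["p"]
    np.testing.assert_allclose(w.density, cont.evaluate(w.grid), atol=1e-9)
    assert state.history == 0


def test_init_state_empty_is_error():
    with pytest.raises(ValueError, match="empty"):
        init_state({}, ProtocolConfig())


def test_init_state_duplicate_labels_is_error():
    cont = make_continuous(discrete_gaussian())
    with pytest.raises(ValueError, match="duplicate"):
        init_state([("p", cont), ("p", cont)], ProtocolConfig())


def test_init_state_requires_unit_area():
    from confspace.distributions import DistanceDistribution
    r = np.linspace(20, 40, 201)
    d = DistanceDistribution(r=r, p=np.full_like(r, 0.5))  # area 10
    with pytest.raises(ValueError, match="unit-area"):
        init_state({"p": make_continuous(d)}, ProtocolConfig())


# ----------------------------------------------------------- subtraction

def _one_restraint_state(mu=30.0, sigma=2.5, n_iter=5, n_sel=2):
    cont = make_continuous(discrete_gaussian(mu=mu, sigma=sigma, step=0.1))
    cfg = ProtocolConfig(n_iterations=n_iter, n_calculated=max(4, n_sel),
                         n_selected=n_sel, anneal_steps=10)
    return init_state({"p": cont}, cfg), cfg


def _conformer_at(dist_value):
    return Conformer(quaternion=[0.0, 0.0, 0.0, 1.0], translation=np.zeros(3),
                     linker_torsions=[0.0], linker_bends=[0.0],
                     pair_distances={"p": dist_value})


def test_subtract_clamps_at_zero():
    state, cfg = _one_restraint_state(mu=30.0)
    w = state.working["p"]
    far = w.grid[-1]  # tail, density ~0
    before = w.density.copy()
    subtract_conformer(state, _conformer_at(far), cfg)
    assert np.all(w.density >= 0.0)
    # region far from the subtraction centre is untouched
    near_mu = np.abs(w.grid - 30.0) < 1.0
    np.testing.assert_allclose(w.density[near_mu], before[near_mu], atol=1e-12)


def test_subtract_area_is_one_over_n():
    state, cfg = _one_restraint_state(n_iter=250 // 2, n_sel=20)  # n = 2500
    assert cfg.subtraction_area == 1.0 / 2500
    w = state.working["p"]
    before = w.density.copy()
    subtract_conformer(state, _conformer_at(30.0), cfg)
    removed = np.trapezoid(before - w.density, w.grid)
    # nothing clamped at the mode of a unit-area original
    assert abs(removed - 1.0 / 2500) < 1e-9
    assert state.history == 1


def test_n_subtractions_cancel_matching_original():
    # n Gaussians of area 1/n at the original's mean cancel it exactly at mu
    n_iter, n_sel = 5, 4
    state, cfg = _one_restraint_state(mu=40.0, sigma=2.5, n_iter=n_iter,
                                      n_sel=n_sel)
    w = state.working["p"]
    for _ in range(n_iter * n_sel):
        subtract_conformer(state, _conformer_at(40.0), cfg)
    at_mu = np.argmin(np.abs(w.grid - 40.0))
    assert w.density[at_mu] < 1e-6
    assert w.subtracted_area == pytest.approx(1.0, abs=1e-9)


def test_working_area_non_increasing():
    state, cfg = _one_restraint_state()
    w = state.working["p"]
    areas = [w.area]
    rng = np.random.default_rng(0)
    for _ in range(10):
        subtract_conformer(state, _conformer_at(rng.uniform(25, 35)), cfg)
        areas.append(w.area)
    assert all(a2 <= a1 + 1e-12 for a1, a2 in zip(areas, areas[1:]))


def test_subtract_missing_distance_is_error():
    state, cfg = _one_restraint_state()
    conf = _conformer_at(30.0)
    conf.pair_distances = {}
    with pytest.raises(KeyError):
        subtract_conformer(state, conf, cfg)


# ------------------------------------------------------- target function

@pytest.fixture(scope="module")
def small_bench():
    system, truth, dists, restraints = make_benchmark(seed=1, n_label_pairs=2)
    return system, truth, dists, restraints


def test_target_zero_restraints_steric_only(small_bench):
    system, truth, dists, restraints = small_bench
    cfg = ProtocolConfig(n_iterations=1, n_calculated=1, n_selected=1,
                         anneal_steps=150, rng_seed=3)
    conf = optimize_structure(system, None, cfg, 0)
    assert conf.target_value == pytest.approx(0.0, abs=1e-9)
    placement = system.place(conf)
    from confspace.structure import steric_score
    assert steric_score(placement, system.stationary, system.moving) == 0.0


def test_target_violated_restraint_contributes_at_least_A(small_bench):
    system, truth, dists, restraints = small_bench
    # a restraint whose support no conformer can reach: P = 0 there
    unreachable = discrete_gaussian(mu=500.0, sigma=2.5, step=0.1, label="far")
    cfg = ProtocolConfig(n_iterations=1, n_calculated=1, n_selected=1)
    label = dists[0].label
    state = init_state({label: make_continuous(
        discrete_gaussian(mu=500.0, sigma=2.5, step=0.1))}, cfg)
    conf = Conformer(quaternion=[0, 0, 0, 1.0], translation=np.zeros(3),
                     linker_torsions=np.zeros(system.linker.n_residues),
                     linker_bends=np.zeros(system.linker.n_residues))
    value = target_function(conf, state, cfg, system)
    assert value >= 10.0


def test_target_additivity_monotone(small_bench):
    system, truth, dists, restraints = small_bench
    cfg = ProtocolConfig(n_iterations=1, n_calculated=1, n_selected=1)
    far1 = make_continuous(discrete_gaussian(mu=500.0, sigma=2.5, step=0.1))
    far2 = make_continuous(discrete_gaussian(mu=600.0, sigma=2.5, step=0.1))
    labels = [d.label for d in dists[:2]]
    conf = Conformer(quaternion=[0, 0, 0, 1.0], translation=np.zeros(3),
                     linker_torsions=np.zeros(system.linker.n_residues),
                     linker_bends=np.zeros(system.linker.n_residues))
    one = target_function(conf, init_state({labels[0]: far1}, cfg), cfg, system)
    two = target_function(conf, init_state({labels[0]: far1, labels[1]: far2},
                                           cfg), cfg, system)
    assert two >= one - 1e-12


# ----------------------------------------------------------- optimization

def test_optimize_reaches_plateau_single_restraint():
    system, truth, dists, restraints = make_benchmark(seed=2, n_states=1,
                                                      n_label_pairs=1)
    (label, cont), = restraints.items()
    cfg = ProtocolConfig(n_iterations=1, n_calculated=1, n_selected=1,
                         anneal_steps=900, rng_seed=5)
    state = init_state({label: cont}, cfg)
    conf = optimize_structure(system, state, cfg, 1)
    d = conf.pair_distances[label]
    # plateau of a Gaussian: normalized density >= 0.75
    assert cont.evaluate(d) / cont.p_max >= 0.75 - 1e-6


def test_optimize_deterministic(small_bench):
    system, truth, dists, restraints = small_bench
    cfg = ProtocolConfig(n_iterations=1, n_calculated=1, n_selected=1,
                         anneal_steps=200, rng_seed=0)
    state1 = init_state(restraints, cfg)
    state2 = init_state(restraints, cfg)
    c1 = optimize_structure(system, state1, cfg, 42)
    c2 = optimize_structure(system, state2, cfg, 42)
    np.testing.assert_array_equal(c1.quaternion, c2.quaternion)
    np.testing.assert_array_equal(c1.linker_torsions, c2.linker_torsions)
    assert c1.target_value == c2.target_value
    assert c1.pair_distances == c2.pair_distances


# ------------------------------------------------------------ iterations

def test_run_iteration_selects_lowest(small_bench):
    system, truth, dists, restraints = small_bench
    cfg = ProtocolConfig(n_iterations=2, n_calculated=5, n_selected=2,
                         anneal_steps=60, rng_seed=9)
    state = init_state(restraints, cfg)
    selected = run_iteration(system, state, cfg, iteration=0, subtract=False)
    # oracle: recompute all five structures from their derived seeds
    all_targets = [optimize_structure(system, state, cfg,
                                      _structure_seed(cfg.rng_seed, 0, i)).target_value
                   for i in range(cfg.n_calculated)]
    expect = sorted(all_targets)[:2]
    assert [c.target_value for c in selected] == expect


def test_run_iteration_increments_history(small_bench):
    system, truth, dists, restraints = small_bench
    cfg = ProtocolConfig(n_iterations=2, n_calculated=4, n_selected=3,
                         anneal_steps=60, rng_seed=9)
    state = init_state(restraints, cfg)
    run_iteration(system, state, cfg, iteration=0)
    assert state.history == 3


def test_run_iteration_tie_break_by_index(small_bench):
    system, truth, dists, restraints = small_bench
    cfg = ProtocolConfig(n_iterations=1, n_calculated=4, n_selected=4,
                         anneal_steps=60, rng_seed=9)
    state = init_state(restraints, cfg)
    selected = run_iteration(system, state, cfg, iteration=0, subtract=False)
    targets = [c.target_value for c in selected]
    # ascending order; equal values keep ascending seed-index order
    assert targets == sorted(targets)


# -------------------------------------------------------------- protocol

def test_run_protocol_size_arithmetic(small_bench):
    system, truth, dists, restraints = small_bench
    cfg = ProtocolConfig(n_iterations=4, n_calculated=3, n_selected=2,
                         anneal_steps=50, rng_seed=2)
    ens = run_protocol(system, restraints, cfg)
    assert len(ens.conformers) == 8
    assert ens.restraint_labels == tuple(restraints)


def test_run_protocol_total_subtracted_area(small_bench):
    system, truth, dists, restraints = small_bench
    cfg = ProtocolConfig(n_iterations=4, n_calculated=3, n_selected=2,
                         anneal_steps=50, rng_seed=2)
    captured = {}
    ens = run_protocol(system, restraints, cfg,
                       callback=lambda it, state, sel: captured.update(state=state))
    for w in captured["state"].working.values():
        assert w.subtracted_area == pytest.approx(1.0, abs=1e-9)


def test_run_protocol_flattening_progress(small_bench):
    system, truth, dists, restraints = small_bench
    cfg = ProtocolConfig(n_iterations=6, n_calculated=4, n_selected=2,
                         anneal_steps=150, rng_seed=2)
    area_series = {lab: [] for lab in restraints}
    def cb(it, state, sel):
        for lab, w in state.working.items():
            area_series[lab].append(w.area)
    run_protocol(system, restraints, cfg, callback=cb)
    for lab, series in area_series.items():
        assert all(a2 <= a1 + 1e-12 for a1, a2 in zip(series, series[1:]))
        assert series[-1] < series[0]


def test_run_protocol_reproducible(small_bench):
    system, truth, dists, restraints = small_bench
    cfg = ProtocolConfig(n_iterations=2, n_calculated=3, n_selected=2,
                         anneal_steps=80, rng_seed=11)
    e1 = run_protocol(system, restraints, cfg)
    e2 = run_protocol(system, restraints, cfg)
    for c1, c2 in zip(e1.conformers, e2.conformers):
        np.testing.assert_array_equal(c1.quaternion, c2.quaternion)
        assert c1.pair_distances == c2.pair_distances


def test_run_free_has_no_restraint_labels(small_bench):
    system, truth, dists, restraints = small_bench
    cfg = ProtocolConfig(n_iterations=2, n_calculated=3, n_selected=2,
                         anneal_steps=60, rng_seed=4)
    ens = run_free(system, cfg)
    assert len(ens.conformers) == 4
    assert ens.restraint_labels == ()
    # distances are still recorded for every declared pair
    for conf in ens.conformers:
        assert set(conf.pair_distances) == set(system.pairs)
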