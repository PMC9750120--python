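"""1D loop-extrusion kinetics: binding, stepping, stalling, oracle equivalence."""

import numpy as np
import pytest
from scipy import stats as sps

from polyloopsim.genome_config import (
    BoundaryElement,
    ConfigError,
    GenomeAnnotation,
)
from polyloopsim.lef_engine import (
    LEFSystem,
    advance_1d,
    attempt_leg_step,
    bind_lef,
    exact_stationary_oracle,
    init_population,
    occupancy_accumulate,
    state_of,
)

from conftest import make_params


def _single_lef_system(n_monomers, seed, k_bind=2.0, k_unbind=1.0, step_rate=3.0,
                       boundaries=(), loading=(), **param_overrides):
    params = make_params(
        chain_length_kb=2 * n_monomers,
        n_lef_target=1,
        velocity_kb_per_min=step_rate * 2,
        unbind_rate_per_min=k_unbind,
        **param_overrides,
    )
    genome = GenomeAnnotation(
        n_monomers=n_monomers, boundaries=list(boundaries), loading_sites=list(loading)
    )
    return LEFSystem(params, genome, seed, pool_size=1, k_bind=k_bind), params, genome


class TestPopulation:
    def test_density_parameterization_six_mb_example(self):
        # 1 bound LEF per 60 kb on a 6 Mb chain -> 100 simultaneously bound
        params = make_params(chain_length_kb=6000, n_lef_target=6000 // 60)
        genome = GenomeAnnotation(n_monomers=params.n_monomers)
        system = init_population(params, genome, seed=0)
        assert params.n_lef_target == 100
        assert system.pool_size == 200
        # with pool 2*target, k_bind = k_unbind gives mean bound = target
        assert system.k_bind == pytest.approx(system.k_unbind)

    def test_zero_lefs_never_produce_events(self):
        params = make_params(n_lef_target=0)
        genome = GenomeAnnotation(n_monomers=params.n_monomers)
        system = init_population(params, genome, seed=1)
        _, log = advance_1d(system, 50.0, record=True)
        assert log == [] and system.n_bound == 0

    def test_overfull_pool_rejected(self):
        params = make_params(chain_length_kb=20, n_lef_target=6)
        genome = GenomeAnnotation(n_monomers=10)
        with pytest.raises(ConfigError, match="n_lef_target"):
            init_population(params, genome, seed=0)

    def test_same_seed_identical_event_log(self):
        params = make_params(n_lef_target=3)
        genome = GenomeAnnotation(
            n_monomers=params.n_monomers, boundaries=[BoundaryElement(30)]
        )
        logs = []
        for _ in range(2):
            system = init_population(params, genome, seed=42)
            _, log = advance_1d(system, 30.0, record=True)
            logs.append(log)
        assert logs[0] == logs[1]

    def test_stationary_bound_fraction_two_state_closed_form(self):
        # one LEF, binding at 2/min, unbinding at 1/min -> bound 2/3 of the time
        system, *_ = _single_lef_system(20, seed=3, k_bind=2.0, k_unbind=1.0)
        advance_1d(system, 4000.0)
        bound_frac = system.stats["bound_time"] / system.stats["elapsed"]
        assert bound_frac == pytest.approx(2.0 / 3.0, abs=0.02)


class TestBinding:
    def test_uniform_binding_is_uniform_over_adjacent_pairs(self):
        system, *_ = _single_lef_system(30, seed=7)
        counts = np.zeros(29)
        for _ in range(20000):
            assert bind_lef(system, 0)
            counts[system.lefs[0].left_leg] += 1
            system._unbind(0)
        chi2, p = sps.chisquare(counts)
        assert p > 1e-3

    def test_loading_site_binding_is_anchored(self):
        system, *_ = _single_lef_system(
            30, seed=8, loading=[10], rebind_mode="loading_sites"
        )
        for _ in range(50):
            assert bind_lef(system, 0)
            lef = system.lefs[0]
            assert (lef.left_leg, lef.right_leg) == (10, 11)
            system._unbind(0)

    def test_rejected_binding_leaves_system_unchanged(self):
        # impenetrable mode with the single loading pair already occupied
        params = make_params(
            chain_length_kb=20, n_lef_target=2, rebind_mode="loading_sites"
        )
        genome = GenomeAnnotation(n_monomers=10, loading_sites=[4])
        system = init_population(params, genome, seed=9)
        assert bind_lef(system, 0)
        occ_before = system.occ.copy()
        assert not bind_lef(system, 1)
        assert np.array_equal(system.occ, occ_before)
        assert system.stats["n_bind_rejected"] == 1

    def test_asymmetric_binding_has_exactly_one_mobile_leg(self):
        system, *_ = _single_lef_system(30, seed=10, extrusion_mode="asymmetric")
        sides = set()
        for _ in range(100):
            bind_lef(system, 0)
            lef = system.lefs[0]
            assert lef.left_mobile != lef.right_mobile
            sides.add("L" if lef.left_mobile else "R")
            system._unbind(0)
        assert sides == {"L", "R"}  # both anchors occur


class TestLegStep:
    def test_impermeable_boundary_stalls_arriving_leg(self):
        system, *_ = _single_lef_system(
            12, seed=1, boundaries=[BoundaryElement(5, "blocks_leftward", 0.0)]
        )
        lef = system.lefs[0]
        lef.bound = True
        lef.left_leg, lef.right_leg = 6, 7
        system.occ[6] += 1
        system.occ[7] += 1
        system.bound_ids.append(0)
        system.unbound_ids.remove(0)
        for _ in range(20):
            assert attempt_leg_step(system, 0, "left") == "stalled_boundary"
        assert lef.left_leg == 6

    def test_directionality_only_blocks_the_stated_direction(self):
        # blocks_leftward does not impede a rightward-moving leg
        system, *_ = _single_lef_system(
            12, seed=2, boundaries=[BoundaryElement(8, "blocks_leftward", 0.0)]
        )
        lef = system.lefs[0]
        lef.bound = True
        lef.left_leg, lef.right_leg = 6, 7
        system.occ[6] += 1
        system.occ[7] += 1
        system.bound_ids.append(0)
        system.unbound_ids.remove(0)
        assert attempt_leg_step(system, 0, "right") == "moved"
        assert lef.right_leg == 8

    def test_transparent_boundary_always_passes(self):
        system, *_ = _single_lef_system(
            12, seed=3, boundaries=[BoundaryElement(5, "blocks_both", 1.0)]
        )
        lef = system.lefs[0]
        lef.bound = True
        lef.left_leg, lef.right_leg = 6, 7
        system.occ[6] += 1
        system.occ[7] += 1
        system.bound_ids.append(0)
        system.unbound_ids.remove(0)
        assert attempt_leg_step(system, 0, "left") == "moved"

    def test_chain_end_is_a_permanent_block(self):
        system, *_ = _single_lef_system(6, seed=4)
        lef = system.lefs[0]
        lef.bound = True
        lef.left_leg, lef.right_leg = 0, 5
        system.occ[0] += 1
        system.occ[5] += 1
        system.bound_ids.append(0)
        system.unbound_ids.remove(0)
        assert attempt_leg_step(system, 0, "left") == "stalled_boundary"
        assert attempt_leg_step(system, 0, "right") == "stalled_boundary"

    @pytest.mark.parametrize(
        "collision_mode, expected", [("impenetrable", "stalled_collision"),
                                     ("phantom", "crossed_phantom")]
    )
    def test_leg_collision_outcomes(self, collision_mode, expected):
        params = make_params(chain_length_kb=24, n_lef_target=2,
                             collision_mode=collision_mode,
                             rebind_mode="loading_sites")
        genome = GenomeAnnotation(n_monomers=12, loading_sites=[2, 4])
        system = init_population(params, genome, seed=5)
        # place one LEF at (2,3) and one at (4,5): the first one's right
        # leg then targets the occupied site 4
        for _ in range(100):
            if bind_lef(system, 0):
                break
        for _ in range(200):
            if bind_lef(system, 1) and system.lefs[1].left_leg != system.lefs[0].left_leg:
                break
            if system.lefs[1].bound:
                system._unbind(1)
        placed = {system.lefs[0].left_leg, system.lefs[1].left_leg}
        assert placed == {2, 4}
        mover = 0 if system.lefs[0].left_leg == 2 else 1
        outcome = attempt_leg_step(system, mover, "right")
        assert outcome == expected
        if expected == "crossed_phantom":
            assert system.occ[4] == 2
        else:
            assert system.occ[4] == 1

    def test_step_on_unbound_lef_is_a_contract_violation(self):
        system, *_ = _single_lef_system(10, seed=6)
        with pytest.raises(ConfigError):
            attempt_leg_step(system, 0, "left")


class TestAdvance:
    def test_step_rate_is_velocity_over_monomer_size(self):
        params = make_params(velocity_kb_per_min=100.0, monomer_size_kb=2)
        assert params.step_rate_per_min == 50.0

    def test_legs_ordered_and_no_double_occupancy_impenetrable(self):
        params = make_params(chain_length_kb=100, n_lef_target=5,
                             velocity_kb_per_min=30, unbind_rate_per_min=0.2)
        genome = GenomeAnnotation(n_monomers=50,
                                  boundaries=[BoundaryElement(25)])
        system = init_population(params, genome, seed=11)

        def check(sys_, dt):
            assert np.all(sys_.occ <= 1)
            for i in sys_.bound_ids:
                lef = sys_.lefs[i]
                assert 0 <= lef.left_leg <= lef.right_leg < sys_.n_monomers

        _, log = advance_1d(system, 200.0, record=True, observer=check)
        times = [ev.time_min for ev in log]
        assert times == sorted(times)

    def test_phantom_free_leg_is_a_biased_walk(self):
        # phantom collisions + permeability-1 boundaries = free outward walk:
        # mean displacement of each leg is step_rate * t
        step_rate = 5.0
        system, params, _ = _single_lef_system(
            2000, seed=12, k_bind=10.0, k_unbind=1e-9, step_rate=step_rate,
            boundaries=[BoundaryElement(1100, "blocks_both", 1.0)],
            loading=[1000], rebind_mode="loading_sites", collision_mode="phantom",
        )
        advance_1d(system, 1.0)  # binds quickly
        lef = system.lefs[0]
        assert lef.bound
        start_l, start_r = lef.left_leg, lef.right_leg
        t = 40.0
        advance_1d(system, t)
        expected = step_rate * t
        sd = np.sqrt(expected)
        assert abs((start_l - lef.left_leg) - expected) < 4 * sd
        assert abs((lef.right_leg - start_r) - expected) < 4 * sd

    def test_occupancy_accumulate_counts_two_legs_per_bound_lef(self):
        system, *_ = _single_lef_system(20, seed=13)
        acc = np.zeros(20)
        occupancy_accumulate(system, acc)
        assert acc.sum() == 0
        bind_lef(system, 0)
        occupancy_accumulate(system, acc)
        assert acc.sum() == 2
        with pytest.raises(ConfigError):
            occupancy_accumulate(system, np.zeros(7))

    def test_occupancy_peaks_at_impermeable_boundary(self):
        # long 1D-only run: legs pile up against the boundary, so
        # boundary-adjacent occupancy exceeds the TAD interior
        params = make_params(chain_length_kb=80, n_lef_target=3,
                             velocity_kb_per_min=10, unbind_rate_per_min=0.1)
        genome = GenomeAnnotation(n_monomers=40, boundaries=[BoundaryElement(20)])
        system = init_population(params, genome, seed=14)
        occ_time = np.zeros(40)

        def acc(sys_, dt):
            occ_time[:] += sys_.occ * dt

        advance_1d(system, 20000.0, observer=acc)
        near = occ_time[[19, 21]].mean()
        interior = occ_time[[5, 6, 7, 33, 34, 35]].mean()
        assert near > 2 * interior


class TestOracle:
    def test_engine_matches_oracle_symmetric_free_lattice(self):
        n = 6
        system, *_ = _single_lef_system(n, seed=20, k_bind=2.0, k_unbind=1.0,
                                        step_rate=3.0)
        states, pi = exact_stationary_oracle(n, None, 2.0, 1.0, 3.0)
        occ_time = {}

        def acc(sys_, dt):
            st = state_of(sys_)
            occ_time[st] = occ_time.get(st, 0.0) + dt

        advance_1d(system, 6000.0, observer=acc)
        total = sum(occ_time.values())
        for st, p in zip(states, pi):
            freq = occ_time.get(st, 0.0) / total
            se = np.sqrt(max(p * (1 - p), 1e-12) / (total * 1.0))
            # generous envelope for this smoke check; the acceptance suite
            # does the batch-means 3-sigma comparison across all modes
            assert abs(freq - p) < 0.02 + 5 * se

    def test_unbind_dominated_limit_concentrates_on_unbound(self):
        states, pi = exact_stationary_oracle(6, None, 1.0, 1e6, 3.0)
        assert pi[states.index(("U",))] > 0.999

    def test_states_beyond_impermeable_boundary_are_unreachable(self):
        # LEFs load at site 4; a blocks_leftward permeability-0 boundary at
        # site 2 means the left leg can never enter site 2, so every state
        # with left_leg <= 2 is unreachable and carries zero mass
        genome = GenomeAnnotation(
            n_monomers=6,
            boundaries=[BoundaryElement(2, "blocks_leftward", 0.0)],
            loading_sites=[4],
        )
        states, pi = exact_stationary_oracle(
            6, genome, 2.0, 1.0, 3.0, rebind_mode="loading_sites"
        )
        mass = sum(p for st, p in zip(states, pi) if st != ("U",) and st[0] <= 2)
        assert mass == pytest.approx(0.0, abs=1e-12)

    def test_oracle_rejects_large_lattices(self):
        with pytest.raises(ConfigError):
            exact_stationary_oracle(13, None, 1.0, 1.0, 1.0)
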