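import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metevo import active_support, fitness, initial_network, steady_state
from metevo.evolution import (
    Mutation,
    _apply_mutation,
    apply_kinetic_mutation,
    enumerate_mutations,
    evolve,
    greedy_step,
    is_local_optimum,
    mutated_roots,
)
from metevo.model_core import as_scenario


class TestKineticMutation:
    def test_two_slot_step(self, params):
        out = mutated_roots(np.array([0.5, 0.5]), 0, +1, params.m)
        np.testing.assert_allclose(out, [0.55, 0.45])

    def test_specialized_down_spreads_uniformly(self, params):
        roots = np.zeros(16)
        roots[0] = 1.0
        out = mutated_roots(roots, 0, -1, params.m)
        assert out[0] == pytest.approx(0.95)
        np.testing.assert_allclose(out[1:], 0.05 / 15)

    def test_infeasible_moves(self, params):
        roots = np.zeros(16)
        roots[0] = 1.0
        assert mutated_roots(roots, 0, +1, params.m) is None   # budget exhausted
        assert mutated_roots(roots, 3, -1, params.m) is None   # decreasing zero
        with pytest.raises(ValueError):
            apply_kinetic_mutation(
                type("G", (), {"roots": roots, "copy": lambda s: s})(), 3, -1,
                params)

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=16),
           st.integers(0, 15), st.sampled_from([+1, -1]))
    @settings(derandomize=True, max_examples=200)
    def test_budget_preserved_to_machine_precision(self, raw, slot, direction):
        roots = np.array(raw) / np.sum(raw)
        out = mutated_roots(roots, slot % len(roots), direction, 0.05)
        if out is not None:
            assert abs(out.sum() - 1.0) < 1e-12
            assert np.all(out >= 0)


class TestEnumerateMutations:
    def test_ancestor_candidate_count(self, ancestor, params):
        muts = enumerate_mutations(ancestor, params)
        kinetic = [m for m in muts if m.kind.startswith("kinetic")]
        structural = [m for m in muts if not m.kind.startswith("kinetic")]
        # 5 enzymes x 16 slots x 2 + 1 transporter x 32 slots x 2
        assert len(kinetic) == 224
        assert len(structural) == 12

    def test_specialized_slot_has_no_up_move(self, ancestor, params):
        net = ancestor.copy()
        net.enzymes[0].roots[:] = 0.0
        net.enzymes[0].roots[4] = 1.0
        muts = enumerate_mutations(net, params)
        assert not any(m.kind == "kinetic_up" and m.gene_type == "enzyme"
                       and m.gene_index == 0 and m.reaction_index == 4
                       for m in muts)

    def test_enumeration_is_deterministic(self, ancestor, params):
        assert enumerate_mutations(ancestor, params) == \
            enumerate_mutations(ancestor, params)


class TestGreedyWalk:
    def test_step_from_ancestor_improves_fitness(self, ancestor, params):
        net2, mut = greedy_step(ancestor, "M1", params)
        assert mut is not None
        assert fitness(net2, "M1", params) > fitness(ancestor, "M1", params)

    def test_trajectory_fitness_strictly_increases(self, evolved_m1, params):
        _, traj = evolved_m1
        fits = [traj.start_fitness] + traj.fitnesses
        assert all(b > a for a, b in zip(fits, fits[1:]))

    def test_final_network_survives_exhaustive_audit(self, evolved_m1, params):
        net, _ = evolved_m1
        assert is_local_optimum(net, "M1", params)

    def test_walk_is_deterministic(self, ancestor, params):
        _, t1 = evolve(ancestor, "M1", params, max_generations=40)
        _, t2 = evolve(ancestor, "M1", params, max_generations=40)
        assert [str(r.mutation) for r in t1.records] == \
            [str(r.mutation) for r in t2.records]
        assert t1.fitnesses == t2.fitnesses  # byte-identical trajectory

    def test_enzymes_specialize_over_the_walk(self, evolved_m1, ancestor, params):
        net, _ = evolved_m1
        mean_start = np.mean([len(active_support(e, params))
                              for e in ancestor.enzymes])
        mean_end = np.mean([len(active_support(e, params))
                            for e in net.enzymes])
        assert mean_start == 16.0
        assert mean_end < 16.0

    def test_tradeoff_constraint_holds_along_walk(self, ancestor, params):
        net = ancestor.copy()
        for _ in range(25):
            net, mut = greedy_step(net, "M1", params)
            if mut is None:
                break
            for g in net.enzymes + net.transporters:
                assert abs(g.roots.sum() - 1.0) < 1e-12


class TestTinyWorldOracle:
    """On a 4-metabolite universe the greedy choice is cross-checked against a
    brute-force sweep whose fitness comes from the independent full-ODE
    integration route."""

    @staticmethod
    def _brute_fitness(net, scenario, params):
        sc = as_scenario(scenario)
        ws = []
        for lbl in sc.media:
            r = steady_state(net, net.world.media[lbl], params,
                             method="integrate")
            w = r.W if r.converged else 0.0
            if w <= 0:
                return 0.0
            ws.append(w)
        return float(np.exp(np.mean(np.log(ws))))

    def test_greedy_choice_matches_brute_force(self, tiny_ancestor, tiny_params):
        net = tiny_ancestor
        for _step in range(3):
            stepped, mut = greedy_step(net, "M1", tiny_params)
            muts = enumerate_mutations(net, tiny_params)
            kinetic = [m for m in muts if m.kind.startswith("kinetic")]
            brute = {m: self._brute_fitness(_apply_mutation(net, m, tiny_params),
                                            "M1", tiny_params) for m in kinetic}
            best = max(brute.values())
            assert mut is not None and mut.kind.startswith("kinetic")
            # the fixed mutation is optimal up to solver equivalence
            assert brute[mut] >= best * (1 - 1e-7)
            net = stepped

    def test_tiny_walk_terminates_and_continuation_is_trivial(
            self, tiny_ancestor, tiny_params):
        net, traj = evolve(tiny_ancestor, "M1", tiny_params)
        assert traj.terminated
        again, traj2 = evolve(net, "M1", tiny_params)
        assert traj2.records == []  # already at the local optimum
        assert fitness(again, "M1", tiny_params) == \
            fitness(net, "M1", tiny_params)


class TestModelVariants:
    def test_frequent_duplication_pool_still_terminates(self, tiny_world):
        from metevo import ModelParams, initial_network

        p = ModelParams(n_groups=2, n_biomass=2, dup_frequent=True)
        net0 = initial_network(tiny_world, p)
        net, traj = evolve(net0, "M1", p)
        assert traj.terminated
        fits = [traj.start_fitness] + traj.fitnesses
        assert all(b > a for a, b in zip(fits, fits[1:]))

    def test_background_floor_keeps_every_reaction_alive(self, tiny_world):
        from metevo import initial_network
        from metevo.io_cli import make_params
        from metevo.kinetics import Pack, reachable_metabolites

        p = make_params("background", {"n_groups": 2, "n_biomass": 2})
        assert p.k_bg > 0
        net0 = initial_network(tiny_world, p)
        net, traj = evolve(net0, "M1", p)
        assert traj.terminated
        # even a fully specialized enzyme keeps residual activity everywhere,
        # so every metabolite stays reachable from the medium
        reach = reachable_metabolites(Pack(net, p),
                                      net.world.media["M1"].external)
        assert reach.all()


class TestDuplicationSemantics:
    def test_duplication_adds_independent_copy(self, ancestor, params):
        net = _apply_mutation(ancestor, Mutation("duplication", "enzyme", 2),
                              params)
        assert len(net.enzymes) == 6
        assert net.enzymes[-1].dosage == 1.0
        np.testing.assert_array_equal(net.enzymes[-1].roots,
                                      net.enzymes[2].roots)
        net.enzymes[-1].roots[0] = 0.9  # mutable independently of the parent
        assert net.enzymes[2].roots[0] != 0.9

    def test_deletion_removes_one_gene(self, ancestor, params):
        net = _apply_mutation(ancestor, Mutation("deletion", "transporter", 0),
                              params)
        assert len(net.transporters) == 0
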