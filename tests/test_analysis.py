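import numpy as np
import pytest
from scipy.linalg import null_space

from metevo import Enzyme, Transporter, fitness
from metevo.analysis import (
    batch_run,
    classify_multifunctional_role,
    enzyme_types,
    independent_flux_count,
    is_multifunctional,
    knockout_fitness,
    knockout_network,
    knockout_profile,
    nullity,
    stoichiometric_matrix,
)


class TestEnzymeTypes:
    def test_ancestor_partitions_by_group(self, ancestor, params):
        types = enzyme_types(ancestor, params)
        etypes = [t for t in types if not t.is_transporter]
        assert len(etypes) == 5
        assert len(types) - len(etypes) == 1
        assert all(len(t.support) == 16 for t in etypes)

    def test_exact_duplicates_share_a_type(self, ancestor, params):
        net = ancestor.copy()
        net.enzymes.append(net.enzymes[1].copy())
        types = [t for t in enzyme_types(net, params) if not t.is_transporter]
        assert len(types) == 5
        doubled = [t for t in types if t.n_members == 2]
        assert len(doubled) == 1 and set(doubled[0].members) == {1, 5}

    def test_diverged_copies_split_types(self, ancestor, params):
        net = ancestor.copy()
        twin = net.enzymes[1].copy()
        twin.roots[:] = 0.0
        twin.roots[[0, 1]] = 0.5  # disjoint-support sibling
        net.enzymes.append(twin)
        types = [t for t in enzyme_types(net, params) if not t.is_transporter]
        assert len(types) == 6


class TestMultifunctionality:
    def test_support_size_threshold(self, ancestor, params):
        types = enzyme_types(ancestor, params)
        etype = next(t for t in types if not t.is_transporter)
        assert is_multifunctional(etype, params)  # 16 active reactions
        ttyp = next(t for t in types if t.is_transporter)
        with pytest.raises(ValueError):
            is_multifunctional(ttyp, params)

    @pytest.mark.parametrize("n_active,expected", [(2, False), (3, True)])
    def test_two_reactions_is_one_coupled_transfer(self, ancestor, params,
                                                   n_active, expected):
        net = ancestor.copy()
        e = net.enzymes[0]
        e.roots[:] = 0.0
        e.roots[:n_active] = 1.0 / n_active
        etype = next(t for t in enzyme_types(net, params)
                     if not t.is_transporter and t.members == (0,))
        assert is_multifunctional(etype, params) is expected


class TestKnockouts:
    def test_losing_the_only_importer_is_lethal(self, evolved_m1, params):
        net, _ = evolved_m1
        types = enzyme_types(net, params)
        # remove every transporter at once: nothing can enter the cell
        dead = net.copy()
        dead.transporters = []
        assert fitness(dead, "M1", params) == 0.0
        # and the full per-type profile brackets it: wild type is alive
        prof = knockout_profile(net, "M1", params)
        assert (prof["rel_W"] >= 0).all()

    def test_zero_rate_gene_knockout_saves_cost(self, evolved_m1, params):
        net, _ = evolved_m1
        net = net.copy()
        net.enzymes.append(Enzyme(0, 0.3, np.zeros(16), params.alpha))
        etype = next(t for t in enzyme_types(net, params)
                     if not t.is_transporter and t.support == frozenset())
        rel = knockout_fitness(net, etype, "M1", params)
        assert rel > 1.0  # removal shrinks the cost denominator only

    def test_dead_wild_type_is_an_error(self, ancestor, params):
        dead = ancestor.copy()
        dead.transporters = []
        etype = enzyme_types(dead, params)[0]
        with pytest.raises(ValueError):
            knockout_fitness(dead, etype, "M1", params)

    def test_knockout_removes_all_type_members(self, ancestor, params):
        net = ancestor.copy()
        net.enzymes.append(net.enzymes[0].copy())
        etype = next(t for t in enzyme_types(net, params) if t.n_members == 2)
        ko = knockout_network(net, etype)
        assert len(ko.enzymes) == 4


class TestRoleClassification:
    def test_overlapping_supports_are_isoenzymes(self, ancestor, params):
        net = ancestor.copy()
        net.enzymes.append(net.enzymes[0].copy())
        net.enzymes[-1].roots[0] += 1e-3  # distinct gene, same active support?
        # force distinct supports that overlap: shrink the copy to 3 slots
        net.enzymes[-1].roots[:] = 0.0
        net.enzymes[-1].roots[[0, 1, 2]] = 1 / 3
        etype = next(t for t in enzyme_types(net, params)
                     if not t.is_transporter and t.members == (5,))
        assert is_multifunctional(etype, params)
        assert classify_multifunctional_role(net, etype, params, "M1") \
            == "isoenzyme"

    def test_flux_free_side_reaction_is_nonessential_extra(self, evolved_m1,
                                                           params):
        from metevo.kinetics import Pack, reachable_metabolites

        net, _ = evolved_m1
        net = net.copy()
        reach = reachable_metabolites(Pack(net, params),
                                      net.world.media["M1"].external)
        # give every copy of one enzyme type an extra reaction whose donor and
        # acceptor are both unreachable: active but permanently flux-free
        etypes = [t for t in enzyme_types(net, params) if not t.is_transporter]
        target = etypes[0]
        from metevo.model_core import acceptors_of_group, donors_of_group
        g = target.group
        dead_slot = next(
            s for s in range(16)
            if s not in target.support
            and not reach[donors_of_group(g)[s]]
            and not reach[acceptors_of_group(g)[s]])
        for gi in target.members:
            r = net.enzymes[gi].roots
            r *= 1.0 - 0.02
            r[dead_slot] = 0.02
        etype = next(t for t in enzyme_types(net, params)
                     if not t.is_transporter and dead_slot in t.support)
        assert is_multifunctional(etype, params)
        assert classify_multifunctional_role(net, etype, params, "M1") \
            == "nonessential_extra"


class TestStoichiometry:
    def test_no_reactions_no_fluxes(self, world, params):
        from metevo import Network

        net = Network([], [], world)
        S = stoichiometric_matrix(net, params)
        assert S.shape[1] == 0
        assert independent_flux_count(net, params) == 0

    def test_exchange_column_has_single_entry(self, world, params):
        from metevo import Network

        roots = np.zeros(32)
        roots[7] = 1.0
        net = Network([], [Transporter(roots, params.alpha)], world)
        S, labels = stoichiometric_matrix(net, params, return_labels=True)
        exch = S[:, [i for i, l in enumerate(labels) if l.startswith("T")]]
        assert exch.shape[1] == 1
        assert np.count_nonzero(exch) == 1 and exch[7, 0] == -1

    def test_enzymatic_columns_conserve_groups(self, evolved_m1, params):
        from metevo.model_core import group_bits

        net, _ = evolved_m1
        S, labels = stoichiometric_matrix(net, params, return_labels=True)
        bits = np.array([group_bits(j) for j in range(32)], dtype=float)
        for c, lbl in enumerate(labels):
            if lbl.startswith("E"):
                np.testing.assert_allclose(S[:, c] @ bits, 0.0, atol=1e-12)

    def test_flux_count_matches_svd_oracle_on_network(self, evolved_m1, params):
        net, _ = evolved_m1
        S = stoichiometric_matrix(net, params)
        assert independent_flux_count(net, params) == null_space(S).shape[1]
        rng = np.random.default_rng(5)
        shuffled = S[:, rng.permutation(S.shape[1])]
        assert nullity(shuffled) == nullity(S)  # column order irrelevant


class TestNullity:
    def test_linear_chain_has_one_flux(self):
        # import A, convert A->B, drain B: one degree of freedom
        S = np.zeros((2, 3))
        S[0, 0] = -1.0           # exchange of A
        S[0, 1], S[1, 1] = -1.0, 1.0
        S[1, 2] = -1.0           # biomass drain of B
        assert nullity(S) == 1

    def test_parallel_routes_double_the_freedom(self):
        S = np.zeros((2, 4))
        S[0, 0] = -1.0
        S[0, 1], S[1, 1] = -1.0, 1.0   # route 1
        S[0, 2], S[1, 2] = -1.0, 1.0   # route 2
        S[1, 3] = -1.0
        assert nullity(S) == 2

    def test_duplicate_column_adds_exactly_one(self):
        rng = np.random.default_rng(1)
        S = rng.integers(-1, 2, size=(6, 4)).astype(float)
        S2 = np.column_stack([S, S[:, 2]])
        assert nullity(S2) == nullity(S) + 1

    def test_agrees_with_scipy_nullspace_on_random_matrices(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            m, n = rng.integers(2, 12, size=2)
            S = rng.integers(-2, 3, size=(m, n)).astype(float)
            assert nullity(S) == null_space(S).shape[1]


class TestBatchTables:
    def test_minimal_batch_layout(self, tiny_params):
        res = batch_run(scenarios=("M1",), n_replicates=1, seed0=11,
                        params=tiny_params, include_continued=False)
        assert list(res.networks["run_label"]) == ["M1"]
        assert {"independent_fluxes", "n_multifunctional",
                "n_enzyme_types"} <= set(res.networks.columns)
        assert set(res.robustness["dist_label"]) == {"Rob-M1"}
        D, P = res.ks_matrix()
        assert float(D.loc["Rob-M1", "Rob-M1"]) == 0.0
        assert float(P.loc["Rob-M1", "Rob-M1"]) == 1.0
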