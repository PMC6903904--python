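"""Network construction, fragmented-isotopomer ODEs and the positional oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoflux.isotopomer_model import (
    assemble_mass_isotopomer_odes,
    brute_force_isotopomer_simulation,
    build_default_network,
    glu_mass_ratio_timecourse,
    mm_transport,
    network_from_dict,
    simulate_labeling,
)
from mitoflux.toy_networks import (
    toy_branched,
    toy_condensation_cycle,
    toy_linear_chain,
)

INPUT = lambda t: 0.9 * (1.0 - np.exp(-t / 60.0))  # noqa: E731


class TestNetworkStructure:
    def test_atom_conservation_everywhere(self, default_network):
        for rxn in default_network.reactions:
            sub = sorted("".join(m for _, m in rxn.substrates))
            prod = sorted("".join(m for _, m in rxn.products))
            assert sub == prod, rxn.name

    def test_all_named_pathways_present(self, default_network):
        assert {
            "glycolysis",
            "tca_cycle",
            "exchange",
            "pyruvate_carboxylase",
            "anaplerosis",
            "malic_enzyme",
            "acetyl_coa_synthetase",
        } <= default_network.pathway_tags()

    def test_ode_dimension_reported(self, glu_system):
        labels = glu_system.equation_labels()
        assert len(labels) == glu_system.n_states
        assert glu_system.n_states > 6  # more than the observable alone
        assert any("glu" in lab for lab in labels)

    def test_flux_imbalance_rejected(self):
        doc = {
            "name": "bad",
            "metabolites": [
                {"name": "src", "carbons": 1, "extracellular": True},
                {"name": "a", "carbons": 1, "pool": 1.0},
                {"name": "sink", "carbons": 1, "extracellular": True},
            ],
            "parameters": {"F1": 0.1, "F2": 0.2},
            "reactions": [
                {"name": "in", "equation": "src (a) -> a (a)", "flux": "F1"},
                {"name": "out", "equation": "a (a) -> sink (a)", "flux": "F2"},
            ],
        }
        with pytest.raises(ValueError, match="flux imbalance"):
            network_from_dict(doc)

    def test_atom_map_inconsistency_rejected(self):
        doc = {
            "name": "bad-map",
            "metabolites": [
                {"name": "src", "carbons": 2, "extracellular": True},
                {"name": "a", "carbons": 1, "pool": 1.0},
            ],
            "parameters": {"F": 0.1},
            "reactions": [
                {"name": "r", "equation": "src (ab) -> a (a)", "flux": "F"},
            ],
        }
        with pytest.raises(ValueError, match="conserv"):
            network_from_dict(doc)

    def test_resolved_fluxes_balance_with_overrides(self, default_network):
        fluxes = default_network.resolve_fluxes(F_TCA=0.03, F_X=0.1)
        assert fluxes["F_TCA"] == 0.03
        assert fluxes["F_PDH"] == pytest.approx(0.03 - fluxes["F_ACS"])


class TestMMTransport:
    def test_zero_substrate_zero_rate(self):
        assert mm_transport(0.0, 0.0, 1.0, 2.0) == 0.0

    def test_half_saturation(self):
        assert mm_transport(2.0, 0.0, 3.0, 2.0) == pytest.approx(1.5)

    def test_reversible_symmetric_is_zero(self):
        assert mm_transport(1.7, 1.7, 3.0, 2.0, reversible=True) == 0.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(s=st.floats(0.0, 100.0), vmax=st.floats(0.1, 10.0), km=st.floats(0.1, 10.0))
    def test_rate_bounded_by_vmax(self, s, vmax, km):
        assert 0.0 <= mm_transport(s, 0.0, vmax, km) < vmax

    def test_validation(self):
        with pytest.raises(ValueError):
            mm_transport(-1.0, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            mm_transport(1.0, 0.0, 0.0, 1.0)


class TestSinglePoolBalance:
    def test_rhs_reduces_to_printed_balance_equation(self):
        # one pool fed at flux F with constant input enrichment e:
        # dμ1/dt = (F/[M]) (e - μ1)  ->  μ1(t) = e (1 - exp(-F t / [M]))
        doc = {
            "name": "one-pool",
            "metabolites": [
                {"name": "src", "carbons": 1, "extracellular": True,
                 "enrichment": [0.3]},
                {"name": "a", "carbons": 1, "pool": 0.5},
                {"name": "sink", "carbons": 1, "extracellular": True},
            ],
            "parameters": {"F": 0.05},
            "reactions": [
                {"name": "in", "equation": "src (a) -> a (a)", "flux": "F"},
                {"name": "out", "equation": "a (a) -> sink (a)", "flux": "F"},
            ],
        }
        net = network_from_dict(doc)
        system = assemble_mass_isotopomer_odes(net, observed=["a"])
        t = np.linspace(0, 60, 7)
        tc = simulate_labeling(system, t_grid=t)
        analytic = 0.3 * (1.0 - np.exp(-0.05 * t / 0.5))
        np.testing.assert_allclose(tc.fragment("a")[:, 1], analytic, atol=1e-8)


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "factory, observed",
        [
            (toy_linear_chain, "b"),
            (toy_branched, "c"),
            (toy_condensation_cycle, "obs"),
        ],
    )
    def test_toy_networks_match_brute_force(self, factory, observed):
        net = factory()
        system = assemble_mass_isotopomer_odes(net, observed=[observed])
        t = np.linspace(0, 120, 9)
        tc = simulate_labeling(system, input_fn=INPUT, t_grid=t,
                               rtol=1e-10, atol=1e-12)
        bf = brute_force_isotopomer_simulation(net, input_fn=INPUT, t_grid=t,
                                               rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(
            tc.fragment(observed), bf.mass_marginal(observed), atol=1e-8
        )

    def test_single_carbon_positional_equals_mass(self):
        net = toy_condensation_cycle()
        t = np.linspace(0, 60, 5)
        bf = brute_force_isotopomer_simulation(net, input_fn=INPUT, t_grid=t)
        # z has the 1-carbon feed at position 1: its 1-carbon marginal is
        # exactly the positional distribution of that carbon
        marg = bf.fragment_marginal("z", (1,))
        dist = bf.distributions["z"]
        labeled = dist[:, [i for i in range(8) if i & 1]].sum(axis=1)
        np.testing.assert_allclose(marg[:, 1], labeled, atol=1e-12)

    def test_symmetric_pool_invariant_under_carbon_reversal(self):
        net = toy_branched()
        t = np.linspace(0, 120, 7)
        bf = brute_force_isotopomer_simulation(net, input_fn=INPUT, t_grid=t)
        dist = bf.distributions["c"]  # 2 carbons, symmetric
        # pattern 0b01 (C1 labeled) and 0b10 (C2 labeled) must be equal
        np.testing.assert_allclose(dist[:, 1], dist[:, 2], atol=1e-10)

    def test_state_space_guard(self):
        doc = {
            "name": "huge",
            "metabolites": [
                {"name": "src", "carbons": 17, "extracellular": True},
                {"name": "a", "carbons": 17, "pool": 1.0},
                {"name": "sink", "carbons": 17, "extracellular": True},
            ],
            "parameters": {"F": 0.1},
            "reactions": [
                {"name": "in", "equation": "src (abcdefghijklmnopq) -> a (abcdefghijklmnopq)", "flux": "F"},
                {"name": "out", "equation": "a (abcdefghijklmnopq) -> sink (abcdefghijklmnopq)", "flux": "F"},
            ],
        }
        net = network_from_dict(doc)
        with pytest.raises(ValueError, match="guard"):
            brute_force_isotopomer_simulation(net, t_grid=np.array([0.0, 1.0]))


class TestSimulateLabeling:
    def test_zero_input_stays_unlabeled(self, glu_system):
        tc = simulate_labeling(
            glu_system, input_fn=lambda t: 0.0, t_grid=np.linspace(0, 300, 5)
        )
        for dist in tc.fractions.values():
            np.testing.assert_allclose(dist[:, 0], 1.0, atol=1e-9)

    def test_normalization_preserved(self, noiseless_timecourse):
        for dist in noiseless_timecourse.fractions.values():
            np.testing.assert_allclose(dist.sum(axis=1), 1.0, atol=1e-9)
            assert dist.min() > -1e-9

    def test_rk4_agrees_with_stiff_solver(self, glu_system, acetate, t_grid):
        stiff = simulate_labeling(
            glu_system, input_fn=acetate.as_function(), t_grid=t_grid
        )
        rk4 = simulate_labeling(
            glu_system, input_fn=acetate.as_function(), t_grid=t_grid,
            method="rk4", rk4_max_step=0.05,
        )
        np.testing.assert_allclose(
            rk4.fragment("glu"), stiff.fragment("glu"), atol=1e-6
        )

    def test_fast_exchange_limit_tracks_source_pool(self, default_network):
        # as F_X grows, glutamate follows alpha-ketoglutarate with
        # vanishing lag
        t = np.linspace(0, 300, 7)
        system = assemble_mass_isotopomer_odes(
            default_network, observed=["glu", "akg"]
        )
        gaps = []
        for fx in (0.05, 0.5, 5.0):
            tc = simulate_labeling(
                system, fluxes={"F_X": fx}, input_fn=INPUT, t_grid=t
            )
            gaps.append(
                np.abs(tc.fragment("glu") - tc.fragment("akg")).max()
            )
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.01

    def test_steady_state_matches_direct_solve(self, glu_system):
        # constant enrichment input: long-time fractions must solve
        # rhs(x) = 0, found independently by a root solver
        from scipy.optimize import fsolve

        const_in = lambda t: 0.9  # noqa: E731
        rhs = glu_system.compile_rhs(
            glu_system.network.resolve_fluxes(), input_fn=const_in
        )
        tc = simulate_labeling(
            glu_system, input_fn=const_in, t_grid=np.array([0.0, 20000.0])
        )
        x_end = np.concatenate(
            [tc.fractions[f][-1] for f in glu_system.fragments]
        )
        x_ss = fsolve(lambda x: rhs(0.0, x), x_end, xtol=1e-12)
        np.testing.assert_allclose(x_end, x_ss, atol=1e-7)

    def test_invalid_grid_rejected(self, glu_system):
        with pytest.raises(ValueError):
            simulate_labeling(glu_system, t_grid=np.array([0.0]))
        with pytest.raises(ValueError):
            simulate_labeling(glu_system, t_grid=np.array([2.0, 1.0]))


class TestMassRatio:
    def test_equal_fractions_give_unit_ratio(self, noiseless_timecourse):
        import copy

        tc = copy.deepcopy(noiseless_timecourse)
        key = max((k for k in tc.fractions if k[0] == "glu"), key=lambda k: len(k[1]))
        tc.fractions[key][:, 2] = tc.fractions[key][:, 1]
        ratio = glu_mass_ratio_timecourse(tc)
        valid = ratio[~np.isnan(ratio)]
        np.testing.assert_allclose(valid, 1.0)

    def test_first_turn_ratio_below_one(self, noiseless_timecourse):
        # early cycle turns from [2-13C]acetate give predominantly M+1
        ratio = glu_mass_ratio_timecourse(noiseless_timecourse)
        first_valid = ratio[~np.isnan(ratio)][0]
        assert first_valid < 1.0

    def test_time_zero_masked(self, noiseless_timecourse):
        ratio = glu_mass_ratio_timecourse(noiseless_timecourse)
        assert np.isnan(ratio[0])


class TestConservationProperty:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(data=st.data())
    def test_rhs_conserves_normalization(self, glu_system, data):
        # for any normalized state the per-fragment derivative sums to 0
        rng_seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(rng_seed)
        x = np.empty(glu_system.n_states)
        for frag in glu_system.fragments:
            sl = glu_system.slices[frag]
            v = rng.random(sl.stop - sl.start)
            x[sl] = v / v.sum()
        rhs = glu_system.compile_rhs(
            glu_system.network.resolve_fluxes(), input_fn=lambda t: 0.42
        )
        dx = rhs(100.0, x)
        for frag in glu_system.fragments:
            assert abs(dx[glu_system.slices[frag]].sum()) < 1e-12
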