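import itertools
import math

import numpy as np
import pytest

from prodland import cme_simulator as sim
from prodland.landscape_io import validate_landscape
from prodland.peak_analysis import detect_peaks_1d
from prodland.projection import marginalize_1d


def brute_force_toggle_states(ba, bb):
    """Enumerate the toggle state space by filtering the full hypercube:
    gene-site conservation plus dimer sequestration against each buffer."""
    rows = []
    for pa, pb, da, db, bda, bdb in itertools.product(
        range(ba + 1), range(bb + 1), (0, 1), (0, 1), (0, 1), (0, 1)
    ):
        if da + bda != 1 or db + bdb != 1:
            continue
        if pa + 2 * bdb > ba or pb + 2 * bda > bb:
            continue
        rows.append((pa, pb, da, db, bda, bdb))
    return sorted(rows)


class TestEnumeration:
    def test_reduced_toggle_count_matches_brute_force(self):
        network, _ = sim.toggle_switch_preset((6, 6))
        states = sim.enumerate_states(network)
        expected = brute_force_toggle_states(6, 6)
        assert states.n_states == len(expected) == 144
        assert [tuple(r) for r in states.states] == expected

    @pytest.mark.parametrize("buffers", [(4, 5), (8, 8), (5, 7)])
    def test_small_buffers_equal_hypercube_filter(self, buffers):
        network, _ = sim.toggle_switch_preset(buffers)
        states = sim.enumerate_states(network)
        assert [tuple(r) for r in states.states] == brute_force_toggle_states(
            *buffers
        )

    def test_birth_death_is_a_ladder(self):
        network, _ = sim.birth_death_preset(buffer=5)
        states = sim.enumerate_states(network)
        assert states.states.ravel().tolist() == [0, 1, 2, 3, 4, 5]

    def test_initial_condition_in_space(self):
        network, initial = sim.toggle_switch_preset((6, 6))
        states = sim.enumerate_states(network)
        p0 = initial.to_vector(states)
        assert p0.sum() == 1.0
        row = states.states[np.argmax(p0)]
        assert tuple(row) == (0, 0, 1, 1, 0, 0)

    def test_unbuffered_species_rejected(self):
        from prodland.landscape_io import SpeciesDescriptor

        with pytest.raises(ValueError, match="unbounded"):
            sim.ReactionNetwork(
                [SpeciesDescriptor("P", max_copies=3)],
                [sim.Reaction("birth", {}, {"P": 1}, 1.0)],
                megs=[],
            )

    def test_dimer_needs_buffer_room(self):
        with pytest.raises(ValueError, match="dimer"):
            sim.toggle_switch_preset((2, 6))


class TestSizeBound:
    def test_single_species_single_meg(self):
        network, _ = sim.birth_death_preset(buffer=5)
        assert sim.state_space_size_bound(network) == 6
        assert sim.enumerate_states(network).n_states == 6

    def test_two_species_meg_counts_simplex(self):
        """C(b + 2, 2) equals the number of non-negative integer pairs with
        sum at most b."""
        meg = sim.MolecularEquivalenceGroup("g", {"X": 1, "Y": 1}, 3)
        from prodland.landscape_io import SpeciesDescriptor

        network = sim.ReactionNetwork(
            [
                SpeciesDescriptor("X", max_copies=3),
                SpeciesDescriptor("Y", max_copies=3),
            ],
            [sim.Reaction("swap", {"X": 1}, {"Y": 1}, 1.0)],
            [meg],
        )
        assert sim.state_space_size_bound(network) == math.comb(5, 2) == 10
        pairs = [(x, y) for x in range(4) for y in range(4) if x + y <= 3]
        assert sim.enumerate_states(network).n_states == len(pairs)

    def test_bound_dominates_toggle_enumeration(self, toggle_full_statespace):
        network, _ = sim.toggle_switch_preset((120, 240))
        assert sim.state_space_size_bound(network) >= toggle_full_statespace.n_states


class TestRateMatrix:
    def test_birth_death_tridiagonal(self):
        k, gamma, buffer = 2.0, 0.5, 3
        network, _ = sim.birth_death_preset(k, gamma, buffer)
        states = sim.enumerate_states(network)
        a = sim.build_rate_matrix(network, states).toarray()
        expected = np.zeros((4, 4))
        for x in range(buffer):
            expected[x + 1, x] = k          # birth, suppressed at the cap
        for x in range(1, buffer + 1):
            expected[x - 1, x] = gamma * x  # death
        expected -= np.diag(expected.sum(axis=0))
        np.testing.assert_allclose(a, expected)

    def test_column_sums_cancel_to_machine_precision(self):
        """The diagonal negates each column's off-diagonal mass, so column
        sums vanish up to float round-off relative to the rate scale."""
        network, _ = sim.toggle_switch_preset((8, 8))
        states = sim.enumerate_states(network)
        a = sim.build_rate_matrix(network, states)
        scale = np.abs(a.diagonal()).max()
        residual = np.abs(np.asarray(a.sum(axis=0)).ravel()).max()
        assert residual <= 1e-13 * scale

    def test_nonzeros_match_firing_enumeration(self):
        """Off-diagonal nonzero count equals a brute-force count of
        admissible reaction firings."""
        network, _ = sim.toggle_switch_preset((6, 6))
        states = sim.enumerate_states(network)
        a = sim.build_rate_matrix(network, states).tocoo()
        offdiag = np.count_nonzero(a.row != a.col)
        index = {tuple(r): i for i, r in enumerate(states.states)}
        names = states.names
        firings = set()
        for i, row in enumerate(states.states):
            for reac in network.reactions:
                prop = reac.rate
                for s, m in reac.reactants.items():
                    x = row[names.index(s)]
                    for d in range(m):
                        prop *= max(x - d, 0)
                if prop <= 0:
                    continue
                target = list(row)
                for s, m in reac.reactants.items():
                    target[names.index(s)] -= m
                for s, m in reac.products.items():
                    target[names.index(s)] += m
                if tuple(target) in index:
                    firings.add((i, index[tuple(target)]))
        assert offdiag == len(firings)


class TestPropagate:
    def test_time_zero_returns_p0(self):
        network, initial = sim.birth_death_preset(1.0, 1.0, 5)
        states = sim.enumerate_states(network)
        a = sim.build_rate_matrix(network, states)
        p0 = initial.to_vector(states)
        land = sim.propagate(a, p0, [0.0], states)
        np.testing.assert_array_equal(land.probs[:, 0], p0)

    def test_zero_rates_constant_landscape(self):
        network, initial = sim.birth_death_preset(0.0, 0.0, 4)
        land = sim.run_simulation(network, initial, [0.0, 1.0, 5.0])
        assert np.abs(np.diff(land.probs, axis=1)).max() == 0.0

    def test_non_normalized_p0_rejected(self):
        network, _ = sim.birth_death_preset(1.0, 1.0, 3)
        states = sim.enumerate_states(network)
        a = sim.build_rate_matrix(network, states)
        with pytest.raises(ValueError, match="mass"):
            sim.propagate(a, np.full(4, 0.5), [0.0, 1.0], states)

    def test_birth_death_converges_to_truncated_poisson(self):
        network, initial = sim.birth_death_preset(1.0, 1.0, 30)
        land = sim.run_simulation(network, initial, [0.0, 40.0])
        pi = sim.truncated_poisson(1.0, 30)
        assert np.abs(land.probs[:, -1] - pi).max() < 1e-6

    def test_detailed_balance_of_stationary_law(self):
        k, gamma, buffer = 2.5, 1.0, 20
        network, initial = sim.birth_death_preset(k, gamma, buffer)
        land = sim.run_simulation(network, initial, [0.0, 60.0])
        pi = land.probs[:, -1]
        x = np.arange(buffer)
        assert np.abs(k * pi[x] - gamma * (x + 1) * pi[x + 1]).max() < 1e-8

    def test_ivp_method_agrees_with_expm(self):
        network, initial = sim.birth_death_preset(1.5, 1.0, 10)
        times = [0.0, 1.0, 3.0]
        a = sim.run_simulation(network, initial, times, method="expm")
        b = sim.run_simulation(network, initial, times, method="ivp")
        assert np.abs(a.probs - b.probs).max() < 1e-7

    def test_mass_conserved_over_200_steps(self):
        network, initial = sim.birth_death_preset(1.0, 1.0, 12)
        land = sim.run_simulation(network, initial, np.linspace(0.0, 20.0, 201))
        assert np.abs(land.column_masses() - 1.0).max() <= 1e-9


class TestToggle:
    def test_default_preset_matches_production_descriptor(self):
        network, initial = sim.toggle_switch_preset()
        caps = {s.name: s.max_copies for s in network.species}
        assert caps == {
            "Pa": 120, "Pb": 240, "Da": 1, "Db": 1, "BDa": 1, "BDb": 1,
        }
        assert initial.microstate == (0, 0, 1, 1, 0, 0)

    def test_bistable_run_two_peaks_per_marginal(self, bistable_toggle_landscape):
        land = bistable_toggle_landscape
        for name in ("Pa", "Pb"):
            peaks = detect_peaks_1d(marginalize_1d(land, name).column(land.n_times - 1))
            assert len(peaks) == 2

    def test_symmetric_landscape_invariant_under_swap(self, bistable_toggle_landscape):
        land = bistable_toggle_landscape
        names = land.state_space.names
        swap = {"Pa": "Pb", "Pb": "Pa", "Da": "Db", "Db": "Da",
                "BDa": "BDb", "BDb": "BDa"}
        cols = [names.index(swap[n]) for n in names]
        swapped = land.state_space.states[:, cols]
        index = {tuple(r): i for i, r in enumerate(land.state_space.states)}
        perm = np.array([index[tuple(r)] for r in swapped])
        assert np.abs(land.probs - land.probs[perm]).max() < 1e-9

    def test_landscape_validates(self, reduced_toggle_landscape):
        assert validate_landscape(reduced_toggle_landscape).passed


class TestCascade:
    def test_structure(self):
        network, initial = sim.cascade_preset((6, 6, 12))
        proteins = [s.name for s in network.species if s.is_protein]
        assert proteins == ["Pa", "Pb", "Pc"]
        genes = [s.name for s in network.species if not s.is_protein]
        assert set(genes) == {"Da", "Db", "Dc", "ADca", "ADcb"}
        assert sum(initial.microstate) == 3  # all three genes unbound

    def test_no_regulation_reduces_to_birth_death(self):
        """With both activation bindings at zero, the output protein's
        marginal converges to the truncated Poisson of its basal rate."""
        rates = sim.CascadeRates(binding_a=0.0, binding_b=0.0)
        network, initial = sim.cascade_preset((6, 6, 12), rates)
        land = sim.run_simulation(network, initial, [0.0, 30.0])
        marginal = marginalize_1d(land, "Pc").column(1)
        pi = sim.truncated_poisson(rates.basal_c / rates.degradation, 12)
        assert np.abs(marginal - pi).max() < 1e-8

    def test_default_rates_give_multimodal_output(self):
        network, initial = sim.cascade_preset((10, 10, 40))
        land = sim.run_simulation(network, initial, [0.0, 40.0])
        peaks = detect_peaks_1d(marginalize_1d(land, "Pc").column(1))
        assert len(peaks) >= 2

    def test_mass_conserved(self):
        network, initial = sim.cascade_preset((6, 6, 12))
        land = sim.run_simulation(network, initial, [0.0, 5.0, 10.0])
        assert validate_landscape(land).passed
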