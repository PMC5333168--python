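import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prodland.landscape_io import (
    ProbabilityLandscape,
    SpeciesDescriptor,
    StateSpace,
)
from prodland.peak_analysis import (
    Peak1D,
    SystemPeak,
    classify_suspect,
    combine_peaks,
    detect_peaks_1d,
    evaluate_system_peak,
    find_system_peaks,
)
from prodland.projection import marginalize_1d


def brute_force_peaks(p, threshold=1e-12):
    """Independent exhaustive scan: an index is a peak iff it exceeds the
    threshold and every existing neighbour (one-sided at the boundary)."""
    out = []
    for i in range(len(p)):
        if p[i] <= threshold:
            continue
        left_ok = i == 0 or p[i - 1] < p[i]
        right_ok = i == len(p) - 1 or p[i + 1] < p[i]
        if left_ok and right_ok:
            out.append(i)
    return out


class TestDetectPeaks1D:
    def test_two_interior_peaks(self):
        peaks = detect_peaks_1d(np.array([0.1, 0.3, 0.2, 0.25, 0.15]))
        assert [(p.copy_number, p.value) for p in peaks] == [(1, 0.3), (3, 0.25)]

    def test_boundary_peak_at_zero(self):
        """The extinct state at copy 0 can carry a genuine spike and must be
        peak-eligible with a one-sided comparison."""
        peaks = detect_peaks_1d(np.array([0.5, 0.3, 0.2]))
        assert [p.copy_number for p in peaks] == [0]

    def test_all_below_threshold(self):
        assert detect_peaks_1d(np.full(5, 1e-13)) == []

    def test_plateau_yields_leftmost_index(self):
        peaks = detect_peaks_1d(np.array([0.1, 0.3, 0.3, 0.3, 0.1]))
        assert [p.copy_number for p in peaks] == [1]

    def test_length_one_vector(self):
        assert [p.copy_number for p in detect_peaks_1d(np.array([0.4]))] == [0]
        assert detect_peaks_1d(np.array([0.0])) == []

    def test_empty_and_negative_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks_1d(np.array([]))
        with pytest.raises(ValueError):
            detect_peaks_1d(np.array([0.1, -0.1]))

    def test_oracle_equivalence_1000_random_vectors(self):
        """Scan result equals the exhaustive brute-force oracle on 1,000
        random vectors."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            got = [pk.copy_number for pk in detect_peaks_1d(p)]
            assert got == brute_force_peaks(p)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30),
        st.floats(min_value=0.0, max_value=0.5),
    )
    def test_raising_threshold_never_adds_peaks(self, values, threshold):
        p = np.array(values)
        low = {pk.copy_number for pk in detect_peaks_1d(p, 0.0)}
        high = {pk.copy_number for pk in detect_peaks_1d(p, threshold)}
        assert high <= low


class TestCombinePeaks:
    def test_three_dimension_product(self):
        """One peak in each of two dimensions and three in the third give
        three system peaks at the combined locations."""
        per_dim = [
            [Peak1D("Pa", 3, 0.2)],
            [Peak1D("Pb", 10, 0.3)],
            [Peak1D("Pc", 0, 0.1), Peak1D("Pc", 9, 0.05), Peak1D("Pc", 29, 0.017)],
        ]
        combined = combine_peaks(per_dim)
        assert [pk.location for pk in combined] == [
            (3, 10, 0), (3, 10, 9), (3, 10, 29),
        ]

    def test_two_by_two_gives_four(self):
        per_dim = [
            [Peak1D("Pa", 0, 0.4), Peak1D("Pa", 11, 0.1)],
            [Peak1D("Pb", 0, 0.4), Peak1D("Pb", 11, 0.1)],
        ]
        assert len(combine_peaks(per_dim)) == 4

    def test_single_dimension_passthrough(self):
        per_dim = [[Peak1D("P", 2, 0.5), Peak1D("P", 7, 0.2)]]
        combined = combine_peaks(per_dim)
        assert [pk.location for pk in combined] == [(2,), (7,)]

    def test_empty_dimension_empties_product(self):
        assert combine_peaks([[Peak1D("A", 1, 0.5)], []]) == []

    def test_mismatched_time_indices_rejected(self):
        with pytest.raises(ValueError, match="time"):
            combine_peaks(
                [[Peak1D("A", 1, 0.5, time_index=0)],
                 [Peak1D("B", 2, 0.5, time_index=1)]]
            )

    @given(
        st.lists(
            st.lists(
                st.integers(min_value=0, max_value=9), min_size=0, max_size=4,
                unique=True,
            ),
            min_size=1, max_size=4,
        )
    )
    def test_count_is_product_of_dimension_counts(self, locations):
        per_dim = [
            [Peak1D(f"P{d}", c, 0.1) for c in dim]
            for d, dim in enumerate(locations)
        ]
        expected = int(np.prod([len(d) for d in per_dim]))
        assert len(combine_peaks(per_dim)) == expected


class TestEvaluateSystemPeak:
    @pytest.fixture
    def landscape(self):
        species = [
            SpeciesDescriptor("Pa", max_copies=4),
            SpeciesDescriptor("Pb", max_copies=12),
            SpeciesDescriptor("D", "gene_unbound", 1),
        ]
        states = [[3, 10, 0], [3, 10, 1], [0, 0, 1], [1, 2, 0]]
        probs = [[0.4], [0.35], [0.15], [0.1]]
        return ProbabilityLandscape(
            StateSpace(species, states), [0.0], probs
        )

    def test_aggregates_over_gene_species(self, landscape):
        pk = SystemPeak(location=(3, 10), per_dim_values=(0.7, 0.7))
        assert evaluate_system_peak(landscape, pk).value == pytest.approx(0.75)

    def test_delta_location(self, landscape):
        pk = SystemPeak(location=(0, 0), per_dim_values=(0.1, 0.1))
        assert evaluate_system_peak(landscape, pk).value == pytest.approx(0.15)

    def test_unpopulated_location_is_zero(self, landscape):
        pk = SystemPeak(location=(4, 12), per_dim_values=(0.0, 0.0))
        assert evaluate_system_peak(landscape, pk).value == 0.0

    def test_location_outside_axes_rejected(self, landscape):
        pk = SystemPeak(location=(5, 0), per_dim_values=(0.0, 0.0))
        with pytest.raises(ValueError, match="axis"):
            evaluate_system_peak(landscape, pk)

    def test_matches_group_by_oracle(self, rng, small_random_landscape):
        land = small_random_landscape
        proteins = [s.name for s in land.state_space.proteins]
        loc = tuple(land.state_space.states[7, :len(proteins)])
        pk = evaluate_system_peak(
            landscape=land,
            peak=SystemPeak(location=loc, per_dim_values=(0.0,) * len(loc)),
        )
        cols = np.stack([land.state_space.column(n) for n in proteins], axis=1)
        expected = land.probs[(cols == loc).all(axis=1), 0].sum()
        assert pk.value == pytest.approx(expected, abs=1e-15)


class TestClassifySuspect:
    def _candidates(self, values):
        return [
            SystemPeak(location=(i,), per_dim_values=(v,), value=v)
            for i, v in enumerate(values)
        ]

    def test_eight_candidates_three_authentic(self):
        """Eight candidate peak states with a cutoff between the 3rd and 4th
        largest values leave three authentic and five suspect."""
        values = [0.2, 0.1, 0.017, 1e-9, 5e-10, 3e-10, 2e-10, 1e-10]
        classified = classify_suspect(self._candidates(values), 1e-6)
        assert sum(not pk.suspect for pk in classified) == 3
        assert sum(pk.suspect for pk in classified) == 5

    def test_zero_threshold_all_authentic(self):
        classified = classify_suspect(self._candidates([0.5, 1e-15]), 0.0)
        assert not any(pk.suspect for pk in classified)

    def test_all_below_threshold_all_suspect(self):
        classified = classify_suspect(self._candidates([1e-8, 1e-9]), 1e-6)
        assert all(pk.suspect for pk in classified)

    def test_unevaluated_peaks_rejected(self):
        pk = SystemPeak(location=(0,), per_dim_values=(0.1,))
        with pytest.raises(ValueError, match="evaluate"):
            classify_suspect([pk], 1e-6)


class TestBistableToggle:
    def test_symmetric_marginals_share_peak_set(self, bistable_toggle_landscape):
        """With fully symmetric rates and buffers the Pa and Pb marginals
        have identical peak sets at every output time."""
        land = bistable_toggle_landscape
        for t in range(land.n_times):
            pa = detect_peaks_1d(marginalize_1d(land, "Pa").column(t))
            pb = detect_peaks_1d(marginalize_1d(land, "Pb").column(t))
            assert [(p.copy_number) for p in pa] == [(p.copy_number) for p in pb]

    def test_late_time_four_system_peaks(self, bistable_toggle_landscape):
        land = bistable_toggle_landscape
        peaks = find_system_peaks(land, land.n_times - 1)
        assert len(peaks) == 4
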