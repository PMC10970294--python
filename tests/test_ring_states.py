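"""Hinge angles, equal-count discretization, and ring-state combinatorics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringscape import EnsembleSpec, build_template, discretize_equal_count, hinge_angle
from ringscape.ensemble_io import ConformerEnsemble
from ringscape.ensemble_sim import sample_correlated_angles
from ringscape.ring_states import (
    HexamerState,
    adjacency_stats,
    canonical_rotation,
    enumerate_states,
    map_to_hexamers,
    max_cyclic_run,
    measure_hinge_angles,
    necklace_count,
    state_histogram,
)
from ringscape.toy_complex import swing_n_domain


class TestHingeAngle:
    def test_template_monomer_measures_zero(self, default_template):
        mono = default_template.monomers[0]
        assert abs(hinge_angle(mono.coords, mono)) < 1e-6

    def test_constructed_swing_is_measured_back(self, default_template):
        coords = swing_n_domain(default_template, 0, 17.0)
        mono = default_template.monomers[0]
        per = default_template.atoms_per_monomer
        assert hinge_angle(coords[:per], mono) == pytest.approx(17.0, abs=0.5)

    def test_noisy_swing_recovered_in_the_mean(self, default_template, rng):
        # Monte-Carlo: -30 deg swing, 0.5 A coordinate noise, 1000 replicates
        mono = default_template.monomers[0]
        per = default_template.atoms_per_monomer
        base = swing_n_domain(default_template, 0, -30.0)[:per]
        coords = base[None] + rng.normal(0, 0.5, (1000, *base.shape))
        ensemble = ConformerEnsemble(
            coords=coords,
            particle_ids=np.arange(1000),
            domain_labels=mono.labels,
            n_monomers=1,
        )
        angles = measure_hinge_angles(ensemble, mono)
        assert angles.mean() == pytest.approx(-30.0, abs=2.0)

    def test_degenerate_centroid_raises(self, default_template):
        mono = default_template.monomers[0]
        coords = mono.coords.copy()
        coords[mono.domain_mask("N")] = mono.hinge_point
        with pytest.raises(ValueError, match="hinge"):
            hinge_angle(coords, mono)


class TestDiscretizeEqualCount:
    def test_three_values_three_regions(self):
        labels, boundaries = discretize_equal_count(np.array([1.0, 2.0, 3.0]), 3)
        assert labels.tolist() == [0, 1, 2]
        assert boundaries.tolist() == [1.5, 2.5]

    def test_seven_values_split_three_two_two(self):
        labels, _ = discretize_equal_count(np.arange(7.0), 3)
        assert np.bincount(labels).tolist() == [3, 2, 2]

    def test_labels_follow_value_order_not_input_order(self):
        values = np.array([30.0, -30.0, 0.0])
        labels, _ = discretize_equal_count(values, 3)
        assert labels.tolist() == [2, 0, 1]

    def test_all_identical_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            discretize_equal_count(np.ones(10), 3)

    @settings(max_examples=50, deadline=None)
    @given(
        n=st.integers(4, 200),
        k=st.integers(2, 6),
        seed=st.integers(0, 1000),
    )
    def test_region_sizes_differ_by_at_most_one(self, n, k, seed):
        if n < k:
            return
        values = np.random.default_rng(seed).normal(size=n)
        labels, boundaries = discretize_equal_count(values, k)
        sizes = np.bincount(labels, minlength=k)
        assert sizes.max() - sizes.min() <= 1
        assert len(boundaries) == k - 1
        assert np.all(np.diff(boundaries) >= 0)


class TestCanonicalization:
    def test_single_substitution_rotates_to_the_end(self):
        assert canonical_rotation((1, 0, 0, 0, 0, 0)) == (0, 0, 0, 0, 0, 1)

    def test_uniform_tuple_is_its_own_canonical_form(self):
        assert canonical_rotation((2, 2, 2, 2, 2, 2)) == (2, 2, 2, 2, 2, 2)

    @settings(max_examples=200, deadline=None)
    @given(
        t=st.tuples(*[st.integers(0, 2)] * 6),
        k=st.integers(0, 5),
    )
    def test_canonical_form_is_rotation_invariant_and_idempotent(self, t, k):
        rotated = t[k:] + t[:k]
        c = canonical_rotation(t)
        assert canonical_rotation(rotated) == c
        assert canonical_rotation(c) == c
        assert c in [t[i:] + t[:i] for i in range(6)]
        assert all(c <= t[i:] + t[:i] for i in range(6))


class TestEnumerateStates:
    @pytest.mark.parametrize("k,expected", [(1, 1), (2, 14), (3, 130)])
    def test_known_counts(self, k, expected):
        assert enumerate_states(k) == expected

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_brute_force_matches_necklace_formula(self, k):
        assert enumerate_states(k) == necklace_count(k)


def _states_from_labels(label_rows):
    return [
        HexamerState(particle_id=i, labels=tuple(row))
        for i, row in enumerate(label_rows)
    ]


def _tertile_labels(angles):
    return np.digitize(angles, [-10.0, 10.0])


class TestMapToHexamers:
    def _table(self, n):
        return pd.DataFrame(
            {
                "monomer_record_id": np.arange(6 * n),
                "parent_particle_id": np.repeat(np.arange(n), 6),
                "monomer_index": np.tile(np.arange(6), n),
            }
        )

    def test_uniform_hexamer(self):
        states = map_to_hexamers(np.zeros(6, dtype=int), self._table(1))
        assert states[0].labels == (0, 0, 0, 0, 0, 0)
        assert states[0].canonical == (0, 0, 0, 0, 0, 0)

    def test_cyclic_rotations_share_canonical_form(self):
        labels = np.array([1, 0, 2, 0, 0, 0, 0, 2, 0, 0, 0, 1])
        states = map_to_hexamers(labels, self._table(2))
        assert states[0].labels != states[1].labels
        assert states[0].canonical == states[1].canonical

    def test_missing_monomer_names_the_particle(self):
        table = self._table(2).iloc[:-1]
        with pytest.raises(ValueError, match="particle 1"):
            map_to_hexamers(np.zeros(11, dtype=int), table)


class TestStateStatistics:
    def test_identical_particles_collapse_to_one_bin(self):
        states = _states_from_labels([(0, 1, 0, 1, 0, 1)] * 40)
        hist = state_histogram(states)
        assert len(hist) == 1
        assert hist["count"].iloc[0] == 40

    def test_independent_labels_match_multinomial_expectation(self):
        # 100,000 independent-uniform hexamers; expected count of each
        # canonical state is proportional to its orbit size under rotation
        from collections import Counter
        from itertools import product

        from scipy.stats import chisquare

        n = 100_000
        spec = EnsembleSpec(n_particles=n, neighbor_coupling=0.0, seed=17)
        angles = sample_correlated_angles(n, spec, np.random.default_rng(17))
        states = _states_from_labels(_tertile_labels(angles))
        hist = state_histogram(states)

        orbit = Counter(
            "".join(map(str, canonical_rotation(t)))
            for t in product(range(3), repeat=6)
        )
        expected = np.array([n * orbit[s] / 729 for s in hist["state"]])
        observed = hist["count"].to_numpy(dtype=float)
        # fold any unobserved states into the expectation check
        assert observed.sum() == n
        p = chisquare(observed, expected * observed.sum() / expected.sum()).pvalue
        assert p > 0.001

    def test_coupling_enriches_all_equal_states(self):
        n = 30_000
        freqs = {}
        for rho in (0.0, 0.9):
            spec = EnsembleSpec(n_particles=n, neighbor_coupling=rho, seed=23)
            angles = sample_correlated_angles(n, spec, np.random.default_rng(23))
            labels = _tertile_labels(angles)
            freqs[rho] = np.mean([len(set(row)) == 1 for row in labels])
        assert freqs[0.9] > freqs[0.0]

    def test_adjacency_examples(self):
        frame = adjacency_stats(
            _states_from_labels([(0, 0, 0, 0, 0, 1), (1, 0, 0, 0, 0, 0)])
        )
        assert frame["max_run"].tolist() == [5, 5]
        assert frame["n_distinct"].tolist() == [2, 2]
        assert frame["ge5_equal"].all()

    def test_max_cyclic_run_cases(self):
        assert max_cyclic_run((0, 0, 0, 0, 0, 0)) == 6
        assert max_cyclic_run((0, 1, 0, 1, 0, 1)) == 1
        assert max_cyclic_run((1, 1, 0, 0, 1, 1)) == 4

    def test_fraction_with_five_equal_matches_exact_enumeration(self):
        # exact result for independent uniform labels: 39/729
        n = 100_000
        spec = EnsembleSpec(n_particles=n, neighbor_coupling=0.0, seed=31)
        angles = sample_correlated_angles(n, spec, np.random.default_rng(31))
        frame = adjacency_stats(_states_from_labels(_tertile_labels(angles)))
        expected = 39.0 / 729.0
        tol = 4.0 * np.sqrt(expected * (1 - expected) / n)
        assert frame["ge5_equal"].mean() == pytest.approx(expected, abs=tol)
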