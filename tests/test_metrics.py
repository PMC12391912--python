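"""Diversity profiles and biomass: oracle values and structural invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import hill_oracle, jackknife_oracle
from savannagrad.metrics import (
    SpeciesAttributes,
    UndefinedDiversityError,
    berger_parker,
    block_biomass,
    diversity_profile,
    hill_number,
    jackknife_richness,
)


class TestHillNumbers:
    @pytest.mark.parametrize(
        "p, q, expected",
        [
            ([1.0], 0, 1.0),
            ([1.0], 2, 1.0),
            ([0.25] * 4, 2, 4.0),
            ([0.8, 0.2], 1, 1.6494),
            ([0.5, 0.3, 0.2], 10, 2.1586),
        ],
    )
    def test_reference_values(self, p, q, expected):
        assert hill_number(p, q) == pytest.approx(expected, abs=5e-4)

    def test_identities_against_entropy_and_simpson(self, rng):
        """^1D = exp(Shannon) and ^2D = 1/sum(p^2) to near machine precision."""
        for _ in range(200):
            p = rng.dirichlet(np.full(rng.integers(2, 15), 0.6))
            shannon = -np.sum(p * np.log(p))
            assert hill_number(p, 1) == pytest.approx(np.exp(shannon), abs=1e-10)
            assert hill_number(p, 2) == pytest.approx(1.0 / np.sum(p**2), abs=1e-10)

    def test_scale_invariance(self, rng):
        c = rng.uniform(0.1, 20, size=8)
        for q in (0, 1, 2, 10):
            assert hill_number(c, q) == pytest.approx(hill_number(c * 37.5, q), rel=1e-12)

    @given(
        st.lists(st.floats(0.01, 100.0), min_size=1, max_size=25),
        st.sampled_from([0.0, 0.5, 1.0, 2.0, 5.0, 10.0]),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_direct_formula(self, counts, q):
        p = np.asarray(counts) / np.sum(counts)
        assert hill_number(p, q) == pytest.approx(hill_oracle(p, q), rel=1e-9)

    def test_empty_community_is_undefined(self):
        with pytest.raises(UndefinedDiversityError):
            hill_number([0.0, 0.0], 1)


class TestBergerParker:
    def test_reciprocal_of_top_share(self):
        assert berger_parker([0.6, 0.4]) == pytest.approx(1.6667, abs=1e-4)
        assert berger_parker([1.0]) == 1.0

    def test_tie_for_top_abundance_is_undefined(self):
        assert np.isnan(berger_parker([0.5, 0.5]))
        assert np.isnan(berger_parker([0.4, 0.4, 0.2]))


class TestJackknifeRichness:
    def test_no_rare_species_keeps_raw_count(self):
        assert jackknife_richness([100, 100, 100]) == (3.0, 0)

    def test_all_singletons_first_order(self):
        # S + f1 (n-1)/n with n = 3
        assert jackknife_richness([1, 1, 1]) == (5.0, 1)

    def test_all_zero_vector_errors(self):
        with pytest.raises(UndefinedDiversityError):
            jackknife_richness([0, 0])

    def test_agrees_with_closed_form_oracle(self, rng):
        """200 random vectors against the frozen coefficient-table oracle."""
        for _ in range(200):
            s = rng.integers(2, 25)
            counts = rng.geometric(rng.uniform(0.1, 0.7), size=s)
            est, order = jackknife_richness(counts)
            oest, oorder = jackknife_oracle(counts)
            assert est == pytest.approx(oest, rel=1e-9)
            assert order == oorder
            assert est >= np.sum(counts > 0) - 1e-9


class TestDiversityProfile:
    def test_empty_block(self):
        p = diversity_profile([0, 0, 0])
        assert p.richness_raw == 0 and np.isnan(p.d1)

    def test_equal_counts_inactive_adjustment(self, rng):
        """No rare species: every order returns the unadjusted Hill number."""
        for k in (2, 5, 9):
            counts = np.full(k, 40.0)
            p = diversity_profile(counts)
            for q, val in [(0, p.d0), (1, p.d1), (2, p.d2), (10, p.d10)]:
                assert val == pytest.approx(hill_oracle(counts, q), rel=1e-9)

    def test_profile_nonincreasing_in_order(self, rng):
        """500 random blocks: ^qD nonincreasing over q = 0, 1, 2, 10, inf."""
        checked = 0
        while checked < 500:
            counts = rng.poisson(rng.uniform(0.2, 8.0), size=12)
            if counts.sum() == 0:
                continue
            p = diversity_profile(counts)
            seq = [p.d0, p.d1, p.d2, p.d10]
            if not np.isnan(p.d_inf):
                seq.append(p.d_inf)
            assert all(a >= b - 1e-9 for a, b in zip(seq, seq[1:]))
            assert p.d0 >= p.richness_raw - 1e-9
            assert p.d10 >= 1.0 - 1e-12
            checked += 1


class TestBlockBiomass:
    def test_zero_counts(self):
        b = block_biomass({"wildebeest": 0.0, "impala": 0.0})
        assert (b.total_kg, b.migratory_kg, b.nonmigratory_kg) == (0.0, 0.0, 0.0)

    def test_migratory_partition(self):
        attrs = SpeciesAttributes.default()
        m = attrs.mass("wildebeest")
        b = block_biomass({"wildebeest": 10.0})
        assert b.total_kg == pytest.approx(10 * m)
        assert b.migratory_kg == pytest.approx(10 * m)
        assert b.nonmigratory_kg == 0.0

    def test_partition_identity_random_blocks(self, rng):
        attrs = SpeciesAttributes.default()
        wild = attrs.wild_species()
        for _ in range(50):
            counts = {s: float(rng.uniform(0, 30)) for s in wild}
            b = block_biomass(counts, attrs)
            assert b.total_kg == pytest.approx(b.migratory_kg + b.nonmigratory_kg)
            assert b.total_kg >= 0

    def test_unknown_species_is_a_configuration_error(self):
        with pytest.raises(KeyError, match="unicorn"):
            block_biomass({"unicorn": 1.0})
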