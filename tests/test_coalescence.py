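"""Mixing, similarity, provenance, quadrants and elimination assays."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metapart import (
    CommunityLibraryEntry,
    CommunityState,
    Environment,
    coalesce,
    community_mean_performance,
    elimination_assay,
    enumerate_genomes,
    equilibrate,
    maximize_F,
    mix,
    quadrant_select,
    sample_cost_table,
    similarity,
)
from metapart.errors import UndefinedSimilarityError
from tests.conftest import A, AB, B, D3_F


class TestMix:
    def test_self_mix_is_identity(self, env2):
        c = CommunityState({A: 3.0, AB: 7.0})
        for w in (0.0, 0.3, 1.0):
            m = mix(c, c, w)
            assert m.genomes == c.genomes
            assert np.allclose(m.abundances(), c.abundances(), rtol=1e-15)

    def test_disjoint_supports_halve(self):
        c1 = CommunityState({A: 4.0}, n_substrates=2)
        c2 = CommunityState({B: 6.0}, n_substrates=2)
        m = mix(c1, c2, 0.5)
        assert m[A] == 2.0 and m[B] == 3.0

    def test_outcome_independent_of_mixing_ratio(self, env2, d3_costs):
        c1 = CommunityState({A: 50 / 0.9}, n_substrates=2)
        c2 = CommunityState({AB: 100 / 1.9}, n_substrates=2)
        results = [
            coalesce(c1, c2, env2, d3_costs, w=w).result
            for w in (0.01, 0.1, 0.5, 0.9, 0.99)
        ]
        ref = results[0]
        for eq in results[1:]:
            assert set(eq.survivors) == set(ref.survivors)
            for g in ref.survivors:
                assert eq.community[g] == pytest.approx(ref.community[g], rel=1e-4)


class TestCoalesce:
    def test_specialist_meets_generalist_gives_d3(self, env2, d3_costs):
        # {A} + {AB} re-equilibrates to the D3 community {A, AB}
        c1 = CommunityState({A: 50 / 0.9}, n_substrates=2)
        c2 = CommunityState({AB: 100 / 1.9}, n_substrates=2)
        out = coalesce(c1, c2, env2, d3_costs)
        assert set(out.result.survivors) == {A, AB}
        assert out.result.community[A] == pytest.approx(50 / 0.9 - 50, abs=1e-6)
        assert out.result.community[AB] == pytest.approx(50.0, abs=1e-6)
        assert out.result.F == pytest.approx(D3_F, abs=1e-9)
        assert out.provenance == {}

    def test_identical_parents_no_elimination(self, env2, d3_costs, universe2):
        eq = maximize_F(universe2, env2, d3_costs)
        out = coalesce(eq.community, eq.community, env2, d3_costs)
        assert out.provenance == {}
        assert set(out.result.survivors) == set(eq.survivors)

    def test_subset_parent_absorbed_by_uninvadable_winner(self, env2, d3_costs, universe2):
        # parent 1 is the uninvadable optimum over {A, B, AB}; parent 2 loses
        eq = maximize_F(universe2, env2, d3_costs)
        loser = CommunityState({B: 50 / 1.05}, n_substrates=2)
        out = coalesce(eq.community, loser, env2, d3_costs)
        assert set(out.result.survivors) == set(eq.survivors)
        assert out.provenance == {B: "parent2"}

    def test_provenance_partition(self):
        costs = sample_cost_table(4, 1e-2, seed=31)
        env = Environment.equiabundant(4)
        universe = enumerate_genomes(4)
        rng = np.random.default_rng(31)
        half1 = [g for g in universe if rng.random() < 0.6] or universe[:8]
        half2 = [g for g in universe if rng.random() < 0.6] or universe[8:]
        eq1 = equilibrate(half1, env, costs, method="optimize")
        eq2 = equilibrate(half2, env, costs, method="optimize")
        out = coalesce(eq1.community, eq2.community, env, costs)
        s1, s2 = set(eq1.survivors), set(eq2.survivors)
        surv = set(out.result.survivors)
        assert set(out.provenance) == (s1 | s2) - surv
        for g, origin in out.provenance.items():
            expected = "both" if g in s1 and g in s2 else (
                "parent1" if g in s1 else "parent2"
            )
            assert origin == expected


class TestSimilarity:
    def test_hand_value(self):
        c1 = CommunityState({A: 1.0, B: 1.0})
        c2 = CommunityState({A: 1.0}, n_substrates=2)
        assert similarity(c1, c2) == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_disjoint_supports(self):
        c1 = CommunityState({A: 2.0}, n_substrates=2)
        c2 = CommunityState({B: 5.0}, n_substrates=2)
        assert similarity(c1, c2) == 0.0

    def test_zero_abundance_undefined(self):
        c1 = CommunityState({A: 0.0}, n_substrates=2)
        c2 = CommunityState({A: 1.0}, n_substrates=2)
        with pytest.raises(UndefinedSimilarityError):
            similarity(c1, c2)

    @given(
        st.lists(st.floats(0.0, 1e3), min_size=3, max_size=3),
        st.lists(st.floats(0.0, 1e3), min_size=3, max_size=3),
        st.floats(0.01, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_scale_invariance_and_bounds(self, n1, n2, scale):
        genomes = [A, B, AB]
        if sum(n1) == 0 or sum(n2) == 0:
            return
        c1 = CommunityState(dict(zip(genomes, n1)))
        c2 = CommunityState(dict(zip(genomes, n2)))
        s = similarity(c1, c2)
        assert 0.0 <= s <= 1.0 + 1e-12
        assert s == pytest.approx(similarity(c2, c1), abs=1e-12)
        scaled = CommunityState({g: scale * n for g, n in c1.items()})
        assert similarity(scaled, c2) == pytest.approx(s, abs=1e-9)
        assert similarity(c1, scaled) == pytest.approx(1.0, abs=1e-9)


class TestMeanPerformance:
    def test_single_member(self, d3_costs):
        assert community_mean_performance([A], d3_costs) == pytest.approx(
            d3_costs.f(A)
        )

    def test_balanced_pair_averages_to_zero(self):
        from metapart import CostTable

        table = CostTable.from_costs({A: 1 / 1.01, B: 1 / 0.99}, eps=0.1)
        # f = +0.01 and -0.01
        assert community_mean_performance([A, B], table) == pytest.approx(0.0, abs=1e-12)

    def test_zero_scatter_gives_zero(self):
        costs = sample_cost_table(3, eps=0.0, seed=0)
        assert community_mean_performance(costs.genomes, costs) == 0.0

    def test_abundance_weighted_variant(self, d3_costs):
        c = CommunityState({A: 3.0, AB: 1.0})
        expected = (3 * d3_costs.f(A) + 1 * d3_costs.f(AB)) / 4
        got = community_mean_performance(c, d3_costs, abundance_weighted=True)
        assert got == pytest.approx(expected, abs=1e-12)


def _fake_entry(F, mean_f):
    return CommunityLibraryEntry(members=(), equilibrium=None, F=F, mean_f=mean_f)


class TestQuadrants:
    def test_perfect_correlation_empties_off_diagonal_quadrants(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, 500)
        library = [_fake_entry(v, v) for v in vals]
        quads = quadrant_select(library, q=0.1)
        assert quads["II"] == [] and quads["IV"] == []
        assert len(quads["I"]) >= 1 and len(quads["III"]) >= 1

    def test_independent_measures_fill_each_quadrant_at_q_squared(self):
        rng = np.random.default_rng(1)
        n = 10_000
        library = [
            _fake_entry(rng.uniform(), rng.uniform()) for _ in range(n)
        ]
        quads = quadrant_select(library, q=0.1)
        # each quadrant ~ q^2 = 1% of n; binomial 5-sigma ~ 0.5%
        for key in ("I", "II", "III", "IV"):
            assert abs(len(quads[key]) / n - 0.01) < 0.005

    def test_small_library_rejected(self):
        with pytest.raises(ValueError):
            quadrant_select([_fake_entry(0.0, 0.0)] * 10, q=0.1)


class TestEliminationAssay:
    def test_identical_pools_no_eliminations(self, env2, d3_costs, universe2):
        eq = maximize_F(universe2, env2, d3_costs)
        entry = CommunityLibraryEntry(
            members=tuple(eq.survivors), equilibrium=eq, F=eq.F, mean_f=0.0
        )
        table, summary = elimination_assay(
            [entry], [entry], n_pairs=5, env=env2, costs=d3_costs, seed=0
        )
        assert summary["n_eliminated"] == 0
        assert (table["survived"]).all()

    def test_rows_ordered_by_f_and_summary_fractions_consistent(self):
        costs = sample_cost_table(4, 1e-2, seed=8)
        env = Environment.equiabundant(4)
        universe = enumerate_genomes(4)
        rng = np.random.default_rng(8)
        pools = []
        for _ in range(2):
            chosen = universe[:1]
            while np.bitwise_or.reduce([g.code for g in chosen]) != 15:
                idx = rng.choice(len(universe), 6, replace=False)
                chosen = [universe[i] for i in sorted(idx)]
            eq = equilibrate(chosen, env, costs, method="optimize")
            pools.append(
                CommunityLibraryEntry(
                    members=tuple(chosen),
                    equilibrium=eq,
                    F=eq.F,
                    mean_f=community_mean_performance(chosen, costs),
                )
            )
        table, summary = elimination_assay(
            [pools[0]], [pools[1]], n_pairs=10, env=env, costs=costs, seed=1
        )
        for _, grp in table.groupby("pair_id"):
            fs = grp.sort_values("f_rank_row")["f"].to_numpy()
            assert np.all(np.diff(fs) <= 1e-15)
        if summary["n_eliminated"]:
            total = (
                summary["frac_from_a"]
                + summary["frac_from_b"]
                + summary["frac_from_both"]
            )
            assert total == pytest.approx(1.0, abs=1e-12)
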