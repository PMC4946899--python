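"""Instantaneous quantities, the Lyapunov function, and ODE integration."""

import numpy as np
import pytest

from metapart import (
    CommunityState,
    CostTable,
    Environment,
    Genome,
    equilibrium_F_from_harvests,
    growth_rates,
    harvests,
    integrate,
    interaction_matrix,
    lyapunov_F,
    sample_cost_table,
    surplus,
    usage,
)
from metapart.errors import InfiniteHarvestError, UnpricedGenomeError
from tests.conftest import A, AB, B, D1_F, D3_F


class TestUsageAndHarvests:
    def test_usage_direct_sum(self):
        c = CommunityState({AB: 3.0, B: 2.0})
        assert np.allclose(usage(c), [3.0, 5.0])

    def test_usage_empty(self):
        c = CommunityState({}, n_substrates=4)
        assert np.allclose(usage(c), np.zeros(4))

    def test_generalist_expresses_all_pathways_equally(self):
        G = Genome(10, 2**10 - 1)
        c = CommunityState({G: 17.3})
        assert np.allclose(usage(c), 17.3)

    def test_harvest_values_and_infinity_sentinel(self, env2):
        H = harvests(env2, np.array([100 / 1.9, 100 / 1.9]))
        assert np.allclose(H, 0.95)
        H0 = harvests(env2, np.array([0.0, 10.0]))
        assert H0[0] == np.inf and H0[1] == 5.0


class TestSurplusAndGrowth:
    def test_d1_equilibrium_surplus(self, env2, d1_costs, d1_equilibrium_state):
        d = surplus(env2, d1_costs, d1_equilibrium_state)
        assert d[AB] == pytest.approx(0.0, abs=1e-12)

    def test_d1_invader_surplus(self, env2, d3_costs, d1_equilibrium_state):
        # at D1's harvests H=(0.95, 0.95), an A with cost 0.9 has surplus 0.05
        state = CommunityState({AB: 100.0 / 1.9, A: 0.0})
        d = surplus(env2, d3_costs, state)
        assert d[A] == pytest.approx(0.95 - 0.9, abs=1e-12)

    def test_lone_individual_chemostat(self):
        # lone sigma in an empty world with R_i = R: Delta = R|sigma| - chi
        g = Genome.from_label("ABC", 4)
        costs = CostTable.from_costs({g: 2.9})
        env = Environment(R=np.full(4, 7.0))
        d = surplus(env, costs, CommunityState({g: 1.0}, n_substrates=4))
        assert d[g] == pytest.approx(7.0 * 3 - 2.9)
        rates = growth_rates(env, costs, CommunityState({g: 1.0}, n_substrates=4))
        assert rates[g] == pytest.approx((7.0 * 3 - 2.9) / 2.9)

    def test_unconsumed_substrate_gives_infinite_surplus(self, env2, d3_costs):
        state = CommunityState({A: 10.0, B: 0.0})
        d = surplus(env2, d3_costs, state)
        assert d[B] == np.inf

    def test_zero_abundance_species_has_zero_rate(self, env2, d1_costs):
        state = CommunityState({AB: 100 / 1.9, A: 0.0, B: 0.0})
        rates = growth_rates(env2, d1_costs, state)
        assert rates[A] == 0.0 and rates[B] == 0.0

    def test_unpriced_genome_raises(self, env2, d1_costs):
        g3 = Genome.from_label("A", 2)
        bad = CommunityState({g3: 1.0})
        partial = CostTable.from_costs({AB: 1.9})
        with pytest.raises(UnpricedGenomeError):
            surplus(env2, partial, bad)


class TestLyapunov:
    def test_single_generalist_closed_form(self):
        # F = ln(N chi0 / chi_G) = ln(1 + f_G)
        N = 10
        G = Genome(N, 2**N - 1)
        chi_G = 9.5
        costs = CostTable.from_costs({G: chi_G})
        env = Environment.equiabundant(N, 10.0)
        state = CommunityState({G: env.Rtot / chi_G})
        F = lyapunov_F(env, costs, state)
        assert F == pytest.approx(np.log(N / chi_G), abs=1e-12)
        assert F == pytest.approx(np.log(1 + costs.f(G)), abs=1e-12)

    def test_generalist_zero_scatter_gives_zero_F(self):
        N = 6
        G = Genome(N, 2**N - 1)
        costs = CostTable.from_costs({G: float(N)})
        env = Environment.equiabundant(N, 50.0)
        state = CommunityState({G: env.Rtot / N})
        assert lyapunov_F(env, costs, state) == pytest.approx(0.0, abs=1e-12)

    def test_d1_value_and_equilibrium_form_agreement(
        self, env2, d1_costs, d1_equilibrium_state
    ):
        F = lyapunov_F(env2, d1_costs, d1_equilibrium_state)
        assert F == pytest.approx(D1_F, abs=1e-10)
        H = harvests(env2, usage(d1_equilibrium_state))
        assert equilibrium_F_from_harvests(env2, H) == pytest.approx(F, abs=1e-10)

    def test_uncovered_substrate_gives_minus_infinity(self, env2, d1_costs):
        state = CommunityState({A: 5.0}, n_substrates=2)
        costs = CostTable.from_costs({A: 0.9})
        assert lyapunov_F(env2, costs, state) == -np.inf

    def test_equilibrium_form_examples(self, env2):
        assert equilibrium_F_from_harvests(env2, np.array([1.0, 1.0])) == 0.0
        assert equilibrium_F_from_harvests(
            env2, np.array([0.95, 0.95])
        ) == pytest.approx(D1_F, abs=1e-10)
        assert equilibrium_F_from_harvests(
            env2, np.array([0.9, 1.0])
        ) == pytest.approx(D3_F, abs=1e-10)


class TestInteractionMatrix:
    def test_disjoint_genomes_do_not_interact(self, env2, d2_costs):
        state = CommunityState({A: 10.0, B: 20.0})
        M = interaction_matrix(env2, d2_costs, state)
        assert M[0, 1] == 0.0 and M[1, 0] == 0.0

    def test_single_species_entry(self, env2, d1_costs):
        n = 40.0
        state = CommunityState({AB: n}, n_substrates=2)
        M = interaction_matrix(env2, d1_costs, state)
        delta = 100.0 / n - 1.9
        expected = n * (-(50 / n**2) * 2) + delta
        assert M[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_matches_finite_differences(self, env2, d3_costs):
        state = CommunityState({A: 12.0, B: 7.0, AB: 30.0})
        M = interaction_matrix(env2, d3_costs, state)
        genomes = state.genomes
        h = 1e-6
        for b, gb in enumerate(genomes):
            up = dict(state)
            up[gb] += h
            dn = dict(state)
            dn[gb] -= h
            for a, ga in enumerate(genomes):
                def flux(members, g=ga):
                    from metapart import surplus as _surplus
                    d = _surplus(env2, d3_costs, CommunityState(members))
                    return members[g] * d[g]
                fd = (flux(up) - flux(dn)) / (2 * h)
                assert M[a, b] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_off_diagonals_nonpositive(self):
        rng = np.random.default_rng(5)
        costs = sample_cost_table(4, 1e-2, seed=5)
        env = Environment.equiabundant(4)
        genomes = costs.genomes
        state = CommunityState(
            {g: float(rng.uniform(1, 50)) for g in genomes}
        )
        M = interaction_matrix(env, costs, state)
        off = M - np.diag(np.diag(M))
        assert np.all(off <= 0)

    def test_unconsumed_substrate_is_an_error(self, env2, d2_costs):
        state = CommunityState({A: 3.0}, n_substrates=2)
        with pytest.raises(InfiniteHarvestError):
            interaction_matrix(env2, d2_costs, state)


class TestIntegration:
    def test_equilibrium_start_stays_constant(self, env2, d1_costs, d1_equilibrium_state):
        traj = integrate(d1_equilibrium_state, env2, d1_costs, t_end=50.0)
        final = traj.final
        assert final[AB] == pytest.approx(100 / 1.9, rel=1e-9)

    def test_d1_three_species_converges_to_AB(self, env2, d1_costs, universe2):
        start = CommunityState({g: 10.0 for g in universe2})
        traj = integrate(start, env2, d1_costs)
        assert traj.converged
        assert traj.final.support() == [AB]
        assert traj.final[AB] == pytest.approx(100 / 1.9, rel=1e-6)

    def test_F_monotone_along_trajectory(self, env2, d3_costs, universe2):
        start = CommunityState({A: 0.01, B: 30.0, AB: 0.5})
        traj = integrate(start, env2, d3_costs)
        dF = np.diff(traj.F_values)
        assert np.all(dF >= -1e-8)
        assert traj.F_values[-1] == pytest.approx(D3_F, abs=1e-8)

    def test_species_never_resurrect(self, env2, d2_costs, universe2):
        start = CommunityState({g: 5.0 for g in universe2})
        traj = integrate(start, env2, d2_costs)
        assert AB in traj.extinct
        assert AB not in traj.final

    def test_random_universe_trajectory_monotone(self):
        costs = sample_cost_table(5, 1e-3, seed=9)
        env = Environment.equiabundant(5)
        genomes = costs.genomes
        rng = np.random.default_rng(9)
        start = CommunityState(
            {g: float(rng.uniform(0.1, 10.0)) for g in genomes}
        )
        traj = integrate(start, env, costs)
        assert traj.converged
        assert np.all(np.diff(traj.F_values) >= -1e-8)
        # budget identity at the endpoint
        biomass = traj.final.total_biomass(costs)
        assert abs(biomass - env.Rtot) / env.Rtot < 1e-6
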