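# Methods

## Model

The world supplies one limiting resource in `N` interchangeable forms
("substrates", labelled A, B, C, …) at rates `R_i > 0`; `Rtot = Σ R_i`.
A species is the set of substrate-specific pathways it carries, encoded as
a nonempty binary vector σ; `2^N − 1` species are possible. Scramble
competition splits each substrate's benefit equally over the `T_i = Σ n_σ σ_i`
individuals able to use it, so a member of species σ runs the surplus
`Δ_σ = Σ_i σ_i R_i/T_i − χ_σ` and the biomass-weighted dynamics are
`τ0 χ_σ dn_σ/dt = n_σ Δ_σ`. Costs are random with a single scatter
parameter: `χ_σ = χ0 |σ| (1 + ε ξ_σ)`, `ξ_σ ~ N(0,1)` frozen per species
and truncated (by rejection re-draw) to keep `χ_σ > 0`. This cost model is
deliberately neutral: neither specialists nor generalists are favoured on
average, and the intrinsic performance `f_σ = χ0|σ|/χ_σ − 1 ≈ −ε ξ_σ` is an
order-ε reshuffling of the species pool.

Assumptions inherited from the model class: deterministic dynamics,
well-mixed environment, purely competitive interactions (the Jacobian of
the biomass flux has no positive off-diagonal entries), no cross-feeding,
no demographic stochasticity, no spatial structure.

### The community-level objective

`F = (1/Rtot)(Σ_i R_i ln(T_i/(R_i/χ0)) − Σ_σ χ_σ n_σ + Rtot)` satisfies
`Rtot ∂F/∂n_σ = Δ_σ`, hence `dF/dt = Σ_σ n_σ Δ_σ² / (Rtot χ0 τ0) ≥ 0`:
every trajectory ascends F, and the equilibrium reachable from a species
set Ω is the maximizer of F over nonnegative abundances supported on Ω.
As a function of the abundance vector F is *concave* (its Hessian,
`−Σ_i R_i σ_ai σ_bi / T_i²`, is negative semidefinite) and bounded above
whenever Ω covers every substrate, which is what makes the maximum — and
therefore the equilibrium — unique in value and generically unique in
support. Where the source literature of such models speaks of a "convex"
objective being maximized, we implement the mathematically equivalent
concave maximization; the dynamics are gradient ascent in a skewed metric.

At any equilibrium `Σ χ_σ n_σ = Rtot` (demand matches supply), so
`F = −(1/Rtot) Σ_i R_i ln(H_i/χ0)` up to a constant resolved here as
`ln χ0`, making the two forms agree exactly. Normalizing by `Rtot` makes F
of order ε near equilibrium, directly comparable to f.

## Equilibrium computation

Three independent routes, cross-checked against each other in the tests:

1. **Concave maximization** (`maximize_F`, the workhorse): L-BFGS-B on the
   nonnegative orthant with the free analytic gradient (−Δ per species),
   followed by a Newton polish of `Δ = 0` on the detected support and an
   explicit KKT verification over the full species set (survivors
   `|Δ| ≤ 10⁻⁸ χ0`, absent species `Δ ≤ 10⁻⁸ χ0`); violators are
   re-admitted and the cycle repeats (at most 6 rounds). Usage values are
   floored at `10⁻¹² Rtot` inside the objective so transient boundary
   iterates stay finite.
2. **ODE integration** (`integrate`): log-abundance variables
   (`du/dt = Δ/(τ0 χ)`) preserve positivity and track decay over many
   decades; chunks of geometrically doubling length are integrated (LSODA,
   rtol = atol = 10⁻¹⁰) until `max |Δ|/χ0 < 10⁻⁹` and relative drift
   `< 10⁻⁸` per τ0. Species are pruned at biomass fraction
   `χn/Rtot < 10⁻¹⁰` between chunks and never resurrect. Reported F values
   are recomputed from the sampled states, not integrated, so the
   monotonicity test is meaningful.
3. **Support enumeration** (`support_enumeration_oracle`, ≤ 12 species):
   every subset of at most N species that covers all substrates is solved
   by damped Newton on `Δ = 0`; candidates with strictly positive
   abundances passing the KKT check against the full set are valid.
   Supports with more than N species are skipped: the harvest equations
   `σH = χ` are then overdetermined and solvable only at cost ties, which
   have measure zero under the random cost model.

`equilibrate(..., method="auto")` runs the optimizer and, for at most 64
species, spot-checks it against the ODE route, raising a consistency error
on disagreement (a deliberate bug trap).

## Parameters and defaults

| parameter | meaning | default | why |
|---|---|---|---|
| `χ0` | average cost per pathway (resource units) | 1 | unit choice |
| `τ0` | time unit | 1 | unit choice |
| `R_i/χ0` | substrate supply | 100 | standard setting of the model's published experiments |
| `ε` | cost scatter | 10⁻³ (cohesive regime), 0.1 (individualistic regime) | the two regimes contrasted throughout |
| KKT tolerance | equilibrium residual | 10⁻⁸ χ0 | well above solver precision (~10⁻¹³), far below ε |
| extinction threshold | biomass fraction for pruning | 10⁻¹⁰ | exponential decay never reaches 0; far below any surviving abundance |
| invader introduction | biomass fraction | 10⁻⁶ | leaves F unchanged to < 10⁻⁶ yet clears the pruning threshold |

## Experiments

- **Full competition**: all `2^N − 1` species from equal abundance;
  survivors ≤ N by competitive exclusion; survivor f-ranks reported.
- **Rank sweep**: mean over realizations of the median (and abundance-
  weighted median, defined as the smallest rank whose cumulative abundance
  reaches half the total) survivor rank across an ε grid; the default grid
  is 8 log-spaced values in [10⁻⁴, 10⁻¹], a documented stand-in since no
  canonical grid exists.
- **Trajectories**: random initial conditions are log-uniform over 4
  decades below the equal-biomass share — a documented stand-in for an
  unspecified ensemble; any positive-support distribution converges to the
  same equilibrium. The "far from equilibrium" coupling between F and the
  abundance-weighted mean f is measured as a Spearman correlation over the
  first half of the sampled trajectory *excluding the first integration
  chunk*: the very first samples reflect relaxation of the arbitrary
  initial abundances, during which both quantities move non-monotonically.
- **Community library**: M random genomes, all C(M,k) k-subsets, retained
  if they cover all N substrates ("fully functional", finite F); each is
  equilibrated. The retained count is seed-dependent and reported, never
  asserted. ⟨f⟩ of a community is the unweighted mean over its founding
  members by default (the abundance-weighted variant is available and used
  for trajectory traces); the choice matters little because founders are
  few and the assays compare quantiles.
- **Quadrant assays**: entries in the top/bottom q = 10% of both F and ⟨f⟩
  form quadrants I (low/low), III (high/high), II (high F, low ⟨f⟩),
  IV (low F, high ⟨f⟩). Elimination assays draw pairs with replacement,
  jointly re-equilibrate, and record each eliminated species' parent of
  origin and its row when the pair's species are sorted by f descending.
- **Adaptive dynamics**: invasion attempts are uniform over the universe
  (the attempt distribution is not part of the model; uniform is the
  neutral choice); an attempt succeeds iff `Δ > 10⁻⁸ χ0` at the resident
  harvests, matching the KKT tolerance so accept/reject is consistent with
  equilibrium diagnostics. Termination is detected by testing the entire
  universe.

## What the generator does and does not emulate

All inputs are synthetic by design — the model *is* the object of study,
so the "data generator" is the model itself: a stated world of supplies,
binary genomes, and Gaussian cost scatter. It does not emulate real
metagenomes: no trophic structure, no regulation, no stochastic drift, no
spatial heterogeneity, and pathway presence is binary (carrying =
expressing). A green test therefore establishes internal correctness of
the implementation and the model's own claims (Lyapunov ascent, exclusion
bounds, coalescence phenomenology); it says nothing about any empirical
community.

## Numerical choices and edge cases

- Ties in performance rank (measure zero for ε > 0) break by ascending
  canonical genome encoding (bit i of the integer code = substrate i);
  the same ordering fixes file layouts and iteration order everywhere.
- `T_i = 0` is legal in instantaneous quantities: harvests carry a `+inf`
  sentinel, surpluses of species carrying an unconsumed substrate are
  `+inf`, F is `−inf`, and operations that require finite harvests
  (interaction matrix) raise instead. Assays that need finite F restrict
  to fully functional communities.
- Degenerate cost ties (hand-set costs or ε = 0) can make the optimal
  support non-unique; solvers return a support attaining the optimal F and
  flag `degenerate` in the diagnostics rather than failing.
- Mixing weight w only scales the initial condition of a coalescence;
  every downstream equilibrium is w-independent, which the tests verify at
  w ∈ {0.01, 0.5, 0.99}.
- Replacing the per-species biomass factor χ_σ by arbitrary positive
  constants (the `biomass` option of `integrate`) changes transients only;
  F still ascends because `dF/dt = Σ n Δ²/(Rtot τ0 m_σ) ≥ 0` for any
  positive masses `m_σ`.

## Scaling of the shipped test suite

The acceptance tests run the coalescence experiments at the documented CI
scale — a library over M = 30 random species (27,405 candidate subsets)
instead of the full M = 50 (230,300; the candidate count itself is still
verified at M = 50) — with 500 assay pairs and 10⁴ similarity pairs as in
the full-scale setting. All assertions are majority or monotonicity
statements that are insensitive to this scale; the full-scale library
differs only in runtime (minutes instead of seconds).

## Known limitations

- Enumeration-based routines cap at N = 20 substrates (2²⁰ − 1 genomes);
  the oracle at 12 species; the optimizer has been exercised to ~10³
  species, beyond which L-BFGS-B memory and iteration counts grow.
- The ODE route's convergence time grows like 1/ε (near-degenerate
  competitors separate slowly); for ε ≤ 10⁻⁴ prefer the optimizer.
- No plotting: experiments return DataFrames and write CSVs; figure
  cosmetics are out of scope.
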