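"""Instantaneous model quantities and ODE integration of the competition.

The world supplies a single limiting resource in ``N`` substrate forms with
benefits ``R_i``.  Scramble competition partitions each benefit equally
among the ``T_i`` individuals carrying pathway ``i``:

    T_i   = sum_sigma n_sigma * sigma_i          (community-wide usage)
    H_i   = R_i / T_i                            (per-capita harvest)
    Delta = sum_i sigma_i H_i - chi              (resource surplus)

and abundances follow

    tau0 * chi * dn/dt = n * Delta.

The dynamics admit a Lyapunov function

    F = (1/Rtot) * (sum_i R_i ln(T_i / (R_i/chi0)) - sum chi*n + Rtot)

with Rtot * dF/dn = Delta, so F increases monotonically along every
trajectory and its constrained maximum is the community equilibrium.  F is
interpreted as a community-level fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConvergenceError, InfiniteHarvestError
from .model_core import CostTable, Genome, sigma_matrix

__all__ = [
    "Environment",
    "CommunityState",
    "Trajectory",
    "usage",
    "harvests",
    "surplus",
    "growth_rates",
    "lyapunov_F",
    "equilibrium_F_from_harvests",
    "interaction_matrix",
    "integrate",
]

#: Species are pruned when their biomass fraction chi*n/Rtot drops below this.
EXTINCTION_THRESHOLD = 1e-10

#: Fixed-point condition for survivors: max |Delta|/chi0 below this.
DELTA_TOL = 1e-9

#: Relative abundance drift per unit tau0 below this at convergence.
DRIFT_TOL = 1e-8


@dataclass(frozen=True)
class Environment:
    """Substrate supplies and the unit constants of the model.

    Parameters
    ----------
    R : array-like of shape (N,)
        Benefit supplied by each substrate (resource units); all > 0.
    chi0 : float
        Average cost per pathway; sets the resource unit.  Must match the
        ``chi0`` of the cost table used alongside.
    tau0 : float
        Time unit of the dynamics.
    """

    R: np.ndarray
    chi0: float = 1.0
    tau0: float = 1.0

    def __post_init__(self):
        R = np.atleast_1d(np.asarray(self.R, dtype=float))
        if R.ndim != 1 or R.size < 1:
            raise ValueError("R must be a 1-D vector")
        if not np.all(R > 0):
            raise ValueError("all substrate supplies must be > 0")
        if self.chi0 <= 0 or self.tau0 <= 0:
            raise ValueError("chi0 and tau0 must be > 0")
        object.__setattr__(self, "R", R)
        R.flags.writeable = False

    @classmethod
    def equiabundant(
        cls, n_substrates: int, R_over_chi0: float = 100.0,
        chi0: float = 1.0, tau0: float = 1.0,
    ) -> "Environment":
        """Equal supplies ``R_i = R_over_chi0 * chi0`` for all substrates."""
        return cls(R=np.full(n_substrates, R_over_chi0 * chi0), chi0=chi0, tau0=tau0)

    @property
    def n_substrates(self) -> int:
        return int(self.R.size)

    @property
    def Rtot(self) -> float:
        """Total supply, the normalization making F order-eps at equilibrium."""
        return float(self.R.sum())


class CommunityState(Mapping[Genome, float]):
    """Sparse community composition: genome -> abundance (>= 0, finite).

    Iteration order is canonical (ascending genome encoding).  The state is
    immutable; derived states are produced by :meth:`with_abundances` or by
    the dynamics/equilibrium routines.
    """

    __slots__ = ("_members", "_n_substrates")

    def __init__(
        self,
        members: Mapping[Genome, float] | Sequence[tuple[Genome, float]] = (),
        n_substrates: int | None = None,
    ):
        items = dict(members)
        for g, n in items.items():
            if not isinstance(g, Genome):
                raise TypeError("community keys must be Genome instances")
            if not np.isfinite(n) or n < 0:
                raise ValueError(f"abundance of {g.label} must be finite and >= 0")
        ns = {g.n_substrates for g in items}
        if len(ns) > 1:
            raise ValueError("all genomes must share the same N")
        if n_substrates is None:
            if not ns:
                raise ValueError("n_substrates required for an empty community")
            n_substrates = ns.pop()
        elif ns and ns.pop() != n_substrates:
            raise ValueError("genome N does not match declared n_substrates")
        self._members = {g: float(items[g]) for g in sorted(items)}
        self._n_substrates = int(n_substrates)

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, genome: Genome) -> float:
        return self._members[genome]

    def __iter__(self) -> Iterator[Genome]:
        return iter(self._members)

    def __len__(self) -> int:
        return len(self._members)

    # -- views ------------------------------------------------------------
    @property
    def n_substrates(self) -> int:
        return self._n_substrates

    @property
    def genomes(self) -> list[Genome]:
        return list(self._members)

    def abundances(self) -> np.ndarray:
        return np.asarray(list(self._members.values()))

    def support(self) -> list[Genome]:
        """Genomes present at strictly positive abundance."""
        return [g for g, n in self._members.items() if n > 0]

    def restrict(self, genomes: Sequence[Genome]) -> "CommunityState":
        keep = set(genomes)
        return CommunityState(
            {g: n for g, n in self._members.items() if g in keep},
            n_substrates=self._n_substrates,
        )

    def with_abundances(
        self, genomes: Sequence[Genome], n: np.ndarray
    ) -> "CommunityState":
        return CommunityState(dict(zip(genomes, n)), n_substrates=self._n_substrates)

    def total_biomass(self, costs: CostTable) -> float:
        """Total biomass sum(chi * n); equals Rtot at any equilibrium."""
        return float(sum(costs.chi(g) * n for g, n in self._members.items()))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        body = ", ".join(f"{g.label}: {n:.4g}" for g, n in self._members.items())
        return f"CommunityState({{{body}}}, N={self._n_substrates})"


# ---------------------------------------------------------------------------
# Vectorized kernels shared by dynamics, equilibrium and coalescence code.
# All operate on (sigma, n, chi, R) arrays for one fixed genome ordering.
# ---------------------------------------------------------------------------

def _usage_vec(sigma: np.ndarray, n: np.ndarray) -> np.ndarray:
    return sigma.T @ n


def _harvest_vec(R: np.ndarray, T: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(T > 0, R / np.where(T > 0, T, 1.0), np.inf)


def _delta_vec(sigma, n, chi, R) -> np.ndarray:
    H = _harvest_vec(R, _usage_vec(sigma, n))
    finite = np.isfinite(H)
    if finite.all():
        return sigma @ H - chi
    delta = sigma[:, finite] @ H[finite] - chi
    delta[(sigma[:, ~finite] > 0).any(axis=1)] = np.inf
    return delta


def _lyapunov_vec(sigma, n, chi, R, chi0) -> float:
    T = _usage_vec(sigma, n)
    if np.any(T <= 0):
        return float("-inf")
    Rtot = R.sum()
    return float((R @ np.log(T / (R / chi0)) - chi @ n + Rtot) / Rtot)


def community_arrays(
    community: CommunityState, costs: CostTable
) -> tuple[list[Genome], np.ndarray, np.ndarray, np.ndarray]:
    """(genomes, sigma, n, chi) arrays in canonical genome order."""
    genomes = community.genomes
    sigma = sigma_matrix(genomes, community.n_substrates)
    return genomes, sigma, community.abundances(), costs.chi_array(genomes)


# ---------------------------------------------------------------------------
# Public instantaneous quantities
# ---------------------------------------------------------------------------

def usage(community: CommunityState, n_substrates: int | None = None) -> np.ndarray:
    """Community-wide pathway expression ``T_i = sum_sigma n_sigma sigma_i``."""
    if n_substrates is None:
        n_substrates = community.n_substrates
    if len(community) == 0:
        return np.zeros(n_substrates)
    sigma = sigma_matrix(community.genomes, n_substrates)
    return _usage_vec(sigma, community.abundances())


def harvests(env: Environment, T: np.ndarray) -> np.ndarray:
    """Per-capita benefits ``H_i = R_i/T_i``; ``+inf`` where ``T_i = 0``.

    An infinite harvest marks an unconsumed substrate and is a legal value:
    any species carrying that pathway has infinite surplus there.
    """
    return _harvest_vec(env.R, np.asarray(T, dtype=float))


def surplus(
    env: Environment, costs: CostTable, community: CommunityState
) -> dict[Genome, float]:
    """Resource surplus ``Delta = sum_i sigma_i R_i/T_i - chi`` per genome.

    ``+inf`` for genomes carrying an unconsumed substrate.
    """
    genomes, sigma, n, chi = community_arrays(community, costs)
    return dict(zip(genomes, _delta_vec(sigma, n, chi, env.R)))


def growth_rates(
    env: Environment, costs: CostTable, community: CommunityState
) -> dict[Genome, float]:
    """``dn/dt = n * Delta / (tau0 * chi)``; exactly 0 at zero abundance."""
    genomes, sigma, n, chi = community_arrays(community, costs)
    delta = _delta_vec(sigma, n, chi, env.R)
    rates = np.where(n > 0, n * delta / (env.tau0 * chi), 0.0)
    return dict(zip(genomes, rates))


def lyapunov_F(
    env: Environment, costs: CostTable, community: CommunityState
) -> float:
    """Community-level fitness F; ``-inf`` if any substrate is unconsumed."""
    genomes, sigma, n, chi = community_arrays(community, costs)
    if not genomes:
        return float("-inf")
    return _lyapunov_vec(sigma, n, chi, env.R, env.chi0)


def equilibrium_F_from_harvests(env: Environment, H: np.ndarray) -> float:
    """Equilibrium form of F: ``-(1/Rtot) sum_i R_i ln(H_i/chi0)``.

    Valid at equilibrium, where total demand matches total supply
    (``sum chi*n = Rtot``) so the biomass term of F is a constant; the
    constant is resolved so the two forms agree exactly there.  Measures the
    community's ability to deplete all substrates simultaneously (the
    multi-substrate generalization of the R* rule).
    """
    H = np.asarray(H, dtype=float)
    return float(-(env.R @ np.log(H / env.chi0)) / env.Rtot)


def interaction_matrix(
    env: Environment, costs: CostTable, community: CommunityState
) -> np.ndarray:
    """Jacobian ``M_ab = d g_a / d n_b`` of the biomass flux ``g = n*Delta``.

    Off-diagonal entries ``-n_a sum_i sigma_ai sigma_bi R_i/T_i**2`` are
    never positive: the model is purely competitive.

    Raises
    ------
    InfiniteHarvestError
        If some substrate is unconsumed (the matrix is undefined).
    """
    genomes, sigma, n, chi = community_arrays(community, costs)
    T = _usage_vec(sigma, n)
    if np.any(T <= 0):
        raise InfiniteHarvestError(
            "interaction matrix undefined: unconsumed substrate present"
        )
    delta = sigma @ (env.R / T) - chi
    # dDelta_a/dn_b = -sum_i sigma_ai sigma_bi R_i / T_i^2
    ddelta = -(sigma * (env.R / T**2)) @ sigma.T
    return n[:, None] * ddelta + np.diag(delta)


# ---------------------------------------------------------------------------
# ODE integration
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Sampled ODE trajectory with the Lyapunov value recomputed per state."""

    times: np.ndarray
    states: list[CommunityState]
    F_values: np.ndarray
    converged: bool = False
    n_chunks: int = 0
    extinct: list[Genome] = field(default_factory=list)

    @property
    def final(self) -> CommunityState:
        return self.states[-1]


def integrate(
    community: CommunityState,
    env: Environment,
    costs: CostTable,
    t_end: float | None = None,
    *,
    n_samples_per_chunk: int = 20,
    first_chunk: float = 10.0,
    max_chunks: int = 60,
    rtol: float = 1e-10,
    atol: float = 1e-10,
    method: str = "LSODA",
    biomass: dict[Genome, float] | None = None,
) -> Trajectory:
    """Integrate the competition ODE from ``community`` until equilibrium.

    Integration is performed in log-abundance ``u = ln n`` (so
    ``du/dt = Delta/(tau0*chi)``), which preserves positivity and tracks
    exponential decay over many decades accurately.  Species whose biomass
    fraction falls below ``EXTINCTION_THRESHOLD`` are pruned between chunks;
    pruned species never resurrect.  When ``t_end`` is None, chunks of
    geometrically growing length are integrated until the fixed-point
    condition (max |Delta|/chi0 < 1e-9 and relative drift < 1e-8 per tau0)
    holds, else until ``max_chunks``.

    ``biomass`` overrides the per-species mass factor on the left-hand side
    of the dynamics (default: the cost chi).  Any positive choice changes
    transients only, not the equilibrium — the fixed point is Delta = 0
    regardless — which this option exists to demonstrate.

    Returns a :class:`Trajectory` whose ``F_values`` are recomputed from the
    sampled states (not integrated), so Lyapunov monotonicity of the output
    is a meaningful check on the integrator.
    """
    members = [g for g in community.genomes if community[g] > 0]
    if not members:
        raise ValueError("community has no members at positive abundance")
    n_sub = community.n_substrates
    genomes = list(members)
    sigma = sigma_matrix(genomes, n_sub)
    chi = costs.chi_array(genomes)
    mass = (
        chi
        if biomass is None
        else np.asarray([biomass[g] for g in genomes], dtype=float)
    )
    if np.any(mass <= 0):
        raise ValueError("biomass factors must be > 0")
    n0 = np.asarray([community[g] for g in genomes])
    R, tau0, chi0 = env.R, env.tau0, env.chi0
    Rtot = env.Rtot

    times: list[float] = [0.0]
    states: list[CommunityState] = [community.restrict(genomes)]
    extinct: list[Genome] = []

    def rhs_factory(sig, ch, m):
        def rhs(_t, u):
            n = np.exp(u)
            return _delta_vec(sig, n, ch, R) / (tau0 * m)
        return rhs

    t_now = 0.0
    chunk = float(first_chunk)
    converged = False
    n_chunks = 0
    u = np.log(n0)
    while n_chunks < max_chunks:
        if t_end is not None and t_now >= t_end:
            break
        this_chunk = chunk if t_end is None else min(chunk, t_end - t_now)
        t_eval = t_now + np.linspace(0.0, this_chunk, n_samples_per_chunk + 1)[1:]
        sol = solve_ivp(
            rhs_factory(sigma, chi, mass),
            (t_now, t_now + this_chunk),
            u,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise ConvergenceError(
                f"ODE integration failed at t={t_now}: {sol.message}",
                last_state=states[-1],
            )
        for k in range(sol.t.size):
            times.append(float(sol.t[k]))
            states.append(
                CommunityState(dict(zip(genomes, np.exp(sol.y[:, k]))), n_substrates=n_sub)
            )
        u = sol.y[:, -1]
        t_now += this_chunk
        n_chunks += 1

        n_now = np.exp(u)
        # prune extinct species (pruned species never resurrect)
        alive = chi * n_now / Rtot >= EXTINCTION_THRESHOLD
        if not alive.all():
            extinct.extend(g for g, a in zip(genomes, alive) if not a)
            genomes = [g for g, a in zip(genomes, alive) if a]
            sigma = sigma[alive]
            chi = chi[alive]
            mass = mass[alive]
            u = u[alive]
            n_now = n_now[alive]

        delta = _delta_vec(sigma, n_now, chi, R)
        drift = np.abs(delta / (tau0 * mass))  # |dn/dt|/n per unit tau0
        if np.max(np.abs(delta)) / chi0 < DELTA_TOL and np.max(drift) < DRIFT_TOL:
            converged = True
            break
        chunk *= 2.0

    if set(states[-1].genomes) != set(genomes):
        # expose the pruned composition as the endpoint
        times.append(t_now)
        states.append(
            CommunityState(dict(zip(genomes, np.exp(u))), n_substrates=n_sub)
        )

    F_vals = np.asarray([lyapunov_F(env, costs, s) for s in states])
    return Trajectory(
        times=np.asarray(times),
        states=states,
        F_values=F_vals,
        converged=converged,
        n_chunks=n_chunks,
        extinct=extinct,
    )
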