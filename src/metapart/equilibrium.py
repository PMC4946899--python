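"""Direct equilibrium computation by concave maximization of F.

As a function of the abundance vector, F is concave and bounded above on
the nonnegative orthant (as long as the species set covers every
substrate), and the competition dynamics perform gradient ascent on it in a
skewed metric: ``Rtot * dF/dn_sigma = Delta_sigma``.  The equilibrium of a
community is therefore the unique maximizer of F restricted to its species
set, found here with a bound-constrained quasi-Newton pass followed by a
Newton polish of Delta = 0 on the detected support.  KKT conditions are
verified explicitly: survivors have |Delta| <= tol, absent-but-allowed
species have Delta <= tol (complementary slackness).

A brute-force support-enumeration solver is provided as an independent
oracle for small problems, and :func:`equilibrate` cross-checks the
optimizer against direct ODE integration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .dynamics import (
    EXTINCTION_THRESHOLD,
    CommunityState,
    Environment,
    _harvest_vec,
    _lyapunov_vec,
    _usage_vec,
    integrate,
)
from .errors import (
    ConsistencyError,
    DegenerateModelError,
    UncoveredSubstrateError,
)
from .model_core import CostTable, Genome, sigma_matrix

__all__ = [
    "EquilibriumResult",
    "InvasionReport",
    "maximize_F",
    "support_enumeration_oracle",
    "equilibrate",
    "uninvadable_check",
    "KKT_TOL",
]

#: KKT tolerance in units of chi0: survivors satisfy |Delta| <= KKT_TOL*chi0,
#: absent species satisfy Delta <= KKT_TOL*chi0.
KKT_TOL = 1e-8


@dataclass
class EquilibriumResult:
    """A converged community equilibrium with KKT diagnostics.

    Attributes
    ----------
    community : CommunityState
        Survivors only (positive abundance).
    F : float
        Community fitness at the equilibrium.
    H : ndarray
        Harvest vector R_i/T_i (finite when all substrates are consumed).
    diagnostics : dict
        ``max_abs_delta_survivors``, ``max_delta_absent`` (KKT residuals),
        ``iterations``, ``method``, and a ``degenerate`` flag for cost ties.
    """

    community: CommunityState
    F: float
    H: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def survivors(self) -> list[Genome]:
        return self.community.genomes

    @property
    def n_survivors(self) -> int:
        return len(self.community)


@dataclass
class InvasionReport:
    """Outcome of testing a genome universe against an equilibrium."""

    invaders: list[Genome]
    max_delta: float
    deltas: dict[Genome, float] = field(default_factory=dict, repr=False)

    @property
    def uninvadable(self) -> bool:
        return not self.invaders


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _check_coverage(sigma: np.ndarray) -> None:
    covered = sigma.any(axis=0)
    if not covered.all():
        raise UncoveredSubstrateError(np.flatnonzero(~covered).tolist())


def _newton_on_support(
    sigma: np.ndarray,
    chi: np.ndarray,
    R: np.ndarray,
    n0: np.ndarray,
    *,
    tol: float = 1e-12,
    max_iter: int = 80,
) -> tuple[np.ndarray, bool]:
    """Damped Newton for Delta(n) = 0 on a fixed support, in linear n.

    Abundances may go negative during iteration (infeasible supports are
    detected by the caller); steps are backtracked so usage stays positive.
    Returns (n, success).
    """
    n = n0.copy()
    for _ in range(max_iter):
        T = _usage_vec(sigma, n)
        if np.any(T <= 0):
            return n, False
        delta = sigma @ (R / T) - chi
        if np.max(np.abs(delta)) < tol:
            return n, True
        J = -(sigma * (R / T**2)) @ sigma.T
        try:
            step = np.linalg.solve(J, -delta)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(J, -delta, rcond=None)
        # backtrack until all T stay positive and the residual shrinks
        lam = 1.0
        ref = np.max(np.abs(delta))
        for _bt in range(40):
            n_try = n + lam * step
            T_try = _usage_vec(sigma, n_try)
            if np.all(T_try > 0):
                d_try = sigma @ (R / T_try) - chi
                if np.max(np.abs(d_try)) < ref or lam < 1e-6:
                    break
            lam *= 0.5
        else:
            return n, False
        n = n_try
    T = _usage_vec(sigma, n)
    ok = np.all(T > 0) and np.max(np.abs(sigma @ (R / T) - chi)) < tol * 1e2
    return n, bool(ok)


def _make_result(
    genomes: Sequence[Genome],
    sigma: np.ndarray,
    n: np.ndarray,
    chi: np.ndarray,
    env: Environment,
    *,
    method: str,
    iterations: int,
    species_set: Sequence[Genome],
    full_sigma: np.ndarray,
    full_chi: np.ndarray,
    n_substrates: int,
) -> EquilibriumResult:
    """Assemble an EquilibriumResult with KKT residuals over species_set."""
    T = _usage_vec(sigma, n)
    H = _harvest_vec(env.R, T)
    delta_full = _delta_vec_from_H(full_sigma, full_chi, H)
    alive = {g: i for i, g in enumerate(genomes)}
    surv_idx = [i for i, g in enumerate(species_set) if g in alive]
    abs_idx = [i for i, g in enumerate(species_set) if g not in alive]
    max_surv = float(np.max(np.abs(delta_full[surv_idx]))) if surv_idx else 0.0
    max_abs = float(np.max(delta_full[abs_idx])) if abs_idx else float("-inf")
    community = CommunityState(dict(zip(genomes, n)), n_substrates=n_substrates)
    F = _lyapunov_vec(sigma, n, chi, env.R, env.chi0)
    return EquilibriumResult(
        community=community,
        F=F,
        H=H,
        diagnostics={
            "max_abs_delta_survivors": max_surv,
            "max_delta_absent": max_abs,
            "iterations": iterations,
            "method": method,
            "degenerate": False,
        },
    )


def _delta_vec_from_H(sigma: np.ndarray, chi: np.ndarray, H: np.ndarray) -> np.ndarray:
    finite = np.isfinite(H)
    if finite.all():
        return sigma @ H - chi
    delta = sigma[:, finite] @ H[finite] - chi
    delta[(sigma[:, ~finite] > 0).any(axis=1)] = np.inf
    return delta


# ---------------------------------------------------------------------------
# concave maximization
# ---------------------------------------------------------------------------

def maximize_F(
    species_set: Sequence[Genome],
    env: Environment,
    costs: CostTable,
    *,
    kkt_tol: float | None = None,
    x0: np.ndarray | None = None,
    max_rounds: int = 6,
) -> EquilibriumResult:
    """Equilibrate a species set by maximizing F over nonnegative abundances.

    Runs L-BFGS-B with the analytic gradient (Delta/Rtot), detects the
    surviving support at the biomass-fraction threshold, polishes Delta = 0
    on that support by Newton, then verifies the KKT conditions against the
    full ``species_set``; violating species are re-admitted and the process
    repeats (at most ``max_rounds``).

    Raises
    ------
    UncoveredSubstrateError
        If ``species_set`` does not jointly cover every substrate.
    """
    genomes = sorted(set(species_set))
    if not genomes:
        raise ValueError("species_set is empty")
    n_sub = env.n_substrates
    if genomes[0].n_substrates != n_sub:
        raise ValueError("genome N does not match environment N")
    sigma = sigma_matrix(genomes, n_sub)
    _check_coverage(sigma)
    chi = costs.chi_array(genomes)
    R, Rtot, chi0 = env.R, env.Rtot, env.chi0
    tol = (KKT_TOL if kkt_tol is None else kkt_tol) * chi0
    K = len(genomes)

    tiny_T = 1e-12 * Rtot

    def neg_F_and_grad(n):
        T = _usage_vec(sigma, n)
        T_safe = np.maximum(T, tiny_T)
        val = -(R @ np.log(T_safe / (R / chi0)) - chi @ n + Rtot)
        grad = -(sigma @ (R / T_safe) - chi)
        return val, grad

    if x0 is None:
        x0 = Rtot / (K * chi)  # equal biomass shares
    n = np.asarray(x0, dtype=float)

    iterations = 0
    for _round in range(max_rounds):
        res = minimize(
            neg_F_and_grad,
            n,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * K,
            options={"maxiter": 4000, "ftol": 1e-16, "gtol": 1e-10},
        )
        iterations += res.nit
        n = res.x
        alive = chi * n / Rtot >= EXTINCTION_THRESHOLD
        if not alive.any():
            alive = n >= n.max() * 1e-6  # degenerate safeguard
        # Newton-polish Delta=0 on the detected support, dropping species the
        # polish drives non-positive (support slightly over-estimated).
        while alive.any():
            idx = np.flatnonzero(alive)
            n_s, ok = _newton_on_support(sigma[idx], chi[idx], R, n[idx])
            if not ok:
                break
            neg = n_s <= 0
            if not neg.any():
                n = np.zeros(K)
                n[idx] = n_s
                break
            alive[idx[neg]] = False
        # KKT check over the full set at current harvests
        T = _usage_vec(sigma, n)
        H = _harvest_vec(R, T)
        delta = _delta_vec_from_H(sigma, chi, H)
        viol = (~alive) & (delta > tol)
        surv_bad = alive & (np.abs(delta) > tol)
        if not viol.any() and not surv_bad.any():
            break
        # re-admit violators at a small abundance and try again
        n = np.maximum(n, 0.0)
        n[viol] = 1e-6 * Rtot / chi[viol]
        n[alive & (n <= 0)] = EXTINCTION_THRESHOLD * Rtot / chi[alive & (n <= 0)]
    survivors = [g for g, a in zip(genomes, chi * n / Rtot >= EXTINCTION_THRESHOLD) if a]
    mask = chi * n / Rtot >= EXTINCTION_THRESHOLD
    return _make_result(
        survivors,
        sigma[mask],
        n[mask],
        chi[mask],
        env,
        method="optimize",
        iterations=iterations,
        species_set=genomes,
        full_sigma=sigma,
        full_chi=chi,
        n_substrates=n_sub,
    )


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def support_enumeration_oracle(
    species_set: Sequence[Genome],
    env: Environment,
    costs: CostTable,
    *,
    kkt_tol: float | None = None,
    max_species: int = 12,
) -> EquilibriumResult:
    """Brute-force equilibrium finder for small species sets (oracle).

    Enumerates every subset as a candidate survivor support, solves
    Delta = 0 on it by Newton root-finding, keeps candidates with strictly
    positive abundances whose harvests satisfy the KKT conditions against
    the *full* species set, and returns the (generically unique) valid one.
    Supports that do not cover all substrates, or exceed N species, cannot
    be equilibria and are skipped (with more than N survivors the harvest
    equations are overdetermined; valid only at measure-zero cost ties).

    Raises
    ------
    DegenerateModelError
        If no subset passes; this indicates degenerate costs or a bug.
    """
    genomes = sorted(set(species_set))
    if len(genomes) > max_species:
        raise ValueError(
            f"oracle limited to {max_species} species, got {len(genomes)}"
        )
    n_sub = env.n_substrates
    sigma = sigma_matrix(genomes, n_sub)
    _check_coverage(sigma)
    chi = costs.chi_array(genomes)
    R, Rtot, chi0 = env.R, env.Rtot, env.chi0
    tol = (KKT_TOL if kkt_tol is None else kkt_tol) * chi0
    K = len(genomes)

    valid: list[tuple[float, np.ndarray, tuple[int, ...]]] = []
    for size in range(1, min(K, n_sub) + 1):
        for support in itertools.combinations(range(K), size):
            idx = np.asarray(support)
            sig_s = sigma[idx]
            if not sig_s.any(axis=0).all():
                continue  # leaves a substrate unconsumed
            chi_s = chi[idx]
            n0 = Rtot / (size * chi_s)
            n_s, ok = _newton_on_support(sig_s, chi_s, R, n0, tol=1e-12)
            if not ok or np.any(n_s <= 0):
                continue
            H = _harvest_vec(R, _usage_vec(sig_s, n_s))
            delta = _delta_vec_from_H(sigma, chi, H)
            absent = np.setdiff1d(np.arange(K), idx)
            if absent.size and np.max(delta[absent]) > tol:
                continue  # invadable: fails complementary slackness
            F = float(-(R @ np.log(H / chi0)) / Rtot)
            valid.append((F, n_s, support))

    if not valid:
        raise DegenerateModelError(
            "support enumeration found no KKT-valid equilibrium support"
        )
    valid.sort(key=lambda t: -t[0])
    F_best, n_best, support_best = valid[0]
    degenerate = len(valid) > 1 and any(
        abs(F - F_best) < 1e-9 and set(s) != set(support_best)
        for F, _n, s in valid[1:]
    )
    idx = np.asarray(support_best)
    result = _make_result(
        [genomes[i] for i in idx],
        sigma[idx],
        n_best,
        chi[idx],
        env,
        method="support_enumeration",
        iterations=len(valid),
        species_set=genomes,
        full_sigma=sigma,
        full_chi=chi,
        n_substrates=n_sub,
    )
    result.diagnostics["degenerate"] = degenerate
    return result


# ---------------------------------------------------------------------------
# dispatch + invasion report
# ---------------------------------------------------------------------------

def equilibrate(
    community_or_set: CommunityState | Sequence[Genome],
    env: Environment,
    costs: CostTable,
    method: str = "auto",
    *,
    spot_check_limit: int = 64,
    check_rtol: float = 1e-4,
) -> EquilibriumResult:
    """Equilibrate a community (or species set) by the requested route.

    ``method``:

    - ``"optimize"``: concave maximization of F (fast, default workhorse);
    - ``"ode"``: direct integration of the dynamics until the fixed point;
    - ``"auto"``: optimizer, spot-checked against the ODE route when the
      species set has at most ``spot_check_limit`` members — disagreement in
      support or abundances beyond ``check_rtol`` raises
      :class:`ConsistencyError` (a deliberate bug trap, since the two routes
      must agree for this model).

    The outcome depends only on which species are present, not on their
    initial abundances, so passing a bare species set is equivalent to any
    positive-abundance community over it.
    """
    if isinstance(community_or_set, CommunityState):
        community = community_or_set
        species = community.support()
    else:
        species = sorted(set(community_or_set))
        community = None

    if method not in ("auto", "optimize", "ode"):
        raise ValueError(f"unknown method {method!r}")

    if method == "ode":
        return _equilibrate_ode(community, species, env, costs)

    opt = maximize_F(species, env, costs)
    if method == "auto" and len(species) <= spot_check_limit:
        ode = _equilibrate_ode(community, species, env, costs)
        if set(ode.survivors) != set(opt.survivors):
            raise ConsistencyError(
                "optimizer and ODE integration disagree on the survivor set: "
                f"{sorted(g.label for g in opt.survivors)} vs "
                f"{sorted(g.label for g in ode.survivors)}"
            )
        for g in opt.survivors:
            a, b = opt.community[g], ode.community[g]
            if abs(a - b) > check_rtol * max(abs(a), abs(b)):
                raise ConsistencyError(
                    f"abundance mismatch for {g.label}: {a} (optimize) vs {b} (ode)"
                )
        opt.diagnostics["ode_spot_check"] = True
    return opt


def _equilibrate_ode(
    community: CommunityState | None,
    species: Sequence[Genome],
    env: Environment,
    costs: CostTable,
) -> EquilibriumResult:
    if community is None:
        chi = costs.chi_array(species)
        n0 = env.Rtot / (len(species) * chi)
        community = CommunityState(dict(zip(species, n0)))
    sigma = sigma_matrix(list(species), env.n_substrates)
    _check_coverage(sigma)
    traj = integrate(community, env, costs)
    final = traj.final
    genomes = final.genomes
    sig = sigma_matrix(genomes, env.n_substrates)
    chi = costs.chi_array(genomes)
    # polish the ODE endpoint to the exact fixed point on its support
    n, ok = _newton_on_support(sig, chi, env.R, final.abundances())
    if not ok or np.any(n <= 0):
        n = final.abundances()
    full_sigma = sigma_matrix(sorted(set(species)), env.n_substrates)
    full_chi = costs.chi_array(sorted(set(species)))
    result = _make_result(
        genomes,
        sig,
        n,
        chi,
        env,
        method="ode",
        iterations=traj.n_chunks,
        species_set=sorted(set(species)),
        full_sigma=full_sigma,
        full_chi=full_chi,
        n_substrates=env.n_substrates,
    )
    result.converged = traj.converged
    return result


def uninvadable_check(
    eq: EquilibriumResult,
    universe: Sequence[Genome],
    costs: CostTable,
    *,
    tol: float | None = None,
) -> InvasionReport:
    """Test every genome in ``universe`` for invasion at ``eq``'s harvests.

    A genome invades when its surplus Delta at the equilibrium harvest
    vector exceeds the KKT tolerance; resident survivors have Delta = 0 and
    never appear as invaders.  The global maximizer of F over the universe
    is uninvadable by construction.
    """
    genomes = sorted(set(universe))
    sigma = sigma_matrix(genomes, eq.community.n_substrates)
    chi = costs.chi_array(genomes)
    delta = _delta_vec_from_H(sigma, chi, eq.H)
    t = (KKT_TOL if tol is None else tol)
    invaders = [g for g, d in zip(genomes, delta) if d > t]
    return InvasionReport(
        invaders=invaders,
        max_delta=float(np.max(delta)) if len(delta) else float("-inf"),
        deltas=dict(zip(genomes, delta)),
    )
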