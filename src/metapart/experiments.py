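"""Scripted numerical experiments on the resource-partitioning model.

Each experiment is a pure function of its parameters and seed and returns
in-memory results (dataclasses / DataFrames); pass ``out_dir`` to also
write a resolved ``config.json`` plus summary CSVs.  Full-scale defaults
match the published setting (N = 10 substrates, R_i/chi0 = 100, cost
scatter eps = 1e-3, 1023-species universe, M = 50 community library);
every size can be scaled down for quick runs.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .coalescence import (
    CommunityLibraryEntry,
    coalesce,
    community_mean_performance,
    elimination_assay,
    quadrant_select,
    similarity,
)
from .dynamics import (
    CommunityState,
    Environment,
    Trajectory,
    harvests,
    integrate,
    lyapunov_F,
    usage,
)
from .equilibrium import EquilibriumResult, equilibrate, maximize_F
from .io import substream
from .model_core import (
    CostTable,
    Genome,
    enumerate_genomes,
    performance_ranks,
    sample_cost_table,
)

__all__ = [
    "CompetitionReport",
    "TrajectoryReport",
    "SimilarityReport",
    "IslandAnalyticsReport",
    "run_full_competition",
    "run_rank_sweep",
    "run_trajectories",
    "sample_library_genomes",
    "enumerate_subcommunities",
    "build_community_library",
    "run_quadrant_assays",
    "run_similarity_experiment",
    "island_analytics",
]


# ---------------------------------------------------------------------------
# full-universe competition and rank statistics
# ---------------------------------------------------------------------------

@dataclass
class CompetitionReport:
    """Equilibrium of the all-species competition with rank bookkeeping."""

    equilibrium: EquilibriumResult
    survivors: pd.DataFrame  # label, abundance, f, rank (ordered by abundance)
    max_rank: int
    n_species: int


def run_full_competition(
    n_substrates: int = 10,
    eps: float = 1e-3,
    R_over_chi0: float = 100.0,
    seed: int | np.random.SeedSequence = 0,
    *,
    costs: CostTable | None = None,
    out_dir: str | Path | None = None,
) -> CompetitionReport:
    """Equilibrate all ``2**N - 1`` species started from equal abundance.

    By competitive exclusion at most N species survive; survivors are
    reported in descending abundance with their intrinsic-performance ranks.
    """
    universe = enumerate_genomes(n_substrates)
    if costs is None:
        costs = sample_cost_table(n_substrates, eps, seed=seed)
    env = Environment.equiabundant(n_substrates, R_over_chi0, chi0=costs.chi0)
    eq = maximize_F(universe, env, costs)
    ranks = performance_ranks(costs)
    rows = [
        {
            "label": g.label,
            "genome_bits": g.bitstring,
            "abundance": eq.community[g],
            "f": costs.f(g),
            "rank": ranks[g],
        }
        for g in eq.survivors
    ]
    df = pd.DataFrame(rows).sort_values("abundance", ascending=False, ignore_index=True)
    report = CompetitionReport(
        equilibrium=eq,
        survivors=df,
        max_rank=int(df["rank"].max()),
        n_species=len(universe),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "survivors.csv", index=False)
        _write_config(out, n_substrates=n_substrates, eps=eps,
                      R_over_chi0=R_over_chi0, seed=_seed_repr(seed))
    return report


def _weighted_median_rank(ranks: np.ndarray, weights: np.ndarray) -> float:
    """Smallest rank whose cumulative abundance reaches half the total."""
    order = np.argsort(ranks)
    cum = np.cumsum(weights[order])
    idx = int(np.searchsorted(cum, 0.5 * cum[-1]))
    return float(ranks[order][min(idx, len(ranks) - 1)])


def run_rank_sweep(
    eps_grid: Sequence[float] | None = None,
    n_realizations: int = 100,
    n_substrates: int = 10,
    R_over_chi0: float = 100.0,
    seed: int | None = 0,
    *,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Median survivor f-rank vs cost scatter, averaged over realizations.

    For each eps, ``n_realizations`` independent cost tables are sampled,
    the full universe is equilibrated, and the median (and abundance-
    weighted median) intrinsic-performance rank of the survivors recorded.
    Default grid: 8 log-spaced values in [1e-4, 1e-1].
    """
    if eps_grid is None:
        eps_grid = np.logspace(-4, -1, 8)
    universe = enumerate_genomes(n_substrates)
    rows = []
    for i_eps, eps in enumerate(eps_grid):
        med, wmed = [], []
        for j in range(n_realizations):
            ss = substream(seed, 0, i_eps, j)
            costs = sample_cost_table(n_substrates, eps, seed=ss)
            env = Environment.equiabundant(n_substrates, R_over_chi0)
            eq = maximize_F(universe, env, costs)
            ranks = performance_ranks(costs)
            r = np.asarray([ranks[g] for g in eq.survivors], dtype=float)
            w = eq.community.abundances()
            med.append(float(np.median(r)))
            wmed.append(_weighted_median_rank(r, w))
        rows.append(
            {
                "eps": float(eps),
                "mean_median_rank": float(np.mean(med)),
                "mean_weighted_median_rank": float(np.mean(wmed)),
                "sd_median_rank": float(np.std(med)),
                "n_realizations": n_realizations,
            }
        )
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "rank_sweep.csv", index=False)
        _write_config(out, eps_grid=[float(e) for e in eps_grid],
                      n_realizations=n_realizations, n_substrates=n_substrates,
                      R_over_chi0=R_over_chi0, seed=seed)
    return df


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def early_coupling(trace: pd.DataFrame, burn_in: int = 20) -> float:
    """Spearman correlation of F with abundance-weighted mean f, far from
    equilibrium: over the first half of the sampled trajectory, excluding
    the first integration chunk (the relaxation of the arbitrary initial
    abundances, during which both quantities move non-monotonically)."""
    half = len(trace) // 2
    F = trace["F"].to_numpy()[burn_in:half]
    wf = trace["weighted_mean_f"].to_numpy()[burn_in:half]
    return float(spearmanr(F, wf).statistic)


@dataclass
class TrajectoryReport:
    """Ensemble of trajectories with community-level summary traces."""

    trajectories: list[Trajectory]
    traces: list[pd.DataFrame]  # per run: time, F, weighted_mean_f, mean_availability
    final_supports: list[frozenset]

    @property
    def common_support(self) -> bool:
        return len(set(self.final_supports)) == 1


def _random_initial_community(
    universe: Sequence[Genome],
    costs: CostTable,
    env: Environment,
    rng: np.random.Generator,
    decades: float = 4.0,
) -> CommunityState:
    # Log-uniform abundances over `decades` decades below the equal-biomass
    # share (stand-in for the unspecified random-initial-condition ensemble).
    chi = costs.chi_array(universe)
    n_hi = env.Rtot / (len(universe) * chi)
    u = rng.uniform(-decades, 0.0, size=len(universe))
    return CommunityState(dict(zip(universe, n_hi * 10.0**u)))


def run_trajectories(
    n_traj: int = 10,
    n_substrates: int = 10,
    eps: float = 1e-3,
    R_over_chi0: float = 100.0,
    seed: int | None = 0,
    *,
    costs: CostTable | None = None,
    universe: Sequence[Genome] | None = None,
    out_dir: str | Path | None = None,
) -> TrajectoryReport:
    """Integrate the full competition from random initial conditions.

    All runs share one cost realization and must converge to the same
    survivor set; per-run traces record F, the abundance-weighted mean
    intrinsic performance, and the mean substrate availability (mean H_i),
    which decreases as the community depletes its substrates.
    """
    if universe is None:
        universe = enumerate_genomes(n_substrates)
    if costs is None:
        costs = sample_cost_table(n_substrates, eps, seed=substream(seed, 1, 0))
    env = Environment.equiabundant(n_substrates, R_over_chi0, chi0=costs.chi0)
    trajectories, traces, supports = [], [], []
    for i in range(n_traj):
        rng = np.random.default_rng(substream(seed, 1, 1, i))
        init = _random_initial_community(universe, costs, env, rng)
        traj = integrate(init, env, costs)
        rows = []
        for t, state, F in zip(traj.times, traj.states, traj.F_values):
            H = harvests(env, usage(state, n_substrates))
            rows.append(
                {
                    "time": t,
                    "F": F,
                    "weighted_mean_f": community_mean_performance(
                        state, costs, abundance_weighted=True
                    ),
                    "mean_availability": float(np.mean(H[np.isfinite(H)])),
                }
            )
        trajectories.append(traj)
        traces.append(pd.DataFrame(rows))
        supports.append(frozenset(g for g in traj.final.support()))
    report = TrajectoryReport(
        trajectories=trajectories, traces=traces, final_supports=supports
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, tr in enumerate(traces):
            tr.to_csv(out / f"trace_{i}.csv", index=False)
        _write_config(out, n_traj=n_traj, n_substrates=n_substrates, eps=eps,
                      R_over_chi0=R_over_chi0, seed=seed)
    return report


# ---------------------------------------------------------------------------
# community library (sub-community sampling)
# ---------------------------------------------------------------------------

def sample_library_genomes(
    universe: Sequence[Genome], M: int, rng: np.random.Generator
) -> list[Genome]:
    """Draw M distinct genomes uniformly from the universe."""
    if M > len(universe):
        raise ValueError(f"M={M} exceeds universe size {len(universe)}")
    idx = rng.choice(len(universe), size=M, replace=False)
    return [universe[i] for i in sorted(idx)]


def enumerate_subcommunities(
    members: Sequence[Genome], k: int, n_substrates: int
) -> tuple[int, list[tuple[Genome, ...]]]:
    """All k-subsets of ``members``; returns (candidate count, covering ones).

    A subset is retained iff its genomes jointly cover all substrates
    ("fully functional": finite F).  The candidate count is C(len(members), k).
    """
    full = (1 << n_substrates) - 1
    n_candidates = math.comb(len(members), k)
    covering = [
        combo
        for combo in itertools.combinations(members, k)
        if _union_code(combo) == full
    ]
    return n_candidates, covering


def _union_code(genomes: Sequence[Genome]) -> int:
    code = 0
    for g in genomes:
        code |= g.code
    return code


def build_community_library(
    M: int = 50,
    k: int = 4,
    n_substrates: int = 10,
    eps: float = 1e-3,
    R_over_chi0: float = 100.0,
    seed: int | None = 0,
    *,
    costs: CostTable | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[CommunityLibraryEntry], dict]:
    """Exhaustively equilibrate all fully functional k-species communities.

    Draws M distinct genomes, forms all C(M, k) subsets, keeps those
    covering every substrate, and equilibrates each, recording the
    community fitness F and the (unweighted) mean intrinsic performance of
    the founding members.  The retained count is seed-dependent and is
    reported in the info dict, not asserted.
    """
    universe = enumerate_genomes(n_substrates)
    if costs is None:
        costs = sample_cost_table(n_substrates, eps, seed=substream(seed, 2, 0))
    env = Environment.equiabundant(n_substrates, R_over_chi0, chi0=costs.chi0)
    rng = np.random.default_rng(substream(seed, 2, 1))
    members = sample_library_genomes(universe, M, rng)
    n_candidates, covering = enumerate_subcommunities(members, k, n_substrates)
    entries = []
    for combo in covering:
        eq = maximize_F(combo, env, costs)
        entries.append(
            CommunityLibraryEntry(
                members=combo,
                equilibrium=eq,
                F=eq.F,
                mean_f=community_mean_performance(combo, costs),
            )
        )
    info = {
        "M": M,
        "k": k,
        "n_candidates": n_candidates,
        "n_retained": len(entries),
        "eps": eps,
        "seed": seed,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "members": ["+".join(g.label for g in e.members) for e in entries],
                "F": [e.F for e in entries],
                "mean_f": [e.mean_f for e in entries],
                "n_survivors": [e.equilibrium.n_survivors for e in entries],
            }
        ).to_csv(out / "library.csv", index=False)
        _write_config(out, **info)
    return entries, info


def run_quadrant_assays(
    library: Sequence[CommunityLibraryEntry],
    env: Environment,
    costs: CostTable,
    n_pairs: int = 500,
    q: float = 0.10,
    seed: int | None = 0,
    *,
    out_dir: str | Path | None = None,
) -> dict:
    """Elimination assays between the library's extreme quadrants.

    Runs I-vs-III (both measures agree) and II-vs-IV (collective fitness F
    against mean intrinsic performance) with ``n_pairs`` random pairs each.
    An assay whose quadrants are empty (expected at large cost scatter) is
    reported as ``{"empty": True}``.
    """
    quads = quadrant_select(library, q=q)
    results: dict = {"quadrant_sizes": {k: len(v) for k, v in quads.items()}}
    for name, (pa, pb) in {
        "I_vs_III": ("I", "III"),
        "II_vs_IV": ("II", "IV"),
    }.items():
        if not quads[pa] or not quads[pb]:
            results[name] = {"empty": True}
            continue
        table, summary = elimination_assay(
            quads[pa], quads[pb], n_pairs, env, costs,
            seed=substream(seed, 3, 0 if name == "I_vs_III" else 1),
        )
        results[name] = {"empty": False, "table": table, "summary": summary}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("I_vs_III", "II_vs_IV"):
            res = results[name]
            if not res.get("empty", True):
                res["table"].to_csv(out / f"assay_{name}.csv", index=False)
                (out / f"assay_{name}_summary.json").write_text(
                    json.dumps(res["summary"], indent=2)
                )
        _write_config(out, n_pairs=n_pairs, q=q, seed=seed,
                      quadrant_sizes=results["quadrant_sizes"])
    return results


# ---------------------------------------------------------------------------
# similarity experiment
# ---------------------------------------------------------------------------

@dataclass
class SimilarityReport:
    """Post-coalescence similarity to parent 1 vs parent fitness differences."""

    pairs: pd.DataFrame
    binned_F: pd.DataFrame
    binned_mean_f: pd.DataFrame
    spearman_F: float
    spearman_mean_f: float


def _binned_mean(x: np.ndarray, y: np.ndarray, n_bins: int) -> pd.DataFrame:
    edges = np.linspace(x.min(), x.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        rows.append(
            {
                "bin_center": 0.5 * (edges[b] + edges[b + 1]),
                "mean_S": float(y[m].mean()) if m.any() else np.nan,
                "sd_S": float(y[m].std()) if m.any() else np.nan,
                "count": int(m.sum()),
            }
        )
    return pd.DataFrame(rows)


def run_similarity_experiment(
    library: Sequence[CommunityLibraryEntry],
    env: Environment,
    costs: CostTable,
    n_pairs: int = 10_000,
    n_bins: int = 7,
    seed: int | None = 0,
    *,
    out_dir: str | Path | None = None,
) -> SimilarityReport:
    """Similarity of the coalescence outcome to its parents vs fitness gap.

    For random library pairs (C1, C2), coalesce to C* and record
    S1 = S(C1, C*).  The difference in community fitness F and in mean
    member performance, each scaled so its largest magnitude is 1, are the
    two candidate predictors; the report carries binned means of S1 against
    both and their Spearman rank correlations.
    """
    rng = np.random.default_rng(substream(seed, 4, 0))
    rows = []
    for pair_id in range(n_pairs):
        i = int(rng.integers(len(library)))
        j = int(rng.integers(len(library)))
        while j == i:
            j = int(rng.integers(len(library)))
        e1, e2 = library[i], library[j]
        c1, c2 = e1.equilibrium.community, e2.equilibrium.community
        out = coalesce(c1, c2, env, costs)
        c_star = out.result.community
        rows.append(
            {
                "pair_id": pair_id,
                "F1": e1.F,
                "F2": e2.F,
                "mean_f1": e1.mean_f,
                "mean_f2": e2.mean_f,
                "S1": similarity(c1, c_star),
                "S2": similarity(c2, c_star),
            }
        )
    pairs = pd.DataFrame(rows)
    dF = (pairs["F1"] - pairs["F2"]).to_numpy()
    dmf = (pairs["mean_f1"] - pairs["mean_f2"]).to_numpy()
    pairs["dF_scaled"] = dF / np.max(np.abs(dF))
    pairs["dmf_scaled"] = dmf / np.max(np.abs(dmf))
    S1 = pairs["S1"].to_numpy()
    report = SimilarityReport(
        pairs=pairs,
        binned_F=_binned_mean(pairs["dF_scaled"].to_numpy(), S1, n_bins),
        binned_mean_f=_binned_mean(pairs["dmf_scaled"].to_numpy(), S1, n_bins),
        spearman_F=float(spearmanr(pairs["dF_scaled"], S1).statistic),
        spearman_mean_f=float(spearmanr(pairs["dmf_scaled"], S1).statistic),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pairs.to_csv(out / "similarity_pairs.csv", index=False)
        report.binned_F.to_csv(out / "similarity_binned_F.csv", index=False)
        report.binned_mean_f.to_csv(out / "similarity_binned_mean_f.csv", index=False)
        _write_config(out, n_pairs=n_pairs, n_bins=n_bins, seed=seed)
    return report


# ---------------------------------------------------------------------------
# closed-form island analytics
# ---------------------------------------------------------------------------

@dataclass
class IslandAnalyticsReport:
    """Closed forms for the one-generalist and all-specialist islands.

    The generalist island expresses all pathways at one level
    (T_i = n_G = Rtot/chi_G); the specialist island tracks the supply
    vector exactly (T_i = R_i/chi_i).  ``*_simulated`` carry the
    equilibrium solver's values for direct comparison.
    """

    generalist_n: float
    generalist_F: float
    generalist_n_simulated: float
    generalist_F_simulated: float
    specialist_T: np.ndarray
    specialist_T_simulated: np.ndarray
    specialist_F: float
    specialist_F_simulated: float
    max_rel_error: float = field(init=False)

    def __post_init__(self):
        errs = [
            abs(self.generalist_n_simulated - self.generalist_n)
            / abs(self.generalist_n),
            abs(self.generalist_F_simulated - self.generalist_F)
            / max(abs(self.generalist_F), 1e-12),
            float(
                np.max(
                    np.abs(self.specialist_T_simulated - self.specialist_T)
                    / np.abs(self.specialist_T)
                )
            ),
        ]
        self.max_rel_error = float(max(errs))


def island_analytics(
    env: Environment, costs: CostTable
) -> IslandAnalyticsReport:
    """Verify the simulator against the two exactly solvable islands.

    Requires the cost table to price the full generalist and every
    specialist.  The generalist's closed-form F = ln(N*chi0/chi_G) holds for
    equiabundant supplies; for general supplies the Lyapunov form is used.
    """
    N = env.n_substrates
    generalist = Genome(N, (1 << N) - 1)
    specialists = [Genome(N, 1 << i) for i in range(N)]
    chi_G = costs.chi(generalist)
    n_G = env.Rtot / chi_G
    if np.allclose(env.R, env.R[0]):
        F_G = math.log(N * env.chi0 / chi_G)
    else:
        F_G = lyapunov_F(
            env, costs, CommunityState({generalist: n_G})
        )
    eq_G = equilibrate([generalist], env, costs, method="optimize")
    chi_S = costs.chi_array(specialists)
    T_spec = env.R / chi_S
    F_spec = float(-(env.R @ np.log((env.R / T_spec) / env.chi0)) / env.Rtot)
    eq_S = equilibrate(specialists, env, costs, method="optimize")
    T_sim = usage(eq_S.community, N)
    return IslandAnalyticsReport(
        generalist_n=n_G,
        generalist_F=F_G,
        generalist_n_simulated=float(eq_G.community[generalist]),
        generalist_F_simulated=eq_G.F,
        specialist_T=T_spec,
        specialist_T_simulated=T_sim,
        specialist_F=F_spec,
        specialist_F_simulated=eq_S.F,
    )


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------

def _seed_repr(seed):
    return seed if isinstance(seed, (int, type(None))) else "seedsequence"


def _write_config(out: Path, **params) -> None:
    (out / "config.json").write_text(json.dumps(params, indent=2, sort_keys=True))
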