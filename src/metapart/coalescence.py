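"""Community coalescence: mixing, similarity, and elimination assays.

A coalescence event brings the equilibrium communities of two habitat
patches into contact in a shared environment; the merged community then
re-equilibrates.  Because the equilibrium depends only on which species are
present, the outcome is independent of the mixing ratio.  The assays here
ask which parent a species that went extinct during re-equilibration came
from ("provenance"), and how well the community-level fitness F of the
native community predicts a member's survival compared with the member's
own intrinsic performance f.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .dynamics import CommunityState, Environment
from .equilibrium import EquilibriumResult, equilibrate
from .errors import UndefinedSimilarityError
from .model_core import CostTable, Genome

__all__ = [
    "CoalescenceOutcome",
    "CommunityLibraryEntry",
    "mix",
    "coalesce",
    "similarity",
    "community_mean_performance",
    "quadrant_select",
    "elimination_assay",
]

Provenance = Literal["parent1", "parent2", "both"]


@dataclass
class CoalescenceOutcome:
    """Result of merging two communities and re-equilibrating.

    ``provenance`` maps each species eliminated during re-equilibration to
    the parent(s) it came from.
    """

    parents: tuple[CommunityState, CommunityState]
    mixed: CommunityState
    result: EquilibriumResult
    provenance: dict[Genome, Provenance] = field(default_factory=dict)

    @property
    def eliminated(self) -> list[Genome]:
        return list(self.provenance)


@dataclass
class CommunityLibraryEntry:
    """One equilibrated k-species community from a library.

    ``mean_f`` is the unweighted mean intrinsic performance of the founding
    members; ``F`` the equilibrium community fitness.
    """

    members: tuple[Genome, ...]
    equilibrium: EquilibriumResult
    F: float
    mean_f: float


def mix(c1: CommunityState, c2: CommunityState, w: float = 0.5) -> CommunityState:
    """Weighted union ``w*n1 + (1-w)*n2`` of two communities.

    Downstream equilibria do not depend on ``w`` (only on the union
    support), so the default 0.5 is a convention, not a model parameter.
    """
    if c1.n_substrates != c2.n_substrates:
        raise ValueError("communities live in worlds with different N")
    if not (0.0 <= w <= 1.0):
        raise ValueError("mixing weight must be in [0, 1]")
    merged: dict[Genome, float] = {}
    for g, n in c1.items():
        merged[g] = w * n
    for g, n in c2.items():
        merged[g] = merged.get(g, 0.0) + (1.0 - w) * n
    return CommunityState(merged, n_substrates=c1.n_substrates)


def coalesce(
    c1: CommunityState,
    c2: CommunityState,
    env: Environment,
    costs: CostTable,
    w: float = 0.5,
    method: str = "optimize",
) -> CoalescenceOutcome:
    """Merge two (equilibrium) communities and re-equilibrate.

    Species present in a parent but absent from the re-equilibrated
    community are recorded as eliminated, tagged with their provenance
    (``parent1`` / ``parent2`` / ``both``).
    """
    mixed = mix(c1, c2, w)
    result = equilibrate(mixed, env, costs, method=method)
    survivors = set(result.survivors)
    s1, s2 = set(c1.support()), set(c2.support())
    provenance: dict[Genome, Provenance] = {}
    for g in sorted(s1 | s2):
        if g in survivors:
            continue
        if g in s1 and g in s2:
            provenance[g] = "both"
        elif g in s1:
            provenance[g] = "parent1"
        else:
            provenance[g] = "parent2"
    return CoalescenceOutcome(
        parents=(c1, c2), mixed=mixed, result=result, provenance=provenance
    )


def similarity(c1: CommunityState, c2: CommunityState) -> float:
    """Cosine similarity of the two species-abundance vectors, in [0, 1].

    Scale-invariant; 1 iff the communities are proportional, 0 for disjoint
    supports.
    """
    support = sorted(set(c1) | set(c2))
    if not support:
        raise UndefinedSimilarityError("both communities are empty")
    v1 = np.asarray([c1.get(g, 0.0) for g in support])
    v2 = np.asarray([c2.get(g, 0.0) for g in support])
    norm1, norm2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if norm1 == 0 or norm2 == 0:
        raise UndefinedSimilarityError("a community has zero total abundance")
    return float(v1 @ v2 / (norm1 * norm2))


def community_mean_performance(
    members: Sequence[Genome] | CommunityState,
    costs: CostTable,
    *,
    weights: Sequence[float] | None = None,
    abundance_weighted: bool = False,
) -> float:
    """Mean intrinsic performance of a community's members.

    Unweighted by default (each member species counts once); set
    ``abundance_weighted=True`` (with a CommunityState) or pass explicit
    ``weights`` for the abundance-weighted variant used along dynamical
    trajectories.
    """
    if isinstance(members, CommunityState):
        genomes = members.genomes
        if abundance_weighted and weights is None:
            weights = members.abundances()
    else:
        genomes = list(members)
        if abundance_weighted and weights is None:
            raise ValueError("abundance weighting needs a CommunityState or weights")
    if not genomes:
        raise ValueError("community has no members")
    f = costs.f_array(genomes)
    if weights is None:
        return float(f.mean())
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive total")
    return float(f @ w / w.sum())


def quadrant_select(
    library: Sequence[CommunityLibraryEntry],
    q: float = 0.10,
) -> dict[str, list[CommunityLibraryEntry]]:
    """Partition library extremes by empirical quantiles of F and mean f.

    Quadrants (fractions ``q`` per tail, default 10%):

    - ``"I"``   : bottom-q in both F and mean f;
    - ``"II"``  : top-q F, bottom-q mean f (collectively fit, individually weak);
    - ``"III"`` : top-q in both;
    - ``"IV"``  : bottom-q F, top-q mean f (individually fit, collectively weak).

    Empty quadrants are legal and expected when F and mean f are strongly
    coupled (large cost scatter).
    """
    if not (0 < q < 0.5):
        raise ValueError("q must be in (0, 0.5)")
    if len(library) < 10 / q:
        raise ValueError(f"library too small for q={q}: need >= {10 / q:.0f} entries")
    F = np.asarray([e.F for e in library])
    mf = np.asarray([e.mean_f for e in library])
    F_lo, F_hi = np.quantile(F, q), np.quantile(F, 1.0 - q)
    m_lo, m_hi = np.quantile(mf, q), np.quantile(mf, 1.0 - q)
    quads: dict[str, list[CommunityLibraryEntry]] = {
        "I": [], "II": [], "III": [], "IV": []
    }
    for e, Fv, mv in zip(library, F, mf):
        lowF, hiF = Fv <= F_lo, Fv >= F_hi
        lowm, him = mv <= m_lo, mv >= m_hi
        if lowF and lowm:
            quads["I"].append(e)
        elif hiF and him:
            quads["III"].append(e)
        elif hiF and lowm:
            quads["II"].append(e)
        elif lowF and him:
            quads["IV"].append(e)
    return quads


def elimination_assay(
    pool_a: Sequence[CommunityLibraryEntry],
    pool_b: Sequence[CommunityLibraryEntry],
    n_pairs: int,
    env: Environment,
    costs: CostTable,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[pd.DataFrame, dict]:
    """Pairwise community competitions recording eliminated species.

    For each of ``n_pairs`` random (a, b) pairs (sampled with replacement,
    one community from each pool), the two equilibrium communities are
    jointly re-equilibrated.  Each species of the union is a row: its
    ``f_rank_row`` is its 1-based position when the pair's species are
    ordered by intrinsic performance f, descending (row 1 = best), and
    eliminated species carry their provenance.

    Returns the long-format table and a summary dict with elimination
    fractions by provenance and by table half (top half = higher f).
    """
    if not pool_a or not pool_b:
        raise ValueError("assay pools must be nonempty")
    rng = np.random.default_rng(seed)
    rows = []
    for pair_id in range(n_pairs):
        ea = pool_a[rng.integers(len(pool_a))]
        eb = pool_b[rng.integers(len(pool_b))]
        ca, cb = ea.equilibrium.community, eb.equilibrium.community
        out = coalesce(ca, cb, env, costs)
        union = sorted(set(ca.support()) | set(cb.support()))
        order = sorted(union, key=lambda g: (-costs.f(g), g.code))
        survivors = set(out.result.survivors)
        for row_idx, g in enumerate(order, start=1):
            prov = out.provenance.get(g)
            rows.append(
                {
                    "pair_id": pair_id,
                    "genome_bits": g.bitstring,
                    "label": g.label,
                    "f": costs.f(g),
                    "f_rank_row": row_idx,
                    "n_rows": len(order),
                    "provenance": {"parent1": "a", "parent2": "b", "both": "both"}[prov]
                    if prov is not None
                    else "",
                    "survived": g in survivors,
                }
            )
    table = pd.DataFrame(rows)
    elim = table[~table["survived"]]
    n_elim = len(elim)
    summary = {
        "n_pairs": n_pairs,
        "n_eliminated": n_elim,
        "frac_from_a": float((elim["provenance"] == "a").mean()) if n_elim else 0.0,
        "frac_from_b": float((elim["provenance"] == "b").mean()) if n_elim else 0.0,
        "frac_from_both": float((elim["provenance"] == "both").mean()) if n_elim else 0.0,
        # top half of the f-ordered rows = intrinsically better species
        "frac_top_half": float(
            (elim["f_rank_row"] <= (elim["n_rows"] + 1) // 2).mean()
        )
        if n_elim
        else 0.0,
    }
    return table, summary
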