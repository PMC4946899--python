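"""CSV/JSON interchange for communities, cost tables and run metadata.

All on-disk formats are plain text.  Genomes travel as ``genome_bits``
strings with bit 0 (substrate A) first, e.g. ``"1101000000"`` for ABD in a
ten-substrate world, alongside the human-readable letter label.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .dynamics import CommunityState, Trajectory
from .equilibrium import EquilibriumResult
from .errors import CommunityValidationError
from .model_core import CostTable, Genome, performance_ranks

__all__ = [
    "RunConfig",
    "read_community",
    "write_community",
    "read_cost_table",
    "write_cost_table",
    "write_equilibrium",
    "write_trajectory",
    "substream",
]


def substream(seed: int | None, *path: int) -> np.random.SeedSequence:
    """Deterministic child seed stream for a given run seed and stream id.

    Experiments derive one substream per logical task (library build, assay
    sampling, trajectory inits, ...) so partial re-runs reproduce exactly.
    """
    return np.random.SeedSequence(entropy=seed, spawn_key=path)


@dataclass
class RunConfig:
    """Resolved parameters of a run, serializable next to its outputs."""

    n_substrates: int
    eps: float
    chi0: float = 1.0
    tau0: float = 1.0
    R_over_chi0: float = 100.0
    seed: int | None = 0
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

def write_community(state: CommunityState, path: str | Path) -> None:
    rows = [
        {"genome_bits": g.bitstring, "label": g.label, "abundance": n}
        for g, n in state.items()
    ]
    pd.DataFrame(rows, columns=["genome_bits", "label", "abundance"]).to_csv(
        path, index=False
    )


def read_community(path: str | Path, n_substrates: int | None = None) -> CommunityState:
    """Read a community CSV (``genome_bits,label,abundance``), validating rows."""
    df = pd.read_csv(path, dtype={"genome_bits": str})
    required = {"genome_bits", "abundance"}
    if not required.issubset(df.columns):
        raise CommunityValidationError(
            f"missing columns {sorted(required - set(df.columns))} in {path}"
        )
    members: dict[Genome, float] = {}
    width = None
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        bits = str(row.genome_bits)
        if set(bits) - {"0", "1"}:
            raise CommunityValidationError(
                f"row {row_no}: malformed genome_bits {bits!r}"
            )
        if width is None:
            width = len(bits)
        elif len(bits) != width:
            raise CommunityValidationError(
                f"row {row_no}: genome_bits length {len(bits)} != {width}"
            )
        n = float(row.abundance)
        if not np.isfinite(n) or n < 0:
            raise CommunityValidationError(
                f"row {row_no}: abundance must be finite and >= 0, got {row.abundance}"
            )
        members[Genome.from_bitstring(bits)] = n
    if n_substrates is None:
        n_substrates = width
    return CommunityState(members, n_substrates=n_substrates)


# ---------------------------------------------------------------------------
# cost tables
# ---------------------------------------------------------------------------

def write_cost_table(table: CostTable, path: str | Path) -> None:
    """Cost-table CSV: genome_bits, label, n_pathways, xi, chi, f, rank."""
    ranks = performance_ranks(table)
    rows = [
        {
            "genome_bits": g.bitstring,
            "label": g.label,
            "n_pathways": g.n_pathways,
            "xi": table.xi(g),
            "chi": table.chi(g),
            "f": table.f(g),
            "rank": ranks[g],
        }
        for g in table.genomes
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cost_table(
    path: str | Path, eps: float, chi0: float = 1.0
) -> CostTable:
    """Rebuild a CostTable from its CSV (exact costs; xi recomputed)."""
    df = pd.read_csv(path, dtype={"genome_bits": str})
    costs = {
        Genome.from_bitstring(str(r.genome_bits)): float(r.chi)
        for r in df.itertuples(index=False)
    }
    return CostTable.from_costs(costs, chi0=chi0, eps=eps)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_equilibrium(eq: EquilibriumResult, prefix: str | Path) -> None:
    """Community CSV + JSON sidecar (F, harvests, diagnostics)."""
    prefix = Path(prefix)
    write_community(eq.community, prefix.with_suffix(".csv"))
    meta = {
        "F": eq.F,
        "H": [None if not np.isfinite(h) else float(h) for h in eq.H],
        "converged": eq.converged,
        "diagnostics": {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in eq.diagnostics.items()
        },
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def write_trajectory(traj: Trajectory, prefix: str | Path) -> None:
    """Long-format abundances CSV plus a per-time F CSV."""
    prefix = Path(prefix)
    rows = []
    for t, state in zip(traj.times, traj.states):
        for g, n in state.items():
            rows.append({"time": t, "genome_bits": g.bitstring, "abundance": n})
    pd.DataFrame(rows).to_csv(f"{prefix}_abundance.csv", index=False)
    pd.DataFrame({"time": traj.times, "F": traj.F_values}).to_csv(
        f"{prefix}_F.csv", index=False
    )
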