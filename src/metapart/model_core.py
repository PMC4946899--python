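"""Species genomes, random maintenance costs, and intrinsic performance.

A species is identified with the set of metabolic pathways it carries,
encoded as a binary vector over the ``N`` substrate forms of a single
limiting resource.  Its maintenance cost is random,

    chi = chi0 * |sigma| * (1 + eps * xi),       xi ~ Normal(0, 1),

truncated so that chi > 0, with the draw made once per species and then
frozen.  The intrinsic (community-independent) performance is the inverse
cost per pathway,

    f = chi0 * |sigma| / chi - 1,

a dimensionless quantity of order ``eps``.  Under this cost model neither
specialists nor generalists are systematically favoured.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import SizeLimitError, UnpricedGenomeError

__all__ = [
    "Genome",
    "CostTable",
    "enumerate_genomes",
    "sample_cost_table",
    "performance_ranks",
]

#: Hard cap on substrate count for full-universe enumeration (2^20 - 1 genomes).
MAX_SUBSTRATES = 20

_LETTERS = string.ascii_uppercase


@dataclass(frozen=True, order=True)
class Genome:
    """A species, as the set of substrate pathways it carries.

    Canonical scalar encoding: ``code`` is the integer whose bit ``i``
    (0-based, least significant first) indicates the pathway for substrate
    ``i``; substrate 0 is labelled ``A``.  Ordering of genomes is by
    ``(n_substrates, code)``, i.e. ascending encoding within a universe.

    Parameters
    ----------
    n_substrates : int
        Number of substrate forms N in the world this genome lives in.
    code : int
        Canonical integer encoding, ``1 <= code <= 2**N - 1`` (at least
        one pathway must be carried).
    """

    n_substrates: int
    code: int

    def __post_init__(self):
        if self.n_substrates < 1:
            raise ValueError("n_substrates must be >= 1")
        if not (1 <= self.code < 2 ** self.n_substrates):
            raise ValueError(
                f"code {self.code} out of range for N={self.n_substrates} "
                "(genomes must carry at least one pathway)"
            )

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_bits(cls, bits: Sequence[int]) -> "Genome":
        """Build from a pathway presence vector (bit 0 = substrate A)."""
        code = sum(1 << i for i, b in enumerate(bits) if b)
        return cls(n_substrates=len(bits), code=code)

    @classmethod
    def from_bitstring(cls, s: str) -> "Genome":
        """Build from a string like ``"1101000000"`` (bit 0 first)."""
        if set(s) - {"0", "1"}:
            raise ValueError(f"invalid bitstring {s!r}")
        return cls.from_bits([int(c) for c in s])

    @classmethod
    def from_label(cls, label: str, n_substrates: int) -> "Genome":
        """Build from a substrate-letter label like ``"ABD"``."""
        code = 0
        for c in label:
            i = _LETTERS.index(c)
            if i >= n_substrates:
                raise ValueError(f"substrate {c!r} out of range for N={n_substrates}")
            code |= 1 << i
        return cls(n_substrates=n_substrates, code=code)

    # -- views ------------------------------------------------------------
    @property
    def bits(self) -> tuple[int, ...]:
        """Pathway presence vector, substrate 0 first."""
        return tuple((self.code >> i) & 1 for i in range(self.n_substrates))

    @property
    def bitstring(self) -> str:
        return "".join(str(b) for b in self.bits)

    @property
    def label(self) -> str:
        """Substrate letters of carried pathways, ascending (e.g. ``"ABD"``)."""
        return "".join(
            _LETTERS[i] for i in range(self.n_substrates) if (self.code >> i) & 1
        )

    @property
    def n_pathways(self) -> int:
        """|sigma|: the number of pathways carried."""
        return int(self.code).bit_count()

    def carries(self, substrate: int) -> bool:
        return bool((self.code >> substrate) & 1)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Genome({self.label!r}, N={self.n_substrates})"


def enumerate_genomes(n_substrates: int) -> list[Genome]:
    """All ``2**N - 1`` possible species, sorted by canonical encoding.

    Raises
    ------
    SizeLimitError
        If ``n_substrates`` is outside ``1..MAX_SUBSTRATES``.
    """
    if not (1 <= n_substrates <= MAX_SUBSTRATES):
        raise SizeLimitError(
            f"n_substrates must be in 1..{MAX_SUBSTRATES}, got {n_substrates}"
        )
    return [Genome(n_substrates, c) for c in range(1, 2 ** n_substrates)]


def sigma_matrix(genomes: Sequence[Genome], n_substrates: int | None = None) -> np.ndarray:
    """Pathway presence matrix, shape (n_genomes, N), dtype float."""
    if n_substrates is None:
        if not genomes:
            raise ValueError("need n_substrates for an empty genome list")
        n_substrates = genomes[0].n_substrates
    codes = np.asarray([g.code for g in genomes], dtype=np.int64)
    shifts = np.arange(n_substrates, dtype=np.int64)
    return ((codes[:, None] >> shifts[None, :]) & 1).astype(float)


@dataclass(frozen=True)
class CostTable:
    """Frozen per-species costs for one realization of the cost model.

    Entries are immutable once sampled: the normal draw ``xi`` is made once
    for each species.  ``f = chi0*|sigma|/chi - 1`` holds exactly for every
    entry.
    """

    n_substrates: int
    eps: float
    chi0: float
    seed: int | None
    _entries: Mapping[int, tuple[float, float]] = field(repr=False)
    # _entries: genome code -> (xi, chi)

    def __post_init__(self):
        if self.eps < 0:
            raise ValueError("eps must be >= 0")
        if self.chi0 <= 0:
            raise ValueError("chi0 must be > 0")

    # -- lookups ----------------------------------------------------------
    def _entry(self, genome: Genome) -> tuple[float, float]:
        try:
            return self._entries[genome.code]
        except KeyError:
            raise UnpricedGenomeError(
                f"genome {genome.label} (code {genome.code}) has no cost entry"
            ) from None

    def xi(self, genome: Genome) -> float:
        """The frozen standard-normal draw for this species."""
        return self._entry(genome)[0]

    def chi(self, genome: Genome) -> float:
        """Maintenance cost chi (resource units); always > 0."""
        return self._entry(genome)[1]

    def f(self, genome: Genome) -> float:
        """Intrinsic performance ``chi0*|sigma|/chi - 1`` (dimensionless)."""
        return self.chi0 * genome.n_pathways / self.chi(genome) - 1.0

    def chi_array(self, genomes: Sequence[Genome]) -> np.ndarray:
        return np.asarray([self.chi(g) for g in genomes])

    def f_array(self, genomes: Sequence[Genome]) -> np.ndarray:
        return np.asarray([self.f(g) for g in genomes])

    def __contains__(self, genome: Genome) -> bool:
        return genome.code in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def genomes(self) -> list[Genome]:
        """Priced genomes in canonical (ascending encoding) order."""
        return [Genome(self.n_substrates, c) for c in sorted(self._entries)]

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_costs(
        cls,
        costs: Mapping[Genome, float],
        chi0: float = 1.0,
        eps: float = 0.0,
    ) -> "CostTable":
        """Build a table from explicitly chosen costs (for worked examples).

        ``xi`` is back-computed from the cost model when ``eps > 0`` and set
        to NaN otherwise.
        """
        if not costs:
            raise ValueError("costs mapping is empty")
        n = next(iter(costs)).n_substrates
        entries: dict[int, tuple[float, float]] = {}
        for g, chi in costs.items():
            if g.n_substrates != n:
                raise ValueError("all genomes must share the same N")
            if chi <= 0:
                raise ValueError(f"cost for {g.label} must be > 0")
            xi = (chi / (chi0 * g.n_pathways) - 1.0) / eps if eps > 0 else float("nan")
            entries[g.code] = (xi, float(chi))
        return cls(n_substrates=n, eps=eps, chi0=chi0, seed=None, _entries=entries)


def sample_cost_table(
    n_substrates: int,
    eps: float,
    chi0: float = 1.0,
    seed: int | np.random.SeedSequence | None = 0,
    genomes: Iterable[Genome] | None = None,
) -> CostTable:
    """Sample one realization of the random cost model.

    One standard-normal ``xi`` per genome, redrawn (rejection) while the
    resulting cost would be non-positive; for ``eps <= 0.1`` rejections are
    practically nonexistent, so the bulk of the distribution is undistorted.
    Deterministic given ``seed``; covers ``genomes`` (default: the full
    universe of ``2**N - 1`` species) in canonical order.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    if chi0 <= 0:
        raise ValueError("chi0 must be > 0")
    if genomes is None:
        genome_list = enumerate_genomes(n_substrates)
    else:
        genome_list = sorted(set(genomes))
        for g in genome_list:
            if g.n_substrates != n_substrates:
                raise ValueError("genome N does not match table N")
    rng = np.random.default_rng(seed)
    xi = rng.standard_normal(len(genome_list))
    if eps > 0:
        bad = 1.0 + eps * xi <= 0.0
        while np.any(bad):  # rejection: keep chi strictly positive
            xi[bad] = rng.standard_normal(int(bad.sum()))
            bad = 1.0 + eps * xi <= 0.0
    entries = {
        g.code: (float(x), float(chi0 * g.n_pathways * (1.0 + eps * x)))
        for g, x in zip(genome_list, xi)
    }
    seed_int = seed if isinstance(seed, int) else None
    return CostTable(
        n_substrates=n_substrates, eps=eps, chi0=chi0, seed=seed_int, _entries=entries
    )


def performance_ranks(table: CostTable) -> dict[Genome, int]:
    """Rank genomes by intrinsic performance, 1 = highest ``f``.

    Ties (measure-zero for ``eps > 0``) are broken by ascending canonical
    encoding, so the ranking is a deterministic bijection onto
    ``1..len(table)``.
    """
    if len(table) == 0:
        raise ValueError("cost table is empty")
    genomes = table.genomes
    f = table.f_array(genomes)
    order = sorted(range(len(genomes)), key=lambda i: (-f[i], genomes[i].code))
    return {genomes[i]: rank for rank, i in enumerate(order, start=1)}
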