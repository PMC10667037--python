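"""Migration graphs for deme-structured serial-dilution populations.

A migration graph on ``D`` demes is a ``D x D`` matrix ``m`` of migration
probabilities.  Under the default *incoming-normalized* convention,
``m[i, j]`` is the probability that an individual sampled into deme ``j``'s
next bottleneck originates from deme ``i`` (the diagonal entry is the
self/retention term), and every column sums to 1, so every deme has the
same average bottleneck size ``K``.  The *outgoing-normalized* variant
instead makes every row sum to 1, so every deme contributes the same
average number of individuals to the next bottleneck of the population.

A *circulation* is a graph in which, for every deme, the total incoming
migration probability equals the total outgoing one.  Circulations play a
special role: they leave mutant fixation probabilities unchanged relative
to a well-mixed population of the same total size, while every other graph
strictly suppresses selection in the frequent-migration regime (see
:mod:`demefix.branching`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "INCOMING",
    "OUTGOING",
    "MigrationGraph",
    "StarSpec",
    "DirichletCliqueSpec",
    "Violation",
    "make_clique",
    "make_star",
    "make_dirichlet_clique",
    "make_random_circulation",
    "is_circulation",
    "validate",
    "ensure_valid",
]

INCOMING = "incoming_normalized"
OUTGOING = "outgoing_normalized"

#: tolerance on column/row normalization checks
_NORM_TOL = 1e-9


@dataclass(frozen=True)
class MigrationGraph:
    """A migration-probability matrix with its normalization convention.

    Parameters
    ----------
    m
        ``(D, D)`` array; ``m[i, j]`` is the probability that an individual
        forming deme ``j``'s next bottleneck originates from deme ``i``.
    convention
        ``"incoming_normalized"`` (columns sum to 1, default) or
        ``"outgoing_normalized"`` (rows sum to 1).
    """

    m: np.ndarray
    convention: str = INCOMING

    def __post_init__(self) -> None:
        m = np.array(self.m, dtype=float, copy=True)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"migration matrix must be square, got shape {m.shape}")
        if self.convention not in (INCOMING, OUTGOING):
            raise ValueError(f"unknown convention {self.convention!r}")
        m.setflags(write=False)
        object.__setattr__(self, "m", m)

    @property
    def D(self) -> int:
        """Number of demes."""
        return self.m.shape[0]

    @property
    def column_sums(self) -> np.ndarray:
        return self.m.sum(axis=0)

    @property
    def row_sums(self) -> np.ndarray:
        return self.m.sum(axis=1)

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> None:
        """Write the matrix as headerless CSV (one row per origin deme)."""
        np.savetxt(path, self.m, delimiter=",", fmt="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, convention: str = INCOMING) -> "MigrationGraph":
        m = np.loadtxt(path, delimiter=",", ndmin=2)
        return cls(m=m, convention=convention)

    def to_json(self, path: str | Path) -> None:
        payload = {"D": self.D, "convention": self.convention, "m": self.m.tolist()}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MigrationGraph":
        payload = json.loads(Path(path).read_text())
        return cls(m=np.asarray(payload["m"], dtype=float), convention=payload["convention"])


@dataclass(frozen=True)
class StarSpec:
    """Star graph: one center deme exchanging with ``D - 1`` leaves.

    ``mO`` is the outgoing migration probability from the center to each
    leaf; the incoming probability from a leaf to the center is
    ``mI = alpha * mO``.  ``alpha`` is the incoming/outgoing asymmetry
    ``mI / mO``; the star is a circulation iff ``alpha == 1``.
    """

    D: int
    mO: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.D < 2:
            raise ValueError("star needs D >= 2")
        if not 0 < self.mO <= 1:
            raise ValueError("mO must be in (0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def mI(self) -> float:
        return self.alpha * self.mO


@dataclass(frozen=True)
class DirichletCliqueSpec:
    """Random all-to-all graph with Dirichlet-distributed incoming flows.

    For each destination deme the vector of incoming migration
    probabilities (including retention) is one draw from a Dirichlet
    distribution, so columns sum to 1 exactly.  With a single concentration
    ``eta`` all origins are exchangeable: every entry has mean ``1/D`` and a
    variance that shrinks as ``eta`` grows (``eta -> inf`` recovers the
    uniform clique).  With the pair ``(eta0, 1)`` one *advantaged* deme has
    concentration ``eta0 >= 1`` in every column's draw, so its outgoing
    migration probabilities are larger on average.
    """

    D: int
    eta: float | tuple[float, float] = 1.0
    seed: int | None = None
    advantaged_deme: int = 0

    def __post_init__(self) -> None:
        if self.D < 2:
            raise ValueError("Dirichlet clique needs D >= 2")
        conc = self.concentrations()
        if np.any(conc <= 0):
            raise ValueError("Dirichlet concentration parameters must be positive")

    def concentrations(self) -> np.ndarray:
        """Length-D vector of per-origin Dirichlet concentration parameters."""
        if isinstance(self.eta, tuple):
            eta0, eta_rest = self.eta
            conc = np.full(self.D, float(eta_rest))
            conc[self.advantaged_deme] = float(eta0)
            return conc
        return np.full(self.D, float(self.eta))


@dataclass(frozen=True)
class Violation:
    """One structural problem found by :func:`validate`."""

    kind: str
    message: str


def make_clique(D: int, m: float) -> MigrationGraph:
    """Uniform all-to-all graph (Wright's island model).

    All off-diagonal migration probabilities equal ``m`` and the retention
    term is ``1 - (D - 1) m``, so both rows and columns sum to 1: the clique
    is a circulation for every valid ``(D, m)``.
    """
    if D < 2:
        raise ValueError("clique needs D >= 2")
    if not 0 < m <= 1:
        raise ValueError("m must be in (0, 1]")
    if (D - 1) * m > 1:
        raise ValueError(
            f"(D-1)*m = {(D - 1) * m:g} > 1: the retention term 1-(D-1)m would be negative"
        )
    mat = np.full((D, D), m)
    np.fill_diagonal(mat, 1.0 - (D - 1) * m)
    return MigrationGraph(m=mat)


def make_star(spec: StarSpec) -> MigrationGraph:
    """Star graph with center at index 0 and leaves at 1..D-1.

    Column normalization fixes the diagonal: each leaf retains ``1 - mO``
    and the center retains ``1 - (D - 1) * alpha * mO``, which constrains
    ``(D - 1) * alpha * mO <= 1`` (for alpha > 1 the admissible range of
    ``mO`` shrinks accordingly).
    """
    D, mO, mI = spec.D, spec.mO, spec.mI
    if mI > 1:
        raise ValueError(f"mI = alpha*mO = {mI:g} > 1 is not a probability")
    if (D - 1) * mI > 1:
        raise ValueError(
            f"(D-1)*alpha*mO = {(D - 1) * mI:g} > 1: the center column cannot "
            "normalize (its retention term 1-(D-1)*alpha*mO would be negative)"
        )
    mat = np.zeros((D, D))
    leaves = np.arange(1, D)
    mat[0, leaves] = mO          # center -> leaf
    mat[leaves, 0] = mI          # leaf -> center
    mat[leaves, leaves] = 1.0 - mO
    mat[0, 0] = 1.0 - (D - 1) * mI
    return MigrationGraph(m=mat)


def make_dirichlet_clique(spec: DirichletCliqueSpec) -> MigrationGraph:
    """Sample a Dirichlet clique (one Dirichlet draw per destination column)."""
    rng = np.random.default_rng(spec.seed)
    conc = spec.concentrations()
    # one draw per destination deme j; row order = origin demes
    cols = rng.dirichlet(conc, size=spec.D).T
    return MigrationGraph(m=cols)


def make_random_circulation(
    D: int, seed: int | None = None, n_permutations: int = 6
) -> MigrationGraph:
    """Random doubly stochastic graph (hence a circulation).

    Built as a Dirichlet-weighted mixture of random permutation matrices
    plus the identity (Birkhoff representation), which is exactly doubly
    stochastic.  Resamples until the off-diagonal support is connected.
    """
    rng = np.random.default_rng(seed)
    for _ in range(100):
        mats = [np.eye(D)]
        for _ in range(n_permutations):
            perm = rng.permutation(D)
            p = np.zeros((D, D))
            p[perm, np.arange(D)] = 1.0
            mats.append(p)
        w = rng.dirichlet(np.ones(len(mats)))
        m = sum(wi * pi for wi, pi in zip(w, mats))
        g = MigrationGraph(m=m)
        if _is_connected(g):
            return g
    raise RuntimeError("failed to sample a connected doubly stochastic matrix")


def is_circulation(g: MigrationGraph, tol: float = 1e-9) -> bool:
    """True iff each deme's total incoming flow equals its total outgoing flow.

    With the incoming-normalized convention this reduces to every row also
    summing to 1, i.e. the matrix being doubly stochastic.
    """
    return bool(np.max(np.abs(g.row_sums - g.column_sums)) <= tol)


def _is_connected(g: MigrationGraph) -> bool:
    off = np.array(g.m, copy=True)
    np.fill_diagonal(off, 0.0)
    support = csr_matrix(off > 0)
    n, _ = connected_components(support, directed=False)
    return n == 1


def validate(g: MigrationGraph) -> list[Violation]:
    """Structural report: entry bounds, normalization, connectivity.

    Returns an empty list for a valid graph; computations that require
    validity call :func:`ensure_valid`, which raises on the first report.
    """
    out: list[Violation] = []
    m = g.m
    if np.any(m < 0) or np.any(m > 1):
        out.append(Violation("bounds", "entries outside [0, 1]"))
    sums = g.column_sums if g.convention == INCOMING else g.row_sums
    axis = "column" if g.convention == INCOMING else "row"
    bad = np.abs(sums - 1.0) > _NORM_TOL
    if np.any(bad):
        idx = np.nonzero(bad)[0]
        out.append(
            Violation(
                "normalization",
                f"{axis} sums differ from 1 at demes {idx.tolist()} "
                f"(sums {sums[idx].round(12).tolist()})",
            )
        )
    if not _is_connected(g):
        out.append(Violation("connectivity", "off-diagonal support graph is disconnected"))
    return out


def ensure_valid(g: MigrationGraph) -> None:
    problems = validate(g)
    if problems:
        raise ValueError(
            "invalid migration graph: " + "; ".join(v.message for v in problems)
        )
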