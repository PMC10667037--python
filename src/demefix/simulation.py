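"""Stochastic simulation of growth + dilution-migration cycles.

One cycle of the serial-dilution model has two phases.  Each deme first
grows deterministically for a time ``t``: wild-types divide at rate 1 and
mutants at rate ``1 + s``, so a deme with bottleneck mutant fraction
``x_i`` reaches size ``N'_i = M_i e^{(1+s)t} + W_i e^t`` with mutant
fraction ``x'_i = x_i e^{st} / (1 + x_i (e^{st} - 1))``.  Then a
dilution-migration step samples the next bottleneck of every deme from the
grown demes, transferring on average ``K m_ij`` individuals from deme
``i`` to deme ``j``.  Cycles repeat until mutants fix or go extinct.

Three sampling variants of the dilution step are provided:

``independent_binomial`` (default)
    For every ordered pair ``(i, j)`` the numbers of mutant and wild-type
    migrants are two independent binomial draws with ``N'_i`` trials and
    success probabilities ``K m_ij x'_i / N'_i`` and
    ``K m_ij (1 - x'_i) / N'_i``.  Bottleneck sizes fluctuate around ``K``.

``multinomial_fixed``
    Deme ``j``'s next bottleneck has exactly ``K`` individuals, drawn from
    a multinomial over (origin, type) categories with probabilities
    proportional to ``m_ij x'_i`` and ``m_ij (1 - x'_i)``.  Useful at small
    ``K`` where bottleneck fluctuations could empty demes.

``deterministic_migration_binomial``
    Offspring migrate deterministically and each deme then draws
    ``M_j ~ Binomial(K, sum_i m_ij x'_i)``; with a single deme this is
    exactly the Wright-Fisher map, one bottleneck per generation.

Selection is *soft*: each deme's expected contribution to the next
bottleneck is set by the migration matrix alone, not by its mean fitness.

Monte-Carlo replicates are simulated in vectorized blocks of fixed size;
each block draws from its own RNG substream keyed by ``(seed, block)``, so
estimates are reproducible bit-for-bit and independent of how blocks are
scheduled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .graphs import INCOMING, MigrationGraph, ensure_valid

__all__ = [
    "VARIANTS",
    "ModelParams",
    "PopulationState",
    "GrownState",
    "ReplicateOutcome",
    "FixationEstimate",
    "growth_step",
    "dilution_migration_step",
    "run_replicate",
    "estimate_fixation",
    "initial_state",
]

INDEPENDENT_BINOMIAL = "independent_binomial"
MULTINOMIAL_FIXED = "multinomial_fixed"
DETERMINISTIC_MIGRATION_BINOMIAL = "deterministic_migration_binomial"
VARIANTS = (
    INDEPENDENT_BINOMIAL,
    MULTINOMIAL_FIXED,
    DETERMINISTIC_MIGRATION_BINOMIAL,
)

EXTINCT, FIXED, CENSORED = 0, 1, 2
_OUTCOME_NAMES = {EXTINCT: "extinct", FIXED: "fixed", CENSORED: "censored"}

#: replicates per vectorized block; fixed so that estimates do not depend on
#: how replicates are chunked across workers
_BLOCK = 1 << 15


@dataclass(frozen=True)
class ModelParams:
    """Parameters of one growth/dilution cycle.

    ``K`` is the average bottleneck size per deme, ``s`` the mutant
    selection coefficient (division rate ``1 + s`` vs 1), ``t`` the growth
    duration.  The product ``st`` is the effective per-cycle fitness
    advantage and is the only combination entering the mutant-fraction map.
    """

    K: int
    s: float
    t: float
    variant: str = INDEPENDENT_BINOMIAL

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be a positive integer")
        if self.s <= -1:
            raise ValueError("s must be > -1 (growth rate 1+s must be positive)")
        if self.t <= 0:
            raise ValueError("t must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")

    @property
    def st(self) -> float:
        return self.s * self.t


@dataclass
class PopulationState:
    """Mutant and wild-type counts per deme at a bottleneck."""

    M: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.int64)
        self.W = np.asarray(self.W, dtype=np.int64)
        if self.M.shape != self.W.shape or self.M.ndim != 1:
            raise ValueError("M and W must be 1-D arrays of equal length")
        if np.any(self.M < 0) or np.any(self.W < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def D(self) -> int:
        return self.M.shape[0]

    @property
    def is_extinct(self) -> bool:
        return bool(self.M.sum() == 0)

    @property
    def is_fixed(self) -> bool:
        return bool(self.W.sum() == 0) and not self.is_extinct

    @property
    def is_absorbing(self) -> bool:
        return bool(self.M.sum() == 0 or self.W.sum() == 0)

    @property
    def global_mutant_fraction(self) -> float:
        tot = self.M.sum() + self.W.sum()
        return float(self.M.sum() / tot) if tot > 0 else 0.0


@dataclass
class GrownState:
    """Post-growth deme sizes and mutant fractions (pre-dilution)."""

    Nprime: np.ndarray
    xprime: np.ndarray


@dataclass
class ReplicateOutcome:
    outcome: str  # "fixed" | "extinct" | "censored"
    n_cycles: int
    trajectory: np.ndarray | None = None  # global mutant fraction per bottleneck


@dataclass
class FixationEstimate:
    """Monte-Carlo fixation estimate with conditional absorption times.

    ``p_fix`` is the fraction of absorbed (non-censored) replicates that
    fixed; ``se`` its binomial standard error.  Times are in dilution
    steps, conditioned on the corresponding outcome; censored replicates
    are excluded from both the probability and the time averages.
    """

    p_fix: float
    se: float
    mean_time_fix: float
    mean_time_ext: float
    n_reps: int
    n_censored: int
    seed: int

    @property
    def n_absorbed(self) -> int:
        return self.n_reps - self.n_censored


# --------------------------------------------------------------------------
# batched kernels (replicates along axis 0)
# --------------------------------------------------------------------------

def _grow(M: np.ndarray, W: np.ndarray, params: ModelParams):
    est = math.exp(params.st)
    Np = M * math.exp((1.0 + params.s) * params.t) + W * math.exp(params.t)
    num = M * est
    den = num + W
    with np.errstate(invalid="ignore", divide="ignore"):
        xp = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return Np, xp


def _dilute(Np, xp, m, params: ModelParams, rng: np.random.Generator):
    R, D = Np.shape
    K = params.K
    if params.variant == INDEPENDENT_BINOMIAL:
        Mn = np.zeros((R, D), dtype=np.int64)
        Wn = np.zeros((R, D), dtype=np.int64)
        trials = np.rint(Np).astype(np.int64)
        for i in range(D):
            cols = np.nonzero(m[i])[0]
            if cols.size == 0:
                continue
            Ni = Np[:, i]
            occupied = Ni > 0
            safe = np.where(occupied, Ni, 1.0)
            base = (K * m[i, cols])[None, :] / safe[:, None]  # (R, c)
            if np.any(base[occupied] > 1.0 + 1e-12):
                raise ValueError(
                    "binomial success probability K*m_ij*x'_i/N'_i exceeds 1; "
                    "the growth phase is too short for this K and m_ij "
                    "(increase t or reduce K*m_ij)"
                )
            base = np.where(occupied[:, None], base, 0.0)
            n = np.broadcast_to(trials[:, i][:, None], base.shape)
            Mn[:, cols] += rng.binomial(n, np.minimum(base * xp[:, i][:, None], 1.0))
            Wn[:, cols] += rng.binomial(n, np.minimum(base * (1.0 - xp[:, i][:, None]), 1.0))
        return Mn, Wn

    if params.variant == MULTINOMIAL_FIXED:
        Mn = np.zeros((R, D), dtype=np.int64)
        Wn = np.zeros((R, D), dtype=np.int64)
        occupied = Np > 0
        for j in range(D):
            rows = np.nonzero(m[:, j])[0]
            r = rows.size
            wm = m[rows, j][None, :] * xp[:, rows]
            ww = m[rows, j][None, :] * (1.0 - xp[:, rows])
            wm = np.where(occupied[:, rows], wm, 0.0)
            ww = np.where(occupied[:, rows], ww, 0.0)
            pv = np.concatenate([wm, ww], axis=1)
            tot = pv.sum(axis=1)
            fed = tot > 0
            if np.any(fed):
                pv[fed] /= tot[fed, None]
                draws = rng.multinomial(K, pv[fed])
                Mn[fed, j] = draws[:, :r].sum(axis=1)
                Wn[fed, j] = draws[:, r:].sum(axis=1)
        return Mn, Wn

    # deterministic migration of offspring, then one binomial per deme
    pmut = np.clip(xp @ m, 0.0, 1.0)
    Mn = rng.binomial(params.K, pmut)
    Wn = params.K - Mn
    return Mn.astype(np.int64), Wn.astype(np.int64)


def _simulate_block(m, params: ModelParams, M, W, rng, max_cycles: int):
    """Run a block of replicates to absorption; returns (outcome, n_cycles)."""
    R = M.shape[0]
    outcome = np.full(R, CENSORED, dtype=np.int8)
    ncyc = np.full(R, max_cycles, dtype=np.int64)
    idx = np.arange(R)

    ext0 = M.sum(axis=1) == 0
    fix0 = (W.sum(axis=1) == 0) & ~ext0
    done = ext0 | fix0
    outcome[idx[ext0]] = EXTINCT
    outcome[idx[fix0]] = FIXED
    ncyc[idx[done]] = 0
    keep = ~done
    idx, M, W = idx[keep], M[keep], W[keep]

    for cycle in range(1, max_cycles + 1):
        if idx.size == 0:
            break
        Np, xp = _grow(M, W, params)
        M, W = _dilute(Np, xp, m, params, rng)
        ext = M.sum(axis=1) == 0
        fix = (W.sum(axis=1) == 0) & ~ext
        done = ext | fix
        if np.any(done):
            outcome[idx[ext]] = EXTINCT
            outcome[idx[fix]] = FIXED
            ncyc[idx[done]] = cycle
            keep = ~done
            idx, M, W = idx[keep], M[keep], W[keep]
    return outcome, ncyc


# --------------------------------------------------------------------------
# public single-state operations
# --------------------------------------------------------------------------

def growth_step(state: PopulationState, params: ModelParams) -> GrownState:
    """Deterministic exponential growth of every deme for time ``t``.

    Empty demes stay empty (``N' = 0``, ``x'`` defined as 0).
    """
    Np, xp = _grow(state.M[None, :].astype(float), state.W[None, :].astype(float), params)
    return GrownState(Nprime=Np[0], xprime=xp[0])


def dilution_migration_step(
    grown: GrownState,
    g: MigrationGraph,
    params: ModelParams,
    rng: np.random.Generator,
) -> PopulationState:
    """Sample the next bottleneck of every deme from the grown demes."""
    Mn, Wn = _dilute(
        np.asarray(grown.Nprime, dtype=float)[None, :],
        np.asarray(grown.xprime, dtype=float)[None, :],
        g.m,
        params,
        rng,
    )
    return PopulationState(M=Mn[0], W=Wn[0])


def run_replicate(
    g: MigrationGraph,
    params: ModelParams,
    init: PopulationState,
    rng: np.random.Generator,
    max_cycles: int = 1_000_000,
    record_trajectory: bool = False,
) -> ReplicateOutcome:
    """Alternate growth and dilution-migration until fixation or extinction."""
    ensure_valid(g)
    state = PopulationState(M=init.M.copy(), W=init.W.copy())
    traj = [state.global_mutant_fraction] if record_trajectory else None
    if state.is_absorbing:
        name = "fixed" if state.is_fixed else "extinct"
        return ReplicateOutcome(outcome=name, n_cycles=0,
                                trajectory=np.array(traj) if traj else None)
    for cycle in range(1, max_cycles + 1):
        grown = growth_step(state, params)
        state = dilution_migration_step(grown, g, params, rng)
        if traj is not None:
            traj.append(state.global_mutant_fraction)
        if state.is_absorbing:
            name = "fixed" if state.is_fixed else "extinct"
            return ReplicateOutcome(outcome=name, n_cycles=cycle,
                                    trajectory=np.array(traj) if traj is not None else None)
    return ReplicateOutcome(outcome="censored", n_cycles=max_cycles,
                            trajectory=np.array(traj) if traj is not None else None)


def initial_state(D: int, K: int, kind, deme: int | None = None) -> PopulationState:
    """Build a deterministic initial bottleneck.

    ``kind`` is ``"deme"`` (one mutant in ``deme``) or ``"full_deme"``
    (deme ``deme`` entirely mutant); the uniformly random placement is
    handled inside :func:`estimate_fixation`.
    """
    M = np.zeros(D, dtype=np.int64)
    W = np.full(D, K, dtype=np.int64)
    if kind == "deme":
        M[deme], W[deme] = 1, K - 1
    elif kind == "full_deme":
        M[deme], W[deme] = K, 0
    else:
        raise ValueError(f"unknown init kind {kind!r}")
    return PopulationState(M=M, W=W)


def _parse_init(init_spec) -> tuple[str, int | None]:
    if isinstance(init_spec, tuple):
        return init_spec
    s = str(init_spec)
    if s == "uniform" or s == "single_mutant_uniform":
        return ("uniform", None)
    for prefix, kind in (("deme:", "deme"), ("full-deme:", "full_deme"),
                         ("full_deme:", "full_deme")):
        if s.startswith(prefix):
            return (kind, int(s.split(":", 1)[1]))
    raise ValueError(f"unknown init spec {init_spec!r}")


def estimate_fixation(
    g: MigrationGraph,
    params: ModelParams,
    init_spec="uniform",
    n_reps: int = 10_000,
    seed: int = 0,
    max_cycles: int = 1_000_000,
) -> FixationEstimate:
    """Monte-Carlo fixation probability with conditional absorption times.

    ``init_spec`` is ``"uniform"`` (one mutant placed uniformly at random
    per replicate, i.e. that deme starts at ``(M=1, W=K-1)`` and every
    other at ``(0, K)``), ``"deme:i"`` or ``"full-deme:i"``.
    Replicates run in fixed-size blocks with substreams keyed by
    ``(seed, block)``, so results are bit-reproducible.
    """
    ensure_valid(g)
    if g.convention != INCOMING:
        raise ValueError("simulation requires the incoming-normalized convention")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    kind, deme = _parse_init(init_spec)
    D, K = g.D, params.K

    n_ext = n_fix = n_cens = 0
    t_ext = t_fix = 0.0
    for block in range(0, (n_reps + _BLOCK - 1) // _BLOCK):
        nb = min(_BLOCK, n_reps - block * _BLOCK)
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(block,)))
        M = np.zeros((nb, D), dtype=np.int64)
        W = np.full((nb, D), K, dtype=np.int64)
        if kind == "uniform":
            start = rng.integers(0, D, size=nb)
            M[np.arange(nb), start] = 1
            W[np.arange(nb), start] = K - 1
        elif kind == "deme":
            M[:, deme], W[:, deme] = 1, K - 1
        else:  # full_deme
            M[:, deme], W[:, deme] = K, 0
        outcome, ncyc = _simulate_block(g.m, params, M, W, rng, max_cycles)
        n_ext += int(np.sum(outcome == EXTINCT))
        n_fix += int(np.sum(outcome == FIXED))
        n_cens += int(np.sum(outcome == CENSORED))
        t_ext += float(ncyc[outcome == EXTINCT].sum())
        t_fix += float(ncyc[outcome == FIXED].sum())

    n_abs = n_ext + n_fix
    p = n_fix / n_abs if n_abs else float("nan")
    se = math.sqrt(p * (1.0 - p) / n_abs) if n_abs else float("nan")
    return FixationEstimate(
        p_fix=p,
        se=se,
        mean_time_fix=t_fix / n_fix if n_fix else float("nan"),
        mean_time_ext=t_ext / n_ext if n_ext else float("nan"),
        n_reps=n_reps,
        n_censored=n_cens,
        seed=seed,
    )
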