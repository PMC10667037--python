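"""Coarse-grained analytics for the rare-migration regime.

When migrations are much slower than within-deme selective sweeps, every
deme is effectively either fully mutant or fully wild-type between
migration events, and the metapopulation reduces to an absorbing Markov
chain on these coarse configurations — the same state space as
evolutionary graph theory with one individual per node.  A single mutant
must first fix within its own deme (probability given by the haploid
diffusion approximation with per-cycle selection ``st`` and population
size ``K``); the overall fixation probability is the product of that
within-deme probability and the absorption probability of the deme-level
chain started from one fully mutant deme.

Per cycle, a fully mutant deme ``i`` sends on average ``K m_ij`` mutants
into deme ``j``'s bottleneck, each founding a lineage that sweeps deme
``j`` with the within-deme fixation probability; wild-type back-invasions
of mutant demes work symmetrically with selection ``-st``.  Cycle length
cancels in the embedded jump chain, so absorption probabilities depend
only on flip-weight ratios.

In this regime the star with asymmetry ``alpha = mI/mO > 1`` can *amplify*
natural selection — exceed the fixation probability of a well-mixed
population with ``K*D`` individuals — but only for effective advantages
``st`` of order ``1/K``; for ``st >> 1/K`` the two converge.  With
``alpha = D - 1`` the coarse chain coincides with the star of evolutionary
graph theory under the Birth-death update rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import spsolve

from .graphs import MigrationGraph, ensure_valid
from .simulation import ModelParams

__all__ = [
    "RareRegimeCheck",
    "deme_fixation_prob",
    "wellmixed_fixation_prob",
    "coarse_chain_fixation",
    "star_rare_fixation",
    "rare_regime_check",
]


@dataclass
class RareRegimeCheck:
    """Is the coarse-grained (deme-by-deme) description applicable?

    ``ratio`` is the expected number of *successful* migrant lineages
    arriving in the most-exposed deme during one within-deme sweep:
    (migrants per cycle) x (lineage success probability) x (sweep length
    in cycles).  The coarse description needs ``ratio`` well below 1.
    """

    in_regime: bool
    ratio: float
    threshold: float


def deme_fixation_prob(st: float, K: int, beneficial: bool = True) -> float:
    """Fixation probability of one invader in an isolated deme.

    Haploid diffusion approximation for a Wright-Fisher-like deme of
    bottleneck size ``K`` with per-cycle selection ``st``:
    ``(1 - e^{-2 st}) / (1 - e^{-2 K st})``.  ``beneficial=False`` gives
    the wild-type-into-mutant-deme case (selection ``-st``).  The neutral
    limit is ``1/K``; for ``K st >> 1`` the value approaches ``2 st``, the
    classic well-mixed result for a weakly beneficial mutant.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    s_eff = st if beneficial else -st
    if abs(s_eff) < 1e-12:
        return 1.0 / K
    return -math.expm1(-2.0 * s_eff) / -math.expm1(-2.0 * K * s_eff)


def wellmixed_fixation_prob(st: float, N: int) -> float:
    """Diffusion fixation probability of one mutant in a well-mixed
    population of ``N`` individuals (``N = K*D`` for the structured
    comparison)."""
    return deme_fixation_prob(st, N, beneficial=True)


def rare_regime_check(
    g: MigrationGraph, params: ModelParams, threshold: float = 0.5
) -> RareRegimeCheck:
    """Expected successful migrant lineages per within-deme sweep.

    The sweep length of a beneficial mutant is estimated as
    ``ln(K)/st`` cycles (``K`` cycles at neutrality); a migrant lineage
    succeeds with the within-deme fixation probability.  Disconnected or
    migration-free graphs give ratio 0 (degenerate, flagged elsewhere by
    graph validation).
    """
    off = np.array(g.m, copy=True)
    np.fill_diagonal(off, 0.0)
    inflow = off.sum(axis=0).max()  # worst-case migrants per deme per cycle / K
    st, K = params.st, params.K
    sweep = math.log(K) / st if st > 0 else float(K)
    ratio = K * inflow * deme_fixation_prob(st, K) * sweep
    return RareRegimeCheck(in_regime=ratio < threshold, ratio=ratio, threshold=threshold)


def _chain_absorption(Q_rows, n_states, full_index, transient):
    """Solve h = P(absorb all-mutant) for the embedded jump chain."""
    index = {s: k for k, s in enumerate(transient)}
    A = lil_matrix((len(transient), len(transient)))
    b = np.zeros(len(transient))
    for s in transient:
        k = index[s]
        A[k, k] = 1.0
        for s2, prob in Q_rows[s]:
            if s2 == full_index:
                b[k] += prob
            elif s2 in index:
                A[k, index[s2]] -= prob
    h = spsolve(A.tocsr(), b)
    return index, np.atleast_1d(h)


def coarse_chain_fixation(
    g: MigrationGraph, params: ModelParams, start_deme: int = 0
) -> float:
    """Fixation probability of a single mutant via the coarse-grained chain.

    Builds the absorbing chain on subsets of fully mutant demes, with flip
    weights ``sum_{i in S} m_ij * rho_+`` (wild-type deme ``j`` turns
    mutant) and ``sum_{i not in S} m_ij * rho_-`` (mutant deme ``j``
    reverts), and returns ``rho_+ x P(absorb all-mutant | start {deme})``.
    Generic subsets scale as ``2^D``; graphs with ``D > 20`` are rejected
    (use the symmetry-reduced star solver for large stars).
    """
    ensure_valid(g)
    D = g.D
    if D > 20:
        raise ValueError("generic coarse chain limited to D <= 20 (2^D states); "
                         "use a symmetry-reduced solver")
    check = rare_regime_check(g, params)
    if not check.in_regime:
        import warnings

        warnings.warn(
            f"rare-migration ratio {check.ratio:.3g} >= {check.threshold}: the "
            "coarse-grained description may not hold",
            stacklevel=2,
        )
    st, K = params.st, params.K
    rho_p = deme_fixation_prob(st, K, beneficial=True)
    rho_m = deme_fixation_prob(st, K, beneficial=False)
    m = g.m
    full = (1 << D) - 1
    Q_rows: dict[int, list[tuple[int, float]]] = {}
    transient = []
    for S in range(1, full):
        members = [i for i in range(D) if S >> i & 1]
        weights = []
        for j in range(D):
            if S >> j & 1:
                w = sum(m[i, j] for i in range(D) if not S >> i & 1) * rho_m
                weights.append((S & ~(1 << j), w))
            else:
                w = sum(m[i, j] for i in members) * rho_p
                weights.append((S | (1 << j), w))
        tot = sum(w for _, w in weights)
        if tot <= 0:
            raise ValueError(f"coarse state {S:b} has no outgoing flips (disconnected graph?)")
        Q_rows[S] = [(s2, w / tot) for s2, w in weights if w > 0]
        transient.append(S)
    index, h = _chain_absorption(Q_rows, full + 1, full, transient)
    return rho_p * float(h[index[1 << start_deme]])


def star_rare_fixation(
    D: int, K: int, st: float, alpha: float, start: str = "uniform"
) -> float:
    """Rare-migration fixation probability of a single mutant in a star.

    Uses the symmetry-reduced chain on states ``(center type, number of
    mutant leaves)`` — ``2 D`` states instead of ``2^D`` — solved exactly;
    it agrees with :func:`coarse_chain_fixation` on the star to machine
    precision.  ``start`` is ``"center"``, ``"leaf"`` or ``"uniform"``
    (the average ``[center + (D-1) leaf] / D``).  The outgoing migration
    probability ``mO`` cancels from the embedded chain.
    """
    if D < 2:
        raise ValueError("star needs D >= 2")
    if start not in ("center", "leaf", "uniform"):
        raise ValueError(f"unknown start {start!r}")
    rho_p = deme_fixation_prob(st, K, beneficial=True)
    rho_m = deme_fixation_prob(st, K, beneficial=False)
    L = D - 1

    def sid(c: int, k: int) -> int:
        return c * D + k  # k = number of mutant leaves, 0..L

    n_states = 2 * D
    ext, full = sid(0, 0), sid(1, L)
    Q_rows: dict[int, list[tuple[int, float]]] = {}
    transient = []
    for c in (0, 1):
        for k in range(L + 1):
            s = sid(c, k)
            if s in (ext, full):
                continue
            weights = []
            if c == 1:
                if k < L:
                    weights.append((sid(1, k + 1), (L - k) * rho_p))        # leaf gains
                    weights.append((sid(0, k), (L - k) * alpha * rho_m))    # center reverts
            else:
                if k > 0:
                    weights.append((sid(1, k), k * alpha * rho_p))          # center gains
                    weights.append((sid(0, k - 1), k * rho_m))              # leaf reverts
            tot = sum(w for _, w in weights)
            Q_rows[s] = [(s2, w / tot) for s2, w in weights if w > 0]
            transient.append(s)
    index, h = _chain_absorption(Q_rows, n_states, full, transient)
    h_center = float(h[index[sid(1, 0)]])
    h_leaf = float(h[index[sid(0, 1)]])
    if start == "center":
        chain = h_center
    elif start == "leaf":
        chain = h_leaf
    else:
        chain = (h_center + L * h_leaf) / D
    return rho_p * chain
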