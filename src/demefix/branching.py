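"""Multitype branching-process predictions for mutant fixation.

In the regime ``K >> 1``, ``K*st >> 1``, ``st << 1`` the descendants of a
single mutant lineage are independent, and the number of descendants a
mutant in deme ``i`` leaves in deme ``j`` at the next bottleneck is well
approximated by a Poisson draw with mean ``lam[i, j] = m_ij * e^{st}``:
the lineage grows to ``e^{(1+s)t}`` copies, each of which is sampled into
deme ``j``'s bottleneck with probability ``K m_ij / (K e^t)``.

Writing ``f_i(x)`` for the probability generating function of the
offspring of one mutant in deme ``i``, the vector of extinction
probabilities ``p = (p_1, ..., p_D)`` is the minimal fixed point of
``f``; fixation probabilities are ``rho_i = 1 - p_i``.  To first order in
``st`` the fixed point gives ``rho_i = st * v_i``, where ``v`` is the
right 1-eigenvector of the migration matrix normalized by
``sum v_i^2 = 2 sum v_i``.  Two structural results follow:

* on any *circulation* (doubly stochastic ``m``) the eigenvector is
  uniform and every deme has ``rho_i = 2 st``, the well-mixed value;
* on any other graph the average ``sum_i rho_i / D`` is strictly below
  ``2 st`` (Cauchy-Schwarz), so every non-circulation strictly suppresses
  natural selection in this regime.

Iterates ``q^(n) = f(q^(n-1))`` give the probability of being extinct by
bottleneck ``n``, hence mean extinction times conditioned on extinction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .graphs import INCOMING, MigrationGraph, ensure_valid
from .simulation import ModelParams

__all__ = [
    "POISSON",
    "BINOMIAL_POWER",
    "OffspringModel",
    "BPResult",
    "ExtinctionTimeResult",
    "build_offspring_model",
    "gf_apply",
    "solve_extinction",
    "first_order_fixation",
    "extinction_time",
]

POISSON = "poisson"
BINOMIAL_POWER = "binomial_power"


@dataclass(frozen=True)
class OffspringModel:
    """Offspring law of one mutant lineage over one cycle.

    ``lam[i, j]`` is the expected number of descendants in deme ``j`` at
    the next bottleneck of one mutant currently in deme ``i``.  In
    ``poisson`` mode the offspring counts are Poisson with these means; in
    ``binomial_power`` mode the generating function keeps the full
    binomial factors ``(1 - b_ij + b_ij x_j)^G`` with ``G = e^{(1+s)t}``
    trials and per-copy sampling probability ``b_ij = m_ij e^{-t}``
    (relevant bookkeeping for rare migrations; numerically the two modes
    agree closely whenever ``G`` is large).
    """

    lam: np.ndarray
    mode: str = POISSON
    st: float = 0.0
    K: int | None = None
    b: np.ndarray | None = None
    G: float | None = None

    @property
    def D(self) -> int:
        return self.lam.shape[0]


@dataclass
class BPResult:
    """Per-deme extinction/fixation probabilities from the branching process."""

    p: np.ndarray        # extinction probability, one initial mutant in deme i
    rho: np.ndarray      # fixation probability 1 - p
    rho_avg: float       # uniform average over the initial deme
    validity_flags: list[str] = field(default_factory=list)
    n_iterations: int = 0


@dataclass
class ExtinctionTimeResult:
    """Conditional mean extinction times from generating-function iterates."""

    q_iterates: np.ndarray   # (n+1, D); q[n, i] = P(extinct by bottleneck n)
    tau: np.ndarray          # conditional mean extinction time per start deme
    tau_avg: float           # uniform average over start demes
    tau_avg_weighted: float  # average weighted by extinction probability
    tail_fraction: float     # share of the mean from geometric-tail extrapolation


def build_offspring_model(
    g: MigrationGraph, params: ModelParams, mode: str = POISSON
) -> OffspringModel:
    """Offspring means ``lam = e^{st} m`` (row = origin deme)."""
    ensure_valid(g)
    if g.convention != INCOMING:
        raise ValueError("branching-process analysis requires incoming normalization")
    if mode not in (POISSON, BINOMIAL_POWER):
        raise ValueError(f"unknown mode {mode!r}")
    lam = math.exp(params.st) * g.m
    b = G = None
    if mode == BINOMIAL_POWER:
        b = g.m * math.exp(-params.t)
        G = math.exp((1.0 + params.s) * params.t)
    return OffspringModel(lam=lam, mode=mode, st=params.st, K=params.K, b=b, G=G)


def gf_apply(model: OffspringModel, x: np.ndarray) -> np.ndarray:
    """Evaluate the offspring generating function componentwise.

    Poisson mode: ``f_i(x) = exp(sum_j lam_ij (x_j - 1))``.  The map is
    nondecreasing and convex in ``x`` and fixes the all-ones vector.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.D:
        raise ValueError("x has wrong dimension")
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("x must lie in the unit cube [0, 1]^D")
    if model.mode == POISSON:
        return np.exp((x - 1.0) @ model.lam.T)
    # binomial_power: f_i = prod_j (1 - b_ij (1 - x_j))^G
    return np.exp(model.G * np.log1p(-model.b * (1.0 - x)[..., None, :]).sum(axis=-1))


def _gf_jacobian(model: OffspringModel, q: np.ndarray) -> np.ndarray:
    f = gf_apply(model, q)
    if model.mode == POISSON:
        return f[:, None] * model.lam
    inner = model.G * model.b / (1.0 - model.b * (1.0 - q)[None, :])
    return f[:, None] * inner


def _validity_flags(model: OffspringModel) -> list[str]:
    flags = []
    if model.K is not None and model.st * model.K <= 5:
        flags.append(
            f"K*st = {model.st * model.K:.3g} <= 5: outside the branching-process "
            "validity regime (needs K*st >> 1)"
        )
    if model.st >= 0.3:
        flags.append(f"st = {model.st:.3g} >= 0.3: first-order-in-st regime left")
    return flags


def solve_extinction(
    model: OffspringModel, tol: float = 1e-13, max_iter: int = 5_000_000
) -> BPResult:
    """Minimal fixed point of the generating function.

    Iterates ``q <- f(q)`` from ``q = 0``; the sequence increases
    monotonically to the extinction-probability vector.  Guarded Newton
    steps (which also converge monotonically from below for these convex
    systems) accelerate the plain iteration near criticality.  A process
    with spectral radius of ``lam`` at most 1 is (sub)critical and goes
    extinct surely: ``p = 1`` is returned with a flag.
    """
    flags = _validity_flags(model)
    radius = float(np.max(np.abs(np.linalg.eigvals(model.lam))))
    D = model.D
    if radius <= 1.0 + 1e-12:
        flags.append(f"subcritical or critical process (spectral radius {radius:.6g})")
        p = np.ones(D)
        return BPResult(p=p, rho=np.zeros(D), rho_avg=0.0, validity_flags=flags)

    q = np.zeros(D)
    resid = np.inf
    for it in range(1, max_iter + 1):
        fq = gf_apply(model, q)
        resid = float(np.max(np.abs(fq - q)))
        if resid <= tol:
            q = fq
            break
        q = fq
        if it % 20 == 0:
            # Newton polish: solve (I - J) d = f(q) - q; from below the
            # iterates stay below the minimal fixed point.
            try:
                J = _gf_jacobian(model, q)
                d = np.linalg.solve(np.eye(D) - J, gf_apply(model, q) - q)
            except np.linalg.LinAlgError:
                continue
            cand = q + d
            if np.all(cand >= q - 1e-15) and np.all(cand < 1.0):
                r_cand = float(np.max(np.abs(gf_apply(model, cand) - cand)))
                if r_cand < resid:
                    q = cand
    else:
        raise RuntimeError(
            f"extinction fixed point did not converge in {max_iter} iterations "
            f"(residual {resid:.3g}, spectral radius {radius:.6g})"
        )
    # final Newton polish: the plain-iteration stopping rule controls the
    # residual, not the error p - q, whose gap scales like 1/st near
    # criticality; a few quadratic steps close it to machine precision
    for _ in range(5):
        try:
            J = _gf_jacobian(model, q)
            cand = q + np.linalg.solve(np.eye(D) - J, gf_apply(model, q) - q)
        except np.linalg.LinAlgError:
            break
        if not (np.all(cand >= 0.0) and np.all(cand < 1.0)):
            break
        r_cand = float(np.max(np.abs(gf_apply(model, cand) - cand)))
        if r_cand >= resid:
            break
        q, resid = cand, r_cand
    rho = 1.0 - q
    return BPResult(p=q, rho=rho, rho_avg=float(rho.mean()),
                    validity_flags=flags, n_iterations=it)


def first_order_fixation(g: MigrationGraph, st: float) -> np.ndarray:
    """Fixation probabilities to first order in ``st``.

    Returns ``rho_i = st * v_i`` where ``v`` is the right eigenvector of
    the migration matrix for eigenvalue 1 (it exists because columns sum
    to 1), scaled by the solvability condition of the second-order
    perturbation, ``sum v_i^2 = 2 sum v_i``.  On a circulation ``v`` is
    uniform and every deme gets exactly ``2 st``; on any other connected
    graph the deme average falls strictly below ``2 st``.
    """
    ensure_valid(g)
    if g.convention != INCOMING:
        raise ValueError("first-order analysis requires incoming normalization")
    ns = scipy.linalg.null_space(g.m - np.eye(g.D), rcond=1e-10)
    if ns.shape[1] != 1:
        raise ValueError(
            f"eigenvalue-1 eigenspace has dimension {ns.shape[1]}; "
            "the migration graph is reducible"
        )
    v = ns[:, 0]
    if v.sum() < 0:
        v = -v
    if np.any(v < -1e-10 * np.max(np.abs(v))):
        raise ValueError("leading eigenvector is not sign-definite; graph is reducible")
    v = np.clip(v, 0.0, None)
    v *= 2.0 * v.sum() / np.dot(v, v)
    return st * v


def extinction_time(
    model: OffspringModel, tol: float = 1e-10, horizon: int = 1_000_000
) -> ExtinctionTimeResult:
    """Mean extinction time (in dilution steps) conditioned on extinction.

    The iterate ``q^(n)`` is the probability of being extinct by
    bottleneck ``n``; the increments give the extinction-time law,
    ``tau_i = sum_n n (q_i^(n) - q_i^(n-1)) / p_i``.  The geometric tail
    beyond the stopping point is extrapolated from the local contraction
    ratio and its contribution reported in ``tail_fraction``.
    """
    bp = solve_extinction(model)
    p = bp.p
    D = model.D
    q = np.zeros(D)
    S = np.zeros(D)          # sum of n * increment
    iterates = [q.copy()]
    delta = None
    ratio = 0.0
    n = 0
    for n in range(1, horizon + 1):
        qn = gf_apply(model, q)
        new_delta = qn - q
        S += n * new_delta
        if delta is not None:
            ok = delta > 0
            ratio = float(np.max(new_delta[ok] / delta[ok])) if np.any(ok) else 0.0
        delta = new_delta
        q = qn
        iterates.append(q.copy())
        rem = np.maximum(p - q, 0.0)
        if n > 2 and ratio < 1.0:
            tail_bound = rem * (n + 1.0 / max(1.0 - ratio, 1e-12))
            if float(np.max(tail_bound / np.maximum(S, 1e-300))) < tol:
                break
    else:
        raise RuntimeError(
            f"extinction-time iteration did not converge within horizon={horizon}; "
            f"partial tau = {(S / np.maximum(p, 1e-300)).tolist()}"
        )
    rem = np.maximum(p - q, 0.0)
    tail = rem * (n + 1.0 / max(1.0 - ratio, 1e-12))
    tau = (S + tail) / np.maximum(p, 1e-300)
    tail_fraction = float(np.max(tail / np.maximum(S + tail, 1e-300)))
    return ExtinctionTimeResult(
        q_iterates=np.asarray(iterates),
        tau=tau,
        tau_avg=float(tau.mean()),
        tau_avg_weighted=float(np.dot(p, tau) / p.sum()),
        tail_fraction=tail_fraction,
    )
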