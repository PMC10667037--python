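# Methods

## Model

The population lives on `D` demes connected by a migration graph `m`,
with `m[i, j]` the probability that an individual forming deme `j`'s next
bottleneck originates from deme `i`. The default convention normalizes
columns (`Σ_i m_ij = 1`), so every deme has average bottleneck size `K`;
the row-normalized variant (every deme *contributes* `K` on average) is
supported by the data structures and validation, while the analytical
solvers require the column-normalized form. Diagonal entries are stored
explicitly rather than inferred, so arbitrary user matrices round-trip
through validation unchanged.

One cycle is deterministic exponential growth (`fW = 1`, `fM = 1 + s`,
duration `t`) followed by stochastic dilution-migration. Growth maps the
mutant fraction through `x' = x e^{st} / (1 + x (e^{st} − 1))` and the
deme size to `N' = M e^{(1+s)t} + W e^t`. Selection is soft: a deme's
contribution to the next bottleneck does not depend on its mean fitness.
Mutations arise only in the initial condition; growth is noiseless; demes
cannot go permanently extinct in the fixed-bottleneck variants.

### Sampling variants

* `independent_binomial` (default): for each ordered pair `(i, j)` the
  mutant and wild-type migrant counts are independent
  `Binomial(round(N'_i), K m_ij x'_i / N'_i)` and
  `Binomial(round(N'_i), K m_ij (1 − x'_i) / N'_i)` draws — two separate
  binomials per pair, not a joint hypergeometric. Bottleneck sizes
  fluctuate (approximately Poisson with mean `K`), and a deme can empty at
  small `K`; empty demes simply stay empty through growth.
* `multinomial_fixed`: each deme's next bottleneck has exactly `K`
  individuals, drawn from one multinomial over (origin, type) categories
  with probabilities `m_ij x'_i` and `m_ij (1 − x'_i)` (these sum to 1 by
  column normalization). Useful at small `K`.
* `deterministic_migration_binomial`: offspring migrate deterministically
  and deme `j` draws `M_j ~ Binomial(K, Σ_i m_ij x'_i)` — the structured
  Wright–Fisher scheme; with `D = 1` it is exactly Wright–Fisher with one
  bottleneck per generation.

Post-growth sizes are kept as reals and binomial trial counts use
`round(N')`; the rounding error is `O(1/N')` and irrelevant for `t` of a
few doublings. The dilution step validates `K m_ij / N'_i ≤ 1` at runtime
and raises with a remediation hint (increase `t` or reduce `K m_ij`)
rather than silently clipping.

### Monte-Carlo estimator

Replicates are vectorized in fixed blocks of 32768, each block drawing
from an RNG substream keyed by `(seed, block index)`. Because the block
size is a constant of the implementation, estimates are bit-reproducible
and independent of scheduling; keying substreams by block rather than by
individual replicate keeps the sampler fully vectorized at identical
statistical guarantees. Censored replicates (no absorption within
`max_cycles`, default 10^6) are counted separately and excluded from both
the fixation probability and the conditional time averages — they are
never folded into either absorption class.

## Branching-process solver

In the regime `K ≫ 1`, `K st ≫ 1`, `st ≪ 1` mutant lineages are
independent and the offspring of one mutant in deme `i` that land in deme
`j` are `Binomial(e^{(1+s)t}, m_ij e^{−t})`-distributed, hence Poisson
with mean `λ_ij = m_ij e^{st}` to excellent accuracy (the generating
functions differ by `O(e^{(1+s)t} (m_ij e^{−t})²)` in the exponent; the
full binomial-power generating function is available as a mode for
bookkeeping at rare migrations). Extinction probabilities are the minimal
fixed point of the generating function, found by monotone iteration from
zero with guarded Newton steps — Newton on these convex systems also
converges monotonically from below, so the guard (iterates must stay in
`[q, 1)`) protects only against numerical degeneracies. A final Newton
polish closes the gap between the residual-based stopping rule
(`‖f(q) − q‖∞ ≤ 10^{-13}`) and the true error, which otherwise scales
like `residual / st` near criticality. Processes with spectral radius
`≤ 1` return `p = 1` with a flag instead of iterating.

Solving the fixed point numerically covers all migration strengths with
one code path; we deliberately do not transcribe closed-form expansions,
and instead validate the first-order formula against the numeric fixed
point (Richardson extrapolation of `ρ/st` at `st = 10^{-4}, 2×10^{-4}`
agrees with the eigenvector formula to better than `10^{-4}` relative).

First-order probabilities use the right 1-eigenvector of `m` (computed
via the nullspace of `m − I`; an eigenspace of dimension > 1 means a
reducible graph and is an error), scaled by the second-order solvability
condition `Σ v² = 2 Σ v`. Validity flags fire at `K st ≤ 5` and at
`st ≥ 0.3`, where the approach is known to degrade.

Extinction times iterate `q^{(n)} = f(q^{(n−1)})`; the increment
`q^{(n)} − q^{(n−1)}` is the probability of going extinct exactly at
bottleneck `n`, and the conditional mean is the increment-weighted index
sum divided by `p`. Iteration stops once the remaining mass, bounded by a
geometric tail with the observed contraction ratio, contributes less than
`10^{-10}` of the accumulated sum; the extrapolated tail is added and its
share reported. Two averages are exposed: the uniform deme average and
the extinction-probability-weighted average, which is the correct
comparison target for simulations that place the initial mutant uniformly
and condition on extinction.

## Rare-migration regime

When migrations are slower than within-deme sweeps, demes are effectively
monomorphic and the system is an absorbing chain on subsets of mutant
demes. Flip weights per cycle: deme `j` turns mutant with weight
`Σ_{i∈S} K m_ij ρ₊` and reverts with `Σ_{i∉S} K m_ij ρ₋`, where `ρ₊`/`ρ₋`
are within-deme fixation probabilities of a single beneficial/deleterious
invader. The cycle length cancels in the embedded jump chain. Starting
from one mutant, the total fixation probability is the product of the
within-deme probability and the chain's absorption probability. The
generic solver enumerates `2^D` subsets (rejected for `D > 20`); the star
has a symmetry-reduced chain on `(center type, mutant-leaf count)` —
`2D` states — that matches the generic solver to machine precision and
handles `D = 20` instantly. With `α = D − 1` this chain coincides with
the star of evolutionary graph theory under the Birth–death update rule.

Within-deme fixation uses the haploid diffusion form
`(1 − e^{−2st}) / (1 − e^{−2Kst})` with per-cycle selection `st` and
variance-effective size equal to the bottleneck `K` (neutral limit
`1/K`). Its accuracy is `O(st)` relative; the tests validate it against
the exact `K+1`-state Wright–Fisher chain and against isolated-deme
simulation. An exactly matched within-deme formula would shift
rare-migration predictions at `O(st²)` only.

### Regime check

The applicability diagnostic is the expected number of *successful*
migrant lineages arriving in the most-exposed deme during one sweep:
`K · max_j Σ_{i≠j} m_ij · ρ₊ · ln(K)/st` (sweep length `ln(K)/st` cycles;
`K` cycles at neutrality), with default threshold 0.5. The success factor
`ρ₊` matters: unsuccessful migrants perturb a deme only transiently and do
not break the monomorphic description, and only with this factor does the
diagnostic reproduce the empirical boundary (for `D = 5`, `K = 1000`,
`α = 4` the coarse description holds up to `mO` of order `10^{-6}`).

### Where amplification lives

Numerically, the star with `α = 4` at `D = 5`, `K = 100` amplifies
(exceeds the well-mixed diffusion value at `N = KD`) for `st` up to about
`1/K`, with a margin of ~2% at `st = 1/K` and ~10% at `st = 0.5/K`; by
`st = 2/K` the two curves already agree to 5 digits, and the margin grows
with `D` (~8% at `D = 20`, `st = 1/K`). Amplification in this model is
weak, confined to `st` of order `1/K`, and disappears entirely as
migrations become frequent.

## Synthetic graph generators

* **Dirichlet cliques** draw each destination column from a Dirichlet
  distribution (concentration `η` for all origins, or `η₀ ≥ 1` for one
  advantaged deme and 1 for the rest), so columns sum to 1 exactly and
  the in/out asymmetry is tuned by `η`: entry variance is
  `(1/D)(1 − 1/D)/(Dη + 1)`.
* **Random circulations** are Dirichlet-weighted mixtures of random
  permutation matrices plus the identity (Birkhoff form) — exactly doubly
  stochastic by construction, resampled until connected.

These generators emulate the *structure* of migration patterns, not any
measured biology: passing tests demonstrate the theory's internal
consistency on such graphs, not agreement with data from a particular
experimental system.

## Default study conditions and problem sizes

Headline comparisons use `D = 5`, `K = 1000`, `t = 5`, a single mutant
placed uniformly at random, and `st` between 0.025 and 0.1; the star
suppressor uses `α = 4` with `mO ≤ 1/16` (the largest value the center
column can normalize; with `α = 1/4` the full range `mO ≤ 1` is open).
Simulation checks in the test suite run 10^5 replicates per point
(3-standard-error bands), the neutral control 10^6 replicates at
`K = 200`, and rare-migration crossover scans use `K = 100` with the
Wright–Fisher sampling variant, whose single draw per deme per cycle
makes it the cheapest of the three equivalent schemes.

## Known limitations

* Mutants appear only at a bottleneck; mutations during growth, multiple
  segregating mutants, changing environments, deme extinctions and range
  expansions are out of scope.
* The branching process treats wild-types as an unperturbed background;
  it predicts extinction probabilities and times, not fixation times.
* The diffusion stand-in for within-deme fixation is `O(st)`-accurate;
  rare-migration predictions inherit that accuracy.
* The outgoing-normalized convention is validated and stored but the
  solvers operate on the incoming-normalized (main) convention.
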