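# Methods

## Models

**Pairwise model.** Binary states `s ∈ {0,1}^N`;
`P_p(s) ∝ exp(Σ h_i s_i + Σ_{i<j} J_ij s_i s_j)` with symmetric,
zero-diagonal J.  Constraints are time averages of a binned raster:
`m_i = <s_i>`, `g_ij = <s_i s_j>` (the "coupled activity"; `g_ii = m_i`
since `s² = s`).  Bins are half-open `[tΔ, (t+1)Δ)` with Δ = 3 ms by
default; a spike exactly at the recording end T is rejected as out of
range.  Covariances `c = g − m mᵀ` and Pearson coefficients
`ρ_ij = c_ij / sqrt(var_i var_j)` follow; pairs involving a unit with
`m_i ∈ {0, 1}` have undefined ρ and are excluded from the population
average with a logged warning rather than an error, because silent units
are common in recordings.

**Reduced model.** When only the population averages `(m̄, ḡ)` are
constrained, symmetry forces homogeneous multipliers and the distribution
of the total activity `S = N s̄` is exactly

    P_r(S) ∝ C(N,S) · exp[ h_r S + ½ J_r S(S−1) ],   S ∈ {0, …, N},

computed in the log domain with log-gamma binomials (stable for N in the
thousands).  Its first two factorial moments are `E[S] = N m̄` and
`E[S(S−1)] = N(N−1) ḡ`.

**Inhibited model.** `P_i(s) ∝ P_p-weight × exp[J_I · N G(s̄ − θ)]` with
`G(x) = x H(x)` and the convention `H(0) = 1` ("at or above threshold").
The threshold is stored as the integer `Θ = ⌈Nθ⌉`: the inhibitor state only
depends on whether `S ≥ Nθ`, so every θ in `((Θ−1)/N, Θ/N]` defines the
same model, and the integer grid makes the discrete identity
`N G(x + 1/N) − N G(x) = H(x)` exact — the key step in the stationarity
proof of the inhibited dynamics.  As `J_I → −∞`, `P_i` converges pointwise
to the truncated distribution (pairwise weights restricted to `s̄ ≤ θ`);
the package verifies this numerically by total-variation distance.

## Fitting the reduced model

`fit_reduced` minimises the convex dual
`ln Z_r − h_r·N m̄ − ½ J_r·N(N−1) ḡ` by damped Newton iteration:
gradient = moment mismatch, Hessian = covariance of the sufficient
statistics `(S, S(S−1)/2)`.  Start `(logit(m̄), 0)`; Armijo backtracking;
when the certified decrease falls below the float resolution of the dual,
the full Newton step is taken (this happens only inside the quadratic
convergence basin).  Convergence: max relative moment mismatch < 1e−10
(refits reproduce constraints to ≥ 7 significant figures).  Multipliers
exceeding 1e3 in magnitude, or constraints on the attainable boundary
(`ḡ = m̄²`-independence is interior and fine; `ḡ = m̄` or the lower pair
bound are not), raise a divergence error: a very large multiplier signals
that a constraint sits at its extreme value, where the maximum-entropy
approximation itself breaks down.

## Bimodality analysis

The continuous extension of `ln P_r` replaces `C(N, Ns̄)` by its log-gamma
form.  Stationary points in s̄ solve

    h_r + J_r (N s̄ − ½) − Ψ(N s̄ + 1) + Ψ(N(1−s̄) + 1) = 0,

bracketed on a grid of 10·N points and refined by bisection to 1e−12;
classification is by the trigamma second-derivative sign (minimum iff
`J_r > Ψ′(N s̄+1) + Ψ′(N(1−s̄)+1)`).  Discrete pmf modes (strict local
maxima; plateaus collapse to their leftmost index) and the low/high
peak-probability ratio are reported alongside, since near the onset of
bimodality the continuous and discrete pictures can differ by a grid step.

The phase boundary in the `(E(s̄), ρ̄)` plane is swept parametrically: on
the boundary a stationary point at s̄_m is degenerate, giving
`J_r = Ψ′(1+(1−s̄_m)N) + Ψ′(1+s̄_m N)` and the matching h_r in closed
form; each boundary point is mapped to moment coordinates through the
exact pmf.  2000 sweep points with geometric refinement near s̄_m = 0, 1;
degenerate endpoints (zero variance) are dropped.

### Reference values and their internal consistency

For the published constraints `(N=159, m̄=0.0499, ḡ=0.00261)` the package
obtains `h_r = −3.2457`, `J_r = 0.03711`, while the reference values quoted
alongside those constraints are `(−3.259, 0.03859)`.  The two printed pairs
are mutually inconsistent: inverting the reference multipliers through the
exact pmf yields implied constraints `m̄ = 0.04984`, `ḡ = 0.0026114`, which
do not round to the printed constraint values.  The discrepancy is
explained by rounding sensitivity — `|∂J_r/∂ḡ| ≈ 200`, so the third
significant figure of ḡ moves J_r by ~1e−3.  The package treats the
printed constraints as the canonical input and reports what exact fitting
of them gives.  The same sensitivity propagates to derived quantities: the
smallest bimodal N for these constraints is 155, with onset maxima at
`s̄ = 0.0444` and `0.8064` (at onset the new maximum necessarily appears
next to the degenerate saddle; it migrates towards `s̄ ≈ 0.95` only as N
grows — at N=1000 the maxima sit at 0.0488 and 0.9498), and the N=300
discrete peak ratio is 17935, decreasing monotonically towards a ~7000
plateau for N ≳ 2000.

## Glauber dynamics

One step = one single-unit update attempt: unit i uniform at random, set to
1 with probability `σ(F_i)`.  `standard`: `F_i = h_i + Σ_{k≠i} J_ik s_k`.
`inhibited_single`: one inhibitory unit `s_I = H(Σ_k s_k/N − θ)` updated
deterministically after every step contributes `J_I s_I` — the simulation
algorithm with a single physical inhibitor; it is only approximately
stationary for P_i.  `inhibited_excluded`: the inhibitor's input excludes
the updating unit, `F_i` gains `J_I H(Σ_{k≠i} s_k/N − θ)`; this variant
satisfies detailed balance with P_i exactly and is the default for
surrogate generation and learning.  Exactness of both claims is verified
against enumeration: stationary vectors of the sparse transition matrix
match exact distributions to 1e−10, detailed-balance violations are at
machine precision for standard/excluded and strictly positive for the
single-inhibitor variant.

Implementation: numba-JIT inner loop with incremental field updates
(`O(N)` per flip); the legacy MT19937 stream is seeded inside the kernel
and every variant consumes exactly two values per step (unit index,
acceptance draw), so `J_I = 0` reproduces the standard trajectory
bit-for-bit under the same seed.  Default burn-in 100·N attempts; traces
record the total activity every `record_every` attempts.  The time axis is
update attempts — the dynamics samples the stationary law and does not
model physiological time.

## Boltzmann learning

`h_i += η_h (m_i − m̂_i)`, `J_ij += η_J (g_ij − ĝ_ij)` per iteration, with
moments from a fresh Glauber run (default 1e6 attempts) or, for N ≤ 20,
from enumeration ("exact gradients", which isolates the learning rule from
sampling noise; with exact gradients random 10-unit models are recovered to
1e−6 in the multipliers).  Defaults η = 0.1 with geometric decay 0.99 per
iteration; the decay stabilises sampled learning but caps asymptotic
precision, so exact-gradient studies use decay 1.0.  The weak-correlation
inversion `J_ij = c_ij/[m_i(1−m_i) m_j(1−m_j)]`,
`h_i = logit(m_i) − Σ_j J_ij m_j` provides the start.  Boundary targets
(some `g_ij` at 0 or `min(m_i, m_j)`) are rejected, not regularised.

After learning, an optional verification run (recommended 5e7 attempts)
probes ergodicity: the trace is cut into ~100 windows and the flag is
raised when the window-mean activities span more than 0.3 — the signature
of a jump between metastable regimes, i.e. the moments measured during
learning were conditional on one basin.  For cortex-like constraints the
weak-correlation start overestimates J (it ignores the m̄² ≫ c̄ structure
of ḡ), so short standard-sampler learning sits deep in the bimodal region
and the verification run jumps within a few million steps; the inhibited
variant shows no jump.

Inhibition parameters `(J_I, θ)` are never learned.  Fitting them to data
is ill-posed (the empirical average of `G(s̄ − θ)` is typically zero,
pushing `J_I → −∞`); they are chosen a priori, defaults `J_I = −24.7`,
`θ = 0.3` — a threshold comfortably above observed activity and below the
high-activity fixed point, with a coupling strong enough to suppress
activity at threshold.

## Inhibition-term expansion

`N G(s̄ − θ) = Σ_{K>Θ} f_K C(S, K)` with
`f_K = C(−Θ, K−Θ−1) = (−1)^{K−Θ−1} C(K−2, K−Θ−1)`.  Computed two ways —
`f = v P⁻¹` with the (N+1)-dimensional Pascal matrix `P[K,S] = C(S,K)`,
`P⁻¹[S,K] = (−1)^{K−S} C(K,S)`, and the closed form — in exact Python
integer arithmetic (the coefficients alternate in sign and grow
combinatorially; floats would cancel catastrophically).  Both routes must
agree entry-by-entry and reconstruct `max(0, S−Θ)` for every S, or the
function raises.  Growing N appends rows/columns without changing existing
entries (nesting).

## Synthetic data

The generators double as the package's surrogate-data use case and as the
test substrate.  `jittered_multipliers` draws `h_i ~ N(h_r, σ_h²)` and
`J_ij ~ N(J_r, σ_J²)` (mirrored, zero diagonal) with defaults
`σ_h = 0.8`, `σ_J = 0.009` — the small-jitter inhomogeneous setting used
for the bistability studies.  `surrogate_raster` records one state per
sweep-equivalent (`record_every = N`) after a 100·N burn-in, starting from
the all-silent state, so raster bins are approximately independent draws
from the stationary law.  What the synthetic data do *not* emulate:
refractoriness, non-stationarity, trial structure, or temporal
correlations beyond the residual autocorrelation of the chain — so
passing tests certify the statistical machinery, not any claim about
temporal structure in real recordings.

## Numerical choices and problem sizes

- All normalisations via log-sum-exp; enumeration capped at N = 20
  (override explicitly), transition matrices at N = 12 (sparse solve of
  `(Pᵀ − I)π = 0`), detailed balance at N = 10.
- Chi-square sampler validation at N = 6 uses 1e7 attempts thinned by 13
  with an effective-sample-size correction for residual autocorrelation.
- Bistability probes at N = 159 use 1e5 attempts per start (the
  high-activity regime's escape time at the reference multipliers is
  ≳ 5e5 attempts, the low regime's ≳ 1e16, so both basins are cleanly
  resolved); basin labels threshold the final-quarter window mean at the
  continuous minimum of the homogeneous proxy model.
- Sampled-learning studies use 10-unit models with 4e5 attempts per
  iteration; the scan for the smallest bimodal N covers N = 100…300.

## Known limitations

- The exact fitter and oracles are exponential in N by design (oracle
  role); large-N inference goes through Boltzmann learning only.
- `inhibited_single` has no exact stationary law here; it is provided for
  fidelity to the single-inhibitor simulation algorithm and quantified by
  its detailed-balance violation.
- The spike-count correlation uses disjoint windows; cross-correlogram
  areas (the sliding-window equivalent) are not implemented, and the
  `ρ ≳ r_SC/20` rule is exposed as the deliberately conservative survey
  heuristic it is.
- No non-stationarity corrections, trial structure, or alternatives to
  Glauber sampling (parallel tempering etc.).
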