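# Methods

## Model

Cumulative merging percolation (CMP) is defined on a static undirected
simple graph. A node is *active* iff its degree k ≥ k_a (the Θ(k − k_a)
activation is taken inclusive, so k_a = k_min activates every node). Each
active node seeds a cluster of mass m = k; a cluster of mass m interacts out
to topological distance r(m), by default r(m) = m/k_a so that the smallest
active node has range exactly 1. Two clusters merge when some pair of their
member nodes lies within *both* ranges, d ≤ min{r(m_α), r(m_β)} — mutuality
is essential: a massive cluster cannot capture a distant small one. Masses
add on merging and the iteration runs to a fixed point. Members of a cluster
need not induce a connected subgraph; inactive nodes only provide distances.
Clusters never span disconnected components (distance = ∞). With r ≡ 1 the
limiting partition is exactly the set of connected components of the
active-induced subgraph (degree-ordered percolation, DOP).

## Engine

The engine keeps a union-find structure over active nodes and a work queue
of clusters. Processing cluster α runs a bounded multi-source BFS from all
its members to depth ⌊r(m_α)⌋ (distances are integers, so only the floor of
a real range matters); every foreign active node found at distance d is
grouped by cluster and merged when its cluster's minimum distance satisfies
d ≤ r(m_β). A merged cluster is re-enqueued: mutuality failures are healed
when the blocked cluster itself grows and re-scans. The queue-empty state is
the fixed point; it is verified against a brute-force pairwise-scan oracle
on hundreds of small graphs and is independent of processing order (the
engine accepts an explicit order or a shuffling RNG precisely to test this).
BFS uses a timestamp array so repeated searches avoid O(N) resets; a sweep
over 20 k_a values on an N = 10⁶ network takes seconds.

Giant-component counts require at least one merge: a lone active node is
never reported as a "giant component" of size 1 (this keeps
N_GC ≤ N_NI exact at large k_a where the partition is all singletons).
Largest-cluster ties break toward the smallest cluster id; cluster ids are
the smallest member node id, so outputs are deterministic and diffable.

## Networks

Degrees are sampled i.i.d. by exact inverse-CDF from a discretised power law
on [k_min, M], with cell-integrated weights
P(k) ∝ ∫_{max(k−½, k_min)}^{k+½} x^−γ dx. The cell integration matters: a
bare k^−γ mass function at k_min = 3 depresses ⟨k⟩ by ~14% and tail
probabilities by ~30% relative to the continuous density that every closed
form in the theory assumes, while the cell-integrated version agrees to a
few percent (e.g. ⟨k⟩ = 4.94 vs 5.00 at γ = 3.5). An odd degree sum is fixed
by resampling the last entry. Cutoffs: structural M = ⌊√N⌋ for γ < 3,
hard M = ⌊N^{1/(γ−1)}⌋ for γ > 3 (suppressing outlier hubs), or none. Stub
matching followed by edge-swap rewiring of self-loops/multi-edges realises
the sequence exactly; irreducible conflicts trigger discard-and-regenerate.

Moments of the *realised* graph are cutoff-truncated: the branching factor
κ = ⟨k²⟩/⟨k⟩ − 1 at (γ = 3.5, N = 10⁵) is ≈ 6.5 against the infinite-cutoff
8.0. Theory functions therefore accept a measured κ override; the default
is the infinite-cutoff continuous value k_min(γ−2)/(γ−3) − 1 so that theory
curves need no graph in hand.

## Theory: numerical choices

* Γ(1−γ, x) (negative first argument) is computed by the downward recurrence
  Γ(a−1, x) = [Γ(a, x) − x^{a−1}e^{−x}]/(a−1) from a positive base (or
  Γ(0, x) = E₁(x) when 1−γ+⌈γ⌉ vanishes), with adaptive quadrature as a
  fallback. Verified against 40-digit reference integrals to < 10⁻⁹ over the
  working range x ∈ (0, 8].
* The N_NI/N closed form subtracts two nearly equal terms as k_a/k_c → 0;
  in double precision this is fine over the simulable range but fails at the
  k₂* solve, which therefore evaluates it at 50-digit precision (mpmath).
* k₁* is obtained by equating the large-k_a expansions of N_NI/N and
  N_{r≥2}/N including the first-order bracket, giving
  k₁* = [(γ−2)/(γ−1) · 2^{1−γ}/(1+2^{2−γ}) · k_min^{2−γ}]^{1/(3−γ)}; the
  closed form matches an independent root solve to 10⁻⁶ and reproduces the
  known minimum network size ≈ 4.2×10⁵ near γ ≈ 5 (k_min = 3).
* The expansions converge slowly for γ near 3 (error ∼ k_a/k_c): the 5%
  level is only reached around 10³·k₀*, and the N_{r≥2} bracket goes
  negative below ≈ 30·k₀*. Tests assert convergence *toward* the asymptote
  rather than agreement at 10·k₀*.
* k₂* solves S₁(k) = S₂(k) using the *non-isolated branch* S₁ ≈ N_NI/N.
  Using the full S₁ = N_NI/N + N_{r≥2}/N the equation has no root at all:
  beyond k₁* both sides share the k_a^{1−γ} leading power and the isolated
  contribution's prefactor exceeds S₂'s ω^{1−γ} suppression. Since the
  crossover being located is precisely "preasymptotic scaling
  (∼k_a^{2(2−γ)}) versus distant-hub scaling", the N_NI branch is the
  correct comparison; the cluster accounting confirms the isolated-r≥2 term
  is dynamically suppressed anyway. The bracket search marches upward in
  decades from 2·k₀, since for γ ≲ 3.3 the root sits slightly below k₁*.
  Resulting N₂* = k₂*^{γ−1} has its minimum ≈ 5.6×10¹⁰ near γ ≈ 3.9
  (k_min = 3).
* The ω fixed point uses damped iteration (damping ½, tolerance 10⁻¹⁰,
  ≤ 10⁴ iterations); the map is a slowly varying logarithm and converges
  from ω = 1 for every tested (γ, κ, k_a).
* Asymptotic (∼) results — the γ > 3, k_max > k₂* threshold
  (ln κ/(γ−3))·k_max/ln k_max, the λ_c ∼ ω^{1/2}k_max^{−1/2} law and all
  prevalence scalings — are returned prefactor-free and flagged as such; no
  constants are invented.

## SIS

The mapping k_a = (a/λ²) ln(1/λ) uses ln(1/λ) by default; the threshold
condition is also exposed with the ln(1/λ²) convention (`lam_sq`), the two
differing by a factor 2 inside a logarithm. The constant a (1 or 4) is not
theoretically determined and is always an explicit parameter.

The simulator is an exact rejection-based (phantom-process) Gillespie
implementation: event times are exponential with the upper-bound rate
μI + βΣ_{i infected} k_i; a recovery picks a uniform infected node; an
infection attempt picks an infected source with probability ∝ its degree
(rejection against k_max) and a uniform neighbour, discarding attempts on
already-infected targets. Thinning makes the accepted process exactly the
SIS chain; agreement with absorbing-Markov-chain linear solves on ≤ 4-node
graphs is verified to Monte-Carlo error. The loop is a numba kernel;
rejection overhead is bounded by ⟨k_inf⟩/k_max and is acceptable at desk
scale (worst case: stars).

Lifespan-method conventions (not fixed by the theory): runs start from one
uniformly random seed; a run is endemic when its distinct-node coverage
reaches 0.5, at which point it stops; 200 runs per λ by default; the
threshold estimate is the interior peak of the mean lifetime of non-endemic
runs, with half-grid-spacing uncertainty.

## Synthetic data: what a green test establishes

The generator emulates uncorrelated power-law networks with the stated
(γ, k_min, N, cutoff) — the exact substrate the theory addresses. It does
not emulate degree correlations, clustering, weighted or temporal edges, or
stretched-exponential degree tails. Stochastic tests run at N = 10⁵–10⁶ and
verify *scaling properties* (slopes, ratios, orderings, cutoff locations)
with realization noise in mind; they do not reproduce published N = 10⁷–10⁸
curves. Known desk-scale limits worth keeping explicit:

* the S₁ window [k₀*, k_a^c/2] at γ = 3.5, N = 10⁶ spans barely one decade;
  the fitted slope lands at −3 ± 0.3 across seeds (asymptotic value −3,
  local theory slope over the same window −2.7);
* for γ < 3 the measured S level includes the structural-cutoff truncation
  of the degree tail, so it is compared with Eq.-8 scaling through its
  log-slope (−1.7 ± 0.2 at γ = 2.7), not its absolute prefactor;
* the ordering λ_c^QMF < λ_c(N) < λ_c^HMF is asymptotic; at N = 10⁵,
  γ = 3.5 it holds for a = 1 but the a = 4 curve still exceeds λ_c^HMF
  (it would need k_max ≳ 640, N ≳ 10⁷). The corresponding test is left
  failing deliberately as a record of this finite-size fact.

## Limitations

General exponents α ≠ 1 in r(m) = (m/k_a)^α are accepted by the engine (any
monotone range function with r ≥ 1) but carry no theory here. Mass merging
is strictly additive; saturating ranges, general g(m_α, m_β), degree
correlations and stretched-exponential tails are out of scope. The
Griffiths-like slow-decay phase below λ_c(N) is not characterised.
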