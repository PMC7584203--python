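# Methods

This note records the model choices, parameter conventions, numerical
details, and known limitations of the package, in the order a user meets
them.

## Adjacency convention

`A[i, j]` counts edges from node *j* into node *i*: row sums are realised
in-degrees, column sums realised out-degrees.  Matrices are dense
`int64` numpy arrays throughout; at N = 5000 this is ~200 MB, which we treat
as the practical ceiling.  File formats (Matrix Market coordinate integer,
edge-list TSV) use 1-based node indices; everything in memory is 0-based.

## Graphicality gate

Binary mode uses the classical Gale–Ryser criterion (with **k**ᵢₙ sorted
non-increasing on a copy; **k**ₒᵤₜ enters only through order-free sums), run
once before assembly.  Degrees above N are rejected separately — with 0/1
entries no margin can exceed the node count — and reported distinctly from an
inequality violation.  The criterion permits self-loops (the diagonal is
unconstrained).  Two deliberate gaps:

* loop-free binary graphicality has no closed-form pre-test here; beyond
  rejecting sequences that *force* a loop (a degree equal to N), infeasible
  cases surface as a runtime assembly failure carrying the diagnostic trace;
* passing the gate never guarantees the stochastic assembly converges — rare
  dead-ends ("cul-de-sacs") are a property of the method, reported as
  `AssemblyFailure` with the per-sweep trace attached.

Multi-edge mode needs only the degree-sum identity: unlimited multiplicity
makes any balanced sequence placeable.

## Assembly

**Precursor.**  Row *i* receives `k_in[i]` edge units, left-packed (skipping
the diagonal cell when self-loops are forbidden).  In multi-edge mode the
target number of surplus units is `round(p · Σ k_in)`; units are folded onto
occupied cells by drawing uniformly from per-row capacity slots, then the
extra units within a row are spread multinomially over its occupied cells.

Two capacity rules matter.  A row of `k` units can absorb at most `k − 1`
surplus units (everything on one cell) and at least `k − max_occupied`
(only N, or N − 1 without loops, cells exist).  Within those bounds the
allocator prefers to keep **at least two occupied cells per row**: under the
like-type transfer rule (below) a row whose entire in-degree sits in a single
cell can never change again — it cannot donate a solo unit (it has none) nor
move surplus units (no other occupied cell in the row) — so fully
concentrated rows are created only when the requested proportion is
unreachable otherwise.  When the target exceeds total capacity (or falls
below the forced floor), the achieved count is the closest feasible one and
the shortfall is recorded on the trace; the degree sequence is never bent to
meet the proportion.

**Permutation.**  Each row's cells are permuted independently and uniformly
(argsort of iid uniforms — a vectorised Fisher–Yates), once, at
initialisation.  In no-loop mode the diagonal cell (empty by construction)
is pinned and the remaining N − 1 cells are permuted.

**Donor loops.**  Donors are visited in **ascending column order** every
sweep, one transfer per donor per visit.  For each donor the full feasible
(row, recipient) set is enumerated; its size `n_e` is multiplied into the
trajectory weight and one move is drawn uniformly.  Feasibility: the unit
stays in its row (in-degrees inviolate by construction); binary mode
requires an empty destination cell; multi mode follows the like-type rule —
a solo unit (cell value 1) may only land on an empty cell, a surplus unit
(cell value ≥ 2) only on an occupied one, so the total multi-edge count is
invariant through the whole pipeline; self-loops are respected via the
destination's row index.

The deterministic visiting order is deliberate.  The exhaustive
small-instance oracle expands exactly the branching generated by uniform
*move* choice under fixed ascending donor order; with a randomised order the
sampled ensemble would mix trajectories from different orders and converge
to a measurably different distribution on the 3-node test instance, breaking
the correspondence between sampler, weights, and oracle.  All residual
randomness (which move, the initial permutation, shuffling) comes from one
seeded generator per run.

**Inert shuffling.**  When a sweep's transfers-per-donor ratio falls below
`inert_activation_ratio` (default 0.5), checkerboard swaps are attempted:
rows r₁ ≠ r₂, columns c₁ (inert) and c₂ (donor or recipient) with occupied
cells at (r₁, c₁) and (r₂, c₂) swap one unit diagonally.  Both row and both
column sums are preserved, so the residual is untouched; the move only
relocates edges, which can unlock transfers for stuck donors — a simulated
annealing kick.  `"auto"` attempts one swap per inert column (capped at
1000), each with a bounded number of random proposals.

**Termination.**  Converged when `r_out < ε` (default ε = 0.5: residuals are
integers, so this is exact matching with float-round-off headroom).
Failure paths: `max_donor_loops` exhausted; `stall_sweeps` (50) consecutive
sweeps with neither transfers nor successful shuffles; or a hard safety
limit of `no_transfer_limit` (1000) transfer-free sweeps even while shuffles
keep succeeding, which catches structurally frozen states quickly instead of
spinning.  On convergence the row/column sums are re-verified before the
result is returned.

## Trajectory weights and the exhaustive oracle

A run's probability conditional on its initial permutation is `Π 1/n_e`, so
the weight `w(t) = Π n_e` de-biases ensemble averages via
`⟨Q⟩ = Σ wⱼQⱼ / Σ wⱼ` (computed with a log-sum-exp shift; the log-weight is
always maintained, the exact big-integer product only for N ≤ 64, where
Python's arbitrary-precision integers make overflow a non-issue).  Inert
shuffles are not covered by the weight formula — they are
probability-symmetric randomisations, not donor transfers — so any run that
shuffled is flagged `shuffle_tainted` and `weighted_mean` warns when such
samples enter an estimate.

The oracle (`exact_assembly_distribution`) enumerates, for instances of up
to 4 nodes, every equally-likely initial permutation and every transfer
branch with `fractions.Fraction` arithmetic; masses (plus any dead-end mass)
sum to exactly 1, and the per-start incidence table shows how the initial
permutation restricts the reachable final matrices.  On the 3-node instance
k_in = k_out = (1, 2, 1) the five realisations are produced with exact
probabilities 0.2099, 0.2006, 0.1790, 0.2099, 0.2006 (4 d.p.) — the
column-symmetric realisation is the depressed one — and the weighted
spectral-radius estimate settles within O(10⁻³) of the ensemble mean
1.51628: the weights correct the per-matrix bias exactly, leaving only the
slight degeneracy in the number of trajectories terminating on each matrix.

## Metrics

**ANND.**  For orientation matrix M (the stored A for the `out` variant,
its transpose for `in`, the symmetrised support/weight for `undirected`),

    annd(i) = Σ_{j≠i} Σ_{k≠j} M_ij M_jk / Σ_j M_ij .

The binary form uses the 0/1 support; the weighted form applies the same
formula to the multiplicity matrix with per-node strength normalisation and
no global factor — the reading under which weighted and binary coincide on
matrices without multi-edges (for the undirected variant they differ:
symmetrisation gives mutual pairs weight 2).  Nodes with zero denominator
are returned as NaN and excluded from the per-degree-class summaries, never
silently zeroed.  A literal double-loop evaluator serves as the conformance
oracle in the tests.

**Spectral radius** is the largest eigenvalue modulus (dense `eigvals`).
The tested sandwich is the Perron–Frobenius one:
max(min row sum, min column sum) ≤ ρ ≤ min(max row sum, max column sum).

## Theta-neuron simulator

`dθᵢ/dt = (1 − cos θᵢ) + (1 + cos θᵢ)(ηᵢ + Iᵢ)` with
`Iᵢ = (κ/⟨k⟩) Σⱼ Aᵢⱼ Pₙ(θⱼ)` and pulse `Pₙ(θ) = dₙ(1 − cos θ)ⁿ`,
`dₙ = 2ⁿ/C(2n, n)` so ∫₀²π Pₙ = 2π for every sharpness n.  Defaults: n = 2,
fixed-step classical RK4 with dt = 0.01 dimensionless time, t_end = 200,
phases wrapped to [0, 2π) each step.  A spike is an upward crossing of π
(the velocity there is exactly 2, so all crossings are upward), with
linearly interpolated spike times.  Self-loops feed a neuron's own input —
the current has no j ≠ i restriction.  With κ = 0 the coupling term is
skipped entirely, so uncoupled networks integrate identically to independent
single neurons; a zero mean degree with κ > 0 is rejected.

The benchmark configuration is a 1000-neuron directed ring (each neuron
drives its successor) with excitabilities drawn from Cauchy(η₀ = −2,
Δ = 0.1) and phases started evenly on the circle (|R(0)| = 0).  Almost all
neurons are strongly quiescent; the few excitable ones (≈ 1–2 %) drive
activity along the ring.  At κ = 1 the network is nearly fully coherent
(most neurons simply sit at their rest phase); at κ = 2 the steady-state
mean of |R| over the final 20 % of the run lands at ≈ 0.43–0.45 across
excitability draws — a half-coherent plateau.  The "steady-state" observable
is this tail mean rather than the final instantaneous |R|: the instantaneous
value of a 1000-dimensional phase system is not a numerically stable
quantity, while the plateau mean changes by well under 10⁻³ when the step
size is halved.

## Synthetic degree sequences

The generator draws (k_in, k_out) pairs from a Gaussian copula (latent
Pearson correlation 2·sin(πρ/6), giving Spearman rank correlation ≈ ρ) with
uniform or discrete power-law marginals on [k_min, k_max], then repairs the
generically unequal totals by unit adjustments of k_out at uniformly chosen
nodes within the bounds.  It emulates the degree structure used throughout
the experiments here (controlled range, controlled in/out correlation); it
does not emulate heavy-tailed real connectomes beyond the power-law option,
degree-degree assortativity between *different* nodes, or community
structure — so passing tests demonstrate correctness of the assembly
machinery on such sequences, not faithfulness to any particular real
network.

## Problem sizes in the test-suite

The bundled tests exercise: the exhaustive 3-node oracle (27 starts, all
branches, exact rationals); 50,000 sampled assemblies checked against the
exact distribution at 3 binomial standard errors per category; a
100,000-sample weighted spectral-radius estimate (1 % relative tolerance);
100 random 100-node sequences and one 500-node sequence (degrees 75–200,
binary and 50 % multi-edges) assembled to exact degree match; and the
1000-neuron ring benchmark with a ±0.15 band around |R| ≈ 0.5.  These sizes
were chosen as the smallest that make each statistical check sharp.

## Known limitations

* Dense matrices only; N ≳ 10⁴ would want a sparse column-indexed
  representation.
* The sampler's non-uniformity is corrected *per metric* by weights, not
  removed; weights of shuffled runs cover only their transfer steps.
* Multi-edge mode can still dead-end on adversarial small instances even
  with the concentration-avoiding allocator; such runs fail fast with a
  trace rather than being repaired.
* The exhaustive oracle is limited to ~4 nodes (binary mode) by design.
* The loop-free graphicality question (whether a stronger pre-test is
  needed) is left to runtime failure reporting.
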