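# Methods

## The restricted Boolean network model

A gene regulatory network over genes `x_1 … x_n` is represented by a
signed regulation matrix `A` with `a_ij ∈ {−1, 0, 1}`: `+1` for
activation of target `i` by regulator `j`, `−1` for inhibition, `0` for
no direct regulation. A network state is a binary vector
`S(t) = (x_1(t), …, x_n(t))`. The *input* of gene `i` is the integer

    u_i(t) = Σ_j a_ij · x_j(t),

and all genes update synchronously by the threshold rule

    x_i(t+1) = 1        if u_i(t) > 0
    x_i(t+1) = 0        if u_i(t) < 0
    x_i(t+1) = x_i(t)   if u_i(t) = 0 and gene i does not self-degrade
    x_i(t+1) = 0        if u_i(t) = 0 and gene i self-degrades.

Self-degradation is a per-gene boolean configuration (`d_i`), not an
entry of `A`. Only threshold functions are expressible — that is the
"restriction" — and it is what makes consistency with data a system of
*integer sign inequalities* rather than a search over all Boolean
functions: the candidate space per gene shrinks from `2^(2^n)` functions
to `3^n` rows, and the rows of `A` are mutually independent, so the
whole problem decomposes into `n` separate row problems.

Because dynamics are deterministic on a finite state space, every orbit
ends in a cycle (an *attractor*); the set of states whose orbits reach a
given attractor is its *basin*. `find_attractors` follows every orbit of
the full `2^n` state space (bound: 20 genes), so basin sizes always sum
to `2^n`. States are encoded as integers with gene index 0 as the most
significant bit; attractors are ordered by descending basin size with
ties broken by the lexicographically smallest cycle state, and each
cycle is rotated to start at that state. These conventions are arbitrary
but fixed, so reports are reproducible bit-for-bit.

## From transitions to constraints

A network is *consistent* with an observed series
`S(1) → … → S(m)` when one synchronous step maps each state to its
successor. Consistency of row `i` depends only on gene `i`'s column of
the transitions, giving per-gene constraint problems over variables
`a_i1 … a_in` with domains `⊆ {−1, 0, 1}`.

**Transition constraints** (complete). For the active set
`A(t) = {j : x_j(t) = 1}` and `Σ = Σ_{j∈A(t)} a_ij`:

| change | without self-degradation | with self-degradation |
|--------|--------------------------|-----------------------|
| 0 → 1  | `Σ ≥ 1`                  | `Σ ≥ 1`               |
| 0 → 0  | `Σ ≤ 0`                  | `Σ ≤ 0`               |
| 1 → 0  | `Σ ≤ −1`                 | `Σ ≤ 0`               |
| 1 → 1  | `Σ ≥ 0`                  | `Σ ≥ 1`               |

Strict bounds are normalised to non-strict integer form (`> 0` ⇒ `≥ 1`),
which makes propagation exact. A row satisfies all transition
constraints of a series **iff** it is consistent with the series (the
property suite verifies this equivalence against direct simulation).
A transition that no row can produce — a gene switching on out of the
all-zero state — is reported as an infeasibility naming the gene and
time; on noisy data the pipeline records the gene as infeasible instead
of aborting the run.

**Triplet restrictions** (implied). If two consecutive states differ in
exactly one gene `k`, any gene `i` that changes on the following step is
directly regulated by `k`, removing 0 from the domain of `a_ik`.

**Pairwise difference constraints** (implied). For two transitions of
the same gene whose constraints bound the input sum in opposite
directions, subtracting them cancels the shared active regulators and
bounds `D = Σ_{j∈P} a_ij − Σ_{j∈Q} a_ij` over the symmetric difference
`P = A(t_a)\A(t_b)`, `Q = A(t_b)\A(t_a)`. Same-direction pairs are
uninformative. By default difference constraints are generated for *all*
ordered transition pairs within a segment — they are sound consequences
either way and aid pruning during sampling; a `similar` scope (source
states within Hamming distance 1, the motivating special case) and `off`
are available. The implied families never change the solution set (this
redundancy is property-tested); they exist to propagate.

Group-level prior knowledge ("genes of phase P are not regulated by
genes of phase Q") compiles to entries pinned to domain `{0}` before
solving. Multiple segments (separate observed cycles) are solved
independently and their row sets pooled by default (union), matching the
use of independent cycles as replicate observations; an intersection
mode conjoins the constraints instead.

## Solving the row problems

*Enumeration* (default up to 13 genes ≈ 1.6M candidates): the
domain-restricted candidate grid is generated in lexicographic order
(−1 < 0 < 1) and filtered against every inequality with vectorised
integer arithmetic. This is exact, duplicate-free and canonical, and on
the 11-gene benchmark takes about 1.5 s for all genes together.

*Sampling* (any size): each draw restarts a depth-first descent with a
uniformly random variable order and uniformly random value order,
pruning a partial assignment as soon as some inequality's best
attainable completion misses its bound, and backtracking otherwise.
Draws are with replacement; a `distinct` mode deduplicates. A descent is
a complete search, so an exhausted first descent proves infeasibility,
which is returned as a flagged empty result. The descent distribution is
*approximately* uniform over solutions — solutions reachable through
wider subtrees are somewhat favoured (on the benchmark the sampled
zero-frequency of the top-ranked entry is 0.31 versus 0.356 under exact
enumeration) — which is accepted here because frequencies feed
classifications and ranks, not probability statements. Default sample
sizes are 100 rows per gene at benchmark scale and 10,000 at the scale
of a 20-gene expression study. All sampling is reproducible from one
integer seed; per-gene child seeds are spawned from it.

## Frequencies, classification, rank, induction

Over a row set, each entry `a_ij` has empirical frequencies of −1/0/+1
(summing to 1 exactly, since they are ratios of counts). A connection is

* **determined** — one value has frequency 1 (for arrows, the
  *determined-nonzero* count excludes a determined absence; both counts
  are reported, since a determined 0 cannot be drawn as an arrow);
* **partially determined** — exactly one value has frequency 0;
* **undetermined** — all three values occur.

Frequencies from enumerated sets are exact and seed-independent;
frequencies from samples are estimates, and every table carries the row
counts behind it. Finite samples miss rare values, so sample-based
classification counts are biased toward "more determined" relative to
exact enumeration — on the packaged benchmark exact enumeration gives 8
determined (nonzero) and 15 partially determined connections, while
small-sample bar charts can suggest a few more of each.

Undirected pairs are ranked by

    rank({i,j}) = inh(i←j) + act(i←j) + inh(j←i) + act(j←i)
                = 2 − freq0(a_ij) − freq0(a_ji) ∈ [0, 2],

descending, ties broken by the lexicographic gene-name pair; diagonal
entries are reported separately (a self-pair has one direction only).
Validation against a reference network counts the fraction of the top-k
pairs present in the reference's undirected edge set (direction- and
sign-agnostic). On the packaged benchmark this true-positive rate is
100% at k = 5 and 10 and never falls below 75% for k = 5…25.

*Induction*: for every non-determined entry and every value it still
takes, restrict the row set to rows with that value and sum the
determination weights (1 / 0.5 / 0) of all entries on the restriction.
Restricting can only remove values from a column, so determination is
monotone and every induction score is at least the unrestricted score.
The scan evaluates the `3g` single assignments (`g` = non-determined
entries) rather than all `3^g` joint assignments: the goal is the single
most informative wet-lab experiment, and the scores of single
assignments are what that decision needs.

## Preprocessing

Continuous profiles are binarized per gene at the arithmetic mean of the
gene's own profile, strictly-greater-than ("exceeding") semantics:
values equal to the mean map to 0. Constant profiles (all zeros after
thresholding) are flagged. Runs of consecutive states within Hamming
distance `h` of the run's first state (default `h = 0`, exact repeats;
"very similar" has no canonical definition, so the radius is an explicit
parameter) are collapsed to a per-gene majority vote (ties keep the
first state's bit) — these runs are resting attractor passages between
cycles — and the stretches between runs are returned as candidate cycle
segments. Which segments enter the analysis is the analyst's call (a
biologically compromised cycle should be dropped by hand, not by a
heuristic), so segment selection is an explicit argument, not automated.

## Synthetic benchmark generator

`GeneratorConfig` defaults mirror the packaged benchmark's conditions:
11 genes, edge density 0.25 (the benchmark matrix has 28 nonzero entries
of 121), balanced signs, self-degradation probability 0.45 (5 of 11
genes), 13 time points, no noise. Matrix entries are independent
(diagonal included — the model allows explicit self-edges), the initial
state is uniform, and optional noise flips each observed bit
independently after simulation — the simplest symmetric measurement-noise
model. The generator does **not** emulate autocorrelated probe noise,
unequal class balance of expression levels, or the attractor-heavy
sampling of real time courses; passing the recovery properties on
synthetic data therefore demonstrates algorithmic soundness (the
generating row is always recovered; no determined connection ever
contradicts the ground truth on noise-free data), not field performance
on microarray data.

## Numerical and degenerate-case choices

All constraint logic is integer-only; frequencies are exact ratios; no
tolerance enters any comparison except a 1e−12 slack in property tests
on floats. A single-state trajectory is vacuously consistent. An empty
reference edge set yields a true-positive rate of 0 with a warning. An
all-determined row set yields an empty induction scan. Enumeration above
the gene bound and exhaustive attractor search above 20 genes refuse
with explicit errors pointing to the scalable alternative.

## Known limitations

* The sampler is not exactly uniform over solutions; classification
  counts and ranks from samples inherit a mild, size-dependent bias.
* Union-mode pooling of segments treats each segment as an independent
  witness; rows need only explain one segment to enter the pool.
* Consistency uses successive states only; constraints spanning longer
  horizons (powers of the regulation matrix) are not generated.
* The model is synchronous and deterministic; asynchronous or
  probabilistic update schemes are out of scope.
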