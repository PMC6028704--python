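# Methods

## Model of the computation

The enumerator works on a purely topological abstraction of metabolism: a
directed bipartite graph with metabolite and reaction node partitions, where
a reaction is *fireable* once all of its input metabolites are available.
Stoichiometric coefficients are read and discarded — only presence/absence
of a metabolite in a reaction matters — so no flux balance, thermodynamic or
atom-mapping feasibility is implied by any result. A reversible model
reaction contributes two unidirectional reaction nodes (`id` and `id_rev`,
cross-linked as a pair); both halves may appear in one pathway, in which
case the pathway is flagged `contains_reversible_pair` rather than
suppressed, since silently excluding such sets would change counts in a way
the user cannot audit.

Seeds are assumed simultaneously and inexhaustibly available. This is the
intended way to handle currency metabolites (H⁺, H₂O, ATP, NAD(P)H, …):
placing them in the seed set removes their spurious shortcut effect without
deleting nodes, and reactions among seeds are allowed — their products
legitimately join the scope.

## Phase 1: guided BFS

Scope expansion is the classic network-expansion fixpoint. The
implementation is event-driven: each reaction carries a missing-precursor
counter; when a metabolite first enters the scope it decrements the counters
of its consumers, and a reaction whose counter reaches zero is queued on a
min-heap keyed by its readiness step, 1 + max(ℓ of its inputs). Because
pushed readiness values strictly exceed the step being popped, pops are
monotone (Dijkstra-style) and the assigned step counts are minimal
edge-distances from the seed frontier: seeds at ℓ = 0, seed-fed reactions at
ℓ = 1, their products at ℓ = 2, and so on. Total work is O(|E|) plus heap
overhead, and the result — scope, visited set, stuck set and all ℓ values —
is independent of adjacency order (tested by permutation).

A reaction is reported *stuck* when at least one input entered the scope (or
was a seed) but at least one precursor never did; reactions none of whose
inputs ever became available are reported *untouched*. Stuck reactions whose
missing precursors appear later are promoted to visited automatically by the
counter mechanism.

## Phase 2: enumeration semantics

The ground truth the table must reproduce is the **size-capped derivation
closure**: the least family of reaction sets containing the empty set for
every seed and closed under "pick a reaction r and one derived set per input
of r; their union plus r derives every output of r", restricted to sets of
at most β reactions. This is exactly the family of complete sub-networks the
definitions describe, and it has two properties worth making explicit:

* every member is *complete* — firing its reactions from the seeds on the
  induced subgraph visits all of them (checked as an invariant test); and
* the family is monotone in β — raising the cut-off never changes which
  sets of size ≤ β exist, only adds larger ones.

A literal single sweep of columns 2..β with partition entries capped at
k−1 does not quite reach this closure: a cyclic pathway can first surface
through a by-product at a column *beyond its own cardinality* (the smallest
counterexamples have four reactions and a multi-product reaction feeding a
loop), after the sweep has already passed the column where dependent
combinations would need it. The implementation therefore runs the column
sweep from 2 to β+1 and repeats it until no cell changes. A
(reaction, partition) pair is re-expanded only when one of its component
cells has grown since the last expansion — cells only ever grow, so
comparing cardinalities suffices — which keeps the repeated sweeps cheap.
Convergence is guaranteed because the store is bounded and monotone. The
fixpoint also makes the final table independent of reaction iteration
order; lexicographic order is used anyway so logs and outputs reproduce
byte-for-byte.

Candidates exceeding β are discarded at generation time instead of being
kept in overflow columns: under the fixpoint schedule a set larger than β
can never be a component of a stored result (components are themselves
capped at β), so retaining them would cost memory — cross products over
large cells at sums up to n·(k−1) — and buy nothing observable.

Partition generation is streamed: ordered tuples (p₁…p\_n) with p\_i drawn
from the columns currently known non-⊥ for input i, p\_i ≤ k−1, and
k−1 ≤ Σp\_i ≤ n·(k−1), produced by a depth-first generator with
suffix-min/max sum pruning, never materialised wholesale. Restricting p\_i
to non-⊥ columns is the main combinatorial control; cross products with an
unknown cell are vacuous by construction.

Two optimisations are deliberately output-neutral and are tested as such:

* **Step-count pruning.** A reaction r with ⌈ℓ\_r/2⌉ > k is skipped at
  column k: any complete pathway containing r needs at least ⌈ℓ\_r/2⌉
  reactions (its BFS layer in the induced subgraph cannot be smaller than
  the global one), and every combination skipped this way reappears at a
  later column of the same pass or the next pass.
* **Snapshot-free reuse.** Combinations read live cells; the fixpoint loop
  guarantees late-arriving content is re-offered, so no sweep schedule
  detail leaks into results.

The memory guard (default 10⁷ stored pathway entries, configurable) raises
a hard error naming the cell being filled; exhaustive enumeration is
worst-case exponential and failing loudly beats thrashing.

Cycle classification builds the digraph of the pathway's reactions and all
their metabolites and tests for a directed cycle. No seed exclusion is
applied: a metabolite can only lie on a cycle if some member produces it
*and* some member consumes it, so seeds never made by the pathway are
harmless, while a regenerated seed (a TCA-like loop re-making its primer)
correctly marks the pathway cyclic. Each cyclic reaction set is stored
once — set-union semantics deduplicate re-traversals of the loop.

## The naive oracle

`pathenum.oracle.naive_derivations` restates the closure directly: iterate
over all reactions, combine every choice of already-derived sets per input
via a cross product, keep unions of size ≤ β, repeat until stable. It shares
no code with the table machinery (no columns, no partitions, no pruning) and
serves as the independent reference in the equivalence tests: on 200+
randomised toy networks (≤ 10 model reactions, β ≤ 6) the DP's per-target,
per-size pathway sets are asserted identical to the oracle's. It is
exponential and intended for toy scale only.

## Community graphs and exchanges

Multi-organism graphs are joined through the extracellular compartment:
intracellular nodes receive an `orgN:` prefix (so identical namespaces —
e.g. two knockout strains of one reconstruction — cannot collide), while
extracellular metabolites keep their bare ids and merge by identity. A
reaction counts as an exchange if its id matches a configurable prefix list
(default `EX_`), it has an empty side (boundary), or it touches an
extracellular metabolite. Extracellular ids touched by exchange reactions of
≥ 2 organisms form the shared pool; exchange metabolites private to one
organism stay attached only to that organism. Periplasmic and all other
compartments remain per-organism — the join rule is deliberately confined to
the extracellular space, the only compartment with a defensible shared-pool
interpretation.

An exchange report (metabolite, donor, recipient) is emitted when a pathway
spans ≥ 2 organisms and contains a donor exchange reaction producing a
shared extracellular metabolite that a recipient reaction consumes. The
optional load-bearing check re-runs the completeness test on the recipient's
members alone: the exchange is load-bearing when they fail from the
original seeds but succeed once the exchanged metabolite is added. It is
opt-in because it costs one scope expansion per (report, witness).

## Synthetic fixtures

The toy generator is a pure function of its spec (kind, reaction count, RNG
seed, reversible fraction); identical specs give identical bytes. Structured
kinds (chain, parallel routes, branched join, cycle, two-organism
cross-feeding pair) carry exact expected pathway inventories by
construction. The `random` kind wires each new reaction to consume an
already-producible metabolite with probability 0.7 and a fresh orphan
otherwise (so both the fireable and the stuck branches of the BFS are
exercised), adds a second input 40 % of the time, a second product 30 % of
the time, and redirects outputs onto existing metabolites with probability
0.3 (creating cycles), within caps of 12 reactions and 8 metabolites; its
ground truth comes from the naive oracle at β = min(n, 6), the largest
cut-off at which the exponential reference stays comfortably tractable.

What the toys emulate is the combinatorial structure of pathway enumeration
— branching, convergence, cycles, by-product merges, stuck precursors,
reversible pairs. What they do not emulate: realistic stoichiometry, network
scale (thousands of reactions), compartmentalisation beyond the `_e` suffix
convention, or the degree distribution of genome-scale reconstructions.
Passing tests therefore certify algorithmic correctness of the enumeration
semantics, not biological plausibility of any particular model's output.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on generated toys:
200 random networks of 10 reactions at β ∈ {3..6} for oracle equivalence,
100 instances each for the scope-fixpoint and monotonicity properties —
sizes at which the exponential oracle is exact and the whole suite completes
in about two minutes. Checks that need full genome-scale reconstructions
(graph node/edge counts of published models, pathway counts at β = 15) are
kept in the suite but load their SBML inputs from `models/`, to be supplied
by the user; they are reproduction targets, not toy-scale properties.

Jaccard bins are closed-open `[lo, hi)` by default; the top edge of the
highest bin is inclusive so that a `[0.9, 1.0]`-style last bin captures
identical pairs, and range queries used for reproduction runs take an
explicit inclusive flag. Most-different-pair ties break by smallest combined
size, then lexicographic reaction ids. Jaccard of two empty sets is defined
as 1. All floating-point output is plain double precision; no tolerances
are involved anywhere in the enumeration itself, which is exact set
arithmetic.

## Known limitations

* Enumeration is exponential in β by nature; the memory guard bounds damage
  but large models at large β genuinely require hours and gigabytes.
* Results inherit every gap and artefact of the input reconstruction;
  an exchange predicted on a draft model may be a model artefact.
* No ranking, weighting or flux feasibility: every complete sub-network
  within the cut-off is reported equally. Downstream constraint-based or
  experimental triage is expected.
* GPR-based knockouts require fbc gene associations; models without them
  warn and knockouts become no-ops.
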