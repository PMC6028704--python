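# pathenum

Exhaustive enumeration of branched and cyclic biosynthetic pathways in
metabolic networks, for systems and synthetic biologists who want *every*
route — not just the shortest one — between a set of available metabolites
and a target compound, using nothing but network topology.

## The problem and the method

A metabolic reconstruction is represented as a directed **bipartite graph
G(M, R, E)**: metabolite nodes M, reaction nodes R, an edge m → r for every
reactant and r → m for every product. Reversible reactions become two
opposite reaction nodes. Given a **seed set S** (carbon sources plus
co-factors, co-enzymes and currency metabolites, all treated as freely
available), a **target set T** and a **size cut-off β**, the tool answers:
which reaction sets R′ ⊆ R of size |R′| ≤ β produce each target such that
every input of every member reaction is itself producible from S? Such sets
are *complete* sub-networks; they may be **branched** (several routes
converging on one reaction's inputs) or **cyclic** (a metabolite taking part
in its own production).

The computation runs in two phases:

1. **Guided BFS (scope).** Starting from S, fire every reaction whose
   inputs are all available, add its products, repeat to a fixpoint. This
   yields the scope M\_s ⊇ S, the visited reaction set R\_v, the reactions
   left *stuck* for want of a precursor, and shortest-path step counts
   ℓ\_m / ℓ\_r used later for pruning.
2. **Memoised dynamic programming (enumeration).** A table with one row per
   scoped metabolite and one column per size holds, at `Table[m][k]`, every
   pathway of size exactly k producing m (⊥ where none exists). Seeds get
   the empty pathway at column 0; column 1 holds singletons {r} for
   seed-fed reactions; higher columns are filled by picking, for each input
   of a reaction, one tabulated sub-pathway per an ordered integer
   **partition** (p₁…p\_n) of candidate sizes, taking the union and adding
   the reaction. Unions deduplicate shared reactions, so a merge can come
   out smaller than the sum of its parts — the sweep therefore covers
   partition sums up to n·(k−1) and files every pathway under its true
   cardinality. Sweeps repeat until a fixpoint, making the result exactly
   the size-capped derivation closure, independently reproduced by the
   naive recursive enumerator in `pathenum.oracle`.

Downstream analytics: Jaccard similarity |A∩B|/|A∪B| between pathways,
similarity spectra over all pairs, most-different pathway pairs, and — on
multi-organism **community graphs** joined through a shared extracellular
medium — detection of cross-fed metabolites (exported by one organism's
exchange reactions and consumed by another inside one pathway).

## Worked example

```
$ pathenum toy --kind branched_join --n 5 --out fixture
$ pathenum enumerate --model fixture/reactions.tsv --seeds fixture/seeds.txt \
      --all-scope --cutoff 5 --out run
enumerate: 5 pathways for 5 target(s), beta=5
$ cat run/pathways.jsonl
{"contains_reversible_pair": false, "is_cyclic": false, "reactions": ["a1"], "size": 1, "target": "ma1"}
{"contains_reversible_pair": false, "is_cyclic": false, "reactions": ["a1", "a2"], "size": 2, "target": "ma2"}
{"contains_reversible_pair": false, "is_cyclic": false, "reactions": ["b1"], "size": 1, "target": "mb1"}
{"contains_reversible_pair": false, "is_cyclic": false, "reactions": ["b1", "b2"], "size": 2, "target": "mb2"}
{"contains_reversible_pair": false, "is_cyclic": false, "reactions": ["a1", "a2", "b1", "b2", "join"], "size": 5, "target": "t"}
```

The fixture is two 2-step chains from the seed m0 converging on a final
`join` reaction. Each intermediate gets its chain prefix as its only
pathway, and the target `t` gets exactly one *branched* pathway containing
all five reactions — `join` alone is not complete because its two inputs
must themselves be made. Pairwise similarity over these five pathways:

```
$ pathenum similarity --pathways run/pathways.jsonl --out sim
similarity: 10 pairs over 5 pathways
```

with the histogram in `sim/histogram.json` showing e.g. 4 of the 10 pairs
at Jaccard < 0.2 (the disjoint a-chain/b-chain pairs).

The library API mirrors the CLI:

```python
from pathenum import build_graph, guided_bfs, enumerate_pathways, get_pathways
from pathenum.model import read_tsv_model

graph = build_graph(read_tsv_model("fixture/reactions.tsv"))
scope = guided_bfs(graph, {"m0"})
table = enumerate_pathways(graph, scope, scope.seeds, beta=5)
get_pathways(table, "t", graph=graph)
# [Pathway(size=5, reactions=('a1', 'a2', 'b1', 'b2', 'join'), ...)]
```

SBML Level 2/3 models are read through cobrapy (`read_sbml_model`), gene
knockouts are applied through fbc GPR rules (`apply_gene_knockout`), and
passing several `--model` files joins them into a community graph.

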