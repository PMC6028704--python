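"""Phase 2: exhaustive enumeration of branched and cyclic pathways.

A *pathway* (or sub-network) producing a metabolite m from a seed set S is a
set R' of reaction nodes such that m is an output of at least one member and
every input of every member is producible from S; its *size* is |R'|.  A
pathway is *cyclic* when some metabolite it produces takes part in its own
production.  The enumerator finds every distinct pathway of size at most the
cut-off β for every metabolite in the scope of S.

The computation is a memoised dynamic programme over a table with one row per
scoped metabolite and one column per pathway size.  ``Table[m][k]`` holds the
set of all pathways of size exactly k producing m; the absent entry is the
"unknown/impossible" sentinel ⊥ (represented as ``None``).  Column 0 holds the
empty pathway for every seed, column 1 the singleton pathways {r} for
reactions fireable directly from seeds.  Higher columns are filled by
combining, for each reaction r with inputs m_1..m_n, one already-tabulated
sub-pathway per input.  The combination space is organised by ordered integer
*partitions* (p_1..p_n): entry p_i picks the column of input m_i.  Because
merging is a set union, two sub-pathways sharing reactions (for example when
one reaction produces several inputs at once) collapse, so the merged size can
be smaller than 1 + Σ p_i; the partition sweep therefore covers sums all the
way up to n·(k−1) rather than stopping at k−1, and every stored pathway is
placed at the column equal to its true cardinality.

Column sweeps run from 2 to β+1 and are repeated until a fixpoint: a pathway
discovered late (cyclic routes can first surface through a by-product at a
column beyond their own size) is then re-offered to every combination that
could extend it.  On return the table is exhaustive: it holds exactly the
derivation closure of the seed set capped at size β, the same set produced by
the naive recursive enumerator in :mod:`pathenum.oracle`.  Candidates larger
than β are discarded on the spot — they can never appear in a result nor seed
a combination whose result is within the cut-off.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass

from .graph import BipartiteGraph, induced_subgraph
from .scope import ScopeResult, guided_bfs

__all__ = [
    "Pathway",
    "PathwayTable",
    "MemoryGuardExceeded",
    "generate_partitions",
    "populate_table",
    "enumerate_pathways",
    "get_pathways",
    "classify_cyclic",
    "pathway_is_complete",
    "write_pathways_jsonl",
    "write_pathways_tsv",
    "write_pathway_dot",
]


class MemoryGuardExceeded(RuntimeError):
    """Raised when the total number of stored pathways exceeds the cap."""


@dataclass(frozen=True, order=True)
class Pathway:
    """An immutable reaction set annotated for reporting."""

    size: int
    reactions: tuple[str, ...]
    is_cyclic: bool = False
    contains_reversible_pair: bool = False
    target: str = ""

    @property
    def reaction_set(self) -> frozenset[str]:
        return frozenset(self.reactions)


class PathwayTable:
    """The |M_s| × (β+1) memoisation table of pathway sets.

    ``get(m, k)`` returns ``None`` for the ⊥ sentinel ("no pathway of exactly
    this size is known/possible"), otherwise the set of reaction-id frozensets
    of size exactly k producing m.
    """

    def __init__(self, beta: int, seeds, max_pathways: int = 10_000_000):
        if beta < 1:
            raise ValueError(f"size cut-off beta must be >= 1, got {beta}")
        self.beta = int(beta)
        self.seeds = frozenset(seeds)
        self.max_pathways = int(max_pathways)
        self.n_stored = 0
        self._cells: dict[str, dict[int, set[frozenset[str]]]] = {}
        for s in self.seeds:
            self._cells[s] = {0: {frozenset()}}
            self.n_stored += 1

    def get(self, metabolite_id: str, k: int):
        return self._cells.get(metabolite_id, {}).get(k)

    def sizes(self, metabolite_id: str) -> list[int]:
        """Sorted columns that are not ⊥ for this metabolite."""
        return sorted(self._cells.get(metabolite_id, {}))

    def insert(self, metabolite_id: str, reaction_set: frozenset[str]) -> bool:
        """Store *reaction_set* at its exact-size column; True if new."""
        k = len(reaction_set)
        cell = self._cells.setdefault(metabolite_id, {}).setdefault(k, set())
        if reaction_set in cell:
            return False
        if self.n_stored >= self.max_pathways:
            raise MemoryGuardExceeded(
                f"pathway store exceeded {self.max_pathways} entries while filling "
                f"cell ({metabolite_id!r}, {k})"
            )
        cell.add(reaction_set)
        self.n_stored += 1
        return True

    def metabolites(self):
        return sorted(self._cells)


def _bounded_tuples(choices, lo, hi):
    """Yield ordered tuples picking one value per position from *choices*
    (each a sorted list of ints) with total sum in [lo, hi]."""
    n = len(choices)
    suffix_min = [0] * (n + 1)
    suffix_max = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix_min[i] = suffix_min[i + 1] + choices[i][0]
        suffix_max[i] = suffix_max[i + 1] + choices[i][-1]

    def rec(i, acc, prefix):
        if i == n:
            if lo <= acc <= hi:
                yield tuple(prefix)
            return
        for v in choices[i]:
            total = acc + v
            if total + suffix_min[i + 1] > hi:
                break  # choices sorted ascending: larger v only worse
            if total + suffix_max[i + 1] < lo:
                continue
            prefix.append(v)
            yield from rec(i + 1, total, prefix)
            prefix.pop()

    if n and all(choices):
        yield from rec(0, 0, [])


def generate_partitions(n: int, k: int, feasible_sizes):
    """Stream the ordered partitions for an n-input reaction at column k.

    Each yielded tuple (p_1..p_n) satisfies p_i ∈ feasible_sizes[i],
    p_i ≤ k−1 and k−1 ≤ Σ p_i ≤ n·(k−1); position i binds to input i.  An
    input with no feasible size yields an empty stream (the reaction cannot
    be combined at this column).  Tuples are generated lazily and never
    repeated.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 2:
        raise ValueError("k must be >= 2")
    feasible = [sorted(v for v in sizes if v <= k - 1) for sizes in feasible_sizes]
    if len(feasible) != n:
        raise ValueError("feasible_sizes must have one entry per input")
    if any(not f for f in feasible):
        return
    yield from _bounded_tuples(feasible, k - 1, n * (k - 1))


def populate_table(table: PathwayTable, reaction_id: str, partition, inputs, outputs) -> bool:
    """Merge one sub-pathway per input according to *partition* and record results.

    For every element of the cross product of ``Table[inputs[i]][partition[i]]``
    the union of the chosen sub-pathways plus the reaction itself forms a new
    pathway; its size j is the cardinality of the union (set semantics may
    deduplicate shared reactions, making j smaller than 1 + Σ partition).  The
    pathway is stored at column j for every output of the reaction, provided
    j does not exceed the cut-off.  Returns True if anything new was stored.
    """
    cells = []
    for m, p in zip(inputs, partition):
        cell = table.get(m, p)
        if cell is None:
            raise ValueError(f"Table[{m!r}][{p}] is unknown (⊥); partition violates its precondition")
        cells.append(sorted(cell))  # snapshot, deterministic order
    changed = False
    beta = table.beta
    radd = frozenset((reaction_id,))
    for combo in itertools.product(*cells):
        merged = frozenset().union(*combo) | radd
        if len(merged) > beta:
            continue
        for y in outputs:
            if table.insert(y, merged):
                changed = True
    return changed


def enumerate_pathways(
    graph: BipartiteGraph,
    scope_result: ScopeResult,
    seeds,
    beta: int,
    prune: bool = True,
    max_pathways: int = 10_000_000,
    progress=None,
) -> PathwayTable:
    """Fill the pathway table for every scoped metabolite up to size *beta*.

    *scope_result* must come from :func:`pathenum.scope.guided_bfs` on the
    same graph and seed set.  With ``prune`` enabled, a reaction whose minimum
    number of preceding reaction layers (⌈ℓ_r / 2⌉ from the BFS step counts)
    exceeds the current column is skipped; the pruning is output-neutral.
    The memory guard raises :class:`MemoryGuardExceeded` once more than
    *max_pathways* pathway entries are stored.  *progress*, if given, is
    called after every column sweep with ``(sweep, column, pathways_stored)``
    so long enumerations stay observable.
    """
    seeds = frozenset(seeds)
    table = PathwayTable(beta, seeds, max_pathways=max_pathways)
    visited = sorted(scope_result.visited_reactions)

    # column 1: reactions fireable from seeds alone
    for rid in visited:
        rxn = graph.reactions[rid]
        if rxn.inputs <= seeds:
            for y in rxn.outputs:
                table.insert(y, frozenset((rid,)))

    min_layer = {rid: math.ceil(scope_result.steps_reaction[rid] / 2) for rid in visited}
    inputs_of = {rid: tuple(sorted(graph.reactions[rid].inputs)) for rid in visited}
    outputs_of = {rid: tuple(sorted(graph.reactions[rid].outputs)) for rid in visited}
    # (reaction, partition) pairs whose component cells have not grown since
    # they were last expanded contribute nothing new and are skipped.
    seen_state: dict[tuple, tuple[int, ...]] = {}

    changed = True
    sweep = 0
    while changed:
        changed = False
        sweep += 1
        for k in range(2, beta + 2):
            for rid in visited:
                if prune and min_layer[rid] > k:
                    continue
                inputs = inputs_of[rid]
                if not inputs:
                    continue  # boundary uptake: already placed at column 1
                feasible = [table.sizes(m) for m in inputs]
                if any(not f for f in feasible):
                    continue
                for partition in generate_partitions(len(inputs), k, feasible):
                    state = tuple(len(table.get(m, p)) for m, p in zip(inputs, partition))
                    key = (rid, partition)
                    if seen_state.get(key) == state:
                        continue
                    seen_state[key] = state
                    if populate_table(table, rid, partition, inputs, outputs_of[rid]):
                        changed = True
            if progress is not None:
                progress(sweep, k, table.n_stored)
    return table


def classify_cyclic(pathway_reactions, graph: BipartiteGraph, seeds=frozenset()) -> bool:
    """True iff some metabolite made by the pathway takes part in its own production.

    Checked as a directed cycle in the metabolite/reaction digraph restricted
    to the member reactions and their metabolites.  A metabolite can only lie
    on a cycle if it is both produced and consumed by members, so seed
    metabolites never made by the pathway cannot close one; a seed that the
    pathway regenerates can (e.g. {A→B, B→A} from seed A is cyclic).
    """
    import networkx as nx

    g = nx.DiGraph()
    for rid in pathway_reactions:
        rxn = graph.reactions[rid]
        for m in rxn.inputs:
            g.add_edge(m, rid)
        for m in rxn.outputs:
            g.add_edge(rid, m)
    return not nx.is_directed_acyclic_graph(g)


def _contains_reversible_pair(reaction_set, graph: BipartiteGraph) -> bool:
    for rid in reaction_set:
        pair = graph.reactions[rid].pair_id
        if pair and pair in reaction_set:
            return True
    return False


def pathway_is_complete(graph: BipartiteGraph, pathway_reactions, seeds) -> bool:
    """Check completeness: on the subgraph induced by the pathway's reactions,
    guided BFS from the original seeds must visit every member reaction."""
    sub = induced_subgraph(graph, pathway_reactions)
    present_seeds = frozenset(seeds) & sub.metabolites.keys()
    if not present_seeds:
        return False
    result = guided_bfs(sub, present_seeds)
    return set(pathway_reactions) <= result.visited_reactions


def get_pathways(
    table: PathwayTable,
    target: str,
    beta: int | None = None,
    graph: BipartiteGraph | None = None,
) -> list[Pathway]:
    """All pathways of size 1..beta producing *target*, deterministically ordered.

    The empty pathway a seed holds at column 0 is excluded; nontrivial cyclic
    pathways regenerating a seed are still listed.  Cycle and reversible-pair
    flags require *graph*; without it they default to False.  An unknown or
    out-of-scope target yields an empty list with a warning.
    """
    beta = table.beta if beta is None else min(beta, table.beta)
    sizes = table.sizes(target)
    if not sizes:
        warnings.warn(f"no pathways recorded for '{target}' (outside the scope?)", stacklevel=2)
        return []
    out = []
    for k in sizes:
        if not 1 <= k <= beta:
            continue
        for rset in sorted(table.get(target, k)):
            reactions = tuple(sorted(rset))
            cyc = classify_cyclic(reactions, graph) if graph is not None else False
            rev = _contains_reversible_pair(rset, graph) if graph is not None else False
            out.append(Pathway(k, reactions, cyc, rev, target))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# output formats

def write_pathways_jsonl(pathways, path) -> None:
    """One JSON object per line: target, size, reactions, flags."""
    with open(str(path), "w", encoding="utf-8") as fh:
        for p in pathways:
            fh.write(
                json.dumps(
                    {
                        "target": p.target,
                        "size": p.size,
                        "reactions": list(p.reactions),
                        "is_cyclic": p.is_cyclic,
                        "contains_reversible_pair": p.contains_reversible_pair,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_pathways_jsonl(path) -> list[Pathway]:
    out = []
    with open(str(path), encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(
                Pathway(
                    d["size"],
                    tuple(d["reactions"]),
                    d.get("is_cyclic", False),
                    d.get("contains_reversible_pair", False),
                    d.get("target", ""),
                )
            )
    return out


def write_pathways_tsv(pathways, path) -> None:
    with open(str(path), "w", encoding="utf-8") as fh:
        fh.write("target\tsize\tis_cyclic\tcontains_reversible_pair\treactions\n")
        for p in pathways:
            fh.write(
                f"{p.target}\t{p.size}\t{int(p.is_cyclic)}\t"
                f"{int(p.contains_reversible_pair)}\t{';'.join(p.reactions)}\n"
            )


def write_pathway_dot(pathway: Pathway, graph: BipartiteGraph, path) -> None:
    """Render one pathway as a bipartite subgraph in DOT (reactions as boxes)."""
    sub = induced_subgraph(graph, pathway.reactions)
    sub.write_dot(path)
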