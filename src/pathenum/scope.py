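"""Phase 1: precursor-guided breadth-first expansion from a seed set.

Starting from a set S of seed metabolites (assumed simultaneously and
inexhaustibly available — sources plus co-factors, co-enzymes and currency
metabolites), the traversal fires every reaction whose inputs are all
available, adds its products to the available pool, and repeats until no
further reaction can fire.  The result is the *scope* M_s ⊇ S (everything the
network can make from S), the set R_v of *visited* reactions, and the set of
*stuck* reactions — reactions that were examined because at least one of their
precursors became available but that still lack one or more precursors at
termination.  A stuck reaction whose missing precursors appear later is
automatically promoted to visited.

Alongside membership, the traversal records step counts: the number of edges
on a shortest alternating metabolite/reaction path from the seed frontier.
Seeds have step 0, a reaction fireable directly from seeds has step 1, its
products step 2, and so on (reaction steps are odd, metabolite steps even).
These step counts do not equal the number of reactions needed to make a
metabolite; they are used only to prune hopeless reactions during phase-2
enumeration.

Implementation: event-driven propagation with a per-reaction missing-precursor
counter and a min-heap keyed on readiness (1 + the largest step among the
reaction's inputs), which makes the result independent of adjacency order.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

from .graph import BipartiteGraph

__all__ = [
    "ScopeResult",
    "SeedError",
    "guided_bfs",
    "check_target_reachability",
    "stuck_producers",
    "read_seed_file",
    "write_scope_report",
]


class SeedError(ValueError):
    """Raised for an empty seed set or seed ids absent from the graph."""


@dataclass(frozen=True)
class ScopeResult:
    """Outcome of the guided BFS."""

    scope: frozenset[str]
    visited_reactions: frozenset[str]
    stuck_reactions: frozenset[str]
    steps_metabolite: dict[str, int]
    steps_reaction: dict[str, int]
    seeds: frozenset[str]

    def status_of(self, reaction_id: str) -> str:
        if reaction_id in self.visited_reactions:
            return "visited"
        if reaction_id in self.stuck_reactions:
            return "stuck"
        return "untouched"


def _validate_seeds(graph: BipartiteGraph, seeds) -> frozenset[str]:
    seeds = frozenset(seeds)
    if not seeds:
        raise SeedError("seed set is empty")
    unknown = sorted(seeds - graph.metabolites.keys())
    if unknown:
        raise SeedError(f"seed metabolite(s) not in graph: {unknown}")
    return seeds


def guided_bfs(graph: BipartiteGraph, seeds) -> ScopeResult:
    """Compute the scope of *seeds* in *graph*.

    Returns a :class:`ScopeResult` at the expansion fixpoint: no reaction
    outside ``visited_reactions`` has all of its inputs in ``scope``.
    Total work is O(|E|): each edge decrements a counter at most once.
    """
    seeds = _validate_seeds(graph, seeds)
    steps_m: dict[str, int] = {s: 0 for s in seeds}
    steps_r: dict[str, int] = {}
    scope: set[str] = set(seeds)
    visited: set[str] = set()
    examined: set[str] = set()

    missing = {rid: len(rxn.inputs - seeds) for rid, rxn in graph.reactions.items()}
    heap: list[tuple[int, str]] = []
    for rid in graph.reactions:
        if missing[rid] == 0:
            heapq.heappush(heap, (1, rid))

    while heap:
        step, rid = heapq.heappop(heap)
        if rid in visited:
            continue
        visited.add(rid)
        steps_r[rid] = step
        for product in sorted(graph.reactions[rid].outputs):
            if product in scope:
                continue
            scope.add(product)
            steps_m[product] = step + 1
            for consumer in graph.consumers_of(product):
                examined.add(consumer)
                missing[consumer] -= 1
                if missing[consumer] == 0 and consumer not in visited:
                    ready = 1 + max(steps_m[m] for m in graph.reactions[consumer].inputs)
                    heapq.heappush(heap, (ready, consumer))

    for rid, rxn in graph.reactions.items():
        if rxn.inputs & seeds:
            examined.add(rid)
    stuck = frozenset(rid for rid in examined - visited if missing[rid] > 0)
    return ScopeResult(
        scope=frozenset(scope),
        visited_reactions=frozenset(visited),
        stuck_reactions=stuck,
        steps_metabolite=steps_m,
        steps_reaction=steps_r,
        seeds=seeds,
    )


def check_target_reachability(scope_result: ScopeResult, targets, graph: BipartiteGraph | None = None):
    """Map each target id to whether it lies in the computed scope.

    Unknown target ids map to False with a warning.  When *graph* is given,
    the warning for an unreachable target names the stuck reactions that
    could produce it (the nearest blockers).
    """
    result: dict[str, bool] = {}
    for target in sorted(set(targets)):
        reachable = target in scope_result.scope
        result[target] = reachable
        if not reachable:
            if graph is not None and target not in graph.metabolites:
                warnings.warn(f"target '{target}' is not a metabolite of the graph", stacklevel=2)
            elif graph is not None:
                blockers = stuck_producers(scope_result, graph, target)
                warnings.warn(
                    f"target '{target}' unreachable from seeds"
                    + (f"; stuck producing reactions: {blockers}" if blockers else ""),
                    stacklevel=2,
                )
            else:
                warnings.warn(f"target '{target}' unreachable from seeds", stacklevel=2)
    return result


def stuck_producers(scope_result: ScopeResult, graph: BipartiteGraph, target: str) -> list[str]:
    """Stuck reactions having *target* among their outputs (nearest blockers)."""
    return sorted(
        rid for rid in graph.producers_of(target) if rid in scope_result.stuck_reactions
    )


def read_seed_file(path) -> frozenset[str]:
    """Read a seed list: one metabolite id per line, '#' starts a comment."""
    seeds: set[str] = set()
    with open(str(path), encoding="utf-8") as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                seeds.add(entry)
    if not seeds:
        raise SeedError(f"{path}: no seed metabolites found")
    return frozenset(seeds)


def write_scope_report(scope_result: ScopeResult, graph: BipartiteGraph, path) -> None:
    """Write the TSV scope report (metabolite block, then reaction block)."""
    with open(str(path), "w", encoding="utf-8") as fh:
        fh.write("node_id\tkind\tstatus\tsteps\n")
        for mid in graph.metabolites:
            in_scope = mid in scope_result.scope
            steps = scope_result.steps_metabolite.get(mid, "")
            fh.write(f"{mid}\tmetabolite\t{'in_scope' if in_scope else 'out_of_scope'}\t{steps}\n")
        for rid in graph.reactions:
            status = scope_result.status_of(rid)
            steps = scope_result.steps_reaction.get(rid, "")
            fh.write(f"{rid}\treaction\t{status}\t{steps}\n")
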