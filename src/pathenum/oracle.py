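"""Naive reference enumerator used to validate the dynamic programme.

This module restates the pathway semantics as directly as possible, with none
of the table/partition machinery: starting from the empty pathway for every
seed, repeatedly apply the single derivation rule

    pick a reaction r and, for each input of r, any already-derived pathway
    for that input; their union plus r is a pathway for every output of r

keeping only reaction sets of size at most β, until nothing new appears.
The result is the size-capped derivation closure — the ground truth the
memoised enumerator must reproduce exactly, per metabolite and per size.

Intended for small networks only (the closure is worst-case exponential);
fixture generation and the equivalence tests keep inputs at toy scale.
"""

from __future__ import annotations

import itertools

from .graph import BipartiteGraph

__all__ = ["naive_derivations", "pathways_by_size"]


def naive_derivations(graph: BipartiteGraph, seeds, beta: int) -> dict[str, set[frozenset[str]]]:
    """Map every metabolite to all derivable reaction sets of size ≤ *beta*.

    Seeds additionally carry the empty set (no reaction needed).  Metabolites
    with no derivation map to an empty set.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    seeds = frozenset(seeds)
    paths: dict[str, set[frozenset[str]]] = {m: set() for m in graph.metabolites}
    for s in seeds:
        if s in paths:
            paths[s].add(frozenset())
    changed = True
    while changed:
        changed = False
        for rid in sorted(graph.reactions):
            rxn = graph.reactions[rid]
            pools = [sorted(paths[m]) for m in sorted(rxn.inputs)]
            if any(not pool for pool in pools):
                continue
            radd = frozenset((rid,))
            for combo in itertools.product(*pools):
                merged = frozenset().union(*combo) | radd
                if len(merged) > beta:
                    continue
                for y in rxn.outputs:
                    if merged not in paths[y]:
                        paths[y].add(merged)
                        changed = True
    return paths


def pathways_by_size(derivations: set[frozenset[str]]) -> dict[int, set[frozenset[str]]]:
    """Group reaction sets by cardinality, dropping the empty (seed) pathway."""
    out: dict[int, set[frozenset[str]]] = {}
    for rset in derivations:
        if rset:
            out.setdefault(len(rset), set()).add(rset)
    return out
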