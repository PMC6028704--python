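"""Directed bipartite metabolite/reaction graphs.

A metabolic network is represented as a directed bipartite graph G(M, R, E):
one node per metabolite, one node per reaction, an edge m -> r for every
reactant m of r and an edge r -> m for every product m.  Reversible model
reactions are split into two reaction nodes — the forward node keeps the model
id, the reverse node appends ``_rev`` and swaps inputs and outputs — so every
reaction node is unidirectional.

Community graphs join several organisms through a shared extracellular
medium: intracellular nodes are prefixed with an organism label
(``org1:PFK``), extracellular metabolites keep their bare id, and the ones
touched by exchange reactions of at least two organisms form the shared pool
through which cross-feeding can be detected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .model import MetabolicModel

__all__ = [
    "MetaboliteNode",
    "ReactionNode",
    "BipartiteGraph",
    "CommunityGraph",
    "GraphConstructionError",
    "build_graph",
    "build_community_graph",
    "induced_subgraph",
]

REVERSE_SUFFIX = "_rev"
DEFAULT_EXCHANGE_PREFIXES = ("EX_",)


class GraphConstructionError(ValueError):
    """Raised when a model cannot be turned into a well-formed bipartite graph."""


@dataclass(frozen=True)
class MetaboliteNode:
    id: str
    organism_tag: str = ""
    is_extracellular: bool = False


@dataclass(frozen=True)
class ReactionNode:
    id: str
    inputs: frozenset[str]
    outputs: frozenset[str]
    direction_role: str = "irreversible"  # irreversible | forward_of_pair | reverse_of_pair
    pair_id: str = ""
    is_exchange: bool = False
    organism_tag: str = ""


class BipartiteGraph:
    """Immutable-ish container for G(M, R, E) with adjacency indexes.

    Node dictionaries are keyed by id and kept in lexicographic order so that
    every iteration over the graph is deterministic.
    """

    def __init__(self, metabolites, reactions):
        self.metabolites: dict[str, MetaboliteNode] = {
            m.id: m for m in sorted(metabolites, key=lambda n: n.id)
        }
        self.reactions: dict[str, ReactionNode] = {
            r.id: r for r in sorted(reactions, key=lambda n: n.id)
        }
        overlap = self.metabolites.keys() & self.reactions.keys()
        if overlap:
            raise GraphConstructionError(f"ids used for both metabolite and reaction: {sorted(overlap)}")
        self._producers: dict[str, tuple[str, ...]] = {}
        self._consumers: dict[str, tuple[str, ...]] = {}
        prod: dict[str, list[str]] = {m: [] for m in self.metabolites}
        cons: dict[str, list[str]] = {m: [] for m in self.metabolites}
        for rid, rxn in self.reactions.items():
            for m in rxn.inputs | rxn.outputs:
                if m not in self.metabolites:
                    raise GraphConstructionError(
                        f"reaction '{rid}' references undeclared metabolite '{m}'"
                    )
            for m in rxn.outputs:
                prod[m].append(rid)
            for m in rxn.inputs:
                cons[m].append(rid)
        self._producers = {m: tuple(v) for m, v in prod.items()}
        self._consumers = {m: tuple(v) for m, v in cons.items()}

    # -- queries ----------------------------------------------------------
    def producers_of(self, metabolite_id: str) -> tuple[str, ...]:
        """Reaction ids having *metabolite_id* among their outputs."""
        return self._producers.get(metabolite_id, ())

    def consumers_of(self, metabolite_id: str) -> tuple[str, ...]:
        return self._consumers.get(metabolite_id, ())

    @property
    def edges(self):
        """Directed (source, target) pairs, metabolite->reaction and reaction->metabolite."""
        for rid, rxn in self.reactions.items():
            for m in sorted(rxn.inputs):
                yield (m, rid)
            for m in sorted(rxn.outputs):
                yield (rid, m)

    @property
    def n_nodes(self) -> int:
        return len(self.metabolites) + len(self.reactions)

    @property
    def n_edges(self) -> int:
        return sum(len(r.inputs) + len(r.outputs) for r in self.reactions.values())

    # -- export -----------------------------------------------------------
    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for mid, node in self.metabolites.items():
            g.add_node(mid, bipartite="metabolite",
                       organism=node.organism_tag, extracellular=node.is_extracellular)
        for rid, node in self.reactions.items():
            g.add_node(rid, bipartite="reaction",
                       organism=node.organism_tag, exchange=node.is_exchange)
        g.add_edges_from(self.edges)
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))

    def write_dot(self, path) -> None:
        """Write a Graphviz DOT rendering: reactions as boxes, metabolites as circles."""
        with open(str(path), "w", encoding="utf-8") as fh:
            fh.write("digraph metabolic {\n  rankdir=LR;\n")
            for mid in self.metabolites:
                fh.write(f'  "{mid}" [shape=ellipse, bipartite=metabolite];\n')
            for rid in self.reactions:
                fh.write(f'  "{rid}" [shape=box, bipartite=reaction];\n')
            for src, dst in self.edges:
                fh.write(f'  "{src}" -> "{dst}";\n')
            fh.write("}\n")


class CommunityGraph(BipartiteGraph):
    """A bipartite graph joining several organisms through a shared medium."""

    def __init__(self, metabolites, reactions, organisms, shared_extracellular_ids):
        super().__init__(metabolites, reactions)
        self.organisms: tuple[str, ...] = tuple(organisms)
        self.shared_extracellular_ids: frozenset[str] = frozenset(shared_extracellular_ids)


def _reaction_is_exchange(reactants, products, rid, extracellular, prefixes) -> bool:
    if any(rid.startswith(p) for p in prefixes):
        return True
    if not reactants or not products:  # boundary reaction
        return True
    return bool((reactants | products) & extracellular)


def _split_reactions(model: MetabolicModel, prefixes) -> list[ReactionNode]:
    nodes: list[ReactionNode] = []
    ids = set(model.reaction_ids)
    for rxn in model.reactions:
        exch = _reaction_is_exchange(rxn.reactants, rxn.products, rxn.id, model.extracellular, prefixes)
        if not exch and (not rxn.reactants or not rxn.products):
            raise GraphConstructionError(
                f"internal reaction '{rxn.id}' has an empty reactant or product side"
            )
        if rxn.reversible:
            rev_id = rxn.id + REVERSE_SUFFIX
            if rev_id in ids:
                raise GraphConstructionError(
                    f"cannot split reversible '{rxn.id}': id '{rev_id}' already exists"
                )
            nodes.append(ReactionNode(rxn.id, rxn.reactants, rxn.products,
                                      "forward_of_pair", rev_id, exch))
            nodes.append(ReactionNode(rev_id, rxn.products, rxn.reactants,
                                      "reverse_of_pair", rxn.id, exch))
        else:
            nodes.append(ReactionNode(rxn.id, rxn.reactants, rxn.products,
                                      "irreversible", "", exch))
    return nodes


def build_graph(model: MetabolicModel, exchange_prefixes=DEFAULT_EXCHANGE_PREFIXES) -> BipartiteGraph:
    """Build the directed bipartite graph of a single-organism model.

    Reversible reactions become two reaction nodes with swapped input/output
    sets.  Raises :class:`GraphConstructionError` for a model with zero
    reactions or a reaction referencing an undeclared metabolite.
    """
    if not model.reactions:
        raise GraphConstructionError(f"model '{model.name}' has zero reactions")
    for rxn in model.reactions:
        missing = (rxn.reactants | rxn.products) - model.metabolites
        if missing:
            raise GraphConstructionError(
                f"reaction '{rxn.id}' references undeclared metabolite(s) {sorted(missing)}"
            )
    mets = [
        MetaboliteNode(m, "", m in model.extracellular)
        for m in sorted(model.metabolites)
    ]
    return BipartiteGraph(mets, _split_reactions(model, exchange_prefixes))


def build_community_graph(
    models,
    labels=None,
    exchange_prefixes=DEFAULT_EXCHANGE_PREFIXES,
) -> CommunityGraph:
    """Join ≥1 organism models through their common extracellular medium.

    Intracellular nodes get a ``label:`` prefix so identical namespaces (for
    example two strains of the same reconstruction) never collide.
    Extracellular metabolites are never prefixed; ids appearing in exchange
    reactions of two or more organisms merge into one shared node and are
    recorded in ``shared_extracellular_ids``.  Exchange metabolites unique to
    one organism stay attached only to that organism's exchange reactions.
    """
    models = list(models)
    if not models:
        raise GraphConstructionError("no models given")
    if labels is None:
        labels = [f"org{i + 1}" for i in range(len(models))]
    labels = [str(lbl) for lbl in labels]
    if len(labels) != len(models):
        raise GraphConstructionError("number of labels must match number of models")
    if len(set(labels)) != len(labels):
        raise GraphConstructionError(f"duplicate organism labels: {labels}")

    met_nodes: dict[str, MetaboliteNode] = {}
    rxn_nodes: list[ReactionNode] = []
    exchange_touched: dict[str, set[str]] = {}  # extracellular metabolite -> organism labels

    for label, model in zip(labels, models):
        graph = build_graph(model, exchange_prefixes)
        if not any(r.is_exchange for r in graph.reactions.values()):
            warnings.warn(
                f"model '{model.name}' ({label}) has no identifiable exchange reactions; "
                "it is joined with zero shared metabolites",
                stacklevel=2,
            )

        def rename(mid: str) -> str:
            return mid if graph.metabolites[mid].is_extracellular else f"{label}:{mid}"

        for mid, node in graph.metabolites.items():
            new_id = rename(mid)
            if node.is_extracellular:
                met_nodes.setdefault(new_id, MetaboliteNode(new_id, "", True))
            else:
                met_nodes[new_id] = MetaboliteNode(new_id, label, False)
        for rid, node in graph.reactions.items():
            new_rid = f"{label}:{rid}"
            pair = f"{label}:{node.pair_id}" if node.pair_id else ""
            rxn_nodes.append(
                ReactionNode(
                    new_rid,
                    frozenset(rename(m) for m in node.inputs),
                    frozenset(rename(m) for m in node.outputs),
                    node.direction_role,
                    pair,
                    node.is_exchange,
                    label,
                )
            )
            if node.is_exchange:
                for m in node.inputs | node.outputs:
                    if graph.metabolites[m].is_extracellular:
                        exchange_touched.setdefault(m, set()).add(label)

    shared = {m for m, orgs in exchange_touched.items() if len(orgs) >= 2}
    return CommunityGraph(met_nodes.values(), rxn_nodes, labels, shared)


def induced_subgraph(graph: BipartiteGraph, reaction_ids) -> BipartiteGraph:
    """The bipartite subgraph of the given reactions plus all their metabolites."""
    reaction_ids = set(reaction_ids)
    missing = reaction_ids - graph.reactions.keys()
    if missing:
        raise KeyError(f"unknown reaction id(s): {sorted(missing)}")
    rxns = [graph.reactions[rid] for rid in sorted(reaction_ids)]
    met_ids = set()
    for r in rxns:
        met_ids |= r.inputs | r.outputs
    mets = [graph.metabolites[m] for m in sorted(met_ids)]
    cls = BipartiteGraph
    sub = cls(mets, rxns)
    return sub
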