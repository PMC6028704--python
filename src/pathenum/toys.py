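"""Programmatic toy metabolic networks with known pathway inventories.

Every generator is a pure function of its :class:`ToySpec`: the same spec
always yields byte-identical fixtures.  Structured kinds (chains, parallel
routes, branched joins, cycles, a two-organism cross-feeding pair) carry
their exact expected pathway sets by construction; the ``random`` kind wires
reactions stochastically — biased so that most consume something already
producible, with occasional orphan precursors (exercising stuck-reaction
handling) and occasional back-edges (creating cycles) — and derives its
ground truth from the naive reference enumerator.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path

from .graph import BipartiteGraph, CommunityGraph, build_community_graph, build_graph
from .model import MetabolicModel, ReactionRecord
from .oracle import naive_derivations

__all__ = ["ToySpec", "ToyNetwork", "generate", "write_fixture", "write_ground_truth"]

KINDS = ("linear_chain", "parallel_routes", "branched_join", "cycle", "community_pair", "random")

#: the naive oracle is exponential; random fixtures stay below this
MAX_RANDOM_REACTIONS = 12
MAX_RANDOM_METABOLITES = 8


@dataclass(frozen=True)
class ToySpec:
    kind: str
    n_reactions: int = 4
    seed: int = 0
    reversible_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown toy kind '{self.kind}'; choose from {KINDS}")
        if self.n_reactions < 1:
            raise ValueError("n_reactions must be >= 1")
        if not 0.0 <= self.reversible_fraction <= 1.0:
            raise ValueError("reversible_fraction must be in [0, 1]")
        if self.kind == "random" and self.n_reactions > MAX_RANDOM_REACTIONS:
            raise ValueError(
                f"random toys support at most {MAX_RANDOM_REACTIONS} reactions "
                "(ground truth comes from the exponential reference enumerator)"
            )


@dataclass(frozen=True)
class ToyNetwork:
    graph: BipartiteGraph  # or CommunityGraph
    seeds: frozenset[str]
    targets: tuple[str, ...]
    #: target id -> set of expected reaction-id frozensets (exact inventory,
    #: at the beta recorded in ground_truth_beta)
    ground_truth: dict
    ground_truth_beta: int
    models: tuple[MetabolicModel, ...] = ()


def _model(name, rows) -> MetabolicModel:
    reactions = tuple(
        ReactionRecord(rid, rev, frozenset(ins), frozenset(outs)) for rid, rev, ins, outs in rows
    )
    mets = frozenset().union(*(r.reactants | r.products for r in reactions))
    extracellular = frozenset(m for m in mets if m.endswith("_e"))
    return MetabolicModel(name, reactions, mets, extracellular)


def _linear_chain(spec: ToySpec) -> ToyNetwork:
    n = spec.n_reactions
    rows = [(f"r{i}", False, [f"m{i - 1}"], [f"m{i}"]) for i in range(1, n + 1)]
    model = _model("linear_chain", rows)
    target = f"m{n}"
    truth = {target: {frozenset(f"r{i}" for i in range(1, n + 1))}}
    return ToyNetwork(build_graph(model), frozenset(["m0"]), (target,), truth, n, (model,))


def _parallel_routes(spec: ToySpec) -> ToyNetwork:
    n = spec.n_reactions
    rows = [(f"r{i}", False, ["m0"], ["m1"]) for i in range(1, n + 1)]
    model = _model("parallel_routes", rows)
    truth = {"m1": {frozenset([f"r{i}"]) for i in range(1, n + 1)}}
    return ToyNetwork(build_graph(model), frozenset(["m0"]), ("m1",), truth, 1, (model,))


def _branched_join(spec: ToySpec) -> ToyNetwork:
    # two chains from the seed, converging on a final join reaction
    n = max(spec.n_reactions, 3)
    left = (n - 1 + 1) // 2
    right = n - 1 - left
    rows = []
    prev = "m0"
    for i in range(1, left + 1):
        rows.append((f"a{i}", False, [prev], [f"ma{i}"]))
        prev = f"ma{i}"
    left_end = prev
    prev = "m0"
    for i in range(1, right + 1):
        rows.append((f"b{i}", False, [prev], [f"mb{i}"]))
        prev = f"mb{i}"
    right_end = prev
    rows.append(("join", False, sorted({left_end, right_end}), ["t"]))
    model = _model("branched_join", rows)
    truth = {"t": {frozenset(r[0] for r in rows)}}
    return ToyNetwork(build_graph(model), frozenset(["m0"]), ("t",), truth, n, (model,))


def _cycle(spec: ToySpec) -> ToyNetwork:
    n = max(spec.n_reactions, 2)
    rows = [(f"r{i}", False, [f"m{i - 1}"], [f"m{i % n}"]) for i in range(1, n + 1)]
    model = _model("cycle", rows)
    full = frozenset(f"r{i}" for i in range(1, n + 1))
    truth = {"m0": {full}}  # regenerating the seed takes the whole loop, once
    return ToyNetwork(build_graph(model), frozenset(["m0"]), ("m0",), truth, n, (model,))


def _community_pair(spec: ToySpec) -> ToyNetwork:
    feeder = _model(
        "feeder",
        [
            ("upt", False, ["glc_e"], ["acald_c"]),
            ("sec", False, ["acald_c"], ["ac_e"]),
        ],
    )
    consumer = _model(
        "consumer",
        [
            ("imp", False, ["ac_e"], ["acon_c"]),
            ("fin", False, ["acon_c"], ["tgt_c"]),
        ],
    )
    graph = build_community_graph([feeder, consumer], labels=["org1", "org2"])
    target = "org2:tgt_c"
    truth = {target: {frozenset(["org1:upt", "org1:sec", "org2:imp", "org2:fin"])}}
    return ToyNetwork(graph, frozenset(["glc_e"]), (target,), truth, 4, (feeder, consumer))


def _random(spec: ToySpec) -> ToyNetwork:
    rng = random.Random(spec.seed)
    seeds = ["s0", "s1"]
    mets: list[str] = list(seeds)
    rows = []
    fresh = 0
    for i in range(1, spec.n_reactions + 1):
        inputs: set[str] = set()
        if i <= 2:
            inputs.add(seeds[i - 1])  # both seeds appear in the graph
        elif rng.random() < 0.7 or len(mets) >= MAX_RANDOM_METABOLITES:
            inputs.add(rng.choice(mets))
        else:  # orphan precursor: may stay unproducible -> stuck reactions
            fresh += 1
            orphan = f"x{fresh}"
            mets.append(orphan)
            inputs.add(orphan)
        if rng.random() < 0.4:
            inputs.add(rng.choice(mets))
        outputs: set[str] = set()
        n_out = 2 if rng.random() < 0.3 else 1
        for _ in range(n_out):
            if rng.random() < 0.3 or len(mets) >= MAX_RANDOM_METABOLITES:
                outputs.add(rng.choice(mets))  # back-edges: cycles
            else:
                fresh += 1
                new = f"p{fresh}"
                mets.append(new)
                outputs.add(new)
        if outputs == inputs:
            outputs.add(rng.choice(mets))
            if outputs == inputs:
                continue
        reversible = rng.random() < spec.reversible_fraction
        rows.append((f"r{i}", reversible, sorted(inputs), sorted(outputs)))
    if not rows:
        rows.append(("r1", False, ["s0"], ["p1"]))
    model = _model(f"random_{spec.seed}", rows)
    graph = build_graph(model)
    used_seeds = frozenset(s for s in seeds if s in model.metabolites)
    # the closure is worst-case exponential in beta; keep ground truth tractable
    beta = min(spec.n_reactions, 6)
    derivations = naive_derivations(graph, used_seeds, beta)
    targets = tuple(m for m in sorted(graph.metabolites) if m not in used_seeds)
    truth = {t: {rs for rs in derivations[t] if rs} for t in targets}
    return ToyNetwork(graph, used_seeds, targets, truth, beta, (model,))


_GENERATORS = {
    "linear_chain": _linear_chain,
    "parallel_routes": _parallel_routes,
    "branched_join": _branched_join,
    "cycle": _cycle,
    "community_pair": _community_pair,
    "random": _random,
}


def generate(spec: ToySpec) -> ToyNetwork:
    """Build the toy network, seed set, targets and ground-truth inventory."""
    return _GENERATORS[spec.kind](spec)


def _rows_from_graph(graph: BipartiteGraph):
    """Recover model rows by re-merging reversible reaction-node pairs."""
    rows = []
    for rid in graph.reactions:
        node = graph.reactions[rid]
        if node.direction_role == "reverse_of_pair":
            continue
        rows.append(
            (
                rid,
                "1" if node.direction_role == "forward_of_pair" else "0",
                ";".join(sorted(node.inputs)),
                ";".join(sorted(node.outputs)),
            )
        )
    return rows


def write_fixture(graph, seeds, path) -> list[Path]:
    """Write the TSV reaction list(s) plus the seed file under *path* (a directory).

    Single-organism graphs produce ``reactions.tsv``; community graphs produce
    one ``reactions_<organism>.tsv`` per member with organism prefixes
    stripped, so the set round-trips through ``build_community_graph``.
    Returns the written file paths.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def dump(rows, fname):
        target = path / fname
        with open(target, "w", encoding="utf-8") as fh:
            fh.write("reaction_id\treversible\treactants\tproducts\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")
        written.append(target)

    if isinstance(graph, CommunityGraph):
        for org in graph.organisms:
            sub_rxns = [r for r in graph.reactions.values() if r.organism_tag == org]
            strip = lambda mid: mid.split(":", 1)[1] if mid.startswith(f"{org}:") else mid
            rows = []
            for node in sub_rxns:
                if node.direction_role == "reverse_of_pair":
                    continue
                rows.append(
                    (
                        strip(node.id),
                        "1" if node.direction_role == "forward_of_pair" else "0",
                        ";".join(sorted(strip(m) for m in node.inputs)),
                        ";".join(sorted(strip(m) for m in node.outputs)),
                    )
                )
            dump(rows, f"reactions_{org}.tsv")
    else:
        dump(_rows_from_graph(graph), "reactions.tsv")

    seed_path = path / "seeds.txt"
    with open(seed_path, "w", encoding="utf-8") as fh:
        fh.write("# seed metabolites\n")
        for s in sorted(seeds):
            fh.write(s + "\n")
    written.append(seed_path)
    return written


def write_ground_truth(toy: ToyNetwork, path) -> Path:
    """Serialise the expected pathway inventory as JSON."""
    path = Path(path)
    payload = {
        "ground_truth_beta": toy.ground_truth_beta,
        "targets": {
            target: sorted(sorted(rs) for rs in sets)
            for target, sets in sorted(toy.ground_truth.items())
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
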