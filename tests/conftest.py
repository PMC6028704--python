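"""Shared fixtures: tiny hand-built networks used across the suite."""

from __future__ import annotations

import pytest

from pathenum.graph import build_graph
from pathenum.model import MetabolicModel, ReactionRecord


def make_model(rows, name="toy", reversible=(), extracellular=None):
    """Build a model from (rid, inputs, outputs) triples.

    *reversible* lists reaction ids to flag reversible; *extracellular*
    optionally overrides the '_e'-suffix default.
    """
    reactions = tuple(
        ReactionRecord(rid, rid in set(reversible), frozenset(ins), frozenset(outs))
        for rid, ins, outs in rows
    )
    mets = frozenset().union(*(r.reactants | r.products for r in reactions))
    if extracellular is None:
        extracellular = frozenset(m for m in mets if m.endswith("_e"))
    return MetabolicModel(name, reactions, mets, frozenset(extracellular))


def make_graph(rows, **kwargs):
    return build_graph(make_model(rows, **kwargs))


@pytest.fixture
def chain_graph():
    """r1: A -> B, r2: B -> C — one linear route."""
    return make_graph([("r1", ["A"], ["B"]), ("r2", ["B"], ["C"])])


@pytest.fixture
def branched_graph():
    """r1: A -> B, r2: A -> C, r3: B + C -> D — a convergent branch."""
    return make_graph([("r1", ["A"], ["B"]), ("r2", ["A"], ["C"]), ("r3", ["B", "C"], ["D"])])


@pytest.fixture
def byproduct_graph():
    """rp makes both inputs of r at once — the size-collapsing merge case."""
    return make_graph([("rp", ["s"], ["m1", "m2"]), ("r", ["m1", "m2"], ["y"])])


@pytest.fixture
def two_cycle_graph():
    """r1: A -> B, r2: B -> A — the smallest cyclic pathway."""
    return make_graph([("r1", ["A"], ["B"]), ("r2", ["B"], ["A"])])


@pytest.fixture
def community_models():
    """org1 secretes ac_e from glc_e; org2 consumes ac_e to a target."""
    feeder = make_model(
        [("upt", ["glc_e"], ["acald_c"]), ("sec", ["acald_c"], ["ac_e"])], name="feeder"
    )
    consumer = make_model(
        [("imp", ["ac_e"], ["acon_c"]), ("fin", ["acon_c"], ["tgt_c"])], name="consumer"
    )
    return feeder, consumer
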