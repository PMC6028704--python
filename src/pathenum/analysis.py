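"""Post-enumeration analytics.

Pathway similarity is measured with the Jaccard index over constituent
reaction sets, |A∩B| / |A∪B|: 1 for identical pathways, 0 for disjoint ones.
The similarity spectrum of an enumeration scores every unordered pair and
bins the values, which separates near-duplicate routes (transporter variants,
J close to 1) from genuinely alternative chemistry (J close to 0).  On
community graphs, pathways spanning more than one organism reveal candidate
cross-fed metabolites: extracellular species exported by one organism's
exchange reactions and consumed by another organism within the same pathway.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

from .enumeration import Pathway
from .graph import CommunityGraph, induced_subgraph
from .scope import guided_bfs

__all__ = [
    "jaccard",
    "similarity_spectrum",
    "most_different_pair",
    "ExchangeReport",
    "find_exchanges",
    "exchange_is_load_bearing",
    "write_similarity_tsv",
    "write_histogram",
    "write_exchange_tsv",
]


def _as_set(p) -> frozenset[str]:
    return p.reaction_set if isinstance(p, Pathway) else frozenset(p)


def jaccard(a, b) -> float:
    """|A∩B| / |A∪B| over reaction sets; 1.0 when both are empty."""
    sa, sb = _as_set(a), _as_set(b)
    union = sa | sb
    if not union:
        return 1.0
    return len(sa & sb) / len(union)


def similarity_spectrum(pathways, bins, inclusive_last: bool = True,
                        subsample: int | None = None, rng_seed: int = 0):
    """Score unordered pathway pairs and count them per bin.

    *bins* is a list of (lo, hi) ranges, closed-open by default; with
    ``inclusive_last`` the upper edge of each range's ``hi`` equal to the
    global maximum edge also counts (so a [0.9, 1.0] bin captures J = 1).
    Pairs are streamed — no N×N matrix is materialised — and all C(N,2) of
    them are scored exactly by default.  For very large collections
    (N > 10⁴ gives > 5·10⁷ pairs) pass *subsample* to score only that many
    uniformly drawn pairs, seeded by *rng_seed*.  Returns
    ``(counts, total_pairs)`` with ``counts`` aligned to *bins*; values
    falling in no bin are not counted.
    """
    import random

    pathways = list(pathways)
    if len(pathways) < 2:
        raise ValueError("similarity spectrum needs at least 2 pathways")
    bins = [(float(lo), float(hi)) for lo, hi in bins]
    top = max(hi for _, hi in bins) if bins else None
    counts = [0] * len(bins)
    total = 0
    sets = [_as_set(p) for p in pathways]
    if subsample is not None:
        rng = random.Random(rng_seed)
        n = len(sets)

        def sampled():
            for _ in range(subsample):
                i = rng.randrange(n)
                j = rng.randrange(n - 1)
                yield sets[i], sets[j if j < i else j + 1]

        pair_iter = sampled()
    else:
        pair_iter = itertools.combinations(sets, 2)
    for sa, sb in pair_iter:
        total += 1
        j = jaccard(sa, sb)
        for i, (lo, hi) in enumerate(bins):
            if lo <= j < hi or (inclusive_last and j == hi == top):
                counts[i] += 1
    return counts, total


def count_pairs_in_range(pathways, lo: float, hi: float, inclusive: bool = True):
    """Exact pair count with J in [lo, hi] (inclusive) or [lo, hi) otherwise."""
    sets = [_as_set(p) for p in pathways]
    n = 0
    for sa, sb in itertools.combinations(sets, 2):
        j = jaccard(sa, sb)
        if (lo <= j <= hi) if inclusive else (lo <= j < hi):
            n += 1
    return n


def most_different_pair(pathways):
    """The unordered pair minimising the Jaccard index.

    Ties break deterministically: smallest combined size first, then
    lexicographic reaction-id tuples.  Raises ``ValueError`` on fewer than
    two pathways.
    """
    pathways = list(pathways)
    if len(pathways) < 2:
        raise ValueError("need at least 2 pathways to compare")
    keyed = sorted(pathways, key=lambda p: (tuple(sorted(_as_set(p)))))
    best = None
    for a, b in itertools.combinations(keyed, 2):
        sa, sb = _as_set(a), _as_set(b)
        j = jaccard(sa, sb)
        key = (j, len(sa) + len(sb), tuple(sorted(sa)), tuple(sorted(sb)))
        if best is None or key < best[0]:
            best = (key, a, b, j)
    return best[1], best[2], best[3]


@dataclass(frozen=True)
class ExchangeReport:
    """A candidate cross-feeding: donor exports *metabolite*, recipient consumes it."""

    metabolite: str
    donor: str
    recipient: str
    witnessing_pathways: tuple[Pathway, ...]


def find_exchanges(community_graph: CommunityGraph, pathways) -> list[ExchangeReport]:
    """Detect metabolite exchanges inside multi-organism pathways.

    For every pathway whose member reactions span ≥2 organism tags, every
    extracellular metabolite produced by one organism's exchange reaction and
    consumed by a different organism's reaction within the same pathway is
    reported, aggregated per (metabolite, donor, recipient) with the
    witnessing pathways attached.  Ordering is deterministic.
    """
    if not isinstance(community_graph, CommunityGraph):
        raise TypeError("find_exchanges requires a CommunityGraph with organism tags")
    buckets: dict[tuple[str, str, str], list[Pathway]] = {}
    for pathway in pathways:
        members = [community_graph.reactions[rid] for rid in pathway.reactions]
        tags = {r.organism_tag for r in members if r.organism_tag}
        if len(tags) < 2:
            continue
        for rxn in members:
            if not rxn.is_exchange:
                continue
            for met in rxn.outputs:
                node = community_graph.metabolites[met]
                if not node.is_extracellular:
                    continue
                consumers = {
                    other.organism_tag
                    for other in members
                    if met in other.inputs and other.organism_tag != rxn.organism_tag
                }
                for recipient in consumers:
                    buckets.setdefault((met, rxn.organism_tag, recipient), []).append(pathway)
    reports = []
    for (met, donor, recipient) in sorted(buckets):
        witnesses = tuple(sorted(set(buckets[(met, donor, recipient)])))
        reports.append(ExchangeReport(met, donor, recipient, witnesses))
    return reports


def exchange_is_load_bearing(
    community_graph: CommunityGraph, report: ExchangeReport, seeds
) -> bool:
    """Check that the exchanged metabolite is required by the recipient.

    For some witnessing pathway, the recipient's member reactions alone must
    fail the completeness check from the original seeds, yet pass it once the
    exchanged metabolite is added as a seed — the exchange carries load.
    This re-runs the scope expansion per witness, so it is offered as an
    optional verification rather than computed for every report.
    """
    seeds = frozenset(seeds)
    for pathway in report.witnessing_pathways:
        recipient_rxns = [
            rid
            for rid in pathway.reactions
            if community_graph.reactions[rid].organism_tag == report.recipient
        ]
        if not recipient_rxns:
            continue
        sub = induced_subgraph(community_graph, recipient_rxns)
        base = seeds & sub.metabolites.keys() - {report.metabolite}
        boosted = base | {report.metabolite}
        if report.metabolite not in sub.metabolites:
            continue
        without = (
            guided_bfs(sub, base).visited_reactions if base else frozenset()
        )
        withm = guided_bfs(sub, boosted).visited_reactions
        if not set(recipient_rxns) <= without and set(recipient_rxns) <= withm:
            return True
    return False


# ---------------------------------------------------------------------------
# output formats

def write_similarity_tsv(pathways, path) -> None:
    pathways = list(pathways)
    with open(str(path), "w", encoding="utf-8") as fh:
        fh.write("pathway_a_index\tpathway_b_index\tjaccard\n")
        for (i, a), (j, b) in itertools.combinations(enumerate(pathways), 2):
            fh.write(f"{i}\t{j}\t{jaccard(a, b):.6f}\n")


def write_histogram(bins, counts, total, tsv_path=None, json_path=None) -> None:
    if tsv_path is not None:
        with open(str(tsv_path), "w", encoding="utf-8") as fh:
            fh.write("bin_lo\tbin_hi\tcount\n")
            for (lo, hi), c in zip(bins, counts):
                fh.write(f"{lo}\t{hi}\t{c}\n")
            fh.write(f"# total_pairs\t{total}\n")
    if json_path is not None:
        payload = {
            "bins": [{"lo": lo, "hi": hi, "count": c} for (lo, hi), c in zip(bins, counts)],
            "total_pairs": total,
        }
        with open(str(json_path), "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def write_exchange_tsv(reports, path) -> None:
    with open(str(path), "w", encoding="utf-8") as fh:
        fh.write("metabolite\tdonor\trecipient\tn_witnessing_pathways\texample_pathway_reactions\n")
        for rep in reports:
            example = ";".join(rep.witnessing_pathways[0].reactions) if rep.witnessing_pathways else ""
            fh.write(
                f"{rep.metabolite}\t{rep.donor}\t{rep.recipient}\t"
                f"{len(rep.witnessing_pathways)}\t{example}\n"
            )
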