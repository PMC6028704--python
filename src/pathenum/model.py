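"""Metabolic model records and readers.

A :class:`MetabolicModel` is the minimal, purely topological view of a
metabolic reconstruction that pathway enumeration needs: reaction identifiers,
reversibility flags, reactant/product sets, optional gene-protein-reaction
(GPR) Boolean rules, and which metabolites live in the extracellular
compartment.  Stoichiometric coefficients are deliberately not kept — the
enumeration method is topological and only presence/absence of a metabolite in
a reaction matters.

Two input dialects are supported: SBML (read through cobrapy, which handles
Level 2/3 and the fbc gene-association package) and a plain TSV reaction list
used throughout the test fixtures::

    reaction_id  reversible  reactants       products
    PFK          0           f6p_c;atp_c     fdp_c;adp_c

with ``reversible`` as 0/1 and metabolite ids separated by semicolons.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "ReactionRecord",
    "MetabolicModel",
    "ModelError",
    "read_tsv_model",
    "read_sbml_model",
    "apply_gene_knockout",
]

#: compartment identifiers commonly used for the extracellular space in SBML
EXTRACELLULAR_COMPARTMENTS = frozenset({"e", "e0", "C_e", "extracellular", "extracellular space"})

#: metabolite-id suffix marking extracellular species in the TSV dialect
EXTRACELLULAR_SUFFIX = "_e"


class ModelError(ValueError):
    """Raised for malformed or inconsistent model inputs."""


@dataclass(frozen=True)
class ReactionRecord:
    """One model reaction: topology plus optional GPR rule."""

    id: str
    reversible: bool
    reactants: frozenset[str]
    products: frozenset[str]
    gpr: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("reaction with empty identifier")
        if not self.reactants and not self.products:
            raise ModelError(f"reaction '{self.id}' has neither reactants nor products")


@dataclass(frozen=True)
class MetabolicModel:
    """A parsed metabolic network (topology only)."""

    name: str
    reactions: tuple[ReactionRecord, ...]
    metabolites: frozenset[str]
    extracellular: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ModelError(f"duplicate reaction id '{rxn.id}'")
            seen.add(rxn.id)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    def genes(self) -> frozenset[str]:
        """All gene ids mentioned in any GPR rule."""
        from cobra.core.gene import GPR

        out: set[str] = set()
        for rxn in self.reactions:
            if rxn.gpr:
                out |= set(GPR.from_string(rxn.gpr).genes)
        return frozenset(out)


def _infer_extracellular(metabolites: set[str], suffix: str) -> frozenset[str]:
    return frozenset(m for m in metabolites if m.endswith(suffix))


def read_tsv_model(path, name: str | None = None, extracellular_suffix: str = EXTRACELLULAR_SUFFIX) -> MetabolicModel:
    """Read a model from the TSV reaction-list dialect.

    Metabolites are declared implicitly by appearing in a reaction row;
    those whose id ends with *extracellular_suffix* are flagged extracellular.
    """
    path = str(path)
    reactions: list[ReactionRecord] = []
    metabolites: set[str] = set()
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"reaction_id", "reversible", "reactants", "products"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ModelError(f"{path}: TSV header must contain columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            rid = (row["reaction_id"] or "").strip()
            if not rid:
                raise ModelError(f"{path}:{lineno}: empty reaction_id")
            rev_field = (row["reversible"] or "").strip()
            if rev_field not in {"0", "1"}:
                raise ModelError(f"{path}:{lineno}: reversible must be 0 or 1, got '{rev_field}'")
            reactants = frozenset(x.strip() for x in (row["reactants"] or "").split(";") if x.strip())
            products = frozenset(x.strip() for x in (row["products"] or "").split(";") if x.strip())
            if not reactants and not products:
                raise ModelError(f"{path}:{lineno}: reaction '{rid}' has no metabolites")
            gpr = (row.get("gpr") or "").strip()
            reactions.append(ReactionRecord(rid, rev_field == "1", reactants, products, gpr))
            metabolites |= reactants | products
    if not reactions:
        raise ModelError(f"{path}: model has zero reactions")
    return MetabolicModel(
        name=name or path,
        reactions=tuple(reactions),
        metabolites=frozenset(metabolites),
        extracellular=_infer_extracellular(metabolites, extracellular_suffix),
    )


def read_sbml_model(path, name: str | None = None) -> MetabolicModel:
    """Read an SBML Level 2/3 model via cobrapy.

    Metabolite ids keep cobrapy's convention (compartment suffix included,
    e.g. ``glc__D_e``).  A metabolite is extracellular when its compartment is
    one of :data:`EXTRACELLULAR_COMPARTMENTS` or when it sits on the boundary.
    """
    import cobra.io

    cb = cobra.io.read_sbml_model(str(path))
    metabolites = {m.id for m in cb.metabolites}
    extracellular = {
        m.id
        for m in cb.metabolites
        if (m.compartment or "").lower() in EXTRACELLULAR_COMPARTMENTS or getattr(m, "boundary", False)
    }
    reactions = []
    for rxn in cb.reactions:
        reactants = frozenset(m.id for m in rxn.reactants)
        products = frozenset(m.id for m in rxn.products)
        # purely topological direction: lower_bound < 0 <= upper_bound means
        # reversible; a strictly backward reaction is flipped
        reversible = rxn.reversibility
        if not reversible and rxn.upper_bound <= 0 and rxn.lower_bound < 0:
            reactants, products = products, reactants
        if not reactants and not products:
            continue
        reactions.append(
            ReactionRecord(rxn.id, bool(reversible), reactants, products, rxn.gene_reaction_rule or "")
        )
    if not reactions:
        raise ModelError(f"{path}: model has zero reactions")
    return MetabolicModel(
        name=name or cb.id or str(path),
        reactions=tuple(reactions),
        metabolites=frozenset(metabolites),
        extracellular=frozenset(extracellular),
    )


def apply_gene_knockout(model: MetabolicModel, gene_ids) -> MetabolicModel:
    """Return a copy of *model* with reactions disabled by the knockouts removed.

    A reaction is removed iff its GPR rule evaluates to False when every gene
    in *gene_ids* is set false and all other genes true.  Reactions without a
    GPR rule are always retained.  Unknown gene ids trigger a warning and are
    ignored.  Metabolites left with zero degree are retained (inert nodes keep
    downstream indexing stable and are harmless to traversal).
    """
    from cobra.core.gene import GPR

    gene_ids = set(gene_ids)
    known = model.genes()
    unknown = gene_ids - known
    if unknown:
        warnings.warn(f"unknown gene id(s) ignored: {sorted(unknown)}", stacklevel=2)
    knockouts = gene_ids & known
    kept = tuple(
        rxn
        for rxn in model.reactions
        if not rxn.gpr or GPR.from_string(rxn.gpr).eval(knockouts=knockouts)
    )
    return replace(model, reactions=kept)
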