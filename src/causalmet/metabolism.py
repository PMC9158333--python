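"""Activity-flow encoding of metabolic reactions and pathway definitions.

An enzymatic reaction (substrates S, products P, enzymes E) is embedded into
the signed causal network as a triad of activity-flow edges:

* ``S -> P``  activating — the substrate is necessary to yield the product;
* ``E -> P``  activating — so is the catalysing enzyme;
* ``E -> S``  inhibiting — enzyme activity consumes the substrate.

Multi-substrate / multi-product reactions expand by full cross product.
Currency metabolites (ATP, NADH, ...) are excluded before expansion so they
do not create meaningless two-step shortcuts between unrelated pathways.

Pathways are named sets of member enzymes with a flagged rate-limiting
subset (RLEs) — the targets of the downstream path search.  A demerge
mapping can split one curated pathway (e.g. glycolysis/gluconeogenesis)
into separate analysis pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import pandas as pd
import yaml

from .errors import FormatError
from .network import CausalEdge, CausalNetwork, Entity, EntityClass

log = logging.getLogger(__name__)

#: default currency-metabolite exclusion list (matched case-insensitively)
CURRENCY_METABOLITES = frozenset({
    "ATP", "ADP", "AMP", "GTP", "GDP", "NAD+", "NADH", "NADP+", "NADPH",
    "FAD", "FADH2", "H2O", "PI", "PPI", "CO2", "H+", "COA",
})

MECH_CONVERSION = "metabolic conversion"
MECH_CATALYSIS = "catalysis"
MECH_CONSUMPTION = "substrate consumption"


@dataclass(frozen=True)
class MetabolicReaction:
    """One curated enzymatic reaction assigned to a pathway."""

    reaction_id: str
    pathway: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    enzymes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValueError(
                f"reaction {self.reaction_id}: substrates and products "
                "must be non-empty")
        overlap = set(self.substrates) & set(self.products)
        if overlap:
            raise ValueError(
                f"reaction {self.reaction_id}: substrates and products "
                f"overlap: {sorted(overlap)}")


@dataclass(frozen=True)
class ConversionConfig:
    """Parameters of the reaction-to-edges conversion.

    ``default_score`` follows the small-molecule score convention (0.8),
    so every generated metabolic edge has distance 0.2 unless overridden.
    """

    excluded_metabolites: frozenset[str] = CURRENCY_METABOLITES
    default_score: float = 0.8

    def is_excluded(self, metabolite: str) -> bool:
        return metabolite.upper() in {m.upper() for m in self.excluded_metabolites}


@dataclass(frozen=True)
class PathwayDefinition:
    """A metabolic pathway: member enzymes and its rate-limiting subset."""

    name: str
    member_enzymes: frozenset[str]
    rate_limiting: frozenset[str]
    parent: str | None = None

    def __post_init__(self) -> None:
        stray = self.rate_limiting - self.member_enzymes
        if stray:
            raise FormatError(
                f"pathway {self.name!r}: rate-limiting enzymes not among "
                f"members: {sorted(stray)}")
        if not self.rate_limiting:
            log.warning("pathway %r has no rate-limiting enzyme; it cannot "
                        "be used as a path-search target", self.name)


def reaction_to_af_edges(reaction: MetabolicReaction,
                         config: ConversionConfig | None = None
                         ) -> list[CausalEdge]:
    """Convert one reaction into its activity-flow triad edges.

    Returns ``|S|·|P|`` substrate->product (+1), ``|E|·|P|`` enzyme->product
    (+1) and ``|E|·|S|`` enzyme->substrate (-1) edges, after removing
    currency metabolites.  A reaction whose product list empties out after
    exclusion is skipped with a warning (empty result).  Enzyme-free
    reactions emit only the substrate->product edges (spontaneous
    conversion).
    """
    config = config or ConversionConfig()
    substrates = [s for s in reaction.substrates if not config.is_excluded(s)]
    products = [p for p in reaction.products if not config.is_excluded(p)]
    if not products:
        log.warning("reaction %s: all products excluded as currency "
                    "metabolites; skipped", reaction.reaction_id)
        return []
    score = config.default_score
    prov = (reaction.reaction_id,) if reaction.reaction_id else ()
    edges: list[CausalEdge] = []
    for s in substrates:
        for p in products:
            edges.append(CausalEdge(s, p, +1, score, MECH_CONVERSION,
                                    provenance=prov))
    for e in reaction.enzymes:
        for p in products:
            edges.append(CausalEdge(e, p, +1, score, MECH_CATALYSIS,
                                    provenance=prov))
        for s in substrates:
            edges.append(CausalEdge(e, s, -1, score, MECH_CONSUMPTION,
                                    provenance=prov))
    return edges


# ---------------------------------------------------------------------------
# Reaction / pathway file readers
# ---------------------------------------------------------------------------

_REACTION_COLUMNS = ("reaction_id", "pathway", "substrates", "products",
                     "enzymes", "reversible")


def _split(cell: str) -> tuple[str, ...]:
    return tuple(x.strip() for x in str(cell).split(";") if x.strip())


def read_reactions_tsv(source: Union[str, Path, TextIO]) -> list[MetabolicReaction]:
    """Read the reaction TSV dialect.

    Columns: ``reaction_id pathway substrates products enzymes reversible``
    with semicolon-separated member lists.  A reversible reaction expands
    into two directional reactions (``<id>_fwd`` / ``<id>_rev``) because
    activity-flow edges are directional.
    """
    frame = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.strip().lower() for c in frame.columns}
    missing = [c for c in _REACTION_COLUMNS if c not in cols]
    if missing:
        raise FormatError("reaction table missing column(s): " + ", ".join(missing))
    frame.columns = [c.strip().lower() for c in frame.columns]
    reactions: list[MetabolicReaction] = []
    for _, row in frame.iterrows():
        base = dict(
            pathway=row["pathway"],
            substrates=_split(row["substrates"]),
            products=_split(row["products"]),
            enzymes=_split(row["enzymes"]),
        )
        reversible = str(row["reversible"]).strip() in ("1", "true", "yes")
        if reversible:
            reactions.append(MetabolicReaction(
                reaction_id=f"{row['reaction_id']}_fwd", **base))
            reactions.append(MetabolicReaction(
                reaction_id=f"{row['reaction_id']}_rev", pathway=row["pathway"],
                substrates=base["products"], products=base["substrates"],
                enzymes=base["enzymes"]))
        else:
            reactions.append(MetabolicReaction(
                reaction_id=row["reaction_id"], **base))
    return reactions


def write_reactions_tsv(reactions: Sequence[MetabolicReaction],
                        path: Union[str, Path]) -> None:
    rows = [
        {"reaction_id": r.reaction_id, "pathway": r.pathway,
         "substrates": ";".join(r.substrates), "products": ";".join(r.products),
         "enzymes": ";".join(r.enzymes), "reversible": 0}
        for r in reactions
    ]
    pd.DataFrame(rows, columns=list(_REACTION_COLUMNS)).to_csv(
        path, sep="\t", index=False)


def load_pathway_definitions(source: Union[str, Path, TextIO],
                             apply_demerge: bool = True
                             ) -> list[PathwayDefinition]:
    """Load pathway definitions from YAML.

    Schema::

        pathways:
          - name: Glycolysis and Gluconeogenesis
            enzymes: [HK1, PFKL, FBP1, ...]
            rate_limiting: [HK1, PFKL, FBP1]
        demerge:                       # optional
          Glycolysis and Gluconeogenesis:
            - {name: Glycolysis, enzymes: [...], rate_limiting: [...]}
            - {name: Gluconeogenesis, enzymes: [...], rate_limiting: [...]}

    With ``apply_demerge`` each parent listed in the mapping is replaced by
    its sub-pathways (which record the parent name), e.g. turning nine
    curated pathways into ten analysis pathways.
    """
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
    else:
        data = yaml.safe_load(source.read())
    if not isinstance(data, Mapping) or "pathways" not in data:
        raise FormatError("pathway file must contain a top-level 'pathways' list")

    def make(block: Mapping, parent: str | None = None) -> PathwayDefinition:
        try:
            name = block["name"]
            enzymes = frozenset(str(e) for e in block["enzymes"])
        except KeyError as exc:
            raise FormatError(f"pathway block missing key {exc}") from exc
        rle = frozenset(str(e) for e in block.get("rate_limiting", ()))
        return PathwayDefinition(name=name, member_enzymes=enzymes,
                                 rate_limiting=rle, parent=parent)

    demerge: Mapping = data.get("demerge") or {}
    defs: list[PathwayDefinition] = []
    for block in data["pathways"]:
        name = block.get("name")
        if apply_demerge and name in demerge:
            for sub in demerge[name]:
                defs.append(make(sub, parent=name))
        else:
            defs.append(make(block))
    names = [d.name for d in defs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise FormatError(f"duplicate pathway name(s): {sorted(dupes)}")
    return defs


def write_pathway_yaml(definitions: Sequence[PathwayDefinition],
                       path: Union[str, Path]) -> None:
    payload = {"pathways": [
        {"name": d.name, "enzymes": sorted(d.member_enzymes),
         "rate_limiting": sorted(d.rate_limiting)}
        for d in definitions
    ]}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False),
                          encoding="utf-8")


# ---------------------------------------------------------------------------
# Merge into the causal network
# ---------------------------------------------------------------------------

def merge_metabolic_layer(network: CausalNetwork,
                          reactions: Iterable[MetabolicReaction],
                          config: ConversionConfig | None = None,
                          in_place: bool = False) -> CausalNetwork:
    """Embed converted reactions into the causal network.

    New metabolites are registered as ``smallmolecule`` entities and new
    enzymes as ``protein`` entities; converted edges collapse under the
    network's usual (source, target, sign) max-score rule, so merging the
    same reactions twice is idempotent.  An identifier collision with a
    differently-classed existing entity raises, naming both classes.
    """
    config = config or ConversionConfig()
    net = network if in_place else network.copy()
    for reaction in reactions:
        edges = reaction_to_af_edges(reaction, config)
        if not edges:
            continue
        kept_substrates = {s for s in reaction.substrates
                           if not config.is_excluded(s)}
        kept_products = {p for p in reaction.products
                         if not config.is_excluded(p)}
        for met in sorted(kept_substrates | kept_products):
            net.add_entity(Entity(met, met, EntityClass.SMALL_MOLECULE))
        for enz in reaction.enzymes:
            net.add_entity(Entity(enz, enz, EntityClass.PROTEIN))
        for edge in edges:
            net.add_edge(edge)
    return net
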