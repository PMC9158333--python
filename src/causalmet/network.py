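"""Signed directed causal interactome: domain model and SIGNOR-dialect reader.

The causal network is a signed, scored, directed graph over biological
entities (proteins, complexes, small molecules, phenotypes, ...).  Each edge
states that the activity of the source entity up-regulates (+1) or
down-regulates (-1) the target, with a reliability score ``s`` in [0.1, 1].
The functional distance of an edge is ``d = 1 - s``: highly supported links
are "close", weakly supported ones "far".

The reader consumes the tab-separated causal-interaction dialect used by the
SIGNOR download (entity A/B names, classes, identifiers, effect verb,
mechanism, direct flag, score), tolerating column supersets.
"""

from __future__ import annotations

import difflib
import enum
import io
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import networkx as nx
import pandas as pd

from .errors import EntityClassConflictError, FormatError

log = logging.getLogger(__name__)

HUMAN_TAXON = 9606


class EntityClass(str, enum.Enum):
    """Classes of biological entities carried by the causal network."""

    PROTEIN = "protein"
    COMPLEX = "complex"
    PROTEIN_FAMILY = "proteinfamily"
    SMALL_MOLECULE = "smallmolecule"
    CHEMICAL = "chemical"
    PHENOTYPE = "phenotype"
    STIMULUS = "stimulus"
    FUSION_PROTEIN = "fusionprotein"
    MIRNA = "mirna"
    ANTIBODY = "antibody"

    @classmethod
    def coerce(cls, text: str, strict: bool = False) -> "EntityClass":
        """Normalise a free-text class label to a member of the enumeration.

        With ``strict=False`` an unknown label is mapped to the closest known
        class name (with a warning); with ``strict=True`` it raises.
        """
        key = text.strip().lower().replace(" ", "").replace("_", "").replace("-", "")
        try:
            return cls(key)
        except ValueError:
            pass
        match = difflib.get_close_matches(key, [m.value for m in cls], n=1, cutoff=0.6)
        if match and not strict:
            log.warning("unknown entity class %r coerced to %r", text, match[0])
            return cls(match[0])
        raise FormatError(f"unknown entity class: {text!r}")


#: classes whose score-less interactions default to 0.8
CHEMICAL_LIKE = frozenset({EntityClass.CHEMICAL, EntityClass.SMALL_MOLECULE})


@dataclass(frozen=True)
class Entity:
    """One node of the causal network."""

    identifier: str
    display_name: str
    entity_class: EntityClass
    taxon: int | None = None

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("entity identifier must be non-empty")


@dataclass(frozen=True)
class CausalEdge:
    """One signed, scored, directed causal link.

    ``sign`` is +1 (activating), -1 (inhibiting) or 0 (no usable sign, e.g.
    complex formation).  ``score`` is the reliability estimate in [0.1, 1].
    """

    source: str
    target: str
    sign: int
    score: float
    mechanism: str = ""
    direct: bool = True
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sign not in (-1, 0, 1):
            raise ValueError(f"edge sign must be -1, 0 or +1, got {self.sign}")
        if not (0.1 - 1e-12 <= self.score <= 1 + 1e-12):
            raise ValueError(
                f"edge score must lie in [0.1, 1], got {self.score} "
                f"({self.source} -> {self.target})"
            )
        if self.source == self.target:
            raise ValueError(f"self-loop not allowed: {self.source}")

    @property
    def distance(self) -> float:
        return edge_distance(self)


def edge_distance(edge: CausalEdge) -> float:
    """Functional distance of an edge, ``d = 1 - s``; in [0, 0.9]."""
    if not (0.1 - 1e-12 <= edge.score <= 1 + 1e-12):
        raise ValueError(f"edge score outside [0.1, 1]: {edge.score}")
    return 1.0 - edge.score


class CausalNetwork:
    """Signed directed causal graph with unique entities and collapsed edges.

    At most one edge is kept per (source, target, sign) triple; parallel
    records collapse onto the maximum score with the union of provenance.
    Self-loops are rejected.  Entity identifiers are unique; registering the
    same identifier under a different class raises.
    """

    def __init__(self, metadata: Mapping | None = None) -> None:
        self._entities: dict[str, Entity] = {}
        self._edges: dict[tuple[str, str, int], CausalEdge] = {}
        self.metadata: dict = dict(metadata or {})
        self._graph_cache: dict[bool, nx.MultiDiGraph] = {}

    # -- construction ------------------------------------------------------
    def add_entity(self, entity: Entity) -> Entity:
        existing = self._entities.get(entity.identifier)
        if existing is None:
            self._entities[entity.identifier] = entity
            self._graph_cache.clear()
            return entity
        if existing.entity_class is not entity.entity_class:
            raise EntityClassConflictError(
                f"identifier {entity.identifier!r} already registered as "
                f"{existing.entity_class.value}, cannot re-register as "
                f"{entity.entity_class.value}"
            )
        return existing

    def add_edge(self, edge: CausalEdge) -> CausalEdge:
        """Add an edge, collapsing onto any existing (source, target, sign)."""
        for end in (edge.source, edge.target):
            if end not in self._entities:
                raise KeyError(f"edge endpoint {end!r} is not a registered entity")
        key = (edge.source, edge.target, edge.sign)
        old = self._edges.get(key)
        if old is not None:
            prov = tuple(sorted(set(old.provenance) | set(edge.provenance)))
            best = edge if edge.score > old.score else old
            edge = replace(best, provenance=prov, direct=old.direct and edge.direct)
        self._edges[key] = edge
        self._graph_cache.clear()
        return edge

    def copy(self) -> "CausalNetwork":
        dup = CausalNetwork(self.metadata)
        dup._entities = dict(self._entities)
        dup._edges = dict(self._edges)
        return dup

    # -- access ------------------------------------------------------------
    @property
    def n_entities(self) -> int:
        return len(self._entities)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def entities(self) -> list[Entity]:
        return list(self._entities.values())

    def entity(self, identifier: str) -> Entity:
        return self._entities[identifier]

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._entities

    def edges(self) -> list[CausalEdge]:
        return list(self._edges.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CausalNetwork):
            return NotImplemented
        return self._entities == other._entities and self._edges == other._edges

    def __repr__(self) -> str:
        return f"CausalNetwork({self.n_entities} entities, {self.n_edges} edges)"

    def graph(self, include_unsigned: bool = False) -> nx.MultiDiGraph:
        """networkx view; unsigned (sign 0) edges are excluded by default.

        The multigraph key of each edge is its sign, so a +1 and a -1 link
        between the same pair coexist as distinct traversable edges.
        """
        cached = self._graph_cache.get(include_unsigned)
        if cached is not None:
            return cached
        g = nx.MultiDiGraph()
        for ent in self._entities.values():
            g.add_node(ent.identifier, entity_class=ent.entity_class.value,
                       display_name=ent.display_name)
        for edge in self._edges.values():
            if edge.sign == 0 and not include_unsigned:
                continue
            g.add_edge(edge.source, edge.target, key=edge.sign,
                       sign=edge.sign, score=edge.score, distance=edge.distance,
                       mechanism=edge.mechanism)
        self._graph_cache[include_unsigned] = g
        return g


# ---------------------------------------------------------------------------
# SIGNOR-dialect parsing
# ---------------------------------------------------------------------------

#: lower-cased mandatory header names of the causal-interaction dialect
MANDATORY_COLUMNS = (
    "entitya", "typea", "ida", "entityb", "typeb", "idb",
    "effect", "mechanism", "direct", "score",
)

_TRUTHY = {"yes", "t", "true", "1", "y"}


@dataclass(frozen=True)
class SignorRecord:
    """One verbatim row of a causal-interaction table.

    Raw strings are preserved so that parse -> serialize -> parse round-trips
    exactly; ``score`` / ``is_direct`` / ``taxon`` expose parsed views.
    """

    entity_a: str
    type_a: str
    id_a: str
    entity_b: str
    type_b: str
    id_b: str
    effect: str
    mechanism: str
    direct: str
    score_raw: str
    tax_id: str = ""
    record_id: str = ""

    @property
    def score(self) -> float | None:
        text = self.score_raw.strip()
        if not text:
            return None
        try:
            return float(text)
        except ValueError:
            return None

    @property
    def is_direct(self) -> bool:
        return self.direct.strip().lower() in _TRUTHY

    @property
    def taxon(self) -> int | None:
        text = self.tax_id.strip()
        if not text or text in ("-1", "NA"):
            return None
        try:
            return int(text)
        except ValueError:
            return None


@dataclass(frozen=True)
class ParseOptions:
    """Options for :func:`parse_signor_tsv` (the defaults fit the public
    SIGNOR download)."""

    id_column: str = "signor_id"      # fallback provenance column
    alt_id_column: str = "pmid"


def _open_text(source: Union[str, Path, TextIO]) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8")
    return source


def parse_signor_tsv(
    source: Union[str, Path, TextIO],
    options: ParseOptions | None = None,
) -> list[SignorRecord]:
    """Parse a causal-interaction TSV into verbatim records.

    The header must contain (case-insensitively) the mandatory columns
    ``ENTITYA TYPEA IDA ENTITYB TYPEB IDB EFFECT MECHANISM DIRECT SCORE``;
    extra columns are tolerated and ignored.  Non-numeric score strings are
    reported at warning level and treated as absent.  Rows with empty
    mandatory identifier fields are reported, never silently dropped.
    """
    options = options or ParseOptions()
    handle = _open_text(source)
    frame = pd.read_csv(handle, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in frame.columns}
    missing = [c for c in MANDATORY_COLUMNS if c not in cols]
    if missing:
        raise FormatError(
            "missing mandatory column(s): " + ", ".join(c.upper() for c in missing)
        )

    def col(row, name: str, default: str = "") -> str:
        actual = cols.get(name)
        return str(row[actual]) if actual is not None else default

    records: list[SignorRecord] = []
    for idx, row in frame.iterrows():
        rec_id = col(row, options.id_column) or col(row, options.alt_id_column) \
            or f"row{idx}"
        rec = SignorRecord(
            entity_a=col(row, "entitya"), type_a=col(row, "typea"),
            id_a=col(row, "ida"),
            entity_b=col(row, "entityb"), type_b=col(row, "typeb"),
            id_b=col(row, "idb"),
            effect=col(row, "effect"), mechanism=col(row, "mechanism"),
            direct=col(row, "direct"), score_raw=col(row, "score"),
            tax_id=col(row, "tax_id"), record_id=rec_id,
        )
        if rec.score_raw.strip() and rec.score is None:
            log.warning("row %d: non-numeric score %r treated as absent",
                        idx, rec.score_raw)
        if not rec.id_a or not rec.id_b:
            log.warning("row %d: empty entity identifier (A=%r, B=%r)",
                        idx, rec.id_a, rec.id_b)
        records.append(rec)
    return records


def write_signor_tsv(records: Iterable[SignorRecord],
                     destination: Union[str, Path, TextIO]) -> None:
    """Serialize records back to the supported columns of the dialect."""
    frame = pd.DataFrame(
        [
            {
                "ENTITYA": r.entity_a, "TYPEA": r.type_a, "IDA": r.id_a,
                "ENTITYB": r.entity_b, "TYPEB": r.type_b, "IDB": r.id_b,
                "EFFECT": r.effect, "MECHANISM": r.mechanism,
                "TAX_ID": r.tax_id, "DIRECT": r.direct, "SCORE": r.score_raw,
                "SIGNOR_ID": r.record_id,
            }
            for r in records
        ]
    )
    if isinstance(destination, (str, Path)):
        frame.to_csv(destination, sep="\t", index=False)
    else:
        frame.to_csv(destination, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BuildOptions:
    """Assembly options.

    direct_only
        Keep only interactions flagged as direct (the published analysis
        uses the direct interactome).
    taxa
        Accepted taxa; records whose taxon is listed, or absent
        (taxon-free entities such as phenotypes and chemicals), are kept.
    class_default_score / fallback_default_score
        Score assigned to score-less records: 0.8 when either endpoint is a
        chemical or small molecule, otherwise 0.5 (with a warning).
    strict_classes
        If true, unknown entity-class strings reject the record instead of
        being coerced to the closest known class.
    """

    direct_only: bool = True
    taxa: tuple[int, ...] = (HUMAN_TAXON,)
    keep_taxon_free: bool = True
    class_default_score: float = 0.8
    fallback_default_score: float = 0.5
    strict_classes: bool = False


def sign_from_effect(effect: str) -> int:
    """Map an effect verb to a sign by prefix.

    ``up-regulates*`` -> +1, ``down-regulates*`` -> -1, everything else
    (complex formation, "unknown", ...) -> 0.
    """
    verb = effect.strip().lower()
    if verb.startswith("up-regulates"):
        return 1
    if verb.startswith("down-regulates"):
        return -1
    return 0


def build_network(records: Sequence[SignorRecord],
                  options: BuildOptions | None = None) -> CausalNetwork:
    """Assemble a :class:`CausalNetwork` from parsed records.

    Applies the direct-interaction and taxon filters, maps effect verbs to
    signs, fills class-default scores, removes self-loops and collapses
    parallel (source, target, sign) records onto the maximum score.
    Building is idempotent: rebuilding from the same records yields an equal
    network.
    """
    options = options or BuildOptions()
    net = CausalNetwork(metadata={"options": options})
    stats = {"records": len(records), "dropped_indirect": 0, "dropped_taxon": 0,
             "dropped_selfloop": 0, "dropped_invalid": 0, "defaulted_scores": 0}
    if not records:
        log.warning("building from an empty record list: empty network")

    for rec in records:
        if not rec.id_a or not rec.id_b:
            stats["dropped_invalid"] += 1
            continue
        if options.direct_only and not rec.is_direct:
            stats["dropped_indirect"] += 1
            continue
        taxon = rec.taxon
        if taxon is None:
            if not options.keep_taxon_free:
                stats["dropped_taxon"] += 1
                continue
        elif taxon not in options.taxa:
            stats["dropped_taxon"] += 1
            continue
        try:
            class_a = EntityClass.coerce(rec.type_a, strict=options.strict_classes)
            class_b = EntityClass.coerce(rec.type_b, strict=options.strict_classes)
        except FormatError as exc:
            log.warning("record %s rejected: %s", rec.record_id, exc)
            stats["dropped_invalid"] += 1
            continue
        if rec.id_a == rec.id_b:
            stats["dropped_selfloop"] += 1
            continue

        score = rec.score
        if score is None:
            if class_a in CHEMICAL_LIKE or class_b in CHEMICAL_LIKE:
                score = options.class_default_score
            else:
                score = options.fallback_default_score
                log.warning(
                    "record %s (%s -> %s) has no score and no chemical "
                    "endpoint; defaulting to %.2f",
                    rec.record_id, rec.id_a, rec.id_b, score)
            stats["defaulted_scores"] += 1
        if not (0.1 <= score <= 1.0):
            clamped = min(max(score, 0.1), 1.0)
            log.warning("record %s score %.3g outside [0.1, 1]; clamped to %.3g",
                        rec.record_id, score, clamped)
            score = clamped

        net.add_entity(Entity(rec.id_a, rec.entity_a or rec.id_a, class_a, taxon))
        net.add_entity(Entity(rec.id_b, rec.entity_b or rec.id_b, class_b, taxon))
        net.add_edge(CausalEdge(
            source=rec.id_a, target=rec.id_b, sign=sign_from_effect(rec.effect),
            score=score, mechanism=rec.mechanism, direct=rec.is_direct,
            provenance=(rec.record_id,) if rec.record_id else (),
        ))
    net.metadata["build_stats"] = stats
    return net


def read_signor_network(path: Union[str, Path],
                        options: BuildOptions | None = None,
                        parse_options: ParseOptions | None = None) -> CausalNetwork:
    """Parse + build in one step."""
    return build_network(parse_signor_tsv(path, parse_options), options)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

_SIF_RELATION = {1: "activates", -1: "inhibits", 0: "unsigned"}


def write_sif(network: CausalNetwork, destination: Union[str, Path, TextIO]) -> None:
    """Write ``source<TAB>relation<TAB>target`` lines; relation encodes sign."""
    lines = [
        f"{e.source}\t{_SIF_RELATION[e.sign]}\t{e.target}"
        for e in sorted(network.edges(), key=lambda e: (e.source, e.target, e.sign))
    ]
    text = "\n".join(lines) + ("\n" if lines else "")
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text, encoding="utf-8")
    else:
        destination.write(text)


def write_graphml(network: CausalNetwork, path: Union[str, Path]) -> None:
    g = network.graph(include_unsigned=True)
    nx.write_graphml(g, path)


def edge_table(network: CausalNetwork) -> pd.DataFrame:
    rows = [
        {
            "source": e.source, "target": e.target, "sign": e.sign,
            "score": e.score, "distance": round(e.distance, 12),
            "mechanism": e.mechanism, "direct": int(e.direct),
            "provenance": ";".join(e.provenance),
        }
        for e in sorted(network.edges(), key=lambda e: (e.source, e.target, e.sign))
    ]
    return pd.DataFrame(rows, columns=["source", "target", "sign", "score",
                                       "distance", "mechanism", "direct",
                                       "provenance"])


def write_edge_table(network: CausalNetwork, path: Union[str, Path]) -> None:
    edge_table(network).to_csv(path, sep="\t", index=False)


def node_table(network: CausalNetwork) -> pd.DataFrame:
    rows = [
        {"identifier": ent.identifier, "display_name": ent.display_name,
         "entity_class": ent.entity_class.value,
         "taxon": "" if ent.taxon is None else ent.taxon}
        for ent in sorted(network.entities(), key=lambda x: x.identifier)
    ]
    return pd.DataFrame(rows, columns=["identifier", "display_name",
                                       "entity_class", "taxon"])
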