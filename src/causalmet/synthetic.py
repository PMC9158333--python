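"""Synthetic signed causal networks with a metabolic layer and planted paths.

The generator produces everything the analysis consumes — a random signed
scored interactome, a chained metabolic layer converted through the same
activity-flow triad rule, pathway definitions with flagged rate-limiting
enzymes (RLEs), and planted ground-truth paths whose distance and sign are
known analytically — so the whole pipeline is testable without any
download.  Fixtures are emitted in the same TSV/YAML/CSV dialects the real
readers consume, so synthetic and real data share one code path.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import yaml

from .metabolism import (ConversionConfig, MetabolicReaction,
                         PathwayDefinition, merge_metabolic_layer,
                         write_pathway_yaml, write_reactions_tsv)
from .network import (CausalEdge, CausalNetwork, Entity, EntityClass,
                      SignorRecord, write_signor_tsv)
from .paths import PathSign

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study; fully reproducible from the seed."""

    n_nodes: int = 60
    n_edges: int = 150
    p_inhibiting: float = 0.25
    score_low: float = 0.1
    score_high: float = 1.0
    n_pathways: int = 2
    reactions_per_pathway: int = 4
    enzymes_per_pathway: int = 3
    rle_per_pathway: int = 1
    n_crosstalk_edges: int = 12
    share_terminal_metabolites: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_edges > self.n_nodes * (self.n_nodes - 1):
            raise ValueError("n_edges exceeds the number of ordered pairs")
        if not (0.0 <= self.p_inhibiting <= 1.0):
            raise ValueError("p_inhibiting must lie in [0, 1]")
        if not (0.1 <= self.score_low <= self.score_high <= 1.0):
            raise ValueError("score range must lie within [0.1, 1]")
        if self.rle_per_pathway > self.enzymes_per_pathway:
            raise ValueError("rle_per_pathway exceeds enzymes_per_pathway")

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SyntheticSpec":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**data)


def _gene_name(i: int) -> str:
    return f"GEN{i:04d}"


def _round_score(x: float) -> float:
    """Scores are rounded so TSV round-trips reproduce the network exactly."""
    return float(np.clip(round(x, 6), 0.1, 1.0))


def generate_network(spec: SyntheticSpec) -> CausalNetwork:
    """Uniform random simple directed graph with signed, scored edges.

    Exactly ``n_edges`` distinct ordered pairs (no self-loops); each edge is
    inhibiting with probability ``p_inhibiting`` and scored uniformly on
    [score_low, score_high].  Same seed, same network.
    """
    rng = np.random.default_rng(spec.seed)
    net = CausalNetwork(metadata={"synthetic_spec": asdict(spec)})
    for i in range(spec.n_nodes):
        net.add_entity(Entity(_gene_name(i), _gene_name(i), EntityClass.PROTEIN))
    pairs: set[tuple[int, int]] = set()
    while len(pairs) < spec.n_edges:
        need = spec.n_edges - len(pairs)
        u = rng.integers(0, spec.n_nodes, size=2 * need + 8)
        v = rng.integers(0, spec.n_nodes, size=2 * need + 8)
        for a, b in zip(u, v):
            if a != b and (int(a), int(b)) not in pairs:
                pairs.add((int(a), int(b)))
                if len(pairs) == spec.n_edges:
                    break
    for a, b in sorted(pairs):
        sign = -1 if rng.random() < spec.p_inhibiting else 1
        score = _round_score(rng.uniform(spec.score_low, spec.score_high))
        net.add_edge(CausalEdge(_gene_name(a), _gene_name(b), sign, score,
                                mechanism="synthetic"))
    return net


def generate_metabolic_layer(spec: SyntheticSpec
                             ) -> tuple[list[MetabolicReaction],
                                        list[PathwayDefinition]]:
    """Chained reactions per pathway plus pathway definitions with RLE flags.

    Each pathway is a linear chain of single-substrate reactions, so its
    metabolite graph is connected; with ``share_terminal_metabolites`` each
    pathway starts from the previous pathway's terminal metabolite, so the
    merged layer forms one connected component (mirroring how the curated
    pathways merge into a single metabolic network).
    """
    reactions: list[MetabolicReaction] = []
    definitions: list[PathwayDefinition] = []
    for p in range(spec.n_pathways):
        pname = f"Pathway {p + 1}"
        enzymes = [f"ENZ{p + 1}_{j + 1}" for j in range(spec.enzymes_per_pathway)]
        mets = []
        for t in range(spec.reactions_per_pathway + 1):
            if t == 0 and spec.share_terminal_metabolites and p > 0:
                mets.append(f"MET{p}_{spec.reactions_per_pathway}")
            else:
                mets.append(f"MET{p + 1}_{t}")
        for r in range(spec.reactions_per_pathway):
            reactions.append(MetabolicReaction(
                reaction_id=f"RXN{p + 1}_{r + 1}", pathway=pname,
                substrates=(mets[r],), products=(mets[r + 1],),
                enzymes=(enzymes[r % len(enzymes)],)))
        definitions.append(PathwayDefinition(
            name=pname, member_enzymes=frozenset(enzymes),
            rate_limiting=frozenset(enzymes[: spec.rle_per_pathway])))
    return reactions, definitions


def wire_crosstalk(network: CausalNetwork, enzymes: Sequence[str],
                   n_edges: int, seed: int,
                   p_inhibiting: float = 0.25) -> CausalNetwork:
    """Add random signalling edges from network genes onto enzymes.

    This emulates the regulation of metabolic enzymes by the signalling
    layer and gives background genes a baseline chance of reaching RLEs.
    Mutates and returns the network.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(e.identifier for e in network.entities()
                   if e.entity_class is EntityClass.PROTEIN
                   and not e.identifier.startswith("ENZ"))
    enzymes = sorted(enzymes)
    for enz in enzymes:
        if enz not in network:
            network.add_entity(Entity(enz, enz, EntityClass.PROTEIN))
    for _ in range(n_edges):
        src = genes[int(rng.integers(len(genes)))]
        dst = enzymes[int(rng.integers(len(enzymes)))]
        sign = -1 if rng.random() < p_inhibiting else 1
        score = _round_score(rng.uniform(0.1, 1.0))
        network.add_edge(CausalEdge(src, dst, sign, score,
                                    mechanism="synthetic crosstalk"))
    return network


@dataclass(frozen=True)
class PlantedPath:
    """Ground truth for one inserted path."""

    source: str
    pathway: str
    node_chain: tuple[str, ...]
    edge_signs: tuple[int, ...]
    edge_scores: tuple[float, ...]
    expected_distance: float
    expected_sign: str

    @classmethod
    def build(cls, source: str, pathway: str, chain: Sequence[str],
              signs: Sequence[int], scores: Sequence[float]) -> "PlantedPath":
        distance = float(sum(1.0 - s for s in scores))
        parity = sum(1 for s in signs if s == -1) % 2
        sign = (PathSign.INHIBITING if parity else PathSign.ACTIVATING).value
        return cls(source=source, pathway=pathway, node_chain=tuple(chain),
                   edge_signs=tuple(signs), edge_scores=tuple(scores),
                   expected_distance=distance, expected_sign=sign)


def plant_path(network: CausalNetwork, source: str, target: str,
               signs: Sequence[int], scores: Sequence[float],
               pathway: str = "", cutoff_hint: int = 4
               ) -> tuple[CausalNetwork, PlantedPath]:
    """Insert a guaranteed simple path from ``source`` to ``target``.

    Fresh intermediate nodes are created, so the planted route cannot
    collide with existing paths.  The source and target are registered as
    protein entities if absent.  A planted path longer than ``cutoff_hint``
    triggers a warning: it is invisible to the bounded search and serves as
    a negative control.
    """
    if len(signs) != len(scores) or not signs:
        raise ValueError("signs and scores must be equally long and non-empty")
    length = len(signs)
    if length > cutoff_hint:
        warnings.warn(
            f"planted path of length {length} exceeds the search cutoff "
            f"{cutoff_hint}; it will not be found (negative control)",
            stacklevel=2)
    for node in (source, target):
        if node not in network:
            network.add_entity(Entity(node, node, EntityClass.PROTEIN))
    chain = [source]
    for i in range(length - 1):
        mid = f"PLT_{source}_{i + 1}"
        if mid in network:
            raise ValueError(f"intermediate node {mid!r} already exists")
        network.add_entity(Entity(mid, mid, EntityClass.PROTEIN))
        chain.append(mid)
    chain.append(target)
    scores = [_round_score(s) for s in scores]
    for (u, v), sign, score in zip(zip(chain, chain[1:]), signs, scores):
        network.add_edge(CausalEdge(u, v, int(sign), score,
                                    mechanism="planted"))
    return network, PlantedPath.build(source, pathway, chain, signs, scores)


# ---------------------------------------------------------------------------
# The mini-interactome study fixture
# ---------------------------------------------------------------------------

@dataclass
class MiniStudy:
    """A small self-contained study with known ground truth.

    Planted query genes:

    * ``QACT`` — short strong all-activating path to the RLE of pathway 1:
      a significant activator.
    * ``QINH`` — short strong path with one inhibitory step: a significant
      inhibitor.
    * ``QFAR`` — planted route of length 5, invisible at cutoff 4: an
      unreachable gene exercising distance imputation.

    Three background genes carry long weak paths so the finite distance
    distribution has realistic spread and a well-defined imputation value.
    """

    spec: SyntheticSpec
    network: CausalNetwork
    reactions: list[MetabolicReaction]
    pathway_defs: list[PathwayDefinition]
    planted: dict[str, PlantedPath]
    negative_controls: dict[str, PlantedPath]
    classes: dict[str, str]


def build_study(spec: SyntheticSpec) -> MiniStudy:
    """Full study from a spec: network + metabolic layer + planted truth."""
    net = generate_network(spec)
    reactions, pdefs = generate_metabolic_layer(spec)
    net = merge_metabolic_layer(net, reactions)
    enzymes = sorted({e for d in pdefs for e in d.member_enzymes})
    wire_crosstalk(net, enzymes, spec.n_crosstalk_edges, seed=spec.seed + 1,
                   p_inhibiting=spec.p_inhibiting)
    rle1 = sorted(pdefs[0].rate_limiting)[0]
    rle2 = sorted(pdefs[-1].rate_limiting)[0]

    planted: dict[str, PlantedPath] = {}
    negatives: dict[str, PlantedPath] = {}
    _, planted["QACT"] = plant_path(net, "QACT", rle1, signs=(1, 1),
                                    scores=(0.95, 0.9), pathway=pdefs[0].name)
    _, planted["QINH"] = plant_path(net, "QINH", rle1, signs=(1, -1),
                                    scores=(0.9, 0.9), pathway=pdefs[0].name)
    # long weak background routes: they anchor the imputation value well
    # above the planted distances
    for i, (bkg, scr) in enumerate([("BKG1", 0.4), ("BKG2", 0.35),
                                    ("BKG3", 0.3)]):
        pdef = pdefs[i % len(pdefs)]
        _, planted[bkg] = plant_path(net, bkg,
                                     sorted(pdef.rate_limiting)[0],
                                     signs=(1, 1, 1, -1),
                                     scores=(scr, scr, scr, scr),
                                     pathway=pdef.name)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, negatives["QFAR"] = plant_path(net, "QFAR", rle2,
                                          signs=(1, 1, 1, 1, 1),
                                          scores=(0.9,) * 5,
                                          pathway=pdefs[1].name)
    classes = {"QACT": "oncogene", "BKG1": "oncogene", "GEN0001": "oncogene",
               "QINH": "TSG", "BKG2": "TSG", "GEN0002": "TSG"}
    return MiniStudy(spec=spec, network=net, reactions=reactions,
                     pathway_defs=pdefs, planted=planted,
                     negative_controls=negatives, classes=classes)


def mini_study(seed: int = 42) -> MiniStudy:
    """The shipped 60-node mini-interactome study (see :class:`MiniStudy`)."""
    return build_study(SyntheticSpec(seed=seed))


# ---------------------------------------------------------------------------
# Fixture emission in the real input dialects
# ---------------------------------------------------------------------------

_EFFECT = {1: "up-regulates activity", -1: "down-regulates activity",
           0: "form complex"}


def network_to_records(network: CausalNetwork) -> list[SignorRecord]:
    """Express a network as causal-interaction rows the parser reads back."""
    records = []
    for i, edge in enumerate(sorted(network.edges(),
                                    key=lambda e: (e.source, e.target, e.sign))):
        src = network.entity(edge.source)
        dst = network.entity(edge.target)
        records.append(SignorRecord(
            entity_a=src.display_name, type_a=src.entity_class.value,
            id_a=src.identifier,
            entity_b=dst.display_name, type_b=dst.entity_class.value,
            id_b=dst.identifier,
            effect=_EFFECT[edge.sign], mechanism=edge.mechanism,
            direct="YES", score_raw=f"{edge.score:g}",
            tax_id="" if src.taxon is None else str(src.taxon),
            record_id=f"SYN-{i:05d}"))
    return records


def write_study(outdir: Union[str, Path], study: MiniStudy) -> dict:
    """Write a study as files consumable by the package's own readers.

    Emits ``network.tsv`` (causal-interaction dialect, signalling +
    metabolic + planted edges), ``reactions.tsv``, ``pathways.yaml``,
    ``gene_classes.csv``, ``spec.yaml`` and a ``manifest.json`` of analytic
    ground truth.  Returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_signor_tsv(network_to_records(study.network), outdir / "network.tsv")
    write_reactions_tsv(study.reactions, outdir / "reactions.tsv")
    write_pathway_yaml(study.pathway_defs, outdir / "pathways.yaml")
    with open(outdir / "gene_classes.csv", "w", encoding="utf-8") as fh:
        fh.write("gene_symbol,role\n")
        for gene in sorted(study.classes):
            fh.write(f"{gene},{study.classes[gene]}\n")
    study.spec.to_yaml(outdir / "spec.yaml")
    connected = {n for e in study.network.edges()
                 for n in (e.source, e.target)}
    manifest = {
        "n_entities": study.network.n_entities,
        # isolated entities cannot be expressed in the edge-list dialect;
        # a rebuild from network.tsv recovers exactly the connected ones
        "n_entities_connected": len(connected),
        "n_edges": study.network.n_edges,
        "pathways": [d.name for d in study.pathway_defs],
        "planted": {k: asdict(v) for k, v in study.planted.items()},
        "negative_controls": {k: asdict(v)
                              for k, v in study.negative_controls.items()},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return manifest
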