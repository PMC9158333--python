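"""Bounded signed path enumeration and pathway-proximity scoring.

For a query gene and a metabolic pathway, the method enumerates every simple
directed path of at most ``cutoff`` edges (default 4) from the gene to any
rate-limiting enzyme (RLE) of the pathway, traversing only signed edges.
Each path carries

* a distance — the sum of edge distances ``d = 1 - s`` (low distance means
  strong cumulative support, i.e. short "functional distance"); and
* a sign — inhibiting if it contains an odd number of inhibitory edges,
  activating otherwise (the sign-parity rule; equivalently the product of
  the edge signs).

The gene-level distance to a pathway is the minimum over its paths; genes
that cannot reach any RLE within the cutoff are imputed the highest finite
gene-level distance observed for that pathway.  Proximity is judged by a
Z-score of the gene's distance within the pathway's network-wide distance
distribution; genes with Z < -1.96 (two-sided normal p < 0.05) are called
significantly close.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDistributionError
from .metabolism import PathwayDefinition
from .network import CausalNetwork, EntityClass

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 4
DEFAULT_Z_THRESHOLD = -1.96


class PathSign(str, enum.Enum):
    ACTIVATING = "activating"
    INHIBITING = "inhibiting"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class CausalPath:
    """A simple signed path; ``nodes`` has one more element than ``signs``.

    A single-node path (length 0) is the self-path convention for a query
    that is itself a rate-limiting enzyme: distance 0, sign activating.
    """

    nodes: tuple[str, ...]
    signs: tuple[int, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.signs) + 1 or len(self.signs) != len(self.scores):
            raise ValueError("inconsistent path: need |nodes| = |edges| + 1")

    @property
    def length(self) -> int:
        return len(self.signs)

    @property
    def distance(self) -> float:
        return float(sum(1.0 - s for s in self.scores))

    @property
    def sign(self) -> PathSign:
        if any(s == 0 for s in self.signs):
            return PathSign.INDETERMINATE
        return (PathSign.INHIBITING
                if sum(1 for s in self.signs if s == -1) % 2 == 1
                else PathSign.ACTIVATING)

    @property
    def source(self) -> str:
        return self.nodes[0]

    @property
    def target(self) -> str:
        return self.nodes[-1]


def path_distance(path: CausalPath) -> float:
    """Path distance score: sum of ``1 - s`` over the edges."""
    return path.distance


def path_sign(path: CausalPath) -> PathSign:
    """Sign-parity rule: odd count of inhibitory edges -> inhibiting."""
    return path.sign


def enumerate_paths(network: CausalNetwork,
                    source: str,
                    targets: Iterable[str],
                    cutoff: int = DEFAULT_CUTOFF,
                    include_unsigned: bool = False) -> list[CausalPath]:
    """All simple directed paths of <= ``cutoff`` edges from source to targets.

    Only signed (+1/-1) edges are traversed unless ``include_unsigned``;
    parallel edges of opposite sign between the same pair yield distinct
    paths.  A target node terminates a path: no enumerated path crosses a
    target as an intermediate node.  Results are in deterministic
    lexicographic order by node sequence, then edge signs.
    """
    if cutoff < 1:
        raise ValueError(f"cutoff must be >= 1, got {cutoff}")
    target_set = set(targets)
    if not target_set:
        log.warning("enumerate_paths called with an empty target set")
        return []
    g = network.graph(include_unsigned=include_unsigned)
    if source not in g:
        raise KeyError(f"source {source!r} not in network")
    missing = sorted(t for t in target_set if t not in g)
    if missing:
        raise KeyError(f"target(s) not in network: {missing}")

    paths: list[CausalPath] = []
    for epath in nx.all_simple_edge_paths(g, source, target_set, cutoff=cutoff):
        if not epath:  # degenerate source-in-targets case
            continue
        nodes = (source,) + tuple(v for _, v, _ in epath)
        if any(n in target_set for n in nodes[1:-1]):
            continue
        signs = tuple(g.edges[u, v, k]["sign"] for u, v, k in epath)
        scores = tuple(g.edges[u, v, k]["score"] for u, v, k in epath)
        paths.append(CausalPath(nodes, signs, scores))
    paths.sort(key=lambda p: (p.nodes, p.signs))
    return paths


def gene_pathway_distance(paths: Sequence[CausalPath],
                          imputation_value: float | None = None
                          ) -> tuple[float, bool]:
    """Aggregate a gene's paths to one distance.

    Minimum path distance when any path exists; otherwise the imputation
    value (the highest finite gene-level distance in the pathway's
    distribution) with the imputed flag set.
    """
    if paths:
        return min(p.distance for p in paths), False
    if imputation_value is None:
        raise ValueError("no paths and no imputation value available "
                         "(finite distribution must be computed first)")
    return float(imputation_value), True


@dataclass(frozen=True)
class GenePathwayScore:
    """Proximity call for one (gene, pathway) pair."""

    gene: str
    pathway: str
    distance: float
    imputed: bool
    z: float
    p: float
    significant: bool
    n_paths: int = 0
    n_activating: int = 0
    n_inhibiting: int = 0


def compute_pathway_zscores(distances: Mapping[str, float],
                            pathway: str = "",
                            threshold: float = DEFAULT_Z_THRESHOLD,
                            ddof: int = 0,
                            path_stats: Mapping[str, tuple[bool, int, int, int]]
                            | None = None) -> list[GenePathwayScore]:
    """Z-score every gene's distance within the full distance distribution.

    ``z = (d - mean) / sd`` with population sd by default (``ddof=0``);
    ``p`` is the two-sided standard-normal tail; a gene is significant iff
    ``z < threshold`` (strict).  ``path_stats`` optionally supplies
    (imputed, n_paths, n_activating, n_inhibiting) per gene.
    """
    if len(distances) < 2:
        raise DegenerateDistributionError(
            "need at least 2 genes to form a distance distribution")
    genes = sorted(distances)
    values = np.array([distances[g] for g in genes], dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=ddof))
    if sd == 0:
        raise DegenerateDistributionError(
            "distance distribution has zero standard deviation")
    scores = []
    for gene, d in zip(genes, values):
        z = float((d - mean) / sd)
        p = float(2 * sps.norm.sf(abs(z)))
        imputed, n_paths, n_act, n_inh = (path_stats or {}).get(
            gene, (False, 0, 0, 0))
        scores.append(GenePathwayScore(
            gene=gene, pathway=pathway, distance=float(d), imputed=imputed,
            z=z, p=p, significant=bool(z < threshold),
            n_paths=n_paths, n_activating=n_act, n_inhibiting=n_inh))
    return scores


def classify_gene_effect(paths: Sequence[CausalPath]
                         ) -> tuple[int, int, str]:
    """Count activating/inhibiting paths and give a majority verdict.

    Zero-length self-paths and indeterminate paths are excluded from the
    counts.  Verdict: ``activator`` / ``inhibitor`` / ``mixed`` (tie,
    including the no-signed-path case).
    """
    n_act = sum(1 for p in paths
                if p.length > 0 and p.sign is PathSign.ACTIVATING)
    n_inh = sum(1 for p in paths
                if p.length > 0 and p.sign is PathSign.INHIBITING)
    if n_act > n_inh:
        verdict = "activator"
    elif n_inh > n_act:
        verdict = "inhibitor"
    else:
        verdict = "mixed"
    return n_act, n_inh, verdict


def best_path(paths: Sequence[CausalPath]) -> CausalPath | None:
    """Representative path: smallest distance, then shortest, then lexicographic."""
    if not paths:
        return None
    return min(paths, key=lambda p: (p.distance, p.length, p.nodes))


# ---------------------------------------------------------------------------
# Network-wide scoring pipeline
# ---------------------------------------------------------------------------

@dataclass
class PathwayScoring:
    """Result of scoring every universe gene against every pathway."""

    scores: dict[str, dict[str, GenePathwayScore]]   # pathway -> gene -> score
    paths: dict[tuple[str, str], list[CausalPath]]   # (gene, pathway) -> paths
    universe: list[str]
    params: dict

    def pathways(self) -> list[str]:
        return list(self.scores)

    def score(self, gene: str, pathway: str) -> GenePathwayScore:
        return self.scores[pathway][gene]

    def significant_genes(self, pathway: str) -> list[str]:
        return [g for g, s in self.scores[pathway].items() if s.significant]

    def is_significant_anywhere(self, gene: str) -> bool:
        return any(gene in byg and byg[gene].significant
                   for byg in self.scores.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": s.gene, "pathway": s.pathway,
             "distance": s.distance, "imputed": int(s.imputed),
             "z": s.z, "p": s.p, "significant": int(s.significant),
             "n_paths": s.n_paths, "n_activating": s.n_activating,
             "n_inhibiting": s.n_inhibiting}
            for pw in self.scores
            for s in sorted(self.scores[pw].values(), key=lambda s: s.gene)
        ]
        return pd.DataFrame(rows, columns=[
            "gene", "pathway", "distance", "imputed", "z", "p",
            "significant", "n_paths", "n_activating", "n_inhibiting"])

    def paths_frame(self, only_significant: bool = True) -> pd.DataFrame:
        rows = []
        for (gene, pw), plist in sorted(self.paths.items()):
            if only_significant and not self.scores[pw][gene].significant:
                continue
            for p in plist:
                rows.append({
                    "gene": gene, "pathway": pw,
                    "nodes": "|".join(p.nodes),
                    "edge_signs": "|".join(str(s) for s in p.signs),
                    "length": p.length, "distance": round(p.distance, 12),
                    "sign": p.sign.value})
        return pd.DataFrame(rows, columns=["gene", "pathway", "nodes",
                                           "edge_signs", "length",
                                           "distance", "sign"])


def default_universe(network: CausalNetwork) -> list[str]:
    """Genes eligible for scoring/sampling: protein-class entities."""
    return sorted(e.identifier for e in network.entities()
                  if e.entity_class is EntityClass.PROTEIN)


def score_network(network: CausalNetwork,
                  pathway_defs: Sequence[PathwayDefinition],
                  universe: Sequence[str] | None = None,
                  cutoff: int = DEFAULT_CUTOFF,
                  z_threshold: float = DEFAULT_Z_THRESHOLD,
                  include_unsigned: bool = False,
                  aggregate: str = "min",
                  ddof: int = 0) -> PathwayScoring:
    """Score every universe gene against every pathway's rate-limiting enzymes.

    For each pathway: enumerate bounded signed paths from each gene to the
    RLE set, aggregate to a gene-level distance (``min`` by default,
    ``mean`` optional), impute unreachable genes at the highest finite
    gene-level distance, then Z-score the full distribution.  A gene that is
    itself an RLE of the pathway receives the zero-length self-path
    (distance 0, one activating path excluded from up/down counts).
    """
    if aggregate not in ("min", "mean"):
        raise ValueError(f"aggregate must be 'min' or 'mean', got {aggregate!r}")
    universe = list(universe) if universe is not None else default_universe(network)
    scores: dict[str, dict[str, GenePathwayScore]] = {}
    all_paths: dict[tuple[str, str], list[CausalPath]] = {}

    for pdef in pathway_defs:
        rles = sorted(t for t in pdef.rate_limiting if t in network)
        if not rles:
            raise ValueError(
                f"pathway {pdef.name!r} has no rate-limiting enzyme present "
                "in the network; cannot be a path-search target")
        dropped = sorted(set(pdef.rate_limiting) - set(rles))
        if dropped:
            log.warning("pathway %r: RLE(s) absent from network ignored: %s",
                        pdef.name, dropped)
        rle_set = set(rles)

        finite: dict[str, float] = {}
        stats: dict[str, tuple[bool, int, int, int]] = {}
        unreachable: list[str] = []
        for gene in universe:
            if gene in rle_set:
                plist = [CausalPath((gene,), (), ())]
            else:
                plist = enumerate_paths(network, gene, rle_set, cutoff=cutoff,
                                        include_unsigned=include_unsigned)
            if plist:
                all_paths[(gene, pdef.name)] = plist
                dists = [p.distance for p in plist]
                finite[gene] = (min(dists) if aggregate == "min"
                                else float(np.mean(dists)))
                n_act, n_inh, _ = classify_gene_effect(plist)
                stats[gene] = (False, len(plist), n_act, n_inh)
            else:
                unreachable.append(gene)
        if not finite:
            raise DegenerateDistributionError(
                f"pathway {pdef.name!r}: no universe gene reaches an RLE "
                f"within {cutoff} steps")
        imputation_value = max(finite.values())
        distances = dict(finite)
        for gene in unreachable:
            d, imp = gene_pathway_distance([], imputation_value)
            distances[gene] = d
            stats[gene] = (imp, 0, 0, 0)
        per_gene = compute_pathway_zscores(
            distances, pathway=pdef.name, threshold=z_threshold,
            ddof=ddof, path_stats=stats)
        scores[pdef.name] = {s.gene: s for s in per_gene}

    return PathwayScoring(
        scores=scores, paths=all_paths, universe=universe,
        params={"cutoff": cutoff, "z_threshold": z_threshold,
                "aggregate": aggregate, "ddof": ddof,
                "include_unsigned": include_unsigned})


def write_scores_tsv(scoring: PathwayScoring, path: Union[str, Path]) -> None:
    scoring.to_frame().to_csv(path, sep="\t", index=False)


def write_paths_tsv(scoring: PathwayScoring, path: Union[str, Path],
                    only_significant: bool = True) -> None:
    scoring.paths_frame(only_significant).to_csv(path, sep="\t", index=False)
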