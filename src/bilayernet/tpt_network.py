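"""Pathway enrichment and the target-protein-target (TPT) network.

Predicted targets are tested for over-representation in pathway gene sets
(hypergeometric upper tail); pathways significant at ``alpha`` define the
TPT layer, in which two targets are linked iff they co-occur in at least
one enriched pathway, weighted by the number of shared enriched pathways.
Louvain then partitions the layer into functional modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from .errors import InputError
from .partition import louvain_partition, module_members, pool_small_modules
from .cs_network import module_name

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayAnnotation:
    id: str
    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise InputError(f"pathway {self.id!r} has an empty member set")


@dataclass(frozen=True)
class EnrichmentResult:
    """One pathway's over-representation test.

    ``pathway_size`` is the member count after intersection with the
    background; ``overlap_members`` is the query ∩ pathway gene set kept for
    downstream network construction.
    """

    pathway_id: str
    name: str
    overlap: int
    pathway_size: int
    query_size: int
    background_size: int
    p: float
    overlap_members: frozenset[str] = field(default=frozenset(), compare=False)


def load_gmt(path: str | Path) -> list[PathwayAnnotation]:
    """Read pathway gene sets in GMT format.

    Dialect: ``pathway<TAB>description<TAB>gene1<TAB>gene2...`` per line.
    Duplicate genes within a line are deduplicated; lines with fewer than
    three fields are skipped with a warning; an empty file is fatal.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"GMT file not found: {path}")
    annotations: list[PathwayAnnotation] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                log.warning("%s:%d: fewer than 3 fields, skipped", path, lineno)
                continue
            pid, desc = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                log.warning("%s:%d: no member genes, skipped", path, lineno)
                continue
            name = desc or pid
            if name in names:
                raise InputError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            names.add(name)
            annotations.append(PathwayAnnotation(id=pid, name=name, members=members))
    if not annotations:
        raise InputError(f"{path}: no pathway records")
    return annotations


def enrich_targets(query: Iterable[str],
                   pathways: Sequence[PathwayAnnotation],
                   background: Iterable[str],
                   alpha: float = 0.05,
                   fdr: bool = False) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in each pathway.

    p = P(X >= overlap) for X ~ Hypergeom(N=|background|, K=|pathway ∩
    background|, n=|query|).  Pathway members are intersected with the
    background first; pathways with an empty intersection are dropped.
    Results with p < ``alpha`` (or Benjamini-Hochberg q < alpha when
    ``fdr=True``) are returned sorted by ascending p.
    """
    query = set(query)
    background = set(background)
    if not query:
        raise InputError("enrichment query is empty")
    if not query <= background:
        missing = sorted(query - background)[:5]
        raise InputError(
            f"query is not a subset of the background (e.g. {missing})")
    N, n = len(background), len(query)
    results = []
    for pw in pathways:
        members = pw.members & background
        if not members:
            continue
        hit = members & query
        K, k = len(members), len(hit)
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(
            pathway_id=pw.id, name=pw.name, overlap=k, pathway_size=K,
            query_size=n, background_size=N, p=p,
            overlap_members=frozenset(hit)))
    if fdr and results:
        q = false_discovery_control([r.p for r in results], method="bh")
        results = [r for r, qv in zip(results, q) if qv < alpha]
    else:
        results = [r for r in results if r.p < alpha]
    results.sort(key=lambda r: (r.p, r.pathway_id))
    return results


@dataclass
class TPTNetwork:
    """Target co-pathway graph plus its module partition."""

    graph: nx.Graph
    partition: dict[str, int]

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def module_name(self, label: int) -> str:
        return module_name(label, "TPT")

    def members(self) -> dict[int, set]:
        return module_members(self.partition)


def build_tpt_network(enriched: Sequence[EnrichmentResult],
                      pathways: Sequence[PathwayAnnotation],
                      restrict_to: Iterable[str] | None = None,
                      resolution: float = 1.0,
                      seed: int = 0,
                      min_module_size: int = 1) -> TPTNetwork:
    """Project enriched target-pathway relations into a target-target graph.

    Nodes are targets belonging to >= 1 enriched pathway (optionally
    intersected with ``restrict_to``, e.g. the predicted-target query);
    edge weight = number of shared enriched pathways.
    """
    if not enriched:
        raise InputError("no enriched pathway; cannot build the TPT network")
    by_id = {pw.id: pw for pw in pathways}
    restrict = set(restrict_to) if restrict_to is not None else None
    g = nx.Graph()
    for res in enriched:
        members = set(by_id[res.pathway_id].members)
        if restrict is not None:
            members &= restrict
        members = sorted(members)
        g.add_nodes_from(members)
        for i, t1 in enumerate(members):
            for t2 in members[i + 1:]:
                if g.has_edge(t1, t2):
                    g[t1][t2]["weight"] += 1
                else:
                    g.add_edge(t1, t2, weight=1)
    if g.number_of_nodes() == 0:
        raise InputError("enriched pathways have no member targets after restriction")
    part = louvain_partition(g, resolution=resolution, seed=seed, weight="weight")
    if min_module_size > 1:
        part = pool_small_modules(part, min_size=min_module_size)
    return TPTNetwork(graph=g, partition=part)


def module_propensity(net: TPTNetwork,
                      enriched: Sequence[EnrichmentResult],
                      pathways: Sequence[PathwayAnnotation],
                      top_k: int = 5) -> pd.DataFrame:
    """Rank pathways per module by coverage x significance.

    Score = (fraction of the pathway's in-network members lying inside the
    module) x (-log10 p).  This functional-propensity score is this
    package's construction and is isolated here for easy replacement.
    """
    import math

    by_id = {pw.id: pw for pw in pathways}
    nodes = net.nodes
    rows = []
    for label, mem in sorted(net.members().items()):
        scored = []
        for res in enriched:
            in_net = by_id[res.pathway_id].members & nodes
            if not in_net:
                continue
            coverage = len(in_net & mem) / len(in_net)
            if coverage == 0:
                continue
            score = coverage * (-math.log10(max(res.p, 1e-300)))
            scored.append((score, coverage, res))
        scored.sort(key=lambda t: (-t[0], t[2].pathway_id))
        for rank, (score, coverage, res) in enumerate(scored[:top_k], 1):
            rows.append({
                "module": label, "module_name": net.module_name(label),
                "rank": rank, "pathway_id": res.pathway_id,
                "pathway": res.name, "coverage": coverage,
                "p": res.p, "score": score,
            })
    return pd.DataFrame(rows)


def write_enrichment_tsv(results: Sequence[EnrichmentResult],
                         path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write("pathway_id\tname\toverlap\tpathway_size\tquery_size\t"
                 "background_size\tp\n")
        for r in results:
            fh.write(f"{r.pathway_id}\t{r.name}\t{r.overlap}\t{r.pathway_size}"
                     f"\t{r.query_size}\t{r.background_size}\t{r.p:.6g}\n")
            n += 1
    return n
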