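"""The compound-similarity (CS) network layer.

Nodes are compounds that (a) have at least one structural-similarity edge
at the Tc threshold and (b) carry at least one predicted target; edges are
the thresholded Tanimoto pairs, weighted by Tc.  The layer is partitioned
into modules by seeded Louvain, with sub-minimum modules pooled into a
"CS_others" bucket.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .chem import Compound, SimilarityEdge
from .errors import InputError
from .partition import (OTHERS_LABEL, louvain_partition, module_members,
                        pool_small_modules)

log = logging.getLogger(__name__)


def module_name(label: int, prefix: str = "CS") -> str:
    return f"{prefix}_others" if label == OTHERS_LABEL else f"{prefix}_Module_{label}"


@dataclass
class CSNetwork:
    """Compound-similarity graph plus its module partition."""

    graph: nx.Graph
    partition: dict[str, int]
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def module_name(self, label: int) -> str:
        return module_name(label, "CS")

    def members(self) -> dict[int, set]:
        return module_members(self.partition)


def assemble_cs_network(compounds: Iterable[Compound],
                        edges: Iterable[SimilarityEdge],
                        targeted_compounds: Iterable[str],
                        resolution: float = 1.0,
                        seed: int = 0,
                        min_module_size: int = 3,
                        weighted: bool = True) -> CSNetwork:
    """Filter to networked compounds and partition them into modules.

    ``targeted_compounds`` is the set of compound ids with >= 1 predicted
    target (e.g. ``InteractionTable.compound_ids``).  Compounds failing
    either filter are excluded and counted by reason.  Louvain uses Tc as
    the edge weight by default (``weighted=False`` for the unweighted run).
    """
    comps = {c.id: c for c in compounds}
    targeted = set(targeted_compounds)
    edges = list(edges)
    with_edge = {e.a for e in edges} | {e.b for e in edges}

    survivors = {cid for cid in comps if cid in with_edge and cid in targeted}
    excluded = {
        "no_similarity_edge": sum(1 for c in comps if c not in with_edge),
        "no_predicted_target": sum(
            1 for c in comps if c in with_edge and c not in targeted),
    }
    log.info("CS filter: %d/%d compounds kept (%d without similarity edge, "
             "%d without predicted target)", len(survivors), len(comps),
             excluded["no_similarity_edge"], excluded["no_predicted_target"])
    if not survivors:
        raise InputError(
            "no compound passed both CS filters (similarity edge at threshold "
            "AND >= 1 predicted target); check the Tc threshold and the "
            "interaction table's compound ids")

    g = nx.Graph()
    g.add_nodes_from(survivors)
    for e in edges:
        if e.a in survivors and e.b in survivors:
            g.add_edge(e.a, e.b, tc=e.tc, weight=e.tc)

    part = louvain_partition(g, resolution=resolution, seed=seed,
                             weight="weight" if weighted else None)
    part = pool_small_modules(part, min_size=min_module_size)
    return CSNetwork(graph=g, partition=part, excluded=excluded)


def summarize_modules(net: CSNetwork, top_n: int = 3) -> pd.DataFrame:
    """Per-module summary: size, mean intra-module Tc, top-degree members.

    The overall mean inter-module Tc (over edges crossing module borders)
    is attached as ``df.attrs["mean_inter_tc"]`` for comparison; singleton
    or edge-free modules report an empty (NaN) intra-module Tc.
    """
    deg = net.degrees
    rows = []
    inter_tcs = []
    intra: dict[int, list[float]] = {}
    for a, b, d in net.graph.edges(data=True):
        if net.partition[a] == net.partition[b]:
            intra.setdefault(net.partition[a], []).append(d["tc"])
        else:
            inter_tcs.append(d["tc"])
    for label, mem in sorted(net.members().items(),
                             key=lambda kv: (kv[0] == OTHERS_LABEL, kv[0])):
        tcs = intra.get(label, [])
        top = sorted(mem, key=lambda n: (-deg[n], n))[:top_n]
        rows.append({
            "module": label,
            "name": net.module_name(label),
            "size": len(mem),
            "mean_intra_tc": sum(tcs) / len(tcs) if tcs else float("nan"),
            "top_degree_members": ";".join(top),
        })
    df = pd.DataFrame(rows)
    df.attrs["mean_inter_tc"] = (
        sum(inter_tcs) / len(inter_tcs) if inter_tcs else float("nan"))
    return df


def to_graphml(net: CSNetwork, path: str | Path, prefix: str = "CS") -> None:
    """GraphML export with module/degree node attributes and tc edge attribute."""
    g = net.graph.copy()
    deg = net.degrees
    for n in g.nodes:
        g.nodes[n]["module"] = module_name(net.partition[n], prefix)
        g.nodes[n]["degree"] = deg[n]
    nx.write_graphml(g, str(path))


def write_membership_tsv(net: CSNetwork, path: str | Path,
                         prefix: str = "CS") -> int:
    """``compound<TAB>module<TAB>degree`` membership table, sorted by id."""
    deg = net.degrees
    n = 0
    with open(path, "w") as fh:
        fh.write("id\tmodule\tdegree\n")
        for node in sorted(net.graph.nodes):
            fh.write(f"{node}\t{module_name(net.partition[node], prefix)}\t{deg[node]}\n")
            n += 1
    return n
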