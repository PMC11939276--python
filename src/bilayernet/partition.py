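"""Seeded Louvain partitioning shared by the compound and target layers.

Community labels follow one convention everywhere: modules are numbered
1..k in order of descending size (ties broken by the lexically smallest
member id); label 0 is reserved for the pooled "others" bucket of modules
below a minimum size.
"""

from __future__ import annotations

import networkx as nx

from .errors import InputError

OTHERS_LABEL = 0


def louvain_partition(graph: nx.Graph, resolution: float = 1.0, seed: int = 0,
                      weight: str | None = "weight") -> dict:
    """Louvain community detection, deterministic for a fixed seed.

    Returns a node -> module-label map with labels 1..k assigned by
    descending module size, ties by smallest member id.  Singleton
    components come out as their own modules.  Pass ``weight=None`` for the
    unweighted variant.
    """
    if graph.number_of_nodes() == 0:
        raise InputError("cannot partition an empty graph")
    communities = nx.community.louvain_communities(
        graph, weight=weight, resolution=resolution, seed=seed)
    ordered = sorted(communities, key=lambda c: (-len(c), min(str(n) for n in c)))
    return {node: label for label, comm in enumerate(ordered, start=1) for node in comm}


def pool_small_modules(partition: dict, min_size: int = 3) -> dict:
    """Relabel modules below ``min_size`` into the 0 ("others") bucket.

    Surviving modules are renumbered contiguously from 1, preserving the
    size-then-id ordering of :func:`louvain_partition`.
    """
    sizes: dict[int, int] = {}
    for lab in partition.values():
        sizes[lab] = sizes.get(lab, 0) + 1
    members: dict[int, list] = {}
    for node, lab in partition.items():
        members.setdefault(lab, []).append(node)
    keep = [lab for lab, s in sizes.items() if s >= min_size]
    keep.sort(key=lambda lab: (-sizes[lab], min(str(n) for n in members[lab])))
    relabel = {lab: i for i, lab in enumerate(keep, start=1)}
    return {node: relabel.get(lab, OTHERS_LABEL) for node, lab in partition.items()}


def partition_modularity(graph: nx.Graph, partition: dict,
                         weight: str | None = "weight") -> float:
    """Newman modularity of a node->label partition."""
    groups: dict[int, set] = {}
    for node, lab in partition.items():
        groups.setdefault(lab, set()).add(node)
    return nx.community.modularity(graph, groups.values(), weight=weight)


def module_members(partition: dict) -> dict[int, set]:
    """Invert a node->label map into label -> member set."""
    out: dict[int, set] = {}
    for node, lab in partition.items():
        out.setdefault(lab, set()).add(node)
    return out
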