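"""Coupling the CS and TPT layers: e_uv and per-compound contributions.

The compound->target prediction table supplies interaction weights d_ij.
For a compound module m_u and a target module m_v, the module association

    e_uv = sum over i in m_u, j in m_v of d_ij

measures how strongly the chemistry of m_u points at the biology of m_v,
and each compound's contribution

    C(i)_uv = sum over j in m_v of d_ij        (i in m_u)

decomposes e_uv (sum_i C(i)_uv = e_uv) and ranks candidate active
compounds within the module pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cs_network import CSNetwork, module_name
from .errors import InputError
from .tpt_network import EnrichmentResult, PathwayAnnotation, TPTNetwork

log = logging.getLogger(__name__)

KNOWN_SOURCES = frozenset({"SuperPred", "SEA", "TCMSP"})
WEIGHTINGS = ("indicator", "source_count")


@dataclass
class InteractionTable:
    """Merged compound->target predictions with weights d_ij > 0.

    ``df`` has one row per (compound, target) pair with columns
    ``compound, target, sources (frozenset), d (float)``.
    """

    df: pd.DataFrame
    weighting: str = "indicator"

    @property
    def compound_ids(self) -> set[str]:
        return set(self.df["compound"])

    @property
    def target_ids(self) -> set[str]:
        return set(self.df["target"])

    @property
    def total_weight(self) -> float:
        return float(self.df["d"].sum())

    def __len__(self) -> int:
        return len(self.df)


def _merge_pairs(rows: pd.DataFrame, weighting: str) -> pd.DataFrame:
    merged = (rows.groupby(["compound", "target"], sort=True)["source"]
              .agg(lambda s: frozenset(s)).reset_index()
              .rename(columns={"source": "sources"}))
    if weighting == "indicator":
        merged["d"] = 1.0
    else:
        merged["d"] = merged["sources"].map(len).astype(float)
    return merged


def load_interactions(path: str | Path, weighting: str = "indicator",
                      known_sources: frozenset[str] = KNOWN_SOURCES) -> InteractionTable:
    """Read a 3-column TSV ``compound<TAB>target<TAB>source``.

    Rows are merged on (compound, target); d = 1 per pair (indicator) or
    the number of distinct predictor sources (source_count).  Unknown
    source labels are kept with a warning; malformed rows are skipped and
    counted.
    """
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    path = Path(path)
    if not path.is_file():
        raise InputError(f"interaction table not found: {path}")
    records, skipped, unknown = [], 0, set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:2] == ["compound", "target"]:
                continue
            if len(fields) < 3 or not all(f.strip() for f in fields[:3]):
                skipped += 1
                continue
            comp, targ, source = (f.strip() for f in fields[:3])
            if source not in known_sources:
                unknown.add(source)
            records.append((comp, targ, source))
    if skipped:
        log.warning("%s: skipped %d malformed row(s)", path, skipped)
    if unknown:
        log.warning("%s: unknown predictor source label(s) kept: %s",
                    path, ", ".join(sorted(unknown)))
    if not records:
        raise InputError(f"{path}: no interaction rows")
    rows = pd.DataFrame(records, columns=["compound", "target", "source"])
    return InteractionTable(df=_merge_pairs(rows, weighting), weighting=weighting)


def interactions_from_pairs(pairs: Iterable[tuple[str, str, str]],
                            weighting: str = "indicator") -> InteractionTable:
    """Build an InteractionTable from in-memory (compound, target, source) triples."""
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    rows = pd.DataFrame(list(pairs), columns=["compound", "target", "source"])
    if rows.empty:
        raise InputError("no interaction rows")
    return InteractionTable(df=_merge_pairs(rows, weighting), weighting=weighting)


@dataclass
class ModuleAssociation:
    """The e_uv matrix plus per-compound contributions C(i)_uv.

    ``e`` is indexed by compound-module label (rows) x target-module label
    (columns); ``contributions`` has one row per (compound, u, v) with a
    positive contribution; ``links`` keeps the module-annotated interaction
    rows the sums were taken over.
    """

    e: pd.DataFrame
    contributions: pd.DataFrame
    links: pd.DataFrame = field(repr=False)
    compound_module: dict[str, int] = field(repr=False)
    compound_degree: dict[str, int] = field(repr=False)
    n_excluded: dict[str, int] = field(default_factory=dict)

    def contribution(self, compound: str, u: int, v: int) -> float:
        sel = self.contributions
        m = sel[(sel["compound"] == compound) & (sel["u"] == u) & (sel["v"] == v)]
        return float(m["C"].sum())


def module_association(cs: CSNetwork, tpt: TPTNetwork,
                       interactions: InteractionTable) -> ModuleAssociation:
    """Compute e_uv and C(i)_uv from the two partitions and d_ij.

    Interaction rows whose compound or target fell out of its layer are
    excluded from all sums (counted in ``n_excluded``).  It is fatal if no
    interaction joins the two layers.
    """
    df = interactions.df
    in_cs = df["compound"].isin(cs.nodes)
    in_tpt = df["target"].isin(tpt.nodes)
    kept = df[in_cs & in_tpt].copy()
    n_excluded = {
        "compound_not_in_cs": int((~in_cs).sum()),
        "target_not_in_tpt": int((in_cs & ~in_tpt).sum()),
    }
    if n_excluded["compound_not_in_cs"] or n_excluded["target_not_in_tpt"]:
        log.info("bilayer join: %d rows kept, %d dropped (compound off-layer), "
                 "%d dropped (target off-layer)", len(kept),
                 n_excluded["compound_not_in_cs"], n_excluded["target_not_in_tpt"])
    if kept.empty:
        raise InputError(
            "no interaction joins the CS and TPT layers; check that compound "
            "and target ids match the network node ids")
    kept["u"] = kept["compound"].map(cs.partition)
    kept["v"] = kept["target"].map(tpt.partition)

    u_labels = sorted(set(cs.partition.values()))
    v_labels = sorted(set(tpt.partition.values()))
    e = (kept.pivot_table(index="u", columns="v", values="d", aggfunc="sum",
                          fill_value=0.0)
         .reindex(index=u_labels, columns=v_labels, fill_value=0.0))
    e.index.name, e.columns.name = "u", "v"

    contrib = (kept.groupby(["compound", "u", "v"], sort=True)["d"].sum()
               .reset_index().rename(columns={"d": "C"}))
    return ModuleAssociation(
        e=e, contributions=contrib, links=kept,
        compound_module=dict(cs.partition), compound_degree=cs.degrees,
        n_excluded=n_excluded)


def rank_compounds(ma: ModuleAssociation, u: int, v: int,
                   k: int = 3, normalized: bool = False) -> pd.DataFrame:
    """Top-k compounds of module u by contribution C(i)_uv to module v.

    All members of m_u are ranked (zero contributions included); ties are
    broken by CS-network degree descending, then lexical id.  With
    ``normalized=True`` scores are divided by e_uv (monotone-equivalent).
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    if u not in ma.e.index or v not in ma.e.columns:
        raise InputError(f"module pair (u={u}, v={v}) not present in the association")
    members = sorted(c for c, lab in ma.compound_module.items() if lab == u)
    sel = ma.contributions
    cvals = (sel[(sel["u"] == u) & (sel["v"] == v)]
             .set_index("compound")["C"].to_dict())
    e_uv = float(ma.e.loc[u, v])
    rows = []
    for c in members:
        score = cvals.get(c, 0.0)
        if normalized:
            score = score / e_uv if e_uv > 0 else 0.0
        rows.append({"compound": c, "u": u, "v": v, "C": score,
                     "degree": ma.compound_degree.get(c, 0)})
    rows.sort(key=lambda r: (-r["C"], -r["degree"], r["compound"]))
    out = pd.DataFrame(rows[:k])
    out.insert(0, "rank", range(1, len(out) + 1))
    return out


@dataclass
class PathwayFocus:
    """Highlighted module-pair cells for one enriched pathway of interest."""

    pathway_id: str
    pathway_name: str
    member_targets: set[str]          # pathway members present in the TPT layer
    target_modules: list[int]         # highlighted columns v
    compound_modules: list[int]       # highlighted rows u (interact with members)
    cells: list[tuple[int, int]]
    ranking: pd.DataFrame             # contribution restricted to member targets


def pathway_focus(ma: ModuleAssociation, tpt: TPTNetwork,
                  enriched: Sequence[EnrichmentResult],
                  pathway_name: str,
                  pathways: Sequence[PathwayAnnotation] | None = None,
                  top_k: int | None = None) -> PathwayFocus:
    """Highlight the (u, v) cells touched by one enriched pathway.

    The pathway must be among the enrichment results (matched by name or
    id).  Returns the target modules holding its members, the compound
    modules interacting with those targets, and a compound ranking by
    contribution restricted to the pathway's member targets.
    """
    match = [r for r in enriched if pathway_name in (r.name, r.pathway_id)]
    if not match:
        raise InputError(
            f"pathway {pathway_name!r} is not among the enriched pathways")
    res = match[0]
    members = set(res.overlap_members)
    if pathways is not None:
        by_id = {pw.id: pw for pw in pathways}
        members |= set(by_id[res.pathway_id].members)
    members &= tpt.nodes
    if not members:
        raise InputError(f"pathway {pathway_name!r} has no member in the TPT layer")
    v_modules = sorted({tpt.partition[t] for t in members})

    links = ma.links
    touching = links[links["target"].isin(members)]
    u_modules = sorted(set(touching["u"]))
    cells = sorted({(int(r.u), int(r.v)) for r in touching.itertuples()})

    restricted = (touching.groupby(["compound", "u"], sort=True)["d"].sum()
                  .reset_index().rename(columns={"d": "C_restricted"}))
    restricted["degree"] = restricted["compound"].map(
        lambda c: ma.compound_degree.get(c, 0))
    restricted = restricted.sort_values(
        by=["C_restricted", "degree", "compound"],
        ascending=[False, False, True], kind="mergesort").reset_index(drop=True)
    if top_k is not None:
        restricted = restricted.head(top_k).copy()
    restricted.insert(0, "rank", range(1, len(restricted) + 1))
    return PathwayFocus(
        pathway_id=res.pathway_id, pathway_name=res.name,
        member_targets=members, target_modules=v_modules,
        compound_modules=u_modules, cells=cells, ranking=restricted)


def export_association_heatmap_table(ma: ModuleAssociation,
                                     path: str | Path | None = None) -> pd.DataFrame:
    """e_uv as a labelled matrix (rows: CS modules, columns: TPT modules).

    Row/column order follows the module labels; the "others" bucket, when
    present, is label 0 and sorts last.  Optionally written as TSV.
    """
    order_u = sorted(ma.e.index, key=lambda l: (l == 0, l))
    order_v = sorted(ma.e.columns, key=lambda l: (l == 0, l))
    table = ma.e.loc[order_u, order_v].copy()
    table.index = [module_name(l, "CS") for l in order_u]
    table.columns = [module_name(l, "TPT") for l in order_v]
    if path is not None:
        table.to_csv(path, sep="\t", float_format="%.6g")
    return table


def write_contributions_tsv(ma: ModuleAssociation, path: str | Path) -> int:
    """``compound, m_u, m_v, C, rank`` with ranks per (u, v) cell."""
    df = ma.contributions.copy()
    df["degree"] = df["compound"].map(lambda c: ma.compound_degree.get(c, 0))
    df = df.sort_values(by=["u", "v", "C", "degree", "compound"],
                        ascending=[True, True, False, False, True],
                        kind="mergesort")
    df["rank"] = df.groupby(["u", "v"]).cumcount() + 1
    out = df[["compound", "u", "v", "C", "rank"]].rename(
        columns={"u": "m_u", "v": "m_v"})
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return len(out)
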