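"""End-to-end orchestration of the bilayer CS-TPT analysis.

``analyze`` runs the whole method in memory (similarity -> CS network ->
enrichment -> TPT network -> module association -> ranking);
``run_pipeline`` wraps it with file input/output, logging and a run
manifest, driven by a :class:`RunConfig` that can be loaded from YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import bilayer, chem, cs_network, synthetic, tpt_network
from .bilayer import InteractionTable, ModuleAssociation, PathwayFocus
from .chem import Compound
from .cs_network import CSNetwork
from .errors import ConfigError, InputError
from .tpt_network import EnrichmentResult, PathwayAnnotation, TPTNetwork

log = logging.getLogger(__name__)

STAGES = ("inputs", "similarity", "cs_network", "enrichment", "tpt_network",
          "scoring")


def stage_seed(seed: int, stage_index: int) -> int:
    """Fan one config seed out to per-stage seeds (documented derivation).

    stage_seed = (seed * 7919 + stage_index) mod (2^31 - 1); 7919 is just a
    fixed odd prime, keeping derived seeds below 2^31 and distinct per stage.
    """
    return (seed * 7919 + stage_index) % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    ``mode`` is "synthetic" (inputs generated from ``synthetic``) or "real"
    (``structures``/``compounds``, ``interactions`` and ``pathways`` paths).
    The analysis constants default to the study's stated values: Tc
    threshold 0.8, Louvain resolution 1.0, enrichment alpha 0.05, top 3.
    """

    mode: str = "synthetic"
    synthetic: synthetic.SyntheticSpec | None = None
    structures: str | None = None       # SMILES/SDF file (real mode)
    compounds: str | None = None        # fingerprint table (synthetic-format input)
    interactions: str | None = None
    pathways: str | None = None
    tc_threshold: float = 0.8
    resolution: float = 1.0
    seed: int = 0
    alpha: float = 0.05
    fdr: bool = False
    weighting: str = "indicator"
    weighted_louvain: bool = True
    min_module_size: int = 3
    fp_length: int = 2048
    fp_kind: str = "morgan"
    focal_pathway: str | None = None
    top_k: int = 3
    outdir: str = "bilayernet_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
            d["synthetic"]["pathway_size_range"] = list(
                self.synthetic.pathway_size_range)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


_CONFIG_TYPES = {
    "mode": str, "structures": str, "compounds": str, "interactions": str,
    "pathways": str, "tc_threshold": (int, float), "resolution": (int, float),
    "seed": int, "alpha": (int, float), "fdr": bool, "weighting": str,
    "weighted_louvain": bool, "min_module_size": int, "fp_length": int,
    "fp_kind": str, "focal_pathway": str, "top_k": int, "outdir": str,
}


def validate_config_dict(raw: dict) -> RunConfig:
    """Build a RunConfig from a plain dict, collecting all errors at once."""
    errors: list[str] = []
    kwargs: dict = {}
    raw = dict(raw or {})
    syn_raw = raw.pop("synthetic", None)
    spec_fields = {f.name for f in dataclasses.fields(synthetic.SyntheticSpec)}
    for key, value in raw.items():
        if key not in _CONFIG_TYPES:
            log.warning("config: unknown key %r ignored", key)
            continue
        want = _CONFIG_TYPES[key]
        if value is not None and not isinstance(value, want):
            errors.append(f"{key}: expected {want}, got {type(value).__name__}")
            continue
        kwargs[key] = value
    spec = None
    if syn_raw is not None:
        if not isinstance(syn_raw, dict):
            errors.append("synthetic: expected a mapping of generator parameters")
        else:
            bad = set(syn_raw) - spec_fields
            for key in sorted(bad):
                log.warning("config: unknown synthetic key %r ignored", key)
            clean = {k: v for k, v in syn_raw.items() if k in spec_fields}
            if "pathway_size_range" in clean:
                clean["pathway_size_range"] = tuple(clean["pathway_size_range"])
            try:
                spec = synthetic.SyntheticSpec(**clean)
                spec.validate()
            except (TypeError, InputError) as exc:
                errors.append(f"synthetic: {exc}")
    cfg = RunConfig(synthetic=spec, **kwargs)

    if cfg.mode not in ("synthetic", "real"):
        errors.append(f"mode must be 'synthetic' or 'real', got {cfg.mode!r}")
    if not 0.0 < cfg.tc_threshold <= 1.0:
        errors.append(f"tc_threshold must be in (0,1], got {cfg.tc_threshold}")
    if cfg.resolution <= 0:
        errors.append(f"resolution must be positive, got {cfg.resolution}")
    if not 0.0 < cfg.alpha <= 1.0:
        errors.append("alpha must be in (0,1]")
    if cfg.weighting not in bilayer.WEIGHTINGS:
        errors.append(f"weighting must be one of {bilayer.WEIGHTINGS}")
    if cfg.top_k <= 0:
        errors.append(f"top_k must be positive, got {cfg.top_k}")
    if cfg.min_module_size < 1:
        errors.append(f"min_module_size must be >= 1, got {cfg.min_module_size}")
    if cfg.mode == "synthetic":
        if cfg.synthetic is None:
            cfg.synthetic = synthetic.SyntheticSpec(seed=cfg.seed)
    else:
        if cfg.structures is None and cfg.compounds is None:
            errors.append("real mode needs 'structures' (SMILES/SDF) or "
                          "'compounds' (fingerprint table), and no synthetic "
                          "spec was given")
        if cfg.interactions is None:
            errors.append("real mode needs an 'interactions' TSV path")
        if cfg.pathways is None:
            errors.append("real mode needs a 'pathways' GMT path")
    if errors:
        raise ConfigError(errors)
    return cfg


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.is_file():
        raise ConfigError([f"config file not found: {path}"])
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a YAML mapping"])
    return validate_config_dict(raw)


@dataclass
class AnalysisResult:
    """All stage outputs of one in-memory run."""

    compounds: list[Compound]
    edges: list[chem.SimilarityEdge]
    interactions: InteractionTable
    cs: CSNetwork
    query_targets: set[str]
    background: set[str]
    enriched: list[EnrichmentResult]
    tpt: TPTNetwork
    ma: ModuleAssociation
    focus: PathwayFocus | None
    top_compounds: "object"  # DataFrame: the final ranked report
    counts: dict = field(default_factory=dict)


def analyze(compounds: Sequence[Compound],
            interactions: InteractionTable,
            pathways: Sequence[PathwayAnnotation],
            *,
            tc_threshold: float = 0.8,
            resolution: float = 1.0,
            seed: int = 0,
            alpha: float = 0.05,
            fdr: bool = False,
            min_module_size: int = 3,
            weighted_louvain: bool = True,
            focal_pathway: str | None = None,
            top_k: int = 3) -> AnalysisResult:
    """Run the full bilayer analysis in memory.

    The enrichment query is the set of targets predicted for networked
    compounds; the background is the annotation universe (all GMT genes)
    united with the query.  The final ranking is the focal pathway's
    restricted contribution ranking when ``focal_pathway`` is given,
    otherwise the C(i)_uv ranking of the strongest e_uv cell.
    """
    edges = chem.build_similarity_edges(compounds, threshold=tc_threshold)
    cs = cs_network.assemble_cs_network(
        compounds, edges, interactions.compound_ids,
        resolution=resolution, seed=stage_seed(seed, 2),
        min_module_size=min_module_size, weighted=weighted_louvain)

    idf = interactions.df
    query = set(idf.loc[idf["compound"].isin(cs.nodes), "target"])
    background = set().union(*(pw.members for pw in pathways)) | query
    enriched = tpt_network.enrich_targets(query, pathways, background,
                                          alpha=alpha, fdr=fdr)
    tpt = tpt_network.build_tpt_network(
        enriched, pathways, restrict_to=query,
        resolution=resolution, seed=stage_seed(seed, 4))
    ma = bilayer.module_association(cs, tpt, interactions)

    focus = None
    if focal_pathway is not None:
        focus = bilayer.pathway_focus(ma, tpt, enriched, focal_pathway,
                                      pathways=pathways, top_k=top_k)
        top = focus.ranking
    else:
        u_star, v_star = ma.e.stack().idxmax()
        top = bilayer.rank_compounds(ma, int(u_star), int(v_star), k=top_k)

    counts = {
        "compounds_in": len(compounds),
        "similarity_edges": len(edges),
        "networked_compounds": len(cs.nodes),
        "cs_edges": cs.graph.number_of_edges(),
        "cs_modules": len({l for l in cs.partition.values() if l != 0}),
        "interaction_pairs": len(interactions),
        "predicted_targets": len(set(idf["target"])),
        "query_targets": len(query),
        "enriched_pathways": len(enriched),
        "enriched_targets": len(tpt.nodes),
        "tpt_edges": tpt.graph.number_of_edges(),
        "tpt_modules": len(set(tpt.partition.values())),
    }
    return AnalysisResult(
        compounds=list(compounds), edges=edges, interactions=interactions,
        cs=cs, query_targets=query, background=background, enriched=enriched,
        tpt=tpt, ma=ma, focus=focus, top_compounds=top, counts=counts)


def planted_module_pair(res: AnalysisResult,
                        ds: "synthetic.SyntheticDataset") -> tuple[int, int]:
    """Recovered (u, v) labels of the planted active cluster and focal module.

    u is the majority CS-module label among networked members of the planted
    active cluster; v is the majority TPT-module label among the focal
    pathway's in-network member targets.
    """
    from collections import Counter

    gt = ds.ground_truth
    cluster_members = [c for c, cl in gt.compound_cluster.items()
                       if cl == gt.active_cluster and c in res.cs.nodes]
    if not cluster_members:
        raise InputError("no member of the planted active cluster is networked")
    u = Counter(res.cs.partition[c] for c in cluster_members).most_common(1)[0][0]
    focal = next(p for p in ds.pathways if p.id == gt.focal_pathway_id)
    in_net = [t for t in focal.members if t in res.tpt.nodes]
    if not in_net:
        raise InputError("no focal-pathway member reached the TPT layer")
    v = Counter(res.tpt.partition[t] for t in in_net).most_common(1)[0][0]
    return u, v


def _load_inputs(cfg: RunConfig, outdir: Path):
    if cfg.mode == "synthetic":
        spec = cfg.synthetic
        ds = synthetic.generate_dataset(spec)
        synthetic.emit_dataset(spec, outdir / "inputs")
        interactions = ds.interaction_table(weighting=cfg.weighting)
        focal = cfg.focal_pathway or ds.ground_truth.focal_pathway_name
        return ds.compounds, interactions, ds.pathways, focal
    if cfg.structures is not None:
        compounds = chem.parse_structures(cfg.structures)
        for c in compounds:
            chem.compute_fingerprint(c, fp_length=cfg.fp_length,
                                     fp_kind=cfg.fp_kind)
    else:
        compounds = synthetic.load_fingerprint_table(cfg.compounds,
                                                     fp_length=cfg.fp_length)
    interactions = bilayer.load_interactions(cfg.interactions,
                                             weighting=cfg.weighting)
    pathways = tpt_network.load_gmt(cfg.pathways)
    return compounds, interactions, pathways, cfg.focal_pathway


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages, write every stage's output file, return the manifest.

    The manifest records the config and its hash, per-stage row counts, the
    final top-k table and a ``manifest_hash`` over the stable content
    (everything except the timestamp), so identical configs reproduce
    identical hashes.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("bilayernet")
    root.addHandler(handler)
    try:
        try:
            compounds, interactions, pathways, focal = _load_inputs(cfg, outdir)
        except InputError as exc:
            raise InputError(f"stage 'inputs' failed: {exc}") from exc
        try:
            res = analyze(
                compounds, interactions, pathways,
                tc_threshold=cfg.tc_threshold, resolution=cfg.resolution,
                seed=cfg.seed, alpha=cfg.alpha, fdr=cfg.fdr,
                min_module_size=cfg.min_module_size,
                weighted_louvain=cfg.weighted_louvain,
                focal_pathway=focal, top_k=cfg.top_k)
        except InputError as exc:
            raise InputError(f"analysis failed: {exc}") from exc

        chem.write_edge_tsv(res.edges, outdir / "similarity_edges.tsv")
        cs_network.to_graphml(res.cs, outdir / "cs_network.graphml", "CS")
        cs_network.write_membership_tsv(res.cs, outdir / "cs_modules.tsv", "CS")
        summary = cs_network.summarize_modules(res.cs)
        summary.to_csv(outdir / "cs_module_summary.tsv", sep="\t", index=False)
        tpt_network.write_enrichment_tsv(res.enriched, outdir / "enrichment.tsv")
        cs_network.to_graphml(res.tpt, outdir / "tpt_network.graphml", "TPT")
        cs_network.write_membership_tsv(res.tpt, outdir / "tpt_modules.tsv", "TPT")
        propensity = tpt_network.module_propensity(res.tpt, res.enriched, pathways)
        propensity.to_csv(outdir / "tpt_module_propensity.tsv", sep="\t", index=False)
        bilayer.export_association_heatmap_table(res.ma, outdir / "e_uv.tsv")
        bilayer.write_contributions_tsv(res.ma, outdir / "contributions.tsv")
        res.top_compounds.to_csv(outdir / "top_compounds.tsv", sep="\t", index=False)

        manifest = {
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash(),
            "stage_seeds": {name: stage_seed(cfg.seed, i)
                            for i, name in enumerate(STAGES)},
            "stages": res.counts,
            "focal_pathway": focal,
            "top_compounds": res.top_compounds.to_dict(orient="records"),
            "outputs": sorted(p.name for p in outdir.iterdir()
                              if p.is_file()
                              and p.name not in ("run.log", "manifest.json")),
        }
        # the hash witnesses reproducibility of the analysis, not of the
        # output location: drop 'outdir' before hashing
        hashed = json.loads(json.dumps(manifest, sort_keys=True, default=str))
        hashed["config"].pop("outdir", None)
        hashed.pop("config_hash", None)  # covers outdir as well
        manifest["manifest_hash"] = hashlib.sha256(
            json.dumps(hashed, sort_keys=True).encode()).hexdigest()
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()
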