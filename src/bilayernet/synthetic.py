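"""Planted-structure synthetic data for the bilayer pipeline.

Generates a compound library (fingerprints with planted structural
clusters), a pathway annotation (GMT with planted target modules), and a
compound->target prediction table (background rate plus boosted
cluster-module pairs plus a small set of planted "active" compounds whose
extra targets concentrate in one focal pathway), together with the ground
truth needed to score recovery.

Everything is a pure function of the :class:`SyntheticSpec`: the same spec
reproduces byte-identical output files.  All generation decisions use
integer RNG comparisons so determinism cannot depend on platform
floating-point behaviour.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .bilayer import InteractionTable, interactions_from_pairs
from .chem import Compound
from .errors import InputError
from .tpt_network import PathwayAnnotation

log = logging.getLogger(__name__)

SOURCES = ("SuperPred", "SEA", "TCMSP")
FOCAL_PATHWAY_NAME = "Oxidative stress response (focal)"

_BERN_SCALE = 1_000_000_000


def _bernoulli(rng: np.random.Generator, p: float, size) -> np.ndarray:
    """Bernoulli(p) draws via integer comparison (platform-stable)."""
    return rng.integers(0, _BERN_SCALE, size=size) < int(round(p * _BERN_SCALE))


@dataclass(frozen=True)
class SyntheticSpec:
    """All parameters of the planted-structure generator.

    Defaults emulate the scale of the motivating study: ~1000 compounds of
    which ~730 sit in 15 structural clusters (the rest are structurally
    isolated "others" that never reach the Tc threshold), ~850 targets in
    4 functional blocks, ~120 pathways mostly drawn from a single block,
    and 3 planted active compounds whose extra targets concentrate in one
    focal pathway.
    """

    n_compounds: int = 1000
    n_clusters: int = 15
    cluster_size_power: float = 0.8     # sizes ~ rank^(-power), truncated
    others_fraction: float = 0.27       # structurally isolated compounds
    fp_length: int = 2048
    seed_bit_density: float = 0.25      # see Tc derivation in generate_compounds
    within_cluster_flip_rate: float = 0.02
    between_cluster_overlap: float = 0.05
    n_targets: int = 850
    n_background_genes: int = 1650      # annotation universe beyond the targets
    n_pathways: int = 120
    n_target_modules: int = 4
    pathway_module_purity: float = 0.9
    pathway_target_fraction: float = 0.7
    background_pathway_fraction: float = 0.25  # target-poor, never enriched
    pathway_size_range: tuple[int, int] = (10, 40)
    background_interaction_rate: float = 0.004
    planted_pair_boost: float = 12.0
    n_boosted_pairs: int = 6
    n_planted_actives: int = 3
    active_extra_targets: int = 8
    focal_pathway_size: int = 15
    max_sources_per_interaction: int = 3
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "others_fraction": self.others_fraction,
            "seed_bit_density": self.seed_bit_density,
            "within_cluster_flip_rate": self.within_cluster_flip_rate,
            "between_cluster_overlap": self.between_cluster_overlap,
            "pathway_module_purity": self.pathway_module_purity,
            "pathway_target_fraction": self.pathway_target_fraction,
            "background_pathway_fraction": self.background_pathway_fraction,
            "background_interaction_rate": self.background_interaction_rate,
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {r}")
        counts = {
            "n_compounds": self.n_compounds, "n_clusters": self.n_clusters,
            "fp_length": self.fp_length, "n_targets": self.n_targets,
            "n_pathways": self.n_pathways,
            "n_target_modules": self.n_target_modules,
            "n_planted_actives": self.n_planted_actives,
            "focal_pathway_size": self.focal_pathway_size,
        }
        for name, c in counts.items():
            if c <= 0:
                raise InputError(f"{name} must be positive, got {c}")
        if self.active_extra_targets > self.focal_pathway_size:
            raise InputError("active_extra_targets cannot exceed focal_pathway_size")
        if self.planted_pair_boost < 1.0:
            raise InputError("planted_pair_boost must be >= 1")

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Planted labels written alongside the generated dataset."""

    compound_cluster: dict[str, int] = field(default_factory=dict)  # 0 = others
    target_module: dict[str, int] = field(default_factory=dict)
    planted_actives: list[str] = field(default_factory=list)
    focal_pathway_id: str = ""
    focal_pathway_name: str = FOCAL_PATHWAY_NAME
    active_cluster: int = 0
    focal_target_module: int = 0
    boosted_pairs: list[tuple[int, int]] = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        d["boosted_pairs"] = [list(p) for p in self.boosted_pairs]
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["boosted_pairs"] = [tuple(p) for p in d["boosted_pairs"]]
        return cls(**d)


def _cluster_sizes(spec: SyntheticSpec) -> list[int]:
    """Truncated power-law cluster sizes summing to the clustered count."""
    n_clustered = spec.n_compounds - int(round(spec.n_compounds * spec.others_fraction))
    w = np.arange(1, spec.n_clusters + 1, dtype=float) ** (-spec.cluster_size_power)
    raw = w / w.sum() * n_clustered
    sizes = np.floor(raw).astype(int)
    # largest-remainder rounding so sizes sum exactly
    for i in np.argsort(-(raw - sizes))[: n_clustered - sizes.sum()]:
        sizes[i] += 1
    sizes = np.maximum(sizes, max(3, spec.n_planted_actives))
    return sizes.tolist()


def generate_compounds(spec: SyntheticSpec,
                       rng: np.random.Generator | None = None
                       ) -> tuple[list[Compound], dict[str, int]]:
    """Fingerprint library with planted structural clusters.

    Each cluster has a seed fingerprint with ``seed_bit_density * fp_length``
    set bits (sharing a small core across clusters, ``between_cluster_overlap``
    of the set bits); members flip every bit independently at rate eps.

    Expected Tanimoto between two members of one cluster, with k set seed
    bits out of L and flip rate eps:

        E[Tc] ~ (k(1-eps)^2 + (L-k)eps^2) / (k(1-eps^2) + (L-k)(2eps))

    At the defaults (L=2048, density 0.25 so k=512, eps=0.02) this is
    ~0.855, comfortably above the 0.8 edge threshold, while unrelated
    fingerprints at density 0.25 sit near Tc ~ 0.15.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    L = spec.fp_length
    k = int(round(spec.seed_bit_density * L))
    core_n = int(round(spec.between_cluster_overlap * k))
    core = rng.choice(L, size=core_n, replace=False)
    non_core = np.setdiff1d(np.arange(L), core)
    # When the fingerprint is long enough, every cluster seed draws its
    # non-core bits from a private pool, so clusters with zero overlap and
    # zero flip rate are exactly Tc = 0 apart.  At the defaults the pools
    # would need n_clusters * (k - core_n) bits > L, so seeds fall back to
    # shared sampling (cross-cluster Tc ~ 0.15, still far below 0.8).
    per_cluster = k - core_n
    disjoint = spec.n_clusters * per_cluster <= len(non_core)
    if disjoint:
        shuffled = rng.permutation(non_core)
        pools = [shuffled[i * per_cluster:(i + 1) * per_cluster]
                 for i in range(spec.n_clusters)]

    sizes = _cluster_sizes(spec)
    compounds: list[Compound] = []
    cluster_of: dict[str, int] = {}
    idx = 0
    for c_label, size in enumerate(sizes, start=1):
        seed_fp = np.zeros(L, dtype=np.uint8)
        seed_fp[core] = 1
        if disjoint:
            seed_fp[pools[c_label - 1]] = 1
        else:
            seed_fp[rng.choice(non_core, size=per_cluster, replace=False)] = 1
        flips = _bernoulli(rng, spec.within_cluster_flip_rate, (size, L))
        member_fps = np.bitwise_xor(seed_fp[None, :], flips.astype(np.uint8))
        for row in member_fps:
            idx += 1
            cid = f"C{idx:04d}"
            compounds.append(Compound(id=cid, name=f"syn-compound-{idx}",
                                      fingerprint=row))
            cluster_of[cid] = c_label
    n_others = spec.n_compounds - idx
    others_fp = _bernoulli(rng, spec.seed_bit_density,
                           (n_others, L)).astype(np.uint8)
    for row in others_fp:
        idx += 1
        cid = f"C{idx:04d}"
        compounds.append(Compound(id=cid, name=f"syn-compound-{idx}",
                                  fingerprint=row))
        cluster_of[cid] = 0
    return compounds, cluster_of


def generate_pathways_and_targets(spec: SyntheticSpec,
                                  rng: np.random.Generator | None = None
                                  ) -> tuple[list[str], list[PathwayAnnotation],
                                             dict[str, int], str, int]:
    """Pathway annotation with planted target modules.

    Targets are split into ``n_target_modules`` blocks.  Most pathways are
    target-rich: ``pathway_target_fraction`` of their members are targets,
    drawn from one home block with probability ``pathway_module_purity``;
    the rest of the membership comes from non-target background genes, so
    a hypergeometric ORA of the predicted targets flags them.  A
    ``background_pathway_fraction`` of pathways are target-poor and stay
    unenriched.  One designated focal pathway (the oxidative-stress-response
    analog) sits entirely inside one block.

    Returns (targets, pathways, target->module map, focal pathway id,
    focal module label).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    targets = [f"T{i:04d}" for i in range(1, spec.n_targets + 1)]
    genes = [f"G{i:04d}" for i in range(1, spec.n_background_genes + 1)]

    perm = rng.permutation(spec.n_targets)
    blocks: dict[int, list[str]] = {}
    target_module: dict[str, int] = {}
    for pos, t_idx in enumerate(perm):
        m = pos % spec.n_target_modules + 1
        blocks.setdefault(m, []).append(targets[t_idx])
        target_module[targets[t_idx]] = m
    for m in blocks:
        blocks[m].sort()

    focal_module = int(rng.integers(1, spec.n_target_modules + 1))
    focal_members = sorted(rng.choice(blocks[focal_module],
                                      size=spec.focal_pathway_size,
                                      replace=False))
    pathways = [PathwayAnnotation(id="PWY0000", name=FOCAL_PATHWAY_NAME,
                                  members=frozenset(focal_members))]
    lo, hi = spec.pathway_size_range
    for i in range(1, spec.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        is_background = bool(_bernoulli(rng, spec.background_pathway_fraction, ()))
        target_frac = 0.1 if is_background else spec.pathway_target_fraction
        n_t = min(int(round(size * target_frac)), spec.n_targets)
        home = int(rng.integers(1, spec.n_target_modules + 1))
        n_home = min(int(round(n_t * spec.pathway_module_purity)), len(blocks[home]))
        members = set(rng.choice(blocks[home], size=n_home, replace=False))
        away = sorted(set(targets) - set(blocks[home]))
        n_away = min(n_t - n_home, len(away))
        if n_away > 0:
            members |= set(rng.choice(away, size=n_away, replace=False))
        n_bg = max(size - len(members), 0)
        members |= set(rng.choice(genes, size=min(n_bg, len(genes)), replace=False))
        pathways.append(PathwayAnnotation(
            id=f"PWY{i:04d}",
            name=f"Synthetic pathway {i}" + (" (background)" if is_background else ""),
            members=frozenset(members)))
    return targets, pathways, target_module, "PWY0000", focal_module


def generate_interactions(spec: SyntheticSpec,
                          compounds: Sequence[Compound],
                          targets: Sequence[str],
                          cluster_of: dict[str, int],
                          target_module: dict[str, int],
                          focal_members: Sequence[str],
                          focal_module: int,
                          rng: np.random.Generator | None = None
                          ) -> tuple[list[tuple[str, str, str]], GroundTruth]:
    """Compound->target prediction triples with planted signal.

    Every (compound, target) pair is Bernoulli(p0); for ``n_boosted_pairs``
    designated (cluster, target-module) pairs the rate is boosted to
    ``planted_pair_boost * p0`` (clipped at 1 with a warning).  The planted
    active compounds — members of one randomly chosen cluster — each
    additionally receive ``active_extra_targets`` interactions drawn
    uniformly without replacement from the focal pathway's members.  The
    (active cluster, focal module) pair is never boosted, so the actives'
    advantage comes only from the planted extras.  Each interaction gets
    1..max_sources_per_interaction predictor source labels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 2) if rng is None else rng
    comp_ids = [c.id for c in compounds]
    p0 = spec.background_interaction_rate
    boosted_rate = spec.planted_pair_boost * p0
    if boosted_rate > 1.0:
        log.warning("boosted interaction rate %.3f clipped to 1", boosted_rate)
        boosted_rate = 1.0

    eligible = [cl for cl in range(1, spec.n_clusters + 1)
                if sum(1 for v in cluster_of.values() if v == cl)
                >= spec.n_planted_actives]
    active_cluster = int(rng.choice(eligible))
    candidates = [(cl, m) for cl in range(1, spec.n_clusters + 1)
                  for m in range(1, spec.n_target_modules + 1)
                  if (cl, m) != (active_cluster, focal_module)]
    picked = rng.choice(len(candidates),
                        size=min(spec.n_boosted_pairs, len(candidates)),
                        replace=False)
    boosted_pairs = sorted(candidates[i] for i in picked)
    boosted_set = set(boosted_pairs)

    comp_cluster = np.array([cluster_of[c] for c in comp_ids])
    targ_module = np.array([target_module[t] for t in targets])
    thr = np.full((len(comp_ids), len(targets)),
                  int(round(p0 * _BERN_SCALE)), dtype=np.int64)
    for (cl, m) in boosted_set:
        mask = np.outer(comp_cluster == cl, targ_module == m)
        thr[mask] = int(round(boosted_rate * _BERN_SCALE))
    hits = rng.integers(0, _BERN_SCALE, size=thr.shape) < thr

    members = sorted(c for c, v in cluster_of.items() if v == active_cluster)
    actives = sorted(str(a) for a in rng.choice(
        members, size=spec.n_planted_actives, replace=False))
    t_index = {t: j for j, t in enumerate(targets)}
    c_index = {c: i for i, c in enumerate(comp_ids)}
    focal_sorted = sorted(focal_members)
    for a in actives:
        extra = rng.choice(focal_sorted, size=spec.active_extra_targets,
                           replace=False)
        for t in extra:
            hits[c_index[a], t_index[t]] = True

    triples: list[tuple[str, str, str]] = []
    ii, jj = np.nonzero(hits)
    for i, j in zip(ii.tolist(), jj.tolist()):
        n_src = int(rng.integers(1, spec.max_sources_per_interaction + 1))
        chosen = rng.choice(len(SOURCES), size=n_src, replace=False)
        for s in sorted(chosen.tolist()):
            triples.append((comp_ids[i], targets[j], SOURCES[s]))

    gt = GroundTruth(
        compound_cluster=dict(cluster_of),
        target_module=dict(target_module),
        planted_actives=list(actives),
        active_cluster=active_cluster,
        focal_target_module=focal_module,
        boosted_pairs=[tuple(p) for p in boosted_pairs])
    return triples, gt


@dataclass
class SyntheticDataset:
    """In-memory bundle of one generated study."""

    spec: SyntheticSpec
    compounds: list[Compound]
    pathways: list[PathwayAnnotation]
    interaction_triples: list[tuple[str, str, str]]
    ground_truth: GroundTruth

    def interaction_table(self, weighting: str = "indicator") -> InteractionTable:
        return interactions_from_pairs(self.interaction_triples, weighting=weighting)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Run all three generators off one seed and assemble the ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    compounds, cluster_of = generate_compounds(spec, rng)
    targets, pathways, target_module, focal_id, focal_module = \
        generate_pathways_and_targets(spec, rng)
    focal_members = sorted(next(p for p in pathways if p.id == focal_id).members)
    triples, gt = generate_interactions(
        spec, compounds, targets, cluster_of, target_module,
        focal_members, focal_module, rng)
    gt.focal_pathway_id = focal_id
    gt.focal_pathway_name = FOCAL_PATHWAY_NAME
    return SyntheticDataset(spec=spec, compounds=compounds, pathways=pathways,
                            interaction_triples=triples, ground_truth=gt)


def fingerprint_to_hex(fp: np.ndarray) -> str:
    return np.packbits(fp.astype(np.uint8)).tobytes().hex()


def hex_to_fingerprint(hexstr: str, length: int) -> np.ndarray:
    raw = np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8)
    return np.unpackbits(raw)[:length].astype(np.uint8)


def emit_dataset(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the generated dataset as plain-text files.

    Emits ``compounds.tsv`` (id, name, hex-encoded fingerprint),
    ``interactions.tsv``, ``pathways.gmt`` and ``ground_truth.json``.
    Re-running with the same spec reproduces byte-identical files.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise InputError(f"output directory not writable: {outdir}: {exc}")
    ds = generate_dataset(spec)
    paths = {
        "compounds": outdir / "compounds.tsv",
        "interactions": outdir / "interactions.tsv",
        "pathways": outdir / "pathways.gmt",
        "ground_truth": outdir / "ground_truth.json",
    }
    with open(paths["compounds"], "w") as fh:
        fh.write("id\tname\tfingerprint_hex\n")
        for c in ds.compounds:
            fh.write(f"{c.id}\t{c.name}\t{fingerprint_to_hex(c.fingerprint)}\n")
    with open(paths["interactions"], "w") as fh:
        fh.write("compound\ttarget\tsource\n")
        for comp, targ, src in ds.interaction_triples:
            fh.write(f"{comp}\t{targ}\t{src}\n")
    with open(paths["pathways"], "w") as fh:
        for pw in ds.pathways:
            fh.write("\t".join([pw.id, pw.name] + sorted(pw.members)) + "\n")
    paths["ground_truth"].write_text(ds.ground_truth.to_json() + "\n")
    return paths


def load_fingerprint_table(path: str | Path,
                           fp_length: int = 2048) -> list[Compound]:
    """Read a ``compounds.tsv`` written by :func:`emit_dataset`."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"fingerprint table not found: {path}")
    out: list[Compound] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise InputError(f"{path}: missing 'id' header line")
        for line in fh:
            cid, name, hexfp = line.rstrip("\n").split("\t")
            out.append(Compound(id=cid, name=name,
                                fingerprint=hex_to_fingerprint(hexfp, fp_length)))
    if not out:
        raise InputError(f"{path}: zero records")
    return out
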