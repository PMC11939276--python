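"""Shared fixtures and independent brute-force oracles for the test suite."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import settings

from bilayernet import Compound

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


# ---------------------------------------------------------------- oracles

def brute_tanimoto(fa, fb) -> float:
    """Set-arithmetic Tanimoto, independent of the vectorised code path."""
    sa = {i for i, b in enumerate(fa) if b}
    sb = {i for i, b in enumerate(fb) if b}
    union = sa | sb
    return len(sa & sb) / len(union) if union else 0.0


def brute_edges(fps, threshold):
    """Double-loop similarity scan over all unordered index pairs."""
    out = []
    for i in range(len(fps)):
        for j in range(i + 1, len(fps)):
            tc = brute_tanimoto(fps[i], fps[j])
            if tc >= threshold:
                out.append((i, j, tc))
    return out


def brute_hypergeom_tail(k, N, K, n) -> float:
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws.

    The population is {0..N-1} with successes {0..K-1}; feasible for N <= 12.
    """
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total


def brute_comembership(member_sets):
    """Pairwise shared-set counts over a list of gene sets."""
    weights = {}
    for members in member_sets:
        for t1, t2 in itertools.combinations(sorted(members), 2):
            weights[(t1, t2)] = weights.get((t1, t2), 0) + 1
    return weights


def brute_e_uv(rows, comp_module, targ_module):
    """Direct double sum of d_ij grouped by module pair."""
    e = {}
    for comp, targ, d in rows:
        key = (comp_module[comp], targ_module[targ])
        e[key] = e.get(key, 0.0) + d
    return e


def random_bilayer_instance(rng):
    """A random two-layer instance for conservation checks.

    Returns (cs, tpt, interaction table, raw (compound, target, d) rows,
    compound->module map, target->module map) with interactions restricted
    to networked nodes by construction.
    """
    import networkx as nx

    from bilayernet import interactions_from_pairs
    from bilayernet.cs_network import CSNetwork
    from bilayernet.tpt_network import TPTNetwork

    n_c = int(rng.integers(4, 25))
    n_t = int(rng.integers(3, 20))
    comps = [f"c{i}" for i in range(n_c)]
    targs = [f"t{i}" for i in range(n_t)]
    cmod = {c: int(rng.integers(1, 5)) for c in comps}
    tmod = {t: int(rng.integers(1, 4)) for t in targs}
    gc = nx.Graph()
    gc.add_nodes_from(comps)
    gt = nx.Graph()
    gt.add_nodes_from(targs)
    cs = CSNetwork(graph=gc, partition=cmod)
    tpt = TPTNetwork(graph=gt, partition=tmod)
    sources = ("SuperPred", "SEA", "TCMSP")
    triples = []
    for c in comps:
        for t in targs:
            if rng.random() < 0.3:
                for s in range(int(rng.integers(1, 4))):
                    triples.append((c, t, sources[s]))
    if not triples:
        triples.append((comps[0], targs[0], "SEA"))
    weighting = "source_count" if rng.random() < 0.5 else "indicator"
    it = interactions_from_pairs(triples, weighting=weighting)
    rows = [(r.compound, r.target, r.d) for r in it.df.itertuples()]
    return cs, tpt, it, rows, cmod, tmod


@pytest.fixture
def oracles():
    return {
        "tanimoto": brute_tanimoto,
        "edges": brute_edges,
        "hypergeom": brute_hypergeom_tail,
        "comembership": brute_comembership,
        "e_uv": brute_e_uv,
    }


# ---------------------------------------------------------------- fixtures

@pytest.fixture
def fp_compounds():
    """Compounds carrying hand-made fingerprints (no structures)."""
    def make(bitsets, length=16, prefix="c"):
        comps = []
        for i, bits in enumerate(bitsets, 1):
            fp = np.zeros(length, dtype=np.uint8)
            fp[list(bits)] = 1
            comps.append(Compound(id=f"{prefix}{i}", fingerprint=fp))
        return comps
    return make


@pytest.fixture
def small_spec():
    """A scaled-down synthetic spec for fast pipeline tests."""
    from bilayernet import SyntheticSpec
    return SyntheticSpec(
        n_compounds=150, n_clusters=4, others_fraction=0.2, fp_length=512,
        n_targets=120, n_background_genes=300, n_pathways=24,
        n_target_modules=3, focal_pathway_size=10, active_extra_targets=6,
        background_interaction_rate=0.01, n_boosted_pairs=3, seed=7)
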