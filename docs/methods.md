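# Methods

This note records the models, the defaults and the genuinely open design
choices behind `bilayernet`, in the package's own terms.

## Similarity layer

Structures are canonicalized on parse, so SMILES dialects (kekulized vs
aromatic) cannot change any downstream result. The default fingerprint is
the 2048-bit circular (Morgan) fingerprint of radius 2 — the standard
choice for Tanimoto-based structural similarity; kind and length are
configurable (`fp_kind`, `fp_length`) because the choice is a convention,
not part of the method. The Tanimoto coefficient of two all-zero vectors
is defined as 0 (with a warning): a featureless structure must never form
a similarity edge. All-pairs similarity is computed as an exact float64
bit-count matmul, so the vectorised path agrees with set arithmetic to
machine identity; the O(n²) scan warns above 20 000 compounds.

Formula weights are sums of conventional (2005 IUPAC) average atomic
masses over all atoms including implicit hydrogens, rounded half-up to
two decimals. An explicit mass table is used rather than RDKit's current
one: reference values printed in vendor catalogues and the older
literature (e.g. senkyunolide I, C12H16O4 = 224.25 g/mol) were computed
with the older masses, and the most recent IUPAC revision shifts some
two-decimal roundings (224.26). Elements outside the table fall back to
RDKit's periodic table.

## Community detection

Both layers are partitioned by Louvain modularity maximisation
(networkx implementation) at resolution 1.0, seeded and therefore
deterministic per seed. Edges are weighted — Tc in the CS layer, the
shared-enriched-pathway count in the TPT layer — with an unweighted mode
available, since tools that draw these networks honor weights by default
but the choice is rarely reported. Module labels follow one convention
everywhere: 1..k by descending module size, ties by lexically smallest
member id; CS modules below `min_module_size` (default 3) are pooled into
a label-0 "others" bucket, mirroring how small structural families are
reported in practice. The TPT layer does not pool by default.

## Enrichment

Over-representation uses the hypergeometric upper tail
P(X ≥ k), X ~ Hypergeom(N, K, n), with pathway members intersected with
the background first and results filtered at raw p < 0.05 (the
convention this analysis inherits); Benjamini–Hochberg is available
behind `fdr=True`. The background is the annotation universe — all genes
appearing in the GMT, united with the query — which is the standard ORA
default when no explicit universe is supplied. Using the predicted-target
set itself as background would make query ≈ background and destroy all
power, so the pipeline never does that.

## Bilayer scoring

d_ij defaults to the indicator weighting (1 per predicted compound–target
pair); `source_count` weights a pair by the number of agreeing predictors.
Both satisfy the defining identity e_uv = Σ d_ij, and within one module
pair the ranking by C(i)_uv is unchanged by any positive rescaling, so
the choice only matters across pairs. C(i)_uv is reported raw (so the
cell identity Σ_i C(i)_uv = e_uv holds exactly); a normalized form
C(i)_uv / e_uv is available. Interaction rows whose compound or target
fell out of its layer (similarity filter, enrichment filter) are excluded
from all sums and counted.

Ties in compound ranking break by CS-network degree (a more connected
compound is a more representative member of its structural family), then
lexical id — deterministic and documented rather than arbitrary.

For a pathway of interest, `pathway_focus` highlights the target modules
containing the pathway's members and the compound modules interacting
with them, and ranks compounds by their contribution **restricted to the
pathway's member targets**. The pipeline's final report uses this
restricted ranking: it is the direct answer to "which compounds act on
this pathway", and it is robust to background associations that an
unrestricted whole-module ranking across many highlighted cells would
pick up. The per-module-pair ranking (`rank_compounds`) is the primitive
underneath and is what validation uses for the planted module pair.

The per-module functional-propensity score (fraction of a pathway's
in-network members inside the module × −log10 p) is this package's own
construction, isolated in one function for easy replacement.

## Synthetic generator

The generator is a pure function of `SyntheticSpec`; identical specs give
byte-identical files. All Bernoulli decisions are integer RNG
comparisons, so determinism cannot depend on platform float behaviour.

What it emulates, and the defaults:

- **Compound layer.** 1000 compounds; 73% sit in 15 structural clusters
  whose sizes follow a truncated power law (uneven chemical families),
  the remaining 27% ("others") get independent random fingerprints and
  therefore never reach Tc ≥ 0.8 — this sets the ~1000 → ~700 networked
  attrition. Cluster members are the cluster seed fingerprint with each
  bit flipped at rate ε = 0.02. With seed-bit density 0.25 (k = 512 of
  L = 2048), the expected within-cluster Tanimoto is
  (k(1−ε)² + (L−k)ε²) / (k(1−ε²) + (L−k)·2ε) ≈ 0.855 > 0.8, while
  unrelated fingerprints sit near 0.15. Cluster seeds share a small core
  (5% of set bits) and draw the rest from private per-cluster pools when
  the fingerprint is long enough, falling back to shared sampling (as at
  the defaults) when it is not.
- **Target layer.** 850 targets in 4 equal blocks inside a 2500-gene
  annotation universe (1650 non-target background genes). 120 pathways of
  size 10–40: three quarters are target-rich (70% of members are targets,
  drawn from one home block with purity 0.9, the rest background genes)
  and get enriched; one quarter are target-poor (10%) and stay
  unenriched. This shapes the ~850 → ~680 enriched-target attrition and
  makes the TPT layer recover the four blocks. One focal pathway of 15
  targets sits entirely inside one block.
- **Interactions.** Every (compound, target) pair is Bernoulli(p0),
  p0 = 0.004 (≈ 3–4 targets per compound); 6 designated
  (cluster, target-module) pairs are boosted 12× to create heatmap
  structure. Three planted actives from one randomly chosen cluster each
  receive 8 extra interactions drawn from the focal pathway's members.
  The (active cluster, focal module) pair is never boosted — a boost
  there would hand the module-pair ranking to background compounds and
  make planted-recovery validation meaningless. Each interaction carries
  1–3 predictor source labels.

What the generator does **not** emulate: real chemistry (fingerprints are
abstract bit vectors, not derived from structures), correlated prediction
errors between predictors, pathway ontology overlap/hierarchy, and
compound-specific target promiscuity. Passing recovery tests therefore
shows the *algebra and the filters* behave correctly at realistic scale
and signal-to-noise, not that the method's nominations are biologically
correct on real data.

## Pipeline and determinism

One config seed fans out to per-stage seeds via
`(seed · 7919 + stage_index) mod (2³¹ − 1)` so each stage is individually
reproducible. The run manifest records the config and its hash, per-stage
row counts and the final top-k table; `manifest_hash` is computed over
everything except the output directory, so identical analyses hash
identically regardless of where they are written.

Problem sizes used in validation: oracle-equivalence checks run at
n ≤ 50 compounds / background ≤ 12 genes where exhaustive enumeration is
exact; module-recovery checks use 40-node planted two-block graphs
(p_in = 0.9, p_out = 0.02) over 20 seeds; end-to-end planted-active
recovery uses the full default generator over 50 seeds; the scale-band
check (600–800 networked compounds) uses 20 seeds. These sizes keep the
suite fast while leaving every statistical claim at the scale it is made.

## Known limitations

- The TPT projection rule (co-membership in ≥ 1 enriched pathway,
  weighted by shared-pathway count) is the minimal reading of
  "target–pathway interactions define the network"; other rules
  (e.g. Jaccard-normalised weights) would change module boundaries.
- Louvain at resolution 1.0 can split large functional blocks when
  pathway cliques overlap weakly; `pathway_focus` tolerates a focal
  pathway split across modules by highlighting all touched columns.
- No gene-identifier mapping: interaction tables and GMT files must share
  a symbol namespace.
- Stereochemistry and 3D conformers are outside the similarity model.
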