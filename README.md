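# bilayernet

Bilayer **compound-similarity / target-protein-target (CS–TPT) network
analysis** for nominating the active constituents of multi-component
mixtures — herbal injections, botanical extracts, any preparation with
hundreds of chemical constituents and noisy computational target
predictions.

## The problem and the method

A multi-herb preparation may contain ~1000 identifiable compounds, each
with dozens of predicted human targets from tools such as SuperPred, SEA
and TCMSP. Which few constituents plausibly drive an observed effect on a
pathway of interest? `bilayernet` answers this with a two-layer network
analysis:

1. **CS layer.** Compounds become nodes; an edge joins every pair with
   Tanimoto similarity *Tc* ≥ 0.8 between their 2048-bit circular
   fingerprints (*Tc* = |A∩B|/|A∪B| over set bits). Compounds with no
   similarity partner or no predicted target are dropped. Seeded Louvain
   community detection (resolution 1.0, Tc-weighted) partitions the layer
   into structural modules m_u (`CS_Module_1 …`, small leftovers pooled as
   `CS_others`) that correspond to chemical classes.
2. **TPT layer.** Predicted targets are tested for over-representation in
   pathway gene sets by the hypergeometric upper tail
   P(X ≥ k) with X ~ Hypergeom(N, K, n); pathways with *p* < 0.05 define
   the layer. Two targets are linked iff they co-occur in an enriched
   pathway (weight = number of shared enriched pathways) and Louvain
   yields functional modules m_v (`TPT_Module_1 …`).
3. **Bilayer coupling.** With interaction weights d_ij from the prediction
   table (d_ij = 1 per predicted pair by default, or the number of
   agreeing predictors), the module association is

       e_uv = Σ_{i∈m_u} Σ_{j∈m_v} d_ij

   and each compound's contribution C(i)_uv = Σ_{j∈m_v} d_ij decomposes it
   (Σ_i C(i)_uv = e_uv). Ranking C(i)_uv inside the module pair that hosts
   a pathway of interest — e.g. the NRF2/oxidative-stress axis — nominates
   candidate active compounds for wet-lab follow-up.

Because real constituent tables and prediction services are proprietary or
remote, the package ships a first-class **synthetic-data generator** with
planted structure at the realistic scale (~1000 compounds collapsing to
~700 networked ones, ~850 targets of which ~680 end up in enriched
pathways, and 3 planted "actives" whose targets concentrate in one focal
pathway), so that every stage of the method can be validated against known
ground truth.

## Worked example

`examples/02_full_synthetic_run.py` generates a default synthetic study
and runs the whole analysis:

```
compounds generated        1000
networked (Tc>=0.8 AND >=1 target)  716
CS modules                 15
predicted targets in play  845
targets in enriched pathways (p<0.05)  662
TPT modules                4

Top-3 contributions C(i)_uv for the focal pair (CS_Module_14, TPT_Module_1):
  rank 1: C0701  C = 9
  rank 2: C0695  C = 8
  rank 3: C0703  C = 8
planted actives were ['C0695', 'C0701', 'C0703']
```

Of 1000 generated compounds, 716 survive the two network filters and fall
into 15 structural modules; 662 of the predicted targets belong to
enriched pathways, and the TPT layer decomposes into 4 functional modules.
The three compounds with the highest contribution to the focal module pair
are exactly the three planted actives — the analysis recovers the known
signal. The other examples demonstrate fingerprints/Tanimoto/formula
weights (`01`), enrichment and the TPT projection (`03`), and the e_uv /
C(i)_uv algebra on a hand-sized instance (`04`).

A `bilayernet` CLI wraps the same pipeline for shell use
(`simulate`, `build-cs`, `build-tpt`, `score`, `rank`, and `run` with a
YAML config; see `bilayernet --help`).

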