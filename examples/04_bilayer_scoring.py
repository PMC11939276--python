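"""e_uv and C(i)_uv on a hand-sized bilayer instance.

Two compound modules, two target modules, indicator interactions.  Shows
the association matrix, the conservation identity sum_i C(i)_uv = e_uv,
and the within-module ranking used to nominate active compounds.
"""

import networkx as nx

from bilayernet import (export_association_heatmap_table,
                        interactions_from_pairs, module_association,
                        rank_compounds)
from bilayernet.cs_network import CSNetwork
from bilayernet.tpt_network import TPTNetwork

cs_graph = nx.Graph([("tanshinone", "cryptotanshinone"), ("luteolin", "baicalein")])
cs = CSNetwork(graph=cs_graph,
               partition={"tanshinone": 1, "cryptotanshinone": 1,
                          "luteolin": 2, "baicalein": 2})
tpt_graph = nx.Graph([("KEAP1", "NFE2L2"), ("F2", "F10")])
tpt = TPTNetwork(graph=tpt_graph,
                 partition={"KEAP1": 1, "NFE2L2": 1, "F2": 2, "F10": 2})

it = interactions_from_pairs([
    ("tanshinone", "KEAP1", "SEA"), ("tanshinone", "NFE2L2", "TCMSP"),
    ("cryptotanshinone", "KEAP1", "SEA"),
    ("luteolin", "KEAP1", "SuperPred"), ("baicalein", "F2", "SEA"),
    ("baicalein", "F10", "SEA"),
])

ma = module_association(cs, tpt, it)
print("e_uv association matrix (rows: compound modules; cols: target modules):")
print(export_association_heatmap_table(ma).to_string())

print("\ncontribution decomposition (sum of C(i)_uv over a module = e_uv):")
print(ma.contributions.to_string(index=False))

top = rank_compounds(ma, u=1, v=1, k=2)
print("\ntop compounds of CS_Module_1 for TPT_Module_1 (redox targets):")
print(top.to_string(index=False))
print("(tanshinone leads: it interacts with both targets of the module)")
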