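"""GO-term over-representation with classic / elim / weight decorrelation.

A three-term chain where the leaf term holds all the signal: classic
flags leaf and parent alike; elim and weight attribute the signal to the
leaf and discount the parent.
"""

import networkx as nx

import panpflow as pf
from panpflow.genesets import GoDag

universe = {f"g{i}" for i in range(60)}
significant = {f"g{i}" for i in range(10)}

graph = nx.DiGraph([("GO:leaf", "GO:mid"), ("GO:mid", "GO:root")])
dag = GoDag(
    graph=graph,
    direct={
        "GO:leaf": {f"g{i}" for i in range(10)},  # exactly the significant genes
        "GO:mid": {"g30", "g31", "g32", "g33"},
        "GO:root": set(),
    },
    names={"GO:leaf": "specific process", "GO:mid": "broader process",
           "GO:root": "biological process"},
)

for method in ("classic", "elim", "weight"):
    out = pf.go_enrichment(dag, significant, universe, method=method)
    print(f"\n{method}:")
    print(out[["term", "annotated", "significant", "expected", "p_display"]]
          .to_string(index=False))

fam = pf.GeneSetAnnotation(
    families={"famA": {f"g{i}" for i in range(12)}, "famB": {f"g{i}" for i in range(40, 55)}},
    universe=universe,
)
print("\ntwo-sided family test vs the whole universe:")
print(pf.family_enrichment(significant, fam).to_string(index=False))
# elim/weight leave the leaf p untouched but raise the ancestors' p —
# the inherited genes no longer count as independent evidence.
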