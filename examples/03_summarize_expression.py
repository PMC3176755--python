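"""Summarize probe intensities to probeset expression with RMA and MBEI.

RMA: convolution background correction, quantile normalization, log2,
median polish. MBEI: multiplicative model PM ≈ φ·θ fitted per probeset.
Both should recover the planted +3 log2 tissue contrast.
"""

import panpflow as pf
from panpflow.annotate import ProbesetAnnotation

config = pf.SimulationConfig(
    n_genes=30, probes_per_set=11, n_tissues=4, replicates_per_tissue=4,
    n_negative_probes=20, planted_enriched=(("G00003", "tissue01", 3.0),),
    expressed_fraction=1.0, seed=7,
)
_, _, _, truth = pf.generate_sequences(config)
raw = pf.simulate_intensities(config, truth)

sets: dict[str, list[str]] = {}
for p, g in truth.probe_to_gene.items():
    sets.setdefault(f"{g}_at", []).append(p)
ann = ProbesetAnnotation(
    probeset_to_gene={ps: ps[:-3] for ps in sets},
    probeset_to_probes={ps: sorted(v) for ps, v in sets.items()},
    removed_probes={},
)

for method in (pf.rma, pf.mbei):
    expr = method(raw, ann)
    frame = expr.to_frame()
    groups = expr.groups()
    row = frame.loc["G00003_at"]
    target = row[groups["tissue01"]].mean()
    rest = row[[a for t in groups for a in groups[t] if t != "tissue01"]].mean()
    print(f"{expr.method}: expression matrix {expr.values.shape}, "
          f"planted +3.0 contrast recovered as {target - rest:+.2f} log2")
# MBEI tracks the observed-intensity fold change; RMA reports the contrast
# on the estimated signal component, which exceeds the observed-scale
# effect when the gene's baseline expression is close to the optical
# background (subtracting background stretches low-end differences).
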