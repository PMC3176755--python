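import numpy as np
import pandas as pd
import pytest

import panpflow as pf
from panpflow.annotate import ProbesetAnnotation


@pytest.fixture(scope="session")
def small_config():
    return pf.SimulationConfig(
        n_genes=6,
        probes_per_set=5,
        n_tissues=3,
        replicates_per_tissue=4,
        n_negative_probes=40,
        n_multimap_probes=1,
        planted_enriched=(("G00000", "tissue00", 4.0),),
        seed=101,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Sequences + truth + raw intensities for the small synthetic study."""
    transcripts, genome, probes, truth = pf.generate_sequences(small_config)
    raw = pf.simulate_intensities(small_config, truth)
    return {
        "config": small_config,
        "transcripts": transcripts,
        "genome": genome,
        "probes": probes,
        "truth": truth,
        "raw": raw,
    }


@pytest.fixture(scope="session")
def small_annotation(small_world):
    truth = small_world["truth"]
    transcripts = small_world["transcripts"]
    mapping = pd.DataFrame(
        [
            {"probe_id": p, "probeset_id": f"{g}_at", "gene_id": g}
            for p, g in truth.probe_to_gene.items()
        ]
    )
    hits = pf.map_probes(small_world["probes"], transcripts, 2, "transcript")
    hits += pf.map_probes(small_world["probes"], small_world["genome"], 2, "genomic")
    t2g = {g: g for g in transcripts} | {f"chr_{g}": g for g in transcripts}
    ann = pf.build_probeset_annotation(hits, mapping, target_to_gene=t2g)
    return {"annotation": ann, "hits": hits, "mapping": mapping}


def trivial_annotation(truth) -> ProbesetAnnotation:
    """Probeset annotation straight from the generator's ground truth."""
    sets: dict[str, list[str]] = {}
    for p, g in truth.probe_to_gene.items():
        sets.setdefault(f"{g}_at", []).append(p)
    return ProbesetAnnotation(
        probeset_to_gene={ps: ps[:-3] for ps in sets},
        probeset_to_probes={ps: sorted(pl) for ps, pl in sets.items()},
        removed_probes={},
    )


@pytest.fixture(scope="session")
def atlas():
    """Mid-size multi-tissue study used by the recovery-style tests."""
    planted = tuple(
        (f"G{i:05d}", "tissue00", float(e)) for i, e in zip(range(10), np.linspace(2, 4, 10))
    )
    cfg = pf.SimulationConfig(
        n_genes=120,
        probes_per_set=11,
        n_tissues=6,
        replicates_per_tissue=4,
        n_negative_probes=40,
        planted_enriched=planted,
        seed=202,
    )
    _, _, _probes, truth = pf.generate_sequences(cfg)
    raw = pf.simulate_intensities(cfg, truth)
    ann = trivial_annotation(truth)
    return {"config": cfg, "truth": truth, "raw": raw, "annotation": ann}
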