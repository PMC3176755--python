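"""Synthetic probe-level array data with known ground truth.

Emulates the data-generating assumptions behind short-oligo expression
arrays profiled from laser-microdissected tissue: per-probe multiplicative
affinities, additive Gaussian optical background plus an exponential
expressed-signal component (the convolution model that RMA background
correction assumes), a replicated multi-tissue design with planted
tissue-enriched genes of known log2 effect size, a pool of orphan probes
carrying background only, and binomial progeny counts from reciprocal
crosses under a reduced transmission probability.

Intensities are simulated on the log2 scale and then exponentiated, so the
convolution assumption holds approximately rather than exactly — an
intentional model-mismatch stress for the downstream summarization.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CrossCounts",
    "generate_sequences",
    "simulate_intensities",
    "simulate_cross",
    "write_ground_truth",
    "read_ground_truth",
]

PROBE_LEN = 25  # Affymetrix-style 25-mer probes
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic array experiment.

    Intensity parameters are on the log2 scale: ``background_mean`` is the
    log2 optical background level, ``background_sd`` its per-observation
    spread, ``signal_rate`` the exponential rate of the expressed-signal
    component (mean expressed signal = 1/signal_rate log2 units above
    background), and ``affinity_sd`` the spread of probe-specific,
    array-invariant log2 affinities.
    """

    n_genes: int = 50
    probes_per_set: int = 11
    n_tissues: int = 8
    replicates_per_tissue: int = 4
    n_negative_probes: int = 100
    planted_enriched: tuple[tuple[str, str, float], ...] = ()
    background_mean: float = 6.0
    background_sd: float = 0.5
    signal_rate: float = 0.25
    affinity_sd: float = 0.5
    expressed_fraction: float = 0.6
    max_signal: float = 8.0
    n_multimap_probes: int = 0
    transcript_len: int = 400
    probe_len: int = PROBE_LEN
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "probes_per_set", "n_tissues", "replicates_per_tissue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_negative_probes < 0 or self.n_multimap_probes < 0:
            raise ValueError("probe counts must be non-negative")
        if self.background_sd <= 0:
            raise ValueError("background_sd must be > 0")
        if self.signal_rate <= 0:
            raise ValueError("signal_rate must be > 0")
        if self.max_signal <= 0:
            raise ValueError("max_signal must be > 0")
        if not 0.0 <= self.expressed_fraction <= 1.0:
            raise ValueError("expressed_fraction must be in [0, 1]")
        for g, t, eff in self.planted_enriched:
            if not np.isfinite(eff):
                raise ValueError(f"planted effect for {g}/{t} is not finite")
        if self.transcript_len < self.probe_len:
            raise ValueError("transcript_len must be >= probe_len")
        # object()-style normalisation: allow lists in YAML configs
        object.__setattr__(self, "planted_enriched", tuple(
            (str(g), str(t), float(e)) for g, t, e in self.planted_enriched
        ))

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i:02d}" for i in range(self.n_tissues)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["planted_enriched"] = tuple(
            tuple(item) for item in raw.get("planted_enriched", ())
        )
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["planted_enriched"] = [list(x) for x in self.planted_enriched]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Machine-readable record of every planted fact."""

    expressed: dict[str, dict[str, bool]]
    enriched: set[tuple[str, str, float]]
    negative_probe_ids: set[str]
    multimap_probe_ids: set[str]
    probe_to_gene: dict[str, str] = field(default_factory=dict)
    gene_levels: dict[str, float] = field(default_factory=dict)
    affinities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, t, _ in self.enriched:
            if not self.expressed.get(g, {}).get(t, False):
                raise ValueError(f"planted enriched gene {g} not expressed in {t}")
        assigned = set(self.probe_to_gene)
        if self.negative_probe_ids & assigned:
            raise ValueError("negative probes must belong to no gene")


@dataclass(frozen=True)
class CrossCounts:
    """Genotyped progeny of one heterozygote × wild-type cross."""

    n_het: int
    n_wt: int
    direction: str = "female"
    line: str = ""

    def __post_init__(self) -> None:
        if self.n_het < 0 or self.n_wt < 0:
            raise ValueError("counts must be non-negative")
        if self.n_het + self.n_wt < 1:
            raise ValueError("cross must have at least one progeny")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _encode(seq: str) -> np.ndarray:
    """Map ACGT to 0..3; anything else to 255 (mismatches everything)."""
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _window_matrix(seqs: list[str], k: int) -> np.ndarray:
    """All k-windows of all sequences (and nothing else), stacked row-wise."""
    mats = []
    for s in seqs:
        enc = _encode(s)
        if len(enc) < k:
            continue
        win = np.lib.stride_tricks.sliding_window_view(enc, k)
        mats.append(win)
    if not mats:
        return np.empty((0, k), dtype=np.uint8)
    return np.concatenate(mats, axis=0)


_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _min_mismatches(probe: str, windows: np.ndarray) -> int:
    if windows.shape[0] == 0:
        return len(probe)
    enc = _encode(probe)
    return int((windows != enc).sum(axis=1).min())


def generate_sequences(
    config: SimulationConfig, max_retries: int = 1000
) -> tuple[dict[str, str], dict[str, str], dict[str, str], GroundTruth]:
    """Build transcripts, a genome, the probe set and the ground truth.

    Returns ``(transcripts, genome, probes, truth)`` as id→sequence dicts.
    Each gene receives ``probes_per_set`` exact 25-mer substrings of its
    transcript; ``n_multimap_probes`` of these are injected verbatim into a
    second gene so they match ≥2 genes perfectly; negative probes are random
    25-mers verified by a brute-force Hamming scan to sit at ≥3 mismatches
    from every target window (both genome strands).
    """
    rng = np.random.default_rng(config.seed)
    k = config.probe_len

    transcripts: dict[str, str] = {
        g: _random_seq(rng, config.transcript_len) for g in config.gene_ids
    }

    # choose evenly spread probe offsets per gene
    probes: dict[str, str] = {}
    probe_to_gene: dict[str, str] = {}
    n_slots = config.transcript_len - k + 1
    for g in config.gene_ids:
        offsets = np.sort(rng.choice(n_slots, size=config.probes_per_set, replace=False))
        for j, off in enumerate(offsets):
            pid = f"{g}_p{j:02d}"
            probes[pid] = transcripts[g][off : off + k]
            probe_to_gene[pid] = g

    # plant multi-mapping probes: copy a probe's 25-mer into another gene's
    # transcript so it becomes a perfect substring of >=2 genes
    multimap_ids: set[str] = set()
    if config.n_multimap_probes:
        if config.n_genes < 2:
            raise ValueError("multimap probes need >= 2 genes")
        pids = list(probes)
        chosen = rng.choice(len(pids), size=config.n_multimap_probes, replace=False)
        for idx in chosen:
            pid = pids[int(idx)]
            host_gene = probe_to_gene[pid]
            others = [g for g in config.gene_ids if g != host_gene]
            target = others[int(rng.integers(len(others)))]
            off = int(rng.integers(n_slots))
            s = transcripts[target]
            transcripts[target] = s[:off] + probes[pid] + s[off + k :]
            multimap_ids.add(pid)
        # re-extract all probe sequences (an injection may overwrite a window
        # another probe was read from; the probe keeps its original sequence)
        # — original sequences were captured above, nothing to do.

    # genome: each transcript embedded in decoy flanks, plus a decoy contig
    genome: dict[str, str] = {}
    for g in config.gene_ids:
        left = _random_seq(rng, 50)
        right = _random_seq(rng, 50)
        genome[f"chr_{g}"] = left + transcripts[g] + right
    genome["chr_decoy"] = _random_seq(rng, 2000)

    # brute-force window tables for negative-probe verification
    if config.n_negative_probes:
        targets = list(transcripts.values()) + list(genome.values())
        targets += [revcomp(s) for s in genome.values()]
        windows = _window_matrix(targets, k)
    negatives: dict[str, str] = {}
    for i in range(config.n_negative_probes):
        pid = f"NEG_{i:05d}"
        for attempt in range(max_retries):
            cand = _random_seq(rng, k)
            if _min_mismatches(cand, windows) >= 3:
                negatives[pid] = cand
                break
        else:
            raise RuntimeError(
                f"could not place negative probe {pid} after {max_retries} retries"
            )

    all_probes = dict(probes)
    all_probes.update(negatives)

    tissues = config.tissues
    planted_genes = {g for g, _, _ in config.planted_enriched}
    unknown = planted_genes - set(config.gene_ids)
    if unknown:
        raise ValueError(f"planted genes not in gene list: {sorted(unknown)}")

    expressed: dict[str, dict[str, bool]] = {}
    for g in config.gene_ids:
        if g in planted_genes:
            # enriched genes are expressed everywhere so the target-vs-rest
            # contrast equals the planted effect
            expressed[g] = {t: True for t in tissues}
        else:
            expressed[g] = {
                t: bool(rng.random() < config.expressed_fraction) for t in tissues
            }

    # intrinsic abundance: exponential on the log2 scale, truncated at
    # max_signal so background + signal stays inside a real scanner's
    # dynamic range (~2^16); inverse-CDF keeps the draw seed-deterministic.
    # Planted genes keep headroom for their effect — a fold change on a
    # saturated gene would be unmeasurable on a real array too.
    headroom: dict[str, float] = {}
    for g, _t, e in config.planted_enriched:
        headroom[g] = max(headroom.get(g, 0.0), max(e, 0.0))

    def draw_level(cap: float) -> float:
        mass = 1.0 - np.exp(-config.signal_rate * cap)
        return float(-np.log(1.0 - rng.random() * mass) / config.signal_rate)

    gene_levels = {
        g: draw_level(max(config.max_signal - headroom.get(g, 0.0), 0.5))
        for g in config.gene_ids
    }
    affinities = {
        pid: float(rng.normal(0.0, config.affinity_sd)) for pid in all_probes
    }

    truth = GroundTruth(
        expressed=expressed,
        enriched={(g, t, e) for g, t, e in config.planted_enriched},
        negative_probe_ids=set(negatives),
        multimap_probe_ids=multimap_ids,
        probe_to_gene=probe_to_gene,
        gene_levels=gene_levels,
        affinities=affinities,
    )
    return transcripts, genome, all_probes, truth


def simulate_intensities(config: SimulationConfig, truth: GroundTruth):
    """Draw the raw probe × array intensity matrix.

    log2 intensity = probe affinity + N(background_mean, background_sd)
    plus, for probes of genes expressed in the array's tissue, the gene's
    intrinsic exponential level and any planted log2 effect for that tissue.
    Returns an :class:`panpflow.containers.IntensityMatrix`.
    """
    from .containers import IntensityMatrix

    rng = np.random.default_rng(config.seed + 1)
    tissues = config.tissues
    arrays = []
    meta = []
    for t in tissues:
        for r in range(config.replicates_per_tissue):
            arrays.append(f"{t}_rep{r}")
            meta.append((t, r))

    probe_ids = sorted(truth.affinities)
    n_probes, n_arrays = len(probe_ids), len(arrays)

    effect = {(g, t): e for g, t, e in truth.enriched}

    aff = np.array([truth.affinities[p] for p in probe_ids])
    log2 = rng.normal(config.background_mean, config.background_sd, size=(n_probes, n_arrays))
    log2 += aff[:, None]

    gene_of = truth.probe_to_gene
    for i, pid in enumerate(probe_ids):
        g = gene_of.get(pid)
        if g is None:
            continue  # negative probe: background only
        level = truth.gene_levels[g]
        for a, (t, _r) in enumerate(meta):
            if truth.expressed[g][t]:
                log2[i, a] += level + effect.get((g, t), 0.0)

    values = np.exp2(log2)
    return IntensityMatrix(
        values=values,
        probe_ids=probe_ids,
        array_ids=arrays,
        array_meta={a: {"tissue": t, "replicate": r} for a, (t, r) in zip(arrays, meta)},
    )


def simulate_cross(
    n_progeny: int,
    transmission_prob: float,
    seed: int,
    direction: str = "female",
    line: str = "synthetic",
) -> CrossCounts:
    """Binomial progeny of a het × wild-type cross.

    A mutant allele transmitted with probability ``transmission_prob``
    relative to the wild-type allele yields heterozygote frequency
    p/(1+p) among scored progeny.
    """
    if n_progeny <= 0:
        raise ValueError("n_progeny must be > 0")
    if not 0.0 <= transmission_prob <= 1.0:
        raise ValueError("transmission_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p_het = transmission_prob / (1.0 + transmission_prob)
    n_het = int(rng.binomial(n_progeny, p_het))
    return CrossCounts(n_het=n_het, n_wt=n_progeny - n_het, direction=direction, line=line)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    d = {
        "expressed": truth.expressed,
        "enriched": sorted([list(x) for x in truth.enriched]),
        "negative_probe_ids": sorted(truth.negative_probe_ids),
        "multimap_probe_ids": sorted(truth.multimap_probe_ids),
        "probe_to_gene": truth.probe_to_gene,
        "gene_levels": truth.gene_levels,
        "affinities": truth.affinities,
    }
    Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        expressed=d["expressed"],
        enriched={(g, t, float(e)) for g, t, e in d["enriched"]},
        negative_probe_ids=set(d["negative_probe_ids"]),
        multimap_probe_ids=set(d["multimap_probe_ids"]),
        probe_to_gene=d["probe_to_gene"],
        gene_levels=d["gene_levels"],
        affinities=d["affinities"],
    )
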