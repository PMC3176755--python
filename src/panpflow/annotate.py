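"""Probe→target mapping, probeset annotation and negative-probe selection.

Probes are mapped by an exact substitution-only (Hamming) search: the probe
is split into ``max_mismatches + 1`` seeds, any valid hit must contain at
least one exact seed (pigeonhole), and each seeded candidate window is
verified by direct comparison. Transcript targets are searched on the sense
strand only (probes are designed antisense to the mRNA, i.e. matching the
cDNA); genomic targets are searched on both strands. No gaps: a hit is a
window of the target at Hamming distance ≤ the cap.

Probes with perfect hits to more than one gene are dropped from their
probesets; probesets left with fewer than ``min_probes`` probes are dropped
entirely. Probes used by no retained probeset whose best hit anywhere is
more than two mismatches away (or that have no hit at all) form the
negative pool used to build the empirical detection-call background.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import _encode, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeHit",
    "ProbesetAnnotation",
    "NegativeProbePool",
    "map_probes",
    "build_probeset_annotation",
    "select_negative_probes",
    "hits_to_frame",
]


@dataclass(frozen=True)
class ProbeHit:
    probe_id: str
    target_id: str
    target_kind: str  # "transcript" | "genomic"
    offset: int  # 0-based start, half-open interval on the forward strand
    strand: str  # "+" | "-"
    mismatches: int


@dataclass
class ProbesetAnnotation:
    probeset_to_gene: dict[str, str]
    probeset_to_probes: dict[str, list[str]]
    removed_probes: dict[str, str]  # probe_id -> reason
    removed_probesets: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for ps, plist in self.probeset_to_probes.items():
            for p in plist:
                if p in seen:
                    raise ValueError(f"probe {p} in probesets {seen[p]} and {ps}")
                seen[p] = ps

    @property
    def used_probes(self) -> set[str]:
        return {p for plist in self.probeset_to_probes.values() for p in plist}


@dataclass
class NegativeProbePool:
    probe_ids: list[str]
    provenance: dict[str, int | None]  # probe -> best-hit mismatch count (None: no hit)

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise ValueError("negative probe pool is empty; detection calling impossible")
        for p in self.probe_ids:
            mm = self.provenance.get(p)
            if mm is not None and mm <= 2:
                raise ValueError(f"probe {p} has a best hit at {mm} mismatches (<= 2)")


class _SeedIndex:
    """Positions of every L-mer of every target, for pigeonhole seeding.

    Seeds are the ``max_mismatches + 1`` disjoint equal-length prefixed
    segments of the probe (length ``k // (m+1)``); a window at Hamming
    distance ≤ m must carry at least one of them exactly.
    """

    def __init__(self, targets: dict[str, str], seed_len: int) -> None:
        self.seed_len = seed_len
        self.index: dict[str, list[tuple[str, int]]] = {}
        self.encoded = {tid: _encode(seq) for tid, seq in targets.items()}
        self.lengths = {tid: len(seq) for tid, seq in targets.items()}
        for tid, seq in targets.items():
            for pos in range(len(seq) - seed_len + 1):
                self.index.setdefault(seq[pos : pos + seed_len], []).append((tid, pos))

    def candidates(self, probe_seq: str, n_seeds: int, k: int):
        out: set[tuple[str, int]] = set()
        L = self.seed_len
        for s in range(n_seeds):
            occs = self.index.get(probe_seq[s * L : (s + 1) * L])
            if not occs:
                continue
            off = s * L
            for tid, pos in occs:
                start = pos - off
                if 0 <= start <= self.lengths[tid] - k:
                    out.add((tid, start))
        return out


def _verify(
    probe_enc: np.ndarray, seed_index: _SeedIndex, cand: tuple[str, int], cap: int
) -> int | None:
    tid, start = cand
    window = seed_index.encoded[tid][start : start + probe_enc.size]
    mm = int(np.count_nonzero(window != probe_enc))
    return mm if mm <= cap else None


def map_probes(
    probes: dict[str, str],
    targets: dict[str, str],
    max_mismatches: int = 2,
    target_kind: str = "transcript",
    strands: str | None = None,
) -> list[ProbeHit]:
    """All windows of all targets within ``max_mismatches`` of each probe.

    ``strands`` defaults by kind: "sense" for transcripts, "both" for
    genomic targets. A reverse-strand hit is found by matching the
    reverse-complemented probe on the forward strand and is reported at its
    forward-strand offset with strand "-".
    """
    if not probes:
        raise ValueError("empty probe FASTA")
    if not targets:
        raise ValueError("empty target FASTA")
    if max_mismatches > 5:
        raise ValueError("max_mismatches must be <= 5")
    lengths = {len(s) for s in probes.values()}
    if len(lengths) != 1:
        raise ValueError(f"probes must have uniform length, got lengths {sorted(lengths)}")
    if strands is None:
        strands = "sense" if target_kind == "transcript" else "both"
    if strands not in ("sense", "both"):
        raise ValueError(f"unknown strand policy {strands!r}")

    k = lengths.pop()
    n_seeds = max_mismatches + 1
    seed_len = k // n_seeds
    if seed_len < 1:
        raise ValueError("probe too short for the requested mismatch cap")
    targets = {tid: seq.upper() for tid, seq in targets.items()}
    seed_index = _SeedIndex(targets, seed_len)

    hits: list[ProbeHit] = []
    for pid, pseq in probes.items():
        pseq = pseq.upper()
        queries = [(pseq, "+")]
        if strands == "both":
            queries.append((revcomp(pseq), "-"))
        for qseq, strand in queries:
            q_enc = _encode(qseq)
            if np.any(q_enc > 3):
                # non-ACGT characters mismatch everything, themselves included
                q_enc = q_enc.copy()
                q_enc[q_enc > 3] = 254
                warnings.warn(
                    f"probe {pid} contains non-ACGT characters; "
                    "treated as mismatching every base (brute-force scan)"
                )
                cands = {
                    (tid, s)
                    for tid, n in seed_index.lengths.items()
                    for s in range(n - k + 1)
                }
            else:
                cands = seed_index.candidates(qseq, n_seeds, k)
            for cand in sorted(cands):
                mm = _verify(q_enc, seed_index, cand, max_mismatches)
                if mm is not None:
                    hits.append(
                        ProbeHit(pid, cand[0], target_kind, cand[1], strand, mm)
                    )
    return hits


def hits_to_frame(hits: list[ProbeHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.probe_id, h.target_id, h.target_kind, h.offset, h.strand, h.mismatches)
            for h in hits
        ],
        columns=["probe_id", "target_id", "kind", "offset", "strand", "mismatches"],
    )


def build_probeset_annotation(
    hits: list[ProbeHit],
    declared_mapping: pd.DataFrame,
    min_probes: int = 1,
    target_to_gene: dict[str, str] | None = None,
) -> ProbesetAnnotation:
    """Assemble the probeset (CDF-like) annotation.

    ``declared_mapping`` needs columns ``probe_id`` and ``probeset_id`` and
    may carry ``gene_id``; without it the gene is inferred from perfect
    transcript hits of the probeset's probes. Probes whose perfect hits span
    more than one gene are removed (reason "multimap"); probesets whose
    retained probe count falls below ``min_probes`` are removed.
    """
    t2g = target_to_gene or {}

    def gene_of(hit: ProbeHit) -> str:
        return t2g.get(hit.target_id, hit.target_id)

    perfect_genes: dict[str, set[str]] = {}
    for h in hits:
        if h.mismatches == 0:
            perfect_genes.setdefault(h.probe_id, set()).add(gene_of(h))

    removed_probes: dict[str, str] = {}
    probeset_to_probes: dict[str, list[str]] = {}
    probeset_declared_gene: dict[str, set[str]] = {}

    for _, row in declared_mapping.iterrows():
        pid, ps = str(row["probe_id"]), str(row["probeset_id"])
        if "gene_id" in declared_mapping.columns and not pd.isna(row.get("gene_id")):
            probeset_declared_gene.setdefault(ps, set()).add(str(row["gene_id"]))
        if len(perfect_genes.get(pid, set())) > 1:
            removed_probes[pid] = "multimap"
            continue
        probeset_to_probes.setdefault(ps, []).append(pid)

    removed_probesets: set[str] = set()
    for ps in list(probeset_to_probes):
        if len(probeset_to_probes[ps]) < min_probes:
            removed_probesets.add(ps)
            del probeset_to_probes[ps]
    # probesets whose probes were all removed never reach the dict above
    declared_sets = {str(s) for s in declared_mapping["probeset_id"]}
    removed_probesets |= declared_sets - set(probeset_to_probes)

    probeset_to_gene: dict[str, str] = {}
    for ps, plist in probeset_to_probes.items():
        declared = probeset_declared_gene.get(ps, set())
        if len(declared) > 1:
            raise ValueError(f"probeset {ps} mapped to multiple genes: {sorted(declared)}")
        if declared:
            probeset_to_gene[ps] = next(iter(declared))
            continue
        inferred = set()
        for p in plist:
            inferred |= perfect_genes.get(p, set())
        if len(inferred) > 1:
            raise ValueError(f"probeset {ps} mapped to multiple genes: {sorted(inferred)}")
        probeset_to_gene[ps] = next(iter(inferred)) if inferred else ps

    return ProbesetAnnotation(
        probeset_to_gene=probeset_to_gene,
        probeset_to_probes=probeset_to_probes,
        removed_probes=removed_probes,
        removed_probesets=removed_probesets,
    )


def select_negative_probes(
    all_probes: dict[str, str] | list[str],
    hits: list[ProbeHit],
    annotation: ProbesetAnnotation | None = None,
) -> NegativeProbePool:
    """Probes usable as background measures.

    A probe qualifies when it is used by no retained probeset and its best
    hit over all targets and strands has more than two mismatches — or it
    has no hit at all within the search cap (recorded as ``None`` in the
    provenance, flagging that its true best distance is only bounded below).
    """
    probe_ids = list(all_probes)
    used = annotation.used_probes if annotation is not None else set()
    best: dict[str, int] = {}
    for h in hits:
        cur = best.get(h.probe_id)
        if cur is None or h.mismatches < cur:
            best[h.probe_id] = h.mismatches

    pool: list[str] = []
    provenance: dict[str, int | None] = {}
    for pid in probe_ids:
        if pid in used:
            continue
        mm = best.get(pid)
        if mm is not None and mm <= 2:
            continue
        pool.append(pid)
        provenance[pid] = mm
    if not pool:
        raise ValueError("no probes qualify as negative; detection calling impossible")
    logger.info("selected %d negative probes", len(pool))
    return NegativeProbePool(probe_ids=pool, provenance=provenance)
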