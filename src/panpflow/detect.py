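"""Present/marginal/absent detection calls from a resampled negative null.

Negative probes — probes matching no target within the mismatch cap — are
resampled into pseudo-probesets (sets of 11 by default, 2,000 sets per
repeat, 20 repeats) and pushed through the same summarization path as real
probesets, giving an empirical per-array background distribution of
probeset signals. Each real probeset's detection p-value on an array is
its smoothed upper-tail rank in that null, averaged over the repeats.
Group-level calls: present when enough replicate arrays fall at or below
the p-value threshold (≥ 3 of 4 by default), marginal when ≥ 2 of 4 but
not present, absent otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import ceil

import numpy as np
import pandas as pd

from .annotate import NegativeProbePool, ProbesetAnnotation
from .containers import DetectionTable, ExpressionMatrix, IntensityMatrix
from .summarize import _preprocessed_log2, median_polish_blocks, rma

logger = logging.getLogger(__name__)

__all__ = [
    "NegativeProbesetSample",
    "sample_negative_probesets",
    "null_signals",
    "detection_pvalues",
    "call_presence",
    "venn_counts",
    "detection_workflow",
]


@dataclass
class NegativeProbesetSample:
    """One resampling repeat: ``n_sets`` pseudo-probesets of ``set_size`` probes."""

    repeat: int
    probesets: list[list[str]]
    seed: int

    def __post_init__(self) -> None:
        sizes = {len(ps) for ps in self.probesets}
        if len(sizes) > 1:
            raise ValueError("pseudo-probesets must share one size")
        for ps in self.probesets:
            if len(set(ps)) != len(ps):
                raise ValueError("probes within a pseudo-probeset must be distinct")


def sample_negative_probesets(
    pool: NegativeProbePool,
    set_size: int = 11,
    n_sets: int = 2000,
    n_repeats: int = 20,
    seed: int = 0,
) -> list[NegativeProbesetSample]:
    """Uniform draws: without replacement within a set, with replacement
    across sets; fully determined by ``seed``."""
    ids = list(pool.probe_ids)
    if len(ids) < set_size:
        raise ValueError(
            f"negative pool has {len(ids)} probes, need at least {set_size}"
        )
    samples = []
    for r in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence((seed, r)))
        sets = [
            [ids[i] for i in rng.choice(len(ids), size=set_size, replace=False)]
            for _ in range(n_sets)
        ]
        samples.append(NegativeProbesetSample(repeat=r, probesets=sets, seed=seed))
    return samples


def null_signals(
    sample: NegativeProbesetSample,
    raw: IntensityMatrix,
    expr_fn: str = "rma",
    log2_values: np.ndarray | None = None,
    background_params: dict | None = None,
) -> np.ndarray:
    """Summarize one repeat's pseudo-probesets: n_sets × arrays, log2 scale.

    Uses the identical RMA path as real probesets. ``log2_values`` may carry
    a precomputed background-corrected, quantile-normalized log2 matrix
    aligned to ``raw`` (the shared normalization pass); otherwise it is
    computed here.
    """
    if expr_fn != "rma":
        warnings.warn(f"null signals are defined on the RMA path; got {expr_fn!r}")
    if log2_values is None:
        log2_values = _preprocessed_log2(raw, params=background_params)
    index = {p: i for i, p in enumerate(raw.probe_ids)}
    try:
        rows = np.array([[index[p] for p in ps] for ps in sample.probesets])
    except KeyError as e:
        raise ValueError(f"pool probe missing from intensity matrix: {e}") from e
    blocks = log2_values[rows, :]  # (n_sets, set_size, arrays)
    return median_polish_blocks(blocks)


def detection_pvalues(
    expr: ExpressionMatrix,
    nulls: list[np.ndarray],
) -> pd.DataFrame:
    """Smoothed empirical upper-tail p-values, averaged over repeats.

    Per array a and probeset signal x: p_r = (#{null_r,a ≥ x} + 1)/(n_sets+1)
    for each repeat r, then the arithmetic mean over repeats. Values lie in
    (0, 1]; x above every null signal gives 1/(n_sets+1) per repeat.
    """
    if not nulls:
        raise ValueError("need at least one repeat of null signals")
    n_arrays = len(expr.array_ids)
    acc = np.zeros((len(expr.probeset_ids), n_arrays))
    for null in nulls:
        null = np.asarray(null, dtype=float)
        if null.ndim != 2 or null.shape[1] != n_arrays:
            raise ValueError(
                f"null signals have {null.shape} but expression has {n_arrays} arrays"
            )
        n_sets = null.shape[0]
        for a in range(n_arrays):
            col = np.sort(null[:, a])
            # count of null >= x  ==  n_sets - searchsorted(col, x, 'left')
            ge = n_sets - np.searchsorted(col, expr.values[:, a], side="left")
            acc[:, a] += (ge + 1) / (n_sets + 1)
    acc /= len(nulls)
    return pd.DataFrame(acc, index=expr.probeset_ids, columns=expr.array_ids)


def call_presence(
    pvalues: pd.DataFrame,
    groups: dict[str, list[str]],
    threshold: float = 0.02,
    present_frac: float = 3 / 4,
    marginal_frac: float = 2 / 4,
) -> pd.DataFrame:
    """P/M/A calls per probeset per group.

    Array-level present iff p ≤ threshold. Group call P when present in at
    least ceil(present_frac·R) of the R replicate arrays; else M when at
    least ceil(marginal_frac·R); else A. P and M are disjoint.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    calls = {}
    for g, arrays in groups.items():
        if len(arrays) < 2:
            raise ValueError(f"group {g} has fewer than 2 arrays")
        sub = pvalues[arrays].to_numpy(float)
        n_present = (sub <= threshold).sum(axis=1)
        r = len(arrays)
        need_p = ceil(present_frac * r)
        need_m = ceil(marginal_frac * r)
        col = np.where(n_present >= need_p, "P", np.where(n_present >= need_m, "M", "A"))
        calls[g] = col
    return pd.DataFrame(calls, index=pvalues.index)


def venn_counts(sets: dict[str, set[str]]) -> dict[frozenset, int]:
    """Counts of every exclusive intersection region of ≥ 2 named sets.

    Keys are frozensets of the group names whose region the count belongs
    to (elements in exactly those sets and no other); counts sum to the
    size of the union.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = sorted(sets)
    out: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            for other in names:
                if other not in combo:
                    inside = inside - sets[other]
            out[frozenset(combo)] = len(inside)
    return out


def detection_workflow(
    raw: IntensityMatrix,
    annotation: ProbesetAnnotation,
    pool: NegativeProbePool,
    set_size: int = 11,
    n_sets: int = 2000,
    n_repeats: int = 20,
    threshold: float = 0.02,
    seed: int = 0,
    background_params: dict | None = None,
) -> tuple[ExpressionMatrix, DetectionTable]:
    """End-to-end detection calling with a single shared normalization pass.

    Real and pseudo probesets are summarized from the same background-
    corrected, quantile-normalized log2 matrix (negative probes included in
    the normalization), as one joint pass.
    """
    expr = rma(raw, annotation, background_params=background_params)
    log2 = _preprocessed_log2(raw, params=background_params)
    samples = sample_negative_probesets(
        pool, set_size=set_size, n_sets=n_sets, n_repeats=n_repeats, seed=seed
    )
    nulls = [null_signals(s, raw, log2_values=log2) for s in samples]
    pvals = detection_pvalues(expr, nulls)
    calls = call_presence(pvals, raw.groups(), threshold=threshold)
    table = DetectionTable(pvalues=pvals, calls=calls, threshold=threshold, n_repeats=n_repeats)
    return expr, table
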