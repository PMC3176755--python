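"""Per-gene group fits, empirical-Bayes moderated t/F, BH adjustment, and
the all-contrast enrichment rules.

The model is a per-gene one-way layout (cell means), variance pooled over
groups. Residual variances are shrunk toward a common prior by empirical
Bayes: a scaled inverse-chi-square prior with df d0 and scale s0² gives
posterior variance s̃² = (d0·s0² + df·s²)/(d0 + df), and t statistics built
on s̃ gain d0 extra degrees of freedom. The hyperparameters (d0, s0²) are
estimated by matching moments of log s² (digamma/trigamma equations).

Two selection rules mirror the two analyses they serve:
  * ``atlas``: a gene is enriched in the target group when every contrast
    target-vs-other has adjusted p < 0.01 (BH within contrast) and positive
    log fold change;
  * ``gametophyte``: a moderated-F gate at FDR < 0.05 first, then the same
    all-contrast up-significance requirement at 0.05 within the gated set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import DetectionTable, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GroupFit",
    "ModeratedStats",
    "EnrichmentVerdict",
    "fit_groups",
    "ebayes",
    "bh_adjust",
    "prefilter_by_detection",
    "enriched_in_all_contrasts",
    "trigamma_inverse",
]


@dataclass
class GroupFit:
    genes: list[str]
    group_names: list[str]
    group_sizes: dict[str, int]
    means: pd.DataFrame  # genes × groups, log2
    s2: np.ndarray  # pooled residual variance per gene
    df: int  # residual df, sum over groups of (n_g - 1)

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("residual df must be >= 1")
        if np.any(self.s2 < 0):
            raise ValueError("negative residual variance")


@dataclass
class ModeratedStats:
    fit: GroupFit
    d0: float
    s0_2: float
    s2_post: np.ndarray
    df_total: float


@dataclass
class EnrichmentVerdict:
    gene: str
    target: str
    contrasts: dict[str, tuple[float, float]] = field(default_factory=dict)  # other -> (logFC, adj p)
    enriched: bool = False
    rule: str = "atlas-0.01-all"


def fit_groups(expr: ExpressionMatrix, groups: dict[str, list[str]]) -> GroupFit:
    """Cell-means fit with variance pooled across groups (per gene OLS)."""
    group_names = list(groups)
    sizes = {g: len(a) for g, a in groups.items()}
    if any(n < 1 for n in sizes.values()):
        raise ValueError("every group needs at least one array")
    df = sum(n - 1 for n in sizes.values())
    if df < 1:
        raise ValueError("total residual df is zero; need replication somewhere")
    frame = expr.to_frame()
    means = pd.DataFrame(index=expr.probeset_ids, columns=group_names, dtype=float)
    rss = np.zeros(len(expr.probeset_ids))
    for g in group_names:
        block = frame[groups[g]].to_numpy(float)
        m = block.mean(axis=1)
        means[g] = m
        rss += ((block - m[:, None]) ** 2).sum(axis=1)
    s2 = rss / df
    return GroupFit(
        genes=list(expr.probeset_ids),
        group_names=group_names,
        group_sizes=sizes,
        means=means,
        s2=s2,
        df=df,
    )


def trigamma_inverse(x: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Monotone decreasing target; the iteration in 1/y is globally stable
    for the range met in practice.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = 0.5 + 1.0 / x  # starting value, exact as x -> 0
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if np.max(np.abs(dif) / y) < 1e-10:
            break
    return y if y.size > 1 else float(y[0])


def ebayes(fit: GroupFit, d0: float | None = None, s0_2: float | None = None) -> ModeratedStats:
    """Estimate (d0, s0²) from the spread of log s² and shrink variances.

    Method of moments on z = log s²: E[z] and Var[z] involve digamma and
    trigamma at df/2; excess spread beyond trigamma(df/2) determines
    trigamma(d0/2). Non-positive excess → d0 = ∞ (full shrinkage).
    ``d0``/``s0_2`` may be injected for testing.
    """
    s2 = fit.s2
    ok = s2 > 0
    if d0 is None or s0_2 is None:
        if ok.sum() < 10:
            raise ValueError("need >= 10 genes with positive variance to fit the prior")
        z = np.log(s2[ok])
        d = fit.df
        e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
        ebar = e.mean()
        n = e.size
        excess = np.mean((e - ebar) ** 2) * n / (n - 1) - special.polygamma(1, d / 2.0)
        if excess <= 0:
            warnings.warn("log-variance spread at or below sampling noise; d0 = inf")
            d0 = np.inf
            s0_2 = float(np.exp(ebar))
        else:
            d0 = float(2.0 * trigamma_inverse(excess))
            s0_2 = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + fit.df * s2) / (d0 + fit.df)
        df_total = d0 + fit.df
    logger.info("ebayes prior: d0=%.3f s0^2=%.5f", d0, s0_2)
    return ModeratedStats(fit=fit, d0=d0, s0_2=s0_2, s2_post=s2_post, df_total=df_total)


def moderated_t(
    mstats: ModeratedStats, group_a: str, group_b: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(logFC, t, two-sided p) for the contrast group_a − group_b."""
    fit = mstats.fit
    na, nb = fit.group_sizes[group_a], fit.group_sizes[group_b]
    logfc = (fit.means[group_a] - fit.means[group_b]).to_numpy(float)
    se = np.sqrt(mstats.s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    if np.isinf(mstats.df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=mstats.df_total)
    return logfc, t, p


def moderated_f(mstats: ModeratedStats) -> tuple[np.ndarray, np.ndarray]:
    """One-way moderated F over all groups: (F, p)."""
    fit = mstats.fit
    sizes = np.array([fit.group_sizes[g] for g in fit.group_names], dtype=float)
    m = fit.means.to_numpy(float)
    grand = (m * sizes[None, :]).sum(axis=1) / sizes.sum()
    between = ((m - grand[:, None]) ** 2 * sizes[None, :]).sum(axis=1)
    df1 = len(fit.group_names) - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(mstats.s2_post > 0, between / df1 / mstats.s2_post, np.inf)
    if np.isinf(mstats.df_total):
        p = stats.chi2.sf(f * df1, df=df1)
    else:
        p = stats.f.sf(f, df1, mstats.df_total)
    return f, p


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def prefilter_by_detection(
    genes: list[str],
    calls: DetectionTable,
    arrays: list[str],
    min_present_arrays: int = 3,
) -> list[str]:
    """Genes with array-level present (p ≤ threshold) in enough arrays."""
    missing = set(arrays) - set(calls.pvalues.columns)
    if missing:
        raise ValueError(f"detection table lacks arrays: {sorted(missing)}")
    sub = calls.pvalues.loc[genes, arrays].to_numpy(float)
    n_present = (sub <= calls.threshold).sum(axis=1)
    return [g for g, n in zip(genes, n_present) if n >= min_present_arrays]


def enriched_in_all_contrasts(
    mstats: ModeratedStats,
    target: str,
    others: list[str] | None = None,
    alpha: float = 0.01,
    rule: str = "atlas",
    f_fdr: float = 0.05,
) -> pd.DataFrame:
    """Apply the all-contrast enrichment rule for one target group.

    Returns a tidy frame (gene, contrast columns, enriched flag). ``atlas``:
    adj p < alpha and logFC > 0 in every target-vs-other contrast.
    ``gametophyte``: moderated-F BH-FDR < ``f_fdr`` gate, then per-contrast
    adjusted significance (within the gated genes) and positive logFC in
    all contrasts.
    """
    fit = mstats.fit
    if others is None:
        others = [g for g in fit.group_names if g != target]
    if target in others:
        raise ValueError("target group must not appear among the others")
    if not others:
        raise ValueError("need at least one contrast group")

    genes = np.array(fit.genes)
    keep = np.ones(len(genes), dtype=bool)
    rule_tag = f"atlas-{alpha}-all"
    if rule == "gametophyte":
        _, fp = moderated_f(mstats)
        keep = bh_adjust(fp) < f_fdr
        rule_tag = f"gametophyte-FDR{f_fdr}-all{len(others)}"
    elif rule != "atlas":
        raise ValueError(f"unknown rule {rule!r}")

    records: dict[str, np.ndarray] = {}
    enriched = keep.copy()
    for other in others:
        logfc, _t, p = moderated_t(mstats, target, other)
        adj = np.full(len(genes), np.nan)
        if keep.any():
            adj[keep] = bh_adjust(p[keep])
        ok = keep & (adj < alpha) & (logfc > 0)
        enriched &= ok
        records[f"logFC_{other}"] = logfc
        records[f"adj_p_{other}"] = adj
    out = pd.DataFrame({"gene": genes, **records, "enriched": enriched})
    out["rule"] = rule_tag
    return out
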