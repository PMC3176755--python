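"""Over-representation tests for families and GO terms.

Family tests are two-sided Fisher's exact tests of the significant set
against the whole array-genome. GO tests are one-sided (over-representation)
per-term Fisher tests on true-path-propagated annotations, with optional
DAG decorrelation: ``elim`` removes the genes of significant child terms
from their ancestors before those are tested; ``weight`` softly
down-weights them in proportion to how much better the child explains the
signal (child p over parent p), a pinned variant of the published
child-parent reweighting scheme — the small-fixture algorithm traces in the
test suite are the normative definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetAnnotation",
    "GoDag",
    "fisher_exact_2x2",
    "family_enrichment",
    "propagate_annotations",
    "go_enrichment",
    "read_dag_tsv",
    "read_obo_subset",
    "format_pvalue",
]


@dataclass
class GeneSetAnnotation:
    families: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        for fam, genes in self.families.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(f"family {fam} has genes outside the universe: {sorted(extra)[:5]}")


@dataclass
class GoDag:
    """Terms with is_a/part_of parent links and per-term gene annotations.

    ``graph`` holds edges child → parent. ``direct`` maps term → directly
    annotated genes; ``propagated`` (after :func:`propagate_annotations`)
    adds every descendant's genes (true-path rule).
    """

    graph: nx.DiGraph
    direct: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)
    propagated: dict[str, set[str]] | None = None

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"term graph contains a cycle: {cycle}")

    def children(self, term: str) -> list[str]:
        return sorted(self.graph.predecessors(term))

    def ancestors(self, term: str) -> set[str]:
        return set(nx.descendants(self.graph, term))


def read_dag_tsv(path) -> GoDag:
    """Parent-child TSV with columns child, parent (header optional)."""
    df = pd.read_csv(path, sep="\t")
    if "child" not in df.columns:
        df = pd.read_csv(path, sep="\t", header=None, names=["child", "parent"])
    g = nx.DiGraph()
    for _, row in df.iterrows():
        g.add_edge(str(row["child"]), str(row["parent"]))
    return GoDag(graph=g, direct={t: set() for t in g.nodes})


def read_obo_subset(path) -> GoDag:
    """Minimal OBO reader: [Term] stanzas, id/name/is_a lines only."""
    g = nx.DiGraph()
    names: dict[str, str] = {}
    term = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line == "[Term]":
                term = None
            elif line.startswith("id:"):
                term = line.split("id:", 1)[1].strip()
                g.add_node(term)
            elif line.startswith("name:") and term:
                names[term] = line.split("name:", 1)[1].strip()
            elif line.startswith("is_a:") and term:
                parent = line.split("is_a:", 1)[1].strip().split("!")[0].strip()
                g.add_edge(term, parent)
    return GoDag(graph=g, direct={t: set() for t in g.nodes}, names=names)


def fisher_exact_2x2(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> float:
    """Fisher's exact test on [[a, b], [c, d]].

    Hypergeometric point probabilities for the fixed margins; two-sided p
    sums every table whose point probability is ≤ the observed one (with a
    1 + 1e-7 relative slack for floating-point ties); ``greater``/``less``
    are the upper/lower tails in cell a.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cells must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    rv = stats.hypergeom(n, row1, col1)
    if alternative == "greater":
        return float(min(1.0, rv.sf(a - 1)))
    if alternative == "less":
        return float(min(1.0, rv.cdf(a)))
    if alternative != "two-sided":
        raise ValueError(f"unknown alternative {alternative!r}")
    lo, hi = max(0, col1 - (c + d)), min(row1, col1)
    support = np.arange(lo, hi + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-7)].sum()))


def family_enrichment(
    sig_genes: set[str], annotation: GeneSetAnnotation, alpha: float = 0.01
) -> pd.DataFrame:
    """Two-sided Fisher per family against the whole universe.

    Columns: family, annotated, significant, expected, odds_ratio, p,
    flagged. Direction follows the odds ratio (over if > 1).
    """
    extra = sig_genes - annotation.universe
    if extra:
        raise ValueError(f"significant genes outside the universe: {sorted(extra)[:5]}")
    n_universe = len(annotation.universe)
    n_sig = len(sig_genes)
    rows = []
    for fam in sorted(annotation.families):
        genes = annotation.families[fam]
        if not genes:
            logger.info("skipping empty family %s", fam)
            continue
        a = len(genes & sig_genes)
        b = len(genes) - a
        c = n_sig - a
        d = n_universe - len(genes) - c
        p = fisher_exact_2x2(a, b, c, d, "two-sided")
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append(
            {
                "family": fam,
                "annotated": len(genes),
                "significant": a,
                "expected": len(genes) * n_sig / n_universe if n_universe else 0.0,
                "odds_ratio": odds,
                "p": p,
                "flagged": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def propagate_annotations(dag: GoDag) -> GoDag:
    """True-path closure: each term inherits all descendants' direct genes."""
    propagated: dict[str, set[str]] = {}
    for term in nx.topological_sort(dag.graph):  # children before parents
        genes = set(dag.direct.get(term, set()))
        for child in dag.graph.predecessors(term):
            genes |= propagated[child]
        propagated[term] = genes
    for term, genes in propagated.items():
        for parent in dag.graph.successors(term):
            assert propagated[parent] >= genes
    return GoDag(graph=dag.graph, direct=dag.direct, names=dag.names, propagated=propagated)


def _levels_bottom_up(dag: GoDag) -> list[list[str]]:
    """Terms grouped by height above the leaves, leaves first."""
    height: dict[str, int] = {}
    for term in nx.topological_sort(dag.graph):  # children first
        kids = list(dag.graph.predecessors(term))
        height[term] = 0 if not kids else 1 + max(height[k] for k in kids)
    out: dict[int, list[str]] = {}
    for t, h in height.items():
        out.setdefault(h, []).append(t)
    return [sorted(out[h]) for h in sorted(out)]


def _weighted_fisher(
    term_genes: set[str], sig: set[str], universe: set[str], w: dict[str, float]
) -> float:
    """One-sided Fisher with down-weighted gene contributions.

    Weighted counts are rounded to the nearest integer before the
    hypergeometric evaluation.
    """
    a = round(sum(w.get(g, 1.0) for g in term_genes & sig))
    ann = round(sum(w.get(g, 1.0) for g in term_genes))
    b = max(ann - a, 0)
    c = len(sig) - a
    d = len(universe) - len(sig) - b
    if c < 0 or d < 0:  # heavy down-weighting edge case
        return 1.0
    return fisher_exact_2x2(a, b, c, d, "greater")


def go_enrichment(
    dag: GoDag,
    sig_genes: set[str],
    universe: set[str],
    method: str = "classic",
    alpha_elim: float = 0.01,
) -> pd.DataFrame:
    """Per-term over-representation table (term, name, annotated,
    significant, expected, p, p_display).

    classic: plain one-sided Fisher on propagated sets. elim: bottom-up;
    genes of terms with p < ``alpha_elim`` are removed from all ancestors
    before those are tested. weight: bottom-up; each child more significant
    than its parent multiplies its genes' weights in the parent and the
    parent's ancestors by p_child/p_parent, and the parent p is recomputed
    with the new weights (child p-values are never revised).
    """
    if dag.propagated is None:
        dag = propagate_annotations(dag)
    prop = {t: g & universe for t, g in dag.propagated.items()}
    sig = sig_genes & universe
    if sig != sig_genes:
        raise ValueError("significant genes must be a subset of the universe")
    n_uni, n_sig = len(universe), len(sig)

    def classic_p(genes: set[str]) -> float:
        a = len(genes & sig)
        b = len(genes) - a
        c = n_sig - a
        d = n_uni - len(genes) - c
        return fisher_exact_2x2(a, b, c, d, "greater")

    pvals: dict[str, float] = {}
    if method == "classic":
        for t in prop:
            pvals[t] = classic_p(prop[t])
    elif method == "elim":
        working = {t: set(g) for t, g in prop.items()}
        for level in _levels_bottom_up(dag):
            for t in level:
                pvals[t] = classic_p(working[t])
                if pvals[t] < alpha_elim:
                    for anc in dag.ancestors(t):
                        working[anc] -= prop[t]
    elif method == "weight":
        weights: dict[str, dict[str, float]] = {t: {} for t in prop}
        for level in _levels_bottom_up(dag):
            for t in level:
                p_t = _weighted_fisher(prop[t], sig, universe, weights[t])
                for child in dag.children(t):
                    p_c = pvals[child]
                    if p_c < p_t and p_t > 0:
                        ratio = p_c / p_t
                        for node in {t} | dag.ancestors(t):
                            wmap = weights[node]
                            for g in prop[child]:
                                wmap[g] = wmap.get(g, 1.0) * ratio
                        p_t = _weighted_fisher(prop[t], sig, universe, weights[t])
                pvals[t] = p_t
    else:
        raise ValueError(f"unknown method {method!r}")

    rows = []
    for t in sorted(prop):
        genes = prop[t]
        rows.append(
            {
                "term": t,
                "name": dag.names.get(t, ""),
                "annotated": len(genes),
                "significant": len(genes & sig),
                "expected": len(genes) * n_sig / n_uni if n_uni else 0.0,
                "p": pvals[t],
                "p_display": format_pvalue(pvals[t]),
            }
        )
    return pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)


def format_pvalue(p: float, floor: float = 1e-30) -> str:
    """Report convention: values below the floor print as '<1e-30'."""
    return f"<{floor:g}" if p < floor else f"{p:.3g}"
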