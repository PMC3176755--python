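"""Fisher tests against enumeration oracles; GO DAG propagation and the
classic/elim/weight decorrelation on hand-traced fixtures."""

from itertools import product
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import panpflow as pf
from panpflow.genesets import GoDag, format_pvalue, read_dag_tsv, read_obo_subset


def enumerate_two_sided(a, b, c, d):
    """Sum point probabilities <= observed over all tables with the margins."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    denom = comb(n, col1)

    def prob(x):
        if x < 0 or x > row1 or col1 - x > n - row1:
            return 0.0
        return comb(row1, x) * comb(n - row1, col1 - x) / denom

    p_obs = prob(a)
    return sum(prob(x) for x in range(col1 + 1) if prob(x) <= p_obs * (1 + 1e-7))


class TestFisher:
    def test_enumerated_2_2_table(self):
        # margins (2,2)/(2,2): three tables, extremes have probability 1/6
        assert pf.fisher_exact_2x2(2, 0, 0, 2) == pytest.approx(1 / 3)

    def test_proportional_rows_give_one(self):
        assert pf.fisher_exact_2x2(4, 6, 2, 3) == pytest.approx(1.0)

    def test_all_zero_margins(self):
        assert pf.fisher_exact_2x2(0, 0, 0, 0) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_two_sided_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            a, b, c, d = (int(rng.integers(0, 12)) for _ in range(4))
            if a + b + c + d == 0:
                continue
            got = pf.fisher_exact_2x2(a, b, c, d)
            assert got == pytest.approx(enumerate_two_sided(a, b, c, d), rel=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_one_sided_matches_hypergeom_survival(self, seed):
        rng = np.random.default_rng(100 + seed)
        for _ in range(5):
            a, b, c, d = (int(rng.integers(0, 10)) for _ in range(4))
            n, row1, col1 = a + b + c + d, a + b, a + c
            if n == 0:
                continue
            want_greater = sum(
                comb(row1, x) * comb(n - row1, col1 - x) / comb(n, col1)
                for x in range(a, min(row1, col1) + 1)
                if col1 - x <= n - row1
            )
            assert pf.fisher_exact_2x2(a, b, c, d, "greater") == pytest.approx(
                want_greater, rel=1e-9
            )

    def test_agrees_with_scipy_cross_check(self):
        rng = np.random.default_rng(55)
        for _ in range(20):
            a, b, c, d = (int(rng.integers(0, 15)) for _ in range(4))
            for alt in ("two-sided", "greater", "less"):
                want = stats.fisher_exact([[a, b], [c, d]], alternative=alt).pvalue
                assert pf.fisher_exact_2x2(a, b, c, d, alt) == pytest.approx(want, rel=1e-6)

    def test_rejects_negative_cells(self):
        with pytest.raises(ValueError):
            pf.fisher_exact_2x2(-1, 2, 3, 4)


class TestFamilyEnrichment:
    def test_family_equal_to_sig_set_is_top_hit(self):
        universe = {f"g{i}" for i in range(40)}
        sig = {f"g{i}" for i in range(8)}
        ann = pf.GeneSetAnnotation(
            families={"fam_sig": set(sig), "fam_other": {f"g{i}" for i in range(20, 30)}},
            universe=universe,
        )
        out = pf.family_enrichment(sig, ann).set_index("family")
        assert out.loc["fam_sig", "p"] < out.loc["fam_other", "p"]
        assert out.loc["fam_sig", "odds_ratio"] > 1

    def test_universe_equals_sig_set_degenerate(self):
        universe = {f"g{i}" for i in range(10)}
        ann = pf.GeneSetAnnotation(
            families={"f": {f"g{i}" for i in range(4)}}, universe=universe
        )
        out = pf.family_enrichment(set(universe), ann)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_random_families_give_uniform_pvalues(self):
        """Null calibration: a random family's p-value is ~Uniform(0,1)."""
        rng = np.random.default_rng(77)
        universe = {f"g{i}" for i in range(200)}
        sig = {f"g{i}" for i in range(60)}
        ps = []
        for k in range(300):
            fam = set(rng.choice(sorted(universe), size=25, replace=False))
            ann = pf.GeneSetAnnotation(families={"f": fam}, universe=universe)
            ps.append(pf.family_enrichment(sig, ann)["p"].iloc[0])
        # discrete + two-sided, so only a coarse KS sanity check
        assert stats.kstest(ps, "uniform").statistic < 0.2
        assert np.mean(np.array(ps) < 0.05) < 0.12

    def test_expected_column_identity(self):
        universe = {f"g{i}" for i in range(50)}
        sig = {f"g{i}" for i in range(10)}
        fam = {f"g{i}" for i in range(5, 25)}
        ann = pf.GeneSetAnnotation(families={"f": fam}, universe=universe)
        out = pf.family_enrichment(sig, ann)
        assert out["expected"].iloc[0] == pytest.approx(len(fam) * len(sig) / 50)


def chain_dag():
    g = nx.DiGraph()
    g.add_edge("leaf", "mid")
    g.add_edge("mid", "root")
    return g


class TestPropagation:
    def test_chain_counts_gene_at_all_levels(self):
        dag = GoDag(graph=chain_dag(), direct={"leaf": {"g1"}, "mid": set(), "root": set()})
        out = pf.propagate_annotations(dag)
        assert out.propagated == {"leaf": {"g1"}, "mid": {"g1"}, "root": {"g1"}}

    def test_diamond_no_double_counting(self):
        g = nx.DiGraph()
        for child, parent in [("d", "b"), ("d", "c"), ("b", "a"), ("c", "a")]:
            g.add_edge(child, parent)
        dag = GoDag(graph=g, direct={"d": {"g1"}, "b": {"g2"}, "c": set(), "a": set()})
        out = pf.propagate_annotations(dag)
        assert out.propagated["a"] == {"g1", "g2"}
        assert len(out.propagated["a"]) == 2

    def test_random_dag_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(13)
        nodes = [f"t{i}" for i in range(12)]
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for i in range(12):
            for j in range(i + 1, 12):
                if rng.random() < 0.25:
                    g.add_edge(nodes[i], nodes[j])  # edges child->parent, acyclic
        direct = {
            n: {f"g{k}" for k in rng.choice(30, size=rng.integers(0, 4), replace=False)}
            for n in nodes
        }
        out = pf.propagate_annotations(GoDag(graph=g, direct=direct))
        # oracle: reachability via boolean matrix powers
        idx = {n: i for i, n in enumerate(nodes)}
        adj = np.zeros((12, 12), dtype=bool)
        for u, v in g.edges:
            adj[idx[u], idx[v]] = True  # u's genes flow to v
        reach = adj.copy()
        for _ in range(12):
            reach = reach | (reach @ adj)
        for n in nodes:
            want = set(direct[n])
            for m in nodes:
                if reach[idx[m], idx[n]]:
                    want |= direct[m]
            assert out.propagated[n] == want

    def test_cycle_detected(self):
        g = nx.DiGraph([("a", "b"), ("b", "a")])
        with pytest.raises(ValueError, match="cycle"):
            GoDag(graph=g, direct={})


class TestGoEnrichment:
    def _single_term(self):
        g = nx.DiGraph()
        g.add_node("t1")
        universe = {f"g{i}" for i in range(30)}
        dag = GoDag(graph=g, direct={"t1": {f"g{i}" for i in range(10)}})
        sig = {f"g{i}" for i in range(8)}
        return dag, sig, universe

    def test_single_term_all_methods_agree_with_plain_fisher(self):
        dag, sig, universe = self._single_term()
        want = pf.fisher_exact_2x2(8, 2, 0, 20, "greater")
        for method in ("classic", "elim", "weight"):
            out = pf.go_enrichment(dag, sig, universe, method=method)
            assert out["p"].iloc[0] == pytest.approx(want)
            assert out["significant"].iloc[0] == 8
            assert out["expected"].iloc[0] == pytest.approx(10 * 8 / 30)

    def test_classic_invariant_to_topology(self):
        universe = {f"g{i}" for i in range(30)}
        sig = {f"g{i}" for i in range(6)}
        direct = {"leaf": {f"g{i}" for i in range(6)}, "mid": set(), "root": set()}
        chained = pf.go_enrichment(
            GoDag(graph=chain_dag(), direct=direct), sig, universe, "classic"
        ).set_index("term")
        flat_graph = nx.DiGraph()
        flat_graph.add_nodes_from(["leaf", "mid", "root"])
        flat = pf.go_enrichment(
            GoDag(graph=flat_graph, direct={"leaf": direct["leaf"], "mid": set(), "root": set()}),
            sig, universe, "classic",
        ).set_index("term")
        assert chained.loc["leaf", "p"] == pytest.approx(flat.loc["leaf", "p"])

    def test_elim_raises_parent_p_above_classic(self):
        """Chain with a significant leaf: elim strips the leaf's genes from
        its ancestors, weakening (raising) the parent p-value."""
        universe = {f"g{i}" for i in range(40)}
        sig = {f"g{i}" for i in range(8)}
        direct = {
            "leaf": {f"g{i}" for i in range(8)},  # exactly the significant genes
            "mid": {"g20", "g21"},
            "root": set(),
        }
        dag = GoDag(graph=chain_dag(), direct=direct)
        classic = pf.go_enrichment(dag, sig, universe, "classic").set_index("term")
        elim = pf.go_enrichment(dag, sig, universe, "elim", alpha_elim=0.01).set_index("term")
        assert elim.loc["leaf", "p"] == pytest.approx(classic.loc["leaf", "p"])
        assert elim.loc["mid", "p"] > classic.loc["mid", "p"]
        assert elim.loc["root", "p"] > classic.loc["root", "p"]

    def test_weight_leaves_disjoint_siblings_at_classic_p(self):
        """Siblings sharing no genes keep their classic p under weight."""
        g = nx.DiGraph([("s1", "root"), ("s2", "root")])
        universe = {f"g{i}" for i in range(40)}
        sig = {f"g{i}" for i in range(8)}
        direct = {
            "s1": {f"g{i}" for i in range(6)},
            "s2": {f"g{i}" for i in range(20, 28)},
            "root": set(),
        }
        dag = GoDag(graph=g, direct=direct)
        classic = pf.go_enrichment(dag, sig, universe, "classic").set_index("term")
        weight = pf.go_enrichment(dag, sig, universe, "weight").set_index("term")
        for s in ("s1", "s2"):
            assert weight.loc[s, "p"] == pytest.approx(classic.loc[s, "p"])

    def test_weight_downweights_parent_of_better_child(self):
        """Hand-traced two-term chain: the child explains the signal, so the
        parent's weighted p must be larger than its classic p."""
        universe = {f"g{i}" for i in range(40)}
        sig = {f"g{i}" for i in range(8)}
        direct = {
            "leaf": {f"g{i}" for i in range(8)},
            "mid": {"g20", "g21", "g22"},  # extra non-significant annotation
            "root": set(),
        }
        dag = GoDag(graph=chain_dag(), direct=direct)
        classic = pf.go_enrichment(dag, sig, universe, "classic").set_index("term")
        weight = pf.go_enrichment(dag, sig, universe, "weight").set_index("term")
        assert weight.loc["leaf", "p"] == pytest.approx(classic.loc["leaf", "p"])
        assert weight.loc["mid", "p"] > classic.loc["mid", "p"]

    def test_unknown_method_errors(self):
        dag, sig, universe = self._single_term()
        with pytest.raises(ValueError, match="unknown method"):
            pf.go_enrichment(dag, sig, universe, method="parentchild")


class TestReaders:
    def test_dag_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "dag.tsv"
        path.write_text("child\tparent\nleaf\tmid\nmid\troot\n")
        dag = read_dag_tsv(path)
        assert set(dag.graph.edges) == {("leaf", "mid"), ("mid", "root")}

    def test_minimal_obo(self, tmp_path):
        path = tmp_path / "mini.obo"
        path.write_text(
            "format-version: 1.2\n\n[Term]\nid: GO:1\nname: root\n\n"
            "[Term]\nid: GO:2\nname: child\nis_a: GO:1 ! root\n"
        )
        dag = read_obo_subset(path)
        assert ("GO:2", "GO:1") in dag.graph.edges
        assert dag.names["GO:2"] == "child"


def test_pvalue_truncation_format():
    assert format_pvalue(1e-40) == "<1e-30"
    assert format_pvalue(0.0044) == "0.0044"
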