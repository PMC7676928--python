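import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from herbnet.errors import ValidationError
from herbnet.networks import TypedNetwork, build_ct_network
from herbnet.targets import CompoundTargetMap
from herbnet.topology import (SelectionRule, centrality_table, class_summary,
                              select_nodes)
from oracles import brute_force_betweenness


def _net(nodes, edges, kind="protein"):
    net = TypedNetwork()
    for n in nodes:
        net.add_node(n, kind)
    for a, b in edges:
        net.add_edge(a, b)
    return net


def _random_net(rng, n_max=8, p=0.4):
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"N{i}" for i in range(n)]
    edges = [(nodes[i], nodes[j]) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return _net(nodes, edges)


class TestCentrality:
    def test_star_degrees_and_bc(self):
        net = _net("CABDE", [("C", x) for x in "ABDE"])
        table = centrality_table(net).set_index("node")
        assert table.loc["C", "dc"] == 4
        assert all(table.loc[list("ABDE"), "dc"] == 1)
        assert table.loc["C", "bc"] == pytest.approx(1.0)
        assert all(table.loc[list("ABDE"), "bc"] == 0)

    def test_path_midpoint(self):
        net = _net("ABC", [("A", "B"), ("B", "C")])
        table = centrality_table(net).set_index("node")
        assert table.loc["B", "bc"] == pytest.approx(1.0)
        raw = centrality_table(net, normalized=False).set_index("node")
        assert raw.loc["B", "bc"] == pytest.approx(1.0)

    def test_isolated_node_zero(self):
        net = _net("AB", [])
        table = centrality_table(net).set_index("node")
        assert (table["dc"] == 0).all() and (table["bc"] == 0).all()

    @pytest.mark.parametrize("normalized", [True, False])
    def test_matches_brute_force_enumeration(self, normalized):
        rng = np.random.default_rng(20240901)
        for _ in range(40):
            net = _random_net(rng)
            table = centrality_table(net, normalized=normalized).set_index("node")
            oracle = brute_force_betweenness(net.nodes(), net.edges(), normalized)
            for node, expect in oracle.items():
                assert table.loc[node, "bc"] == pytest.approx(expect, abs=1e-12)

    def test_disconnected_normalization_uses_full_n(self):
        # two triangles sharing nothing: BC accumulates within components but
        # the denominator is (n-1)(n-2)/2 with n = 6
        net = _net("ABCDEF", [("A", "B"), ("B", "C"), ("A", "C"),
                              ("D", "E"), ("E", "F"), ("D", "F")])
        table = centrality_table(net)
        oracle = brute_force_betweenness(net.nodes(), net.edges(), True)
        for row in table.itertuples(index=False):
            assert row.bc == pytest.approx(oracle[row.node], abs=1e-12)

    def test_bipartite_degree_sum_identity(self):
        net = build_ct_network(CompoundTargetMap(
            {("c1", "A"), ("c1", "B"), ("c2", "B"), ("c2", "C")}))
        table = centrality_table(net)
        by_kind = table.groupby("kind")["dc"].sum()
        assert by_kind["compound"] == by_kind["target"] == net.n_edges


class TestClassSummary:
    def test_simple_median_and_mean(self):
        table = pd.DataFrame({"node": list("abc"), "kind": ["target"] * 3,
                              "dc": [1, 2, 3], "bc": [0.1, 0.2, 0.3]})
        assert class_summary(table, "median")["target"][0] == 2
        assert class_summary(table, "mean")["target"][0] == 2

    def test_even_count_median_is_midpoint(self):
        table = pd.DataFrame({"node": list("abcd"), "kind": ["target"] * 4,
                              "dc": [1, 2, 10, 20], "bc": [0.0] * 4})
        assert class_summary(table, "median")["target"][0] == 6.0

    def test_published_compound_class_mean(self, ctp_table):
        stats = class_summary(ctp_table, "mean")
        assert stats["compound"][0] == pytest.approx(101 / 11)
        assert round(stats["compound"][0], 2) == 9.18

    def test_published_pathway_class_mean(self, ctp_table):
        stats = class_summary(ctp_table, "mean")
        assert stats["pathway"][0] == pytest.approx(138 / 20)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            class_summary(pd.DataFrame(columns=["node", "kind", "dc", "bc"]))


class TestSelectNodes:
    def test_identical_values_strict_mean_selects_nothing(self):
        table = pd.DataFrame({"node": list("abc"), "kind": ["target"] * 3,
                              "dc": [5, 5, 5], "bc": [0.1, 0.1, 0.1]})
        rule = SelectionRule("mean", 1.0, "AND", strict=True)
        assert select_nodes(table, rule) == []

    def test_published_compound_selection(self, ctp_table):
        sub = ctp_table[ctp_table["kind"] == "compound"]
        sel = select_nodes(sub, SelectionRule("mean", 1.0, "AND", strict=True))
        assert sel == ["Quercetin", "Luteolin", "Kaempferol", "Beta-sitosterol"]

    def test_published_target_selection_dc_only(self, ctp_table):
        sub = ctp_table[ctp_table["kind"] == "target"]
        sel = select_nodes(sub, SelectionRule("mean", 1.0, "DC_ONLY", strict=True))
        assert len(sel) == 15 and sel[0] == "PIK3CG"

    def test_per_class_thresholds(self, ctp_table):
        sel = select_nodes(ctp_table,
                           SelectionRule("mean", 1.0, "AND", strict=True,
                                         per_class=True))
        compounds = [n for n in sel
                     if n in set(ctp_table[ctp_table.kind == "compound"].node)]
        assert compounds == ["Quercetin", "Luteolin", "Kaempferol", "Beta-sitosterol"]

    @given(st.integers(0, 2**31 - 1), st.sampled_from(["median", "mean"]),
           st.sampled_from(["AND", "OR", "DC_ONLY"]), st.booleans())
    def test_matches_exhaustive_filter_oracle(self, seed, statistic, combine, strict):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame({
            "node": [f"n{i}" for i in range(12)],
            "kind": rng.choice(["target", "compound"], size=12),
            "dc": rng.integers(0, 30, size=12),
            "bc": rng.random(12),
        })
        mult = float(rng.uniform(0.5, 3.0))
        rule = SelectionRule(statistic, mult, combine, strict=strict)
        got = set(select_nodes(table, rule))
        stat = getattr(table["dc"], statistic)(), getattr(table["bc"], statistic)()
        expect = set()
        for r in table.itertuples(index=False):
            cmp = (lambda a, b: a > b) if strict else (lambda a, b: a >= b)
            dc_ok, bc_ok = cmp(r.dc, mult * stat[0]), cmp(r.bc, mult * stat[1])
            ok = {"AND": dc_ok and bc_ok, "OR": dc_ok or bc_ok, "DC_ONLY": dc_ok}[combine]
            if ok:
                expect.add(r.node)
        assert got == expect

    @given(st.integers(0, 2**31 - 1), st.floats(1.0, 2.0), st.floats(0.01, 1.0))
    def test_monotone_in_multiplier(self, seed, mult, bump):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame({
            "node": [f"n{i}" for i in range(10)],
            "kind": ["target"] * 10,
            "dc": rng.integers(0, 30, size=10),
            "bc": rng.random(10),
        })
        lo = select_nodes(table, SelectionRule("median", mult, "AND"))
        hi = select_nodes(table, SelectionRule("median", mult + bump, "AND"))
        assert set(hi) <= set(lo)

    def test_output_sorted_by_dc_then_bc(self):
        table = pd.DataFrame({"node": ["a", "b", "c"], "kind": ["target"] * 3,
                              "dc": [10, 10, 20], "bc": [0.5, 0.9, 0.1]})
        sel = select_nodes(table, SelectionRule("mean", 0.1, "OR", strict=False))
        assert sel == ["c", "b", "a"]
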