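import collections

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stppinet.datatypes import IntervalKey, QueryGeneSet
from stppinet.networks import IntervalNetwork, QuerySubnetwork
from stppinet.topology import (GenePartnerProfile, identify_driver, network_overlap,
                               one_way_anova, partner_ratio_anova, partner_ratios,
                               radiality)


def subnet(label, query, partner_map):
    """QuerySubnetwork from {query gene: partner list}."""
    partners = set().union(*map(set, partner_map.values())) if partner_map else set()
    edges = {frozenset((q, p)): "query-partner"
             for q, ps in partner_map.items() for p in ps}
    return QuerySubnetwork(key=IntervalKey.parse(label), query_nodes=set(query),
                           partner_nodes=partners, edges=edges)


class TestOverlap:
    def test_identical_networks_share_everything(self):
        nets = [subnet(l, {"Q1"}, {"Q1": ["A", "B"]}) for l in ("P1R1", "P1R3", "P4R3")]
        ov = network_overlap(nets)
        assert ov.shared_by_all("query") == (1, 1, 1.0)
        assert ov.shared_by_all("partner") == (2, 2, 1.0)

    def test_disjoint_partner_sets(self):
        nets = [subnet("P1R1", {"Q1"}, {"Q1": ["A"]}),
                subnet("P1R3", {"Q1"}, {"Q1": ["B"]}),
                subnet("P4R3", {"Q1"}, {"Q1": ["C"]})]
        ov = network_overlap(nets)
        assert ov.shared_by_all("partner")[0] == 0
        assert ov.partner_shared_by == {1: 3, 2: 0, 3: 0}

    def test_counts_match_membership_tabulation(self):
        rng = np.random.default_rng(12)
        genes = [f"G{i}" for i in range(30)]
        nets = []
        sets = []
        for l in ("P1R1", "P1R3", "P4R3"):
            chosen = list(rng.choice(genes, size=12, replace=False))
            sets.append(set(chosen))
            nets.append(subnet(l, {"Q1"}, {"Q1": chosen}))
        ov = network_overlap(nets)
        tab = collections.Counter(
            sum(g in s for s in sets) for g in set().union(*sets))
        for k in (1, 2, 3):
            assert ov.partner_shared_by[k] == tab.get(k, 0)
        # exactly-k counts partition the union
        assert sum(ov.partner_shared_by.values()) == len(set().union(*sets))

    def test_needs_two_networks(self):
        with pytest.raises(ValueError):
            network_overlap([subnet("P1R1", {"Q"}, {})])


class TestPartnerRatios:
    def make(self, pa, pb):
        a = subnet("P1R1", {"Q1"}, {"Q1": pa})
        b = subnet("P4R3", {"Q1"}, {"Q1": pb})
        (prof,) = partner_ratios(a, b, QueryGeneSet("q", {"Q1"}))
        return prof

    def test_identical_partner_sets(self):
        p = self.make(["X", "Y"], ["X", "Y"])
        assert (p.r_unique_a, p.r_unique_b, p.r_shared) == (0.0, 0.0, 1.0)

    def test_fully_distinct(self):
        p = self.make(["X"], ["Y"])
        assert (p.r_unique_a, p.r_unique_b, p.r_shared) == (0.5, 0.5, 0.0)

    def test_hand_counted_overlap(self):
        # A = {X,Y,Z}, B = {Y,Z,W}: union 4, unique 1 each, shared 2
        p = self.make(["X", "Y", "Z"], ["Y", "Z", "W"])
        assert (p.r_unique_a, p.r_unique_b, p.r_shared) == (0.25, 0.25, 0.5)

    def test_ratios_sum_to_one(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(15)]
        for _ in range(30):
            pa = list(rng.choice(genes, size=rng.integers(1, 8), replace=False))
            pb = list(rng.choice(genes, size=rng.integers(1, 8), replace=False))
            p = self.make(pa, pb)
            assert p.r_unique_a + p.r_unique_b + p.r_shared == pytest.approx(1.0, abs=1e-12)

    def test_empty_union_genes_skipped(self):
        a = subnet("P1R1", {"Q1", "Q2"}, {"Q1": ["X"]})
        b = subnet("P4R3", {"Q1", "Q2"}, {"Q1": ["Y"]})
        profiles = partner_ratios(a, b, QueryGeneSet("q", {"Q1", "Q2"}))
        assert [p.gene for p in profiles] == ["Q1"]


class TestAnova:
    def test_zero_between_group_variance(self):
        res = one_way_anova([[1, 2, 3], [2, 1, 3]])
        assert res.F == 0.0 and res.p == 1.0

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a, b = rng.normal(size=8), rng.normal(1.0, 1, size=11)
            res = one_way_anova([a, b])
            t, pt = stats.ttest_ind(a, b)
            assert res.F == pytest.approx(t ** 2, rel=1e-10)
            assert res.p == pytest.approx(pt, rel=1e-10)
            assert (res.df_between, res.df_within) == (1, 17)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(size=n) for n in (5, 7, 6)]
        res = one_way_anova(groups)
        ref = stats.f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(size=6) for _ in range(3)]
        base = one_way_anova(groups)
        shifted = one_way_anova([np.asarray(g) + 10 for g in groups])
        scaled = one_way_anova([np.asarray(g) * 3.5 for g in groups])
        assert shifted.F == pytest.approx(base.F, rel=1e-9)
        assert scaled.F == pytest.approx(base.F, rel=1e-9)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(400):
            ps.append(one_way_anova([rng.normal(size=5) for _ in range(3)]).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0]])
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0]])


def bfs_radiality_oracle(g: nx.Graph) -> dict:
    """Independent radiality via hand-rolled BFS (no networkx paths)."""
    out = {}
    seen_comp = {}
    comps = []
    for v in g.nodes:
        if v in seen_comp:
            continue
        comp = {v}
        frontier = [v]
        while frontier:
            nxt = []
            for u in frontier:
                for w in g.neighbors(u):
                    if w not in comp:
                        comp.add(w)
                        nxt.append(w)
            frontier = nxt
        for u in comp:
            seen_comp[u] = len(comps)
        comps.append(comp)
    for comp in comps:
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            continue
        dist = {}
        for s in comp:
            d = {s: 0}
            frontier = [s]
            while frontier:
                nxt = []
                for u in frontier:
                    for w in g.neighbors(u):
                        if w not in d:
                            d[w] = d[u] + 1
                            nxt.append(w)
                frontier = nxt
            dist[s] = d
        diam = max(max(d.values()) for d in dist.values())
        n = len(comp)
        for s in comp:
            avg = sum(dist[s][u] for u in comp if u != s) / (n - 1)
            out[s] = (diam + 1 - avg) / diam
    return out


class TestRadiality:
    def test_complete_graph(self):
        g = nx.complete_graph(4)
        table = radiality(g)
        assert (table["radiality"] == 1.0).all()

    def test_path_graph_hand_bfs(self):
        g = nx.path_graph(["A", "B", "C"])
        table = radiality(g)
        assert table.loc["B", "radiality"] == pytest.approx(1.0)
        assert table.loc["A", "radiality"] == pytest.approx(0.75)
        assert table.loc["C", "radiality"] == pytest.approx(0.75)

    def test_random_graphs_match_bfs_oracle(self):
        for seed in range(20):
            g = nx.gnp_random_graph(30, 0.08, seed=seed)
            if g.number_of_nodes() == 0:
                continue
            table = radiality(g)
            oracle = bfs_radiality_oracle(g)
            for v, r in oracle.items():
                assert table.loc[v, "radiality"] == pytest.approx(r, abs=1e-12)
            assert table["radiality"].between(0, 1).all()

    def test_singleton_component_zero(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_node("Z")
        table = radiality(g)
        assert table.loc["Z", "radiality"] == 0.0
        assert table.loc["Z", "component"] != table.loc["A", "component"]

    def test_empty_network_error(self):
        with pytest.raises(ValueError):
            radiality(nx.Graph())


class TestDriver:
    def test_star_center_wins(self):
        g = nx.star_graph(["HUB", "A", "B", "C"])
        table = radiality(g)
        gene, rad = identify_driver(table, {"HUB", "A"})
        assert gene == "HUB" and rad == 1.0

    def test_tie_broken_by_degree(self):
        table = pd.DataFrame(
            {"radiality": [0.8, 0.8], "degree": [5, 3], "component": [0, 0]},
            index=["GLOW", "GHIGH"])
        table.index.name = "gene"
        gene, _ = identify_driver(table, {"GLOW", "GHIGH"})
        assert gene == "GLOW"

    def test_matches_argmax_oracle(self):
        rng = np.random.default_rng(10)
        g = nx.gnp_random_graph(25, 0.15, seed=3)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in range(25)})
        table = radiality(g)
        cands = set(rng.choice(sorted(g.nodes), size=8, replace=False))
        gene, rad = identify_driver(table, cands)
        best = max(table.loc[sorted(cands & set(table.index)), "radiality"])
        assert rad == pytest.approx(best)

    def test_no_candidates_error(self):
        g = nx.path_graph(["A", "B"])
        with pytest.raises(ValueError):
            identify_driver(radiality(g), {"ZZ"})


def test_partner_ratio_anova_groupings():
    a = subnet("P1R1", {"Q1", "Q2", "Q3"},
               {"Q1": ["X", "Y"], "Q2": ["X"], "Q3": ["W", "V"]})
    b = subnet("P4R3", {"Q1", "Q2", "Q3"},
               {"Q1": ["Y", "Z"], "Q2": ["X"], "Q3": ["U"]})
    q = QueryGeneSet("q", {"Q1", "Q2", "Q3"})
    three = partner_ratio_anova(a, b, q, grouping="three")
    two = partner_ratio_anova(a, b, q, grouping="two")
    assert three.df_between == 2 and two.df_between == 1
    assert 0 <= three.p <= 1 and 0 <= two.p <= 1
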