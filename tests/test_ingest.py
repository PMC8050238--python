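import itertools

import numpy as np
import pandas as pd
import pytest

from stppinet import ingest
from stppinet.datatypes import ExpressionFilterParams, ExpressionMatrix


def write_expression(tmp_path, values, meta):
    vp, mp = tmp_path / "expr.tsv", tmp_path / "meta.tsv"
    ExpressionMatrix(values, meta).to_tsv(vp, mp)
    return vp, mp


def make_meta(samples):
    return pd.DataFrame({"stage": [1] * len(samples),
                         "structure": ["AMY"] * len(samples)}, index=samples)


class TestReadExpression:
    def test_round_trip(self, tiny_matrix, tmp_path):
        vp, mp = tmp_path / "e.tsv", tmp_path / "m.tsv"
        tiny_matrix.to_tsv(vp, mp)
        back = ingest.read_expression(vp, mp)
        assert back.equals(tiny_matrix)
        assert back.shape == (3, 4)

    def test_missing_metadata_column_is_named(self, tiny_matrix, tmp_path):
        vp, mp = tmp_path / "e.tsv", tmp_path / "m.tsv"
        tiny_matrix.to_tsv(vp, mp)
        meta = pd.read_csv(mp, sep="\t")
        meta[meta.sample_id != "s3"].to_csv(mp, sep="\t", index=False)
        with pytest.raises(ValueError, match="s3"):
            ingest.read_expression(vp, mp)

    def test_duplicate_gene_keeps_highest_mean(self, tmp_path):
        # GA appears twice, with means 2.0 and 5.0; the 5.0 row wins
        vp = tmp_path / "e.tsv"
        vp.write_text(
            "gene\ts1\ts2\n"
            "GA\t1.0\t3.0\n"
            "GA\t4.0\t6.0\n"
            "GB\t2.0\t2.0\n"
        )
        mp = tmp_path / "m.tsv"
        make_meta(["s1", "s2"]).rename_axis("sample_id").to_csv(mp, sep="\t")
        m = ingest.read_expression(vp, mp)
        assert m.shape == (2, 2)
        assert m.values.loc["GA"].tolist() == [4.0, 6.0]

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        vp = tmp_path / "e.tsv"
        vp.write_text("gene\ts1\ts2\nGA\t1.0\toops\n")
        mp = tmp_path / "m.tsv"
        make_meta(["s1", "s2"]).rename_axis("sample_id").to_csv(mp, sep="\t")
        with pytest.raises(ValueError, match="GA.*s2"):
            ingest.read_expression(vp, mp)


class TestBrainFilter:
    def test_constant_gene_removed_by_cv(self, tiny_matrix):
        kept, removed = ingest.filter_brain_expressed(tiny_matrix)
        assert "GB" in removed and "CV" in removed["GB"]

    def test_all_zero_gene_removed_by_both(self, tiny_matrix):
        kept, removed = ingest.filter_brain_expressed(tiny_matrix)
        assert "GC" in removed
        assert "log2" in removed["GC"] and "CV" in removed["GC"]

    def test_varying_gene_retained(self, tiny_matrix):
        # GA = (1,2,4,8): population sd/mean = 2.6810.../3.75 = 0.715 >= 0.07
        # and max log2(8+1) = 3.17 >= 0.4
        vals = np.array([1.0, 2.0, 4.0, 8.0])
        cv = vals.std() / vals.mean()
        assert cv == pytest.approx(0.71495, abs=1e-4)
        kept, removed = ingest.filter_brain_expressed(tiny_matrix)
        assert kept.genes == ["GA"]

    def test_and_logic_keeps_constant_expressed_gene(self, tiny_matrix):
        # GB is constant at 10 (low CV) but clearly expressed, so the AND
        # reading retains it
        p = ExpressionFilterParams(filter_logic="and")
        kept, removed = ingest.filter_brain_expressed(tiny_matrix, p)
        assert "GB" in kept.genes and "GC" in removed

    def test_sample_order_invariance(self, small_bundle):
        m = small_bundle.expression
        kept1, _ = ingest.filter_brain_expressed(m)
        perm = list(reversed(m.samples))
        m2 = ExpressionMatrix(m.values[perm], m.meta)
        kept2, _ = ingest.filter_brain_expressed(m2)
        assert set(kept1.genes) == set(kept2.genes)

    def test_empty_matrix_is_error(self):
        m = ExpressionMatrix(pd.DataFrame(index=[], columns=[]),
                             pd.DataFrame(columns=["stage", "structure"]))
        with pytest.raises(ValueError):
            ingest.filter_brain_expressed(m)


class TestReadInteractions:
    TAB2_HEADER = ("Official Symbol Interactor A\tOfficial Symbol Interactor B"
                   "\tExperimental System Type")

    def test_physical_rows_kept(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        rows = ["a1\tb1\tphysical", "a2\tb2\tgenetic", "a3\tb3\tphysical",
                "a4\tb4\tgenetic", "a5\tb5\tphysical"]
        path.write_text(self.TAB2_HEADER + "\n" + "\n".join(rows) + "\n")
        t = ingest.read_interactions(path)
        assert len(t) == 3
        assert set(t.gene_a) == {"A1", "A3", "A5"}  # symbols normalized

    def test_header_driven_column_order(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text(
            "Experimental System Type\tOfficial Symbol Interactor B\t"
            "Official Symbol Interactor A\n"
            "physical\tB1\tA1\nphysical\tB2\tA2\ngenetic\tB3\tA3\nphysical\tB4\tA4\n"
        )
        t = ingest.read_interactions(path)
        assert len(t) == 3
        assert list(t.gene_a) == ["A1", "A2", "A4"]

    def test_minimal_dialect(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("gene_a\tgene_b\tsystem_type\nA\tB\tphysical\n")
        assert len(ingest.read_interactions(path)) == 1

    def test_empty_data_section(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text(self.TAB2_HEADER + "\n")
        assert len(ingest.read_interactions(path)) == 0

    def test_missing_columns_lists_expected(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("foo\tbar\nA\tB\n")
        with pytest.raises(ValueError, match="Official Symbol Interactor A"):
            ingest.read_interactions(path)


class TestBrainInteractome:
    def test_cleaning(self):
        t = pd.DataFrame({"gene_a": ["A", "B", "A", "A"],
                          "gene_b": ["B", "A", "A", "C"],
                          "system_type": ["physical"] * 4})
        g = ingest.build_brain_interactome(t, {"A", "B"})
        assert set(map(frozenset, g.edges)) == {frozenset("AB")}

    def test_disjoint_brain_genes(self):
        t = pd.DataFrame({"gene_a": ["A"], "gene_b": ["B"],
                          "system_type": ["physical"]})
        g = ingest.build_brain_interactome(t, {"X", "Y"})
        assert g.number_of_edges() == 0

    def test_random_pairs_match_set_oracle(self):
        rng = np.random.default_rng(11)
        genes = [f"G{i}" for i in range(20)]
        a = rng.choice(genes, 100)
        b = rng.choice(genes, 100)
        t = pd.DataFrame({"gene_a": a, "gene_b": b, "system_type": ["physical"] * 100})
        g = ingest.build_brain_interactome(t, set(genes))
        oracle = {frozenset((x, y)) for x, y in zip(a, b) if x != y}
        assert set(map(frozenset, g.edges)) == oracle

    def test_simple_graph_invariant(self, small_bundle):
        phys = small_bundle.interactions.query("system_type == 'physical'")
        g = ingest.build_brain_interactome(phys, set(small_bundle.expression.genes))
        assert not any(a == b for a, b in g.edges)
        # unordered uniqueness is structural in nx.Graph; check counts
        assert g.number_of_edges() == len({frozenset(e) for e in g.edges})


class TestQueryGenes:
    def test_23_minus_2_exclusions_gives_21(self, tmp_path):
        genes = [f"LOCUS{i:02d}" for i in range(23)]
        path = tmp_path / "q.txt"
        path.write_text("# locus list\n" + "\n".join(genes) + "\n")
        q = ingest.load_query_genes(
            path,
            exclusions=[("LOCUS00", "not expressed"), ("LOCUS01", "not expressed")],
            brain_genes=set(genes),
        )
        assert len(q.genes) == 21
        assert q.excluded == {"LOCUS00": "not expressed", "LOCUS01": "not expressed"}

    def test_repeated_gene_counts_once(self, tmp_path):
        path = tmp_path / "q.txt"
        path.write_text("GA\nGA\nGB\n")
        q = ingest.load_query_genes(path, brain_genes={"GA", "GB"})
        assert q.genes == {"GA", "GB"}

    def test_exclusion_not_in_list_is_noop(self, tmp_path):
        path = tmp_path / "q.txt"
        path.write_text("GA\n")
        q = ingest.load_query_genes(path, exclusions=[("GZ", "whatever")],
                                    brain_genes={"GA"})
        assert q.genes == {"GA"} and q.excluded == {}

    def test_non_brain_genes_recorded(self, tmp_path):
        path = tmp_path / "q.txt"
        path.write_text("GA\nGB\n")
        q = ingest.load_query_genes(path, brain_genes={"GA"})
        assert q.excluded == {"GB": "not brain-expressed"}

    def test_empty_result_is_error(self, tmp_path):
        path = tmp_path / "q.txt"
        path.write_text("GA\n")
        with pytest.raises(ValueError):
            ingest.load_query_genes(path, brain_genes={"GZ"})
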