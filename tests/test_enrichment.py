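import math

import numpy as np
import pandas as pd
import pytest

from xplat.enrichment import (
    enrich,
    fe_concordance,
    fold_enrichment,
    gostag_cluster,
    gostag_pmatrix,
    load_benchmark_enrichment,
)
from xplat.ontology import GoDag


def chain_dag(n=5, genes=None):
    terms = {f"T{i}": f"term {i}" for i in range(1, n + 1)}
    edges = [(f"T{i}", f"T{i - 1}") for i in range(2, n + 1)]
    return GoDag(terms, edges, genes or {})


class TestFoldEnrichment:
    @pytest.mark.parametrize("count,list_total,pop_hits,expected", [
        (119, 4976, 270, 1.55),   # widely shared hepatic stress category
        (6, 1111, 8, 11.84),      # small targeted-panel category
    ])
    def test_published_examples(self, count, list_total, pop_hits, expected):
        fe = fold_enrichment(count, list_total, pop_hits, 17535)
        assert round(fe, 2) == expected

    def test_zero_count_gives_zero(self):
        assert fold_enrichment(0, 100, 10, 1000) == 0.0

    def test_invalid_totals_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(1, 0, 1, 10)


class TestEnrich:
    def _dag(self):
        # two-leaf DAG under a root; universe of 20 genes
        terms = {"R": "root", "A": "leaf a", "B": "leaf b"}
        edges = [("A", "R"), ("B", "R")]
        ann = {"A": {f"g{i}" for i in range(8)},
               "B": {f"g{i}" for i in range(8, 20)}}
        return GoDag(terms, edges, ann)

    def test_counts_fe_and_up_propagation(self):
        dag = self._dag()
        table = enrich([f"g{i}" for i in range(6)], dag, min_genes=1)
        rows = table.set_index("term_id")
        assert rows.loc["A", "count"] == 6
        assert rows.loc["A", "pop_hits"] == 8
        # root inherits every annotated gene exactly once
        assert rows.loc["R", "count"] == 6
        assert rows.loc["R", "pop_hits"] == 20
        assert rows.loc["R", "fold_enrichment"] == pytest.approx(1.0)
        assert rows.loc["A", "fold_enrichment"] == pytest.approx((6 / 6) / (8 / 20))

    def test_min_genes_excludes_sparse_terms(self):
        dag = self._dag()
        table = enrich([f"g{i}" for i in range(6)] + ["g8"], dag, min_genes=5)
        assert "B" not in set(table["term_id"])  # only 1 list hit

    def test_hypergeometric_matches_exact_tail_sum(self):
        dag = self._dag()
        table = enrich([f"g{i}" for i in range(6)], dag, min_genes=1)
        row = table.set_index("term_id").loc["A"]
        # brute-force tail: P(X >= 6) with universe 20, 8 successes, 6 draws
        def hyper_pmf(k, n, K, m):
            return math.comb(K, k) * math.comb(n - K, m - k) / math.comb(n, m)
        expected = sum(hyper_pmf(k, 20, 8, 6) for k in range(6, 7))
        assert row["p"] == pytest.approx(expected, rel=1e-12)

    def test_outside_genes_dropped_with_warning(self):
        dag = self._dag()
        with pytest.warns(UserWarning, match="outside the annotated universe"):
            table = enrich(["g0", "g1", "g2", "g3", "g4", "alien"], dag, min_genes=1)
        assert table["list_total"].iloc[0] == 5

    def test_empty_annotated_list_rejected(self):
        with pytest.raises(ValueError, match="no query genes"):
            enrich(["alien"], self._dag(), min_genes=1)


class TestFeConcordance:
    def test_identical_tables_correlate_perfectly(self):
        t = pd.DataFrame({"term_id": list("abcde"),
                          "fold_enrichment": [1.0, 2.0, 3.0, 4.0, 5.0]})
        r = fe_concordance({"x": t, "y": t.copy()}, q_max=None)
        assert r[("x", "y")] == pytest.approx(1.0)

    def test_anti_ordered_tables_correlate_negatively(self):
        a = pd.DataFrame({"term_id": list("abcde"),
                          "fold_enrichment": [1.0, 2.0, 3.0, 4.0, 5.0]})
        b = pd.DataFrame({"term_id": list("abcde"),
                          "fold_enrichment": [5.0, 4.0, 3.0, 2.0, 1.0]})
        r = fe_concordance({"x": a, "y": b}, q_max=None)
        assert r[("x", "y")] < 0

    def test_too_few_shared_terms_rejected(self):
        a = pd.DataFrame({"term_id": ["a"], "fold_enrichment": [1.0]})
        with pytest.raises(ValueError, match="<3"):
            fe_concordance({"x": a, "y": a.copy()}, q_max=None)


class TestGoStag:
    def test_pmatrix_imputes_exact_zero(self):
        a = pd.DataFrame({"term_id": ["t1", "t2"], "p": [1e-6, 1e-4],
                          "q": [0.001, 0.01], "fold_enrichment": [2, 2]})
        b = pd.DataFrame({"term_id": ["t1"], "p": [1e-3],
                          "q": [0.02], "fold_enrichment": [2]})
        pmat = gostag_pmatrix({"A": a, "B": b})
        assert pmat.loc["t2", "B"] == 0.0
        assert pmat.loc["t1", "A"] == pytest.approx(6.0)

    def _planted_pmatrix(self, rng, n_per_block=6):
        base1 = np.array([8.0, 1.0, 0.5])
        base2 = np.array([0.5, 1.0, 8.0])
        rows, names = [], []
        for i in range(n_per_block):
            rows.append(base1 + rng.normal(0, 0.05, 3))
            names.append(f"T{i + 1}")
        for i in range(n_per_block):
            rows.append(base2 + rng.normal(0, 0.05, 3))
            names.append(f"T{n_per_block + i + 1}")
        return pd.DataFrame(rows, index=names, columns=["a", "b", "c"])

    def test_two_planted_blocks_give_two_clusters(self):
        rng = np.random.default_rng(0)
        pmat = self._planted_pmatrix(rng)
        dag = chain_dag(12)
        res = gostag_cluster(pmat, dag, min_terms=5)
        assert len(res.clusters) == 2
        sizes = sorted(len(c["terms"]) for c in res.clusters)
        assert sizes == [6, 6]

    def test_small_clusters_discarded(self):
        rng = np.random.default_rng(1)
        pmat = self._planted_pmatrix(rng, n_per_block=4)  # blocks below min_terms
        res = gostag_cluster(pmat, chain_dag(8), min_terms=5)
        assert res.clusters == []

    def test_chain_cluster_labeled_by_deepest_term(self):
        # 5-node is_a chain T5 -> ... -> T1; hand DP: the deepest node has the
        # most rootward paths (4), so it labels the cluster
        rng = np.random.default_rng(2)
        profiles = np.tile([5.0, 1.0, 0.2], (5, 1)) + rng.normal(0, 0.01, (5, 3))
        pmat = pd.DataFrame(profiles, index=[f"T{i}" for i in range(1, 6)],
                            columns=["a", "b", "c"])
        res = gostag_cluster(pmat, chain_dag(5), min_terms=5)
        assert len(res.clusters) == 1
        assert res.clusters[0]["label_term"] == "T5"

    def test_constant_rows_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        pmat = self._planted_pmatrix(rng)
        pmat.loc["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant term profiles"):
            res = gostag_cluster(pmat, chain_dag(13), min_terms=5)
        for c in res.clusters:
            assert "flat" not in c["terms"]


class TestBenchmarkTable:
    def test_loads_49_terms_per_platform(self):
        tables = load_benchmark_enrichment()
        assert set(tables) == {"microarray", "rnaseq", "temposeq"}
        for t in tables.values():
            assert len(t) == 49
            assert (t["universe"] == 17535).all()
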