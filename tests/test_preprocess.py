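import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xplat.core import ExpressionMatrix, IdMap, StudyDesign
from xplat.preprocess import (
    MagicIndexInput,
    cpm_log2,
    filter_low_count_genes,
    log2_ratio,
    magic_index,
    magic_index_matrix,
    merge_platforms_by_cluster_id,
)


def counts_matrix(values, genes=None, samples=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values, "counts")


class TestLowCountFilter:
    def test_boundary_at_threshold(self):
        m = counts_matrix([[214, 0], [215, 0]])
        out = filter_low_count_genes(m, 214)
        assert out.gene_ids == ["g1"]

    def test_all_zero_removes_everything_with_warning(self):
        with pytest.warns(UserWarning, match="no genes survive"):
            out = filter_low_count_genes(counts_matrix([[0, 0], [0, 0]]))
        assert out.n_genes == 0

    def test_threshold_zero_keeps_positive_matrix(self):
        m = counts_matrix([[1, 2], [3, 4]])
        out = filter_low_count_genes(m, 0)
        assert out.gene_ids == m.gene_ids
        assert np.array_equal(out.values, m.values)


class TestCpmLog2:
    def test_zero_count_maps_to_zero(self):
        m = counts_matrix([[0], [10]])
        out = cpm_log2(m)
        assert out.values[0, 0] == 0.0

    def test_hand_value(self):
        col = np.zeros((2, 1), dtype=int)
        col[0, 0] = 100
        col[1, 0] = 1_000_000 - 100
        out = cpm_log2(counts_matrix(col))
        assert out.values[0, 0] == pytest.approx(np.log2(101), abs=1e-12)

    def test_cpm_recovered_exactly(self):
        rng = np.random.default_rng(0)
        m = counts_matrix(rng.integers(0, 500, (20, 4)))
        out = cpm_log2(m)
        cpm = np.exp2(out.values) - 1.0
        assert np.allclose(cpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_total_sample_named(self):
        m = counts_matrix([[0, 1], [0, 2]], samples=["empty", "ok"])
        with pytest.raises(ValueError, match="empty"):
            cpm_log2(m)


class TestMagicIndex:
    def test_low_count_imputed(self):
        assert magic_index(MagicIndexInput(2, 1e8, 1000)) == 5.0
        assert magic_index(MagicIndexInput(0, 10, 10)) == 5.0

    def test_zero_z_limit(self):
        assert magic_index(MagicIndexInput(0, 1e8, 1000), impute=False) == pytest.approx(0.0)

    def test_hand_value(self):
        # Z = (1e12/2) * 1000 / (1e8 * 1000) = 5000
        val = magic_index(MagicIndexInput(1000, 1e8, 1000))
        expected = np.log2(5000 + np.sqrt(4 + 5000**2)) - 1
        assert val == pytest.approx(expected, abs=1e-12)
        assert val == pytest.approx(12.288, abs=1e-3)

    @given(st.integers(3, 10_000), st.integers(3, 10_000))
    def test_strictly_increasing_in_reads(self, n1, n2):
        if n1 == n2:
            return
        lo, hi = sorted((n1, n2))
        assert magic_index(MagicIndexInput(lo, 1e7, 500)) < magic_index(MagicIndexInput(hi, 1e7, 500))

    @given(st.integers(100, 100_000), st.integers(100, 100_000))
    def test_strictly_decreasing_in_length(self, l1, l2):
        if l1 == l2:
            return
        lo, hi = sorted((l1, l2))
        assert magic_index(MagicIndexInput(50, 1e7, hi)) < magic_index(MagicIndexInput(50, 1e7, lo))

    def test_matrix_form_matches_scalar(self):
        rng = np.random.default_rng(1)
        counts = counts_matrix(rng.integers(0, 2000, (10, 3)))
        lengths = pd.Series(rng.integers(300, 3000, 10), index=counts.gene_ids)
        out = magic_index_matrix(counts, lengths)
        depth = counts.values.sum(axis=0)
        for i in range(10):
            for j in range(3):
                expected = magic_index(MagicIndexInput(
                    int(counts.values[i, j]), float(depth[j]), float(lengths.iloc[i])))
                assert out.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            MagicIndexInput(-1, 10, 10)
        with pytest.raises(ValueError):
            MagicIndexInput(1, 0, 10)
        with pytest.raises(ValueError):
            MagicIndexInput(1, 10, 0)


class TestLog2Ratio:
    def test_hand_values_and_control_columns_dropped(self):
        table = pd.DataFrame([
            {"sample_id": "t1", "chemical": "X", "moa": "AhR", "route_class": "r",
             "replicate": 1, "is_control": False, "control_match_group": "r"},
            {"sample_id": "c1", "chemical": "VEH", "moa": "Control", "route_class": "r",
             "replicate": 1, "is_control": True, "control_match_group": "r"},
            {"sample_id": "c2", "chemical": "VEH", "moa": "Control", "route_class": "r",
             "replicate": 2, "is_control": True, "control_match_group": "r"},
        ])
        d = StudyDesign(table)
        m = ExpressionMatrix(["g"], ["t1", "c1", "c2"],
                             np.array([[5.0, 2.0, 4.0]]), "log2norm")
        out = log2_ratio(m, d)
        assert out.sample_ids == ["t1"]
        assert out.values[0, 0] == pytest.approx(2.0)

    def test_canonical_design_yields_45_columns(self, design):
        rng = np.random.default_rng(0)
        m = ExpressionMatrix([f"g{i}" for i in range(10)], design.sample_ids,
                             rng.normal(8, 1, (10, 63)), "log2norm")
        out = log2_ratio(m, design)
        assert out.n_samples == 45
        assert out.scale == "log2ratio"

    def test_self_control_is_zero(self):
        # each treated sample doubles as its own single-member control group
        rows = []
        for i in range(3):
            rows.append({"sample_id": f"t{i}", "chemical": "X", "moa": "AhR",
                         "route_class": "r", "replicate": i + 1, "is_control": False,
                         "control_match_group": f"grp{i}"})
            rows.append({"sample_id": f"c{i}", "chemical": "VEH", "moa": "Control",
                         "route_class": "r", "replicate": i + 1, "is_control": True,
                         "control_match_group": f"grp{i}"})
        d = StudyDesign(pd.DataFrame(rows))
        vals = np.arange(6, dtype=float).reshape(1, 6)
        # make control value equal to its treated partner
        m = ExpressionMatrix(["g"], [r["sample_id"] for r in rows],
                             np.array([[1.0, 1.0, 2.0, 2.0, 3.0, 3.0]]), "log2norm")
        out = log2_ratio(m, d)
        assert np.allclose(out.values, 0.0)


class TestMergePlatforms:
    def _ratio(self, genes, values, samples, label):
        return ExpressionMatrix(genes, samples, np.asarray(values, dtype=float),
                                "log2ratio", label)

    def test_rows_sharing_cluster_id_averaged(self):
        a = self._ratio(["p1", "p2"], [[1.0], [3.0]], ["s1"], "A")
        b = self._ratio(["q1"], [[5.0]], ["s1"], "B")
        idmap = IdMap({"A": {"p1": "u1", "p2": "u1"}, "B": {"q1": "u1"}})
        out = merge_platforms_by_cluster_id([a, b], idmap)
        assert out.gene_ids == ["u1"]
        assert out.sample_ids == ["s1|A", "s1|B"]
        assert np.allclose(out.values, [[2.0, 5.0]])

    def test_disjoint_id_spaces_error(self):
        a = self._ratio(["p1"], [[1.0]], ["s1"], "A")
        b = self._ratio(["q1"], [[2.0]], ["s1"], "B")
        idmap = IdMap({"A": {"p1": "u1"}, "B": {"q1": "u2"}})
        with pytest.raises(ValueError, match="empty intersection"):
            merge_platforms_by_cluster_id([a, b], idmap)

    def test_bundle_intersection_is_temposeq_panel(self, design):
        from xplat.simulate import default_truth, make_three_platform_bundle
        from xplat.preprocess import cpm_log2, filter_low_count_genes, magic_index_matrix
        t = default_truth(200, seed=6, de_fraction=0.0)
        b = make_three_platform_bundle(t, n_genes=200, temposeq_panel_size=80,
                                       temposeq_near_zero=8)
        ts_norm = cpm_log2(filter_low_count_genes(b.temposeq_counts, 214))
        rs_norm = magic_index_matrix(b.rnaseq_counts, b.rnaseq_lengths)
        ratios = [log2_ratio(m, b.design) for m in (b.microarray, rs_norm, ts_norm)]
        merged = merge_platforms_by_cluster_id(
            ratios, b.id_map, platforms=["microarray", "rnaseq", "temposeq"])
        surviving = {b.id_map.for_platform("temposeq")[g] for g in ts_norm.gene_ids}
        assert set(merged.gene_ids) == surviving
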