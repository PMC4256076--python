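import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dyver.dataset_io import (
    ExpressionDataset,
    GenotypeMatrix,
    read_expression_table,
    read_genotype_table,
    split_by_allele,
    stabilize_variance,
    write_genotype_table,
)


def _write_geno(tmp_path, rows, header="\tV1\tV2"):
    path = tmp_path / "geno.tsv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


class TestReadGenotype:
    def test_two_symbol_parse_and_mapping(self, tmp_path):
        path = _write_geno(
            tmp_path, ["s1\tBY\tRM", "s2\tRM\tRM", "s3\tBY\tBY"]
        )
        geno = read_genotype_table(path)
        assert geno.strain_ids == ["s1", "s2", "s3"]
        assert geno.variant_ids == ["V1", "V2"]
        assert geno.allele_labels == ("BY", "RM")
        np.testing.assert_array_equal(geno.codes, [[0, 1], [1, 1], [0, 0]])

    def test_non_biallelic_column_names_variant(self, tmp_path):
        path = _write_geno(
            tmp_path, ["s1\tBY\tBY", "s2\tRM\tRM", "s3\tBY\tXX"]
        )
        with pytest.raises(ValueError, match="V2"):
            read_genotype_table(path)

    def test_heterozygous_code_rejected(self, tmp_path):
        path = _write_geno(tmp_path, ["s1\tBY\tH", "s2\tRM\tRM", "s3\tBY\tBY"])
        with pytest.raises(ValueError, match="[Hh]eterozygous"):
            read_genotype_table(path)

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        geno = GenotypeMatrix(
            [f"s{i}" for i in range(6)],
            [f"v{k}" for k in range(5)],
            rng.integers(0, 2, (6, 5), dtype=np.uint8),
            allele_labels=("BY", "RM"),
        )
        out = tmp_path / "rt.tsv"
        write_genotype_table(geno, out)
        back = read_genotype_table(out)
        assert back.strain_ids == geno.strain_ids
        assert back.variant_ids == geno.variant_ids
        np.testing.assert_array_equal(back.codes, geno.codes)


class TestReadExpression:
    def test_long_layout_missing_entry(self, tmp_path):
        rows = ["gene\tstrain\ttime_min\tlog_expr"]
        for g in ("g1", "g2"):
            for s in ("a", "b", "c", "d"):
                for t in (0, 10, 20):
                    if (g, s, t) == ("g1", "b", 10):
                        continue
                    rows.append(f"{g}\t{s}\t{t}\t1.5")
        path = tmp_path / "expr.tsv"
        path.write_text("\n".join(rows) + "\n")
        ds = read_expression_table(path, layout="long")
        assert ds.values.shape == (2, 4, 3)
        assert (~ds.observed_mask).sum() == 1
        assert not ds.observed_mask[0, 1, 1]

    def test_duplicate_record_rejected(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text(
            "gene\tstrain\ttime_min\tlog_expr\n"
            "g1\ta\t0\t1.0\ng1\ta\t0\t2.0\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_expression_table(path, layout="long")

    def test_wide_layout_differing_strain_sets(self, tmp_path):
        # strain populations may differ between time points; the mask
        # reflects per-time availability
        p0 = tmp_path / "t0.tsv"
        p0.write_text("gene\ta\tb\ng1\t1.0\t2.0\n")
        p1 = tmp_path / "t10.tsv"
        p1.write_text("gene\tb\tc\ng1\t3.0\t4.0\n")
        ds = read_expression_table({0: p0, 10: p1}, layout="wide")
        assert ds.strain_ids == ["a", "b", "c"]
        mask = ds.observed_mask[0]
        np.testing.assert_array_equal(
            mask, [[True, False], [True, True], [False, True]]
        )

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError, match="no genes"):
            ExpressionDataset([], ["a"], [0.0], np.empty((0, 1, 1)))


def _panel(rng, n=50, k=3, T=4, G=2):
    geno = GenotypeMatrix(
        [f"s{i}" for i in range(n)],
        [f"v{j}" for j in range(k)],
        rng.integers(0, 2, (n, k), dtype=np.uint8),
    )
    ds = ExpressionDataset(
        [f"g{j}" for j in range(G)],
        list(geno.strain_ids),
        10.0 * np.arange(T),
        rng.normal(0, 2.0, (G, n, T)) + rng.normal(0, 1, (G, 1, T)),
    )
    return ds, geno


class TestStabilizeVariance:
    def test_closed_form_rescale(self):
        # group {0, 2, 4}: mean 2, sd 2 -> {1, 2, 3} at target variance 1
        geno = GenotypeMatrix(
            ["a", "b", "c", "d", "e"], ["v"],
            np.array([[0], [0], [0], [1], [1]], dtype=np.uint8),
        )
        vals = np.array([[[0.0], [2.0], [4.0], [5.0], [7.0]]])
        ds = ExpressionDataset(["g"], list(geno.strain_ids), [0.0], vals)
        out = stabilize_variance(ds, geno, "v", target_variance=1.0)
        np.testing.assert_allclose(out.values[0, :3, 0], [1.0, 2.0, 3.0])

    def test_unit_variance_group_unchanged(self, rng):
        ds, geno = _panel(rng, n=10, k=1, T=2, G=1)
        once = stabilize_variance(ds, geno, "v0", target_variance=1.0)
        again = stabilize_variance(once, geno, "v0", target_variance=1.0)
        np.testing.assert_allclose(once.values, again.values, atol=1e-10)

    def test_every_cell_variance_and_mean(self, rng):
        ds, geno = _panel(rng, n=50, k=2, T=5, G=3)
        out = stabilize_variance(ds, geno, "v1")
        groups = split_by_allele(geno, "v1")
        for g in range(ds.n_genes):
            cells = []
            for idx in (groups.group_a, groups.group_b):
                for t in range(ds.n_times):
                    cells.append(np.var(out.values[g, idx, t], ddof=1))
                    np.testing.assert_allclose(
                        out.values[g, idx, t].mean(),
                        ds.values[g, idx, t].mean(),
                        atol=1e-10,
                    )
            # default target: all cells share the gene's average variance
            np.testing.assert_allclose(cells, cells[0], atol=1e-9)

    def test_idempotent(self, rng):
        ds, geno = _panel(rng, n=30, k=1, T=3, G=2)
        once = stabilize_variance(ds, geno, "v0")
        twice = stabilize_variance(once, geno, "v0")
        np.testing.assert_allclose(once.values, twice.values, atol=1e-10)

    def test_zero_variance_group_warns_and_passes_through(self):
        geno = GenotypeMatrix(
            ["a", "b", "c", "d"], ["v"],
            np.array([[0], [0], [1], [1]], dtype=np.uint8),
        )
        vals = np.array([[[1.0], [1.0], [0.0], [2.0]]])
        ds = ExpressionDataset(["g"], list(geno.strain_ids), [0.0], vals)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            out = stabilize_variance(ds, geno, "v")
        np.testing.assert_allclose(out.values[0, :2, 0], [1.0, 1.0])


class TestSplitByAllele:
    def test_basic_partition(self):
        geno = GenotypeMatrix(
            ["a", "b", "c", "d"], ["v"],
            np.array([[0], [0], [1], [1]], dtype=np.uint8),
        )
        gr = split_by_allele(geno, "v")
        assert gr.testable
        assert gr.n_a == 2 and gr.n_b == 2

    def test_monomorphic_flagged_untestable(self):
        geno = GenotypeMatrix(
            ["a", "b"], ["v"], np.zeros((2, 1), dtype=np.uint8)
        )
        assert not split_by_allele(geno, "v").testable

    def test_partition_exhaustive_all_variants(self, rng):
        n, k = 40, 100
        geno = GenotypeMatrix(
            [f"s{i}" for i in range(n)],
            [f"v{j}" for j in range(k)],
            rng.integers(0, 2, (n, k), dtype=np.uint8),
        )
        for v in geno.variant_ids:
            gr = split_by_allele(geno, v)
            assert gr.n_a + gr.n_b == n
            assert len(np.union1d(gr.group_a, gr.group_b)) == n

    @given(st.randoms(use_true_random=False))
    def test_partition_invariant_to_strain_order(self, rnd):
        base = ["a", "b", "c", "d", "e"]
        codes = np.array([0, 1, 0, 1, 1], dtype=np.uint8)
        order = list(range(5))
        rnd.shuffle(order)
        geno = GenotypeMatrix(
            [base[i] for i in order], ["v"], codes[order][:, None]
        )
        gr = split_by_allele(geno, "v")
        names_a = {geno.strain_ids[i] for i in gr.group_a}
        assert names_a == {"a", "c"}
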