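import numpy as np
import pandas as pd
import pytest

from holodev.expression_io import (
    ExpressionMatrix,
    log_transform,
    qc_filter,
    read_expression_matrix,
    stage_average,
    write_expression_matrix,
)

from conftest import make_samples


def write_tsv(tmp_path, text, name="m.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadExpressionMatrix:
    def test_round_trip_preserves_ids_and_values(self, tmp_path):
        text = (
            "gene_id\ts1\ts2\ts3\ts4\n"
            "g1\t1\t2\t3\t4\n"
            "g2\t0\t0.5\t1.5\t2\n"
            "g3\t5\t5\t5\t5\n"
        )
        m = read_expression_matrix(write_tsv(tmp_path, text))
        assert m.shape == (3, 4)
        assert m.gene_ids == ["g1", "g2", "g3"]
        assert m.sample_ids == ["s1", "s2", "s3", "s4"]
        assert m.scale == "fpkm"
        out = tmp_path / "copy.tsv"
        write_expression_matrix(m, out)
        m2 = read_expression_matrix(out)
        pd.testing.assert_frame_equal(m.data, m2.data)
        # and the written text round-trips bit-identically
        out2 = tmp_path / "copy2.tsv"
        write_expression_matrix(m2, out2)
        assert out.read_text() == out2.read_text()

    def test_duplicate_gene_id_names_the_duplicate(self, tmp_path):
        text = "gene_id\ts1\ts2\ts3\ng1\t1\t2\t3\ng1\t4\t5\t6\n"
        with pytest.raises(ValueError, match="g1"):
            read_expression_matrix(write_tsv(tmp_path, text))

    def test_negative_cell_cites_coordinates(self, tmp_path):
        text = "gene_id\ts1\ts2\ng1\t1\t2\ng2\t-2.0\t3\n"
        with pytest.raises(ValueError, match="g2.*s1"):
            read_expression_matrix(write_tsv(tmp_path, text))

    def test_non_numeric_cell_cites_coordinates(self, tmp_path):
        text = "gene_id\ts1\ts2\ng1\t1\tabc\n"
        with pytest.raises(ValueError, match="abc.*g1.*s2"):
            read_expression_matrix(write_tsv(tmp_path, text))


class TestQcFilter:
    def _matrix(self, columns, values):
        return ExpressionMatrix(
            pd.DataFrame(values, index=["g1", "g2", "g3"], columns=columns)
        )

    def test_duplicate_columns_keep_first(self):
        samples = make_samples({"embryo": 1, "larva": 1, "pupa": 2, "adult": 1})
        cols = ["embryo_1", "larva_1", "pupa_1", "pupa_2", "adult_1"]
        vals = np.array(
            [[1, 2, 3, 3, 4], [5, 6, 7, 7, 8], [0, 1, 2, 2, 3]], dtype=float
        )
        filtered, report = qc_filter(self._matrix(cols, vals), samples)
        assert filtered.sample_ids == ["embryo_1", "larva_1", "pupa_1", "adult_1"]
        assert report.removed == [("pupa_2", "duplicate of pupa_1")]

    def test_no_females_is_a_noop(self):
        samples = make_samples({"embryo": 1, "larva": 1, "pupa": 1, "adult": 1})
        cols = ["embryo_1", "larva_1", "pupa_1", "adult_1"]
        vals = np.arange(12, dtype=float).reshape(3, 4)
        filtered, report = qc_filter(
            self._matrix(cols, vals), samples, exclude_females=True
        )
        assert filtered.sample_ids == cols
        assert report.removed == []

    def test_removing_only_embryo_sample_is_an_error(self):
        samples = make_samples(
            {"embryo": 1, "larva": 1, "pupa": 1, "adult": 1},
            sexes={"embryo_1": "female"},
        )
        cols = ["embryo_1", "larva_1", "pupa_1", "adult_1"]
        vals = np.arange(12, dtype=float).reshape(3, 4)
        with pytest.raises(ValueError, match="embryo"):
            qc_filter(self._matrix(cols, vals), samples, exclude_females=True)

    def test_mixed_and_unknown_sex_are_retained(self):
        samples = make_samples(
            {"embryo": 1, "larva": 1, "pupa": 1, "adult": 2},
            sexes={"adult_1": "female", "adult_2": "unknown"},
        )
        cols = ["embryo_1", "larva_1", "pupa_1", "adult_1", "adult_2"]
        vals = np.arange(15, dtype=float).reshape(3, 5)
        filtered, report = qc_filter(self._matrix(cols, vals), samples)
        assert "adult_2" in filtered.sample_ids
        assert report.removed == [("adult_1", "female")]

    def test_idempotent(self):
        samples = make_samples(
            {"embryo": 2, "larva": 1, "pupa": 2, "adult": 2},
            sexes={"adult_2": "female"},
        )
        cols = [s for s in samples.data["sample_id"]]
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 10, size=(3, len(cols)))
        vals[:, 3] = vals[:, 2]  # duplicate pupa pair
        m = self._matrix(cols, vals)
        once, _ = qc_filter(m, samples)
        twice, report2 = qc_filter(once, samples)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert report2.removed == []


class TestLogTransform:
    @pytest.mark.parametrize("v,expected", [(0.0, 0.0), (1.0, 1.0), (3.0, 2.0)])
    def test_log2_with_unit_pseudocount(self, v, expected):
        m = ExpressionMatrix(
            pd.DataFrame([[v, v, v]], index=["g"], columns=["a", "b", "c"])
        )
        out = log_transform(m, pseudocount=1.0, base=2)
        assert out.scale == "log"
        assert out.data.iloc[0, 0] == pytest.approx(expected)

    def test_nonpositive_pseudocount_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="pseudocount"):
            log_transform(small_matrix, pseudocount=0.0)

    def test_requires_fpkm_scale(self, small_matrix):
        logged = log_transform(small_matrix)
        with pytest.raises(ValueError, match="FPKM"):
            log_transform(logged)


class TestStageAverage:
    def test_single_sample_per_stage_is_column_reordering(
        self, small_matrix, small_samples
    ):
        out = stage_average(small_matrix, small_samples)
        assert list(out.data.columns) == ["embryo", "larva", "pupa", "adult"]
        np.testing.assert_allclose(
            out.data.to_numpy(), small_matrix.data.to_numpy()
        )

    def test_two_replicates_arithmetic_mean(self):
        samples = make_samples({"embryo": 2, "larva": 1, "pupa": 1, "adult": 1})
        data = pd.DataFrame(
            [[2.0, 4.0, 1.0, 1.0, 1.0]],
            index=["g1"],
            columns=["embryo_1", "embryo_2", "larva_1", "pupa_1", "adult_1"],
        )
        out = stage_average(ExpressionMatrix(data), samples)
        assert out.data.loc["g1", "embryo"] == pytest.approx(3.0)

    def test_matches_independent_per_stage_loop(self):
        """10x12 fixture: column means equal a brute-force loop over samples."""
        samples = make_samples({"embryo": 3, "larva": 3, "pupa": 3, "adult": 3})
        rng = np.random.default_rng(42)
        cols = list(samples.data["sample_id"])
        m = ExpressionMatrix(
            pd.DataFrame(
                rng.uniform(0, 50, size=(10, 12)),
                index=[f"g{i}" for i in range(10)],
                columns=cols,
            )
        )
        out = stage_average(m, samples)
        for stage in ("embryo", "larva", "pupa", "adult"):
            ids = [c for c in cols if c.startswith(stage)]
            for gene in m.gene_ids:
                expected = sum(m.data.loc[gene, s] for s in ids) / len(ids)
                assert out.data.loc[gene, stage] == pytest.approx(expected)

    def test_missing_stage_named(self, small_matrix):
        samples = make_samples({"embryo": 1, "larva": 1, "pupa": 1, "adult": 1})
        sub = ExpressionMatrix(
            small_matrix.data.rename(
                columns=dict(
                    zip(small_matrix.sample_ids,
                        ["embryo_1", "larva_1", "pupa_1", "extra"])
                )
            )[["embryo_1", "larva_1", "pupa_1"]]
        )
        with pytest.raises(ValueError, match="adult"):
            stage_average(sub, samples)


def test_log_then_average_is_the_pipeline_order():
    """Averaging commutes with log only for one sample per stage; with
    replicates the pipeline's log-then-average differs from average-then-log."""
    samples = make_samples({"embryo": 2, "larva": 1, "pupa": 1, "adult": 1})
    data = pd.DataFrame(
        [[1.0, 7.0, 3.0, 3.0, 3.0]],
        index=["g1"],
        columns=["embryo_1", "embryo_2", "larva_1", "pupa_1", "adult_1"],
    )
    m = ExpressionMatrix(data)
    log_first = stage_average(log_transform(m), samples).data.loc["g1", "embryo"]
    avg_first = np.log2(stage_average(m, samples).data.loc["g1", "embryo"] + 1)
    assert log_first == pytest.approx(np.log2(2) / 2 + np.log2(8) / 2)
    assert log_first != pytest.approx(avg_first)
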