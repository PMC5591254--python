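"""Tests for threshold calibration and soft-evidence conversion."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellpath import calibration as cal
from cellpath.pathway_model import MISSING


class TestReadExpressionMatrix:
    def test_reads_toy_tsv(self, toy_expression_tsv):
        m = cal.read_expression_matrix(toy_expression_tsv)
        assert m.genes == ["g1", "g2", "g3"]
        assert m.samples == ["s1", "s2"]
        assert m.values.at["g2", "s2"] == 5.0

    def test_duplicate_gene_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene\ts1\ng1\t1.0\nG1\t2.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            cal.read_expression_matrix(path)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\ts1\ng1\toops\n")
        with pytest.raises(ValueError, match="non-numeric"):
            cal.read_expression_matrix(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("gene\ts1\n")
        with pytest.raises(ValueError):
            cal.read_expression_matrix(path)

    def test_negative_rpkm_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text("gene\ts1\ng1\t-1.0\n")
        with pytest.raises(ValueError, match="negative"):
            cal.read_expression_matrix(path, scale="rpkm")


class TestLogTransform:
    @pytest.mark.parametrize("rpkm,expected", [(0.0, 0.0), (7.0, 3.0), (15.0, 4.0)])
    def test_log2_with_unit_pseudocount(self, rpkm, expected):
        m = cal.ExpressionMatrix(pd.DataFrame({"s": [rpkm]}, index=["g"]), scale="rpkm")
        out = cal.log_transform(m, pseudocount=1.0)
        assert out.values.at["g", "s"] == pytest.approx(expected)
        assert out.scale == "log2"

    def test_double_transform_rejected(self):
        m = cal.ExpressionMatrix(pd.DataFrame({"s": [1.0]}, index=["g"]), scale="log2")
        with pytest.raises(ValueError, match="already"):
            cal.log_transform(m)


class TestFitThresholds:
    def test_midpoint_of_class_means(self):
        m = cal.ExpressionMatrix(
            pd.DataFrame([[4.0, 6.0, 0.0, 2.0]], index=["g"], columns=["a1", "a2", "i1", "i2"])
        )
        labels = {"a1": "active", "a2": "active", "i1": "inactive", "i2": "inactive"}
        thr = cal.fit_thresholds(m, labels)
        assert thr.thresholds["g"] == pytest.approx(3.0)
        assert bool(thr.direction_ok["g"]) is True

    def test_degenerate_equal_means_flagged(self, caplog):
        m = cal.ExpressionMatrix(pd.DataFrame([[1.0, 1.0]], index=["g"], columns=["a", "i"]))
        with caplog.at_level("WARNING"):
            thr = cal.fit_thresholds(m, {"a": "active", "i": "inactive"})
        assert thr.thresholds["g"] == pytest.approx(1.0)
        assert bool(thr.direction_ok["g"]) is False
        assert any("direction_ok" in r.message for r in caplog.records)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(3, 1, size=(2, 6))
        samples = [f"s{i}" for i in range(6)]
        labels = {s: ("active" if i < 3 else "inactive") for i, s in enumerate(samples)}
        m1 = cal.ExpressionMatrix(pd.DataFrame(vals, index=["g1", "g2"], columns=samples))
        shifted = vals.copy()
        shifted[0] += 2.5
        m2 = cal.ExpressionMatrix(pd.DataFrame(shifted, index=["g1", "g2"], columns=samples))
        t1 = cal.fit_thresholds(m1, labels)
        t2 = cal.fit_thresholds(m2, labels)
        assert t2.thresholds["g1"] == pytest.approx(t1.thresholds["g1"] + 2.5)
        assert t2.thresholds["g2"] == pytest.approx(t1.thresholds["g2"])

    def test_missing_class_rejected(self):
        m = cal.ExpressionMatrix(pd.DataFrame([[1.0]], index=["g"], columns=["a"]))
        with pytest.raises(ValueError, match="inactive"):
            cal.fit_thresholds(m, {"a": "active"})


class TestSoftCall:
    def test_half_at_threshold(self):
        for softness in (0.0, 0.25, 2.0):
            assert cal.soft_call(3.0, 3.0, softness) == 0.5

    def test_hard_call(self):
        assert cal.soft_call(3.1, 3.0, 0.0) == 1.0
        assert cal.soft_call(2.9, 3.0, 0.0) == 0.0

    def test_one_softness_unit_above(self):
        assert cal.soft_call(3.25, 3.0, 0.25) == pytest.approx(1 / (1 + math.exp(-1)))

    def test_negative_softness_rejected(self):
        with pytest.raises(ValueError):
            cal.soft_call(1.0, 0.0, -0.1)

    # domain kept where the logistic does not saturate to 0.0/1.0 in floats
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        x1=st.floats(-5, 5),
        dx=st.floats(0.01, 5),
        softness=st.floats(0.5, 3),
    )
    def test_strictly_increasing_and_bounded(self, x1, dx, softness):
        q1 = cal.soft_call(x1, 0.0, softness)
        q2 = cal.soft_call(x1 + dx, 0.0, softness)
        assert 0.0 < q1 < 1.0
        assert q2 > q1


class TestEvidence:
    def _setup(self):
        m = cal.ExpressionMatrix(
            pd.DataFrame(
                [[5.0, 1.0], [2.0, 6.0]], index=["g1", "g2"], columns=["sA", "sB"]
            )
        )
        thr = cal.ThresholdSet(
            thresholds=pd.Series({"g1": 3.0, "g2": 4.0, "g3": 1.0}),
            direction_ok=pd.Series({"g1": True, "g2": True, "g3": True}),
        )
        return m, thr

    def test_hard_calls_and_missing_gene(self):
        m, thr = self._setup()
        ev = cal.evidence_from_sample(m, "sA", thr, softness=0.0)
        assert ev["g1"] == 1.0 and ev["g2"] == 0.0
        assert ev["g3"] is MISSING

    def test_soft_limit_matches_hard(self):
        m, thr = self._setup()
        hard = cal.evidence_from_sample(m, "sB", thr, softness=0.0)
        soft = cal.evidence_from_sample(m, "sB", thr, softness=1e-9)
        for g in ("g1", "g2"):
            assert soft[g] == pytest.approx(hard[g], abs=1e-12)

    def test_unknown_sample_rejected(self):
        m, thr = self._setup()
        with pytest.raises(KeyError):
            cal.evidence_from_sample(m, "nope", thr)


class TestClusterMatrixExport:
    def test_single_cell_body(self, tmp_path):
        path = tmp_path / "q.tsv"
        cal.export_cluster_matrix(pd.DataFrame({"s": [0.5]}, index=["g"]), path)
        body = path.read_text().splitlines()[1]
        assert body.split("\t")[1] == "0.5000"

    def test_round_trip_at_4_decimals(self, tmp_path):
        rng = np.random.default_rng(7)
        q = pd.DataFrame(rng.random((5, 3)), index=list("abcde"), columns=["s1", "s2", "s3"])
        path = tmp_path / "q.tsv"
        cal.export_cluster_matrix(q, path)
        back = pd.read_csv(path, sep="\t", index_col=0)
        assert np.allclose(back.to_numpy(), np.round(q.to_numpy(), 4), atol=1e-12)

    def test_missing_written_as_na(self, tmp_path):
        path = tmp_path / "q.tsv"
        cal.export_cluster_matrix(pd.DataFrame({"s": [np.nan]}, index=["g"]), path)
        assert path.read_text().splitlines()[1].split("\t")[1] == "NA"

    def test_out_of_range_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            cal.export_cluster_matrix(
                pd.DataFrame({"s": [1.5]}, index=["g"]), tmp_path / "q.tsv"
            )


def test_synthetic_round_trip(tmp_path):
    """A generated matrix written to TSV reads back equal."""
    from cellpath.synthetic_data import SyntheticConfig, simulate_expression

    cfg = SyntheticConfig(genes=("g1", "g2", "g3"), n_active=2, n_inactive=2, seed=9)
    m, _, _ = simulate_expression(cfg)
    path = tmp_path / "expr.tsv"
    m.values.to_csv(path, sep="\t", index_label="gene")
    back = cal.read_expression_matrix(path)
    assert np.allclose(back.values.to_numpy(), m.values.to_numpy())
    assert back.genes == m.genes
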