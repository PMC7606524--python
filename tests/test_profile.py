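"""TPM arithmetic and per-biotype detection accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ncembryo as nc
from ncembryo.types import NCRNA_CLASSES

from conftest import make_matrix


class TestComputeTPM:
    def test_two_to_one_rate_ratio(self, tiny_genes):
        # equal counts, lengths 1000 vs 2000: rates 2:1 -> 2/3 and 1/3 of 1e6
        m = make_matrix([[10], [10]], ["g1", "g2"], ["c1"])
        tpm = nc.compute_tpm(m, tiny_genes)
        assert tpm.values[:, 0] == pytest.approx([666666.67, 333333.33], abs=0.01)

    def test_single_gene_is_one_million(self, tiny_genes):
        m = make_matrix([[3]], ["g1"], ["c1"])
        tpm = nc.compute_tpm(m, tiny_genes)
        assert tpm.values[0, 0] == pytest.approx(1e6)

    def test_all_zero_cell_warns_and_stays_zero(self, tiny_genes, caplog):
        m = make_matrix([[1, 0], [1, 0]], ["g1", "g2"], ["c1", "c2"])
        with caplog.at_level("WARNING"):
            tpm = nc.compute_tpm(m, tiny_genes)
        assert (tpm.values[:, 1] == 0).all()
        assert any("all-zero" in msg for msg in caplog.messages)

    def test_missing_length_names_gene(self, tiny_genes):
        m = make_matrix([[1]], ["unknown_gene"], ["c1"])
        with pytest.raises(KeyError, match="unknown_gene"):
            nc.compute_tpm(m, tiny_genes)

    def test_columns_sum_to_one_million(self, small_sim):
        sums = small_sim["tpm"].values.sum(axis=0)
        assert np.allclose(sums[sums > 0], 1e6, atol=1e-3)


class TestLog2TPM:
    def test_elementwise_values(self, tiny_genes):
        m = nc.ExpressionMatrix(
            np.array([[0.0], [1.0], [3.0], [999996.0]]),
            ["a", "b", "c", "d"], ["c1"], "TPM",
        )
        out = nc.log2_tpm(m)
        assert out.values[:3, 0] == pytest.approx([0.0, 1.0, 2.0])
        assert out.kind == "log2tpm"

    def test_wrong_kind_rejected(self):
        m = make_matrix([[1]], ["g"], ["c"], kind="counts")
        with pytest.raises(ValueError, match="TPM"):
            nc.log2_tpm(m)


class TestCountDetected:
    def _tpm(self, col):
        # construct unnormalized TPM-kind columns for threshold tests
        return nc.ExpressionMatrix(
            np.asarray(col, float)[:, None],
            [f"g{i}" for i in range(len(col))], ["c1"], "TPM", _validate=False,
        )

    def test_strict_threshold_excludes_exactly_one(self):
        tpm = self._tpm([0.5, 1.0, 2.0, 10.0])
        genes = [nc.GeneRecord(f"g{i}", "coding", 100) for i in range(4)]
        per_cell, per_gene = nc.count_detected(tpm, genes)
        assert per_cell.tolist() == [2]
        assert per_gene.tolist() == [False, False, True, True]

    def test_all_at_or_below_one_gives_zero(self):
        tpm = self._tpm([0.0, 1.0, 0.9])
        genes = [nc.GeneRecord(f"g{i}", "coding", 100) for i in range(3)]
        per_cell, _ = nc.count_detected(tpm, genes)
        assert per_cell.tolist() == [0]

    def test_filter_with_absent_class_gives_zero(self):
        tpm = self._tpm([5.0, 5.0])
        genes = [nc.GeneRecord(f"g{i}", "coding", 100) for i in range(2)]
        per_cell, per_gene = nc.count_detected(tpm, genes, biotype_filter=["tRNA"])
        assert per_cell.tolist() == [0] and len(per_gene) == 0

    def test_unknown_filter_class_rejected(self):
        tpm = self._tpm([5.0])
        genes = [nc.GeneRecord("g0", "coding", 100)]
        with pytest.raises(ValueError, match="unknown biotype"):
            nc.count_detected(tpm, genes, biotype_filter=["miRNA"])


class TestDetectRatio:
    @pytest.mark.parametrize(
        "detected,annotated,expected",
        [
            (20431, 20447, 99.92),
            (20436, 20447, 99.95),
            (571, 637, 89.64),
            (1546, 1590, 97.23),
            (9843, 10679, 92.17),
            (169, 169, 100.00),
        ],
    )
    def test_printed_percentages(self, detected, annotated, expected):
        assert nc.detect_ratio(detected, annotated) == expected

    def test_half_up_rounding(self):
        # 1/800 = 0.125% -> 0.13 under half-up (banker's would give 0.12)
        assert nc.detect_ratio(1, 800) == 0.13

    def test_bounds_errors(self):
        with pytest.raises(ValueError):
            nc.detect_ratio(5, 0)
        with pytest.raises(ValueError):
            nc.detect_ratio(6, 5)

    @given(st.integers(0, 1000), st.integers(1, 1000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_100_iff_complete(self, detected, annotated):
        detected = min(detected, annotated)
        r = nc.detect_ratio(detected, annotated)
        assert 0 <= r <= 100
        assert (r == 100.0) == (detected == annotated)
        if detected < annotated:
            assert nc.detect_ratio(detected + 1, annotated) >= r


def test_ncrna_class_detections_partition(small_sim):
    """Summing detected totals over the 8 ncRNA classes equals the
    all-ncRNA detected total."""
    tpm, genes = small_sim["tpm"], small_sim["genes"]
    per_class = 0
    for cls in NCRNA_CLASSES:
        _, per_gene = nc.count_detected(tpm, genes, biotype_filter=[cls])
        per_class += int(per_gene.sum())
    _, all_nc = nc.count_detected(tpm, genes, biotype_filter=list(NCRNA_CLASSES))
    assert per_class == int(all_nc.sum())


def test_detection_summary_shape(small_sim):
    df = nc.detection_summary(small_sim["tpm"], small_sim["genes"])
    assert set(df["biotype"]) == {"coding", *NCRNA_CLASSES, "all_ncRNA"}
    assert (df["genes_detected_total"] <= df["genes_annotated"]).all()
    assert df["detect_ratio_pct"].between(0, 100).all()


class TestPerIntervalCorrelation:
    def test_exact_proportionality_gives_r_one(self, small_sim):
        import pandas as pd

        tpm, genes = small_sim["tpm"], small_sim["genes"]
        ann = pd.DataFrame({"cell_id": tpm.cell_ids, "time_interval": "i0"})
        out = nc.per_interval_detection_correlation(tpm, genes, ann)
        # independent recount oracle: brute-force flags per cell
        from ncembryo.types import NCRNA_CLASSES as NCC

        index = {g.gene_id: g for g in genes}
        coding_rows = [i for i, g in enumerate(tpm.gene_ids) if index[g].biotype == "coding"]
        nc_rows = [i for i, g in enumerate(tpm.gene_ids) if index[g].biotype in NCC]
        coding = (tpm.values[coding_rows] > 1).sum(axis=0)
        ncrna = (tpm.values[nc_rows] > 1).sum(axis=0)
        expected_r = np.corrcoef(coding, ncrna)[0, 1]
        assert out.loc[0, "r"] == pytest.approx(expected_r, abs=1e-12)
        assert out.loc[0, "n_cells"] == tpm.n_cells

    def test_small_interval_reported_missing(self, small_sim):
        import pandas as pd

        tpm, genes = small_sim["tpm"], small_sim["genes"]
        intervals = ["tiny"] * 2 + ["big"] * (tpm.n_cells - 2)
        ann = pd.DataFrame({"cell_id": tpm.cell_ids, "time_interval": intervals})
        out = nc.per_interval_detection_correlation(tpm, genes, ann).set_index("time_interval")
        assert np.isnan(out.loc["tiny", "r"]) and out.loc["tiny", "reason"] == "n<3"
        assert np.isfinite(out.loc["big", "r"])
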