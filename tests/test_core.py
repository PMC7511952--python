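"""Contingency arithmetic, container validation and file round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methmarker import (
    BetaMatrix,
    FormatError,
    ValidationError,
    contingency_metrics,
    percent_1dp,
)
from methmarker.core import CohortSet, ERStatus, SampleRecord
from methmarker import io as mio


class TestContingencyMetrics:
    @pytest.mark.parametrize(
        "counts, metric, expected",
        [
            # combined-marker performance of the benchmark cohort
            ((24, 6, 19, 79), "ppv", 24 / 30),
            ((24, 6, 19, 79), "sensitivity", 24 / 43),
            ((24, 6, 19, 79), "specificity", 79 / 85),
            # methylation-marker row of the same cohort
            ((30, 10, 13, 75), "positive_rate", 40 / 128),
            ((30, 10, 13, 75), "pcr_rate_marker_pos", 30 / 40),
            ((0, 0, 5, 5), "sensitivity", 0.0),
            ((0, 0, 5, 5), "specificity", 1.0),
        ],
    )
    def test_metric_values(self, counts, metric, expected):
        assert getattr(contingency_metrics(*counts), metric) == pytest.approx(expected)

    def test_empty_positive_class_has_undefined_ppv(self):
        assert contingency_metrics(0, 0, 5, 5).ppv is None

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            contingency_metrics(-1, 0, 1, 1)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            contingency_metrics(0, 0, 0, 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 50)] * 4).filter(lambda t: sum(t) > 0))
    def test_agrees_with_per_sample_recount(self, counts):
        """Derived metrics equal a brute-force recount over the expanded
        per-sample (call, outcome) label list."""
        tp, fp, fn, tn = counts
        labels = (
            [(True, True)] * tp + [(True, False)] * fp
            + [(False, True)] * fn + [(False, False)] * tn
        )
        ct = contingency_metrics(tp, fp, fn, tn)
        n_pos_outcome = sum(o for _, o in labels)
        n_neg_outcome = len(labels) - n_pos_outcome
        if n_pos_outcome:
            assert ct.sensitivity == sum(c and o for c, o in labels) / n_pos_outcome
        if n_neg_outcome:
            assert ct.specificity == sum((not c) and (not o) for c, o in labels) / n_neg_outcome
        assert ct.positive_rate == sum(c for c, _ in labels) / len(labels)
        for m in (ct.sensitivity, ct.specificity, ct.ppv, ct.npv):
            assert m is None or 0.0 <= m <= 1.0


class TestPercentRounding:
    @pytest.mark.parametrize(
        "num, den, expected",
        [(40, 128, 31.3), (43, 128, 33.6), (65, 128, 50.8), (1, 8, 12.5), (1, 16, 6.3)],
    )
    def test_half_up_one_decimal(self, num, den, expected):
        assert percent_1dp(num, den) == expected


class TestBetaMatrix:
    def test_identity_read(self, tmp_path):
        pd.DataFrame(0.5, index=["p1", "p2"], columns=["s1", "s2"]).rename_axis(
            "probe_id"
        ).to_csv(tmp_path / "b.tsv", sep="\t")
        (tmp_path / "ann.tsv").write_text(
            "probe_id\tchrom\tpos\tgene\tregion_class\tregion_id\n"
            "p1\tchr1\t100\tG\tgenic\tR1\np2\tchr1\t200\tG\tgenic\tR1\n"
        )
        beta, ann = mio.read_beta_matrix(tmp_path / "b.tsv", tmp_path / "ann.tsv")
        assert beta.values.tolist() == [[0.5, 0.5], [0.5, 0.5]]
        assert [a.probe_id for a in ann] == ["p1", "p2"]

    def test_out_of_range_cites_coordinates(self):
        df = pd.DataFrame([[1.2, 0.1]], index=["p1"], columns=["s1", "s2"])
        with pytest.raises(ValidationError, match="p1.*s1"):
            BetaMatrix(df)

    def test_missing_annotation_lists_probes(self, tmp_path):
        pd.DataFrame(0.5, index=["p1", "p2"], columns=["s1"]).rename_axis(
            "probe_id"
        ).to_csv(tmp_path / "b.tsv", sep="\t")
        (tmp_path / "ann.tsv").write_text(
            "probe_id\tchrom\tpos\tgene\tregion_class\tregion_id\n"
            "p1\tchr1\t100\tG\tgenic\tR1\n"
        )
        with pytest.raises(ValidationError, match="p2"):
            mio.read_beta_matrix(tmp_path / "b.tsv", tmp_path / "ann.tsv")


class TestSampleSheet:
    def _sheet(self, tmp_path, body):
        p = tmp_path / "sheet.tsv"
        p.write_text("sample_id\tcohort_set\tpcr\ter_status\tage\ttimepoint\n" + body)
        return p

    def test_reads_in_file_order(self, tmp_path):
        p = self._sheet(
            tmp_path,
            "s1\tscreening\ttrue\tnegative\t50\tbaseline\n"
            "s2\tscreening\tfalse\tpositive\t61\tbaseline\n"
            "s3\tvalidation\ttrue\tnegative\t44\tbaseline\n",
        )
        recs = mio.read_sample_sheet(p)
        assert [r.sample_id for r in recs] == ["s1", "s2", "s3"]
        assert recs[1].pcr is False and recs[2].cohort_set is CohortSet.validation

    def test_duplicate_id_rejected(self, tmp_path):
        p = self._sheet(
            tmp_path,
            "s1\tscreening\ttrue\tnegative\t50\tbaseline\n"
            "s1\tscreening\tfalse\tpositive\t61\tbaseline\n",
        )
        with pytest.raises(ValidationError, match="s1"):
            mio.read_sample_sheet(p)

    def test_blank_er_status_defaults_to_unknown(self, tmp_path):
        p = self._sheet(tmp_path, "s1\tscreening\ttrue\t\t50\tbaseline\n")
        assert mio.read_sample_sheet(p)[0].er_status is ERStatus.unknown

    def test_missing_required_column_named(self, tmp_path):
        p = tmp_path / "sheet.tsv"
        p.write_text("sample\tpcr\na\ttrue\n")
        with pytest.raises(FormatError, match="sample_id"):
            mio.read_sample_sheet(p)

    def test_round_trip_lossless(self, tmp_path):
        records = [
            SampleRecord("s1", CohortSet.screening, True, ERStatus.negative, 50),
            SampleRecord("s2", CohortSet.validation, False, ERStatus.unknown, None),
            SampleRecord("s3", CohortSet.revalidation, None, ERStatus.positive, 61),
        ]
        path = tmp_path / "sheet.tsv"
        mio.write_sample_sheet(records, path)
        back = mio.read_sample_sheet(path)
        assert back == records


def test_beta_matrix_round_trip(tmp_path, bundle):
    sub = bundle.beta.subset_probes(bundle.beta.probe_ids[:20])
    path = tmp_path / "beta.tsv"
    mio.write_beta_matrix(sub, path)
    back = pd.read_csv(path, sep="\t", index_col=0)
    assert np.allclose(back.to_numpy(), sub.values)
    assert list(back.index) == sub.probe_ids and list(back.columns) == sub.sample_ids
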