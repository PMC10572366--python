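import csv
from pathlib import Path

import pytest

from focicount import (
    FociParams,
    Focus,
    ImageSummary,
    NucleusRecord,
    classify_nucleus,
    mean_foci_per_nucleus,
    summarize_image,
    write_outputs,
)


def focus(max_intensity, label=1):
    return Focus(
        nucleus_label=label,
        area_px=4,
        min_intensity=max_intensity / 2,
        max_intensity=max_intensity,
        mean_intensity=max_intensity * 0.75,
        centroid=(0.0, 0.0),
    )


class TestClassifyNucleus:
    def test_thresholds_are_inclusive(self):
        # exactly at both thresholds: 10 foci of exactly 10,000 -> damaged
        assert classify_nucleus([focus(10_000)] * 10, FociParams()) == (10, True)

    def test_count_below_rule_not_damaged(self):
        assert classify_nucleus([focus(60_000)] * 9, FociParams()) == (9, False)

    def test_brightness_below_rule_not_damaged(self):
        assert classify_nucleus([focus(9_999)] * 10, FociParams()) == (0, False)

    def test_no_foci(self):
        assert classify_nucleus([], FociParams()) == (0, False)

    def test_qualifying_never_exceeds_total(self):
        foci = [focus(v) for v in (5_000, 10_000, 20_000)]
        qualifying, _ = classify_nucleus(foci, FociParams())
        assert qualifying == 2 <= len(foci)

    def test_mean_statistic_option(self):
        params = FociParams(brightness_statistic="mean")
        (q, sel) = classify_nucleus([focus(10_000)] * 10, params)
        assert q == 0 and not sel  # mean is 7500 < 10000


class TestMeanFociPerNucleus:
    @pytest.mark.parametrize(
        "counts, expected", [([0, 0, 0], 0.0), ([10], 10.0), ([2, 4, 9], 5.0)]
    )
    def test_arithmetic_mean_of_total_counts(self, counts, expected):
        records = [
            NucleusRecord(nucleus_label=i + 1, foci={"green": [focus(1)] * k})
            for i, k in enumerate(counts)
        ]
        assert mean_foci_per_nucleus(records, "green") == pytest.approx(expected)

    def test_empty_records_undefined(self):
        assert mean_foci_per_nucleus([], "green") is None


class TestSummarize:
    def _records(self, selected_flags):
        return [
            NucleusRecord(
                nucleus_label=i + 1, selected={"green": flag}, foci={"green": []}
            )
            for i, flag in enumerate(selected_flags)
        ]

    @pytest.mark.parametrize(
        "flags, ratio",
        [([True] * 6 + [False] * 2, 0.75), ([False] * 4, 0.0), ([True] * 3, 1.0)],
    )
    def test_ratio(self, flags, ratio):
        records = self._records(flags)
        rois = [object()] * len(records)
        s = summarize_image("img.czi", rois, records, 1234.5, "green")
        assert s.number_total_nuclei == len(flags)
        assert s.ratio_selected_nucleus == pytest.approx(ratio)
        assert 0 <= s.number_selected_nucleus <= s.number_total_nuclei

    def test_zero_nuclei_ratio_undefined(self):
        s = summarize_image("img.czi", [], [], None, "green")
        assert s.ratio_selected_nucleus is None
        assert s.number_total_nuclei == 0


class TestWriteOutputs:
    def _summary(self, name, selected, total):
        return ImageSummary(
            filename=name,
            average_intensity=1500.0,
            number_selected_nucleus=selected,
            number_total_nuclei=total,
            ratio_selected_nucleus=(selected / total) if total else None,
        )

    def _records(self):
        return {
            "a.tif": [
                NucleusRecord(
                    nucleus_label=1, foci={"green": [focus(12_000)], "red": []}
                ),
                NucleusRecord(nucleus_label=2, foci={"green": []}),
            ]
        }

    def test_single_channel_run_writes_only_out_green(self, tmp_path):
        write_outputs(
            {"green": [self._summary("a.tif", 1, 2)]}, self._records(), tmp_path
        )
        assert (tmp_path / "out_green.csv").exists()
        assert not (tmp_path / "out_red.csv").exists()
        assert (tmp_path / "a" / "nucleus_1.csv").exists()
        assert (tmp_path / "a" / "nucleus_2.csv").exists()

    def test_dual_channel_run_writes_four_csvs(self, tmp_path):
        summaries = {
            tag: [self._summary("a.tif", 1, 2)]
            for tag in ("green", "red", "Min", "Max")
        }
        write_outputs(summaries, self._records(), tmp_path)
        for tag in ("green", "red", "Min", "Max"):
            assert (tmp_path / f"out_{tag}.csv").exists()

    def test_summary_schema_and_ratio_consistency(self, tmp_path):
        write_outputs(
            {"green": [self._summary("a.tif", 3, 8), self._summary("b.tif", 0, 0)]},
            {},
            tmp_path,
        )
        with open(tmp_path / "out_green.csv", newline="") as fh:
            rows = list(csv.reader(fh))
        assert rows[0] == [
            "filename",
            "average_intensity",
            "number_selected_nucleus",
            "number_total_nuclei",
            "ratio_selected_nucleus",
        ]
        assert rows[1][0] == "a.tif"
        ratio = float(rows[1][4])
        assert ratio == pytest.approx(int(rows[1][2]) / int(rows[1][3]), abs=1e-6)
        assert rows[2][4] == ""  # zero-nuclei image: empty ratio cell

    def test_per_focus_table_schema(self, tmp_path):
        write_outputs(
            {"green": [self._summary("a.tif", 1, 2)]}, self._records(), tmp_path
        )
        with open(tmp_path / "a" / "nucleus_1.csv", newline="") as fh:
            rows = list(csv.reader(fh))
        assert rows[0] == [
            "channel",
            "focus_id",
            "area_px",
            "min_intensity",
            "max_intensity",
            "mean_intensity",
        ]
        assert rows[1][:3] == ["green", "1", "4"]
        assert float(rows[1][4]) == pytest.approx(12_000.0)

    def test_rewrite_is_byte_identical(self, tmp_path):
        args = ({"green": [self._summary("a.tif", 1, 2)]}, self._records())
        write_outputs(*args, tmp_path / "run1")
        write_outputs(*args, tmp_path / "run2")
        files1 = sorted(p.relative_to(tmp_path / "run1") for p in (tmp_path / "run1").rglob("*.csv"))
        files2 = sorted(p.relative_to(tmp_path / "run2") for p in (tmp_path / "run2").rglob("*.csv"))
        assert files1 == files2
        for rel in files1:
            assert (tmp_path / "run1" / rel).read_bytes() == (
                tmp_path / "run2" / rel
            ).read_bytes()
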