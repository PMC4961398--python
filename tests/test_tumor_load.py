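"""Tumor-load quantification, relapse flagging and biomarker comparison."""

import math

import pytest
from hypothesis import given, strategies as st

from ctdnatrack import tumor_load as tl
from ctdnatrack.io_formats import SampleRecord


def _point(t, mv, cf=25.0, cea=None, ca=None, patient="P1"):
    return tl.TumorLoadPoint(
        patient_id=patient, time_days=t, mean_vaf=mv, cfdna_conc=cf,
        cea=cea, ca199=ca,
    )


class TestMeanVaf:
    def test_union_imputed_is_arithmetic_mean(self):
        assert tl.mean_vaf([0.01, 0.02, 0.03]) == pytest.approx(0.02)

    def test_mode_contrast_on_partial_detection(self):
        vafs = [0.02, 0.0, 0.0, 0.02]
        imputed = [False, True, True, False]
        assert tl.mean_vaf(vafs, "union_imputed", imputed) == pytest.approx(0.01)
        assert tl.mean_vaf(vafs, "detected_only", imputed) == pytest.approx(0.02)

    def test_all_zero_union_column(self):
        assert tl.mean_vaf([0.0, 0.0, 0.0]) == 0.0

    def test_empty_panel_errors(self):
        with pytest.raises(ValueError):
            tl.mean_vaf([], "union_imputed")
        with pytest.raises(ValueError):
            tl.mean_vaf([0.0, 0.0], "detected_only", [True, True])


class TestAbsoluteCtdna:
    @pytest.mark.parametrize(
        "mv,cf,expected", [(0.0, 17.0, 0.0), (1.0, 33.0, 33.0), (0.005, 30.0, 0.15)]
    )
    def test_product(self, mv, cf, expected):
        assert tl.absolute_ctdna(mv, cf) == pytest.approx(expected)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            tl.absolute_ctdna(1.5, 10.0)
        with pytest.raises(ValueError):
            tl.absolute_ctdna(0.5, -1.0)

    @given(mv=st.floats(0, 1), cf=st.floats(0, 200))
    def test_ctdna_never_exceeds_cfdna(self, mv, cf):
        assert tl.absolute_ctdna(mv, cf) <= cf + 1e-9


class TestTumorLoadPoint:
    def test_derived_concentration_consistency_enforced(self):
        p = _point(30, 0.004, cf=25.0)
        assert p.ctdna_ng_per_ml == pytest.approx(0.1)
        with pytest.raises(ValueError, match="inconsistent"):
            tl.TumorLoadPoint(
                patient_id="P1", time_days=30, mean_vaf=0.004,
                cfdna_conc=25.0, ctdna_ng_per_ml=0.5,
            )


class TestFlagRelapse:
    def test_thirteen_fold_rise_over_nadir_flagged(self):
        series = [
            _point(-7, 0.011, 30.0),
            _point(30, 0.001, 20.0),  # nadir: 0.02 ng/mL
            _point(540, 0.013, 20.0),  # 0.26 ng/mL
        ]
        report = tl.flag_relapse(series, fold_threshold=5)
        assert report.first_flagged_time == 540
        assert report.max_fold == pytest.approx(13.0)
        assert report.baseline == pytest.approx(0.02)

    def test_monotone_decreasing_series_never_flags(self):
        series = [_point(t, mv) for t, mv in
                  [(-7, 0.01), (30, 0.004), (120, 0.002), (210, 0.001)]]
        report = tl.flag_relapse(series)
        assert report.flagged_times == [] and not report.relapse_detected

    def test_zero_baseline_gated_by_absolute_arm(self):
        series = [_point(30, 0.0), _point(120, 0.05 / 25.0)]
        report = tl.flag_relapse(series, min_abs_level=0.02)
        assert report.flagged_times == [120]
        assert math.isinf(report.max_fold)

    def test_below_absolute_floor_not_flagged_despite_fold(self):
        series = [_point(30, 0.0), _point(120, 0.01 / 25.0)]
        report = tl.flag_relapse(series, min_abs_level=0.02)
        assert report.flagged_times == []

    def test_fewer_than_two_postop_points_undefined(self):
        report = tl.flag_relapse([_point(-7, 0.01), _point(30, 0.001)])
        assert report.max_fold is None and report.baseline is None
        assert not report.relapse_detected

    def test_single_preop_point_no_flags(self):
        report = tl.flag_relapse([_point(-7, 0.01)])
        assert report.flagged_times == []

    def test_confirmation_requires_consecutive_flags(self):
        blip = [_point(30, 0.001, 20.0), _point(120, 0.013, 20.0),
                _point(210, 0.001, 20.0)]
        sustained = blip + [_point(300, 0.02, 20.0), _point(390, 0.03, 20.0)]
        assert not tl.flag_relapse(blip).relapse_confirmed
        report = tl.flag_relapse(sustained)
        assert report.relapse_confirmed
        assert report.confirmed_relapse_time == 300

    def test_baseline_is_running_nadir_not_previous_point(self):
        # chemo-era fluctuation: rise then dip then modest rise should
        # compare against the nadir, not the immediately preceding point
        series = [_point(30, 0.002), _point(120, 0.004), _point(210, 0.001),
                  _point(300, 0.004)]
        report = tl.flag_relapse(series, fold_threshold=5, min_abs_level=0.0)
        # 0.004*25=0.1 vs nadir 0.025: 4-fold < 5 -> not flagged
        assert report.flagged_times == []


class TestCompareBiomarkers:
    def test_cea_below_cutoff_negative(self):
        series = [_point(540, 0.013, 20.0, cea=3.8, ca=18.7)]
        table, _ = tl.compare_biomarkers(series)
        assert not table.loc[0, "cea_positive"]
        assert not table.loc[0, "ca199_positive"]

    def test_ctdna_only_discordance_counted(self):
        series = [
            _point(30, 0.001, 20.0, cea=2.5, ca=12.0),
            _point(540, 0.013, 20.0, cea=3.8, ca=18.7),
        ]
        tl.flag_relapse(series)
        _, summary = tl.compare_biomarkers(series)
        assert summary["ctdna_only"] == 1
        assert summary["biomarker_only"] == 0

    def test_all_negative_everywhere(self):
        series = [_point(30, 0.0, cea=1.0, ca=5.0), _point(120, 0.0, cea=1.2, ca=6.0)]
        _, summary = tl.compare_biomarkers(series)
        assert summary["ctdna_only"] == 0
        assert summary["biomarker_only"] == 0
        assert summary["concordant_positive"] == 0
        assert summary["concordant_negative"] == 2

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            tl.compare_biomarkers([_point(30, 0.0)], cea_cutoff=0.0)


class TestBuildSeries:
    def _matrix(self):
        from ctdnatrack.marker_tracking import build_marker_set, fill_vaf_matrix
        import pandas as pd
        from ctdnatrack.io_formats import Variant

        v = Variant("chr1", 1, "C", "T", consequence="nonsynonymous_snv")
        ms = build_marker_set("P1", [v], {"b1": []})
        obs = pd.DataFrame(
            [{"sample_id": "b1", "chrom": "chr1", "pos": 1, "ref": "C", "alt": "T",
              "ref_count": 982, "alt_count": 18, "depth": 1000}]
        )
        samples = [
            SampleRecord("b1", "P1", "plasma", -7.0, cfdna_conc=30.0),
            SampleRecord("b2", "P1", "plasma", 30.0, cfdna_conc=20.0),
        ]
        return fill_vaf_matrix(ms, obs, samples), samples

    def test_points_time_ordered_with_invariants(self):
        matrix, samples = self._matrix()
        series = tl.build_series("P1", matrix, samples)
        assert [p.time_days for p in series] == [-7.0, 30.0]
        for p in series:
            assert p.ctdna_ng_per_ml == pytest.approx(p.mean_vaf * p.cfdna_conc)

    def test_missing_sample_sheet_entry_errors(self):
        matrix, samples = self._matrix()
        with pytest.raises(ValueError, match="missing from sample sheet"):
            tl.build_series("P1", matrix, samples[:1])
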