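"""Log parsing, session segmentation, and truncated AUC statistics."""

import numpy as np
import pytest

from iconqa import (
    AUCResult,
    GatingConfig,
    LogParseError,
    MotionTrace,
    Segment,
    TreatmentSession,
    auc_mean,
    cohort_summary,
    make_phantom_log,
    parse_log,
    post_cbct_residuals,
    radial_displacement,
    session_auc,
)
from iconqa.logs import LogRow, write_log_rows

from conftest import oracle_auc_radial, random_piecewise_trace


def make_trace(t, radial, treating=None, xyz=None):
    t = np.asarray(t, float)
    n = t.size
    radial = np.asarray(radial, float)
    return MotionTrace(
        t_s=t,
        xyz_mm=np.zeros((n, 3)) if xyz is None else np.asarray(xyz, float),
        radial_mm=radial,
        treating=np.ones(n, bool) if treating is None else np.asarray(treating, bool),
    )


class TestParseLog:
    def test_phantom_fixture_residual_preserved_verbatim(self, tmp_path):
        # recorded radial 0.09 must NOT be "fixed" to the xyz norm (~0.124):
        # the log stores a windowed radial and instantaneous axes
        path = make_phantom_log(tmp_path / "phantom.csv")
        session = parse_log(path)
        seg = session.segments[0]
        assert seg.residual_mm == (-0.09, 0.06, 0.06)
        assert seg.residual_radial_mm == 0.09
        assert radial_displacement(seg.residual_mm) == pytest.approx(0.124, abs=5e-4)
        assert radial_displacement(seg.residual_mm) != seg.residual_radial_mm

    def test_two_segment_file(self, tmp_path):
        rows = [
            LogRow(0.0, 0.1, 0.0, 0.0, 0.1, "treating", "baseline"),
            LogRow(10.0, 0.2, 0.0, 0.0, 0.2, "treating", "record"),
            LogRow(20.0, 0.05, 0.0, 0.0, 0.05, "treating", "rebaseline"),
            LogRow(30.0, 0.1, 0.0, 0.0, 0.1, "treating", "end"),
        ]
        path = tmp_path / "two.csv"
        write_log_rows(rows, path, session_id="two", gating=GatingConfig())
        session = parse_log(path)
        assert len(session.segments) == 2
        assert session.segments[1].residual_mm == (0.05, 0.0, 0.0)

    def test_round_trip_is_lossless(self, tmp_path):
        rows = [
            LogRow(0.0, -0.031415926535, 0.1, 0.2, 0.123456789012345, "treating", "baseline"),
            LogRow(1.5, 0.3, -0.4, 0.5, 0.6, "treating", "record"),
            LogRow(3.0, 1.7, 0.0, 0.1, 1.71, "paused", "record"),
            LogRow(4.5, 0.2, 0.1, 0.0, 0.25, "treating", "end"),
        ]
        path = tmp_path / "rt.csv"
        write_log_rows(rows, path, session_id="rt", gating=GatingConfig())
        session = parse_log(path)
        assert session.session_id == "rt"
        assert session.to_rows() == rows

    def test_gating_read_from_header(self, tmp_path):
        rows = [LogRow(0.0, 0, 0, 0, 0, "treating", "baseline"),
                LogRow(1.0, 0, 0, 0, 0, "treating", "end")]
        path = tmp_path / "g.csv"
        write_log_rows(rows, path, gating=GatingConfig(threshold_mm=2.0, record_trigger_mm=0.3))
        assert parse_log(path).gating.threshold_mm == 2.0

    @pytest.mark.parametrize(
        "line",
        [
            "5.0,0.1,0.1,0.1,oops,treating,record",     # malformed float
            "0.5,0.1,0.1,0.1,0.1,treating,record",      # non-monotone time
            "5.0,0.1,0.1,0.1,0.1,sleeping,record",      # unknown state
        ],
    )
    def test_malformed_rows_name_the_line(self, tmp_path, line):
        path = tmp_path / "bad.csv"
        path.write_text(
            "t_s,x_mm,y_mm,z_mm,radial_mm,state,event\n"
            "0.0,0.0,0.0,0.0,0.0,treating,baseline\n"
            "1.0,0.1,0.1,0.1,0.1,treating,record\n"
            f"{line}\n"
        )
        with pytest.raises(LogParseError, match="line 4"):
            parse_log(path)

    def test_first_row_must_be_baseline(self, tmp_path):
        path = tmp_path / "nb.csv"
        path.write_text("t_s,x_mm,y_mm,z_mm,radial_mm,state,event\n"
                        "0.0,0.0,0.0,0.0,0.0,treating,record\n")
        with pytest.raises(LogParseError, match="baseline"):
            parse_log(path)


class TestAUCMean:
    def test_constant_radial(self, gating):
        trace = make_trace([0.0, 600.0], [0.5, 0.5])
        result = auc_mean(trace, gating)
        assert result.mean_radial_mm == pytest.approx(0.5)
        assert result.treating_duration_s == pytest.approx(600.0)

    def test_linear_ramp(self, gating):
        trace = make_trace([0.0, 120.0], [0.0, 1.0])
        assert auc_mean(trace, gating).mean_radial_mm == pytest.approx(0.5)

    def test_clipping_at_threshold(self, gating):
        trace = make_trace([0.0, 60.0], [2.0, 2.0])
        assert auc_mean(trace, gating).mean_radial_mm == pytest.approx(1.5)

    def test_clipping_handles_mid_interval_crossing(self, gating):
        # 1.0 -> 2.0 over 60 s crossing 1.5 at the midpoint:
        # first half averages 1.25, second half sits at the cap
        trace = make_trace([0.0, 60.0], [1.0, 2.0])
        assert auc_mean(trace, gating).mean_radial_mm == pytest.approx(1.375)

    def test_all_paused_segment_signals_empty_not_raises(self, gating):
        trace = make_trace([0.0, 10.0, 20.0], [2.0, 2.0, 2.0], treating=[False, False, False])
        assert auc_mean(trace, gating) is None

    def test_paused_intervals_excluded_from_both_sums(self, gating):
        # pause in the middle at high displacement must not bias the mean
        trace = make_trace([0, 10, 20, 30], [0.4, 1.4, 1.4, 0.4],
                           treating=[True, False, True, True])
        result = auc_mean(trace, gating)
        assert result.treating_duration_s == pytest.approx(20.0)
        assert result.mean_radial_mm == pytest.approx((0.9 * 10 + 0.9 * 10) / 20.0)

    def test_signed_axis_means_use_instantaneous_xyz(self, gating):
        xyz = [[-1.0, 0.5, 0.0], [1.0, 0.5, 2.0]]
        trace = make_trace([0.0, 100.0], [0.5, 0.5], xyz=xyz)
        result = auc_mean(trace, gating)
        assert result.mean_x_mm == pytest.approx(0.0)
        assert result.mean_y_mm == pytest.approx(0.5)
        assert result.mean_z_mm == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, gating):
        rng = np.random.default_rng(42)
        for _ in range(25):
            trace = random_piecewise_trace(rng)
            expected, duration = oracle_auc_radial(trace, gating)
            result = auc_mean(trace, gating)
            assert result.mean_radial_mm == pytest.approx(expected, abs=1e-9)
            assert result.treating_duration_s == pytest.approx(duration, abs=1e-9)

    def test_invariant_under_refinement(self, gating):
        rng = np.random.default_rng(3)
        trace = random_piecewise_trace(rng)
        t = trace.t_s
        mid = (t[:-1] + t[1:]) / 2
        t2 = np.sort(np.concatenate([t, mid]))
        fine = MotionTrace(
            t_s=t2,
            xyz_mm=np.column_stack([np.interp(t2, t, trace.xyz_mm[:, j]) for j in range(3)]),
            radial_mm=np.interp(t2, t, trace.radial_mm),
            treating=trace.treating[np.clip(np.searchsorted(t, t2, "right") - 1, 0, len(t) - 1)],
        )
        coarse_result = auc_mean(trace, gating)
        fine_result = auc_mean(fine, gating)
        assert fine_result.mean_radial_mm == pytest.approx(coarse_result.mean_radial_mm, abs=1e-12)
        assert fine_result.mean_x_mm == pytest.approx(coarse_result.mean_x_mm, abs=1e-12)

    def test_mean_radial_never_exceeds_threshold(self, gating):
        rng = np.random.default_rng(11)
        for _ in range(20):
            trace = random_piecewise_trace(rng, radial_scale=5.0)
            assert auc_mean(trace, gating).mean_radial_mm <= gating.threshold_mm + 1e-12

    def test_within_threshold_trace_unaffected_by_clipping(self):
        rng = np.random.default_rng(5)
        trace = random_piecewise_trace(rng, radial_scale=1.0)
        tight = GatingConfig(threshold_mm=1.5)
        loose = GatingConfig(threshold_mm=100.0)
        assert auc_mean(trace, tight).mean_radial_mm == pytest.approx(
            auc_mean(trace, loose).mean_radial_mm, rel=1e-12)


class TestSessionStatistics:
    @staticmethod
    def _session(residuals, sid="s"):
        segments = [
            Segment(residual_mm=tuple(r), residual_radial_mm=radial_displacement(r),
                    trace=make_trace([0.0 + i * 100, 50.0 + i * 100], [0.1, 0.1]))
            for i, r in enumerate(residuals)
        ]
        return TreatmentSession(session_id=sid, gating=GatingConfig(), segments=segments)

    def test_single_residual_means_are_the_values(self):
        comp = post_cbct_residuals([self._session([(-0.02, -0.02, 0.11)])])
        assert comp.axis_mean_mm == pytest.approx((-0.02, -0.02, 0.11))
        assert comp.error_type == "random"

    def test_all_zero_residuals_give_zero_vector_mean(self):
        comp = post_cbct_residuals([self._session([(0.0, 0.0, 0.0)] * 3)])
        assert comp.vector_mean_mm == 0.0

    def test_residual_distribution_recovery(self):
        rng = np.random.default_rng(8)
        mu, sd, n = np.array([-0.02, -0.02, 0.11]), np.array([0.17, 0.21, 0.37]), 30
        draws = rng.normal(mu, sd, (n, 3))
        comp = post_cbct_residuals([self._session([tuple(d)], sid=f"s{i}")
                                    for i, d in enumerate(draws)])
        for j in range(3):
            assert abs(comp.axis_mean_mm[j] - mu[j]) <= 3 * sd[j] / np.sqrt(n)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            post_cbct_residuals([])

    def test_session_auc_weights_segments_by_treating_time(self):
        segments = [
            Segment((0, 0, 0), 0.0, make_trace([0.0, 100.0], [0.2, 0.2])),
            Segment((0, 0, 0), 0.0, make_trace([200.0, 500.0], [0.8, 0.8])),
        ]
        session = TreatmentSession("w", GatingConfig(), segments)
        result = session_auc(session)
        assert result.mean_radial_mm == pytest.approx((0.2 * 100 + 0.8 * 300) / 400)
        assert result.treating_duration_s == pytest.approx(400.0)


class TestCohortSummary:
    def test_identical_results_have_zero_sd(self):
        r = AUCResult(0.1, -0.2, 0.3, 0.5, 600.0)
        comp = cohort_summary([r, r, r])
        assert comp.axis_sd_mm == pytest.approx((0.0, 0.0, 0.0))
        assert comp.vector_sd_mm == 0.0

    def test_two_results_sample_sd(self):
        a = AUCResult(0.0, 0.0, 0.0, 0.4, 60.0)
        b = AUCResult(0.0, 0.0, 0.0, 0.8, 60.0)
        comp = cohort_summary([a, b])
        assert comp.vector_mean_mm == pytest.approx(0.6)
        assert comp.vector_sd_mm == pytest.approx(np.sqrt(0.08))  # sample SD, ddof=1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([])
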