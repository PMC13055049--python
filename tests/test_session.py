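"""Macro execution, plate scanning, session bookkeeping, mode comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zfinject import fixtures as fx
from zfinject import session as ss
from zfinject.segmentation import CLASSES, LabelMap


class TestMacro:
    def test_pulse_requires_prior_await_puncture(self):
        with pytest.raises(ss.MacroError):
            ss.InjectionMacro("bad", ({"action": "pulse"},))

    def test_pulse_inside_repeat_after_await_is_valid(self):
        m = ss.InjectionMacro(
            "ok",
            (
                {"action": "await_puncture"},
                {"action": "repeat", "times": 2, "steps": ({"action": "pulse"},)},
            ),
        )
        assert sum(s["action"] == "pulse" for s in m.flattened()) == 2

    def test_repeat_needs_positive_count(self):
        with pytest.raises(ss.MacroError):
            ss.InjectionMacro("bad", ({"action": "repeat", "times": 0, "steps": ()},))

    def test_yaml_roundtrip(self, tmp_path):
        m = ss.DEFAULT_MACROS["pvs"]
        ss.save_macro(m, tmp_path / "m.yaml")
        back = ss.load_macro(tmp_path / "m.yaml")
        assert back.name == m.name and back.steps == m.steps


class TestExecuteMacro:
    def test_doc_macro_success_trace_in_order(self):
        ctx = ss.OracleContext()
        res = ss.execute_macro(ss.DEFAULT_MACROS["doc"], ctx)
        assert res.outcome == "success"
        assert res.trace == [
            "approach", "descend_coarse", "descend_fine", "await_touchdown",
            "advance_along_axis", "await_puncture", "retract", "pulse",
        ]
        assert res.n_pulses == 1 and len(ctx.pulses) == 1

    def test_double_injection_macro_logs_two_pulses(self):
        ctx = ss.OracleContext()
        res = ss.execute_macro(ss.DEFAULT_MACROS["hindbrain"], ctx)
        assert res.outcome == "success"
        assert res.n_pulses == 2 and res.trace.count("pulse") == 2

    def test_empty_macro_succeeds_with_empty_trace(self):
        res = ss.execute_macro(ss.InjectionMacro("noop", ()), ss.OracleContext())
        assert res.outcome == "success" and res.trace == []

    def test_detector_timeout_is_a_recorded_failure(self):
        class DeafContext(ss.OracleContext):
            def puncture(self):
                return None

        res = ss.execute_macro(ss.DEFAULT_MACROS["doc"], DeafContext())
        assert res.outcome == "failure"
        assert "puncture" in res.reason
        assert res.n_pulses == 0  # execution stopped before the pulse

    def test_operator_abort_in_semi_mode(self):
        res = ss.execute_macro(
            ss.DEFAULT_MACROS["pvs"],
            ss.OracleContext(),
            mode="semi_automated",
            operator=lambda larva, step: "abort",
        )
        assert res.outcome == "failure" and res.reason == "operator abort"

    def test_checkpoint_skipped_in_automated_mode(self):
        res = ss.execute_macro(ss.DEFAULT_MACROS["pvs"], ss.OracleContext())
        assert res.outcome == "success"
        assert "operator_checkpoint:skipped" in res.trace


class TestScanPlate:
    def test_detections_sorted_top_to_bottom(self, segmenter, small_plate):
        dets = ss.scan_plate(small_plate.image, segmenter)
        assert len(dets) == len(small_plate.larvae)
        ys = [d.centroid[1] for d in dets]
        assert ys == sorted(ys)

    def test_empty_plate_yields_empty_list(self, segmenter):
        blank = np.full((400, 400), 230, dtype=np.uint8)
        assert ss.scan_plate(blank, segmenter) == []

    def test_equal_y_breaks_tie_by_x(self, segmenter):
        img = np.full((400, 700), 230, dtype=np.uint8)
        yy, xx = np.mgrid[0:400, 0:700]
        for cx in (500, 150):
            disk = (xx - cx) ** 2 + (yy - 200) ** 2 <= 30**2
            img[disk] = 185  # body gray level
        dets = ss.scan_plate(img, segmenter)
        assert [round(d.centroid[0]) for d in dets] == [150, 500]

    def test_detection_crops_carry_landmark_classes(self, segmenter, small_plate):
        dets = ss.scan_plate(small_plate.image, segmenter)
        for det in dets:
            for cls in ("eye", "yolk", "swim_bladder"):
                assert det.labels.mask(cls).any()


class TestRunSession:
    def _detections(self, segmenter, plate):
        return ss.scan_plate(plate.image, segmenter)

    def test_oracle_backed_plate_all_success(self, segmenter):
        plate = fx.generate_plate(8, (900, 900), seed=6)
        dets = self._detections(segmenter, plate)
        settings = ss.SessionSettings(batch_budget_s=1e9)
        rec = ss.run_session(
            dets, settings, ss.DEFAULT_MACROS["doc"], lambda i: ss.OracleContext()
        )
        assert len(rec) == len(dets)
        assert (rec["outcome"] == "success").all()
        assert rec["t_end"].is_monotonic_increasing

    def test_batch_budget_skips_remaining_larvae(self, segmenter):
        plate = fx.generate_plate(8, (900, 900), seed=6)
        dets = self._detections(segmenter, plate)
        settings = ss.SessionSettings(batch_budget_s=100.0)  # ~2 larvae worth
        rec = ss.run_session(
            dets, settings, ss.DEFAULT_MACROS["doc"], lambda i: ss.OracleContext()
        )
        assert len(rec) == len(dets)
        assert (rec["outcome"] == "skipped").sum() > 0
        done = rec[rec["outcome"] != "skipped"]
        assert (done["t_end"] <= 100.0 + 60).all()

    def test_semi_mode_abort_affects_only_that_larva(self, segmenter):
        plate = fx.generate_plate(5, (800, 800), seed=9)
        dets = self._detections(segmenter, plate)
        settings = ss.SessionSettings(
            site="pvs", mode="semi_automated", batch_budget_s=1e9
        )
        abort_id = dets[2].larva_id
        operator = lambda larva, step: "abort" if larva == abort_id else "continue"
        rec = ss.run_session(
            dets, settings, ss.DEFAULT_MACROS["pvs"],
            lambda i: ss.OracleContext(), operator=operator,
        )
        assert rec.loc[rec["larva_id"] == abort_id, "outcome"].item() == "failure"
        others = rec[rec["larva_id"] != abort_id]
        assert (others["outcome"] == "success").all()

    def test_row_count_partition_invariant(self, segmenter):
        plate = fx.generate_plate(6, (900, 900), seed=12)
        dets = self._detections(segmenter, plate)
        settings = ss.SessionSettings(batch_budget_s=150.0)
        rec = ss.run_session(
            dets, settings, ss.DEFAULT_MACROS["doc"], lambda i: ss.OracleContext()
        )
        counts = rec["outcome"].value_counts()
        assert counts.sum() == len(dets)

    def test_reproducible_under_fixed_seed(self, segmenter):
        plate = fx.generate_plate(4, (800, 800), seed=3)
        dets = self._detections(segmenter, plate)
        settings = ss.SessionSettings(batch_budget_s=1e9)
        run = lambda: ss.run_session(
            dets, settings, ss.DEFAULT_MACROS["doc"],
            lambda i: ss.DetectorContext(seed=1000 + i), seed=5,
        )
        pd.testing.assert_frame_equal(run(), run())


class TestSummarize:
    def _records(self, outcomes, seconds=30.0):
        rows = []
        t = 0.0
        for i, oc in enumerate(outcomes):
            dt = 0.0 if oc == "skipped" else seconds
            rows.append(
                {
                    "larva_id": i, "site": "doc_mid", "mode": "automated",
                    "outcome": oc, "reason": "", "tip_x": 0.0, "tip_y": 0.0,
                    "angle_deg": 0.0, "n_pulses": int(oc == "success"),
                    "t_start": t, "t_end": t + dt,
                    "survived": oc == "success", "trace": "",
                }
            )
            t += dt
        return pd.DataFrame(rows, columns=ss.RECORD_COLUMNS)

    def test_success_rate_is_hand_countable(self):
        rec = self._records(["success"] * 14 + ["failure"] * 6)
        assert ss.summarize(rec).success_rate == pytest.approx(70.0)

    def test_larvae_per_hour_from_mean_time(self):
        rec = self._records(["success"] * 5, seconds=30.0)
        assert ss.summarize(rec).larvae_per_hour == pytest.approx(120.0)

    def test_skipped_rows_excluded_from_rates(self):
        rec = self._records(["success", "failure", "skipped", "skipped"])
        s = ss.summarize(rec)
        assert s.n_injected == 2 and s.n_skipped == 2
        assert s.success_rate == pytest.approx(50.0)

    def test_zero_injected_is_an_error(self):
        rec = self._records(["skipped", "skipped"])
        with pytest.raises(ValueError):
            ss.summarize(rec)

    def test_single_session_aggregate_flags_std(self):
        agg = ss.aggregate([70.0])
        assert agg["std"] == 0.0 and agg["single"]

    def test_aggregate_mean_and_sample_std(self):
        agg = ss.aggregate([60.0, 70.0, 80.0])
        assert agg["mean"] == pytest.approx(70.0)
        assert agg["std"] == pytest.approx(10.0)


class TestCompareModes:
    def test_identical_samples_give_half(self):
        r = ss.compare_modes([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
        assert r.t == pytest.approx(0.0)
        assert r.p_one_tailed == pytest.approx(0.5)

    def test_matches_independent_welch_computation(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        r = ss.compare_modes(a, b)
        t, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
        assert r.t == pytest.approx(t, abs=1e-9)
        assert r.p_one_tailed == pytest.approx(p, abs=1e-9)

    def test_significance_flag(self):
        r = ss.compare_modes([10.0, 11.0, 12.0, 11.5], [1.0, 2.0, 1.5, 2.5])
        assert r.p_one_tailed < 0.05 and r.significant

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            ss.compare_modes([1.0], [1.0, 2.0])

    def test_constant_equal_samples_convention(self):
        r = ss.compare_modes([3.0, 3.0], [3.0, 3.0])
        assert r.p_one_tailed == 0.5 and not r.significant


class TestTargetForSite:
    def test_all_sites_produce_in_bounds_poses(self, segmenter):
        plate = fx.generate_plate(3, (800, 800), seed=15)
        dets = ss.scan_plate(plate.image, segmenter)
        h, w = plate.image.shape
        for site in ss.SITES:
            settings = ss.SessionSettings(site=site, user_point=(0.5, 0.5))
            for det in dets:
                pose = ss.target_for_site(det, settings)
                assert 0 <= pose.tip[0] < w and 0 <= pose.tip[1] < h
                assert 0 <= pose.angle_deg < 360
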