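"""Saccade/blink detection, pursuit gain, and trial-exclusion rules."""

import numpy as np
import pandas as pd
import pytest

from pursuitflash import synthetic as syn
from pursuitflash.core import Condition, EyeTrace, Task
from pursuitflash.qc import (
    UndefinedGainError,
    compute_gain,
    detect_blinks,
    detect_saccades,
    exclude_trials,
    exclusion_span_ms,
)


def _trace(x, valid=None, dt=2.0):
    t = np.arange(len(x)) * dt
    if valid is None:
        valid = np.ones(len(x), bool)
    return EyeTrace(t_ms=t, x_deg=np.asarray(x, float), valid=valid)


def _pursuit_cond(soa=200, placement="ahead", direction="rightward"):
    from pursuitflash.core import expected_hemifield

    return Condition(
        task="pursuit_relative", phase="fine2",
        hemifield=expected_hemifield(direction, placement),
        pursuit_direction=direction, placement=placement, soa_ms=soa,
    )


class TestSaccadeDetection:
    def test_pure_pursuit_is_silent(self):
        # noiseless 10 deg/s pursuit: velocity equals the expected baseline
        t = np.arange(0, 2500, 2.0)
        trace = EyeTrace(t_ms=t, x_deg=10.0 * (t - 1250) / 1000.0,
                         valid=np.ones(len(t), bool))
        assert detect_saccades(trace, _pursuit_cond()) == []

    def test_injected_step_detected_at_its_time(self):
        t = np.arange(0, 2500, 2.0)
        x = 10.0 * (t - 1250) / 1000.0
        x[t >= 1400] += 1.5
        trace = EyeTrace(t_ms=t, x_deg=x, valid=np.ones(len(t), bool))
        events = detect_saccades(trace, _pursuit_cond())
        assert len(events) == 1
        kind, onset, offset = events[0]
        assert kind == "saccade" and onset <= 1400 <= offset

    def test_recall_precision_on_generated_traces(self):
        """Detection recovers >= 95% of injected steps with >= 95% precision."""
        obs = syn.make_observer(0, {"saccade_rate_hz": 1.2, "blink_prob": 0.0})
        cond = _pursuit_cond()
        hits = misses = false_alarms = 0
        for seed in range(400):
            trace = syn.simulate_eye_trace(cond, obs, seed)
            truth = [t0 for kind, t0, _ in trace.events if kind == "saccade"]
            detected = detect_saccades(trace, cond)
            matched = set()
            for t0 in truth:
                ok = [i for i, (_, on, off) in enumerate(detected)
                      if on - 20 <= t0 <= off + 20 and i not in matched]
                if ok:
                    matched.add(ok[0])
                    hits += 1
                else:
                    misses += 1
            false_alarms += len(detected) - len(matched)
        recall = hits / max(hits + misses, 1)
        precision = hits / max(hits + false_alarms, 1)
        assert recall >= 0.95, f"recall {recall:.3f}"
        assert precision >= 0.95, f"precision {precision:.3f}"

    def test_all_invalid_trace_warns_and_returns_empty(self):
        trace = _trace(np.zeros(100), valid=np.zeros(100, bool))
        with pytest.warns(UserWarning):
            assert detect_saccades(trace) == []


class TestBlinkDetection:
    def test_fully_valid_trace(self):
        assert detect_blinks(_trace(np.zeros(500))) == []

    def test_sixty_ms_invalid_run_covered(self):
        valid = np.ones(500, bool)
        valid[100:130] = False  # 60 ms at 2-ms sampling
        events = detect_blinks(_trace(np.zeros(500), valid))
        assert len(events) == 1
        _, onset, offset = events[0]
        assert onset <= 200 and offset >= 258  # run padded by 20 ms each side

    def test_nearby_runs_merge_through_padding(self):
        valid = np.ones(500, bool)
        valid[100:120] = False
        valid[122:142] = False  # 4-ms gap, padding bridges it
        events = detect_blinks(_trace(np.zeros(500), valid))
        assert len(events) == 1

    def test_short_dropout_ignored(self):
        valid = np.ones(500, bool)
        valid[100:104] = False  # 8 ms < 20-ms minimum
        assert detect_blinks(_trace(np.zeros(500), valid)) == []


class TestGain:
    def test_perfect_pursuit(self):
        t = np.arange(0, 2500, 2.0)
        trace = EyeTrace(t_ms=t, x_deg=10.0 * (t - 1250) / 1000.0,
                         valid=np.ones(len(t), bool))
        assert compute_gain(trace, 1250.0, 10.0) == pytest.approx(1.0, abs=1e-6)

    def test_generator_gain_recovered(self):
        obs = syn.make_observer(
            0, {"pursuit_gain": 1.02, "gain_sd": 0.0, "trace_noise_deg": 0.02,
                "saccade_rate_hz": 0.0, "blink_prob": 0.0})
        cond = _pursuit_cond()
        gains = [compute_gain(syn.simulate_eye_trace(cond, obs, s), 1250.0, 10.0,
                              condition=cond)
                 for s in range(25)]
        assert np.mean(gains) == pytest.approx(1.02, abs=0.01)

    def test_stationary_eye_zero_gain(self):
        t = np.arange(0, 2500, 2.0)
        trace = EyeTrace(t_ms=t, x_deg=np.zeros(len(t)),
                         valid=np.ones(len(t), bool))
        assert compute_gain(trace, 1250.0, 10.0) == pytest.approx(0.0, abs=1e-9)

    def test_masked_window_raises(self):
        t = np.arange(0, 2500, 2.0)
        valid = np.ones(len(t), bool)
        valid[(t > 1100) & (t < 1380)] = False  # blink swallows the window
        trace = EyeTrace(t_ms=t, x_deg=10.0 * (t - 1250) / 1000.0, valid=valid)
        with pytest.raises(UndefinedGainError):
            compute_gain(trace, 1250.0, 10.0)


class TestExclusion:
    def test_window_spans(self):
        assert exclusion_span_ms(200) == 400.0
        assert exclusion_span_ms(-200) == 400.0
        assert exclusion_span_ms(0) == 200.0

    def _one_trial(self, trace, cond, trace_id="tr0"):
        row = {
            "task": cond.task.value, "phase": cond.phase.value,
            "hemifield": cond.hemifield.value,
            "direction": cond.pursuit_direction.value,
            "placement": cond.placement.value, "soa_ms": cond.soa_ms,
            "offset_deg": 0.0, "trace_id": trace_id, "frame_drop": False,
        }
        return pd.DataFrame([row]), {trace_id: trace}

    def test_clean_trial_valid(self, clean_observer):
        cond = _pursuit_cond()
        trace = syn.simulate_eye_trace(cond, clean_observer, 0)
        trials, traces = self._one_trial(trace, cond)
        out = exclude_trials(trials, traces)
        assert bool(out["qc_valid"].iloc[0])

    def test_deviation_excludes(self, clean_observer):
        cond = _pursuit_cond()
        trace = syn.simulate_eye_trace(cond, clean_observer, 0)
        # offset the eye by 2.5 deg in a window around the reference flash only
        sel = (trace.t_ms >= 1600) | ((trace.t_ms >= 1230) & (trace.t_ms <= 1270))
        trace.x_deg[(trace.t_ms >= 1230) & (trace.t_ms <= 1270)] += 2.5
        trials, traces = self._one_trial(trace, cond)
        out = exclude_trials(trials, traces)
        assert bool(out["deviation_exceeded"].iloc[0])
        assert not bool(out["qc_valid"].iloc[0])

    def test_saccade_near_target_flash_excludes(self, clean_observer):
        cond = _pursuit_cond(soa=200)  # target flash at 1450 ms
        trace = syn.simulate_eye_trace(cond, clean_observer, 0)
        trace.x_deg[trace.t_ms >= 1530] += 1.5  # saccade 80 ms after the flash
        trials, traces = self._one_trial(trace, cond)
        out = exclude_trials(trials, traces)
        assert bool(out["saccade_blink_near_flash"].iloc[0])

    def test_saccade_far_from_flashes_kept(self, clean_observer):
        cond = _pursuit_cond(soa=200)
        trace = syn.simulate_eye_trace(cond, clean_observer, 0)
        trace.x_deg[trace.t_ms >= 600] += 1.2  # well before ref flash - 100 ms
        trials, traces = self._one_trial(trace, cond)
        out = exclude_trials(trials, traces)
        assert bool(out["qc_valid"].iloc[0])

    def test_missing_trace_flagged_not_dropped(self):
        cond = _pursuit_cond()
        trials = self._one_trial(None, cond)[0]
        with pytest.warns(UserWarning):
            out = exclude_trials(trials, {})
        assert len(out) == 1 and bool(out["missing_trace"].iloc[0])

    def test_idempotent_and_order_independent(self, small_dataset):
        trials, traces, _ = small_dataset
        once = exclude_trials(trials.drop(columns=[
            "deviation_exceeded", "saccade_blink_near_flash",
            "missing_trace", "qc_valid"]), traces)
        twice = exclude_trials(once, traces)
        pd.testing.assert_series_equal(once["qc_valid"], twice["qc_valid"])
        shuffled = trials.sample(frac=1.0, random_state=0)
        out_shuffled = exclude_trials(shuffled, traces).sort_index()
        pd.testing.assert_series_equal(
            out_shuffled["qc_valid"], once["qc_valid"], check_names=False
        )

    def test_matches_interval_overlap_oracle(self):
        """Exclusion decisions equal a brute-force per-event overlap check."""
        obs = syn.make_observer(3, {"saccade_rate_hz": 1.0, "blink_prob": 0.3})
        rows, traces = [], {}
        conds = syn.task_conditions(Task.PURSUIT_RELATIVE, "fine2") + \
            syn.task_conditions(Task.FIXATION_RELATIVE)
        for i in range(120):
            cond = conds[i % len(conds)]
            trace = syn.simulate_eye_trace(cond, obs, 1000 + i)
            tid = f"tr{i}"
            traces[tid] = trace
            rows.append({
                "task": cond.task.value, "phase": cond.phase.value,
                "hemifield": cond.hemifield.value,
                "direction": cond.pursuit_direction.value,
                "placement": cond.placement.value, "soa_ms": cond.soa_ms,
                "offset_deg": 0.0, "trace_id": tid, "frame_drop": False,
            })
        trials = pd.DataFrame(rows)
        out = exclude_trials(trials, traces)
        from pursuitflash.qc import detect_blinks, detect_saccades

        for i, row in out.iterrows():
            trace = traces[row.trace_id]
            cond = conds[i % len(conds)]
            events = detect_saccades(trace, cond) + detect_blinks(trace)
            ref, tgt = 1250.0, 1250.0 + row.soa_ms
            windows = [(ref - 100, ref + 100), (tgt - 100, tgt + 100)]
            oracle = any(
                on <= hi and off >= lo
                for _, on, off in events for lo, hi in windows
            )
            assert bool(row.saccade_blink_near_flash) == oracle
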