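"""Synthetic observers, schedules, eye traces and responses."""

import numpy as np
import pandas as pd
import pytest

from pursuitflash import synthetic as syn
from pursuitflash.core import (
    Condition,
    Phase,
    Task,
    hemifield_sign,
)
from pursuitflash.synthetic import ConfigurationError


class TestMakeObserver:
    def test_deterministic(self):
        assert syn.make_observer(1) == syn.make_observer(1)

    def test_defaults_are_group_means(self):
        obs = syn.make_observer(0)
        assert obs.fixation_pse[200] == pytest.approx(0.75)
        assert obs.fixation_pse[0] == pytest.approx(-0.02)
        assert obs.fixation_pse[-200] == pytest.approx(0.0)
        assert obs.pursuit_gain == pytest.approx(1.02)
        assert obs.gain_sd == pytest.approx(0.03)
        assert (obs.ecc_slope_ahead, obs.ecc_slope_behind) == (0.24, 0.26)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ConfigurationError):
            syn.make_observer(0, {"sigma_deg": -1.0})

    def test_unknown_field_rejected(self):
        with pytest.raises(ConfigurationError):
            syn.make_observer(0, {"sigma": 1.0})

    def test_frame_model_switch(self):
        cond = Condition(task="pursuit_relative", phase="fine2",
                         hemifield="right", pursuit_direction="rightward",
                         placement="ahead", soa_ms=200)
        obs_a = syn.make_observer(0, {"frame_model": "A"})
        obs_c = syn.make_observer(0, {"frame_model": "C"})
        # frame A leaves pursuit PSEs at the fixation value; C adds 2a only
        assert syn.true_pse(obs_a, cond) == obs_a.fixation_pse[200]
        assert syn.true_pse(obs_c, cond) == pytest.approx(0.75 + 0.48)


class TestSchedule:
    def test_coarse_grid(self):
        entries = syn.build_schedule(
            Task.PURSUIT_RELATIVE, Phase.COARSE, n_per_cell=1, seed=0,
            condition=_cond("ahead", 200),
        )
        offsets = sorted(o for _, o, _ in entries)
        assert offsets == [-8, -6, -4, -2, 0, 2, 4, 6, 8]

    def test_fixation_grid(self):
        entries = syn.build_schedule(Task.FIXATION_RELATIVE, n_per_cell=1, seed=0)
        offsets = {o for _, o, _ in entries}
        assert offsets == {-2.5, -1.7, -1.0, -0.3, 0.3, 1.0, 1.7, 2.5}

    def test_fine2_grid_translates(self):
        entries = syn.build_schedule(
            Task.PURSUIT_RELATIVE, Phase.FINE2, center_deg=1.5, n_per_cell=1,
            seed=0, condition=_cond("ahead", 200),
        )
        offsets = sorted(o for _, o, _ in entries)
        assert offsets == pytest.approx(
            [1.5 + d for d in (-2, -1.5, -1, -0.5, 0, 0.5, 1, 1.5, 2)]
        )

    def test_coarse_center_forced_to_zero(self):
        entries = syn.build_schedule(
            Task.PURSUIT_RELATIVE, Phase.COARSE, center_deg=3.0, n_per_cell=1,
            seed=0, condition=_cond("ahead", 200),
        )
        assert 0.0 in {o for _, o, _ in entries}

    def test_ruler_shift_balanced(self):
        entries = syn.build_schedule(
            Task.PURSUIT_ABSOLUTE, n_per_cell=10, seed=0,
            condition=_cond("ahead", 200, task=Task.PURSUIT_ABSOLUTE),
        )
        assert sum(s for _, _, s in entries) == 5
        odd = syn.build_schedule(
            Task.PURSUIT_ABSOLUTE, n_per_cell=7, seed=0,
            condition=_cond("ahead", 200, task=Task.PURSUIT_ABSOLUTE),
        )
        assert sum(s for _, _, s in odd) == 3  # rounds down

    def test_order_pseudo_random_under_seed(self):
        a = syn.build_schedule(Task.FIXATION_RELATIVE, n_per_cell=3, seed=5)
        b = syn.build_schedule(Task.FIXATION_RELATIVE, n_per_cell=3, seed=5)
        c = syn.build_schedule(Task.FIXATION_RELATIVE, n_per_cell=3, seed=6)
        assert a == b and a != c


def _cond(placement, soa, direction="rightward", task=Task.PURSUIT_RELATIVE,
          phase=Phase.FINE2):
    from pursuitflash.core import expected_hemifield

    return Condition(
        task=task, phase=phase if task is Task.PURSUIT_RELATIVE else Phase.NA,
        hemifield=expected_hemifield(direction, placement),
        pursuit_direction=direction, placement=placement, soa_ms=soa,
    )


class TestEyeTrace:
    def test_sample_count_and_rate(self, clean_observer):
        trace = syn.simulate_eye_trace(_cond("ahead", 200), clean_observer, 0)
        assert len(trace) == 1250  # 2500 ms at 500 Hz
        assert np.allclose(np.diff(trace.t_ms), 2.0)
        fix = syn.simulate_eye_trace(
            Condition(task="fixation_relative", hemifield="left", soa_ms=0),
            clean_observer, 0,
        )
        assert len(fix) == 875  # 1750 ms at 500 Hz

    def test_center_crossing_at_reference_flash(self, clean_observer):
        trace = syn.simulate_eye_trace(_cond("ahead", 200), clean_observer, 0)
        idx = np.argmin(np.abs(trace.t_ms - 1250.0))
        assert trace.x_deg[idx] == pytest.approx(0.0, abs=1e-9)

    def test_fixation_holds_zero(self, clean_observer):
        fix = syn.simulate_eye_trace(
            Condition(task="fixation_relative", hemifield="left", soa_ms=0),
            clean_observer, 0,
        )
        assert np.abs(fix.x_deg).max() == pytest.approx(0.0, abs=1e-9)

    def test_steady_state_velocity_is_gain_times_speed(self):
        obs = syn.make_observer(0, {"pursuit_gain": 1.02, "gain_sd": 0.0,
                                    "trace_noise_deg": 0.01,
                                    "saccade_rate_hz": 0.0, "blink_prob": 0.0})
        vels = []
        for seed in range(10):
            trace = syn.simulate_eye_trace(_cond("ahead", 200), obs, seed)
            win = (trace.t_ms >= 1000) & (trace.t_ms <= 1200)
            t, x = trace.t_ms[win] / 1000.0, trace.x_deg[win]
            vels.append(np.polyfit(t, x, 1)[0])
        assert np.mean(vels) == pytest.approx(10.2, abs=0.1)

    def test_leftward_pursuit_descends(self, clean_observer):
        trace = syn.simulate_eye_trace(
            _cond("ahead", 200, direction="leftward"), clean_observer, 0
        )
        assert trace.x_deg[0] > 0 > trace.x_deg[-1]

    def test_events_annotated(self):
        obs = syn.make_observer(0, {"saccade_rate_hz": 2.0, "blink_prob": 1.0})
        trace = syn.simulate_eye_trace(_cond("ahead", 200), obs, 12)
        kinds = {k for k, _, _ in trace.events}
        assert "blink" in kinds
        assert (~trace.valid).sum() >= 30  # blink run of >= 60 ms


class TestTruePse:
    @pytest.mark.parametrize("frame,expected_ahead,expected_behind", [
        ("A", 0.75, 0.75),
        ("B", 2.75, -1.25),
        ("C", 0.75 + 0.48, 0.75 - 0.52),
        ("D", 2.75 + 0.48, -1.25 - 0.52),
    ])
    def test_frame_regimes_at_positive_soa(self, frame, expected_ahead,
                                           expected_behind):
        obs = syn.make_observer(0, {"frame_model": frame})
        assert syn.true_pse(obs, _cond("ahead", 200)) == pytest.approx(expected_ahead)
        assert syn.true_pse(obs, _cond("behind", 200)) == pytest.approx(expected_behind)

    def test_soa_zero_identical_under_every_frame(self):
        for frame in "ABCD":
            obs = syn.make_observer(0, {"frame_model": frame})
            assert syn.true_pse(obs, _cond("ahead", 0)) == pytest.approx(-0.02)

    def test_ahead_behind_differences(self):
        # B/D: Ahead - Behind = 4 deg at |SOA| 200; C: 2(a_ahead + a_behind)
        for frame, expected in [("B", 4.0), ("D", 4.0 + 2 * (0.24 + 0.26)),
                                ("C", 2 * (0.24 + 0.26)), ("A", 0.0)]:
            obs = syn.make_observer(0, {"frame_model": frame})
            diff = syn.true_pse(obs, _cond("ahead", 200)) - syn.true_pse(
                obs, _cond("behind", 200))
            assert diff == pytest.approx(expected), frame

    def test_left_right_symmetry(self):
        """Mirroring direction (hence hemifield) leaves ecc-axis PSEs unchanged."""
        obs = syn.make_observer(0, {"frame_model": "D"})
        for placement in ("ahead", "behind"):
            for soa in (-200, 0, 200):
                r = syn.true_pse(obs, _cond(placement, soa, "rightward"))
                l = syn.true_pse(obs, _cond(placement, soa, "leftward"))
                assert r == pytest.approx(l)


class TestRelativeTrial:
    def test_probability_at_pse_is_half(self):
        obs = syn.make_observer(0, {"guess": 0.02, "lapse": 0.02})
        cond = _cond("ahead", 200)
        pse = syn.true_pse(obs, cond)
        offset_screen = hemifield_sign(cond.hemifield) * pse
        assert syn.p_eccentric(obs, cond, offset_screen) == pytest.approx(0.5)

    def test_saturation(self):
        obs = syn.make_observer(0, {"lapse": 0.0, "guess": 0.0})
        cond = _cond("ahead", 200)
        pse = syn.true_pse(obs, cond)
        off = hemifield_sign(cond.hemifield) * (pse + 10 * obs.sigma_deg)
        assert syn.p_eccentric(obs, cond, off) == pytest.approx(1.0, abs=1e-6)

    def test_monte_carlo_matches_closed_form(self):
        obs = syn.make_observer(0)
        cond = _cond("behind", -200, direction="leftward")
        offset = 0.7
        p = syn.p_eccentric(obs, cond, offset)
        rng = np.random.default_rng(77)
        n = 10_000
        hits = 0
        for _ in range(n):
            row = syn.simulate_relative_trial(obs, cond, offset, rng)
            ecc = row["response_right"] == (cond.hemifield.value == "right")
            hits += ecc
        se = np.sqrt(p * (1 - p) / n)
        assert hits / n == pytest.approx(p, abs=3 * se)

    def test_raw_key_respects_hemifield(self):
        # a certain 'more eccentric' judgment maps to opposite raw keys
        obs = syn.make_observer(0, {"lapse": 0.0, "guess": 0.0, "sigma_deg": 0.05})
        right = _cond("ahead", 200, "rightward")
        left = _cond("ahead", 200, "leftward")
        pse_r = syn.true_pse(obs, right)
        row_r = syn.simulate_relative_trial(obs, right, pse_r + 1.0, 0)
        row_l = syn.simulate_relative_trial(obs, left, -(pse_r + 1.0), 0)
        assert row_r["response_right"] == 1
        assert row_l["response_right"] == 0


class TestAbsoluteTrial:
    def test_ruler_roundtrip(self):
        obs = syn.make_observer(0)
        cond = _cond("behind", 200, task=Task.PURSUIT_ABSOLUTE)
        for seed in range(10):
            row, _ = syn.simulate_absolute_trial(obs, cond, seed)
            pos = syn.decode_ruler(row["reported_label"], row["ruler_labels"],
                                   row["ruler_shifted"])
            lines = syn.ruler_lines(row["ruler_shifted"])
            assert np.min(np.abs(lines - pos)) == pytest.approx(0.0)

    def test_veridical_observer_reports_nearest_line(self, clean_observer):
        from dataclasses import replace

        obs = replace(clean_observer, ecc_slope_ahead=0.0, ecc_slope_behind=0.0,
                      ecc_intercept_ahead=0.0, ecc_intercept_behind=0.0,
                      ruler_noise_deg=0.0)
        cond = _cond("ahead", 0, task=Task.PURSUIT_ABSOLUTE)
        row, _ = syn.simulate_absolute_trial(obs, cond, 3, ruler_shifted=False)
        pos = syn.decode_ruler(row["reported_label"], row["ruler_labels"], False)
        lines = syn.ruler_lines(False)
        assert pos == lines[np.argmin(np.abs(lines - 7.5))]

    def test_behind_condition_mean_matches_linear_model(self):
        """Slope 0.26 with the default intercept puts a 7.5-deg flash at 6.55."""
        obs = syn.make_observer(0, {
            "trace_noise_deg": 0.0, "saccade_rate_hz": 0.0, "blink_prob": 0.0,
            "gain_sd": 0.0, "pursuit_gain": 1.0, "ruler_noise_deg": 0.3})
        cond = _cond("behind", 0, task=Task.PURSUIT_ABSOLUTE)
        decoded = []
        for seed in range(300):
            row, _ = syn.simulate_absolute_trial(obs, cond, seed)
            pos = syn.decode_ruler(row["reported_label"], row["ruler_labels"],
                                   row["ruler_shifted"])
            decoded.append(hemifield_sign(cond.hemifield) * pos)
        assert np.mean(decoded) == pytest.approx(6.55, abs=0.15)

    def test_label_bijection_fresh_per_trial(self):
        obs = syn.make_observer(0)
        cond = _cond("ahead", 200, task=Task.PURSUIT_ABSOLUTE)
        r1, _ = syn.simulate_absolute_trial(obs, cond, 1)
        r2, _ = syn.simulate_absolute_trial(obs, cond, 2)
        assert r1["ruler_labels"] != r2["ruler_labels"]
        labels = [int(s) for s in r1["ruler_labels"].split(",")]
        assert len(labels) == 51 == len(set(labels))
        assert all(0 <= v < 100 for v in labels)


class TestGenerateDataset:
    def test_structure_and_counts(self, small_dataset):
        trials, traces, manifest = small_dataset
        assert set(trials["task"]) == {
            "fixation_relative", "pursuit_relative", "pursuit_absolute"}
        valid = trials[trials.qc_valid]
        rel = valid[(valid.task == "pursuit_relative")
                    & valid.phase.isin(["fine1", "fine2"])]
        per_cell = rel.groupby(["subject", "soa_ms", "direction", "placement"]).size()
        assert per_cell.min() >= 20
        assert len(per_cell) == 2 * 12
        absolute = valid[valid.task == "pursuit_absolute"]
        assert absolute.groupby(
            ["subject", "soa_ms", "direction", "placement"]).size().min() >= 10
        assert all(tid in traces for tid in trials.trace_id)
        assert set(manifest["observers"]) == {"1", "2"}

    def test_deterministic_reruns(self):
        kwargs = dict(
            n_subjects=1,
            counts={"pursuit_relative": 9, "fixation_relative": 16,
                    "pursuit_absolute": 4, "coarse_per_offset": 1},
            seed=9,
        )
        t1, tr1, m1 = syn.generate_dataset(**kwargs)
        t2, tr2, m2 = syn.generate_dataset(**kwargs)
        pd.testing.assert_frame_equal(t1, t2)
        assert m1 == m2
        k = next(iter(tr1))
        assert np.array_equal(tr1[k].x_deg, tr2[k].x_deg)

    def test_io_roundtrip(self, small_dataset, tmp_path):
        trials, traces, manifest = small_dataset
        syn.write_trials(trials, tmp_path / "trials.tsv")
        back = syn.read_trials(tmp_path / "trials.tsv")
        assert len(back) == len(trials)
        assert list(back.columns) == list(trials.columns)
        sub = {k: traces[k] for k in list(traces)[:5]}
        syn.write_traces(sub, tmp_path / "traces.tsv")
        back_tr = syn.read_traces(tmp_path / "traces.tsv")
        k = next(iter(sub))
        assert np.allclose(back_tr[k].x_deg, sub[k].x_deg, atol=1e-4)
        assert np.array_equal(back_tr[k].valid, sub[k].valid)
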