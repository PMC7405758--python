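"""Trial quality control: saccade/blink detection, pursuit gain, exclusions.

Exclusion rules applied to each trial:

* frame drops of the visual stimuli (a boolean input column; projector
  timing itself is not modelled);
* eye position deviating more than 2 deg from the current pursuit target or
  fixation point anywhere from 50 ms before to 50 ms after the reference
  flash;
* a saccade or blink from 100 ms before to 100 ms after either stimulus
  presentation — with the +/-200-ms SOA the union of the two windows spans
  400 ms.

Saccade detection uses a velocity threshold relative to the expected pursuit
velocity (30 deg/s default, minimum duration 8 ms, sub-threshold gaps under
20 ms merged), with Savitzky-Golay smoothed differentiation at the 500-Hz
sampling of the tracker.  Blinks are maximal invalid-sample runs of at least
20 ms, padded by 20 ms on each side.  Pursuit gain is a 20%-trimmed mean of
per-sample eye velocity in the 200-ms window around the flash, divided by
the target speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_coeffs
from scipy.stats import trim_mean

from .core import (
    Condition,
    EyeTrace,
    PURSUIT_SPEED_DEG_S,
    REFERENCE_FLASH_MS,
    SAMPLE_DT_MS,
    direction_sign,
)

#: Default saccade-detection parameters (tracker parser settings unknown;
#: these are conventional and exposed in config).
SACCADE_VELOCITY_THRESHOLD = 30.0  # deg/s relative to expected pursuit velocity
SACCADE_MIN_DURATION_MS = 8.0
SACCADE_MERGE_GAP_MS = 20.0
SAVGOL_WINDOW_SAMPLES = 9  # 18 ms at 500 Hz
SAVGOL_POLYORDER = 2

BLINK_MIN_DURATION_MS = 20.0
BLINK_PAD_MS = 20.0

DEVIATION_LIMIT_DEG = 2.0
DEVIATION_HALF_WINDOW_MS = 50.0
EVENT_HALF_WINDOW_MS = 100.0

GAIN_HALF_WINDOW_MS = 100.0
GAIN_TRIM_FRACTION = 0.2


#: Convolution kernel of the smoothed differentiator, deg/s per sample.
_SAVGOL_DERIV_KERNEL = savgol_coeffs(
    SAVGOL_WINDOW_SAMPLES, SAVGOL_POLYORDER, deriv=1,
    delta=SAMPLE_DT_MS / 1000.0, use="conv",
)


class UndefinedGainError(ValueError):
    """Raised when too much of the gain window is masked to estimate gain."""


@dataclass(frozen=True)
class QCFlags:
    frame_drop: bool = False
    deviation_exceeded: bool = False
    saccade_blink_near_flash: bool = False
    missing_trace: bool = False

    @property
    def valid(self) -> bool:
        return not (
            self.frame_drop
            or self.deviation_exceeded
            or self.saccade_blink_near_flash
            or self.missing_trace
        )


def exclusion_span_ms(soa_ms: float) -> float:
    """Total length of the saccade/blink exclusion window for a given SOA.

    Union of [flash - 100, flash + 100] for both flashes: 200 ms at SOA 0,
    400 ms at |SOA| = 200 ms.
    """
    return 2 * EVENT_HALF_WINDOW_MS + min(abs(soa_ms), 2 * EVENT_HALF_WINDOW_MS)


def _runs(mask: np.ndarray) -> list:
    """(start_index, stop_index_inclusive) of maximal True runs."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), stops.tolist()))


def expected_velocity(condition: Condition) -> float:
    """Nominal eye velocity for the trial, deg/s (0 during fixation)."""
    return direction_sign(condition.pursuit_direction) * PURSUIT_SPEED_DEG_S


def nominal_target_position(condition: Condition, t_ms: np.ndarray) -> np.ndarray:
    """Nominal fixation-point / pursuit-target trajectory on the screen axis.

    The pursuit target crosses the screen center at the reference flash
    (1250 ms) moving at 10 deg/s; the fixation point sits at 0 deg.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    v = expected_velocity(condition)
    return v * (t_ms - REFERENCE_FLASH_MS) / 1000.0


def trace_velocity(trace: EyeTrace) -> np.ndarray:
    """Savitzky-Golay smoothed derivative of gaze position, deg/s.

    Invalid samples are linearly interpolated before differentiation so blink
    gaps do not bleed spurious velocity into neighbouring samples; callers
    mask invalid spans separately.
    """
    x = trace.x_deg.astype(float).copy()
    if not trace.valid.all():
        good = trace.valid
        if good.sum() >= 2:
            x = np.interp(trace.t_ms, trace.t_ms[good], x[good])
        else:
            x = np.zeros_like(x)
    n = len(x)
    if n < SAVGOL_WINDOW_SAMPLES:
        return np.gradient(x, trace.t_ms / 1000.0)
    # FIR form of the Savitzky-Golay derivative (interior exact; edges use
    # edge-value padding, which only matters in the trial's first/last 8 ms)
    half = SAVGOL_WINDOW_SAMPLES // 2
    padded = np.concatenate((np.full(half, x[0]), x, np.full(half, x[-1])))
    return np.convolve(padded, _SAVGOL_DERIV_KERNEL, mode="valid")


def detect_saccades(
    trace: EyeTrace,
    condition: Condition = None,
    velocity_threshold: float = SACCADE_VELOCITY_THRESHOLD,
    min_duration_ms: float = SACCADE_MIN_DURATION_MS,
    expected_velocity_deg_s: float = None,
) -> list:
    """Detect saccades as super-threshold runs of pursuit-relative velocity.

    Returns ``("saccade", onset_ms, offset_ms)`` tuples.  The threshold is
    applied to |velocity - expected pursuit velocity| so steady-state pursuit
    at 10 deg/s produces no events; runs shorter than ``min_duration_ms`` are
    dropped and runs separated by less than 20 ms are merged.
    """
    if trace.valid.sum() < 2:
        warnings.warn("all-invalid trace: no saccade detection possible")
        return []
    if expected_velocity_deg_s is None:
        expected_velocity_deg_s = expected_velocity(condition) if condition else 0.0
    v = trace_velocity(trace) - expected_velocity_deg_s
    mask = np.abs(v) > velocity_threshold
    mask &= trace.valid  # blink gaps are handled by detect_blinks
    events = []
    for start, stop in _runs(mask):
        events.append([trace.t_ms[start], trace.t_ms[stop]])
    # merge runs separated by < 20 ms
    merged = []
    for ev in events:
        if merged and ev[0] - merged[-1][1] < SACCADE_MERGE_GAP_MS:
            merged[-1][1] = ev[1]
        else:
            merged.append(ev)
    return [
        ("saccade", onset, offset)
        for onset, offset in merged
        if offset - onset + SAMPLE_DT_MS >= min_duration_ms
    ]


def detect_blinks(trace: EyeTrace) -> list:
    """Blinks: maximal invalid runs >= 20 ms, padded by 20 ms on each side.

    Padded events that touch or overlap are merged.
    """
    mask = ~trace.valid
    events = []
    for start, stop in _runs(mask):
        onset, offset = trace.t_ms[start], trace.t_ms[stop]
        if offset - onset + SAMPLE_DT_MS >= BLINK_MIN_DURATION_MS:
            events.append([onset - BLINK_PAD_MS, offset + BLINK_PAD_MS])
    merged = []
    for ev in events:
        if merged and ev[0] <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], ev[1])
        else:
            merged.append(ev)
    return [("blink", onset, offset) for onset, offset in merged]


def compute_gain(
    trace: EyeTrace,
    flash_ms: float,
    target_speed: float = PURSUIT_SPEED_DEG_S,
    condition: Condition = None,
) -> float:
    """Pursuit gain around a flash: trimmed-mean eye velocity / target speed.

    Velocity samples within detected saccades or blinks in the
    [flash - 100, flash + 100] ms window are masked; a 20%-trimmed mean of
    the remainder is divided by the (signed) target speed.  Raises
    :class:`UndefinedGainError` if more than half the window is masked.
    """
    lo, hi = flash_ms - GAIN_HALF_WINDOW_MS, flash_ms + GAIN_HALF_WINDOW_MS
    if lo < trace.t_ms[0] or hi > trace.t_ms[-1]:
        raise ValueError("gain window extends beyond the trace")
    if target_speed == 0:
        raise ValueError("target speed must be nonzero")
    window = trace.window_mask(lo, hi)
    keep = window & trace.valid
    events = detect_saccades(trace, condition=condition) + detect_blinks(trace)
    for _, onset, offset in events:
        keep &= ~((trace.t_ms >= onset) & (trace.t_ms <= offset))
    if keep.sum() < 0.5 * window.sum() or keep.sum() < 2:
        raise UndefinedGainError("more than 50% of the gain window is masked")
    v = trace_velocity(trace)[keep]
    return float(trim_mean(v, GAIN_TRIM_FRACTION) / target_speed)


def _events_overlap(events: list, windows: list) -> bool:
    return any(
        onset <= hi and offset >= lo
        for _, onset, offset in events
        for lo, hi in windows
    )


def exclude_trials(
    trials: pd.DataFrame,
    traces: dict,
    velocity_threshold: float = SACCADE_VELOCITY_THRESHOLD,
) -> pd.DataFrame:
    """Apply all exclusion rules; returns the table with QC flag columns added.

    ``traces`` maps ``trace_id`` to :class:`EyeTrace`.  Adds boolean columns
    ``frame_drop``, ``deviation_exceeded``, ``saccade_blink_near_flash``,
    ``missing_trace`` and ``qc_valid``; rows are never dropped, only flagged.
    Exclusion is per-trial, hence idempotent and order-independent.
    """
    out = trials.copy()
    n = len(out)
    if "frame_drop" not in out.columns:
        out["frame_drop"] = False
    out["frame_drop"] = out["frame_drop"].fillna(False).astype(bool)
    deviation = np.zeros(n, dtype=bool)
    near_flash = np.zeros(n, dtype=bool)
    missing = np.zeros(n, dtype=bool)

    cond_cache: dict = {}
    for i, row in enumerate(out.itertuples(index=False)):
        trace = traces.get(row.trace_id)
        if trace is None:
            missing[i] = True
            warnings.warn(f"trial without trace: {row.trace_id!r}")
            continue
        ckey = (row.task, row.hemifield, getattr(row, "direction", "none"),
                getattr(row, "placement", "n/a"), row.soa_ms)
        cond = cond_cache.get(ckey)
        if cond is None:
            cond = cond_cache[ckey] = _row_condition(row)
        ref_ms = cond.reference_flash_ms
        tgt_ms = cond.target_flash_ms

        # deviation from the current fixation point / pursuit target
        dev_mask = trace.window_mask(
            ref_ms - DEVIATION_HALF_WINDOW_MS, ref_ms + DEVIATION_HALF_WINDOW_MS
        )
        target_pos = nominal_target_position(cond, trace.t_ms[dev_mask])
        dev_valid = trace.valid[dev_mask]
        dev = np.abs(trace.x_deg[dev_mask] - target_pos)
        if dev_valid.any() and np.max(dev[dev_valid]) > DEVIATION_LIMIT_DEG:
            deviation[i] = True

        # saccade / blink near either flash
        windows = [
            (ref_ms - EVENT_HALF_WINDOW_MS, ref_ms + EVENT_HALF_WINDOW_MS),
            (tgt_ms - EVENT_HALF_WINDOW_MS, tgt_ms + EVENT_HALF_WINDOW_MS),
        ]
        events = detect_saccades(
            trace, condition=cond, velocity_threshold=velocity_threshold
        ) + detect_blinks(trace)
        if _events_overlap(events, windows):
            near_flash[i] = True

    out["deviation_exceeded"] = deviation
    out["saccade_blink_near_flash"] = near_flash
    out["missing_trace"] = missing
    out["qc_valid"] = ~(
        out["frame_drop"] | deviation | near_flash | missing
    )
    return out


def _row_condition(row) -> Condition:
    return Condition(
        task=row.task,
        phase=getattr(row, "phase", "n/a"),
        hemifield=row.hemifield,
        pursuit_direction=getattr(row, "direction", "none"),
        placement=getattr(row, "placement", "n/a"),
        soa_ms=int(row.soa_ms),
    )


def qc_report(trials: pd.DataFrame) -> pd.DataFrame:
    """Counts per exclusion reason, per (task, soa, placement) condition."""
    flags = ["frame_drop", "deviation_exceeded", "saccade_blink_near_flash",
             "missing_trace"]
    keys = ["task", "soa_ms", "placement"]
    rows = []
    for key, grp in trials.groupby(keys, dropna=False):
        rec = dict(zip(keys, key))
        rec["n_trials"] = len(grp)
        rec["n_valid"] = int(grp["qc_valid"].sum())
        for f in flags:
            rec[f] = int(grp[f].sum())
        rows.append(rec)
    return pd.DataFrame(rows)
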