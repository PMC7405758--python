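"""Synthetic observers, stimulus schedules, eye traces and responses.

Emulates the three experimental designs end to end so the whole analysis
chain is testable without any recorded data:

* *fixation-relative* — 2AFC relative localization of two flashes at 7.5 deg
  eccentricity during fixation, target offsets +/-0.3, +/-1.0, +/-1.7,
  +/-2.5 deg, SOA in {-200, 0, +200} ms;
* *pursuit-relative* — the same judgment during 10 deg/s smooth pursuit,
  with an adaptive coarse (0, +/-2 .. +/-8) -> fine1 (0, +/-1 .. +/-4) ->
  fine2 (0, +/-0.5 .. +/-2) offset schedule re-centered on interim PSE
  estimates;
* *pursuit-absolute* — single-flash localization at 7.5 deg reported on a
  41-deg ruler of lines 0.8 deg apart carrying per-trial shuffled two-digit
  labels, the ruler globally shifted by 0.4 deg on half the trials.

Gaze is simulated at 500 Hz: pursuit at ``10 * gain`` deg/s (gain drawn per
trial around 1.02 +/- 0.03) crossing screen center at the reference flash,
plus white positional noise, instantaneous catch-up saccades (>= 0.8 deg,
with a refractory period) and blinks (>= 60 ms invalid runs), all annotated
with ground-truth event times.

Responses follow the same lapse-augmented cumulative-Gaussian family the
analysis fits, with the generating PSE set by the observer's reference-frame
regime (A-D): the frame model decides whether the intra-SOA eye displacement
(2 deg at 10 deg/s, 200 ms) and/or the eccentricity effect (slope ``a`` per
placement) shift the pursuit PSEs away from the fixation PSEs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd

from . import qc as qc_mod
from .core import (
    Condition,
    EyeTrace,
    Hemifield,
    Phase,
    Placement,
    PURSUIT_SPEED_DEG_S,
    PursuitDirection,
    REFERENCE_ECCENTRICITY_DEG,
    SAMPLE_DT_MS,
    SOAS_MS,
    Task,
    direction_sign,
    expected_hemifield,
    hemifield_sign,
    retinal_position,
)
from .models import FrameModel, compensation_shift, retinal_shift
from .psychometrics import quick_pse

_log = logging.getLogger(__name__)

#: Target-offset grids relative to the reference stimulus, deg (screen axis).
GRIDS = {
    (Task.FIXATION_RELATIVE, Phase.NA): (-2.5, -1.7, -1.0, -0.3, 0.3, 1.0, 1.7, 2.5),
    (Task.PURSUIT_RELATIVE, Phase.COARSE): (-8.0, -6.0, -4.0, -2.0, 0.0, 2.0, 4.0, 6.0, 8.0),
    (Task.PURSUIT_RELATIVE, Phase.FINE1): (-4.0, -3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0, 4.0),
    (Task.PURSUIT_RELATIVE, Phase.FINE2): (-2.0, -1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0),
}

RULER_MIN_DEG = -20.0
RULER_MAX_DEG = 20.0
RULER_SPACING_DEG = 0.8
RULER_SHIFT_DEG = 0.4
RULER_N_LINES = 51
RULER_N_LABELS = 100

SACCADE_MIN_AMP_DEG = 0.8
SACCADE_MAX_AMP_DEG = 1.5
SACCADE_REFRACTORY_MS = 300.0
BLINK_MIN_MS = 60.0
BLINK_MAX_MS = 150.0


class ConfigurationError(ValueError):
    """Unknown or invalid observer/generator parameter."""


@dataclass(frozen=True)
class ObserverParams:
    """Ground-truth parameters of one synthetic observer.

    Defaults are the group means of the study this generator emulates:
    fixation PSEs of 0.00 / -0.02 / +0.75 deg at SOA -200 / 0 / +200 ms,
    pursuit gain 1.02 +/- 0.03, and the representative eccentricity-effect
    slopes a_ahead = 0.24, a_behind = 0.26.  The intercepts place the
    absolute mislocalization at +2.75 deg (ahead) and -0.95 deg (behind)
    for a flash at 7.5 deg retinal eccentricity.
    """

    frame_model: FrameModel = FrameModel.C
    fixation_pse_deg: tuple = ((-200, 0.0), (0, -0.02), (200, 0.75))
    sigma_deg: float = 0.8
    lapse: float = 0.02
    guess: float = 0.02
    ecc_slope_ahead: float = 0.24
    ecc_slope_behind: float = 0.26
    ecc_intercept_ahead: float = 0.95
    ecc_intercept_behind: float = -2.90
    pursuit_gain: float = 1.02
    gain_sd: float = 0.03
    saccade_rate_hz: float = 0.3
    blink_prob: float = 0.03
    ruler_noise_deg: float = 0.5
    trace_noise_deg: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame_model", FrameModel(self.frame_model))
        if isinstance(self.fixation_pse_deg, dict):
            object.__setattr__(
                self, "fixation_pse_deg", tuple(sorted(self.fixation_pse_deg.items()))
            )
        if self.sigma_deg <= 0:
            raise ConfigurationError("sigma_deg must be positive")
        for name in ("lapse", "guess", "blink_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability")
        if self.lapse > 0.06 or self.guess > 0.06:
            raise ConfigurationError("lapse and guess must not exceed 0.06")
        if not 0.5 < self.pursuit_gain < 1.5:
            raise ConfigurationError("pursuit_gain must lie in (0.5, 1.5)")
        if self.gain_sd < 0 or self.saccade_rate_hz < 0 or self.ruler_noise_deg < 0:
            raise ConfigurationError("rates and spreads must be non-negative")

    @property
    def fixation_pse(self) -> dict:
        return dict(self.fixation_pse_deg)

    def ecc_slope(self, placement: Placement) -> float:
        return (
            self.ecc_slope_ahead
            if Placement(placement) is Placement.AHEAD
            else self.ecc_slope_behind
        )

    def ecc_intercept(self, placement: Placement) -> float:
        return (
            self.ecc_intercept_ahead
            if Placement(placement) is Placement.AHEAD
            else self.ecc_intercept_behind
        )


def make_observer(seed: int = 0, overrides: dict = None) -> ObserverParams:
    """Build an observer with defaults, applying named overrides.

    Deterministic for a fixed seed (the seed only matters when downstream
    code draws per-observer jitter; the defaults themselves are fixed).
    Unknown override names raise :class:`ConfigurationError`.
    """
    overrides = dict(overrides or {})
    known = {f.name for f in fields(ObserverParams)}
    unknown = set(overrides) - known
    if unknown:
        raise ConfigurationError(f"unknown observer fields: {sorted(unknown)}")
    if "fixation_pse_deg" in overrides and isinstance(
        overrides["fixation_pse_deg"], dict
    ):
        overrides["fixation_pse_deg"] = tuple(
            sorted(overrides["fixation_pse_deg"].items())
        )
    return ObserverParams(**overrides)


#: Between-subject SDs used by :func:`generate_dataset` (group scatter of the
#: emulated study: fixation PSE SDs 0.42/0.17/0.55 deg; slope SDs are half
#: the per-subject compensation-shift SDs 0.67/0.38).
SUBJECT_JITTER = {
    "fixation_pse_sd": {-200: 0.42, 0: 0.17, 200: 0.55},
    "a_ahead_sd": 0.335,
    "a_behind_sd": 0.19,
    "anchor_sd": 0.3,
    "sigma_sd": 0.15,
}


def _jitter_observer(base: ObserverParams, rng, jitter: dict) -> ObserverParams:
    """Draw one subject around the group means.

    Slopes are jittered around the defaults; the intercepts are re-anchored
    so the mislocalization *at the 7.5-deg reference eccentricity* stays at
    the group level (plus a small anchor jitter): subjects vary in how
    steeply mislocalization grows with eccentricity, yet all mislocalize
    ahead flashes away from and behind flashes toward the fovea there.
    """
    pse_sd = jitter.get("fixation_pse_sd", {})
    pses = tuple(
        (soa, v + rng.normal(0.0, pse_sd.get(soa, 0.0)))
        for soa, v in base.fixation_pse_deg
    )
    a_ahead = max(base.ecc_slope_ahead + rng.normal(0, jitter.get("a_ahead_sd", 0)), 0.02)
    a_behind = max(base.ecc_slope_behind + rng.normal(0, jitter.get("a_behind_sd", 0)), 0.02)
    sigma = max(base.sigma_deg + rng.normal(0, jitter.get("sigma_sd", 0)), 0.2)
    anchor_sd = jitter.get("anchor_sd", 0.0)
    ref = REFERENCE_ECCENTRICITY_DEG
    anchor_ahead = (base.ecc_intercept_ahead + base.ecc_slope_ahead * ref
                    + rng.normal(0, anchor_sd))
    anchor_behind = (base.ecc_intercept_behind + base.ecc_slope_behind * ref
                     + rng.normal(0, anchor_sd))
    return replace(
        base,
        fixation_pse_deg=pses,
        ecc_slope_ahead=a_ahead,
        ecc_slope_behind=a_behind,
        ecc_intercept_ahead=anchor_ahead - a_ahead * ref,
        ecc_intercept_behind=anchor_behind - a_behind * ref,
        sigma_deg=sigma,
    )


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------


def task_conditions(task: Task, phase: Phase = Phase.NA) -> list:
    """All design cells of a task (12 for pursuit, 6 for fixation)."""
    task = Task(task)
    conditions = []
    if task is Task.FIXATION_RELATIVE:
        for soa in SOAS_MS:
            for hemi in (Hemifield.LEFT, Hemifield.RIGHT):
                conditions.append(Condition(task=task, hemifield=hemi, soa_ms=soa))
    else:
        for soa in SOAS_MS:
            for direction in (PursuitDirection.LEFTWARD, PursuitDirection.RIGHTWARD):
                for placement in (Placement.AHEAD, Placement.BEHIND):
                    conditions.append(
                        Condition(
                            task=task,
                            phase=phase if task is Task.PURSUIT_RELATIVE else Phase.NA,
                            hemifield=expected_hemifield(direction, placement),
                            pursuit_direction=direction,
                            placement=placement,
                            soa_ms=soa,
                        )
                    )
    return conditions


def build_schedule(
    task: Task,
    phase: Phase = Phase.NA,
    center_deg: float = 0.0,
    n_per_cell: int = 1,
    seed: int = 0,
    condition: Condition = None,
) -> list:
    """Pseudo-random trial schedule: (Condition, offset_deg, ruler_shifted).

    ``center_deg`` translates the phase grid (screen-axis offsets relative to
    the reference); it is forced to 0 for the fixation task and the coarse
    phase, whose grids are absolute.  For the absolute task there is no
    offset grid; the ruler shift is balanced to exactly half the trials per
    condition (odd counts round the shifted half down).
    """
    task, phase = Task(task), Phase(phase)
    rng = np.random.default_rng(seed)
    conditions = [condition] if condition is not None else task_conditions(task, phase)
    if task in (Task.FIXATION_RELATIVE,) or phase is Phase.COARSE:
        center_deg = 0.0
    entries = []
    if task is Task.PURSUIT_ABSOLUTE:
        for cond in conditions:
            n_shift = n_per_cell // 2
            if n_per_cell % 2:
                _log.info(
                    "odd trial count %d: shifted-ruler half rounds down to %d",
                    n_per_cell, n_shift,
                )
            for j in range(n_per_cell):
                entries.append((cond, 0.0, j < n_shift))
    else:
        grid = GRIDS[(task, phase if task is Task.PURSUIT_RELATIVE else Phase.NA)]
        if n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        for cond in conditions:
            for off in grid:
                for _ in range(n_per_cell):
                    entries.append((cond, round(off + center_deg, 6), False))
    order = rng.permutation(len(entries))
    return [entries[i] for i in order]


# ---------------------------------------------------------------------------
# Eye traces
# ---------------------------------------------------------------------------


def _rng_of(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_eye_trace(
    condition: Condition, observer: ObserverParams, seed=0
) -> EyeTrace:
    """Simulate one 500-Hz gaze trace for a trial.

    Pursuit trials last 2500 ms, start at -/+12.5 deg and cross screen center
    at the 1250-ms reference flash with velocity ``10 * gain`` deg/s (gain
    drawn per trial); fixation trials last 1750 ms holding 0 deg.  White
    positional noise, instantaneous catch-up saccade steps and blink
    invalid-runs are added and annotated as ground-truth events.
    """
    rng = _rng_of(seed)
    duration = condition.trial_duration_ms
    t = np.arange(0.0, duration, SAMPLE_DT_MS)
    events = []
    if condition.is_pursuit:
        gain = observer.pursuit_gain + observer.gain_sd * rng.standard_normal()
        v = direction_sign(condition.pursuit_direction) * PURSUIT_SPEED_DEG_S * gain
        x = v * (t - condition.reference_flash_ms) / 1000.0
    else:
        x = np.zeros_like(t)
    x = x + observer.trace_noise_deg * rng.standard_normal(len(t))

    # catch-up saccades: instantaneous position steps with a refractory period
    n_sacc = rng.poisson(observer.saccade_rate_hz * duration / 1000.0)
    times = np.sort(rng.uniform(100.0, duration - 150.0, size=n_sacc))
    last = -np.inf
    for t0 in times:
        if t0 - last < SACCADE_REFRACTORY_MS:
            continue
        last = t0
        amp = rng.uniform(SACCADE_MIN_AMP_DEG, SACCADE_MAX_AMP_DEG) * rng.choice([-1, 1])
        if condition.is_pursuit:
            x[t >= t0] += amp
            events.append(("saccade", float(t0), float(t0)))
        else:
            # fixational saccade: step out, corrective step back
            t1 = t0 + rng.uniform(100.0, 250.0)
            x[(t >= t0) & (t < t1)] += amp
            events.append(("saccade", float(t0), float(t0)))
            if t1 < duration - SAMPLE_DT_MS:
                events.append(("saccade", float(t1), float(t1)))

    valid = np.ones(len(t), dtype=bool)
    if rng.random() < observer.blink_prob:
        b0 = rng.uniform(100.0, duration - BLINK_MAX_MS - 100.0)
        b1 = b0 + rng.uniform(BLINK_MIN_MS, BLINK_MAX_MS)
        valid[(t >= b0) & (t <= b1)] = False
        events.append(("blink", float(b0), float(b1)))

    return EyeTrace(t_ms=t, x_deg=x, valid=valid, events=sorted(events, key=lambda e: e[1]))


# ---------------------------------------------------------------------------
# Responses
# ---------------------------------------------------------------------------


def true_pse(observer: ObserverParams, condition: Condition) -> float:
    """Generating PSE of a relative-task cell, eccentricity axis, degrees.

    Fixation cells (and all SOA-0 cells) use the observer's fixation PSE for
    that SOA; pursuit cells add the frame-model-dependent shifts: the 2-deg
    eye displacement (frames B, D) and/or the eccentricity compensation
    2a (frames C, D), signed by the (SOA, placement) cell.
    """
    if condition.task is Task.PURSUIT_ABSOLUTE:
        raise ValueError("true_pse is defined for relative-task conditions")
    pse = observer.fixation_pse[condition.soa_ms]
    if not condition.is_pursuit or condition.soa_ms == 0:
        return pse
    frame = observer.frame_model
    placement = condition.placement
    if frame in (FrameModel.B, FrameModel.D):
        pse += retinal_shift(condition.soa_ms, PURSUIT_SPEED_DEG_S, placement)
    if frame in (FrameModel.C, FrameModel.D):
        pse += compensation_shift(
            observer.ecc_slope(placement), condition.soa_ms,
            PURSUIT_SPEED_DEG_S, placement,
        )
    return pse


def p_eccentric(observer: ObserverParams, condition: Condition, offset_deg: float) -> float:
    """P(target judged more eccentric) at a screen-axis offset from the reference."""
    offset_ecc = hemifield_sign(condition.hemifield) * offset_deg
    z = (offset_ecc - true_pse(observer, condition)) / observer.sigma_deg
    phi = 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
    return observer.guess + (1.0 - observer.guess - observer.lapse) * phi


def simulate_relative_trial(
    observer: ObserverParams, condition: Condition, offset_deg: float, seed=0
) -> dict:
    """One 2AFC trial: Bernoulli response re-expressed as the raw key press.

    The stored ``response_right`` is 1 when the observer reports the target
    (lower square) more to the *right*: in the right hemifield that is the
    'more eccentric' judgment, in the left hemifield its mirror.
    """
    rng = _rng_of(seed)
    p = p_eccentric(observer, condition, offset_deg)
    eccentric = bool(rng.random() < p)
    right = eccentric if condition.hemifield is Hemifield.RIGHT else not eccentric
    return {
        "task": condition.task.value,
        "phase": condition.phase.value,
        "hemifield": condition.hemifield.value,
        "direction": condition.pursuit_direction.value,
        "placement": condition.placement.value,
        "soa_ms": condition.soa_ms,
        "offset_deg": float(offset_deg),
        "ruler_shifted": False,
        "response_right": int(right),
        "reported_label": -1,
        "ruler_labels": "",
        "frame_drop": False,
    }


def ruler_lines(shifted: bool) -> np.ndarray:
    """Screen positions of the 51 ruler lines (0.8-deg spacing, +/-20 deg)."""
    lines = RULER_MIN_DEG + RULER_SPACING_DEG * np.arange(RULER_N_LINES)
    return lines + (RULER_SHIFT_DEG if shifted else 0.0)


def simulate_absolute_trial(
    observer: ObserverParams,
    condition: Condition,
    seed=0,
    trace: EyeTrace = None,
    ruler_shifted: bool = None,
) -> tuple:
    """One ruler-report trial of the absolute-localization task.

    The flash appears at 7.5 deg from screen center in the condition's
    hemifield; its perceived position is the actual position plus the linear
    eccentricity-effect mislocalization (evaluated at the retinal
    eccentricity implied by the eye position at flash time) plus ruler
    noise, quantized to the nearest ruler line.  The reported two-digit
    label comes from a fresh random bijection of 100 labels onto the 51
    lines, stored for decoding.
    """
    if condition.task is not Task.PURSUIT_ABSOLUTE:
        raise ValueError("absolute trials belong to the pursuit_absolute task")
    rng = _rng_of(seed)
    if trace is None:
        trace = simulate_eye_trace(condition, observer, rng)
    hemi_s = hemifield_sign(condition.hemifield)
    stim_screen = hemi_s * REFERENCE_ECCENTRICITY_DEG
    idx = int(np.argmin(np.abs(trace.t_ms - condition.target_flash_ms)))
    eye = float(trace.x_deg[idx])
    ret_ecc = retinal_position(stim_screen, eye, condition.hemifield)
    misloc_ecc = (
        observer.ecc_intercept(condition.placement)
        + observer.ecc_slope(condition.placement) * ret_ecc
        + observer.ruler_noise_deg * rng.standard_normal()
    )
    perceived_screen = stim_screen + hemi_s * misloc_ecc
    shifted = bool(rng.random() < 0.5) if ruler_shifted is None else bool(ruler_shifted)
    lines = ruler_lines(shifted)
    clamped = bool(perceived_screen < lines[0] or perceived_screen > lines[-1])
    line_idx = int(np.argmin(np.abs(lines - perceived_screen)))
    labels = rng.permutation(RULER_N_LABELS)[:RULER_N_LINES]
    return {
        "task": condition.task.value,
        "phase": condition.phase.value,
        "hemifield": condition.hemifield.value,
        "direction": condition.pursuit_direction.value,
        "placement": condition.placement.value,
        "soa_ms": condition.soa_ms,
        "offset_deg": 0.0,
        "ruler_shifted": shifted,
        "response_right": -1,
        "reported_label": int(labels[line_idx]),
        "ruler_labels": ",".join(f"{v:02d}" for v in labels),
        "ruler_clamped": clamped,
        "frame_drop": False,
    }, trace


def decode_ruler(reported_label: int, ruler_labels: str, ruler_shifted: bool) -> float:
    """Decode a reported two-digit label back to its ruler-line screen position."""
    labels = [int(s) for s in str(ruler_labels).split(",")]
    line_idx = labels.index(int(reported_label))
    return float(ruler_lines(bool(ruler_shifted))[line_idx])


# ---------------------------------------------------------------------------
# Full datasets
# ---------------------------------------------------------------------------

DEFAULT_COUNTS = {
    "pursuit_relative": 150,  # min valid trials per (SOA x direction x placement)
    "fixation_relative": 150,  # min valid trials per SOA (hemifields pooled)
    "pursuit_absolute": 50,  # min valid trials per cell
    "coarse_per_offset": 3,  # coarse-phase repetitions per grid offset
}


def _simulate_batch(
    observer, subject, entries, seed, counter_start
) -> tuple:
    """Simulate trials+traces for schedule entries; returns (rows, traces)."""
    rows, traces = [], {}
    counter = counter_start
    for cond, offset, shifted in entries:
        rng = np.random.default_rng([seed, subject, counter])
        trace_id = f"s{subject:02d}_t{counter:06d}"
        if cond.task is Task.PURSUIT_ABSOLUTE:
            row, trace = simulate_absolute_trial(observer, cond, rng, ruler_shifted=shifted)
        else:
            trace = simulate_eye_trace(cond, observer, rng)
            row = simulate_relative_trial(observer, cond, offset, rng)
        row["subject"] = subject
        row["trace_id"] = trace_id
        rows.append(row)
        traces[trace_id] = trace
        counter += 1
    return rows, traces, counter


def _valid_counts(df: pd.DataFrame, keys: list) -> dict:
    v = df[df["qc_valid"]]
    if v.empty:
        return {}
    return v.groupby(keys).size().to_dict()


def generate_dataset(
    n_subjects: int = 8,
    observer_spec: dict = None,
    counts: dict = None,
    seed: int = 0,
    jitter: dict = None,
    top_up: bool = True,
) -> tuple:
    """Generate a complete synthetic experiment for ``n_subjects`` observers.

    Per subject: the adaptive coarse -> fine1 -> fine2 pursuit-relative
    sweep (fine centers chosen from interim PSE fits, rounded to the fine
    grid spacing), the fixation-relative block, and the absolute block.  QC
    exclusion runs on everything generated; with ``top_up`` the generator
    adds trials until the requested minimum *valid* counts per cell are met.

    Returns ``(trials, traces, manifest)``: a trial table with QC flags, a
    ``trace_id -> EyeTrace`` store, and a manifest holding the seed and each
    observer's ground-truth parameters.
    """
    counts = {**DEFAULT_COUNTS, **(counts or {})}
    observer_spec = dict(observer_spec or {})
    jitter = SUBJECT_JITTER if jitter is None else jitter
    base = make_observer(seed, observer_spec)
    all_rows, all_traces, observers = [], {}, {}

    for subject in range(1, n_subjects + 1):
        srng = np.random.default_rng([seed, subject, 999_983])
        observer = _jitter_observer(base, srng, jitter) if jitter else base
        observers[subject] = observer
        counter = 0
        sub_rows: list = []

        def run(entries):
            nonlocal counter
            rows, traces, counter = _simulate_batch(
                observer, subject, entries, seed, counter
            )
            df = pd.DataFrame(rows)
            df = qc_mod.exclude_trials(df, traces)
            all_traces.update(traces)
            sub_rows.append(df)
            return df

        # --- pursuit-relative: coarse sweep, one schedule per cell ------
        coarse_cells = task_conditions(Task.PURSUIT_RELATIVE, Phase.COARSE)
        coarse_df = run(
            build_schedule(
                Task.PURSUIT_RELATIVE, Phase.COARSE,
                n_per_cell=counts["coarse_per_offset"],
                seed=int(np.random.default_rng([seed, subject, 1]).integers(2**31)),
            )
        )
        centers1 = _interim_centers(coarse_df, coarse_cells, round_to=1.0)

        # --- fine1, centered per cell on the coarse PSE ------------------
        fine1_cells = task_conditions(Task.PURSUIT_RELATIVE, Phase.FINE1)
        fine1_entries = []
        for cond in fine1_cells:
            center = centers1.get(_cell_key(cond), 0.0)
            fine1_entries += build_schedule(
                Task.PURSUIT_RELATIVE, Phase.FINE1, center_deg=center,
                n_per_cell=max(1, counts["pursuit_relative"] // 18),
                seed=int(np.random.default_rng([seed, subject, 2]).integers(2**31)),
                condition=cond,
            )
        fine1_df = run(fine1_entries)
        centers2 = _interim_centers(fine1_df, fine1_cells, round_to=0.5)

        # --- fine2, centered on the fine1 PSE ----------------------------
        fine2_cells = task_conditions(Task.PURSUIT_RELATIVE, Phase.FINE2)

        def fine2_entries(n_per_cell):
            entries = []
            for cond in fine2_cells:
                center = centers2.get(_cell_key(cond), 0.0)
                entries += build_schedule(
                    Task.PURSUIT_RELATIVE, Phase.FINE2, center_deg=center,
                    n_per_cell=n_per_cell,
                    seed=int(np.random.default_rng([seed, subject, 3]).integers(2**31)),
                    condition=cond,
                )
            return entries

        run(fine2_entries(max(1, counts["pursuit_relative"] // 18)))

        # --- fixation block ----------------------------------------------
        n_fix = max(1, int(np.ceil(counts["fixation_relative"] / 16)))
        run(
            build_schedule(
                Task.FIXATION_RELATIVE, n_per_cell=n_fix,
                seed=int(np.random.default_rng([seed, subject, 4]).integers(2**31)),
            )
        )

        # --- absolute block ----------------------------------------------
        run(
            build_schedule(
                Task.PURSUIT_ABSOLUTE, n_per_cell=counts["pursuit_absolute"],
                seed=int(np.random.default_rng([seed, subject, 5]).integers(2**31)),
            )
        )

        # --- top up cells short of their valid-count minima ---------------
        if top_up:
            for _ in range(20):
                df = pd.concat(sub_rows, ignore_index=True)
                extra = []
                rel = df[df["task"] == Task.PURSUIT_RELATIVE.value]
                rel = rel[rel["phase"].isin(["fine1", "fine2"])]
                got = _valid_counts(rel, ["soa_ms", "direction", "placement"])
                for cond in fine2_cells:
                    short = counts["pursuit_relative"] - got.get(
                        (cond.soa_ms, cond.pursuit_direction.value,
                         cond.placement.value), 0)
                    if short > 0:
                        center = centers2.get(_cell_key(cond), 0.0)
                        extra += build_schedule(
                            Task.PURSUIT_RELATIVE, Phase.FINE2, center_deg=center,
                            n_per_cell=max(1, int(np.ceil(short / 9))),
                            seed=counter, condition=cond,
                        )
                fix = df[df["task"] == Task.FIXATION_RELATIVE.value]
                got = _valid_counts(fix, ["soa_ms"])
                for soa in SOAS_MS:
                    short = counts["fixation_relative"] - got.get(soa, 0)
                    if short > 0:
                        for cond in task_conditions(Task.FIXATION_RELATIVE):
                            if cond.soa_ms == soa:
                                extra += build_schedule(
                                    Task.FIXATION_RELATIVE,
                                    n_per_cell=max(1, int(np.ceil(short / 16))),
                                    seed=counter, condition=cond,
                                )
                absdf = df[df["task"] == Task.PURSUIT_ABSOLUTE.value]
                got = _valid_counts(absdf, ["soa_ms", "direction", "placement"])
                for cond in task_conditions(Task.PURSUIT_ABSOLUTE):
                    short = counts["pursuit_absolute"] - got.get(
                        (cond.soa_ms, cond.pursuit_direction.value,
                         cond.placement.value), 0)
                    if short > 0:
                        extra += build_schedule(
                            Task.PURSUIT_ABSOLUTE, n_per_cell=short,
                            seed=counter, condition=cond,
                        )
                if not extra:
                    break
                run(extra)

        all_rows.append(pd.concat(sub_rows, ignore_index=True))

    trials = pd.concat(all_rows, ignore_index=True)
    manifest = {
        "seed": int(seed),
        "n_subjects": int(n_subjects),
        "counts": counts,
        "observers": {
            str(s): observer_to_dict(obs) for s, obs in observers.items()
        },
    }
    return trials, all_traces, manifest


def _cell_key(cond: Condition) -> tuple:
    return (cond.soa_ms, cond.pursuit_direction.value, cond.placement.value)


def _interim_centers(df: pd.DataFrame, cells: list, round_to: float) -> dict:
    """Quick per-cell PSE estimates, rounded to the next phase's grid spacing.

    Centers are computed on the eccentricity axis and converted back to
    screen-axis offsets (relative to the reference) for schedule building.
    """
    centers = {}
    valid = df[df["qc_valid"]] if "qc_valid" in df.columns else df
    for cond in cells:
        cell = valid[
            (valid["soa_ms"] == cond.soa_ms)
            & (valid["direction"] == cond.pursuit_direction.value)
            & (valid["placement"] == cond.placement.value)
        ]
        if len(cell) < 8:
            centers[_cell_key(cond)] = 0.0
            continue
        sign = hemifield_sign(cond.hemifield)
        offsets = cell["offset_deg"].to_numpy(float) * sign
        resp = (
            cell["response_right"].astype(bool)
            == (cond.hemifield is Hemifield.RIGHT)
        ).astype(int).to_numpy()
        levels, inv = np.unique(np.round(offsets, 6), return_inverse=True)
        k = np.bincount(inv, weights=resp, minlength=len(levels)).astype(int)
        n = np.bincount(inv, minlength=len(levels))
        from .psychometrics import BinnedResponses

        pse_ecc = quick_pse(BinnedResponses(levels=levels, k=k, n=n))
        center_ecc = round_to * round(pse_ecc / round_to)
        centers[_cell_key(cond)] = sign * center_ecc
    return centers


def observer_to_dict(obs: ObserverParams) -> dict:
    d = {}
    for f in fields(ObserverParams):
        v = getattr(obs, f.name)
        if isinstance(v, FrameModel):
            v = v.value
        elif isinstance(v, tuple):
            v = {str(k): val for k, val in v}
        d[f.name] = v
    return d


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_trials(path) -> pd.DataFrame:
    # keep_default_na: the phase/placement value 'n/a' is data, not missing
    df = pd.read_csv(
        path, sep="\t", dtype={"ruler_labels": str},
        keep_default_na=False, na_values=[""],
    )
    df["ruler_labels"] = df["ruler_labels"].fillna("")
    return df


def write_traces(traces: dict, path) -> None:
    """Write the trace store as one long delimited table."""
    frames = []
    for trace_id, trace in traces.items():
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": trace_id,
                    "t_ms": trace.t_ms,
                    "x_deg": trace.x_deg,
                    "valid": trace.valid.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_traces(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {
        tid: EyeTrace(
            t_ms=grp["t_ms"].to_numpy(float),
            x_deg=grp["x_deg"].to_numpy(float),
            valid=grp["valid"].to_numpy(bool),
        )
        for tid, grp in df.groupby("trace_id", sort=False)
    }


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
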