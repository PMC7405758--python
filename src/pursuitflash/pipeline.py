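"""End-to-end orchestration: generate -> QC -> fit -> models -> stats.

:func:`run_pipeline` executes the whole analysis on a synthetic (or loaded)
dataset and writes a delimited-text report bundle: the PSE table, the
eccentricity / compensation-shift table (with a Mean +/- SD row), the
model-comparison report, the statistical test table with Holm flags, and a
JSON run manifest.  Identical config and seed produce byte-identical
outputs; any stage failure removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import default_config
from .core import (
    Hemifield,
    Placement,
    PURSUIT_SPEED_DEG_S,
    REFERENCE_ECCENTRICITY_DEG,
    SOAS_MS,
    Task,
    hemifield_sign,
)
from .models import (
    FrameModel,
    evaluate_model,
    fit_eccentricity,
    predict_pse,
    select_model,
)
from .psychometrics import average_lr, bootstrap_pse_ci, fit_psychometric, pool_trials
from .stats import apply_holm, paired_t, summarize_shift_table
from .synthetic import (
    decode_ruler,
    generate_dataset,
    write_manifest,
    write_trials,
)


class PipelineError(RuntimeError):
    """A stage of the pipeline failed; carries the stage label."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Stage: absolute-task preparation
# ---------------------------------------------------------------------------


def prepare_absolute_table(trials: pd.DataFrame, traces: dict) -> pd.DataFrame:
    """Decode ruler reports and attach retinal eccentricity at flash time.

    Keeps QC-valid absolute-task trials; adds ``perceived_deg`` (decoded
    ruler line, screen axis), ``mislocalization_deg`` (perceived - actual on
    the eccentricity axis) and ``retinal_ecc_deg`` (target eccentricity
    relative to the fovea at the flash, measured from the trace).
    """
    df = trials[trials["task"] == Task.PURSUIT_ABSOLUTE.value]
    if "qc_valid" in df.columns:
        df = df[df["qc_valid"]]
    df = df.copy()
    perceived, ret_ecc = [], []
    for row in df.itertuples(index=False):
        pos = decode_ruler(row.reported_label, row.ruler_labels, row.ruler_shifted)
        perceived.append(pos)
        trace = traces[row.trace_id]
        flash_ms = 1250.0 + row.soa_ms
        idx = int(np.argmin(np.abs(trace.t_ms - flash_ms)))
        hemi_s = hemifield_sign(Hemifield(row.hemifield))
        stim = hemi_s * REFERENCE_ECCENTRICITY_DEG
        ret_ecc.append(hemi_s * (stim - trace.x_deg[idx]))
    df["perceived_deg"] = perceived
    df["retinal_ecc_deg"] = ret_ecc
    hemi_s = df["hemifield"].map(lambda h: hemifield_sign(Hemifield(h)))
    actual = hemi_s * REFERENCE_ECCENTRICITY_DEG
    df["mislocalization_deg"] = hemi_s * (df["perceived_deg"] - actual)
    return df


# ---------------------------------------------------------------------------
# Stage: psychometric fitting
# ---------------------------------------------------------------------------


def fit_all_psychometrics(
    trials: pd.DataFrame, n_boot: int = 0, seed: int = 0
) -> pd.DataFrame:
    """Per-subject PSE table for the fixation and pursuit relative tasks.

    Fixation: one fit per SOA on hemifield-pooled data.  Pursuit: one fit per
    (SOA x direction x placement), parameters then averaged across the two
    directions, yielding one row per (SOA x placement).  ``n_boot > 0`` adds
    bootstrap 95% CIs.
    """
    rows = []
    for subject, sub in trials.groupby("subject"):
        for task in (Task.FIXATION_RELATIVE, Task.PURSUIT_RELATIVE):
            binned = pool_trials(sub, task)
            if task is Task.FIXATION_RELATIVE:
                for key, data in sorted(binned.items()):
                    fit = fit_psychometric(data)
                    if n_boot and fit.converged:
                        ci = bootstrap_pse_ci(
                            data, fit, n_boot,
                            seed=_cell_seed(seed, subject, key),
                        )
                    else:
                        ci = fit.pse_ci95
                    rows.append(_pse_row(subject, task, key[0], None, fit, ci))
            else:
                for soa in SOAS_MS:
                    for placement in ("ahead", "behind"):
                        fits, cis = [], []
                        for direction in ("leftward", "rightward"):
                            key = (soa, direction, placement)
                            if key not in binned:
                                continue
                            fit = fit_psychometric(binned[key])
                            if n_boot and fit.converged:
                                ci = bootstrap_pse_ci(
                                    binned[key], fit, n_boot,
                                    seed=_cell_seed(seed, subject, key),
                                )
                                fit = _with_ci(fit, ci)
                            fits.append(fit)
                        if not fits:
                            continue
                        avg = average_lr(*fits) if len(fits) == 2 else average_lr(fits[0])
                        rows.append(
                            _pse_row(subject, task, soa, placement, avg, avg.pse_ci95)
                        )
    return pd.DataFrame(rows)


def _with_ci(fit, ci):
    from dataclasses import replace

    return replace(fit, pse_ci95=tuple(ci))


def _cell_seed(seed: int, subject: int, key: tuple) -> int:
    h = hashlib.blake2s(repr((seed, subject, key)).encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2**31)


def _pse_row(subject, task, soa, placement, fit, ci):
    return {
        "subject": subject,
        "task": Task(task).value,
        "soa_ms": int(soa),
        "placement": placement,
        "pse": fit.pse,
        "sigma": fit.sigma,
        "guess": fit.guess,
        "lapse": fit.lapse,
        "ci_lo": ci[0],
        "ci_hi": ci[1],
        "n_trials": fit.n_trials,
        "converged": fit.converged,
    }


# ---------------------------------------------------------------------------
# Stage: eccentricity fits and model comparison
# ---------------------------------------------------------------------------


def eccentricity_fits_by_subject(absolute_table: pd.DataFrame) -> dict:
    """{subject: {Placement: EccentricityFit}} from prepared absolute trials."""
    return {
        subject: fit_eccentricity(grp)
        for subject, grp in absolute_table.groupby("subject")
    }


def compensation_table(ecc_fits: dict) -> pd.DataFrame:
    """Per-subject compensation shifts 2a per placement, plus a Mean/SD row.

    The tabulated values are the PSE shifts (speed * |SOA| / 1000 * a at the
    +200-ms SOA) signed as for the (positive SOA) cells: positive ahead,
    negative behind.
    """
    rows = []
    for subject, fits in sorted(ecc_fits.items()):
        rows.append(
            {
                "subject": str(subject),
                "ahead": 2.0 * fits[Placement.AHEAD].slope,
                "behind": -2.0 * fits[Placement.BEHIND].slope,
                "a_ahead": fits[Placement.AHEAD].slope,
                "a_behind": fits[Placement.BEHIND].slope,
            }
        )
    df = pd.DataFrame(rows)
    if len(df) < 2:  # a single subject has no group scatter to summarize
        return df
    summary = summarize_shift_table(df[["ahead", "behind"]])
    mean_row = {"subject": "mean", "ahead": summary["ahead"][0],
                "behind": summary["behind"][0],
                "a_ahead": df["a_ahead"].mean(), "a_behind": df["a_behind"].mean()}
    sd_row = {"subject": "sd", "ahead": summary["ahead"][1],
              "behind": summary["behind"][1],
              "a_ahead": df["a_ahead"].std(ddof=1),
              "a_behind": df["a_behind"].std(ddof=1)}
    return pd.concat([df, pd.DataFrame([mean_row, sd_row])], ignore_index=True)


def model_predictions(pse_table: pd.DataFrame, ecc_fits: dict) -> pd.DataFrame:
    """Predicted and measured pursuit PSEs per subject x (SOA != 0) x placement."""
    fix = pse_table[pse_table["task"] == Task.FIXATION_RELATIVE.value]
    pur = pse_table[pse_table["task"] == Task.PURSUIT_RELATIVE.value]
    rows = []
    for subject in sorted(pse_table["subject"].unique()):
        sfix = fix[fix["subject"] == subject].set_index("soa_ms")["pse"]
        spur = pur[pur["subject"] == subject]
        fits = ecc_fits.get(subject)
        if fits is None:
            continue
        for soa in (-200, 200):
            for placement in (Placement.AHEAD, Placement.BEHIND):
                cell = spur[
                    (spur["soa_ms"] == soa) & (spur["placement"] == placement.value)
                ]
                if cell.empty or soa not in sfix.index:
                    continue
                a = fits[placement].slope
                rec = {
                    "subject": subject,
                    "soa_ms": soa,
                    "placement": placement.value,
                    "measured": float(cell["pse"].iloc[0]),
                    "fixation_pse": float(sfix[soa]),
                }
                for model in FrameModel:
                    rec[f"pred_{model.value}"] = predict_pse(
                        model, sfix[soa], soa, placement, a, PURSUIT_SPEED_DEG_S
                    )
                rows.append(rec)
    return pd.DataFrame(rows)


def compare_models(
    predictions: pd.DataFrame, distance: str = "perpendicular"
) -> tuple:
    """Evaluate all four models and rank them; returns (report_df, ranking)."""
    evaluations = []
    for model in FrameModel:
        ev = evaluate_model(
            model,
            predictions[f"pred_{model.value}"].to_numpy(),
            predictions["measured"].to_numpy(),
            distance=distance,
        )
        evaluations.append(ev)
    ranking = select_model(evaluations)
    report = pd.DataFrame(
        [
            {
                "model": ev.model.value,
                "slope": ev.slope,
                "pearson_r": ev.pearson_r,
                "d_mean": ev.d_mean,
                "d_sd": ev.d_sd,
                "n_points": ev.n_points,
                "rank": ranking.index(ev) + 1,
            }
            for ev in evaluations
        ]
    )
    return report, ranking


# ---------------------------------------------------------------------------
# Stage: statistics
# ---------------------------------------------------------------------------


def run_test_battery(pse_table: pd.DataFrame, battery: list, alpha: float = 0.05):
    """Paired t tests between PSE cells named by the declarative battery."""
    results = []
    for spec in battery:
        a = _cell_series(pse_table, *spec["a"])
        b = _cell_series(pse_table, *spec["b"])
        joined = pd.concat([a, b], axis=1, join="inner").dropna()
        if len(joined) < 2:
            continue
        results.append(
            paired_t(
                joined.iloc[:, 0], joined.iloc[:, 1],
                tails=spec.get("tails", "two"), label=spec["label"],
            )
        )
    return apply_holm(results, alpha)


def _cell_series(pse_table, task, soa, placement) -> pd.Series:
    df = pse_table[(pse_table["task"] == task) & (pse_table["soa_ms"] == soa)]
    if placement is None:
        df = df[df["placement"].isna()]
    else:
        df = df[df["placement"] == placement]
    return df.set_index("subject")["pse"]


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: dict = None) -> dict:
    """Execute the full pipeline and write the report bundle to ``outdir``.

    Returns a dict with the in-memory results (``trials``, ``pse_table``,
    ``ecc_table``, ``model_report``, ``ranking``, ``tests``, ``manifest``).
    """
    cfg = default_config()
    if config:
        from .config import _deep_update

        _deep_update(cfg, config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        stage = "generate"
        if cfg.get("trials_path"):
            from .synthetic import read_traces, read_trials

            trials = read_trials(cfg["trials_path"])
            traces = read_traces(cfg["traces_path"])
            manifest = {"seed": cfg["seed"], "source": str(cfg["trials_path"])}
            if "qc_valid" not in trials.columns:
                stage = "qc"
                from .qc import exclude_trials

                trials = exclude_trials(
                    trials, traces,
                    velocity_threshold=cfg["qc"]["saccade_velocity_threshold"],
                )
        else:
            trials, traces, manifest = generate_dataset(
                n_subjects=cfg["n_subjects"],
                observer_spec=cfg["observer"],
                counts=cfg["counts"],
                seed=cfg["seed"],
            )

        stage = "qc_report"
        from .qc import qc_report

        qc_counts = qc_report(trials)

        stage = "psychometrics"
        pse_table = fit_all_psychometrics(
            trials, n_boot=cfg["n_boot"], seed=cfg["seed"]
        )

        stage = "localization_models"
        abs_table = prepare_absolute_table(trials, traces)
        ecc_fits = eccentricity_fits_by_subject(abs_table)
        ecc_table = compensation_table(ecc_fits)
        predictions = model_predictions(pse_table, ecc_fits)
        model_report, ranking = compare_models(
            predictions, distance=cfg["distance_metric"]
        )

        stage = "stats"
        tests = run_test_battery(pse_table, cfg["tests"], cfg["alpha"])
        tests_df = pd.DataFrame([t.__dict__ for t in tests])

        stage = "report"
        fmt = {"sep": "\t", "index": False, "float_format": "%.6g"}
        for name, df in [
            ("qc_report.tsv", qc_counts),
            ("pse_table.tsv", pse_table),
            ("eccentricity_table.tsv", ecc_table),
            ("model_predictions.tsv", predictions),
            ("model_comparison.tsv", model_report),
            ("tests.tsv", tests_df),
        ]:
            path = outdir / name
            df.to_csv(path, **fmt)
            written.append(path)
        run_manifest = {
            "version": __version__,
            "seed": cfg["seed"],
            "config_hash": hashlib.sha256(
                json.dumps(cfg, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "generator": manifest,
        }
        write_manifest(run_manifest, outdir / "manifest.json")
        written.append(outdir / "manifest.json")
        if not cfg.get("trials_path"):
            write_trials(trials, outdir / "trials.tsv")
            written.append(outdir / "trials.tsv")
    except Exception as exc:  # remove partial outputs, re-raise with stage
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise PipelineError(stage, exc) from exc

    return {
        "trials": trials,
        "traces": traces,
        "qc_report": qc_counts,
        "pse_table": pse_table,
        "absolute_table": abs_table,
        "ecc_fits": ecc_fits,
        "ecc_table": ecc_table,
        "predictions": predictions,
        "model_report": model_report,
        "ranking": ranking,
        "tests": tests,
        "manifest": run_manifest,
        "outdir": outdir,
    }
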