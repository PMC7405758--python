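"""Reference-frame models of relative flash mislocalization during pursuit.

During smooth pursuit the eye moves ~2 deg between two flashes separated by a
200-ms SOA (10 deg/s x 0.2 s).  Four models predict the pursuit-condition PSE
from the fixation-condition PSE of the same subject and SOA:

* Model A — head-/screen-centered frame, no eccentricity effect: the pursuit
  PSE equals the fixation PSE.
* Model B — eye-centered frame: the intra-SOA eye displacement shifts the
  retinocentric frame, adding a signed 2 deg to the fixation PSE.
* Model C — head-/screen-centered frame plus an eccentricity effect: the two
  flashes land at retinal eccentricities differing by 2 deg, and absolute
  mislocalization grows linearly with retinal eccentricity (slope ``a`` from
  the absolute-localization regression), adding a signed ``2a``.
* Model D — eye-centered frame plus the eccentricity effect (both shifts).

The sign of both shifts depends on SOA sign and flash placement (ahead of or
behind the pursuit target): positive for (positive SOA, ahead) and (negative
SOA, behind), negative for the other two cells; zero at SOA 0, where all four
models coincide.

Model predictions are evaluated against measured pursuit PSEs by regressing
predicted on measured, the Pearson correlation, and the mean pointwise
distance ``d`` of the (measured, predicted) points to the identity line.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import Placement, PURSUIT_SPEED_DEG_S


class FrameModel(str, enum.Enum):
    A = "A"  # screen-centered, no eccentricity effect
    B = "B"  # eye-centered, no eccentricity effect
    C = "C"  # screen-centered + eccentricity effect
    D = "D"  # eye-centered + eccentricity effect


@dataclass(frozen=True)
class EccentricityFit:
    """Linear regression of absolute mislocalization on retinal eccentricity.

    ``slope`` is the eccentricity effect ``a``: degrees of mislocalization per
    degree of retinal eccentricity; ``intercept`` in degrees on the
    eccentricity axis.
    """

    placement: Placement
    slope: float
    intercept: float
    n_points: int
    r2: float

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("eccentricity fit needs >= 2 points")


@dataclass(frozen=True)
class ModelEvaluation:
    """Fig-6-style agreement of one model's predictions with measured PSEs."""

    model: FrameModel
    slope: float
    intercept: float
    pearson_r: float
    d_mean: float
    d_sd: float
    n_points: int


class DegenerateRegressionError(ValueError):
    """Raised when a regression has no identifiable slope."""


# ---------------------------------------------------------------------------
# Shifts
# ---------------------------------------------------------------------------


def signed_condition_factor(soa_ms: float, placement: Placement) -> int:
    """Sign of the pursuit-induced PSE shifts for a (SOA, placement) cell.

    +1 for (positive SOA, ahead) and (negative SOA, behind); -1 for the two
    mirror cells; 0 for simultaneous presentation (SOA 0), where the eye does
    not move between the flashes.
    """
    if soa_ms == 0:
        return 0
    placement = Placement(placement)
    if placement is Placement.NA:
        raise ValueError("placement must be ahead or behind")
    ahead = placement is Placement.AHEAD
    positive = soa_ms > 0
    return 1 if ahead == positive else -1


def retinal_shift(
    soa_ms: float,
    speed: float = PURSUIT_SPEED_DEG_S,
    placement: Placement = Placement.AHEAD,
    fraction: float = 1.0,
) -> float:
    """Signed displacement of an eye-centered frame over the SOA, degrees.

    ``speed * |SOA|`` scaled by ``fraction`` (1.0 = full eye displacement;
    0.5 models a frame moving at half the eye speed) and signed by
    :func:`signed_condition_factor`.  Equals +/-2 deg at 10 deg/s and 200 ms.
    """
    if abs(fraction) > 1:
        raise ValueError("fraction must lie in [-1, 1]")
    return (
        signed_condition_factor(soa_ms, placement)
        * speed
        * abs(soa_ms)
        / 1000.0
        * fraction
    )


def compensation_shift(
    a: float,
    soa_ms: float,
    speed: float = PURSUIT_SPEED_DEG_S,
    placement: Placement = Placement.AHEAD,
) -> float:
    """PSE shift compensating the eccentricity effect of the intra-SOA eye move.

    The eye displacement ``speed * |SOA|`` changes the target's retinal
    eccentricity relative to the reference; with mislocalization slope ``a``
    per degree of eccentricity the compensating PSE shift is
    ``sign * (speed * |SOA| / 1000) * a`` — i.e. +/-2a at the design's
    10 deg/s and 200 ms.
    """
    if not np.isfinite(a):
        raise ValueError("slope a must be finite")
    if abs(soa_ms) > 500:
        raise ValueError("|SOA| above 500 ms is outside the supported design")
    return signed_condition_factor(soa_ms, placement) * speed * abs(soa_ms) / 1000.0 * a


def predict_pse(
    model: FrameModel,
    fixation_pse: float,
    soa_ms: float,
    placement: Placement,
    a: float = 0.0,
    speed: float = PURSUIT_SPEED_DEG_S,
) -> float:
    """Predicted pursuit-condition PSE for one subject/cell under a model."""
    model = FrameModel(model)
    pse = float(fixation_pse)
    if model in (FrameModel.B, FrameModel.D):
        pse += retinal_shift(soa_ms, speed, placement)
    if model in (FrameModel.C, FrameModel.D):
        pse += compensation_shift(a, soa_ms, speed, placement)
    return pse


# ---------------------------------------------------------------------------
# Eccentricity regression (absolute-localization task)
# ---------------------------------------------------------------------------


def fit_eccentricity(absolute_trials: pd.DataFrame) -> dict:
    """Per-placement OLS of mislocalization on retinal eccentricity.

    Expects QC-valid absolute-task trials with columns ``placement``,
    ``retinal_ecc_deg`` (target eccentricity on the retina at flash time) and
    ``mislocalization_deg`` (decoded perceived minus actual position on the
    eccentricity axis).  Trials from shifted and unshifted ruler halves are
    pooled.  Returns ``{Placement.AHEAD: EccentricityFit, Placement.BEHIND: ...}``
    for the placements present.
    """
    required = {"placement", "retinal_ecc_deg", "mislocalization_deg"}
    missing = required - set(absolute_trials.columns)
    if missing:
        raise KeyError(f"absolute trial table lacks columns: {sorted(missing)}")
    fits: dict = {}
    for placement, grp in absolute_trials.groupby("placement", sort=True):
        placement = Placement(placement)
        x = np.asarray(grp["retinal_ecc_deg"], dtype=float)
        y = np.asarray(grp["mislocalization_deg"], dtype=float)
        if len(np.unique(x)) < 2:
            raise DegenerateRegressionError(
                f"{placement.value}: a single eccentricity level cannot "
                "identify a slope"
            )
        res = sps.linregress(x, y)
        fits[placement] = EccentricityFit(
            placement=placement,
            slope=float(res.slope),
            intercept=float(res.intercept),
            n_points=len(x),
            r2=float(res.rvalue) ** 2,
        )
    return fits


# ---------------------------------------------------------------------------
# Model evaluation and selection
# ---------------------------------------------------------------------------


def evaluate_model(
    model: FrameModel,
    predicted: np.ndarray,
    measured: np.ndarray,
    distance: str = "perpendicular",
) -> ModelEvaluation:
    """Agreement of predicted with measured PSEs across subject x condition cells.

    Regresses predicted on measured (OLS), computes Pearson r, and the mean
    and SD of the pointwise distances of the (measured, predicted) points to
    the identity line: perpendicular distance ``|p - m|/sqrt(2)`` by default,
    or vertical distance ``|p - m|`` with ``distance='vertical'``.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape or predicted.ndim != 1:
        raise ValueError("predicted and measured must be equal-length 1-D arrays")
    if len(predicted) < 3:
        raise ValueError("need >= 3 matched points")
    if np.ptp(measured) == 0:
        raise DegenerateRegressionError("measured PSEs have zero variance")
    if distance not in ("perpendicular", "vertical"):
        raise ValueError("distance must be 'perpendicular' or 'vertical'")
    res = sps.linregress(measured, predicted)
    dev = np.abs(predicted - measured)
    if distance == "perpendicular":
        dev = dev / np.sqrt(2.0)
    return ModelEvaluation(
        model=FrameModel(model),
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        d_mean=float(dev.mean()),
        d_sd=float(dev.std(ddof=1)) if len(dev) > 1 else 0.0,
        n_points=len(predicted),
    )


def select_model(evaluations: list) -> list:
    """Rank model evaluations: ascending d_mean, ties broken by |slope - 1|.

    Returns the full ranking (stable for exact ties), never a bare winner.
    """
    if len(evaluations) < 1:
        raise ValueError("need at least one evaluation")
    return sorted(evaluations, key=lambda ev: (ev.d_mean, abs(ev.slope - 1.0)))
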