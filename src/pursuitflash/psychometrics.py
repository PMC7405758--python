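"""Trial pooling and maximum-likelihood cumulative-Gaussian PSE estimation.

The psychometric model for a 2AFC "target more eccentric" judgment at signed
offset ``x`` (eccentricity axis, degrees) is the lapse-augmented cumulative
Gaussian

    psi(x) = gamma + (1 - gamma - lambda) * Phi((x - m) / sigma)

with location ``m``, spread ``sigma``, guess rate ``gamma`` and lapse rate
``lambda`` free within [0, 0.06].  The PSE is ``m``, the offset at which
``psi`` reaches the midpoint between its asymptotes; a positive PSE means the
target had to be shown more eccentric than the reference to be perceived at
the same eccentricity.  Fits maximize the binomial log-likelihood with
multistart L-BFGS-B; 95% confidence intervals come from a nonparametric
bootstrap over per-level binomial counts.

Pooling follows the design: fixation trials from the left and right
hemifield are mirrored onto the eccentricity axis and pooled before fitting
(one fit per SOA); pursuit trials pool the two fine phases per
(SOA x direction x placement) cell, are fitted per direction, and the fitted
parameters are then averaged across leftward and rightward pursuit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

from .core import Hemifield, Task

ASYMPTOTE_MAX = 0.06
SIGMA_BOUNDS = (0.05, 20.0)
PSE_MARGIN_DEG = 5.0
N_MULTISTART = 5
N_BOOT_DEFAULT = 999


@dataclass(frozen=True)
class BinnedResponses:
    """Per-level 2AFC counts for one condition cell, on the eccentricity axis."""

    levels: np.ndarray  # distinct sorted signed offsets, deg
    k: np.ndarray  # count judged "target more eccentric"
    n: np.ndarray  # trials per level
    key: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", np.asarray(self.levels, dtype=float))
        object.__setattr__(self, "k", np.asarray(self.k, dtype=int))
        object.__setattr__(self, "n", np.asarray(self.n, dtype=int))
        if not (len(self.levels) == len(self.k) == len(self.n)):
            raise ValueError("levels, k, n must have equal length")
        if (np.diff(self.levels) <= 0).any():
            raise ValueError("levels must be distinct and sorted")
        if ((self.k < 0) | (self.k > self.n)).any():
            raise ValueError("need 0 <= k <= n at every level")


@dataclass(frozen=True)
class PsychometricFit:
    pse: float
    sigma: float
    guess: float
    lapse: float
    loglik: float
    pse_ci95: tuple = (-np.inf, np.inf)
    converged: bool = True
    n_trials: int = 0
    key: tuple = ()
    flags: tuple = ()


def psi(x, pse: float, sigma: float, guess: float = 0.0, lapse: float = 0.0):
    """The psychometric function psi(x); accepts scalars or arrays."""
    return guess + (1.0 - guess - lapse) * ndtr((np.asarray(x, float) - pse) / sigma)


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------


def recode_eccentric(trials: pd.DataFrame) -> pd.Series:
    """Recode raw left/right responses to 'target judged more eccentric'.

    The stored response is the raw key press ``response_right`` (1 = "lower
    [target] stimulus seen more to the right").  In the right hemifield more
    rightward means more eccentric; in the left hemifield it is the mirror.
    """
    right = trials["hemifield"].map(lambda h: Hemifield(h) is Hemifield.RIGHT)
    resp = trials["response_right"].astype(bool)
    return (resp == right).astype(int)


def _bin(offsets: np.ndarray, ecc_resp: np.ndarray, key: tuple) -> BinnedResponses:
    levels, inv = np.unique(np.round(offsets, 6), return_inverse=True)
    k = np.bincount(inv, weights=ecc_resp, minlength=len(levels)).astype(int)
    n = np.bincount(inv, minlength=len(levels))
    return BinnedResponses(levels=levels, k=k, n=n, key=key)


def pool_trials(trials: pd.DataFrame, task: Task) -> dict:
    """Pool QC-valid relative-task trials into per-cell binned responses.

    Fixation: left/right hemifields mirrored and pooled; keys ``(soa_ms,)``.
    Pursuit: fine1 + fine2 pooled; keys ``(soa_ms, direction, placement)``,
    fits per direction (parameter averaging across directions happens
    downstream in :func:`average_lr`).
    """
    task = Task(task)
    df = trials[trials["task"] == task.value]
    if "qc_valid" in df.columns:
        df = df[df["qc_valid"]]
    if task is Task.PURSUIT_RELATIVE:
        df = df[df["phase"].isin(["fine1", "fine2"])]
    if df.empty:
        return {}
    df = df.copy()
    ecc_resp = recode_eccentric(df).to_numpy()
    # target offset relative to the reference, mirrored onto the ecc axis
    sign = df["hemifield"].map(
        lambda h: 1.0 if Hemifield(h) is Hemifield.RIGHT else -1.0
    ).to_numpy()
    offsets = df["offset_deg"].to_numpy(float) * sign

    out: dict = {}
    if task is Task.FIXATION_RELATIVE:
        for soa, idx in df.groupby("soa_ms").indices.items():
            out[(int(soa),)] = _bin(offsets[idx], ecc_resp[idx], (int(soa),))
    else:
        for (soa, direction, placement), idx in df.groupby(
            ["soa_ms", "direction", "placement"]
        ).indices.items():
            key = (int(soa), direction, placement)
            out[key] = _bin(offsets[idx], ecc_resp[idx], key)
    return out


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------


_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _negloglik(params, levels, k, n):
    m, s, g, l = params
    p = g + (1.0 - g - l) * ndtr((levels - m) / s)
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))


def _negloglik_grad(params, levels, k, n):
    """Binomial negative log-likelihood and its analytic gradient."""
    m, s, g, l = params
    z = (levels - m) / s
    cdf = ndtr(z)
    pdf = np.exp(-0.5 * z * z) / _SQRT_2PI
    span = 1.0 - g - l
    p = np.clip(g + span * cdf, 1e-9, 1 - 1e-9)
    nll = -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))
    dldp = -(k / p - (n - k) / (1.0 - p))
    grad = np.array([
        np.sum(dldp * (-span * pdf / s)),
        np.sum(dldp * (-span * pdf * z / s)),
        np.sum(dldp * (1.0 - cdf)),
        np.sum(dldp * (-cdf)),
    ])
    return nll, grad


def _start_points(data: BinnedResponses) -> list:
    """Quantile-based heuristics for multistart initialisation."""
    frac = data.k / np.maximum(data.n, 1)
    span = data.levels[-1] - data.levels[0] if len(data.levels) > 1 else 1.0
    # interpolated crossing of 0.5 (monotone surrogate via cumulative max)
    mono = np.maximum.accumulate(frac)
    m0 = float(np.interp(0.5, np.clip(mono, 0, 1), data.levels))
    s_lo = float(np.interp(0.25, np.clip(mono, 0, 1), data.levels))
    s_hi = float(np.interp(0.75, np.clip(mono, 0, 1), data.levels))
    s0 = max((s_hi - s_lo) / 1.349, 0.1)
    starts = [
        (m0, s0, 0.01, 0.01),
        (m0, max(span / 4.0, 0.1), 0.02, 0.02),
        (float(np.average(data.levels, weights=np.maximum(data.n, 1))),
         max(span / 2.0, 0.2), 0.0, 0.0),
        (m0 - span / 8.0, s0 * 2.0, 0.03, 0.0),
        (m0 + span / 8.0, max(s0 / 2.0, 0.08), 0.0, 0.03),
    ]
    return starts


def fit_psychometric(
    data: BinnedResponses, n_starts: int = N_MULTISTART
) -> PsychometricFit:
    """MLE cumulative-Gaussian fit of one condition cell.

    Degenerate data (responses all 0 or all 1) cannot localise the PSE and
    yield a non-converged fit with an infinite CI.
    """
    if len(data.levels) < 4:
        raise ValueError("need >= 4 distinct stimulus levels")
    total_k, total_n = int(data.k.sum()), int(data.n.sum())
    key = data.key
    if total_k == 0 or total_k == total_n:
        return PsychometricFit(
            pse=float(data.levels[0] if total_k == total_n else data.levels[-1]),
            sigma=float(np.ptp(data.levels)) or 1.0,
            guess=0.0, lapse=0.0, loglik=0.0,
            pse_ci95=(-np.inf, np.inf), converged=False,
            n_trials=total_n, key=key, flags=("degenerate",),
        )
    lo = float(data.levels[0]) - PSE_MARGIN_DEG
    hi = float(data.levels[-1]) + PSE_MARGIN_DEG
    bounds = [(lo, hi), SIGMA_BOUNDS, (0.0, ASYMPTOTE_MAX), (0.0, ASYMPTOTE_MAX)]
    args = (data.levels, data.k.astype(float), data.n.astype(float))
    best = None
    for start in _start_points(data)[:n_starts]:
        start = (
            float(np.clip(start[0], lo, hi)),
            float(np.clip(start[1], *SIGMA_BOUNDS)),
            start[2], start[3],
        )
        res = minimize(
            _negloglik_grad, start, args=args, jac=True,
            method="L-BFGS-B", bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    m, s, g, l = best.x
    return PsychometricFit(
        pse=float(m), sigma=float(s), guess=float(g), lapse=float(l),
        loglik=float(-best.fun), converged=bool(best.success),
        n_trials=total_n, key=key,
    )


def bootstrap_pse_ci(
    data: BinnedResponses,
    fit: PsychometricFit,
    n_boot: int = N_BOOT_DEFAULT,
    seed: int = 0,
) -> tuple:
    """Nonparametric bootstrap percentile 95% CI for the PSE.

    Resamples per-level binomial counts from the observed proportions,
    refits (warm-started at the point fit), and takes the 2.5/97.5
    percentiles.  If more than 20% of refits fail to converge the interval
    is widened by 50% around its midpoint and a warning is issued.
    """
    if not fit.converged:
        raise ValueError("cannot bootstrap a non-converged fit")
    rng = np.random.default_rng(seed)
    phat = data.k / np.maximum(data.n, 1)
    pses, failures = [], 0
    warm = (fit.pse, fit.sigma, fit.guess, fit.lapse)
    lo = float(data.levels[0]) - PSE_MARGIN_DEG
    hi = float(data.levels[-1]) + PSE_MARGIN_DEG
    bounds = [(lo, hi), SIGMA_BOUNDS, (0.0, ASYMPTOTE_MAX), (0.0, ASYMPTOTE_MAX)]
    for _ in range(n_boot):
        k_b = rng.binomial(data.n, phat)
        if k_b.sum() == 0 or k_b.sum() == data.n.sum():
            failures += 1
            continue
        args = (data.levels, k_b.astype(float), data.n.astype(float))
        res = minimize(
            _negloglik_grad, warm, args=args, jac=True,
            method="L-BFGS-B", bounds=bounds,
        )
        if not res.success:
            failures += 1
            continue
        pses.append(res.x[0])
    if not pses:
        return (-np.inf, np.inf)
    ci = tuple(np.percentile(pses, [2.5, 97.5]))
    if failures > 0.2 * n_boot:
        warnings.warn(
            f"{failures}/{n_boot} bootstrap refits failed; widening interval"
        )
        mid, half = (ci[0] + ci[1]) / 2.0, (ci[1] - ci[0]) / 2.0
        ci = (mid - 1.5 * half, mid + 1.5 * half)
    return (float(ci[0]), float(ci[1]))


def average_lr(fit_a: PsychometricFit, fit_b: PsychometricFit = None) -> PsychometricFit:
    """Average fitted parameters across leftward and rightward pursuit.

    Arithmetic mean of PSE, sigma, guess and lapse; the CI is the
    conservative union hull of the two intervals.  With one side missing the
    other is passed through with a flag.
    """
    if fit_b is None:
        return replace(fit_a, flags=fit_a.flags + ("lr_missing",))
    return PsychometricFit(
        pse=(fit_a.pse + fit_b.pse) / 2.0,
        sigma=(fit_a.sigma + fit_b.sigma) / 2.0,
        guess=(fit_a.guess + fit_b.guess) / 2.0,
        lapse=(fit_a.lapse + fit_b.lapse) / 2.0,
        loglik=fit_a.loglik + fit_b.loglik,
        pse_ci95=(
            min(fit_a.pse_ci95[0], fit_b.pse_ci95[0]),
            max(fit_a.pse_ci95[1], fit_b.pse_ci95[1]),
        ),
        converged=fit_a.converged and fit_b.converged,
        n_trials=fit_a.n_trials + fit_b.n_trials,
        key=tuple(x if x == y else "lr" for x, y in zip(fit_a.key, fit_b.key)),
    )


def quick_pse(data: BinnedResponses) -> float:
    """Fast single-start PSE point estimate (used for adaptive centering)."""
    if len(data.levels) < 2:
        return float(data.levels[0]) if len(data.levels) else 0.0
    total_k, total_n = int(data.k.sum()), int(data.n.sum())
    if total_k == 0:
        return float(data.levels[-1])
    if total_k == total_n:
        return float(data.levels[0])
    lo = float(data.levels[0]) - PSE_MARGIN_DEG
    hi = float(data.levels[-1]) + PSE_MARGIN_DEG
    bounds = [(lo, hi), SIGMA_BOUNDS]
    start = _start_points(data)[0][:2]
    start = (float(np.clip(start[0], lo, hi)), float(np.clip(start[1], *SIGMA_BOUNDS)))

    def nll(p):
        f, g = _negloglik_grad((p[0], p[1], 0.0, 0.0), data.levels,
                               data.k.astype(float), data.n.astype(float))
        return f, g[:2]

    res = minimize(nll, start, jac=True, method="L-BFGS-B", bounds=bounds)
    return float(res.x[0])
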