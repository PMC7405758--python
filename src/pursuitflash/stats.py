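"""Inferential statistics: paired t tests, Cohen's dz, Holm step-down.

Effect sizes follow the within-subject convention dz = |t| / sqrt(n); the
sequential-Bonferroni (Holm) procedure orders the p values ascending and
compares the i-th smallest to alpha / (m - i + 1), stopping at the first
failure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    label: str
    t: float
    df: int
    p: float
    dz: float
    tails: str  # 'one' or 'two'
    holm_significant: bool = False
    holm_alpha: float = float("nan")


def cohens_dz(t: float, n: int) -> float:
    """Within-subject effect size |t| / sqrt(n) for a paired t test."""
    if n < 1:
        raise ValueError("n must be positive")
    return abs(t) / np.sqrt(n)


def paired_t(x, y, tails: str = "two", label: str = "") -> TestResult:
    """Paired-sample t test on x - y with dz attached.

    ``tails='one'`` halves the two-sided p (the directional hypothesis is
    taken to be the observed direction of the mean difference).  Differences
    with zero variance leave t undefined and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D samples with n >= 2")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing pairs are not allowed")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: t undefined")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    res = sps.ttest_rel(x, y)
    n = len(x)
    p = float(res.pvalue) / (2.0 if tails == "one" else 1.0)
    return TestResult(
        label=label,
        t=float(res.statistic),
        df=n - 1,
        p=p,
        dz=float(cohens_dz(res.statistic, n)),
        tails=tails,
    )


def one_sample_t(x, popmean: float = 0.0, tails: str = "two", label: str = "") -> TestResult:
    """One-sample t test of a (difference) sample against ``popmean``."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D sample with n >= 2")
    if np.allclose(x.std(ddof=1), 0.0):
        raise ValueError("zero-variance sample: t undefined")
    res = sps.ttest_1samp(x, popmean)
    n = len(x)
    p = float(res.pvalue) / (2.0 if tails == "one" else 1.0)
    return TestResult(
        label=label, t=float(res.statistic), df=n - 1, p=p,
        dz=float(cohens_dz(res.statistic, n)), tails=tails,
    )


def holm_correction(p_values, alpha: float = 0.05) -> list:
    """Holm step-down decisions, mapped back to input order.

    Returns ``[(significant, adjusted_alpha), ...]``: the i-th smallest p is
    compared to ``alpha / (m - i + 1)``; once one fails, all larger p values
    fail too.
    """
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    decisions = [None] * m
    failed = False
    for rank, idx in enumerate(order):
        thresh = alpha / (m - rank)
        ok = (not failed) and (p[idx] <= thresh)
        if not ok:
            failed = True
        decisions[idx] = (bool(ok), float(thresh))
    return decisions


def apply_holm(results: list, alpha: float = 0.05) -> list:
    """Attach Holm decisions to a battery of :class:`TestResult`."""
    decisions = holm_correction([r.p for r in results], alpha)
    return [
        replace(r, holm_significant=sig, holm_alpha=thr)
        for r, (sig, thr) in zip(results, decisions)
    ]


def summarize_shift_table(per_subject_shifts) -> dict:
    """Mean and sample SD (n - 1) per column of a per-subject shift table.

    Accepts a DataFrame or a mapping column -> values; returns
    ``{column: (mean, sd)}``.
    """
    import pandas as pd

    df = pd.DataFrame(per_subject_shifts)
    if len(df) < 2:
        raise ValueError("need >= 2 subjects")
    return {
        col: (float(df[col].mean()), float(df[col].std(ddof=1)))
        for col in df.columns
    }
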