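"""Outcome metrics: SR, BR, throughput, the Fitts CT-ID regression and IP.

Success rate and break rate are plain trial-count fractions.  Throughput
averages ID/CT over successful trials (CT is undefined for failures).  The
speed-accuracy trade-off is summarized by ordinary least squares of mean CT
per ID on ID; the index of performance is the inverse regression slope,
in bits/s.  Percent changes between condition means use the plain relative
difference, 100 * (comparison - reference) / reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .emg import InvalidInputError
from .task import TrialResult

__all__ = [
    "BlockSummary",
    "success_rate",
    "break_rate",
    "throughput",
    "fitts_regression",
    "index_of_performance",
    "relative_change",
    "summarize_block",
    "anova_two_way",
]


@dataclass(frozen=True)
class BlockSummary:
    """Per-condition summary of one block of trials.

    sr, br : success and break fractions in [0, 1] (sr + br <= 1).
    tp : throughput, bits/s (NaN when no trial succeeded).
    slope, intercept, r2 : CT-ID regression (s/bit, s, -); NaN when fewer
        than two IDs have successes.
    ip : index of performance, 1/slope, bits/s (NaN for slope <= 0).
    """

    sr: float
    br: float
    tp: float
    slope: float
    intercept: float
    r2: float
    ip: float
    n_trials: int


def _check_nonempty(results: Sequence[TrialResult]) -> None:
    if len(results) == 0:
        raise InvalidInputError("metrics require at least one trial")


def success_rate(results: Sequence[TrialResult]) -> float:
    """Successful trials / total trials."""
    _check_nonempty(results)
    return sum(r.success for r in results) / len(results)


def break_rate(results: Sequence[TrialResult]) -> float:
    """Breakage failures / total trials (timeouts are not breaks)."""
    _check_nonempty(results)
    return sum(r.outcome == "break" for r in results) / len(results)


def throughput(results: Sequence[TrialResult]) -> float:
    """Mean of ID_i / CT_i over successful trials, bits/s.

    NaN when no trial succeeded (throughput is then undefined).
    """
    _check_nonempty(results)
    ratios = [r.id_bits / r.ct for r in results if r.success]
    if not ratios:
        return math.nan
    return float(np.mean(ratios))


def fitts_regression(
    results: Sequence[TrialResult], per_id_means: bool = True
) -> tuple[float, float, float]:
    """OLS of completion time on index of difficulty.

    By default CT is first averaged within each ID (matching a 6-point
    Fitts plot); ``per_id_means=False`` fits raw successful trials instead.
    Returns (slope s/bit, intercept s, R^2).  Requires successes at >= 2
    distinct IDs.  Zero CT variance yields slope 0 and, by convention,
    R^2 = 0 (no variance explained).
    """
    _check_nonempty(results)
    ok = [r for r in results if r.success]
    ids = np.array([r.id_bits for r in ok])
    cts = np.array([r.ct for r in ok])
    if np.unique(ids).size < 2:
        raise InvalidInputError(
            "CT-ID regression requires successes at >= 2 distinct IDs"
        )
    if per_id_means:
        uniq = np.unique(ids)
        x = uniq
        y = np.array([cts[ids == u].mean() for u in uniq])
    else:
        x, y = ids, cts
    if np.allclose(y, y[0]):
        return 0.0, float(y[0]), 0.0
    fit = _stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def index_of_performance(slope: float) -> float:
    """IP = 1/slope, bits/s; NaN for non-positive slope (undefined)."""
    if slope <= 0 or not math.isfinite(slope):
        return math.nan
    return 1.0 / slope


def relative_change(reference: float, comparison: float) -> float:
    """Percent change of ``comparison`` relative to ``reference``."""
    if reference == 0:
        raise InvalidInputError("relative change undefined for zero reference")
    return 100.0 * (comparison - reference) / reference


def summarize_block(results: Sequence[TrialResult]) -> BlockSummary:
    """All block metrics, mutually consistent (ip = 1/slope, tp as above)."""
    _check_nonempty(results)
    try:
        slope, intercept, r2 = fitts_regression(results)
    except InvalidInputError:
        slope = intercept = r2 = math.nan
    return BlockSummary(
        sr=success_rate(results),
        br=break_rate(results),
        tp=throughput(results),
        slope=slope,
        intercept=intercept,
        r2=r2,
        ip=index_of_performance(slope) if math.isfinite(slope) else math.nan,
        n_trials=len(results),
    )


def anova_two_way(table) -> "pandas.DataFrame":  # noqa: F821
    """Thin two-way ANOVA helper on a per-trial long table.

    ``table`` needs columns ``emg``, ``feedback`` and ``value``.  Delegates
    to statsmodels OLS + anova_lm; provided for exploratory use on simulated
    trial logs (the original factorial analysis concerned human subjects).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("value ~ C(emg) * C(feedback)", data=table).fit()
    return sm.stats.anova_lm(model, typ=2)
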