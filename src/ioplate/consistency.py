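"""Evaluation statistics: split-half consistency, peak likelihood,
band-power correlation, and paired treatment comparison.

The split-half coefficient of variation (CV) asks how repeatable a severity
estimate is within one recording: the analyzed epochs are split into first
and second halves, the statistic is computed on each, and the CV of the pair
(sample SD over mean, equal to sqrt(2) |a-b| / (a+b)) is reported.  A
locomotion-adjusted severity should be more consistent (lower CV) than raw
tremor power, whose halves differ whenever activity drifts.

Treatment comparisons are paired Wilcoxon signed-rank tests on per-subject
severities, reported together with the change in IOP-band (locomotor) power
so a true tremolytic effect can be told apart from sedation: sedation lowers
raw tremor power but leaves the normalized severity unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError
from .spectral import find_peak

__all__ = [
    "CVReport",
    "CorrelationResult",
    "TreatmentEffect",
    "split_half_cv",
    "peak_window_likelihood",
    "correlate_bands",
    "treatment_effect",
]


@dataclass
class CVReport:
    """Split-half coefficient of variation of a per-epoch statistic."""

    method: str
    half1: float
    half2: float
    cv: float
    n_epochs: tuple  # (n first half, n second half)


@dataclass
class CorrelationResult:
    """Pearson correlation with t statistic and Fisher-z 95% CI."""

    r: float
    ci95: tuple
    n: int
    t_stat: float
    p_value: float


@dataclass
class TreatmentEffect:
    """Paired pre/post comparison of severities (Wilcoxon signed-rank)."""

    median_diff: float
    p_value: float
    statistic: float
    n: int
    pre_median: float
    post_median: float
    activity_median_diff: float | None = None
    activity_p_value: float | None = None


def split_half_cv(severity_per_epoch, method: str = "") -> CVReport:
    """CV between first- and second-half mean severities of one recording.

    Odd epoch counts give the extra epoch to the first half.  With only two
    values a and b, the sample-SD/mean CV reduces to sqrt(2)|a-b|/(a+b).
    """
    s = np.asarray(severity_per_epoch, dtype=float)
    if len(s) < 2:
        raise InsufficientDataError("need >= 2 epochs for a split-half CV")
    n1 = (len(s) + 1) // 2
    a = float(s[:n1].mean())
    b = float(s[n1:].mean())
    if a + b == 0:
        raise InvalidInputError("undefined CV: both half means are zero")
    cv = math.sqrt(2.0) * abs(a - b) / (a + b)
    return CVReport(method=method, half1=a, half2=b, cv=cv,
                    n_epochs=(n1, len(s) - n1))


def peak_window_likelihood(spectra, window: tuple = (15.0, 25.0),
                           search: tuple = (2.0, 30.0)) -> float:
    """Fraction of spectra whose concave peak over ``search`` lands in ``window``.

    A spectrum counts as a hit when :func:`find_peak` over the analyzed range
    finds a peak and its frequency lies inside the (closed) target window.
    """
    spectra = list(spectra)
    if not spectra:
        raise InsufficientDataError("empty spectra list")
    hits = 0
    for spec in spectra:
        peak = find_peak(spec, *search)
        if peak.found and window[0] - 1e-9 <= peak.freq <= window[1] + 1e-9:
            hits += 1
    return hits / len(spectra)


def correlate_bands(band_a_per_epoch, band_b_per_epoch) -> CorrelationResult:
    """Pearson correlation of two per-epoch band-power series."""
    a = np.asarray(band_a_per_epoch, dtype=float)
    b = np.asarray(band_b_per_epoch, dtype=float)
    if len(a) != len(b):
        raise InvalidInputError("series lengths differ")
    if len(a) < 3:
        raise InsufficientDataError("need >= 3 epochs to correlate")
    if np.std(a) == 0 or np.std(b) == 0:
        raise InvalidInputError("undefined correlation: a series has zero variance")
    res = stats.pearsonr(a, b)
    r = float(res.statistic)
    n = len(a)
    if abs(r) >= 1.0:
        t = math.inf if r != 0 else 0.0
        ci = (r, r)
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        z = math.atanh(r)
        se = 1.0 / math.sqrt(n - 3)
        ci = (math.tanh(z - 1.959963984540054 * se),
              math.tanh(z + 1.959963984540054 * se))
    return CorrelationResult(r=r, ci95=ci, n=n, t_stat=float(t),
                             p_value=float(res.pvalue))


def treatment_effect(
    pre_severities,
    post_severities,
    pre_activity=None,
    post_activity=None,
) -> TreatmentEffect:
    """Paired pre/post comparison with optional locomotor-activity context.

    ``pre_activity`` / ``post_activity`` are per-subject IOP-band powers;
    when given, their paired comparison is reported alongside so a drop in
    raw tremor caused by sedation (activity also drops, severity does not)
    can be distinguished from true tremor suppression.
    """
    pre = np.asarray(pre_severities, dtype=float)
    post = np.asarray(post_severities, dtype=float)
    if len(pre) != len(post):
        raise InvalidInputError(
            f"unpaired lengths: {len(pre)} pre vs {len(post)} post"
        )
    if len(pre) < 5:
        raise InsufficientDataError("need >= 5 pairs for the signed-rank test")
    diff = post - pre
    if np.all(diff == 0):
        stat, p = 0.0, 1.0
    else:
        res = stats.wilcoxon(pre, post)
        stat, p = float(res.statistic), float(res.pvalue)
    act_diff = act_p = None
    if pre_activity is not None and post_activity is not None:
        pa = np.asarray(pre_activity, dtype=float)
        qa = np.asarray(post_activity, dtype=float)
        if len(pa) != len(qa) or len(pa) != len(pre):
            raise InvalidInputError("activity series must pair with severities")
        act_diff = float(np.median(qa - pa))
        if np.all(qa - pa == 0):
            act_p = 1.0
        else:
            act_p = float(stats.wilcoxon(pa, qa).pvalue)
    return TreatmentEffect(
        median_diff=float(np.median(diff)), p_value=p, statistic=stat,
        n=len(pre), pre_median=float(np.median(pre)),
        post_median=float(np.median(post)),
        activity_median_diff=act_diff, activity_p_value=act_p,
    )
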