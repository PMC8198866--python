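"""Accuracy and precision statistics for method comparison.

The framework compares each single-sensor method's per-participant mean
daily sedentary time against the dual-sensor reference with
Bland-Altman statistics: the **bias** (mean of paired differences,
accuracy at the group level) and the **95% limits of agreement**
(bias ± 1.96 SD of the differences, precision at the individual level),
each with standard errors and t-based confidence intervals. When the
differences depend on the mean of the two methods, the regression
approach replaces the constant bias/LoA with mean-dependent ones.
Supporting measures: relative bias (% of the reference mean), root mean
square error, and the Pearson correlation with a Fisher-z interval.
A daytime analysis repeats the Bland-Altman comparison per 30-min clock
bin, separately for weekdays and weekend days, reporting only bins with
data from at least 80% of the cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import timedelta
from typing import Mapping

import numpy as np
from scipy import stats as sps

from .classification import ClassifiedTimeline, Label
from .errors import InsufficientSampleError
from .preprocessing import WearMask, day_bounds, n_calendar_days

__all__ = [
    "AgreementStats",
    "RegressionAgreement",
    "IntervalAgreement",
    "bland_altman",
    "regression_approach",
    "rmse_and_correlation",
    "daytime_interval_analysis",
]

LOA_MULTIPLIER = 1.96  # classic Bland-Altman; a t-based variant is a config switch
RESIDUAL_LOA_MULTIPLIER = 2.46  # regression approach: LoA(m) = bias(m) ± 2.46·(c0+c1·m)


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman agreement of one method against the reference."""

    n: int
    bias: float
    bias_se: float
    bias_ci: tuple[float, float]
    loa_lower: float
    loa_upper: float
    loa_se: float
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    sd_diff: float
    relative_bias_pct: float
    rmse: float
    pearson_r: float
    pearson_ci: tuple[float, float]
    r_defined: bool
    proportional_bias: bool = False

    @property
    def loa_width(self) -> float:
        return self.loa_upper - self.loa_lower


def _pearson_with_ci(a: np.ndarray, b: np.ndarray, alpha: float = 0.05):
    if a.std() == 0 or b.std() == 0:
        return float("nan"), (float("nan"), float("nan")), False
    r = float(np.corrcoef(a, b)[0, 1])
    n = len(a)
    if n < 4 or abs(r) >= 1.0:
        return r, (r, r), True
    z = np.arctanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zc = sps.norm.ppf(1 - alpha / 2)
    return r, (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))), True


def bland_altman(
    method: np.ndarray,
    reference: np.ndarray,
    loa_multiplier: float = LOA_MULTIPLIER,
) -> AgreementStats:
    """Constant Bland-Altman agreement statistics.

    Differences are method − reference. SE(bias) = SD/√n;
    LoA = bias ± 1.96·SD with SE(LoA) = √(3·SD²/n); 95% CIs use t(n−1).
    The relative bias is the bias as a percentage of the reference mean.
    """
    m = np.asarray(method, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape or m.ndim != 1:
        raise ValueError("method and reference must be 1-d arrays of equal length")
    n = len(m)
    if n < 3:
        raise InsufficientSampleError(f"need >= 3 paired values, got {n}")
    d = m - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    se_bias = sd / math.sqrt(n)
    se_loa = math.sqrt(3.0 * sd * sd / n)
    tc = float(sps.t.ppf(0.975, n - 1))
    loa_lo = bias - loa_multiplier * sd
    loa_hi = bias + loa_multiplier * sd
    rmse = float(np.sqrt(np.mean(d * d)))
    pr, pci, pdef = _pearson_with_ci(m, r)
    ref_mean = float(r.mean())
    return AgreementStats(
        n=n,
        bias=bias,
        bias_se=se_bias,
        bias_ci=(bias - tc * se_bias, bias + tc * se_bias),
        loa_lower=loa_lo,
        loa_upper=loa_hi,
        loa_se=se_loa,
        loa_lower_ci=(loa_lo - tc * se_loa, loa_lo + tc * se_loa),
        loa_upper_ci=(loa_hi - tc * se_loa, loa_hi + tc * se_loa),
        sd_diff=sd,
        relative_bias_pct=100.0 * bias / ref_mean if ref_mean != 0 else float("nan"),
        rmse=rmse,
        pearson_r=pr,
        pearson_ci=pci,
        r_defined=pdef,
    )


@dataclass(frozen=True)
class RegressionAgreement:
    """Mean-dependent bias/LoA from the regression approach.

    When neither slope is significant the object reduces exactly to the
    constant Bland-Altman statistics in ``constant``.
    """

    constant: AgreementStats
    bias_intercept: float
    bias_slope: float
    bias_slope_p: float
    resid_intercept: float
    resid_slope: float
    resid_slope_p: float
    proportional_bias: bool
    proportional_loa: bool

    def bias_at(self, mean_value: float) -> float:
        if self.proportional_bias:
            return self.bias_intercept + self.bias_slope * mean_value
        return self.constant.bias

    def loa_at(self, mean_value: float) -> tuple[float, float]:
        b = self.bias_at(mean_value)
        if self.proportional_loa:
            half = RESIDUAL_LOA_MULTIPLIER * (
                self.resid_intercept + self.resid_slope * mean_value
            )
        else:
            half = LOA_MULTIPLIER * self.constant.sd_diff
        return b - half, b + half


def regression_approach(
    method: np.ndarray,
    reference: np.ndarray,
    alpha: float = 0.05,
) -> RegressionAgreement:
    """Bland-Altman regression approach for mean-dependent bias/LoA.

    The differences d are regressed on the pairwise means m; if the
    slope is significant (two-sided test at ``alpha``), the bias becomes
    b0 + b1·m. The absolute residuals are regressed on m in turn; if that
    slope is significant, the LoA become bias(m) ± 2.46·(c0 + c1·m).
    Otherwise each part falls back to the constant estimates.
    """
    m_arr = np.asarray(method, dtype=float)
    r_arr = np.asarray(reference, dtype=float)
    const = bland_altman(m_arr, r_arr)
    d = m_arr - r_arr
    means = (m_arr + r_arr) / 2.0
    if means.std() == 0:
        return RegressionAgreement(
            constant=const,
            bias_intercept=const.bias,
            bias_slope=0.0,
            bias_slope_p=1.0,
            resid_intercept=const.sd_diff,
            resid_slope=0.0,
            resid_slope_p=1.0,
            proportional_bias=False,
            proportional_loa=False,
        )
    fit = sps.linregress(means, d)
    prop_bias = fit.pvalue < alpha
    resid = d - (fit.intercept + fit.slope * means)
    rfit = sps.linregress(means, np.abs(resid))
    prop_loa = rfit.pvalue < alpha
    const = AgreementStats(
        **{**const.__dict__, "proportional_bias": bool(prop_bias)}
    )
    return RegressionAgreement(
        constant=const,
        bias_intercept=float(fit.intercept),
        bias_slope=float(fit.slope),
        bias_slope_p=float(fit.pvalue),
        resid_intercept=float(rfit.intercept),
        resid_slope=float(rfit.slope),
        resid_slope_p=float(rfit.pvalue),
        proportional_bias=bool(prop_bias),
        proportional_loa=bool(prop_loa),
    )


def rmse_and_correlation(
    method: np.ndarray, reference: np.ndarray
) -> tuple[float, float, tuple[float, float]]:
    """Root mean square error of the paired differences and the Pearson
    correlation with a Fisher-z 95% interval (NaN when undefined)."""
    m = np.asarray(method, dtype=float)
    r = np.asarray(reference, dtype=float)
    if len(m) < 3:
        raise InsufficientSampleError("need >= 3 paired values")
    d = m - r
    rmse = float(np.sqrt(np.mean(d * d)))
    pr, ci, _ = _pearson_with_ci(m, r)
    return rmse, pr, ci


# ---------------------------------------------------------------------------
# daytime interval analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntervalAgreement:
    """Agreement within one 30-min clock bin, as % of the bin length."""

    bin_start_minute: int  # minutes after midnight
    day_type: str  # 'weekday' | 'weekend'
    n: int
    bias_pct: float
    bias_ci_pct: tuple[float, float]
    loa_lower_pct: float
    loa_upper_pct: float


def _bin_means(
    classified: ClassifiedTimeline,
    wear: WearMask,
    bin_minutes: int,
) -> dict[str, dict[int, float]]:
    """Per day-type and clock bin, this participant's mean sedentary
    minutes over days where the bin is fully worn."""
    epoch = classified.recording_epoch
    end = max((b for _, b, _ in classified.intervals), default=0.0)
    acc: dict[str, dict[int, list[float]]] = {"weekday": {}, "weekend": {}}
    bins_per_day = int(24 * 60 / bin_minutes)
    for day in range(n_calendar_days(epoch, end)):
        d0, _ = day_bounds(epoch, day)
        date = (epoch + timedelta(seconds=d0 + 43200)).date()
        kind = "weekend" if date.weekday() >= 5 else "weekday"
        for b in range(bins_per_day):
            t0 = d0 + b * bin_minutes * 60.0
            t1 = t0 + bin_minutes * 60.0
            if wear.wear_seconds_in(t0, t1) < bin_minutes * 60.0 - 1e-6:
                continue
            acc[kind].setdefault(b, []).append(classified.minutes(Label.SEDENTARY, t0, t1))
    return {
        kind: {b: float(np.mean(v)) for b, v in per_bin.items()}
        for kind, per_bin in acc.items()
    }


def daytime_interval_analysis(
    method_timelines: Mapping[str, ClassifiedTimeline],
    reference_timelines: Mapping[str, ClassifiedTimeline],
    wear_masks: Mapping[str, WearMask],
    cohort_size: int | None = None,
    bin_minutes: int = 30,
    min_participation: float = 0.80,
) -> list[IntervalAgreement]:
    """Bland-Altman agreement per non-overlapping clock bin.

    For every participant and day type, sedentary minutes per bin are
    averaged over days with full wear of that bin, for method and
    reference alike; a Bland-Altman comparison across participants is
    then run per bin and expressed as % of the bin length. Bins with
    contributing participants below ``min_participation`` of the cohort
    (at least 80%: with a cohort of 62 that is n >= 50) are suppressed.
    """
    pids = sorted(method_timelines)
    cohort_size = cohort_size if cohort_size is not None else len(pids)
    need = math.ceil(min_participation * cohort_size)
    per_pid = {
        pid: (
            _bin_means(method_timelines[pid], wear_masks[pid], bin_minutes),
            _bin_means(reference_timelines[pid], wear_masks[pid], bin_minutes),
        )
        for pid in pids
    }
    out: list[IntervalAgreement] = []
    for kind in ("weekday", "weekend"):
        bins = sorted({b for mm, _ in per_pid.values() for b in mm[kind]})
        for b in bins:
            pairs = [
                (mm[kind][b], rr[kind][b])
                for mm, rr in per_pid.values()
                if b in mm[kind] and b in rr[kind]
            ]
            if len(pairs) < max(need, 3):
                continue
            scale = 100.0 / bin_minutes
            meth = np.array([p[0] for p in pairs]) * scale
            ref = np.array([p[1] for p in pairs]) * scale
            st = bland_altman(meth, ref)
            out.append(
                IntervalAgreement(
                    bin_start_minute=b * bin_minutes,
                    day_type=kind,
                    n=len(pairs),
                    bias_pct=st.bias,
                    bias_ci_pct=st.bias_ci,
                    loa_lower_pct=st.loa_lower,
                    loa_upper_pct=st.loa_upper,
                )
            )
    return out
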