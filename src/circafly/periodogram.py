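"""Chi-square periodogram rhythmicity analysis for locomotor count series.

The chi-square periodogram (Sokolove & Bushell) scans a grid of trial
periods. For a trial period of ``P`` bins, the first ``K*P`` bins
(``K = floor(N/P)`` complete cycles) are folded into ``P`` phase columns.
With column means ``M_h``, grand mean ``M̄`` over the folded bins and
``n = K*P``::

    Qp = n * K * sum_h (M_h - M̄)**2 / sum_i (x_i - M̄)**2

Under the null of no rhythm, Qp is asymptotically chi-square with
``P - 1`` degrees of freedom; a fly is called rhythmic when Qp exceeds
the chi-square critical value at significance ``alpha`` (default 0.01)
at any trial period. "Rhythm robustness" (power) is defined here as the
height of the peak Qp above its significance line.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .dam_io import ActivitySeries

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Fewer than two complete cycles of the longest trial period."""


@dataclass(frozen=True)
class PeriodogramSettings:
    """Scan configuration: trial-period range (hours) and threshold level."""

    period_range_hours: tuple[float, float] = (16.0, 32.0)
    alpha: float = 0.01


@dataclass
class PeriodogramResult:
    """Qp spectrum over trial periods plus the rhythmicity call."""

    trial_periods_hours: np.ndarray
    qp: np.ndarray
    dof: np.ndarray
    sig_line: np.ndarray
    alpha: float
    peak_period_hours: Optional[float]
    peak_qp: Optional[float]
    power: Optional[float]
    rhythmic: bool

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "period_hours": self.trial_periods_hours,
                "qp": self.qp,
                "dof": self.dof,
                "sig_line": self.sig_line,
            }
        )


@dataclass
class RhythmCall:
    """Per-fly, per-age-window rhythmicity summary.

    ``manual_override`` records a human veto of the automated call (the
    original protocol confirmed periodogram calls by visual inspection of
    the actogram); it is never set by this package.
    """

    fly_id: str
    genotype: str
    run_id: str
    window_label: str
    rhythmic: bool
    period_hours: Optional[float]
    power: Optional[float]
    n_bins_used: int
    manual_override: Optional[bool] = None

    @property
    def effective_rhythmic(self) -> bool:
        return self.rhythmic if self.manual_override is None else self.manual_override


def chi_square_periodogram(
    counts: Sequence[float] | np.ndarray,
    bin_minutes: float,
    period_range_hours: tuple[float, float] = (16.0, 32.0),
    alpha: float = 0.01,
) -> PeriodogramResult:
    """Scan integer bins-per-period trial periods and call rhythmicity.

    Parameters
    ----------
    counts
        Non-negative activity counts on a uniform bin grid.
    bin_minutes
        Bin width in minutes; trial periods are integer multiples of it.
    period_range_hours
        Inclusive scan range; every integer bins-per-period whose period
        falls inside it is evaluated.
    alpha
        Per-period significance level for the chi-square critical line.

    A series with zero variance (all counts equal) yields ``Qp = 0`` at
    every period, ``rhythmic=False`` and a logged warning. A record
    shorter than two complete cycles of the longest trial period raises
    :class:`InsufficientDataError`.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if x.size and x.min() < 0:
        raise ValueError("counts must be non-negative")
    lo_h, hi_h = period_range_hours
    p_min = int(np.ceil(lo_h * 60.0 / bin_minutes - 1e-9))
    p_max = int(np.floor(hi_h * 60.0 / bin_minutes + 1e-9))
    if p_min < 2:
        p_min = 2
    if p_max < p_min:
        raise ValueError("period range contains no trial period at this bin width")
    if x.size < 2 * p_max:
        raise InsufficientDataError(
            f"need >= {2 * p_max} bins (two cycles of the longest trial period), "
            f"got {x.size}"
        )

    periods_bins = np.arange(p_min, p_max + 1)
    trial_hours = periods_bins * bin_minutes / 60.0
    dof = periods_bins - 1
    sig_line = stats.chi2.ppf(1.0 - alpha, dof)
    qp = np.zeros_like(trial_hours)

    zero_variance = np.ptp(x) == 0
    if zero_variance:
        msg = "chi_square_periodogram: zero-variance series; Qp set to 0 everywhere"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    else:
        for i, p in enumerate(periods_bins):
            k = x.size // p
            folded = x[: k * p].reshape(k, p)
            grand = folded.mean()
            denom = ((folded - grand) ** 2).sum()
            if denom == 0:
                continue
            col_means = folded.mean(axis=0)
            qp[i] = k * p * k * ((col_means - grand) ** 2).sum() / denom

    supra = qp > sig_line
    rhythmic = bool(supra.any())
    if rhythmic:
        candidates = np.nonzero(supra)[0]
        # argmax over supra-threshold Qp; ties resolve to the smallest period
        best = candidates[int(np.argmax(qp[candidates]))]
        peak_period = float(trial_hours[best])
        peak_qp = float(qp[best])
        power = float(qp[best] - sig_line[best])
    else:
        peak_period = peak_qp = power = None
    return PeriodogramResult(
        trial_periods_hours=trial_hours,
        qp=qp,
        dof=dof,
        sig_line=sig_line,
        alpha=alpha,
        peak_period_hours=peak_period,
        peak_qp=peak_qp,
        power=power,
        rhythmic=rhythmic,
    )


def classify_rhythm(
    segment: ActivitySeries,
    window_label: str,
    settings: PeriodogramSettings = PeriodogramSettings(),
) -> RhythmCall:
    """Run the periodogram on an age-window segment and wrap the call."""
    result = chi_square_periodogram(
        segment.counts,
        segment.bin_minutes,
        period_range_hours=settings.period_range_hours,
        alpha=settings.alpha,
    )
    return RhythmCall(
        fly_id=segment.fly_id,
        genotype=segment.genotype,
        run_id=segment.run_id,
        window_label=window_label,
        rhythmic=result.rhythmic,
        period_hours=result.peak_period_hours,
        power=result.power,
        n_bins_used=segment.n_bins,
    )


def genotype_period_summary(
    calls: Sequence[RhythmCall], genotype: str, window_label: str
) -> Optional[float]:
    """Mean free-running period (hours) over rhythmic flies of a genotype.

    Returns ``None`` when the genotype has no rhythmic fly in the window,
    in which case consolidation falls back to a 24 h cycle length.
    """
    periods = [
        c.period_hours
        for c in calls
        if c.genotype == genotype
        and c.window_label == window_label
        and c.effective_rhythmic
        and c.period_hours is not None
    ]
    if not periods:
        return None
    return float(np.mean(periods))


def calls_to_frame(calls: Sequence[RhythmCall]):
    """Results table: fly_id, genotype, run_id, window, rhythmic, period, power."""
    import pandas as pd

    return pd.DataFrame(
        {
            "fly_id": [c.fly_id for c in calls],
            "genotype": [c.genotype for c in calls],
            "run_id": [c.run_id for c in calls],
            "window": [c.window_label for c in calls],
            "rhythmic": [c.effective_rhythmic for c in calls],
            "period_hours": [c.period_hours for c in calls],
            "power": [c.power for c in calls],
            "n_bins_used": [c.n_bins_used for c in calls],
        }
    )
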