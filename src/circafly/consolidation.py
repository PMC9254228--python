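"""Daily activity-consolidation statistic r.

Within each circadian cycle, every time bin is treated as a vector whose
angle encodes the phase of the bin within the cycle (constant angular
separation ``bin_minutes * 2π / T``) and whose weight is the activity
count in that bin. The rectangular coordinates of the mean vector are

    X = Σ A_t cos θ_t / Σ A_t      Y = Σ A_t sin θ_t / Σ A_t

and the consolidation statistic is the mean resultant length
``r = sqrt(X² + Y²)``: 1 when all activity falls at one phase, 0 when
activity is spread uniformly around the cycle.

Cycle length T is chosen per fly per age window: a rhythmic fly uses its
own periodogram period; an arrhythmic fly uses the mean period of its
genotype in that window; a fly dying mid-window uses its period from the
prior window if it had one (else the genotype mean); when a
genotype-window has no rhythmic fly at all, a 24 h fallback is used and
logged. The provenance of each choice is recorded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dam_io import ActivitySeries, AgeWindow
from .periodogram import RhythmCall

logger = logging.getLogger(__name__)

FALLBACK_PERIOD_HOURS = 24.0


class DegenerateCycleError(ValueError):
    """Cycle length shorter than two bins."""


class UnknownFlyError(KeyError):
    """Fly not present in the supplied rhythm calls."""


@dataclass(frozen=True)
class CycleLengthChoice:
    """Selected cycle length with its provenance.

    ``source`` is one of ``"own_period"``, ``"genotype_mean"``,
    ``"prior_window"`` or ``"fallback_24h"``.
    """

    fly_id: str
    window_label: str
    T_minutes: float
    source: str


@dataclass
class Cycle:
    """One modulo-T cycle: phase angles (radians) and counts per bin."""

    theta: np.ndarray
    counts: np.ndarray
    start_age_days: float
    partial: bool


@dataclass
class CycleSet:
    """A fly's window segment partitioned into modulo-T cycles."""

    fly_id: str
    genotype: str
    window_label: str
    T_minutes: float
    cycles: list[Cycle]

    @property
    def n_complete(self) -> int:
        return sum(1 for c in self.cycles if not c.partial)


def select_cycle_length(
    fly_id: str,
    window: AgeWindow,
    calls: Sequence[RhythmCall],
    genotype_means: Mapping[tuple[str, str], Optional[float]],
    prior_window_calls: Sequence[RhythmCall] = (),
    death_day: Optional[float] = None,
) -> CycleLengthChoice:
    """Pick the cycle length T (minutes) for one fly in one age window.

    Parameters
    ----------
    calls
        Rhythm calls for this window (any genotypes; the fly must appear).
    genotype_means
        ``(genotype, window_label) -> mean period hours`` over rhythmic
        flies, or ``None`` when the genotype-window had none.
    prior_window_calls
        Calls for the preceding age window, consulted for dying flies.
    death_day
        The fly's death age if it died within this window, else ``None``.
    """
    own = next(
        (c for c in calls if c.fly_id == fly_id and c.window_label == window.label), None
    )
    if own is None:
        raise UnknownFlyError(f"no rhythm call for fly {fly_id} in window {window.label}")

    died_in_window = death_day is not None and window.contains_age(death_day)
    if died_in_window:
        prior = next((c for c in prior_window_calls if c.fly_id == fly_id), None)
        if prior is not None and prior.effective_rhythmic and prior.period_hours is not None:
            return CycleLengthChoice(
                fly_id, window.label, prior.period_hours * 60.0, "prior_window"
            )
        return _genotype_mean_choice(own, window, genotype_means)
    if own.effective_rhythmic and own.period_hours is not None:
        return CycleLengthChoice(fly_id, window.label, own.period_hours * 60.0, "own_period")
    return _genotype_mean_choice(own, window, genotype_means)


def _genotype_mean_choice(
    call: RhythmCall,
    window: AgeWindow,
    genotype_means: Mapping[tuple[str, str], Optional[float]],
) -> CycleLengthChoice:
    mean = genotype_means.get((call.genotype, window.label))
    if mean is None:
        logger.warning(
            "no rhythmic fly in genotype %s window %s; falling back to 24 h cycles "
            "for fly %s",
            call.genotype,
            window.label,
            call.fly_id,
        )
        return CycleLengthChoice(
            call.fly_id, window.label, FALLBACK_PERIOD_HOURS * 60.0, "fallback_24h"
        )
    return CycleLengthChoice(call.fly_id, window.label, mean * 60.0, "genotype_mean")


def partition_cycles(
    segment: ActivitySeries, T_minutes: float, window_label: str = ""
) -> CycleSet:
    """Split a window segment into modulo-T cycles with per-bin phase angles.

    Cycle boundaries sit at ``window_start + k*T`` in continuous time; a
    bin belongs to the cycle containing its midpoint, and its angle is
    ``2π * ((midpoint - cycle_start) mod T) / T``. A trailing cycle that
    the segment does not fully cover is flagged partial.
    """
    if T_minutes < 2 * segment.bin_minutes:
        raise DegenerateCycleError(
            f"cycle length {T_minutes} min is shorter than two {segment.bin_minutes}-min bins"
        )
    mid_minutes = (np.arange(segment.n_bins) + 0.5) * segment.bin_minutes
    cycle_index = np.floor(mid_minutes / T_minutes).astype(int)
    theta = 2.0 * np.pi * np.mod(mid_minutes, T_minutes) / T_minutes
    duration = segment.n_bins * segment.bin_minutes
    cycles: list[Cycle] = []
    for k in range(cycle_index.max() + 1 if segment.n_bins else 0):
        sel = cycle_index == k
        if not sel.any():
            continue
        complete = (k + 1) * T_minutes <= duration + 1e-9
        cycles.append(
            Cycle(
                theta=theta[sel],
                counts=segment.counts[sel].astype(float),
                start_age_days=segment.start_age_days + k * T_minutes / 1440.0,
                partial=not complete,
            )
        )
    return CycleSet(
        fly_id=segment.fly_id,
        genotype=segment.genotype,
        window_label=window_label,
        T_minutes=T_minutes,
        cycles=cycles,
    )


def daily_r(theta: np.ndarray, counts: np.ndarray) -> float:
    """Mean resultant length of activity-weighted phase vectors.

    Returns NaN (missing) for a cycle with zero total activity.
    """
    counts = np.asarray(counts, dtype=float)
    theta = np.asarray(theta, dtype=float)
    total = counts.sum()
    if total == 0:
        return float("nan")
    x = float(np.dot(counts, np.cos(theta)) / total)
    y = float(np.dot(counts, np.sin(theta)) / total)
    return math.hypot(x, y)


def cycle_set_daily_r(cycle_set: CycleSet) -> pd.DataFrame:
    """Per-cycle r for one fly; partial cycles are excluded (r missing).

    Columns: fly_id, genotype, window, cycle_index, nominal_day,
    T_minutes, r. ``nominal_day`` is the labelling convention
    ``start_age + cycle_index`` (cycles coincide with days only when
    T is close to 24 h).
    """
    rows = []
    for k, cyc in enumerate(cycle_set.cycles):
        r = float("nan") if cyc.partial else daily_r(cyc.theta, cyc.counts)
        rows.append(
            {
                "fly_id": cycle_set.fly_id,
                "genotype": cycle_set.genotype,
                "window": cycle_set.window_label,
                "cycle_index": k,
                "nominal_day": cyc.start_age_days,
                "T_minutes": cycle_set.T_minutes,
                "r": r,
            }
        )
    return pd.DataFrame(rows)


def mean_daily_r(daily: pd.DataFrame) -> pd.DataFrame:
    """Average per-cycle r across flies of each genotype.

    For each (genotype, window, cycle_index), the mean, standard error of
    the mean and the number of flies with a defined r at that index.
    Flies whose r is missing at an index (zero-activity or partial cycle)
    drop out of that point's n.
    """
    def _agg(group: pd.Series) -> pd.Series:
        vals = group.dropna()
        n = len(vals)
        mean = vals.mean() if n else float("nan")
        sem = vals.std(ddof=1) / math.sqrt(n) if n > 1 else float("nan")
        return pd.Series({"mean_r": mean, "sem_r": sem, "n": n})

    out = (
        daily.groupby(["genotype", "window", "cycle_index"])["r"]
        .apply(_agg)
        .unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    nominal = daily.groupby(["genotype", "window", "cycle_index"])["nominal_day"].first()
    out = out.merge(nominal.reset_index(), on=["genotype", "window", "cycle_index"])
    return out
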