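"""Reading, writing and slicing TriKinetics DAM2 locomotor monitor data.

A DAM2 monitor records infrared beam crossings for 32 flies housed in glass
tubes. The native file is plain tab-separated text, one row per time bin:
a reading index, a date (``d mmm yy``), a time, a status code, six device
fields (field 10 is the light sensor) and then 32 per-channel activity
counts. This module parses that dialect into :class:`ActivitySeries`
objects keyed by a user-supplied channel map, writes it back, re-bins
counts, detects deaths from terminal quiescence, and slices recordings
into the 7-day age windows used for ageing analyses.

Ages are days post-eclosion. The recording is assumed to start at
``start_age_days`` (default 3, flies being loaded at 3 days old); the age
of bin *i* is ``start_age_days + i * bin_minutes / 1440``.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Status code written for a valid reading.
STATUS_OK = 1

#: Number of channels on a DAM2 monitor.
N_CHANNELS = 32

#: Minimum number of tab-separated fields in a valid data row.
MIN_FIELDS = 42


class DamParseError(ValueError):
    """A monitor file row could not be parsed."""


class DamWriteError(ValueError):
    """A cohort cannot be serialised as a single DAM2 monitor."""


class RebinError(ValueError):
    """Requested bin width is not a multiple of the native bin width."""


@dataclass
class ActivitySeries:
    """One fly's binned locomotor counts with age metadata.

    Parameters
    ----------
    fly_id, genotype, run_id
        Identifiers carried through all downstream tables.
    counts
        Non-negative integer beam-crossing counts, one per bin.
    start_age_days
        Age (days post-eclosion) at the start of the first bin.
    bin_minutes
        Width of each bin in minutes.
    death_day
        Age at death if known (see :func:`detect_death`), else ``None``.
    """

    fly_id: str
    genotype: str
    run_id: str
    counts: np.ndarray
    start_age_days: float = 3.0
    bin_minutes: float = 20.0
    death_day: Optional[float] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.bin_minutes <= 0:
            raise ValueError("bin_minutes must be positive")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def bin_start_ages(self) -> np.ndarray:
        """Age (days) at the start of each bin."""
        return self.start_age_days + np.arange(self.n_bins) * self.bin_minutes / 1440.0

    @property
    def end_age_days(self) -> float:
        return self.start_age_days + self.n_bins * self.bin_minutes / 1440.0

    def total_activity(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class AgeWindow:
    """A closed interval of ages (days), e.g. AW1 = days 3-9."""

    label: str
    start_day: float
    end_day: float

    def __post_init__(self) -> None:
        if self.start_day > self.end_day:
            raise ValueError("start_day must not exceed end_day")

    @property
    def n_days(self) -> float:
        return self.end_day - self.start_day + 1

    def contains_age(self, age_days: float) -> bool:
        return self.start_day <= age_days < self.end_day + 1


#: The three 7-day age windows spanning a 21-day DD recording that starts
#: with 3-day-old flies.
DEFAULT_AGE_WINDOWS = (
    AgeWindow("AW1", 3, 9),
    AgeWindow("AW2", 10, 16),
    AgeWindow("AW3", 17, 23),
)


@dataclass
class ChannelMapRow:
    monitor_file: str
    channel: int
    fly_id: str
    genotype: str
    run_id: str
    start_age_days: float = 3.0

    def __post_init__(self) -> None:
        if not 1 <= self.channel <= N_CHANNELS:
            raise ValueError(f"channel must be in [1, {N_CHANNELS}], got {self.channel}")


@dataclass
class ChannelMap:
    """Mapping from (monitor file, channel) to fly identity."""

    rows: list[ChannelMapRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for row in self.rows:
            key = (row.monitor_file, row.channel)
            if key in seen:
                raise ValueError(f"duplicate channel-map entry for {key}")
            seen.add(key)

    def for_monitor(self, monitor_file: str) -> list[ChannelMapRow]:
        name = Path(monitor_file).name
        return [r for r in self.rows if Path(r.monitor_file).name == name]

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChannelMap":
        rows = []
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                rows.append(
                    ChannelMapRow(
                        monitor_file=rec["monitor_file"],
                        channel=int(rec["channel"]),
                        fly_id=rec["fly_id"],
                        genotype=rec["genotype"],
                        run_id=rec["run_id"],
                        start_age_days=float(rec.get("start_age_days", 3) or 3),
                    )
                )
        return cls(rows)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["monitor_file", "channel", "fly_id", "genotype", "run_id", "start_age_days"]
            )
            for r in self.rows:
                writer.writerow(
                    [r.monitor_file, r.channel, r.fly_id, r.genotype, r.run_id, r.start_age_days]
                )


_DATE_FORMAT = "%d %b %y"


def read_dam_monitor(path: str | Path, channel_map: ChannelMap) -> list[ActivitySeries]:
    """Parse a DAM2 monitor text file into one series per mapped channel.

    Rows whose status code is not :data:`STATUS_OK` are treated as missing
    readings and imputed as zero counts with a logged warning, preserving
    the uniform bin grid the periodogram and consolidation statistics
    require. Rows are ordered by timestamp; duplicate timestamps are a
    parse error.
    """
    path = Path(path)
    mapped = channel_map.for_monitor(str(path))
    records: list[tuple[datetime, np.ndarray]] = []
    n_bad_status = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < MIN_FIELDS:
                raise DamParseError(
                    f"{path.name}:{lineno}: expected >= {MIN_FIELDS} tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                stamp = datetime.strptime(f"{fields[1]} {fields[2]}", _DATE_FORMAT + " %H:%M:%S")
            except ValueError as exc:
                raise DamParseError(f"{path.name}:{lineno}: bad date/time: {exc}") from None
            try:
                status = int(fields[3])
                counts = np.array([int(v) for v in fields[10 : 10 + N_CHANNELS]], dtype=int)
            except ValueError:
                raise DamParseError(
                    f"{path.name}:{lineno}: non-integer status or count field"
                ) from None
            if status != STATUS_OK:
                n_bad_status += 1
                counts = np.zeros(N_CHANNELS, dtype=int)
            records.append((stamp, counts))
    if n_bad_status:
        msg = (
            f"{path.name}: {n_bad_status} row(s) with non-OK status imputed as zero counts"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    records.sort(key=lambda rec: rec[0])
    for (t0, _), (t1, _) in zip(records, records[1:]):
        if t0 == t1:
            raise DamParseError(f"{path.name}: duplicate timestamp {t0}")
    matrix = (
        np.array([c for _, c in records], dtype=int)
        if records
        else np.zeros((0, N_CHANNELS), dtype=int)
    )
    bin_minutes = 20.0
    if len(records) >= 2:
        bin_minutes = (records[1][0] - records[0][0]).total_seconds() / 60.0
    series = []
    for row in mapped:
        series.append(
            ActivitySeries(
                fly_id=row.fly_id,
                genotype=row.genotype,
                run_id=row.run_id,
                counts=matrix[:, row.channel - 1].copy(),
                start_age_days=row.start_age_days,
                bin_minutes=bin_minutes,
            )
        )
    return series


def write_dam_monitor(
    cohort: Sequence[ActivitySeries],
    path: str | Path,
    channels: Optional[Sequence[int]] = None,
    start_datetime: datetime = datetime(2024, 1, 1, 0, 0, 0),
) -> None:
    """Serialise up to 32 aligned series as one DAM2 monitor text file.

    Channels without a series are written as zero counts. An empty cohort
    produces an empty file with a logged error.
    """
    path = Path(path)
    if not cohort:
        logger.error("write_dam_monitor called with an empty cohort; writing empty file")
        path.write_text("")
        return
    if len(cohort) > N_CHANNELS:
        raise DamWriteError(
            f"a DAM2 monitor holds {N_CHANNELS} flies; got {len(cohort)} series"
        )
    bin_minutes = cohort[0].bin_minutes
    n_bins = cohort[0].n_bins
    for s in cohort:
        if s.bin_minutes != bin_minutes or s.n_bins != n_bins:
            raise DamWriteError("all series must share bin width and length")
    if channels is None:
        channels = range(1, len(cohort) + 1)
    matrix = np.zeros((n_bins, N_CHANNELS), dtype=int)
    for ch, s in zip(channels, cohort):
        matrix[:, ch - 1] = s.counts
    with open(path, "w") as fh:
        for i in range(n_bins):
            stamp = start_datetime + timedelta(minutes=i * bin_minutes)
            row = [
                str(i + 1),
                stamp.strftime(_DATE_FORMAT).lstrip("0"),
                stamp.strftime("%H:%M:%S"),
                str(STATUS_OK),
                "0",  # extras monitor
                "0",  # unused
                "0",  # unused
                "0",  # unused
                "0",  # unused
                "0",  # light sensor
            ] + [str(v) for v in matrix[i]]
            fh.write("\t".join(row) + "\n")


def rebin(series: ActivitySeries, new_bin_minutes: float) -> ActivitySeries:
    """Sum counts into wider bins; a trailing incomplete group is dropped.

    ``new_bin_minutes`` must be an integer multiple of the native width.
    Total activity is conserved up to the dropped remainder, which is
    logged.
    """
    ratio = new_bin_minutes / series.bin_minutes
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise RebinError(
            f"new bin width {new_bin_minutes} min is not an integer multiple "
            f"of {series.bin_minutes} min"
        )
    k = int(round(ratio))
    if k == 1:
        return replace(series, counts=series.counts.copy())
    n_groups = series.n_bins // k
    remainder = series.n_bins - n_groups * k
    if remainder:
        dropped = int(series.counts[n_groups * k :].sum())
        msg = (
            f"rebin: dropping trailing incomplete group of {remainder} bin(s) "
            f"({dropped} counts) for fly {series.fly_id}"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    counts = series.counts[: n_groups * k].reshape(n_groups, k).sum(axis=1)
    return replace(series, counts=counts, bin_minutes=new_bin_minutes)


def detect_death(series: ActivitySeries, quiescence_hours: float = 24.0) -> Optional[float]:
    """Estimate the age at death from a terminal run of zero counts.

    Returns the age (days) of the last bin with activity if every later
    bin is zero and that zero tail spans at least ``quiescence_hours``;
    otherwise ``None``. A fly with no activity at all is assigned
    ``start_age_days``.
    """
    if series.n_bins == 0:
        raise ValueError("cannot detect death on an empty series")
    nonzero = np.nonzero(series.counts)[0]
    if nonzero.size == 0:
        return series.start_age_days
    last_active = int(nonzero[-1])
    tail_bins = series.n_bins - 1 - last_active
    tail_hours = tail_bins * series.bin_minutes / 60.0
    if tail_hours >= quiescence_hours:
        return float(series.bin_start_ages[last_active])
    return None


def slice_age_window(series: ActivitySeries, window: AgeWindow) -> ActivitySeries:
    """Return the bins whose start age lies in ``[start_day, end_day + 1)``.

    The returned segment keeps the fly metadata; an empty overlap yields an
    empty segment (flagged by ``n_bins == 0``) with a logged warning.
    """
    ages = series.bin_start_ages
    mask = (ages >= window.start_day) & (ages < window.end_day + 1)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        logger.warning(
            "slice_age_window: window %s does not overlap recording of fly %s",
            window.label,
            series.fly_id,
        )
        return replace(
            series, counts=np.zeros(0, dtype=series.counts.dtype), start_age_days=window.start_day
        )
    return replace(
        series,
        counts=series.counts[idx[0] : idx[-1] + 1].copy(),
        start_age_days=float(ages[idx[0]]),
    )


def cohort_to_frame(cohort: Sequence[ActivitySeries]):
    """Tidy per-bin export: columns fly_id, genotype, age_days, count."""
    import pandas as pd

    frames = []
    for s in cohort:
        frames.append(
            pd.DataFrame(
                {
                    "fly_id": s.fly_id,
                    "genotype": s.genotype,
                    "age_days": s.bin_start_ages,
                    "count": s.counts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
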