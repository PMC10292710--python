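"""Event-time and annual-count containers, embedded study data, and CSV I/O.

Two representations of the same underlying record of rare events are used
throughout the package:

* an :class:`EventSeries` of occurrence times in days since an origin date,
  consumed by the non-homogeneous Poisson process change-point model, and
* :class:`AnnualCounts` of events per calendar year, consumed by the ARIMA
  and hybrid ARIMA-ANN models.

The embedded study data are the U.S. public mass-shooting records of the
Violence Project: 173 event times (days since 1966-08-01) and annual counts
for 1966-2019, plus the single event recorded for 2020.  The two embedded
tables are NOT mutually consistent (the counts sum to 171 while the event
table has 173 rows, the last of which falls in early 2020); both are kept
verbatim and :func:`consistency_report` quantifies the differences.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EventSeries",
    "AnnualCounts",
    "TrainTestSplit",
    "DataValidationError",
    "MalformedRowError",
    "NegativeCountError",
    "UnsortedTimesError",
    "load_event_fixture",
    "load_annual_fixture",
    "events_to_annual_counts",
    "split_by_year",
    "truncate_events",
    "day_offset",
    "read_counts_csv",
    "write_counts_csv",
    "read_events_csv",
    "write_events_csv",
    "consistency_report",
    "ORIGIN_DATE",
]

ORIGIN_DATE = _dt.date(1966, 8, 1)

#: Annual event counts, 1966 through 2019.
_ANNUAL_COUNTS_1966_2019 = (
    2, 1, 1, 1, 1, 0, 2, 1, 0, 1,   # 1966-1975
    1, 3, 1, 0, 3, 2, 3, 3, 4, 1,   # 1976-1985
    1, 1, 3, 2, 1, 5, 4, 6, 2, 3,   # 1986-1995
    2, 4, 4, 8, 3, 4, 1, 4, 3, 4,   # 1996-2005
    4, 4, 5, 5, 5, 4, 6, 5, 3, 6,   # 2006-2015
    5, 7, 8, 8,                     # 2016-2019
)

#: Count recorded for 2020 after the study window closed.
_COUNT_2020 = 1

#: Event occurrence times in days since 1966-08-01 (173 events).
_EVENT_TIMES_DAYS = (
    0, 101, 447, 595, 979, 1512, 2128, 2150, 2351, 3136,
    3631, 3848, 4007, 4040, 4336, 4932, 5071, 5100, 5391, 5550,
    5752, 5848, 5859, 6027, 6055, 6275, 6496, 6538, 6557, 6563,
    6800, 7319, 7567, 7865, 8016, 8081, 8201, 8438, 8717, 9194,
    9200, 9215, 9223, 9228, 9354, 9400, 9564, 9587, 9825, 9860,
    9928, 9976, 9981, 9988, 10179, 10370, 10467, 10573, 10723, 10778,
    10853, 11333, 11359, 11437, 11452, 11535, 11553, 11553, 11609, 11904,
    11944, 11944, 11987, 12043, 12089, 12136, 12194, 12279, 12317, 12555,
    12573, 12599, 12747, 12812, 13011, 13349, 13482, 13531, 13588, 13841,
    13980, 13997, 14095, 14096, 14105, 14262, 14419, 14474, 14530, 14661,
    14796, 14860, 15089, 15093, 15156, 15163, 15197, 15294, 15361, 15573,
    15577, 15785, 15789, 15813, 15942, 16005, 16062, 16073, 16100, 16222,
    16431, 16460, 16496, 16671, 16729, 16779, 16794, 16846, 16923, 17017,
    17055, 17101, 17150, 17200, 17359, 17452, 17603, 17841, 17870, 17945,
    17988, 18006, 18006, 18089, 18108, 18201, 18226, 18302, 18410, 18440,
    18486, 18559, 18675, 18709, 18718, 18797, 18813, 18825, 18881, 18907,
    18947, 19021, 19066, 19076, 19157, 19179, 19285, 19347, 19348, 19375,
    19474, 19474, 19555,
)


class DataValidationError(ValueError):
    """Base class for invalid input data."""


class MalformedRowError(DataValidationError):
    """A CSV row could not be parsed into the expected fields."""


class NegativeCountError(DataValidationError):
    """An annual count was negative."""


class UnsortedTimesError(DataValidationError):
    """Event times were not non-decreasing."""


@dataclass(frozen=True)
class EventSeries:
    """Event occurrence times, in days since ``origin_date``.

    Ties are allowed (two events on the same day are distinct events).
    ``observation_end`` marks the end of the observation window in days;
    every event time must lie in ``[0, observation_end]``.
    """

    event_times: np.ndarray
    origin_date: _dt.date
    observation_end: float

    def __post_init__(self) -> None:
        times = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", times)
        if times.ndim != 1:
            raise DataValidationError("event_times must be one-dimensional")
        if times.size and np.any(np.diff(times) < 0):
            raise UnsortedTimesError("event times must be non-decreasing")
        if times.size and (times[0] < 0 or times[-1] > self.observation_end):
            raise DataValidationError(
                "event times must lie within [0, observation_end]"
            )
        if self.observation_end <= 0:
            raise DataValidationError("observation_end must be positive")

    def __len__(self) -> int:
        return int(self.event_times.size)


@dataclass(frozen=True)
class AnnualCounts:
    """Non-negative event counts for consecutive calendar years."""

    start_year: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 1 or counts.size < 1:
            raise DataValidationError("counts must be a non-empty 1-D sequence")
        if np.any(counts < 0):
            raise NegativeCountError("annual counts must be non-negative")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + len(self.counts))

    @property
    def end_year(self) -> int:
        return self.start_year + len(self.counts) - 1

    def count_for(self, year: int) -> int:
        if not self.start_year <= year <= self.end_year:
            raise KeyError(f"year {year} outside {self.start_year}-{self.end_year}")
        return int(self.counts[year - self.start_year])

    def values(self) -> np.ndarray:
        return self.counts.astype(float)

    def __len__(self) -> int:
        return int(self.counts.size)


@dataclass(frozen=True)
class TrainTestSplit:
    """Contiguous, time-ordered train/test partition of an annual series."""

    train: AnnualCounts
    test: AnnualCounts

    def __post_init__(self) -> None:
        if self.test.start_year != self.train.end_year + 1:
            raise DataValidationError("test must start the year after train ends")


def load_event_fixture() -> EventSeries:
    """The embedded event-time table (173 events, origin 1966-08-01).

    The observation window closes at the last recorded event.
    """
    times = np.asarray(_EVENT_TIMES_DAYS, dtype=float)
    return EventSeries(times, ORIGIN_DATE, float(times[-1]))


def load_annual_fixture(include_2020: bool = False) -> AnnualCounts:
    """The embedded annual-count table (1966-2019; optionally append 2020)."""
    counts = list(_ANNUAL_COUNTS_1966_2019)
    if include_2020:
        counts.append(_COUNT_2020)
    return AnnualCounts(1966, np.asarray(counts))


def day_offset(date: _dt.date, origin: _dt.date = ORIGIN_DATE) -> float:
    """Days elapsed from ``origin`` to ``date`` (real calendar arithmetic)."""
    return float((date - origin).days)


def end_of_year_offset(year: int, origin: _dt.date = ORIGIN_DATE) -> float:
    """Day offset of the last day of ``year`` (inclusive end of that year)."""
    return day_offset(_dt.date(year, 12, 31), origin)


def truncate_events(events: EventSeries, end_day: float) -> EventSeries:
    """Restrict the observation window to ``[0, end_day]``."""
    if end_day <= 0:
        raise DataValidationError("end_day must be positive")
    kept = events.event_times[events.event_times <= end_day]
    return EventSeries(kept, events.origin_date, float(end_day))


def events_to_annual_counts(events: EventSeries) -> AnnualCounts:
    """Bin event times into calendar years of ``origin_date + t`` days.

    Covers the origin year through the calendar year containing the end of
    the observation window (the first and last years may be partial).  The
    total of the output counts equals the number of input events.
    """
    if events.origin_date is None:
        raise DataValidationError("EventSeries has no origin_date")
    origin = events.origin_date
    first_year = origin.year
    end_date = origin + _dt.timedelta(days=float(events.observation_end))
    last_year = end_date.year
    years = np.arange(first_year, last_year + 1)
    counts = np.zeros(len(years), dtype=int)
    for t in events.event_times:
        year = (origin + _dt.timedelta(days=float(t))).year
        counts[year - first_year] += 1
    return AnnualCounts(first_year, counts)


def split_by_year(counts: AnnualCounts, T: int) -> TrainTestSplit:
    """Split into train (start..T) and test (T+1..end), preserving order."""
    if not counts.start_year <= T < counts.end_year:
        raise DataValidationError(
            f"T={T} must satisfy {counts.start_year} <= T < {counts.end_year}"
        )
    k = T - counts.start_year + 1
    return TrainTestSplit(
        train=AnnualCounts(counts.start_year, counts.counts[:k]),
        test=AnnualCounts(T + 1, counts.counts[k:]),
    )


# ---------------------------------------------------------------------------
# CSV I/O.  Counts: header "year,count".  Events: a "# origin_date=YYYY-MM-DD"
# and "# observation_end=<days>" comment pair, then header "index,t_days".
# ---------------------------------------------------------------------------


def write_counts_csv(counts: AnnualCounts, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["year", "count"])
        for year, c in zip(counts.years, counts.counts):
            writer.writerow([int(year), int(c)])


def read_counts_csv(path) -> AnnualCounts:
    years: list[int] = []
    values: list[int] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["year", "count"]:
            raise MalformedRowError(f"expected header 'year,count', got {header!r}")
        for row in reader:
            if not row:
                continue
            try:
                years.append(int(row[0]))
                values.append(int(row[1]))
            except (ValueError, IndexError) as exc:
                raise MalformedRowError(f"cannot parse row {row!r}") from exc
    if not years:
        raise MalformedRowError("no data rows")
    if any(b - a != 1 for a, b in zip(years, years[1:])):
        raise MalformedRowError("years must be consecutive")
    if any(v < 0 for v in values):
        raise NegativeCountError("negative count in CSV")
    return AnnualCounts(years[0], np.asarray(values))


def write_events_csv(events: EventSeries, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# origin_date={events.origin_date.isoformat()}\n")
        fh.write(f"# observation_end={events.observation_end!r}\n")
        writer = csv.writer(fh)
        writer.writerow(["index", "t_days"])
        for i, t in enumerate(events.event_times, start=1):
            writer.writerow([i, repr(float(t))])


def read_events_csv(path) -> EventSeries:
    origin: _dt.date | None = None
    observation_end: float | None = None
    times: list[float] = []
    with open(path, newline="", encoding="utf-8") as fh:
        rows = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                if key.strip() == "origin_date":
                    origin = _dt.date.fromisoformat(value.strip())
                elif key.strip() == "observation_end":
                    observation_end = float(value)
                continue
            rows.append(line)
    if origin is None or observation_end is None:
        raise MalformedRowError(
            "events CSV must carry '# origin_date=' and '# observation_end=' metadata"
        )
    if not rows or rows[0].split(",")[:2] != ["index", "t_days"]:
        raise MalformedRowError("expected header 'index,t_days'")
    for line in rows[1:]:
        parts = line.split(",")
        try:
            times.append(float(parts[1]))
        except (ValueError, IndexError) as exc:
            raise MalformedRowError(f"cannot parse row {line!r}") from exc
    arr = np.asarray(times, dtype=float)
    if arr.size and np.any(np.diff(arr) < 0):
        raise UnsortedTimesError("event times in CSV are out of order")
    return EventSeries(arr, origin, observation_end)


def consistency_report(
    events: EventSeries | None = None, counts: AnnualCounts | None = None
) -> dict:
    """Quantify the disagreement between the two embedded representations.

    The embedded tables disagree: binning the event times into calendar
    years does not reproduce the printed annual counts (171 printed events
    vs 173 event rows, the last falling after the printed year range).
    Differences are reported, never 'fixed'.
    """
    if events is None:
        events = load_event_fixture()
    if counts is None:
        counts = load_annual_fixture()
    binned = events_to_annual_counts(events)
    per_year = []
    for year in range(counts.start_year, max(counts.end_year, binned.end_year) + 1):
        printed = counts.count_for(year) if year <= counts.end_year else None
        from_events = (
            binned.count_for(year)
            if binned.start_year <= year <= binned.end_year
            else 0
        )
        if printed is None or printed != from_events:
            per_year.append(
                {"year": year, "printed": printed, "from_events": from_events}
            )
    return {
        "n_events": len(events),
        "sum_printed_counts": int(counts.counts.sum()),
        "last_event_day": float(events.event_times[-1]),
        "last_event_date": (
            events.origin_date
            + _dt.timedelta(days=float(events.event_times[-1]))
        ).isoformat(),
        "printed_year_range": [counts.start_year, counts.end_year],
        "mismatched_years": per_year,
    }
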