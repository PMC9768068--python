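"""Reading and preprocessing of RR-interval recordings.

Input files are plain-text single-column series (PhysioZoo-style ``.txt``),
holding either RR intervals or monotone beat (R-peak) times, in seconds or
milliseconds.  All downstream code works in milliseconds; unit conversion
happens at this boundary.

Preprocessing follows the standard rodent HRV chain: a physiological range
filter (default 50-240 ms, i.e. 250-1200 bpm) with linear interpolation of
excluded beats, single-pass ectopic removal at ±2 sample SD, exclusion of
the first two minutes of blockade ("abk") recordings to avoid drug-onset
transients, and partitioning into non-overlapping analysis windows of fixed
cumulative duration (default 3 min, matching the period resolved by the
very-low-frequency band edge).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

State = Literal["basal", "abk"]

#: physiological RR range for mice, ms (250-1200 bpm)
RANGE_LO_MS = 50.0
RANGE_HI_MS = 240.0

DEFAULT_VISIT_AGES = (6, 9, 12, 15, 18, 21, 24, 27, 30)


class RRFileError(ValueError):
    """Malformed RR/beat-time file."""


class InsufficientDataError(ValueError):
    """Too few intervals for the requested operation."""


class EmptySegmentError(ValueError):
    """Filtering removed every interval."""


@dataclass
class RRSeries:
    """One labelled beat-to-beat interval series for a (mouse, age, state).

    ``intervals`` are RR durations in ms.  ``onset_times`` (seconds,
    optional) are cumulative beat times; when present they must be strictly
    increasing and consistent with the cumulative interval sums.
    """

    mouse_id: str
    age_months: float
    state: State
    intervals: np.ndarray
    onset_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.state not in ("basal", "abk"):
            raise ValueError(f"state must be 'basal' or 'abk', got {self.state!r}")
        if self.intervals.size and not np.all(self.intervals > 0):
            raise ValueError("RR intervals must all be positive")
        if self.onset_times is not None:
            self.onset_times = np.asarray(self.onset_times, dtype=float)
            if np.any(np.diff(self.onset_times) <= 0):
                raise ValueError("onset_times must be strictly increasing")
            # onset_times[i] closes interval i, so successive onsets differ
            # by the later interval's duration
            implied = self.onset_times[0] + np.cumsum(self.intervals[1:]) / 1000.0
            if self.onset_times.size == self.intervals.size and np.any(
                np.abs(implied - self.onset_times[1:]) > 1e-3 + 1e-6
            ):
                raise ValueError("onset_times inconsistent with cumulative intervals")

    @property
    def duration_s(self) -> float:
        return float(np.sum(self.intervals)) / 1000.0

    def __len__(self) -> int:
        return int(self.intervals.size)

    def replace_intervals(self, intervals: np.ndarray) -> "RRSeries":
        return RRSeries(self.mouse_id, self.age_months, self.state, intervals)


@dataclass
class AnalysisWindow:
    """One filtered, contiguous RR segment eligible for metric computation."""

    parent: RRSeries | None
    intervals: np.ndarray
    window_index: int = 0
    n_replaced: int = 0
    n_ectopic_removed: int = 0
    short_segment: bool = False
    nonstationary: bool = False

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)

    @property
    def duration_s(self) -> float:
        return float(np.sum(self.intervals)) / 1000.0

    @property
    def n_intervals(self) -> int:
        return int(self.intervals.size)


@dataclass
class CohortManifest:
    """Table mapping (mouse_id, age_months, state) to data files."""

    table: pd.DataFrame
    visit_ages: Sequence[float] = field(default_factory=lambda: DEFAULT_VISIT_AGES)

    REQUIRED = ("mouse_id", "age_months", "state", "file")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        key = self.table[["mouse_id", "age_months", "state"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate manifest entry for {dup}")
        bad_age = set(self.table["age_months"]) - set(self.visit_ages)
        if bad_age:
            raise ValueError(f"ages outside declared visit schedule: {sorted(bad_age)}")

    @classmethod
    def read_csv(cls, path: str | Path, visit_ages: Sequence[float] = DEFAULT_VISIT_AGES) -> "CohortManifest":
        return cls(pd.read_csv(path), visit_ages=visit_ages)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.table)

    def iter_records(self) -> Iterator[pd.Series]:
        yield from (row for _, row in self.table.iterrows())


def read_rr_file(
    path: str | Path,
    units_hint: Literal["seconds", "ms", "auto"] = "auto",
    mouse_id: str = "",
    age_months: float = float("nan"),
    state: State = "basal",
) -> RRSeries:
    """Read a single-column RR-interval or beat-time file into an :class:`RRSeries`.

    Lines starting with ``#`` are comments.  A monotone increasing column is
    treated as beat times and first-differenced; units are auto-detected by
    magnitude (median < 10 means seconds) unless ``units_hint`` says otherwise.
    """
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            try:
                values.append(float(text.split()[0]))
            except ValueError:
                raise RRFileError(f"{path}: non-numeric value at line {lineno}: {text!r}")
    if len(values) < 2:
        raise InsufficientDataError(f"{path}: need at least 2 values, got {len(values)}")
    col = np.asarray(values, dtype=float)

    if units_hint == "auto":
        units = "seconds" if float(np.median(np.abs(col))) < 10 else "ms"
    else:
        units = units_hint
    scale = 1000.0 if units == "seconds" else 1.0

    onset = None
    if np.all(np.diff(col) > 0):  # monotone increasing -> beat times
        onset_s = col * scale / 1000.0
        intervals = np.diff(col) * scale
        onset = onset_s[1:]  # onset of each interval's closing beat
    else:
        intervals = col * scale
    if np.any(intervals <= 0):
        raise RRFileError(f"{path}: non-positive RR interval after conversion")
    return RRSeries(mouse_id or Path(path).stem, age_months, state, intervals, onset_times=None if onset is None else onset)


def range_filter(
    intervals: np.ndarray,
    lo: float = RANGE_LO_MS,
    hi: float = RANGE_HI_MS,
) -> tuple[np.ndarray, int]:
    """Replace out-of-range intervals by linear interpolation between in-range neighbours.

    Out-of-range values at the sequence edges have no neighbour on one side
    and are dropped rather than extrapolated.  Returns the filtered sequence
    and the number of interpolated (interior) replacements.
    """
    if not lo < hi:
        raise ValueError("require lo < hi")
    x = np.asarray(intervals, dtype=float)
    ok = (x >= lo) & (x <= hi)
    if not ok.any():
        raise EmptySegmentError("all intervals outside physiological range")
    first, last = np.flatnonzero(ok)[[0, -1]]
    x = x[first : last + 1]
    ok = ok[first : last + 1]
    n_replaced = int((~ok).sum())
    if n_replaced:
        idx = np.arange(x.size)
        x = x.copy()
        x[~ok] = np.interp(idx[~ok], idx[ok], x[ok])
    return x, n_replaced


def remove_ectopics(intervals: np.ndarray, k_sd: float = 2.0) -> tuple[np.ndarray, int]:
    """Delete intervals farther than ``k_sd`` sample SDs from the segment mean.

    Single pass: the mean and SD are those of the input segment; removal is
    not iterated (iterating a trimming rule can cascade on heavy-tailed
    data).  A zero-variance segment is returned unchanged.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    x = np.asarray(intervals, dtype=float)
    if x.size < 2:
        return x, 0
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return x, 0
    keep = np.abs(x - x.mean()) <= k_sd * sd
    return x[keep], int((~keep).sum())


def make_windows(
    series: RRSeries,
    window_s: float = 180.0,
    abk_discard_s: float = 120.0,
    min_intervals: int = 50,
) -> list[AnalysisWindow]:
    """Greedy partition of a series into non-overlapping fixed-duration windows.

    For blockade ("abk") recordings the first ``abk_discard_s`` seconds are
    excluded to avoid drug-onset transients.  A trailing partial window
    shorter than half ``window_s`` is discarded, as are windows with fewer
    than ``min_intervals`` beats.  An empty result is not an error.
    """
    x = series.intervals
    if series.state == "abk" and abk_discard_s > 0:
        ends_s = np.cumsum(x) / 1000.0
        x = x[ends_s > abk_discard_s]
    windows: list[AnalysisWindow] = []
    target_ms = window_s * 1000.0
    start = 0
    widx = 0
    while start < x.size:
        cum = np.cumsum(x[start:])
        # include beats while the duration before adding them is < window_s
        n_take = int(np.searchsorted(cum, target_ms, side="left")) + 1
        n_take = min(n_take, x.size - start)
        seg = x[start : start + n_take]
        dur_s = float(seg.sum()) / 1000.0
        is_last = start + n_take >= x.size
        if is_last and dur_s < window_s / 2:
            break  # trailing remnant
        if seg.size >= min_intervals:
            windows.append(AnalysisWindow(parent=series, intervals=seg, window_index=widx))
            widx += 1
        start += n_take
    if not windows:
        logger.info(
            "make_windows: %s/%s/%s yielded no usable window",
            series.mouse_id, series.age_months, series.state,
        )
    return windows


def _sliding_trend_scores(x: np.ndarray, w: int) -> np.ndarray:
    """|LSQ slope| / segment SD for every length-``w`` contiguous run (vectorised)."""
    n = x.size
    k = np.arange(w) - (w - 1) / 2.0
    denom = float(np.sum(k**2))
    # sliding dot product of x with centred index kernel
    num = np.convolve(x, k[::-1], mode="valid")
    slope = num / denom
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x**2)))
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    var = np.maximum((s2 - s1**2 / w) / (w - 1), 0.0)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(sd > 0, np.abs(slope) / sd, np.where(np.abs(slope) > 0, np.inf, 0.0))
    assert score.size == n - w + 1
    return score


def select_stationary_segment(
    series: RRSeries,
    target_n: int = 512,
    reject_factor: float = 3.0,
) -> AnalysisWindow:
    """Pick the most stationary contiguous run of ``target_n`` intervals.

    Stationarity is scored as the absolute least-squares linear-trend slope
    of RR vs beat index, normalised by the segment SD; the run minimising
    the score wins (ties go to the earliest start).  A series shorter than
    ``target_n`` is returned whole with ``short_segment`` set.  If even the
    best run drifts by more than ``reject_factor`` SDs across its length
    (|slope|*N > reject_factor*SD) the window is flagged ``nonstationary``.
    """
    x = series.intervals
    if x.size < target_n:
        win = AnalysisWindow(parent=series, intervals=x, short_segment=True)
        logger.warning(
            "select_stationary_segment: %s/%s/%s has %d < %d intervals",
            series.mouse_id, series.age_months, series.state, x.size, target_n,
        )
        return win
    scores = _sliding_trend_scores(x, target_n)
    best = int(np.argmin(scores))
    seg = x[best : best + target_n]
    nonstat = bool(scores[best] * target_n > reject_factor)
    return AnalysisWindow(parent=series, intervals=seg, window_index=0, nonstationary=nonstat)


def preprocess_series(
    series: RRSeries,
    lo: float = RANGE_LO_MS,
    hi: float = RANGE_HI_MS,
    k_sd: float = 2.0,
) -> tuple[RRSeries, int, int]:
    """Range-filter then ectopic-clean a series; returns (cleaned, n_replaced, n_removed)."""
    filtered, n_replaced = range_filter(series.intervals, lo=lo, hi=hi)
    cleaned, n_removed = remove_ectopics(filtered, k_sd=k_sd)
    return series.replace_intervals(cleaned), n_replaced, n_removed


def dump_windows(windows: Sequence[AnalysisWindow], path: str | Path) -> None:
    """Serialise windows to CSV, one row per interval."""
    rows = [
        {"window_index": w.window_index, "beat_index": i, "rr_ms": rr}
        for w in windows
        for i, rr in enumerate(w.intervals)
    ]
    pd.DataFrame(rows, columns=["window_index", "beat_index", "rr_ms"]).to_csv(path, index=False)
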