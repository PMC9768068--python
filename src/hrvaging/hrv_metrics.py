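"""Time-domain, fragmentation and nonlinear HRV metrics.

All functions take a 1-D sequence of NN (normal-to-normal) intervals in ms.
Sample statistics use the N-1 denominator throughout.

Fragmentation metrics quantify erratic, aperiodic sign changes of the
beat-to-beat increments DeltaNN_i = NN_{i+1} - NN_i:

PIP   percentage of inflection points (zero crossings of the increment
      series; a zero increment counts as an inflection),
IALS  inverse of the mean acceleration/deceleration segment length, where a
      segment is a maximal run of same-sign increments (lengths counted in
      increments),
PSS   complement of the percentage of NN intervals inside
      acceleration/deceleration segments spanning >= 3 NN intervals,
PAS   percentage of NN intervals inside alternation ("ABAB") segments of
      >= 4 NN intervals whose increments change sign every beat.

Larger values of each denote a more fragmented rhythm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from hrvaging.io_preprocess import InsufficientDataError

__all__ = [
    "HRVRecord",
    "compute_hrv_record",
    "dfa",
    "fragmentation",
    "mean_rr",
    "pnn5",
    "poincare",
    "sample_entropy",
    "sdnn",
]

#: conventional short- and long-range DFA box sizes (beats)
DFA_SHORT_RANGE = (4, 15)
DFA_LONG_RANGE = (16, 64)


@dataclass
class HRVRecord:
    """Full metric vector for one analysis window (or window average)."""

    mean_rr: float = math.nan      # ms
    sdnn: float = math.nan         # ms
    pnn5: float = math.nan         # %
    pip: float = math.nan          # %
    ials: float = math.nan         # 1/beats
    pss: float = math.nan          # %
    pas: float = math.nan          # %
    sd1: float = math.nan          # ms
    sd2: float = math.nan          # ms
    sd1_sd2: float = math.nan
    sampen: float = math.nan
    dfa_alpha1: float = math.nan
    dfa_alpha2: float = math.nan
    n_intervals: int = 0

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    METRIC_NAMES = (
        "mean_rr", "sdnn", "pnn5", "pip", "ials", "pss", "pas",
        "sd1", "sd2", "sd1_sd2", "sampen", "dfa_alpha1", "dfa_alpha2",
    )


def _require(x: np.ndarray, n: int, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < n:
        raise InsufficientDataError(f"{what}: need >= {n} intervals, got {x.size}")
    return x


def mean_rr(intervals: np.ndarray) -> float:
    """Arithmetic mean NN interval (ms)."""
    return float(np.mean(_require(intervals, 1, "mean_rr")))


def sdnn(intervals: np.ndarray) -> float:
    """Sample standard deviation of the NN intervals (ms, N-1 denominator)."""
    return float(np.std(_require(intervals, 2, "sdnn"), ddof=1))


def pnn5(intervals: np.ndarray, threshold: float = 5.0) -> float:
    """Percent of successive NN differences strictly greater than ``threshold`` ms.

    The 5-ms threshold is the murine analogue of the human pNN50.
    """
    x = _require(intervals, 2, "pnn5")
    d = np.abs(np.diff(x))
    return float(100.0 * np.count_nonzero(d > threshold) / (x.size - 1))


def _runs(signs: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal values: list of (start, length, value); zeros break runs."""
    out: list[tuple[int, int, int]] = []
    i = 0
    n = signs.size
    while i < n:
        s = signs[i]
        j = i
        while j < n and signs[j] == s:
            j += 1
        out.append((i, j - i, int(s)))
        i = j
    return out


def fragmentation(intervals: np.ndarray, pss_min_nn: int = 3, pas_min_nn: int = 4) -> tuple[float, float, float, float]:
    """Compute (PIP %, IALS, PSS %, PAS %).

    Zero increments count toward inflection (DeltaNN_i * DeltaNN_{i+1} <= 0)
    and break acceleration/deceleration runs; alternation requires a strict
    sign change at every beat.  A same-sign run of k increments spans k+1 NN
    intervals; the PSS threshold counts NN intervals (default 3).
    """
    x = _require(intervals, 5, "fragmentation")
    n = x.size
    d = np.diff(x)
    s = np.sign(d).astype(int)

    n_inflect = int(np.count_nonzero(d[:-1] * d[1:] <= 0))
    pip = 100.0 * n_inflect / n

    runs = [(start, length) for start, length, val in _runs(s) if val != 0]
    if runs:
        ials = 1.0 / (sum(length for _, length in runs) / len(runs))
    else:
        ials = math.nan

    long_mask = np.zeros(n, dtype=bool)
    for start, length in runs:
        if length + 1 >= pss_min_nn:
            long_mask[start : start + length + 1] = True
    pss = 100.0 - 100.0 * int(long_mask.sum()) / n

    # alternation runs: maximal stretches where successive increments are
    # both nonzero and of opposite sign
    alt_mask = np.zeros(n, dtype=bool)
    flips = (s[:-1] != 0) & (s[1:] != 0) & (s[:-1] == -s[1:])
    for start, length, val in _runs(flips.astype(int)):
        if val == 1:
            # run of `length` flips = length+1 increments = length+2 NN intervals
            if length + 2 >= pas_min_nn:
                alt_mask[start : start + length + 2] = True
    pas = 100.0 * int(alt_mask.sum()) / n

    return pip, ials, pss, pas


def poincare(intervals: np.ndarray) -> tuple[float, float, float]:
    """Poincaré-plot dispersion (SD1, SD2, SD1/SD2).

    SD1 = sqrt(Var(DeltaNN)/2) measures spread across the identity line of
    the lag-1 return map (short-range variability); SD2 =
    sqrt(2 Var(NN) - Var(DeltaNN)/2) measures spread along it (long-range).
    Sample variances (N-1).  The ratio is NaN when SD2 = 0.
    """
    x = _require(intervals, 3, "poincare")
    var_d = float(np.var(np.diff(x), ddof=1))
    var_x = float(np.var(x, ddof=1))
    sd1 = math.sqrt(var_d / 2.0)
    sd2 = math.sqrt(max(2.0 * var_x - var_d / 2.0, 0.0))
    ratio = sd1 / sd2 if sd2 > 0 else math.nan
    return sd1, sd2, ratio


def sample_entropy(intervals: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy: -ln(A/B) with template lengths m+1 (A) and m (B).

    Chebyshev distance, tolerance r = ``r_frac`` times the sample SD,
    self-matches excluded.  NaN when either count is zero.
    """
    x = _require(intervals, m + 2, "sample_entropy")
    n = x.size
    r = r_frac * float(np.std(x, ddof=1))
    if r == 0:
        # constant series: every template matches at both lengths
        return 0.0

    def count_matches(mm: int, n_templates: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)[:n_templates]
        total = 0
        for i in range(n_templates - 1):
            dist = np.max(np.abs(templ[i + 1 :] - templ[i]), axis=1)
            total += int(np.count_nonzero(dist <= r))
        return total

    # both counts use the same n-m template starting points
    a = count_matches(m + 1, n - m)  # matches at length m+1
    b = count_matches(m, n - m)      # matches at length m
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def dfa(
    intervals: np.ndarray,
    short_range: tuple[int, int] = DFA_SHORT_RANGE,
    long_range: tuple[int, int] = DFA_LONG_RANGE,
) -> tuple[float, float]:
    """First-order detrended fluctuation analysis scaling exponents (alpha1, alpha2).

    The mean-centred series is integrated, split into non-overlapping boxes
    of n beats, linearly detrended per box, and the RMS fluctuation F(n)
    computed; alpha is the least-squares slope of log10 F vs log10 n over
    the short (default 4-15) and long (default 16-64) box ranges.  If the
    series is too short for the largest box the long range shrinks.
    """
    x = _require(intervals, 2 * short_range[1], "dfa")
    n = x.size
    y = np.cumsum(x - x.mean())

    lo2, hi2 = long_range
    if hi2 > n // 2:
        hi2 = max(n // 2, lo2)

    def fluctuation(box: int) -> float:
        n_box = n // box
        seg = y[: n_box * box].reshape(n_box, box)
        t = np.arange(box, dtype=float)
        t_c = t - t.mean()
        denom = float(np.sum(t_c**2))
        slope = seg @ t_c / denom
        mean = seg.mean(axis=1)
        detr = seg - mean[:, None] - slope[:, None] * t_c[None, :]
        return float(np.sqrt(np.mean(detr**2)))

    def alpha(lo: int, hi: int) -> float:
        boxes = np.arange(lo, hi + 1)
        boxes = boxes[boxes <= n // 2]
        if boxes.size < 2:
            return math.nan
        f = np.array([fluctuation(int(b)) for b in boxes])
        ok = f > 0
        if ok.sum() < 2:
            return math.nan
        return float(np.polyfit(np.log10(boxes[ok]), np.log10(f[ok]), 1)[0])

    return alpha(*short_range), alpha(lo2, hi2)


def compute_hrv_record(
    intervals: np.ndarray,
    pnn_threshold: float = 5.0,
    sampen_m: int = 2,
    sampen_r_frac: float = 0.2,
) -> HRVRecord:
    """All time-domain, fragmentation and nonlinear metrics for one window.

    Metrics whose preconditions the segment cannot meet are NaN rather than
    errors, so short windows still yield the defined subset.
    """
    x = np.asarray(intervals, dtype=float).ravel()
    rec = HRVRecord(n_intervals=x.size)
    if x.size >= 1:
        rec.mean_rr = mean_rr(x)
    if x.size >= 2:
        rec.sdnn = sdnn(x)
        rec.pnn5 = pnn5(x, threshold=pnn_threshold)
    if x.size >= 3:
        rec.sd1, rec.sd2, rec.sd1_sd2 = poincare(x)
    if x.size >= 5:
        rec.pip, rec.ials, rec.pss, rec.pas = fragmentation(x)
    if x.size >= 100:
        rec.sampen = sample_entropy(x, m=sampen_m, r_frac=sampen_r_frac)
    if x.size >= 200:
        rec.dfa_alpha1, rec.dfa_alpha2 = dfa(x)
    return rec
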