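"""Independent brute-force reference implementations used only by tests.

These are deliberately written in plain-loop style, structured differently
from the package code, so agreement is evidence of correctness rather than
shared bugs.
"""

from __future__ import annotations

import math

import numpy as np


def sdnn_oracle(x) -> float:
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    return math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))


def pnn_oracle(x, threshold: float = 5.0) -> float:
    x = list(map(float, x))
    count = 0
    for a, b in zip(x[:-1], x[1:]):
        if abs(b - a) > threshold:
            count += 1
    return 100.0 * count / (len(x) - 1)


def _sign(v: float) -> int:
    return (v > 0) - (v < 0)


def fragmentation_oracle(x) -> tuple[float, float, float, float]:
    """(pip, ials, pss, pas) by direct scanning of the increment series."""
    x = list(map(float, x))
    n = len(x)
    d = [b - a for a, b in zip(x[:-1], x[1:])]

    inflections = 0
    for i in range(len(d) - 1):
        if d[i] * d[i + 1] <= 0:
            inflections += 1
    pip = 100.0 * inflections / n

    # maximal same-sign runs (zeros break runs)
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(d):
        if _sign(d[i]) == 0:
            i += 1
            continue
        j = i
        while j + 1 < len(d) and _sign(d[j + 1]) == _sign(d[i]):
            j += 1
        runs.append((i, j - i + 1))
        i = j + 1
    ials = len(runs) / sum(length for _, length in runs) if runs else math.nan

    long_intervals: set[int] = set()
    for start, length in runs:
        if length + 1 >= 3:  # run of k increments spans k+1 NN intervals
            long_intervals.update(range(start, start + length + 1))
    pss = 100.0 - 100.0 * len(long_intervals) / n

    alt_intervals: set[int] = set()
    i = 0
    while i < len(d) - 1:
        if _sign(d[i]) != 0 and _sign(d[i + 1]) == -_sign(d[i]):
            j = i
            while (j + 1 < len(d) and _sign(d[j]) != 0
                   and _sign(d[j + 1]) == -_sign(d[j])):
                j += 1
            # increments i..j alternate strictly -> beats i..j+1
            if (j + 1) - i + 1 >= 4:
                alt_intervals.update(range(i, j + 2))
            i = j + 1
        else:
            i += 1
    pas = 100.0 * len(alt_intervals) / n

    return pip, ials, pss, pas


def sampen_oracle(x, m: int = 2, r_frac: float = 0.2) -> float:
    """O(N^2) sample entropy with explicit loops."""
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    r = r_frac * sd
    if r == 0:
        return 0.0

    def count(mm: int) -> int:
        total = 0
        for i in range(n - m - 1):
            for j in range(i + 1, n - m):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    total += 1
        return total

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def poincare_projection_oracle(x) -> tuple[float, float]:
    """SD1/SD2 as dispersions of the lag-1 point cloud projected on the
    +-45 degree principal axes."""
    x = np.asarray(x, dtype=float)
    u, v = x[:-1], x[1:]
    p_minor = (v - u) / math.sqrt(2)
    p_major = (v + u) / math.sqrt(2)
    return float(np.std(p_minor, ddof=1)), float(np.std(p_major, ddof=1))


def pitman_morgan_regression_oracle(x, y) -> tuple[float, float]:
    """Pitman-Morgan via the correlation of the sum and difference scores."""
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r, p = stats.pearsonr(x + y, x - y)
    n = x.size
    t = r * math.sqrt((n - 2) / (1.0 - r**2))
    return t, p
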