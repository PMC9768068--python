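"""Power spectral density of RR tachograms and murine band powers.

The unevenly sampled RR series is turned into an evenly sampled tachogram
by cubic-spline interpolation of RR (ms) against cumulative beat time at
``resample_hz`` (default 20 Hz, keeping the 5 Hz upper HF edge well below
Nyquist), mean-centred, and its PSD estimated either by a Burg
autoregressive model (default, order 30) or by Welch's method (used as the
cross-check path).

Murine frequency bands: VLF 0.0056-0.152 Hz, LF 0.152-1.24 Hz,
HF 1.24-5 Hz.  Normalised LF%/HF% use the (total - VLF) denominator; VLF%
uses the total-power denominator.  beta is the log-log spectral slope below
the VLF upper edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline
from statsmodels.regression.linear_model import burg as _burg

from hrvaging.io_preprocess import AnalysisWindow

__all__ = [
    "BandDefinition",
    "WindowSpectrum",
    "band_powers",
    "beta_slope",
    "estimate_psd",
    "resample_tachogram",
]

DEFAULT_AR_ORDER = 30
DEFAULT_RESAMPLE_HZ = 20.0
#: frequency-grid spacing (Hz); fine enough for the VLF band
DEFAULT_DF = 0.002


class TooShortError(ValueError):
    """Window too short for the requested spectral estimator."""


@dataclass(frozen=True)
class BandDefinition:
    """Murine VLF/LF/HF band edges in Hz (contiguous, increasing)."""

    vlf: tuple[float, float] = (0.0056, 0.152)
    lf: tuple[float, float] = (0.152, 1.24)
    hf: tuple[float, float] = (1.24, 5.0)

    def __post_init__(self) -> None:
        edges = [self.vlf[0], self.vlf[1], self.lf[0], self.lf[1], self.hf[0], self.hf[1]]
        if not (edges[0] < edges[1] == edges[2] < edges[3] == edges[4] < edges[5]):
            raise ValueError(f"band edges must be contiguous and increasing, got {edges}")


@dataclass
class WindowSpectrum:
    """PSD of one analysis window plus band summaries."""

    freqs: np.ndarray          # Hz
    psd: np.ndarray            # ms^2/Hz, one-sided
    total_power: float         # ms^2 (integral over the spectral support)
    vlf: float = math.nan      # ms^2
    lf: float = math.nan
    hf: float = math.nan
    vlf_pct: float = math.nan
    lf_pct: float = math.nan
    hf_pct: float = math.nan
    lf_hf: float = math.nan
    beta: float = math.nan
    f_peak_hf: float = math.nan
    bands: BandDefinition = field(default_factory=BandDefinition)

    def psd_at(self, f: float) -> float:
        """PSD evaluated at the nearest grid frequency."""
        i = int(np.argmin(np.abs(self.freqs - f)))
        return float(self.psd[i])

    def peak_freq(self, band: tuple[float, float] | None = None) -> float:
        """Frequency of the PSD maximum, optionally restricted to a band."""
        mask = np.ones_like(self.freqs, dtype=bool)
        if band is not None:
            mask = (self.freqs >= band[0]) & (self.freqs <= band[1])
        idx = np.flatnonzero(mask)
        return float(self.freqs[idx[np.argmax(self.psd[idx])]])


def resample_tachogram(
    intervals: np.ndarray, resample_hz: float = DEFAULT_RESAMPLE_HZ
) -> tuple[np.ndarray, float]:
    """Cubic-spline resample of RR (ms) vs cumulative time onto an even grid.

    Returns (samples, fs).  The tachogram is evaluated at each interval's
    closing-beat time, the natural instant at which that RR is observed.
    """
    x = np.asarray(intervals, dtype=float)
    if x.size < 4:
        raise TooShortError("need >= 4 intervals to build a tachogram")
    t = np.cumsum(x) / 1000.0
    spline = CubicSpline(t, x)
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    return spline(grid), resample_hz


def _ar_psd(samples: np.ndarray, fs: float, order: int, freqs: np.ndarray) -> np.ndarray:
    """One-sided Burg AR PSD on the given frequency grid, Parseval-normalised."""
    var = float(np.var(samples))
    if var < 1e-12:
        return np.zeros_like(freqs)
    rho, sigma2 = _burg(samples, order=order, demean=True)
    # AR(p): x_t = sum rho_k x_{t-k} + e_t  ->  S(f) = sigma2 / (fs |A(f)|^2), one-sided x2
    w = 2.0 * np.pi * freqs / fs
    k = np.arange(1, order + 1)
    a = 1.0 - np.exp(-1j * np.outer(w, k)) @ rho
    psd = 2.0 * sigma2 / (fs * np.abs(a) ** 2)
    # exact Parseval contract: integral over [0, Nyquist] equals the variance
    integral = float(np.trapezoid(psd, freqs))
    if integral > 0:
        psd = psd * (var / integral)
    return psd


def estimate_psd(
    window: AnalysisWindow | np.ndarray,
    method: Literal["ar", "welch"] = "ar",
    ar_order: int = DEFAULT_AR_ORDER,
    resample_hz: float = DEFAULT_RESAMPLE_HZ,
    df: float = DEFAULT_DF,
    bands: BandDefinition | None = None,
) -> WindowSpectrum:
    """Estimate the one-sided PSD of a window's RR series and its band powers.

    The AR path evaluates the Burg model on a uniform grid of spacing
    ``df`` and is rescaled so the integral over [0, Nyquist] equals the
    variance of the (mean-centred) resampled tachogram.  The Welch path
    returns scipy's density estimate unmodified and serves as the
    independent cross-check of that Parseval contract.
    """
    intervals = window.intervals if isinstance(window, AnalysisWindow) else np.asarray(window, float)
    samples, fs = resample_tachogram(intervals, resample_hz)
    if method == "ar" and samples.size < 4 * ar_order:
        raise TooShortError(
            f"window has {samples.size} samples; AR order {ar_order} needs >= {4 * ar_order}"
        )
    samples = samples - samples.mean()
    nyq = fs / 2.0
    if method == "ar":
        freqs = np.arange(0.0, nyq + df / 2, df)
        psd = _ar_psd(samples, fs, ar_order, freqs)
    elif method == "welch":
        # boxcar segments without overlap or per-segment detrending keep the
        # periodogram-average integral equal to the series mean square, so
        # the Parseval contract holds without rescaling
        # segment length chosen so the segments tile the series (at most
        # n_seg-1 trailing samples dropped), keeping the integral equal to
        # the full-series mean square
        n_seg = max(1, math.ceil(samples.size / 2048))
        nperseg = samples.size // n_seg
        freqs, psd = signal.welch(samples, fs=fs, window="boxcar", nperseg=nperseg,
                                  noverlap=0, detrend=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    total = float(np.trapezoid(psd, freqs))
    spec = WindowSpectrum(freqs=freqs, psd=psd, total_power=total)
    return band_powers(spec, bands or BandDefinition())


def band_powers(spec: WindowSpectrum, bands: BandDefinition | None = None) -> WindowSpectrum:
    """Fill in band powers, normalised percentages, LF/HF, beta and the HF peak.

    Band power is the trapezoidal integral of the PSD over the band;
    lf_pct/hf_pct use the (total - VLF) denominator, vlf_pct the total.
    Percentages are NaN when total - VLF <= 0.
    """
    bands = bands or spec.bands
    spec.bands = bands

    def integrate(band: tuple[float, float]) -> float:
        lo, hi = band
        f, p = spec.freqs, spec.psd
        mask = (f >= lo) & (f <= hi)
        ff, pp = f[mask], p[mask]
        # close the band edges by interpolation so refinement converges
        if ff.size == 0 or ff[0] > lo:
            ff = np.insert(ff, 0, lo)
            pp = np.insert(pp, 0, np.interp(lo, f, p))
        if ff[-1] < hi <= f[-1]:
            ff = np.append(ff, hi)
            pp = np.append(pp, np.interp(hi, f, p))
        return float(np.trapezoid(pp, ff))

    spec.vlf = integrate(bands.vlf)
    spec.lf = integrate(bands.lf)
    spec.hf = integrate(bands.hf)
    total = spec.total_power
    denom = total - spec.vlf
    spec.vlf_pct = 100.0 * spec.vlf / total if total > 0 else math.nan
    if denom > 0:
        spec.lf_pct = 100.0 * spec.lf / denom
        spec.hf_pct = 100.0 * spec.hf / denom
    else:
        spec.lf_pct = spec.hf_pct = math.nan
    spec.lf_hf = spec.lf / spec.hf if spec.hf > 0 else math.nan
    spec.beta = beta_slope(spec)
    spec.f_peak_hf = spec.peak_freq(bands.hf)
    return spec


def beta_slope(spec: WindowSpectrum, f_max: float | None = None) -> float:
    """Log-log spectral slope for 0 < f <= VLF upper edge (power-law exponent).

    Least-squares slope of log10 PSD vs log10 f; NaN with fewer than 4
    usable grid points.
    """
    f_max = f_max if f_max is not None else spec.bands.vlf[1]
    mask = (spec.freqs > 0) & (spec.freqs <= f_max) & (spec.psd > 0)
    if mask.sum() < 4:
        return math.nan
    lf = np.log10(spec.freqs[mask])
    lp = np.log10(spec.psd[mask])
    return float(np.polyfit(lf, lp, 1)[0])
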