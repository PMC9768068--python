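"""Quality control of dual autonomic blockade from paired window spectra.

Atropine + propranolol abolish the vagal respiratory modulation that
dominates the murine HF band, so a successful ("complete") blockade shows
either a collapsed HF spectral peak or a broad drop in total RR power.
The decision compares basal and blocked ("abk") recordings of the same
mouse and age:

1. the representative HF peak frequency f_peak is the mean over basal
   windows of the argmax of the PSD inside the HF band;
2. each mode's normalised peak height is
   H_bar = (1/(S N)) * sum_j H_j(f_peak), with H_j the j-th window's PSD,
   N the number of windows in that mode, and S the total power summed over
   that mode's windows (the double 1/(S N) normalisation is applied exactly
   as defined, making H_bar a per-window-pair normalised density);
3. the mean total power per window is S_bar = S / N (a per-window average,
   because blocked recordings are typically much longer than basal ones).

Blockade passes if H_bar_abk / H_bar_basal < 0.5 (peak criterion) OR
S_bar_abk / S_bar_basal < 0.7 (power criterion); ratios exactly at the
threshold fail.  Recordings that fail are excluded from downstream
analysis in both states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from hrvaging.io_preprocess import InsufficientDataError
from hrvaging.spectral import BandDefinition, WindowSpectrum

__all__ = [
    "BlockadeDecision",
    "decide_blockade",
    "mean_hf_peak_freq",
    "normalized_peak_height",
    "qc_cohort",
    "qc_summary_by_age",
]

PEAK_RATIO_THRESHOLD = 0.5
POWER_RATIO_THRESHOLD = 0.7


@dataclass
class BlockadeDecision:
    """QC verdict for one (mouse, age) with all intermediate ratios."""

    mouse_id: str = ""
    age_months: float = math.nan
    f_peak_bar: float = math.nan
    h_bar_basal: float = math.nan
    h_bar_abk: float = math.nan
    s_bar_basal: float = math.nan
    s_bar_abk: float = math.nan
    peak_ratio: float = math.nan
    power_ratio: float = math.nan
    criterion_peak: bool = False
    criterion_power: bool = False
    passed: bool = False
    n_windows_basal: int = 0
    n_windows_abk: int = 0
    undecidable: bool = False


def mean_hf_peak_freq(
    basal_spectra: Sequence[WindowSpectrum],
    band: tuple[float, float] | None = None,
) -> float:
    """Mean over basal windows of the PSD argmax frequency inside the HF band.

    ``band=None`` uses each spectrum's own HF edges; pass an explicit pair
    (or ``(0, inf)``) to search another range.
    """
    if len(basal_spectra) == 0:
        raise InsufficientDataError("mean_hf_peak_freq: no basal windows")
    peaks = [s.peak_freq(band if band is not None else s.bands.hf) for s in basal_spectra]
    return float(np.mean(peaks))


def normalized_peak_height(spectra: Sequence[WindowSpectrum], f: float) -> float:
    """H_bar = sum_j PSD_j(f) / (S * N), S = summed total power, N = #windows.

    PSD is evaluated at the nearest grid point to ``f``.  NaN when S = 0.
    """
    if len(spectra) == 0:
        raise InsufficientDataError("normalized_peak_height: no windows")
    s_total = float(sum(s.total_power for s in spectra))
    if s_total == 0:
        return math.nan
    height_sum = float(sum(s.psd_at(f) for s in spectra))
    return height_sum / (s_total * len(spectra))


def decide_blockade(
    basal: Sequence[WindowSpectrum],
    abk: Sequence[WindowSpectrum],
    mouse_id: str = "",
    age_months: float = math.nan,
    peak_threshold: float = PEAK_RATIO_THRESHOLD,
    power_threshold: float = POWER_RATIO_THRESHOLD,
    peak_band: tuple[float, float] | None = None,
) -> BlockadeDecision:
    """Apply the two-criterion blockade test to paired basal/abk spectra.

    The representative peak frequency comes from basal windows only and is
    reused for the blocked mode.  Either sequence empty makes the record
    undecidable (flagged for exclusion) rather than an error.
    """
    dec = BlockadeDecision(mouse_id=mouse_id, age_months=age_months,
                           n_windows_basal=len(basal), n_windows_abk=len(abk))
    if len(basal) == 0 or len(abk) == 0:
        dec.undecidable = True
        return dec
    f_bar = mean_hf_peak_freq(basal, band=peak_band)
    dec.f_peak_bar = f_bar
    dec.h_bar_basal = normalized_peak_height(basal, f_bar)
    dec.h_bar_abk = normalized_peak_height(abk, f_bar)
    dec.s_bar_basal = float(sum(s.total_power for s in basal)) / len(basal)
    dec.s_bar_abk = float(sum(s.total_power for s in abk)) / len(abk)
    with np.errstate(divide="ignore", invalid="ignore"):
        dec.peak_ratio = (
            dec.h_bar_abk / dec.h_bar_basal if dec.h_bar_basal > 0 else math.nan
        )
        dec.power_ratio = (
            dec.s_bar_abk / dec.s_bar_basal if dec.s_bar_basal > 0 else math.nan
        )
    dec.criterion_peak = bool(dec.peak_ratio < peak_threshold)
    dec.criterion_power = bool(dec.power_ratio < power_threshold)
    dec.passed = dec.criterion_peak or dec.criterion_power
    return dec


def qc_cohort(
    spectra_store: dict[tuple[str, float, str], Sequence[WindowSpectrum]],
    peak_threshold: float = PEAK_RATIO_THRESHOLD,
    power_threshold: float = POWER_RATIO_THRESHOLD,
) -> pd.DataFrame:
    """One blockade decision per (mouse, age) present in the spectra store.

    ``spectra_store`` maps (mouse_id, age_months, state) to that
    recording's window spectra.  Pairs with a missing state are flagged
    undecidable and excluded from pass-rate denominators.
    """
    pairs = sorted({(m, a) for (m, a, _s) in spectra_store})
    rows = []
    for mouse, age in pairs:
        basal = spectra_store.get((mouse, age, "basal"), [])
        abk = spectra_store.get((mouse, age, "abk"), [])
        dec = decide_blockade(basal, abk, mouse_id=mouse, age_months=age,
                              peak_threshold=peak_threshold, power_threshold=power_threshold)
        rows.append(dec.__dict__.copy())
    columns = list(BlockadeDecision().__dict__)
    return pd.DataFrame(rows, columns=columns)


def qc_summary_by_age(decisions: pd.DataFrame) -> pd.DataFrame:
    """Per-age counts and percentage of mice passing the blockade criteria."""
    usable = decisions[~decisions["undecidable"]]
    if usable.empty:
        return pd.DataFrame(columns=["age_months", "n_mice", "n_pass", "pct_pass"])
    grouped = usable.groupby("age_months")["passed"]
    out = pd.DataFrame({
        "age_months": grouped.size().index,
        "n_mice": grouped.size().to_numpy(),
        "n_pass": grouped.sum().to_numpy().astype(int),
    })
    out["pct_pass"] = 100.0 * out["n_pass"] / out["n_mice"]
    return out.reset_index(drop=True)
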