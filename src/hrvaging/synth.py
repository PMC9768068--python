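"""Synthetic life-course RR-interval cohorts with known ground truth.

The generator emulates the phenomenology of longitudinal murine EKG
studies with paired basal / double-autonomic-blockade ("abk") recordings,
so every pipeline stage can be exercised without animal data:

* mean intrinsic RR stable from 6 to 21 months, then rising steeply to
  about +50% by 30 months (quadratic late-life rise); basal RR rises less
  because autonomic input partially compensates;
* a high-frequency (respiratory-band, ~2.5 Hz) sinusoidal modulation that
  is strong in the basal state and almost abolished after blockade;
* a very-low-frequency oscillation and long-range-correlated fractional
  Gaussian noise whose amplitude / scaling exponent rise with age
  (driving %VLF and DFA alpha2 upward);
* injected "ABAB" alternans runs covering an age-dependent fraction of
  beats (driving PAS upward late in life);
* rare ectopic outliers; and
* per-mouse random intercepts and late-life slopes, with survival dropout
  after 24 months mimicking the shrinking late-life n.

Everything is deterministic given (seed, mouse, age, state).  A separate
table-level generator draws directly from a quadratic mixed-effects model
for testing the longitudinal machinery in isolation.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from hrvaging.io_preprocess import DEFAULT_VISIT_AGES, CohortManifest, RRSeries, State

__all__ = [
    "LMETruth",
    "SimulatedCohort",
    "SynthConfig",
    "fractional_gaussian_noise",
    "simulate_cohort",
    "simulate_metric_table",
    "simulate_rr",
]


@dataclass(frozen=True)
class LMETruth:
    """Ground-truth quadratic mixed-model parameters for one metric."""

    beta0: float
    beta1: float
    beta2: float = 0.0
    sd_b0: float = 0.0
    sd_b1: float = 0.0
    sd_b2: float = 0.0
    sigma_eps: float = 1.0


def _default_lme_truth() -> dict[str, LMETruth]:
    # magnitudes loosely shaped like late-life murine mean-RR trajectories
    return {
        "mean_rr": LMETruth(beta0=400.0, beta1=2.0, beta2=0.5,
                            sd_b0=20.0, sd_b1=1.0, sd_b2=0.0, sigma_eps=5.0),
    }


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Schedules are mappings age -> value, linearly interpolated between the
    listed ages; amplitudes are in ms.
    """

    n_mice: int = 56
    visit_ages: Sequence[float] = DEFAULT_VISIT_AGES
    seed: int = 0

    mean_rr_young: float = 100.0          # ms, both states at 6 months
    mean_rr_rise_frac: float = 0.5        # intrinsic fractional rise from 21 to 30 months
    basal_rise_frac: float = 0.2          # basal fractional rise (autonomic compensation)
    rise_onset_age: float = 21.0

    hf_freq: float = 2.5                  # Hz, respiratory band (young)
    hf_freq_by_age: Mapping[float, float] = field(
        default_factory=lambda: {6.0: 1.0, 34.0: 0.78})  # breathing slows with age
    hf_amp_basal: float = 6.0             # ms
    hf_amp_abk_frac: float = 0.25         # blockade strongly suppresses HF modulation
    hf_amp_by_age: Mapping[float, float] = field(
        default_factory=lambda: {6.0: 1.0, 21.0: 0.85, 27.0: 0.65, 34.0: 0.25})

    vlf_freq: float = 0.05                # Hz
    vlf_amp_by_age: Mapping[float, float] = field(
        default_factory=lambda: {6.0: 1.0, 21.0: 1.5, 30.0: 4.5, 34.0: 5.0})
    lf_freq: float = 0.5                  # Hz, slow (baroreflex-band) rhythm
    lf_amp_by_age: Mapping[float, float] = field(
        default_factory=lambda: {6.0: 0.0, 21.0: 0.0, 30.0: 0.0})

    noise_sd: float = 2.0                 # ms, fGn component at 6 months
    noise_sd_by_age: Mapping[float, float] = field(
        default_factory=lambda: {6.0: 1.0, 34.0: 1.2})
    noise_smooth_by_age: Mapping[float, float] = field(
        default_factory=lambda: {6.0: 5.0, 34.0: 5.0})
    longrange_alpha_by_age: Mapping[float, float] = field(
        default_factory=lambda: {6.0: 0.9, 21.0: 1.0, 34.0: 1.5})

    alternans_pct_by_age: Mapping[float, float] = field(
        default_factory=lambda: {6.0: 5.0, 21.0: 10.0, 34.0: 70.0})
    alternans_amp: float = 0.25           # ms, floor of the ABAB half peak-to-peak

    ectopic_rate: float = 0.002           # per beat
    ectopic_shift_ms: float = 60.0

    dropout_hazard: float = 0.25          # per visit beyond 24 months
    dropout_onset_age: float = 24.0

    basal_duration_s: float = 360.0
    abk_duration_s: float = 900.0

    rr_intercept_sd: float = 3.0          # ms, per-mouse intercept
    aging_rate_sd: float = 0.3            # SD of the per-mouse late-life aging-rate latent

    lme_truth: dict[str, LMETruth] = field(default_factory=_default_lme_truth)

    def schedule(self, mapping: Mapping[float, float], age: float) -> float:
        ages = np.array(sorted(mapping))
        vals = np.array([mapping[a] for a in ages])
        return float(np.interp(age, ages, vals))


def fractional_gaussian_noise(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance fractional Gaussian noise by circulant embedding.

    Valid for 0 < H < 1; H = 0.5 is white noise.  Negative circulant
    eigenvalues (possible for small n) are clipped to zero, a standard and
    here negligible approximation.
    """
    if not 0 < hurst < 1:
        raise ValueError("hurst must be in (0, 1)")
    if hurst == 0.5:
        return rng.standard_normal(n)
    k = np.arange(n)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * hurst) - 2 * np.abs(k) ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.fft(row).real
    eig = np.clip(eig, 0.0, None)
    m = row.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.fft(np.sqrt(eig / m) * z)
    return x.real[:n]


def longrange_noise(n: int, alpha: float, rng: np.random.Generator,
                    smooth_beats: int = 3) -> np.ndarray:
    """Unit-SD 1/f^beta noise with DFA-1 scaling exponent ~``alpha``.

    Synthesised spectrally: white Gaussian noise is shaped to a power-law
    PSD proportional to f^(-beta) with beta = 2*alpha - 1, for which the
    DFA exponent is alpha = (beta + 1)/2 — continuously valid across the
    stationary and non-stationary regimes (alpha = 0.5 is white noise,
    1.0 is pink, 1.5 is Brownian).  Standardising leaves the exponent
    unchanged.

    ``smooth_beats`` applies a short moving average so the noise does not
    itself alternate sign every beat (pacemaker memory makes real
    beat-to-beat noise smooth at this scale); widening it removes fast
    fluctuations, emulating the age-associated loss of short RR intervals.
    Box sizes of a few beats and above, and hence the scaling exponents,
    are essentially unaffected at the default width.
    """
    beta = 2.0 * alpha - 1.0
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid the DC singularity; the mean is removed anyway
    x = np.fft.irfft(spec * f ** (-beta / 2.0), n)
    if smooth_beats > 1:
        x = np.convolve(x, np.ones(smooth_beats) / smooth_beats, mode="same")
    sd = float(np.std(x))
    return (x - float(np.mean(x))) / (sd if sd > 0 else 1.0)


def _rng_for(config: SynthConfig, mouse_id: str, *context: object) -> np.random.Generator:
    tokens = [int(config.seed) & 0x7FFFFFFF, zlib.crc32(mouse_id.encode()) & 0x7FFFFFFF]
    tokens += [zlib.crc32(str(c).encode()) & 0x7FFFFFFF for c in context]
    return np.random.default_rng(tokens)


def _mouse_traits(config: SynthConfig, mouse_id: str) -> tuple[float, float]:
    """Per-mouse latent traits: RR intercept (ms) and aging-rate deviation.

    The aging rate gamma is one shared latent: a mouse with gamma > 0 walks
    through the whole late-life program (mean-RR rise, alternans, spectral
    shifts, scaling-exponent rise) faster than its calendar age.
    """
    rng = _rng_for(config, mouse_id, "traits")
    intercept = rng.normal(0.0, config.rr_intercept_sd)
    gamma = float(np.clip(rng.normal(0.0, config.aging_rate_sd), -0.8, 2.0))
    return float(intercept), gamma


def effective_age(config: SynthConfig, mouse_id: str, age: float) -> float:
    """Calendar age warped by the mouse's aging-rate latent beyond the onset age.

    Capped at a modest extrapolation beyond the last visit age so even the
    fastest ager keeps a physiological mean RR (below the range-filter
    ceiling).
    """
    onset = config.rise_onset_age
    if age <= onset:
        return float(age)
    _, gamma = _mouse_traits(config, mouse_id)
    span = max(config.visit_ages[-1] - onset, 1e-9)
    warped = (age - onset) * (1.0 + gamma)
    return float(onset + min(warped, 1.45 * span))


def mean_rr_truth(config: SynthConfig, mouse_id: str, age: float, state: State) -> float:
    """Ground-truth mean RR (ms) for a (mouse, age, state)."""
    intercept, _ = _mouse_traits(config, mouse_id)
    onset = config.rise_onset_age
    span = max(config.visit_ages[-1] - onset, 1e-9)
    ae = effective_age(config, mouse_id, age)
    rise_shape = max(ae - onset, 0.0) ** 2 / span**2
    frac = config.mean_rr_rise_frac if state == "abk" else config.basal_rise_frac
    return (config.mean_rr_young + intercept) * (1.0 + frac * rise_shape)


def _alternation_flip_runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of >= 2 consecutive increment sign flips, as (first_flip, n_flips).

    A run of k flips spans k+2 NN intervals, so k >= 2 is exactly the
    "alternation segment of >= 4 intervals" that the PAS metric counts.
    """
    d = np.diff(x)
    s = np.sign(d).astype(int)
    flips = (s[:-1] != 0) & (s[1:] != 0) & (s[:-1] == -s[1:])
    runs = []
    i = 0
    n = flips.size
    while i < n:
        if flips[i]:
            j = i
            while j < n and flips[j]:
                j += 1
            if j - i >= 2:
                runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def _break_alternation(x: np.ndarray, max_sweeps: int = 50,
                       protect: np.ndarray | None = None) -> np.ndarray:
    """Suppress spontaneous ABAB runs so injected alternans controls PAS.

    Each sweep replaces one beat near the middle of every alternation run
    with the midpoint of its neighbours, which zeroes the adjacent
    increments and splits the run; sweeps repeat until no countable run
    remains.  Perturbations are single-beat and local, so the spectral and
    long-range structure of the series is essentially untouched.

    ``protect`` marks beats that must not be modified (injected alternans
    runs); runs lying wholly inside the protected region are intended
    alternation and are left alone.
    """
    out = x.copy()
    for _ in range(max_sweeps):
        runs = _alternation_flip_runs(out)
        progress = False
        for first, n_flips in runs:
            # flip i involves beats i .. i+2; candidate repair beats are
            # the run's interior, preferring the middle
            lo, hi = first + 1, first + n_flips + 1
            mid = first + 1 + n_flips // 2
            candidates = sorted(range(lo, hi + 1), key=lambda m: abs(m - mid))
            for m in candidates:
                if m < 1 or m >= out.size - 1:
                    continue
                if protect is not None and protect[m]:
                    continue
                out[m] = 0.5 * (out[m - 1] + out[m + 1])
                progress = True
                break
        if not runs or not progress:
            break
    return out


def _inject_alternans(x: np.ndarray, target_pct: float, amp: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Replace contiguous runs with a strict ABAB pattern until coverage is met.

    Run lengths are 4 + geometric; replacing runs (rather than scattering
    single beats) makes PAS and PSS respond together, as in real
    fragmented rhythms.
    """
    n = x.size
    target = int(round(n * target_pct / 100.0))
    covered = np.zeros(n, dtype=bool)
    out = x.copy()
    injected = 0
    attempts = 0
    while injected < target and attempts < 20 * n:
        attempts += 1
        length = 4 + int(rng.geometric(0.45))
        start = int(rng.integers(1, max(n - length - 1, 2)))
        guard = slice(start - 1, start + length + 1)
        if covered[guard].any():
            continue
        # alternate around a linear local baseline so the run keeps the
        # series' slow structure (a flat pattern would erase the long-range
        # fluctuations wherever coverage is high)
        baseline = np.linspace(float(x[start]), float(x[start + length - 1]), length)
        slope = abs(baseline[1] - baseline[0]) if length > 1 else 0.0
        # amplitude tracks the local increment scale (so the alternation
        # replaces roughly as much beat-scale power as it removes) and
        # shrinks as 1/sqrt(coverage): total alternans power then stays
        # constant as PAS grows, leaving the HF band to the respiratory
        # component.  The local slope is added so the signs truly alternate.
        local_inc_sd = float(np.std(np.diff(x[max(start - 1, 0): start + length + 1])))
        cov_scale = math.sqrt(20.0 / max(target_pct, 5.0))
        amp_run = 0.51 * slope + max(amp, 0.4 * local_inc_sd) * cov_scale
        pattern = baseline + amp_run * np.where(np.arange(length) % 2 == 0, 1.0, -1.0)
        out[start : start + length] = pattern
        # zero-increment guard beats stop the alternation exactly at the run
        # edges, so the injected coverage is what the PAS metric measures
        out[start - 1] = pattern[0]
        out[start + length] = pattern[-1]
        covered[guard] = True
        injected += length
    # boundary edits can seed spurious alternation just outside the runs;
    # clean it up without touching the injected beats
    return _break_alternation(out, protect=covered)


def simulate_rr(config: SynthConfig, mouse_id: str, age: float, state: State) -> RRSeries:
    """Generate one synthetic RR-interval recording.

    RR_i = mu(age, state, mouse) + HF sinusoid + VLF oscillation +
    long-range fGn + injected alternans runs + rare ectopic outliers.
    Deterministic given (config.seed, mouse_id, age, state).
    """
    rng = _rng_for(config, mouse_id, age, state)
    mu = mean_rr_truth(config, mouse_id, age, state)
    duration = config.basal_duration_s if state == "basal" else config.abk_duration_s
    n = int(np.ceil(duration * 1000.0 / mu)) + 1

    ae = effective_age(config, mouse_id, age)  # schedules follow the aging latent
    t = np.arange(n) * (mu / 1000.0)  # nominal beat times for modulation phases
    hf_amp = config.hf_amp_basal * config.schedule(config.hf_amp_by_age, ae)
    hf_freq = config.hf_freq * config.schedule(config.hf_freq_by_age, ae)
    if state == "abk":
        hf_amp *= config.hf_amp_abk_frac
    vlf_amp = config.schedule(config.vlf_amp_by_age, ae)
    phase_hf = rng.uniform(0, 2 * np.pi)
    phase_vlf = rng.uniform(0, 2 * np.pi)

    lf_amp = config.schedule(config.lf_amp_by_age, ae)
    phase_lf = rng.uniform(0, 2 * np.pi)
    x = mu + hf_amp * np.sin(2 * np.pi * hf_freq * t + phase_hf)
    x = x + lf_amp * np.sin(2 * np.pi * config.lf_freq * t + phase_lf)

    alpha = config.schedule(config.longrange_alpha_by_age, ae)
    noise_sd = config.noise_sd * config.schedule(config.noise_sd_by_age, ae)
    if noise_sd > 0:
        smooth = int(round(config.schedule(config.noise_smooth_by_age, ae)))
        x = x + noise_sd * longrange_noise(n, alpha, rng, smooth_beats=smooth)

    x = x + vlf_amp * np.sin(2 * np.pi * config.vlf_freq * t + phase_vlf)
    x = _break_alternation(x)
    pas_target = config.schedule(config.alternans_pct_by_age, ae)
    if pas_target > 0:
        x = _inject_alternans(x, pas_target, config.alternans_amp, rng)

    if config.ectopic_rate > 0:
        ect = rng.random(n) < config.ectopic_rate
        x[ect] += rng.choice([-0.7, 1.0], size=int(ect.sum())) * config.ectopic_shift_ms

    x = np.maximum(x, 1.0)  # RR durations must stay positive
    return RRSeries(mouse_id=mouse_id, age_months=age, state=state, intervals=x)


@dataclass
class SimulatedCohort:
    """In-memory synthetic cohort: manifest, recordings, and ground truth."""

    manifest: CohortManifest
    series: dict[tuple[str, float, str], RRSeries]
    truth: pd.DataFrame


def _survival_ages(config: SynthConfig, mouse_id: str) -> list[float]:
    """Visit ages the mouse is alive for; dropout starts beyond ``dropout_onset_age``."""
    rng = _rng_for(config, mouse_id, "survival")
    ages = []
    for age in config.visit_ages:
        if age > config.dropout_onset_age and rng.random() < config.dropout_hazard:
            break
        ages.append(float(age))
    return ages


def simulate_cohort(
    config: SynthConfig,
    outdir: str | Path | None = None,
    force: bool = False,
) -> SimulatedCohort:
    """Simulate the full cohort; optionally write files + manifest + truth table.

    Mice are followed at every visit age until death; dropout applies only
    beyond ``dropout_onset_age`` (so the cohort resembles a long-lived
    subset with constant n through 24 months).  With ``outdir`` set, one
    plain-text RR file per (mouse, age, state) is written alongside
    ``manifest.csv`` and ``truth.csv``; an existing non-empty directory is
    refused unless ``force``.
    """
    out = None
    if outdir is not None:
        out = Path(outdir)
        if out.exists() and any(out.iterdir()) and not force:
            raise FileExistsError(f"{out} exists and is not empty (use force=True)")
        out.mkdir(parents=True, exist_ok=True)

    rows, truth_rows = [], []
    series: dict[tuple[str, float, str], RRSeries] = {}
    for i in range(config.n_mice):
        mouse = f"M{i:03d}"
        alive_ages = _survival_ages(config, mouse)
        for age in alive_ages:
            for state in ("basal", "abk"):
                rec = simulate_rr(config, mouse, age, state)
                series[(mouse, age, state)] = rec
                fname = f"{mouse}_age{age:04.1f}_{state}.txt"
                rows.append({"mouse_id": mouse, "age_months": age, "state": state, "file": fname})
                truth_rows.append({
                    "mouse_id": mouse,
                    "age_months": age,
                    "state": state,
                    "effective_age": effective_age(config, mouse, age),
                    "mu_rr_ms": mean_rr_truth(config, mouse, age, state),
                    "hf_amp_ms": (config.hf_amp_basal
                                  * config.schedule(config.hf_amp_by_age,
                                                    effective_age(config, mouse, age))
                                  * (config.hf_amp_abk_frac if state == "abk" else 1.0)),
                    "vlf_amp_ms": config.schedule(config.vlf_amp_by_age,
                                                  effective_age(config, mouse, age)),
                    "alpha_target": config.schedule(config.longrange_alpha_by_age,
                                                    effective_age(config, mouse, age)),
                    "pas_target_pct": config.schedule(config.alternans_pct_by_age,
                                                      effective_age(config, mouse, age)),
                    "survival_age": alive_ages[-1],
                })
                if out is not None:
                    np.savetxt(out / fname, rec.intervals, fmt="%.6f",
                               header="RR intervals [ms]")
    manifest_df = pd.DataFrame(rows, columns=["mouse_id", "age_months", "state", "file"])
    truth = pd.DataFrame(truth_rows)
    manifest = CohortManifest(manifest_df, visit_ages=config.visit_ages)
    if out is not None:
        manifest.to_csv(out / "manifest.csv")
        truth.to_csv(out / "truth.csv", index=False)
    return SimulatedCohort(manifest=manifest, series=series, truth=truth)


def simulate_metric_table(
    config: SynthConfig,
    state: State = "abk",
    ages: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a longitudinal metric table directly from the quadratic LME truth.

    y_ij = (beta0+b_i0) + (beta1+b_i1) Age + (beta2+b_i2) Age^2 + eps_ij,
    with mouse random effects drawn from the configured SDs.  Returns
    (tidy table, per-mouse true coefficient table with columns mouse_id,
    metric, b0, b1, b2).
    """
    ages = np.asarray(ages if ages is not None else config.visit_ages, dtype=float)
    rows, truth_rows = [], []
    master = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 0x5E_ED])
    for metric, tr in config.lme_truth.items():
        for i in range(config.n_mice):
            mouse = f"M{i:03d}"
            b0 = master.normal(0.0, tr.sd_b0) if tr.sd_b0 > 0 else 0.0
            b1 = master.normal(0.0, tr.sd_b1) if tr.sd_b1 > 0 else 0.0
            b2 = master.normal(0.0, tr.sd_b2) if tr.sd_b2 > 0 else 0.0
            truth_rows.append({"mouse_id": mouse, "metric": metric, "b0": b0, "b1": b1, "b2": b2})
            eps = master.normal(0.0, tr.sigma_eps, size=ages.size) if tr.sigma_eps > 0 else 0.0
            y = ((tr.beta0 + b0) + (tr.beta1 + b1) * ages + (tr.beta2 + b2) * ages**2 + eps)
            for age, val in zip(ages, np.atleast_1d(y)):
                rows.append({"mouse_id": mouse, "age_months": float(age), "state": state,
                             "metric": metric, "value": float(val)})
    table = pd.DataFrame(rows, columns=["mouse_id", "age_months", "state", "metric", "value"])
    return table, pd.DataFrame(truth_rows)
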