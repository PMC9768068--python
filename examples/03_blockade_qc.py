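"""Decide whether a mouse's double autonomic blockade was complete.

The criterion compares paired basal / blocked window spectra: blockade
passes if the normalised HF peak falls below half its basal value, or if
the average total power per window drops by at least 30%.
"""

from hrvaging import synth
from hrvaging.blockade_qc import decide_blockade
from hrvaging.io_preprocess import make_windows, preprocess_series
from hrvaging.spectral import estimate_psd


def window_spectra(cfg, mouse, age, state):
    cleaned, _, _ = preprocess_series(synth.simulate_rr(cfg, mouse, age, state))
    return [estimate_psd(w) for w in make_windows(cleaned)]


cfg = synth.SynthConfig(seed=11)
basal = window_spectra(cfg, "M010", 12.0, "basal")
abk = window_spectra(cfg, "M010", 12.0, "abk")

dec = decide_blockade(basal, abk, mouse_id="M010", age_months=12.0)
print(f"representative HF peak frequency: {dec.f_peak_bar:.2f} Hz")
print(f"normalised peak height ratio (abk/basal): {dec.peak_ratio:.3f}  "
      f"(< 0.5 required) -> {'pass' if dec.criterion_peak else 'fail'}")
print(f"mean window power ratio   (abk/basal): {dec.power_ratio:.3f}  "
      f"(< 0.7 required) -> {'pass' if dec.criterion_power else 'fail'}")
print(f"blockade complete: {dec.passed}")
print("\nEither criterion suffices; recordings that fail are excluded from")
print("the longitudinal analysis in both states.")
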