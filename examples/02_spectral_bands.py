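"""Estimate RR power spectra and murine band powers, basal vs blockade.

Builds paired recordings for one mouse, estimates each 3-min window's PSD
with the order-30 Burg autoregressive model, and prints the VLF/LF/HF band
decomposition.  Double autonomic blockade abolishes most of the vagal
respiratory (HF-band) modulation, which is exactly what the numbers show.
"""

import numpy as np

from hrvaging import synth
from hrvaging.io_preprocess import make_windows, preprocess_series
from hrvaging.spectral import estimate_psd

cfg = synth.SynthConfig(seed=7)

for state in ("basal", "abk"):
    recording = synth.simulate_rr(cfg, "M003", age=6.0, state=state)
    cleaned, _, _ = preprocess_series(recording)
    windows = make_windows(cleaned)  # 3-min windows; first 2 min of abk dropped
    spectra = [estimate_psd(w, method="ar") for w in windows]
    label = "intrinsic (abk)" if state == "abk" else "basal         "
    tp = np.mean([s.total_power for s in spectra])
    hf = np.mean([s.hf_pct for s in spectra])
    vlf = np.mean([s.vlf_pct for s in spectra])
    fpk = np.mean([s.f_peak_hf for s in spectra])
    print(f"{label}: {len(spectra)} windows | total power {tp:6.1f} ms^2 | "
          f"HF% {hf:5.1f} | VLF% {vlf:5.1f} | HF peak {fpk:.2f} Hz")

print("\nThe basal HF fraction is several-fold the blocked one, and the HF")
print("peak sits at the respiratory frequency (~2.5 Hz in mice).")
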