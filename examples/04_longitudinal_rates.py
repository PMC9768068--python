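"""Fit the quadratic mixed model and extract mouse-specific rates of change.

Simulates a metric table from known mixed-model truth, fits the
random-intercept/slope quadratic model by REML, evaluates each mouse's
trajectory derivative, and compares early- vs late-period rate spread
with the Pitman-Morgan paired-variance test.
"""

import numpy as np

from hrvaging import longitudinal as lg
from hrvaging import synth

truth = synth.LMETruth(beta0=400.0, beta1=2.0, beta2=0.5,
                       sd_b0=20.0, sd_b1=1.0, sd_b2=0.0, sigma_eps=5.0)
cfg = synth.SynthConfig(n_mice=30, seed=3, lme_truth={"mean_rr": truth})
table, _ = synth.simulate_metric_table(cfg, ages=(6, 9, 12, 15, 18, 21))

fit = lg.fit_lme(table, "mean_rr", "abk", period="early")
print(f"model form: {fit.model_form} ({fit.n_mice} mice, {fit.n_obs} observations)")
print(f"fixed effects: b0={fit.beta0:.1f}  b1={fit.beta1:.3f}  b2={fit.beta2:.4f}")
print(f"(truth:        b0=400.0  b1=2.000  b2=0.5000)")

rates = lg.mouse_rates(fit, age_at_eval=6.0)
values = np.array([r.rate for r in rates])
print(f"\nmouse-specific rates at 6 months: mean {values.mean():.2f}, "
      f"SD {values.std(ddof=1):.2f} (truth: mean 8.00, SD 1.00)")

# spread of rates early vs late in a second, late-period fit
late_truth = synth.LMETruth(beta0=400.0, beta1=2.0, beta2=0.5,
                            sd_b0=20.0, sd_b1=3.0, sd_b2=0.0, sigma_eps=5.0)
cfg_late = synth.SynthConfig(n_mice=30, seed=3, lme_truth={"mean_rr": late_truth})
late_tab, _ = synth.simulate_metric_table(cfg_late, ages=(21, 24, 27, 30))
late_fit = lg.fit_lme(late_tab, "mean_rr", "abk", period="late")
late_rates = np.array([r.rate for r in lg.mouse_rates(late_fit, age_at_eval=24.0)])

t, df, p = lg.pitman_morgan(values, late_rates)
print(f"\nPitman-Morgan on paired early/late rates: t={t:.2f}, df={df:.0f}, p={p:.2g}")
print("A small p says the between-mouse spread of rates differs between the")
print("two life periods - here by construction (late slope SD is 3x larger).")
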