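"""Growth-curve metrics and a formaldehyde resistance panel.

Fits lag, exponential rate and maximum OD from a simulated OD600
trajectory, then summarizes growth across a concentration panel as the
highest permissive formaldehyde concentration.
"""

import numpy as np

from formstress import (
    SeededConfig, fit_growth, gen_growth_curve, resistance_summary,
)

times = np.arange(0.0, 40.25, 0.25)
df = gen_growth_curve(lag_h=5.0, rate_per_h=0.25, K=1.0, times_h=times,
                      cfg=SeededConfig(seed=2, replicates=1, noise_sd=0.003))
# with plate-reader noise, give the rate window at least one doubling
# (~3 h here) so low-OD scatter cannot masquerade as steep growth
fit = fit_growth(df["time_h"].to_numpy(), df["od600"].to_numpy(), window_length=13)
print(f"lag = {fit.lag_h:.2f} h, rate = {fit.rate_per_h:.3f} /h, "
      f"max OD = {fit.max_od:.3f} (generating: 5 h, 0.25 /h, K = 1.0)")

# panel: growth up to 8 mM, abolished at 10 mM
fits = {}
for conc, k in [(4.0, 0.9), (6.0, 0.8), (8.0, 0.6), (10.0, 0.012)]:
    d = gen_growth_curve(5.0, 0.25, k, times, SeededConfig(3, 1, 0.0), od0=0.01)
    fits[conc] = fit_growth(d["time_h"].to_numpy(), d["od600"].to_numpy())

panel = resistance_summary(fits, growth_threshold=0.05)
print(f"\ngrowth by concentration: "
      + ", ".join(f"{c:g} mM: {'yes' if g else 'no'}" for c, g in zip(panel.concentrations, panel.grew)))
print(f"highest permissive concentration: {panel.max_permissive_mM} mM")
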