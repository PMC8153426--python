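"""Estimate CFU/mL from a replicate serial-dilution spot series.

A stationary-phase culture is diluted tenfold down to 10**-6 and 10 uL
spots are plated at each dilution.  The two most dilute spots around
the countable endpoint are pooled and divided by 1.1 x dilution x
volume, giving an unbiased density estimate.
"""

from formstress import SeededConfig, PlateGeometry, estimate_cfu, gen_spot_series, pool_replicates

geometry = PlateGeometry()
true_density = 2e8  # CFU/mL

series = gen_spot_series(true_density, geometry.dilution_exponents,
                         geometry.spot_volume_ml, SeededConfig(seed=1, replicates=3))
for s in series:
    print(f"replicate {s.replicate_id}: counts {s.counts}")

estimates = [estimate_cfu(s) for s in series]
for s, e in zip(series, estimates):
    print(f"replicate {s.replicate_id}: {e.cfu_per_ml:.3g} CFU/mL "
          f"(pooled {e.pooled_count} colonies at dilutions {e.dilutions_used})")

pooled = pool_replicates(estimates)
print(f"\nmean {pooled.mean:.3g} +/- {pooled.sd:.2g} CFU/mL (n={pooled.n}); "
      f"truth was {true_density:.3g}")
print("The mean should sit within Poisson counting error (~10%) of truth.")
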