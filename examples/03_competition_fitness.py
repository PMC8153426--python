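"""Malthusian relative fitness from a flow-cytometry competition.

A test strain competes 1:1 against an mCherry reference through a
64-fold population expansion; W compares their realized Malthusian
parameters and equals 1 for a neutral competition.
"""

from formstress import (
    SeededConfig, competition_truth, estimate_competition, fitness_summary,
    gen_competition, malthusian_fitness,
)

print("worked example: F0=0.5, F1=0.6, 64-fold expansion")
print(f"  W = {malthusian_fitness(0.5, 0.6, 64):.4f}  (ln 76.8 / ln 51.2)")
print(f"  32-fold instead: W = {malthusian_fitness(0.5, 0.6, 32):.4f}")

# simulate: test strain expands 76.8x while the reference does 51.2x
f1, true_w = competition_truth(0.5, fold_test=76.8, fold_ref=51.2)
print(f"\nsimulated competition: true F1 = {f1:.3f}, true W = {true_w:.4f}")

results = []
for i in range(3):
    raw = gen_competition(0.5, 76.8, 51.2, n_events=10_000, cfg=SeededConfig(100 + i))
    results.append(estimate_competition(raw, expansion=64.0))
    print(f"  replicate {i + 1}: F0={results[-1].F0:.3f} F1={results[-1].F1:.3f} "
          f"W={results[-1].W:.4f}")

mean_w, sem, n = fitness_summary(results)
print(f"\nmean W = {mean_w:.4f} +/- {sem:.4f} (n={n}); "
      "should match the true W within binomial counting error.")
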