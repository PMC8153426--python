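"""Colorimetric quantification and intracellular normalization.

Fits a Nash (432 nm) standard curve, back-calculates a diluted sample,
and converts a lysate concentration to an intracellular concentration
using the 2.63 fL average cell volume.
"""

from formstress import (
    conc_from_absorbance, fit_standard_curve, intracellular_concentration,
    met_incorporation,
)

cal = fit_standard_curve([0.0, 0.5, 1.0, 2.0], [0.02, 0.27, 0.52, 1.02], assay="nash")
print(f"standard curve: A = {cal.slope:.3f} x mM + {cal.intercept:.3f} "
      f"(R^2 = {cal.r_squared:.4f})")

back = conc_from_absorbance(cal, absorbance=0.27, dilution_factor=10)
print(f"sample at A=0.27, 10x diluted -> {back.conc_mM:.2f} mM in the culture")

c_int = intracellular_concentration(lysate_conc_mM=0.01, cfu_per_ml=2e8)
print(f"\nlysate at 0.01 mM from 2e8 CFU/mL culture -> intracellular "
      f"{c_int:.3f} mM")
print("The ~57x concentration step reflects squeezing the 1.5 mL "
      "extraction into the summed volume of the harvested cells.")

ratio = met_incorporation(peak_218=2e6, peak_222=5e5)
print(f"\ntranslation assay: 222/218 m/z peak ratio = {ratio:.2f} "
      "(heavy-Met fraction of new protein)")
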