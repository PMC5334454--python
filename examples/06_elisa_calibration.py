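"""Histamine ELISA standard-curve calibration and inversion.

A competitive ELISA's absorbance falls with analyte concentration.  The
manufacturer standards are fitted with a 4PL on log concentration; sample
absorbances are inverted through the curve, and readings beyond the
0-concentration standard are rounded up to exactly 0.
"""

import numpy as np

from zfsleep import elisa_concentration, fit_standard_curve, fourpl

# synthetic manufacturer standards (nM) and their absorbances at 405 nm
concentrations = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
absorbances = np.empty_like(concentrations)
absorbances[0] = 2.0
absorbances[1:] = fourpl(np.log10(concentrations[1:]), 0.15, 1.9,
                         np.log10(3.0), -1.1)

curve = fit_standard_curve(concentrations, absorbances)
print(f"fitted 4PL: bottom={curve.fit.bottom:.3f} top={curve.fit.top:.3f} "
      f"logEC50={curve.fit.logec50:.3f} hill={curve.fit.hill:.3f}")

for reading in (1.8, 1.2, 0.6, 2.05):
    conc, flag = elisa_concentration(reading, curve)
    print(f"absorbance {reading:.2f} -> {conc:.3f} nM ({flag})")

print()
print("Lower absorbance means more analyte; the 2.05 reading lies above the")
print("0-standard (2.00), implying a negative concentration, and clamps to 0.")
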