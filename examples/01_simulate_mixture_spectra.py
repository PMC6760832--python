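"""Generate synthetic UV spectra for the published drug/impurity mixture designs.

Builds the 16-mixture calibration design and its 9-mixture test set
(pyridostigmine bromide with impurities A and B, μg mL⁻¹), then produces
Beer–Lambert mixture spectra on the 200–350 nm grid with a 0.002 AU noise
floor.  The printed numbers show the design geometry and the absorbance scale
of the simulated measurements.
"""

import numpy as np

import chemocal as cc

train_design = cc.build_calibration_design()
test_design = cc.build_test_design()
print("training design:", train_design.concentrations.shape, "mixtures × analytes")
print("first training mixture (PR, IMPA, IMPB):", train_design.concentrations[0])
print("test mixtures:", test_design.n_samples)

spectra = cc.generate_mixture_spectra(train_design, noise=cc.NoiseModel(0.002, seed=1))
points = cc.validate_grid(spectra, 200, 350, 1)
print(f"grid: {points} points, {spectra.wavelengths_nm[0]:.0f}–"
      f"{spectra.wavelengths_nm[-1]:.0f} nm")
print(f"absorbance range: {spectra.absorbance.min():.3f}–"
      f"{spectra.absorbance.max():.3f} AU")

# the three pure components peak where the real compounds do
grid = cc.default_grid()
for comp in cc.default_components():
    s = comp.pure_spectrum(grid)
    print(f"{comp.name}: λmax = {grid[np.argmax(s)]:.0f} nm "
          f"(designated {comp.lambda_max_nm:.0f} nm)")
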