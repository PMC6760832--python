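"""Calibrate PLS1 for the drug concentration, selecting the LV count by bootstrap.

Repeated random 2/3–1/3 splits of the 16 training mixtures score each candidate
number of latent variables by held-out RMSEP; the smallest count statistically
indistinguishable from the minimum wins.  The fitted model then predicts the
independent 9-mixture test set; RMSEP near the noise-propagation floor (a few
hundredths of a μg mL⁻¹ here) means the three-component mixture is resolved.
"""

import chemocal as cc

train_d = cc.build_calibration_design()
test_d = cc.build_test_design()
train = cc.generate_mixture_spectra(train_d, noise=cc.NoiseModel(0.002, seed=7))
test = cc.generate_mixture_spectra(test_d, noise=cc.NoiseModel(0.002, seed=8))
y = train_d.column("PR")

boot = cc.bootstrap_select_lv(train, y, max_lv=8, n_iterations=1000, seed=0)
print("mean RMSEP by LV count:")
for lv, r in enumerate(boot.mean_rmsep_by_lv, start=1):
    marker = "  <- chosen" if lv == boot.chosen_lv else ""
    print(f"  {lv} LV: {r:.4f} μg/mL{marker}")

center = cc.fit_center(train, y)
Xc, yc = cc.apply_center(center, train, y)
model = cc.fit_pls1(Xc, yc, boot.chosen_lv, centering=center)

report = cc.summarize(test_d.column("PR"), cc.predict_pls(model, test), "prediction")
print(f"\ntest-set RMSEP: {report.rmse:.4f} μg/mL")
print(f"mean recovery: {report.mean_recovery:.2f}% (SD {report.sd_recovery:.2f})")
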