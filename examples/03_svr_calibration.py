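"""Tune and fit linear ε-SVR by 4-fold cross-validated grid search.

A grid of (ε, C) candidates is scored by RMSECV — each fold held out in turn,
centering re-estimated on the rest — and the tube width/penalty pair with the
lowest RMSECV is refitted on the full training set.  Support vectors are the
mixtures lying on or outside the ε-tube; everything strictly inside it has no
influence on the model.
"""

import chemocal as cc

train_d = cc.build_calibration_design()
test_d = cc.build_test_design()
train = cc.generate_mixture_spectra(train_d, noise=cc.NoiseModel(0.002, seed=7))
test = cc.generate_mixture_spectra(test_d, noise=cc.NoiseModel(0.002, seed=8))
y = train_d.column("PR")

search = cc.grid_search_svr(
    train, y,
    epsilon_grid=(0.01, 0.05, 0.1, 0.2, 0.5),
    cost_grid=(30.0, 100.0, 300.0, 1000.0),
    k=4, seed=0,
)
print(f"grid evaluated: {len(search.grid)} (ε, C) candidates")
print(f"best: ε = {search.best_epsilon}, C = {search.best_cost} "
      f"(RMSECV {search.best_rmsecv:.4f} μg/mL)")

center = cc.fit_center(train, y)
Xc, yc = cc.apply_center(center, train, y)
model = cc.train_linear_svr(
    Xc, yc, search.best_epsilon, search.best_cost, centering=center
)
print(f"support vectors: {model.support_indices.size} of {train.n_samples}")

report = cc.summarize(test_d.column("PR"), cc.predict_svr(model, test), "prediction")
print(f"test-set RMSEP: {report.rmse:.4f} μg/mL, "
      f"mean recovery {report.mean_recovery:.2f}%")
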