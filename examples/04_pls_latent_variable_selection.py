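"""Fit a single-sensor PLS calibration with cross-validated complexity.

The latent-variable count is chosen by 10-fold cross-validation on the
training partition (lowest RMSECV); the fitted model then predicts the
held-out test partition, scored by R2, RMSE and RPD.
"""

from soilfusion import (
    SynthConfig, generate, concatenate, kennard_stone,
    select_lv, fit_pls, summarize,
)

dataset = generate(SynthConfig(n_samples=196, seed=3))
split = kennard_stone(concatenate(dataset.mir, dataset.xrf), 0.8)
train, test = list(split.train_ids), list(split.test_ids)

X_train = dataset.mir.subset(train).values
X_test = dataset.mir.subset(test).values
y_train = dataset.attributes.subset(train).column("pH")
y_test = dataset.attributes.subset(test).column("pH")

cv = select_lv(X_train, y_train, max_lv=15, folds=10, seed=3)
model = fit_pls(X_train, y_train, cv.n_lv)
stats = summarize(y_test, model.predict(X_test).ravel())

print(f"RMSECV by LV count: {[round(float(v), 3) for v in cv.rmsecv[:8]]} ...")
print(f"chosen LVs: {cv.n_lv} (lowest RMSECV = {cv.best_rmsecv:.3f})")
print(f"test set:  R2 = {stats['R2']:.3f}, RMSE = {stats['RMSE']:.3f}, "
      f"RPD = {stats['RPD']:.2f}, RPIQ = {stats['RPIQ']:.2f}  (n = {stats['n']})")
print()
print("RPD > 2 is conventionally read as quantitatively useful; here the")
print("MIR sensor alone sees only part of the pH signal, so fusion helps")
print("(see example 05).")
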