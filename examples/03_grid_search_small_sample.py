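"""Hyperparameter selection in the small-calibration regime.

The two regularization hyperparameters -- the penalty weight alpha and the
Gaussian kernel width r (how far apart two electrodes can be and still count
as neighbors) -- are chosen by cross-validation on the training set only.
This example uses a 60-channel session with just 20 calibration trials, the
regime the spatial prior is designed for.
"""

import srmdrm as sm

spec = sm.SimulationSpec(
    n_channels=60,
    class_variance_ratio=2.0,
    noise_power=2.0,  # a hard session: weak effect, strong sensor noise
    seed=11,
    n_train_trials=20,
    n_test_trials=80,
    n_trials_per_class=50,
)
train, test, truth = sm.simulate_split(spec)

cfg = sm.PipelineConfig(seed=11)  # default 10 x 10 (alpha, r) grids
train_p = sm.bandpass_trials(train, cfg)
test_p = sm.bandpass_trials(test, cfg)

alpha, r, table = sm.grid_search(train_p, truth.montage, cfg)
print(f"evaluated {len(table)} (alpha, r) settings by stratified CV")
print(f"selected alpha = {alpha:g}, r = {r:g} "
      f"(CV accuracy {table['cv_accuracy'].max():.3f})")

fp = sm.fit_srmdrm(train_p, truth.montage, alpha, r, cfg)
res = sm.evaluate(sm.predict_srmdrm(fp, test_p), test_p.labels)
print(f"held-out accuracy with the selected setting: {res.accuracy:.3f}")

# the CV table is a DataFrame; its top rows show how flat or peaked the
# hyperparameter landscape is for this session
print(table.sort_values("cv_accuracy", ascending=False).head())
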