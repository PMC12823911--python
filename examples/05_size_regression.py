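"""Continuous body-size estimation from acoustics alone.

Instead of the hard adult/juvenile split, regress body length (metres)
on SET1 spectral-cepstral features with a Random Forest + XGBoost
ensemble under leave-one-subject-out CV.
"""

from manavoc import features, preprocess, synth
from manavoc.evaluate import regression_metrics
from manavoc.pipeline import size_regression

catalog = synth.reference_cohort(seed=1, n_calls_override=10)
vocs, meta = synth.generate_dataset(catalog, seed=1)
table = features.extract_table([preprocess.highpass(v) for v in vocs], meta, "SET2")

preds = size_regression(table, feature_set="SET1", seed=42)
rep = regression_metrics(preds["y_true"], preds["pred_ensemble"], preds["subject_id"])
print(f"call-level MAE : {rep.mae:.3f} m")
print(f"call-level RMSE: {rep.rmse:.3f} m")
print(f"call-level R^2 : {rep.r2:.2f}")
print("\nper-subject MAE of subject-mean predictions:")
for subj, mae in sorted(rep.per_subject_mae.items()):
    print(f"  {subj}: {mae:.3f} m")
# An MAE around 0.2 m across a 1.7-3.0 m size range gives coarse but
# useful demographic profiling without capturing the animal.
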