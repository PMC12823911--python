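# manavoc

Acoustic demographic inference for Greater Caribbean manatee
(*Trichechus manatus manatus*) vocalizations: classify sex and age
class, and estimate body length, from the spectral structure of tonal
underwater calls — with the leakage-safe evaluation protocols passive
acoustic monitoring needs to generalize to animals never seen in
training.

The package is aimed at bioacousticians and quantitative ecologists
building monitoring pipelines, and at methodologists who need a fully
synthetic, reproducible testbed for subject-grouped audio
classification.

## What it computes

For each call, two descriptor sets: **SET1** (30 features: 12 MFCCs,
12 chroma pitch classes, 6 spectral shape statistics) and **SET2**
(38: SET1 plus duration, f0 summaries from a YIN-family probabilistic
tracker in 1–8 kHz, peak frequency, frequency modulation, and harmonic
structure).  For each demographic task, a leave-one-group-out (LOGO)
cross-validation where every fold, fitted strictly on training
subjects, chains

1. standardization to zero mean, unit variance;
2. ANCOVA residualization of body size: each feature x_j is replaced by
   x_j − b_j·(s − s̄), the size slope b_j de-biased by the auxiliary
   demographic covariate and shrunk by 1/(1+τ), τ = 1.2 fixed or
   τ = 2p/n adaptive;
3. feature selection (ANOVA-F SelectKBest, k = 20/28, or XGBoost-RFE);
4. SMOTE oversampling of the minority class to 1:1, stratified on the
   auxiliary demographic so the joint age–sex distribution survives;
5. one of four fixed-hyperparameter classifiers (Random Forest,
   XGBoost, RBF-SVM, LDA) with class probabilities.

Uncertainty comes from a subject-level bootstrap (resampling
individuals, 10,000 iterations, percentile intervals) that respects
within-individual correlation; decision-threshold sweeps quantify the
minority-recall / false-positive trade-off; Random Forest + XGBoost
ensembles regress body length (MAE/RMSE/R²).  A factorial grid driver
enumerates the 4 × 2 × 2 × 2 × 2 = 64 configurations per task.

Because the study's recordings are not public, a synthetic generator
(`manavoc.synth`) renders cohorts with the statistical structure the
analysis assumes — harmonic-stack squeaks at f0 ≈ 2.5–4 kHz, broadband
squeals for a minority of individuals, sex differences planted in the
spectral envelope (never in pitch), weak size–envelope coupling,
per-subject idiosyncrasy including rare inverted "atypical" animals,
and sub-1 kHz ambient noise.  `docs/methods.md` details the model and
what the generator does and does not emulate.

## Worked example

`examples/03_classify_sex.py` builds a 20-subject synthetic cohort
(10 calls each), extracts SET2 features, and runs the sex task with
XGBoost under LOGO:

```
pooled accuracy : 0.810
macro-F1        : 0.750
  female  precision 0.88  recall 0.87
  male    precision 0.62  recall 0.64
subject-level 95% CI: (0.630, 0.955)
```

Accuracy sits near 80% rather than 100% by design: one cohort member
carries an inverted sex-envelope signature and is misclassified on
essentially every call, which is what drags the lower bootstrap bound
to 0.63 — the same individual-heterogeneity signature that matters for
real monitoring.  The other examples cover cohort synthesis, feature
extraction, juvenile-detection threshold tuning (lowering the cutoff
from 0.5 to 0.3 trades adult recall for juvenile recall), body-size
regression (MAE ≈ 0.2 m over a 1.7–3.0 m range), and the experiment
grid.

The CLI mirrors the same stages for shell use:

```bash
manavoc synth --reference --out data/ --seed 42
manavoc extract --metadata data/metadata.csv --set SET2 --out features.csv
manavoc classify --features features.csv --task sex --clf xgboost --out report.json
manavoc grid --features features.csv --task sex --out grid/
```

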