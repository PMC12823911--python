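"""Classification and regression pipelines under leave-one-group-out CV.

Every fold holds out all calls of one individual and fits the entire
transform chain on the remaining subjects, in strict order:

1. standardization (fit on train),
2. ANCOVA size-residualization (fit on train; auxiliary covariate is age
   when classifying sex and sex when classifying age),
3. feature selection (ANOVA-F SelectKBest or XGBoost-driven RFE, on
   train),
4. stratified SMOTE (train only; test folds keep natural distributions),
5. classifier fit and held-out prediction with class probabilities.

Hyperparameters are fixed a priori (no tuning); the default random state
is 42.  Body-size regression uses the same folding but no SMOTE and no
residualization — size is the target there, not a confound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.feature_selection import f_classif
from sklearn.model_selection import GroupKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier, XGBRegressor

from . import confound as _confound
from .balance import SmoteConfig, stratified_smote
from .features import SET1_NAMES, SET2_NAMES, standardize

__all__ = [
    "TaskConfig",
    "FoldResult",
    "FoldFit",
    "TASK_ROUTING",
    "feature_columns",
    "select_k_best",
    "rfe_select",
    "train_classifier",
    "fit_fold",
    "predict_fold",
    "logo_evaluate",
    "subject_squeal_fractions",
    "squeal_reduced_subjects",
    "size_regression",
]

CLASSIFIERS = ("rf", "xgboost", "svm", "lda")
SELECTORS = ("kbest", "rfe")
FEATURE_SETS = ("SET1", "SET2")
VARIANTS = ("complete", "squeal_reduced")
TAU_MODES = ("fixed", "adaptive")

#: target column, positive (minority) label, auxiliary column per task
TASK_ROUTING = {
    "sex": {
        "target": "sex",
        "positive": "male",
        "negative": "female",
        "auxiliary": "age_class",
    },
    "age": {
        "target": "age_class",
        "positive": "juvenile",
        "negative": "adult",
        "auxiliary": "sex",
    },
}

#: SelectKBest retention per feature set
KBEST_K = {"SET1": 20, "SET2": 28}

FIXED_TAU = 1.2


@dataclass(frozen=True)
class TaskConfig:
    task: str = "sex"
    feature_set: str = "SET2"
    dataset_variant: str = "complete"
    selector: str = "kbest"
    tau_mode: str = "fixed"
    classifier: str = "xgboost"
    seed: int = 42
    squeal_threshold: float = 0.3

    def __post_init__(self) -> None:
        checks = (
            ("task", self.task, tuple(TASK_ROUTING)),
            ("feature_set", self.feature_set, FEATURE_SETS),
            ("dataset_variant", self.dataset_variant, VARIANTS),
            ("selector", self.selector, SELECTORS),
            ("tau_mode", self.tau_mode, TAU_MODES),
            ("classifier", self.classifier, CLASSIFIERS),
        )
        for name, val, allowed in checks:
            if val not in allowed:
                raise ValueError(f"{name} must be one of {allowed}, got {val!r}")

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "feature_set": self.feature_set,
            "dataset_variant": self.dataset_variant,
            "selector": self.selector,
            "tau_mode": self.tau_mode,
            "classifier": self.classifier,
            "seed": self.seed,
            "squeal_threshold": self.squeal_threshold,
        }


@dataclass
class FoldResult:
    held_out_subject: str
    call_ids: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    prob_positive: np.ndarray
    selected_features: tuple[str, ...]
    importance: dict[str, float] | None = None


@dataclass
class FoldFit:
    """Everything fitted on one training fold, for prediction and audit."""

    scaler_mean: pd.Series
    scaler_std: pd.Series
    residual_model: "_confound.ResidualModel"
    selected_features: tuple[str, ...]
    smote_train_shape: tuple[int, int]
    model: object
    positive_label: str
    target_col: str


def feature_columns(df: pd.DataFrame, set_id: str) -> list[str]:
    names = SET1_NAMES if set_id == "SET1" else SET2_NAMES
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    return list(names)


def select_k_best(X: pd.DataFrame, y: np.ndarray, k: int) -> list[int]:
    """Indices of the k largest one-way ANOVA F statistics.

    Ties (and invalid scores from degenerate columns, which rank last)
    break deterministically by column order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > X.shape[1]:
        raise ValueError("k exceeds the number of features")
    import warnings

    with warnings.catch_warnings():
        # degenerate (constant) columns yield NaN F and rank last; the
        # upstream warning adds no information here
        warnings.simplefilter("ignore")
        F, _ = f_classif(np.asarray(X, dtype=float), y)
    F = np.where(np.isfinite(F), F, -np.inf)
    order = np.lexsort((np.arange(len(F)), -F))  # descending F, stable by index
    return sorted(order[:k].tolist())


def _xgb_classifier(seed: int, scale_pos_weight: float = 1.0) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=100,
        learning_rate=0.1,
        max_depth=3,
        min_child_weight=2,
        subsample=0.8,
        colsample_bytree=0.8,
        scale_pos_weight=scale_pos_weight,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )


def _grouped_cv_accuracy(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, seed: int
) -> float:
    n_splits = min(3, len(np.unique(groups)))
    accs = []
    for tr, te in GroupKFold(n_splits=n_splits).split(X, y, groups):
        if len(np.unique(y[tr])) < 2:
            continue
        spw = float((y[tr] == 0).sum()) / max(float((y[tr] == 1).sum()), 1.0)
        m = _xgb_classifier(seed, spw).fit(X[tr], y[tr])
        accs.append(float((m.predict(X[te]) == y[te]).mean()))
    return float(np.mean(accs)) if accs else 0.0


def rfe_select(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    min_features: int = 5,
    seed: int = 42,
) -> list[int]:
    """Backward elimination driven by XGBoost importance.

    One feature is removed per step (the least important; ties break by
    column order).  The retained subset size is the one maximizing mean
    3-fold grouped-CV accuracy, preferring smaller subsets on ties, never
    below ``min_features``.  The inner CV is grouped by subject so
    within-individual correlation cannot leak across inner folds.
    """
    if len(np.unique(groups)) < 3:
        raise ValueError("rfe_select needs at least 3 groups")
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y)
    current = list(range(Xa.shape[1]))
    candidates: list[tuple[float, list[int]]] = []
    while True:
        acc = _grouped_cv_accuracy(Xa[:, current], y, groups, seed)
        candidates.append((acc, list(current)))
        if len(current) <= min_features:
            break
        spw = float((y == 0).sum()) / max(float((y == 1).sum()), 1.0)
        m = _xgb_classifier(seed, spw).fit(Xa[:, current], y)
        imp = np.asarray(m.feature_importances_, dtype=float)
        current.pop(int(np.argmin(imp)))
    best = max(candidates, key=lambda c: (c[0], -len(c[1])))
    return sorted(best[1])


def train_classifier(
    name: str, X: np.ndarray, y: np.ndarray, seed: int = 42
):
    """Fit one of the four fixed-hyperparameter classifiers.

    ``y`` is binary 0/1 with 1 the positive (minority) class.  All models
    expose ``predict`` and ``predict_proba``; tree models additionally
    expose impurity-based ``feature_importances_``.  The boosted model's
    positive-class weight is the residual negative:positive ratio of the
    training data it receives (i.e. computed after SMOTE).
    """
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    if name == "rf":
        model = RandomForestClassifier(
            n_estimators=100,
            max_depth=5,
            min_samples_split=10,
            min_samples_leaf=4,
            class_weight="balanced",
            random_state=seed,
            n_jobs=1,
        )
    elif name == "xgboost":
        spw = float((y == 0).sum()) / float((y == 1).sum())
        model = _xgb_classifier(seed, spw)
    elif name == "svm":
        model = SVC(
            kernel="rbf",
            gamma="scale",
            C=1.0,
            class_weight="balanced",
            probability=True,
            random_state=seed,
        )
    elif name == "lda":
        model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    else:
        raise ValueError(f"unknown classifier {name!r}")
    return model.fit(X, y)


def _tau_for_fold(cfg: TaskConfig, p: int, n: int) -> float:
    if cfg.tau_mode == "fixed":
        return FIXED_TAU
    return _confound.adaptive_tau(p, n)


def fit_fold(
    train: pd.DataFrame, cfg: TaskConfig
) -> FoldFit:
    """Fit every transform and the classifier on one training fold."""
    routing = TASK_ROUTING[cfg.task]
    cols = feature_columns(train, cfg.feature_set)
    Xt = train[cols]

    mean = Xt.mean(axis=0)
    std = Xt.std(axis=0, ddof=0).where(lambda s: s > 0, 1.0)
    Xs = (Xt - mean) / std

    tau = _tau_for_fold(cfg, len(cols), len(train))
    rmodel = _confound.fit_residualizer(
        Xs, train["size_m"].to_numpy(), train[routing["auxiliary"]].to_numpy(), tau
    )
    Xr = _confound.apply_residualizer(rmodel, Xs, train["size_m"].to_numpy())

    y = train[routing["target"]].to_numpy()
    y_bin = (y == routing["positive"]).astype(int)
    if cfg.selector == "kbest":
        idx = select_k_best(Xr, y_bin, KBEST_K[cfg.feature_set])
    else:
        idx = rfe_select(
            Xr, y_bin, train["subject_id"].to_numpy(), min_features=5, seed=cfg.seed
        )
    selected = tuple(cols[i] for i in idx)
    Xsel = Xr.iloc[:, list(idx)]

    Xa, ya, _, _ = stratified_smote(
        Xsel,
        y_bin,
        train[routing["auxiliary"]].to_numpy(),
        SmoteConfig(k_neighbors=5, seed=cfg.seed),
    )
    model = train_classifier(cfg.classifier, np.asarray(Xa, dtype=float), ya, cfg.seed)
    return FoldFit(
        scaler_mean=mean,
        scaler_std=std,
        residual_model=rmodel,
        selected_features=selected,
        smote_train_shape=Xa.shape,
        model=model,
        positive_label=routing["positive"],
        target_col=routing["target"],
    )


def predict_fold(fit: FoldFit, test: pd.DataFrame, cfg: TaskConfig) -> FoldResult:
    """Apply a fitted fold to held-out calls."""
    routing = TASK_ROUTING[cfg.task]
    cols = feature_columns(test, cfg.feature_set)
    Xs = (test[cols] - fit.scaler_mean) / fit.scaler_std
    Xr = _confound.apply_residualizer(
        fit.residual_model, Xs, test["size_m"].to_numpy()
    )
    Xsel = np.asarray(Xr[list(fit.selected_features)], dtype=float)
    prob = fit.model.predict_proba(Xsel)[:, 1]
    pred_bin = fit.model.predict(Xsel).astype(int)
    y_pred = np.where(pred_bin == 1, routing["positive"], routing["negative"])

    importance = None
    if hasattr(fit.model, "feature_importances_"):
        importance = dict(
            zip(fit.selected_features, np.asarray(fit.model.feature_importances_, float))
        )
    subj = test["subject_id"].iloc[0] if len(test) else ""
    return FoldResult(
        held_out_subject=str(subj),
        call_ids=test["call_id"].to_numpy(),
        y_true=test[routing["target"]].to_numpy(),
        y_pred=y_pred,
        prob_positive=prob,
        selected_features=fit.selected_features,
        importance=importance,
    )


def subject_squeal_fractions(table: pd.DataFrame) -> pd.Series:
    """Per-subject squeal share from the call_type column."""
    return (
        (table["call_type"] == "squeal").groupby(table["subject_id"]).mean()
    )


def squeal_reduced_subjects(table: pd.DataFrame, threshold: float = 0.3) -> list[str]:
    """Subjects retained by the squeal-reduced variant (share <= threshold)."""
    frac = subject_squeal_fractions(table)
    return sorted(frac.index[frac <= threshold].tolist())


def _apply_variant(table: pd.DataFrame, cfg: TaskConfig) -> pd.DataFrame:
    if cfg.dataset_variant == "squeal_reduced" and "call_type" in table.columns:
        keep = squeal_reduced_subjects(table, cfg.squeal_threshold)
        return table[table["subject_id"].isin(keep)].reset_index(drop=True)
    return table


def logo_evaluate(table: pd.DataFrame, cfg: TaskConfig) -> list[FoldResult]:
    """Leave-one-subject-out evaluation of a classification task.

    One fold per subject; the union of held-out calls is the full dataset
    with no repeats.  Raises if a subject has no calls or fewer than three
    subjects remain after applying the dataset variant.
    """
    data = _apply_variant(table, cfg)
    subjects = sorted(data["subject_id"].unique().tolist())
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for LOGO evaluation")
    results = []
    for subj in subjects:
        test = data[data["subject_id"] == subj]
        train = data[data["subject_id"] != subj]
        if len(test) == 0:
            raise ValueError(f"subject {subj} has zero calls")
        fold = fit_fold(train.reset_index(drop=True), cfg)
        results.append(predict_fold(fold, test.reset_index(drop=True), cfg))
    return results


def size_regression(
    table: pd.DataFrame,
    feature_set: str = "SET1",
    seed: int = 42,
    dataset_variant: str = "complete",
    squeal_threshold: float = 0.3,
) -> pd.DataFrame:
    """Per-call body-size predictions under LOGO cross-validation.

    Random Forest and XGBoost regressors (200 trees each) are fitted on
    standardized acoustic features alone; the ensemble column is their
    mean.  No SMOTE and no residualization: size is the target here.
    Returns one row per call with ``y_true``, ``pred_rf``, ``pred_xgb``
    and ``pred_ensemble``.
    """
    cfg = TaskConfig(dataset_variant=dataset_variant, squeal_threshold=squeal_threshold)
    data = _apply_variant(table, cfg)
    cols = feature_columns(data, feature_set)
    subjects = sorted(data["subject_id"].unique().tolist())
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for LOGO regression")
    rows = []
    for subj in subjects:
        test = data[data["subject_id"] == subj]
        train = data[data["subject_id"] != subj]
        mean = train[cols].mean(axis=0)
        std = train[cols].std(axis=0, ddof=0).where(lambda s: s > 0, 1.0)
        Xtr = np.asarray((train[cols] - mean) / std, dtype=float)
        Xte = np.asarray((test[cols] - mean) / std, dtype=float)
        ytr = train["size_m"].to_numpy(dtype=float)
        rf = RandomForestRegressor(n_estimators=200, random_state=seed, n_jobs=1).fit(
            Xtr, ytr
        )
        xgb = XGBRegressor(
            n_estimators=200, random_state=seed, n_jobs=1, tree_method="hist"
        ).fit(Xtr, ytr)
        p_rf = rf.predict(Xte)
        p_xgb = xgb.predict(Xte)
        for cid, yt, a, b in zip(
            test["call_id"], test["size_m"].to_numpy(dtype=float), p_rf, p_xgb
        ):
            rows.append(
                {
                    "call_id": cid,
                    "subject_id": subj,
                    "y_true": yt,
                    "pred_rf": float(a),
                    "pred_xgb": float(b),
                    "pred_ensemble": float((a + b) / 2.0),
                }
            )
    return pd.DataFrame(rows)
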