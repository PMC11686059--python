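"""Feature-based predictive modeling.

Cognitive-state classification (4 classes) and chronological-age
regression with RBF-kernel SVMs, subject-wise leave-one-out
cross-validation, per-training-fold z-scoring, a fixed kernel width from
the median-pairwise-distance heuristic, and C tuned by inner
subject-wise resampling.  Feature importance is permutation importance
(model-agnostic), averaged over grouped folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance
from sklearn.metrics import balanced_accuracy_score, confusion_matrix
from sklearn.model_selection import GroupKFold, GroupShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .core_energy import CONDITIONS, REST_CONDITION, WHOLE_BRAIN

#: Condition -> cognitive-state class for 4-class classification.
STATE_OF_CONDITION = {
    "nback0": "working_memory",
    "nback1": "working_memory",
    "nback2": "working_memory",
    "gng_initiation": "inhibitory_control",
    "gng_inhibition": "inhibitory_control",
    "shifting": "cognitive_flexibility",
    REST_CONDITION: "rest",
}
STATES = ("working_memory", "inhibitory_control", "cognitive_flexibility", "rest")

MEASURE_TYPES = ("NE", "GCC", "GE", "GM")
DEFAULT_C_GRID = tuple(2.0**e for e in range(-2, 8))


@dataclass
class FeatureTable:
    """Samples x features with targets and a subject group key."""

    X: pd.DataFrame
    y: pd.Series
    groups: pd.Series
    task: str  # "classify_state" | "predict_age"

    def __post_init__(self):
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")
        if len(self.X) != len(self.y) or len(self.X) != len(self.groups):
            raise ValueError("X, y and groups must align")


def _long_measures(
    energies: pd.DataFrame, measures: pd.DataFrame | None
) -> pd.DataFrame:
    """Stack energy and graph-measure records into one long frame with a
    measure_type column in {NE, GCC, GE, GM}."""
    ne = energies[["subject_id", "condition", "scope", "U"]].rename(
        columns={"U": "value"}
    )
    ne.insert(0, "measure_type", "NE")
    frames = [ne]
    if measures is not None:
        for col, mt in (("gcc", "GCC"), ("ge", "GE"), ("gm", "GM")):
            if col in measures.columns:
                part = measures[["subject_id", "condition", "scope", col]].rename(
                    columns={col: "value"}
                )
                part.insert(0, "measure_type", mt)
                frames.append(part)
    return pd.concat(frames, ignore_index=True)


def build_features(
    energies: pd.DataFrame,
    measures: pd.DataFrame | None = None,
    task: str = "classify_state",
    subset: tuple[str, ...] = ("NE",),
    ages: dict[str, float] | pd.Series | None = None,
) -> FeatureTable:
    """Assemble the model input table from long-format measure records.

    Classification: one sample per subject x condition; columns are
    (measure_type, scope) pairs; the label is the cognitive state of the
    condition.  Regression: one sample per subject; columns are
    (measure_type, scope, condition) triples; the target is age.

    Raises
    ------
    ValueError
        If a requested measure type has no records, or the pivot has
        gaps (missing scope/condition combinations), listing them.
    """
    bad = set(subset) - set(MEASURE_TYPES)
    if bad:
        raise ValueError(f"unknown measure types: {sorted(bad)}")
    long = _long_measures(energies, measures)
    long = long[long["measure_type"].isin(subset)]
    for mt in subset:
        if not (long["measure_type"] == mt).any():
            raise ValueError(f"no records for measure type {mt!r}")

    if task == "classify_state":
        wide = long.pivot_table(
            index=["subject_id", "condition"],
            columns=["measure_type", "scope"],
            values="value",
        )
        wide.columns = [f"{mt}_{scope}" for mt, scope in wide.columns]
        if wide.isna().any().any():
            gaps = wide.columns[wide.isna().any()].tolist()
            raise ValueError(f"missing feature cells for: {gaps}")
        idx = wide.index.to_frame(index=False)
        y = idx["condition"].map(STATE_OF_CONDITION)
        if y.isna().any():
            raise ValueError(
                f"unmapped conditions: {sorted(idx.loc[y.isna(), 'condition'].unique())}"
            )
        return FeatureTable(
            X=wide.reset_index(drop=True),
            y=y.rename("state"),
            groups=idx["subject_id"].rename("subject_id"),
            task=task,
        )
    elif task == "predict_age":
        if ages is None:
            raise ValueError("ages are required for predict_age")
        wide = long.pivot_table(
            index="subject_id",
            columns=["measure_type", "scope", "condition"],
            values="value",
        )
        wide.columns = [f"{mt}_{scope}_{cond}" for mt, scope, cond in wide.columns]
        if wide.isna().any().any():
            gaps = wide.columns[wide.isna().any()].tolist()
            raise ValueError(f"missing feature cells for: {gaps}")
        age_map = pd.Series(ages)
        missing = set(wide.index) - set(age_map.index)
        if missing:
            raise ValueError(f"no age for subjects: {sorted(missing)}")
        subs = wide.index.to_series().reset_index(drop=True)
        return FeatureTable(
            X=wide.reset_index(drop=True),
            y=age_map.reindex(wide.index).reset_index(drop=True).rename("age"),
            groups=subs.rename("subject_id"),
            task=task,
        )
    raise ValueError(f"unknown task {task!r}")


@dataclass
class ClassificationReport:
    balanced_accuracy: float
    per_class_accuracy: dict[str, float]
    confusion_pct: pd.DataFrame  # rows = actual classes, row sums 100
    classes: tuple[str, ...]
    tuned_c: float  # most frequently selected C across folds
    fold_details: list[dict] = field(default_factory=list)
    predictions: pd.DataFrame | None = None


@dataclass
class RegressionReport:
    r2: float  # squared Pearson correlation of predicted vs actual
    r2_sse: float  # 1 - SSE/SST alternative
    mae: float
    tuned_c: float
    fold_details: list[dict] = field(default_factory=list)
    predictions: pd.DataFrame | None = None


def median_distance_sigma(x: np.ndarray) -> float:
    """Median pairwise Euclidean distance; the fixed kernel-width rule.

    Computed on (z-scored) training data only.  Falls back to 1.0 for
    degenerate all-equal data.
    """
    n = len(x)
    if n > 400:  # subsample for cost; deterministic
        idx = np.linspace(0, n - 1, 400).astype(int)
        x = x[idx]
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    vals = np.sqrt(d2[np.triu_indices(len(x), k=1)])
    med = float(np.median(vals)) if len(vals) else 0.0
    return med if med > 0 else 1.0


def _tune_c(
    x_tr, y_tr, groups_tr, gamma, c_grid, model_cls, score_fn, seed, n_splits=5
):
    """Inner subject-wise resampling: pick the C maximizing the score."""
    uniq = np.unique(groups_tr)
    n_splits = min(n_splits, max(2, len(uniq) // 2))
    splitter = GroupShuffleSplit(
        n_splits=n_splits, test_size=max(1, len(uniq) // 5) / len(uniq),
        random_state=seed,
    )
    best_c, best_score = c_grid[0], -np.inf
    for c in c_grid:
        scores = []
        for itr, ite in splitter.split(x_tr, y_tr, groups_tr):
            model = model_cls(C=c, gamma=gamma)
            model.fit(x_tr[itr], y_tr[itr])
            scores.append(score_fn(y_tr[ite], model.predict(x_tr[ite])))
        mean_score = float(np.mean(scores))
        if mean_score > best_score + 1e-12:
            best_score, best_c = mean_score, c
    return best_c


def _svc(C, gamma):
    return SVC(kernel="rbf", C=C, gamma=gamma)


def _svr(C, gamma):
    return SVR(kernel="rbf", C=C, gamma=gamma)


def classify_states(
    ft: FeatureTable,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    seed: int = 0,
) -> ClassificationReport:
    """Subject-wise LOOCV 4-class SVM classification.

    Every preprocessing statistic (z-score means/SDs, sigma, tuned C) is
    computed on the training fold only; held-out predictions are pooled
    into balanced accuracy, per-class recalls and a row-normalized
    percentage confusion matrix.
    """
    x_all = ft.X.to_numpy(dtype=float)
    y_all = ft.y.to_numpy()
    groups = ft.groups.to_numpy()
    subjects = np.unique(groups)
    if len(subjects) < 5:
        raise ValueError("need at least 5 subjects for subject-wise LOOCV")
    classes = tuple(sorted(np.unique(y_all)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")

    preds = np.empty(len(y_all), dtype=object)
    details = []
    for fold, sub in enumerate(subjects):
        te = groups == sub
        tr = ~te
        if len(np.unique(y_all[tr])) < len(classes):
            missing = set(classes) - set(y_all[tr])
            raise ValueError(f"classes absent from training fold: {sorted(missing)}")
        scaler = StandardScaler().fit(x_all[tr])
        x_tr = scaler.transform(x_all[tr])
        x_te = scaler.transform(x_all[te])
        sigma = median_distance_sigma(x_tr)
        gamma = 1.0 / (2.0 * sigma**2)
        c = _tune_c(
            x_tr, y_all[tr], groups[tr], gamma, c_grid, _svc,
            lambda yt, yp: float(np.mean(yt == yp)), seed=seed + fold,
        )
        model = _svc(C=c, gamma=gamma).fit(x_tr, y_all[tr])
        preds[te] = model.predict(x_te)
        details.append(
            {
                "subject": str(sub),
                "C": c,
                "sigma": sigma,
                "scaler_mean": scaler.mean_.copy(),
                "scaler_scale": scaler.scale_.copy(),
            }
        )

    preds = preds.astype(str)
    bal_acc = float(balanced_accuracy_score(y_all, preds))
    cm = confusion_matrix(y_all, preds, labels=list(classes)).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    cm_pct = 100.0 * cm / np.where(row_sums > 0, row_sums, 1)
    per_class = {
        cls: float(cm_pct[i, i]) / 100.0 for i, cls in enumerate(classes)
    }
    c_values = [d["C"] for d in details]
    tuned_c = max(set(c_values), key=c_values.count)
    return ClassificationReport(
        balanced_accuracy=bal_acc,
        per_class_accuracy=per_class,
        confusion_pct=pd.DataFrame(cm_pct, index=list(classes), columns=list(classes)),
        classes=classes,
        tuned_c=float(tuned_c),
        fold_details=details,
        predictions=pd.DataFrame(
            {"subject_id": groups, "actual": y_all, "predicted": preds}
        ),
    )


def predict_age(
    ft: FeatureTable,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    seed: int = 0,
) -> RegressionReport:
    """Subject-wise LOOCV SVM age regression.

    C is tuned by inner resampling minimizing MAE.  Reported R^2 is the
    squared Pearson correlation between held-out predictions and actual
    ages; the 1 - SSE/SST variant is reported alongside.
    """
    x_all = ft.X.to_numpy(dtype=float)
    y_all = ft.y.to_numpy(dtype=float)
    groups = ft.groups.to_numpy()
    subjects = np.unique(groups)
    if len(subjects) < 5:
        raise ValueError("need at least 5 subjects for subject-wise LOOCV")
    if np.ptp(y_all) == 0:
        raise ValueError("constant target: regression undefined")

    preds = np.empty(len(y_all))
    details = []
    for fold, sub in enumerate(subjects):
        te = groups == sub
        tr = ~te
        scaler = StandardScaler().fit(x_all[tr])
        x_tr = scaler.transform(x_all[tr])
        x_te = scaler.transform(x_all[te])
        sigma = median_distance_sigma(x_tr)
        gamma = 1.0 / (2.0 * sigma**2)
        c = _tune_c(
            x_tr, y_all[tr], groups[tr], gamma, c_grid, _svr,
            lambda yt, yp: -float(np.mean(np.abs(yt - yp))), seed=seed + fold,
        )
        model = _svr(C=c, gamma=gamma).fit(x_tr, y_all[tr])
        preds[te] = model.predict(x_te)
        details.append(
            {
                "subject": str(sub),
                "C": c,
                "sigma": sigma,
                "scaler_mean": scaler.mean_.copy(),
                "scaler_scale": scaler.scale_.copy(),
            }
        )

    if np.std(preds) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(preds, y_all)[0, 1] ** 2)
    sst = float(np.sum((y_all - y_all.mean()) ** 2))
    sse = float(np.sum((y_all - preds) ** 2))
    mae = float(np.mean(np.abs(y_all - preds)))
    c_values = [d["C"] for d in details]
    tuned_c = max(set(c_values), key=c_values.count)
    return RegressionReport(
        r2=r2,
        r2_sse=1.0 - sse / sst,
        mae=mae,
        tuned_c=float(tuned_c),
        fold_details=details,
        predictions=pd.DataFrame(
            {"subject_id": groups, "actual": y_all, "predicted": preds}
        ),
    )


def feature_importance(
    ft: FeatureTable,
    n_repeats: int = 20,
    n_folds: int = 5,
    C: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance averaged over grouped CV folds.

    Within each subject-grouped fold, an RBF SVM pipeline (z-scoring +
    median-distance kernel width) is fit on the training part, and each
    held-out feature column is shuffled ``n_repeats`` times; the mean
    performance drop (balanced accuracy for classification, negative MAE
    for regression) is the importance.  Deterministic given the seed.
    """
    x = ft.X.to_numpy(dtype=float)
    y = ft.y.to_numpy()
    groups = ft.groups.to_numpy()
    n_folds = min(n_folds, len(np.unique(groups)))
    scoring = (
        "balanced_accuracy" if ft.task == "classify_state" else "neg_mean_absolute_error"
    )
    importances = np.zeros(x.shape[1])
    splitter = GroupKFold(n_splits=n_folds)
    for fold, (tr, te) in enumerate(splitter.split(x, y, groups)):
        sigma = median_distance_sigma(StandardScaler().fit_transform(x[tr]))
        gamma = 1.0 / (2.0 * sigma**2)
        est = _svc(C, gamma) if ft.task == "classify_state" else _svr(C, gamma)
        pipe = Pipeline([("scale", StandardScaler()), ("svm", est)])
        pipe.fit(x[tr], y[tr])
        res = permutation_importance(
            pipe, x[te], y[te], scoring=scoring,
            n_repeats=n_repeats, random_state=seed + fold,
        )
        importances += res.importances_mean
    importances /= n_folds
    out = pd.DataFrame(
        {"feature": ft.X.columns, "importance": importances}
    ).sort_values("importance", ascending=False, kind="stable")
    return out.reset_index(drop=True)
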