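"""The 10-feature radiomic signature predicting the immune subtypes.

Pipeline: (1) univariate screen of every QC-passed feature across the three
subtypes — one-way ANOVA when every group passes Shapiro-Wilk normality and
Levene's variance-homogeneity test at alpha = 0.05, Kruskal-Wallis otherwise —
keeping raw p < 0.05 (no multiplicity correction at this stage, a deliberately
liberal screen); (2) a 100-tree random forest ranks the survivors by mean
impurity-decrease importance and the top 10 are retained (ties broken by
name); (3) a fresh 100-tree forest trained on those 10 columns is the
signature; (4) evaluation reports accuracy, macro one-vs-rest AUC with a
stratified-bootstrap percentile CI, and per-class/macro sensitivity,
specificity and F1, plus ROC and precision-recall curve points.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_curve, roc_curve

__all__ = [
    "screen_features",
    "rank_and_select",
    "SignatureModel",
    "train_signature",
    "predict",
    "EvaluationReport",
    "evaluate",
    "auc_trapezoidal",
]


def screen_features(
    features: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Routed univariate screen of each feature across the subtype groups.

    Returns a per-feature table with the p-value, the routed test name, and
    the ``keep`` flag (p < alpha).  Constant features get p = 1 and are not
    kept.
    """
    labels = labels.reindex(features.index)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    groups_idx = [labels == g for g in sorted(labels.unique())]
    if len(groups_idx) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.sum() < 3 for g in groups_idx):
        raise ValueError("every group needs at least 3 samples")
    X = features.to_numpy(dtype=np.float64)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, name in enumerate(features.columns):
            samples = [X[g.to_numpy(), j] for g in groups_idx]
            if np.all(X[:, j] == X[0, j]):
                rows.append({"feature": name, "p_value": 1.0, "test": "constant"})
                continue
            normal = all(
                len(np.unique(s)) > 1 and stats.shapiro(s).pvalue > alpha
                for s in samples
            )
            homoscedastic = stats.levene(*samples).pvalue > alpha
            if normal and homoscedastic:
                p = stats.f_oneway(*samples).pvalue
                test = "anova"
            else:
                p = stats.kruskal(*samples).pvalue
                test = "kruskal"
            if np.isnan(p):
                p, test = 1.0, "constant"
            rows.append({"feature": name, "p_value": float(p), "test": test})
    table = pd.DataFrame(rows).set_index("feature")
    table["keep"] = (table["p_value"] < alpha) & (table["test"] != "constant")
    return table


def rank_and_select(
    features: pd.DataFrame,
    labels: pd.Series,
    n_select: int = 10,
    seed: int | None = 0,
    n_trees: int = 100,
) -> list[str]:
    """Select the top features by 100-tree-forest impurity importance.

    Deterministic given the seed; importance ties break by feature name.
    """
    if features.shape[1] < n_select:
        raise ValueError(
            f"only {features.shape[1]} surviving features; need >= {n_select} "
            "(consider relaxing the screening threshold)"
        )
    labels = labels.reindex(features.index)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(features.to_numpy(), labels.to_numpy())
    importance = pd.Series(forest.feature_importances_, index=features.columns)
    ranked = importance.sort_values(ascending=False, kind="stable")
    # stable tie-break by name
    ranked = (
        pd.DataFrame({"imp": ranked})
        .assign(name=lambda d: d.index)
        .sort_values(["imp", "name"], ascending=[False, True], kind="stable")
    )
    return list(ranked.index[:n_select])


@dataclass
class SignatureModel:
    """A trained radiomic signature: 10 feature names + a 100-tree forest."""

    selected_features: list[str]
    classes: list[str]
    n_trees: int
    seed: int | None
    forest: RandomForestClassifier = field(repr=False, default=None)

    def describe(self) -> dict:
        return {
            "selected_features": self.selected_features,
            "classes": self.classes,
            "n_trees": self.n_trees,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        # the forest itself is re-trainable from the stored seed + features;
        # only the description is serialized
        Path(path).write_text(json.dumps(self.describe(), indent=2))


def train_signature(
    features: pd.DataFrame,
    labels: pd.Series,
    selected: list[str],
    seed: int | None = 0,
    n_trees: int = 100,
) -> SignatureModel:
    """Train the final forest on the selected feature columns only."""
    missing = [f for f in selected if f not in features.columns]
    if missing:
        raise ValueError(f"selected features absent from table: {missing}")
    labels = labels.reindex(features.index)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(features[selected].to_numpy(), labels.to_numpy())
    return SignatureModel(
        selected_features=list(selected),
        classes=[str(c) for c in forest.classes_],
        n_trees=n_trees,
        seed=seed,
        forest=forest,
    )


def predict(
    model: SignatureModel, features_new: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-class score vectors (summing to 1) and argmax labels."""
    missing = [f for f in model.selected_features if f not in features_new.columns]
    if missing:
        raise ValueError(f"features missing at prediction time: {missing}")
    proba = model.forest.predict_proba(
        features_new[model.selected_features].to_numpy()
    )
    scores = pd.DataFrame(proba, index=features_new.index, columns=model.classes)
    labels = scores.idxmax(axis=1)
    labels.name = "predicted_subtype"
    return labels, scores


def auc_trapezoidal(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """One-vs-rest ROC AUC by the trapezoidal rule."""
    fpr, tpr, _ = roc_curve(y_true, y_score)
    return float(np.trapezoid(tpr, fpr))


@dataclass
class EvaluationReport:
    accuracy: float
    macro_auc: float
    macro_auc_ci: tuple[float, float]
    per_class: pd.DataFrame  # sensitivity, specificity, f1, auc per class
    macro_sensitivity: float
    macro_specificity: float
    macro_f1: float
    roc_points: dict[str, pd.DataFrame]
    pr_points: dict[str, pd.DataFrame]

    def summary(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_auc": self.macro_auc,
            "macro_auc_ci": list(self.macro_auc_ci),
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "macro_f1": self.macro_f1,
        }


def _macro_auc(y: np.ndarray, scores: np.ndarray, classes: list[str]) -> float:
    aucs = []
    for k, cls in enumerate(classes):
        pos = y == cls
        if pos.all() or not pos.any():
            continue
        aucs.append(auc_trapezoidal(pos, scores[:, k]))
    return float(np.mean(aucs))


def evaluate(
    model: SignatureModel,
    features_test: pd.DataFrame,
    labels_test: pd.Series,
    n_boot: int = 2000,
    seed: int | None = 0,
) -> EvaluationReport:
    """Multiclass evaluation of the signature on a held-out cohort."""
    labels_test = labels_test.reindex(features_test.index)
    predicted, scores = predict(model, features_test)
    y = labels_test.to_numpy().astype(str)
    yhat = predicted.to_numpy().astype(str)
    S = scores.to_numpy()
    classes = model.classes

    accuracy = float((y == yhat).mean())
    rows = {}
    roc_points: dict[str, pd.DataFrame] = {}
    pr_points: dict[str, pd.DataFrame] = {}
    for k, cls in enumerate(classes):
        pos = y == cls
        pred_pos = yhat == cls
        tp = int((pos & pred_pos).sum())
        fn = int((pos & ~pred_pos).sum())
        fp = int((~pos & pred_pos).sum())
        tn = int((~pos & ~pred_pos).sum())
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        if pos.any() and not pos.all():
            auc_k = auc_trapezoidal(pos, S[:, k])
            fpr, tpr, _ = roc_curve(pos, S[:, k])
            prec, rec, _ = precision_recall_curve(pos, S[:, k])
            roc_points[cls] = pd.DataFrame({"fpr": fpr, "tpr": tpr})
            pr_points[cls] = pd.DataFrame({"recall": rec, "precision": prec})
        else:
            warnings.warn(f"class {cls} absent from test set; AUC undefined",
                          stacklevel=2)
            auc_k = np.nan
        rows[cls] = {
            "sensitivity": sens,
            "specificity": spec,
            "f1": f1,
            "auc": auc_k,
        }
    per_class = pd.DataFrame(rows).T
    macro_auc = float(per_class["auc"].mean(skipna=True))

    rng = np.random.default_rng(seed)
    class_indices = [np.where(y == c)[0] for c in classes if (y == c).any()]
    boot_aucs = []
    for _ in range(n_boot):
        idx = np.concatenate(
            [rng.choice(ci, size=len(ci), replace=True) for ci in class_indices]
        )
        boot_aucs.append(_macro_auc(y[idx], S[idx], classes))
    ci = (
        float(np.percentile(boot_aucs, 2.5)),
        float(np.percentile(boot_aucs, 97.5)),
    )

    return EvaluationReport(
        accuracy=accuracy,
        macro_auc=macro_auc,
        macro_auc_ci=ci,
        per_class=per_class,
        macro_sensitivity=float(per_class["sensitivity"].mean(skipna=True)),
        macro_specificity=float(per_class["specificity"].mean(skipna=True)),
        macro_f1=float(per_class["f1"].mean(skipna=True)),
        roc_points=roc_points,
        pr_points=pr_points,
    )
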