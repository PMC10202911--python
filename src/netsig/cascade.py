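"""Three-level cascading classifier over clinicogenomic features.

Level 1 separates case from control; level 2 splits true cases into early
(stages I-II) vs. late (III-IV); level 3 resolves the stage within each
branch (I vs. II, III vs. IV).  Levels 2 and 3 are trained on the *true*
subsets of the training data, which keeps each level independently
testable; at prediction time a sample is routed down the tree by the
preceding levels' decisions, so a sample called control never receives a
stage and a predicted stage is always consistent with its predicted
early/late branch.

The learner is pluggable: anything exposing ``fit(X, y)`` and
``predict_proba(X)`` with rows summing to 1 (the scikit-learn classifier
protocol) works.  :func:`logistic_factory` supplies a deterministic
L2-regularized logistic scorer as the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .evaluate import auc as _auc
from .types import ExpressionMatrix, GROUP_CASE

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierContract",
    "CascadeModel",
    "logistic_factory",
    "build_features",
    "fit_cascade",
    "predict_cascade",
    "evaluate_cascade",
]

EARLY_STAGES = ("I", "II")
LATE_STAGES = ("III", "IV")


class ClassifierContract(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClassifierContract": ...
    def predict_proba(self, X: np.ndarray) -> np.ndarray: ...
    classes_: np.ndarray


def logistic_factory(seed: int = 0) -> Callable[[], ClassifierContract]:
    """Default learner factory: deterministic ridge-regularized logistic
    scorer (lbfgs; the seed only matters for solvers that subsample)."""

    def make() -> ClassifierContract:
        return LogisticRegression(max_iter=1000, random_state=seed)

    return make


class _ConstantClassifier:
    """Degenerate level fallback: always predicts the single seen class."""

    def __init__(self, label: str):
        self.classes_ = np.array([label])

    def fit(self, X, y):  # pragma: no cover - already fitted by construction
        return self

    def predict_proba(self, X):
        return np.ones((len(X), 1))


@dataclass
class CascadeModel:
    level1: ClassifierContract  # control vs case
    level2: ClassifierContract  # early vs late (cases only)
    level3_early: ClassifierContract  # I vs II
    level3_late: ClassifierContract  # III vs IV
    feature_names: list[str]


def build_features(
    m: ExpressionMatrix,
    panel: Sequence[str],
    use_clinical: bool = True,
    clinical: Sequence[str] = ("age", "sex", "smoking"),
) -> pd.DataFrame:
    """Feature matrix: z-scored panel expression columns, plus clinical
    covariates (numeric kept as-is, categoricals one-of-K dropping the
    first level).  Indexed by sample."""
    panel = list(panel)
    missing = sorted(set(panel) - set(m.genes))
    if missing:
        raise KeyError(f"panel genes not in matrix: {', '.join(missing)}")
    vals = m.values.loc[panel]
    sd = vals.std(axis=1, ddof=1).replace(0.0, np.nan)
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0).fillna(0.0)
    features = z.T.copy()
    if use_clinical:
        for col in clinical:
            if col not in m.annotations.columns:
                raise KeyError(f"clinical covariate {col!r} not in annotations")
            series = m.annotations[col]
            if pd.api.types.is_numeric_dtype(series):
                features[col] = series.astype(float)
            else:
                dummies = pd.get_dummies(series.astype(str), prefix=col, drop_first=True)
                features = features.join(dummies.astype(float))
    return features


def _fit_level(
    X: np.ndarray,
    y: np.ndarray,
    factory: Callable[[], ClassifierContract],
    level_name: str,
) -> ClassifierContract:
    classes = np.unique(y)
    if len(classes) < 2:
        label = str(classes[0]) if len(classes) else "none"
        logger.warning(
            "cascade level %s saw a single class (%s); using a constant predictor",
            level_name,
            label,
        )
        return _ConstantClassifier(label)
    clf = factory()
    clf.fit(X, y)
    return clf


def fit_cascade(
    features: pd.DataFrame,
    annotations: pd.DataFrame,
    clf_factory: Callable[[], ClassifierContract] | None = None,
    seed: int = 0,
) -> CascadeModel:
    """Train the three levels on true subsets.

    ``annotations`` must carry ``group`` and (for staged cases) ``stage``.
    """
    if clf_factory is None:
        clf_factory = logistic_factory(seed)
    ann = annotations.loc[features.index]
    X = features.to_numpy(dtype=float)
    group = ann["group"].to_numpy()
    stage = (
        ann["stage"].fillna("none").to_numpy()
        if "stage" in ann.columns
        else np.full(len(ann), "none")
    )

    level1 = _fit_level(X, group, clf_factory, "1 (case/control)")

    is_case = group == GROUP_CASE
    staged = is_case & np.isin(stage, EARLY_STAGES + LATE_STAGES)
    early_late = np.where(np.isin(stage, EARLY_STAGES), "early", "late")
    level2 = _fit_level(X[staged], early_late[staged], clf_factory, "2 (early/late)")

    early = staged & np.isin(stage, EARLY_STAGES)
    late = staged & np.isin(stage, LATE_STAGES)
    level3_early = _fit_level(X[early], stage[early], clf_factory, "3 (I/II)")
    level3_late = _fit_level(X[late], stage[late], clf_factory, "3 (III/IV)")
    return CascadeModel(
        level1=level1,
        level2=level2,
        level3_early=level3_early,
        level3_late=level3_late,
        feature_names=list(features.columns),
    )


def _predict_label(clf: ClassifierContract, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    proba = clf.predict_proba(X)
    labels = np.asarray(clf.classes_)[np.argmax(proba, axis=1)]
    return labels, proba


def predict_cascade(model: CascadeModel, features: pd.DataFrame) -> pd.DataFrame:
    """Route each sample through the cascade.

    Returns a DataFrame indexed by sample with predicted ``group``,
    ``branch`` (early/late/none), ``stage`` (I-IV or none) and the
    case/early probabilities at the levels the sample visited.
    """
    if list(features.columns) != model.feature_names:
        raise ValueError("feature columns do not match the trained cascade")
    X = features.to_numpy(dtype=float)
    n = len(features)
    group_pred, p1 = _predict_label(model.level1, X)
    p_case = _class_probability(model.level1, p1, GROUP_CASE)

    branch = np.full(n, "none", dtype=object)
    stage = np.full(n, "none", dtype=object)
    p_early = np.full(n, np.nan)
    case_idx = np.flatnonzero(group_pred == GROUP_CASE)
    if len(case_idx):
        b_labels, p2 = _predict_label(model.level2, X[case_idx])
        branch[case_idx] = b_labels
        p_early[case_idx] = _class_probability(model.level2, p2, "early")
        for name, clf in (("early", model.level3_early), ("late", model.level3_late)):
            sub = case_idx[branch[case_idx] == name]
            if len(sub):
                s_labels, _ = _predict_label(clf, X[sub])
                stage[sub] = s_labels
    return pd.DataFrame(
        {
            "group": group_pred,
            "branch": branch,
            "stage": stage,
            "p_case": p_case,
            "p_early": p_early,
        },
        index=features.index,
    )


def _class_probability(
    clf: ClassifierContract, proba: np.ndarray, label: str
) -> np.ndarray:
    classes = list(map(str, clf.classes_))
    if label in classes:
        return proba[:, classes.index(label)]
    return np.zeros(len(proba))


def evaluate_cascade(
    model: CascadeModel, features: pd.DataFrame, annotations: pd.DataFrame
) -> dict:
    """Per-level accuracy/AUC on the samples truly belonging to each level,
    plus end-to-end stage accuracy over truly staged cases."""
    ann = annotations.loc[features.index]
    pred = predict_cascade(model, features)
    group = ann["group"].to_numpy()
    stage = (
        ann["stage"].fillna("none").to_numpy()
        if "stage" in ann.columns
        else np.full(len(ann), "none")
    )
    report: dict = {}

    report["level1"] = {
        "accuracy": float(np.mean(pred["group"].to_numpy() == group)),
        "auc": _safe_auc(pred["p_case"].to_numpy(), group == GROUP_CASE),
    }
    staged = (group == GROUP_CASE) & np.isin(stage, EARLY_STAGES + LATE_STAGES)
    if staged.any():
        true_branch = np.where(np.isin(stage, EARLY_STAGES), "early", "late")
        X = features.to_numpy(dtype=float)
        b_labels, p2 = _predict_label(model.level2, X[staged])
        report["level2"] = {
            "accuracy": float(np.mean(b_labels == true_branch[staged])),
            "auc": _safe_auc(
                _class_probability(model.level2, p2, "early"),
                true_branch[staged] == "early",
            ),
        }
        for name, clf, members in (
            ("level3_early", model.level3_early, staged & np.isin(stage, EARLY_STAGES)),
            ("level3_late", model.level3_late, staged & np.isin(stage, LATE_STAGES)),
        ):
            if members.any():
                s_labels, _ = _predict_label(clf, X[members])
                report[name] = {
                    "accuracy": float(np.mean(s_labels == stage[members]))
                }
        report["end_to_end_stage_accuracy"] = float(
            np.mean(pred["stage"].to_numpy()[staged] == stage[staged])
        )
    return report


def _safe_auc(score: np.ndarray, positive: np.ndarray) -> float:
    if positive.all() or (~positive).all():
        return float("nan")
    if np.all(score == score[0]):
        return 0.5
    return _auc(score, positive, direction="case_high").auc
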