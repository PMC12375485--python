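"""Early-screening classifier on V-J usage features.

Workflow: select V-J pairs whose usage differs between groups (uncorrected
Mann-Whitney p below a threshold), mean-center the frequency columns
(no scaling), split samples 70/30 stratified by group, run stratified
3-fold cross-validation on the training portion, and fit three baseline
classifiers — logistic regression, random forest, RBF-kernel SVM — at
pinned default hyperparameters, reporting ROC-AUC per fold and on the
held-out test set.

By default, feature selection and centering use the training samples only
(no test-set leakage).  ``paper_mode=True`` reproduces the alternative
order in which features are selected on the full cohort before splitting;
that mode leaks selection information into the test AUC and is provided
for fidelity comparisons only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._stats import mann_whitney

__all__ = [
    "FeatureSet",
    "SplitPlan",
    "ClassifierReport",
    "select_features",
    "split_and_cv",
    "train_evaluate",
    "project_pca",
]

MODEL_NAMES = ("LR", "RF", "SVM")


@dataclass
class FeatureSet:
    """Selected V-J pairs, their selection p-values and the centering means."""

    features: list[str]
    p_values: pd.Series
    center: pd.Series  # training-column means used for centering

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return matrix[self.features] - self.center


@dataclass
class SplitPlan:
    """Stratified 70/30 split plus stratified k-fold partition of training."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]  # positions within train_idx
    seed: int


@dataclass
class ClassifierReport:
    model: str
    cv_aucs: list[float]
    test_auc: float
    roc: tuple[np.ndarray, np.ndarray]
    features: list[str]
    seed: int

    @property
    def mean_cv_auc(self) -> float:
        return float(np.mean(self.cv_aucs)) if self.cv_aucs else float("nan")


def select_features(
    matrix: pd.DataFrame, groups: pd.Series, p_threshold: float = 0.01
) -> pd.Series:
    """Per-segment Mann-Whitney p-values of the pairs passing the threshold.

    Raises ValueError when nothing passes (relax the threshold or check the
    group labels).
    """
    groups = groups.reindex(matrix.index)
    mal = matrix[groups == "malignant"]
    ben = matrix[groups == "benign"]
    p_values = {}
    for seg in matrix.columns:
        x, y = mal[seg].to_numpy(), ben[seg].to_numpy()
        if np.ptp(np.concatenate([x, y])) == 0:
            continue
        p_values[seg] = mann_whitney(x, y)[1]
    selected = pd.Series(p_values).sort_values()
    selected = selected[selected < p_threshold]
    if selected.empty:
        raise ValueError(
            f"no V-J pair passes p < {p_threshold}; consider relaxing the threshold"
        )
    return selected


def split_and_cv(
    labels: pd.Series | np.ndarray,
    train_prop: float = 0.7,
    folds: int = 3,
    seed: int = 0,
) -> SplitPlan:
    """Stratified train/test split plus stratified k-fold CV plan.

    Per class, ``round(train_prop * n)`` samples go to training (a 12/8
    benign/malignant cohort at 0.7 yields the 8+6 / 4+2 partition), the rest
    to test; the training portion is then partitioned into stratified folds.
    Deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_train = int(np.floor(train_prop * idx.size + 0.5))
        if n_train < folds:
            raise ValueError(
                f"class {cls!r}: {n_train} training samples cannot stratify {folds} folds"
            )
        if n_train == idx.size:
            raise ValueError(f"class {cls!r}: empty test partition")
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    train_idx = np.sort(np.concatenate(train_parts))
    test_idx = np.sort(np.concatenate(test_parts))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_plan = [
        (tr, va) for tr, va in skf.split(np.zeros(train_idx.size), labels[train_idx])
    ]
    return SplitPlan(train_idx=train_idx, test_idx=test_idx, folds=fold_plan, seed=seed)


def _make_model(name: str, seed: int):
    if name == "LR":
        # L2 penalty (the default), C pinned explicitly
        return LogisticRegression(C=1.0, max_iter=5000)
    if name == "RF":
        return RandomForestClassifier(n_estimators=500, random_state=seed)
    if name == "SVM":
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    raise ValueError(f"unknown model {name!r}")


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return model.decision_function(X)
    return model.predict_proba(X)[:, 1]


def train_evaluate(
    matrix: pd.DataFrame,
    groups: pd.Series,
    plan: SplitPlan | None = None,
    p_threshold: float = 0.01,
    models: tuple[str, ...] = MODEL_NAMES,
    seed: int = 0,
    paper_mode: bool = False,
) -> tuple[list[ClassifierReport], FeatureSet]:
    """Select features, fit the baseline classifiers and report ROC-AUCs.

    ``matrix`` is a samples x V-J usage matrix; ``groups`` the benign /
    malignant labels.  Returns one :class:`ClassifierReport` per model plus
    the :class:`FeatureSet` used.  The mean test AUC across models is
    ``np.mean([r.test_auc for r in reports])``.
    """
    groups = groups.reindex(matrix.index)
    y = (groups == "malignant").astype(int).to_numpy()
    if plan is None:
        plan = split_and_cv(y, seed=seed)
    selection_rows = (
        np.arange(len(matrix)) if paper_mode else plan.train_idx
    )
    p_values = select_features(
        matrix.iloc[selection_rows], groups.iloc[selection_rows], p_threshold
    )
    features = list(p_values.index)
    center = matrix.iloc[plan.train_idx][features].mean()
    fs = FeatureSet(features=features, p_values=p_values, center=center)
    X = (matrix[features] - center).to_numpy(dtype=float)

    X_train, y_train = X[plan.train_idx], y[plan.train_idx]
    X_test, y_test = X[plan.test_idx], y[plan.test_idx]
    reports = []
    for name in models:
        cv_aucs = []
        for tr, va in plan.folds:
            if len(np.unique(y_train[va])) < 2:
                warnings.warn(f"{name}: single-class validation fold skipped")
                continue
            model = _make_model(name, plan.seed)
            model.fit(X_train[tr], y_train[tr])
            cv_aucs.append(
                float(roc_auc_score(y_train[va], _scores(model, X_train[va])))
            )
        model = _make_model(name, plan.seed)
        model.fit(X_train, y_train)
        test_scores = _scores(model, X_test)
        test_auc = float(roc_auc_score(y_test, test_scores))
        fpr, tpr, _ = roc_curve(y_test, test_scores)
        reports.append(
            ClassifierReport(
                model=name,
                cv_aucs=cv_aucs,
                test_auc=test_auc,
                roc=(fpr, tpr),
                features=features,
                seed=plan.seed,
            )
        )
    return reports, fs


def project_pca(
    matrix: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of a (centered) feature matrix.

    Returns ``(coordinates, loadings, explained_variance_ratio)``.  With all
    components retained the coordinates reproduce the centered input.
    """
    if matrix.shape[1] < n_components:
        raise ValueError(
            f"{matrix.shape[1]} features cannot support {n_components} components"
        )
    if matrix.shape[0] < 2:
        raise ValueError("need at least two samples")
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(matrix.to_numpy(dtype=float))
    pc_names = [f"PC{i + 1}" for i in range(n_components)]
    coordinates = pd.DataFrame(coords, index=matrix.index, columns=pc_names)
    loadings = pd.DataFrame(pca.components_.T, index=matrix.columns, columns=pc_names)
    return coordinates, loadings, pca.explained_variance_ratio_
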