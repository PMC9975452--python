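"""Multimodal feature assembly and cross-validated classification.

Per-sample summaries from each feature modality (size fractions,
fragment-ratio profile, fragment-fraction similarity, CNV, TSS coverage,
PFE, TF occupancy) are concatenated into a block-labelled feature matrix
and fed to a linear classifier with logistic loss trained by stochastic
gradient descent. Evaluation reports stratified 10-fold cross-validation
(pooled out-of-fold ROC/AUC), a 70/30 train/test split, the confusion
matrix at probability 0.5, and per-modality single-block predictions.
Standardization is fitted on training folds only, so no information leaks
from evaluation data into the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

POSITIVE_LABEL = "cancer"
DEFAULT_BLOCKS = (
    "size_fractions",
    "fragment_ratio",
    "fragment_fraction",
    "cnv",
    "tss",
    "pfe",
)  # + optional "tf"


@dataclass
class CohortFeatureMatrix:
    """Samples x features matrix with per-column modality-block labels."""

    X: pd.DataFrame  # index = sample ids
    labels: pd.Series  # "cancer" / "healthy", aligned with X.index
    blocks: dict[str, list[str]]  # block name -> column names

    def block_matrix(self, block: str) -> pd.DataFrame:
        return self.X[self.blocks[block]]

    @property
    def y(self) -> np.ndarray:
        return (self.labels == POSITIVE_LABEL).to_numpy(int)


@dataclass
class ClassifierReport:
    cv_auc: float  # pooled out-of-fold AUC over all samples
    train_auc: float  # 70/30 split, training partition
    test_auc: float  # 70/30 split, held-out partition
    cv_roc: pd.DataFrame  # pooled out-of-fold ROC points (fpr, tpr)
    test_roc: pd.DataFrame
    confusion: pd.DataFrame  # test partition, threshold 0.5
    probabilities: pd.Series  # pooled out-of-fold probability per sample
    n_folds: int
    params: dict = field(default_factory=dict)


def assemble_features(
    blocks: dict[str, pd.DataFrame],
    labels: pd.Series,
    impute: bool = True,
    drop_constant: bool = True,
) -> CohortFeatureMatrix:
    """Join per-modality summary frames (samples x features) on sample id.

    Columns are renamed ``<block>.<feature>``; samples missing a modality
    are mean-imputed (``impute=True``) or dropped. All-constant columns
    are removed, with a warning, since they carry no signal and break
    standardization.
    """
    if not blocks:
        raise ValueError("no feature blocks given")
    renamed = {}
    for name, df in blocks.items():
        if df.shape[1] == 0:
            warnings.warn(f"block {name!r} has zero columns; skipped")
            continue
        renamed[name] = df.add_prefix(f"{name}.")
    X = pd.concat(renamed.values(), axis=1)
    X = X.loc[[s for s in labels.index if s in X.index]]
    if X.isna().any().any():
        if impute:
            X = X.fillna(X.mean())
        else:
            before = len(X)
            X = X.dropna()
            warnings.warn(f"dropped {before - len(X)} sample(s) missing a modality")
    block_cols = {name: list(df.columns) for name, df in renamed.items()}
    if drop_constant:
        nunique = X.nunique()
        constant = list(nunique[nunique <= 1].index)
        if constant:
            warnings.warn(f"dropped {len(constant)} constant feature column(s)")
            X = X.drop(columns=constant)
            block_cols = {
                n: [c for c in cols if c not in constant]
                for n, cols in block_cols.items()
            }
    block_cols = {n: cols for n, cols in block_cols.items() if cols}
    return CohortFeatureMatrix(X, labels.loc[X.index], block_cols)


def make_sgd(seed: int) -> Pipeline:
    """Standardization + linear model with logistic loss trained by SGD.

    Hyperparameters are fixed sane defaults (L2 alpha 1e-4, optimal
    learning-rate schedule, 1000 max epochs) and recorded in the report.
    """
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "sgd",
                SGDClassifier(
                    loss="log_loss",
                    penalty="l2",
                    alpha=1e-4,
                    learning_rate="optimal",
                    max_iter=1000,
                    tol=1e-4,
                    random_state=seed,
                ),
            ),
        ]
    )


def _oof_probabilities(
    X: np.ndarray, y: np.ndarray, folds: int, seed: int, model=None
) -> tuple[np.ndarray, int]:
    """Pooled out-of-fold positive-class probabilities."""
    _, counts = np.unique(y, return_counts=True)
    max_folds = int(counts.min())
    if max_folds < 2:
        raise ValueError("need >= 2 samples per class")
    if folds > max_folds:
        warnings.warn(f"reducing folds {folds} -> {max_folds} (class sizes)")
        folds = max_folds
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    proba = np.full(len(y), np.nan)
    for tr, te in skf.split(X, y):
        est = clone(model) if model is not None else make_sgd(seed)
        est.fit(X[tr], y[tr])
        proba[te] = est.predict_proba(X[te])[:, 1]
    return proba, folds


def _roc_frame(y: np.ndarray, scores: np.ndarray) -> tuple[pd.DataFrame, float]:
    fpr, tpr, _ = roc_curve(y, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr}), float(auc(fpr, tpr))


def train_eval_sgd(
    matrix: CohortFeatureMatrix,
    folds: int = 10,
    seed: int = 17,
    test_fraction: float = 0.3,
) -> ClassifierReport:
    """Cross-validated SGD classifier with ROC/AUC and confusion matrix.

    Deterministic for a fixed seed: folds, the train/test split and the
    SGD trajectory all derive from it.
    """
    X = matrix.X.to_numpy(float)
    y = matrix.y
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")

    proba, used_folds = _oof_probabilities(X, y, folds, seed)
    cv_roc, cv_auc = _roc_frame(y, proba)

    idx_tr, idx_te = train_test_split(
        np.arange(len(y)), test_size=test_fraction, stratify=y, random_state=seed
    )
    est = make_sgd(seed)
    est.fit(X[idx_tr], y[idx_tr])
    p_tr = est.predict_proba(X[idx_tr])[:, 1]
    p_te = est.predict_proba(X[idx_te])[:, 1]
    _, train_auc = _roc_frame(y[idx_tr], p_tr)
    test_roc, test_auc = _roc_frame(y[idx_te], p_te)
    cm = confusion_matrix(y[idx_te], (p_te >= 0.5).astype(int), labels=[0, 1])
    confusion = pd.DataFrame(
        cm,
        index=["true_healthy", "true_cancer"],
        columns=["pred_healthy", "pred_cancer"],
    )
    return ClassifierReport(
        cv_auc=cv_auc,
        train_auc=train_auc,
        test_auc=test_auc,
        cv_roc=cv_roc,
        test_roc=test_roc,
        confusion=confusion,
        probabilities=pd.Series(proba, index=matrix.X.index),
        n_folds=used_folds,
        params=est.named_steps["sgd"].get_params(),
    )


def per_modality_consistency(
    matrix: CohortFeatureMatrix, folds: int = 10, seed: int = 17
) -> pd.DataFrame:
    """Single-block out-of-fold predictions and their per-sample agreement.

    Returns one row per sample: predicted label per modality block, the
    number of blocks agreeing with the truth, and the majority-vote label.
    """
    if len(matrix.blocks) < 2:
        raise ValueError("need >= 2 feature blocks")
    y = matrix.y
    out = pd.DataFrame(index=matrix.X.index)
    for block, cols in matrix.blocks.items():
        if not cols:
            continue
        Xb = matrix.X[cols].to_numpy(float)
        proba, _ = _oof_probabilities(Xb, y, folds, seed)
        out[f"pred_{block}"] = np.where(proba >= 0.5, POSITIVE_LABEL, "healthy")
    pred_cols = [c for c in out.columns if c.startswith("pred_")]
    truth = matrix.labels
    out["n_agree"] = (out[pred_cols].to_numpy() == truth.to_numpy()[:, None]).sum(
        axis=1
    )
    votes = (out[pred_cols] == POSITIVE_LABEL).sum(axis=1)
    out["majority_vote"] = np.where(
        votes * 2 > len(pred_cols), POSITIVE_LABEL, "healthy"
    )
    out["label"] = truth
    return out


def benchmark_methods(
    matrix: CohortFeatureMatrix,
    methods: dict[str, object],
    folds: int = 10,
    seed: int = 17,
) -> pd.DataFrame:
    """Pooled CV AUC per classifier, on identical folds for every method.

    ``methods`` maps a name to an (unfitted) estimator exposing
    fit/predict_proba; each is wrapped with training-fold-only
    standardization. A method failing on any fold is reported with NaN.
    """
    X = matrix.X.to_numpy(float)
    y = matrix.y
    rows = []
    for name, est in methods.items():
        model = Pipeline([("scale", StandardScaler()), ("clf", clone(est))])
        try:
            proba, _ = _oof_probabilities(X, y, folds, seed, model)
            _, method_auc = _roc_frame(y, proba)
        except Exception as exc:  # noqa: BLE001 - a bad method must not stop the run
            warnings.warn(f"method {name!r} failed: {exc}")
            method_auc = float("nan")
        rows.append((name, method_auc))
    return pd.DataFrame(rows, columns=["method", "cv_auc"]).set_index("method")
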