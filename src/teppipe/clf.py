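"""Subject-level classification with segment voting.

Rows of the feature table are (subject, segment) pairs; classification is
evaluated with leave-one-subject-out cross-validation (LOOCV): each fold
holds out all three segment rows of one subject and trains on everyone
else.  The three predicted segment labels are fused by majority vote into
the subject's label.  Cognitive impairment (CI) is the positive class.

Dimensionality reduction precedes normalization.  Two modes are offered:

``joint``
    t-SNE (which has no out-of-sample transform) embeds *all* rows before
    cross-validation and min-max normalization is likewise fit jointly.
    This replicates a common but leakage-prone protocol; reports produced
    in this mode carry an explicit leakage flag.
``leakage_safe``
    Every data-dependent map is fit on the training rows of each fold
    only.  Because t-SNE cannot project held-out rows, a train-fit PCA of
    matching dimension stands in for it in this mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "ClassifierSpec",
    "ReductionSpec",
    "CvReport",
    "normalize",
    "fit_minmax",
    "apply_minmax",
    "reduce_features",
    "loocv_vote",
    "compute_metrics",
    "feature_importance",
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
]

POSITIVE_LABEL = "CI"
NEGATIVE_LABEL = "HC"

ALGORITHMS = ("svm_linear", "rf", "knn")


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier choice and its (fixed, unsearched) hyperparameters."""

    algorithm: str = "svm_linear"
    rf_n_trees: int = 7
    knn_k: int = 5
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.rf_n_trees % 2 == 0 or self.knn_k % 2 == 0:
            raise ValueError("rf_n_trees and knn_k must be odd (tie-free voting)")

    def build(self):
        if self.algorithm == "svm_linear":
            return SVC(kernel="linear", C=self.svm_c)
        if self.algorithm == "rf":
            return RandomForestClassifier(n_estimators=self.rf_n_trees,
                                          random_state=self.seed)
        return KNeighborsClassifier(n_neighbors=self.knn_k)


@dataclass(frozen=True)
class ReductionSpec:
    """Dimensionality-reduction choice.

    ``perplexity`` must stay well below the row count; with ~129 rows the
    default of 10 is a conservative choice.
    """

    method: str = "none"
    n_dims: int = 3
    mode: str = "leakage_safe"
    perplexity: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("none", "tsne"):
            raise ValueError(f"unknown reduction method {self.method!r}")
        if self.mode not in ("joint", "leakage_safe"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_dims < 1:
            raise ValueError("n_dims must be >= 1")


def fit_minmax(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column min/max of the fitting rows (training or joint)."""
    return X.min(axis=0), X.max(axis=0)


def apply_minmax(X: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                 clip: bool = False) -> np.ndarray:
    """Affine map of each column onto [-1, 1].

    Columns with zero range map to 0.  Rows outside the fitted range (test
    rows in leakage-safe mode) may exceed [-1, 1] unless ``clip``.
    """
    span = hi - lo
    out = np.zeros_like(X, dtype=float)
    nz = span != 0
    out[:, nz] = 2.0 * (X[:, nz] - lo[nz]) / span[nz] - 1.0
    if clip:
        out = np.clip(out, -1.0, 1.0)
    return out


def normalize(X: np.ndarray, clip: bool = False) -> np.ndarray:
    """Joint min-max normalization of a matrix onto [-1, 1] per column."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("cannot normalize an empty matrix")
    lo, hi = fit_minmax(X)
    if (hi == lo).any():
        import warnings

        warnings.warn("constant column(s) mapped to 0 during normalization",
                      stacklevel=2)
    return apply_minmax(X, lo, hi, clip=clip)


def reduce_features(X: np.ndarray, spec: ReductionSpec) -> np.ndarray:
    """Reduce a row matrix to ``spec.n_dims`` dimensions (row order kept).

    ``method='none'`` is the identity (used for per-ROI 14-feature runs);
    ``method='tsne'`` embeds all rows jointly with the configured
    perplexity and seed.
    """
    X = np.asarray(X, dtype=float)
    if spec.method == "none":
        return X
    if spec.n_dims >= X.shape[1]:
        raise ValueError("n_dims must be smaller than the feature count")
    if X.shape[0] < 2 * spec.n_dims:
        raise ValueError("too few rows for the requested embedding dimension")
    tsne = TSNE(n_components=spec.n_dims, perplexity=spec.perplexity,
                random_state=spec.seed, init="pca")
    return tsne.fit_transform(X)


def compute_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity and F1 from a confusion matrix.

    A zero denominator yields ``None`` (serialized as null), never 0.
    """
    counts = (tp, fp, fn, tn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "f1": ratio(2 * tp, 2 * tp + fp + fn),
    }


@dataclass
class CvReport:
    """LOOCV result: per-subject voted labels, confusion counts, metrics."""

    per_subject: list[dict]
    confusion: dict[str, int]
    metrics: dict[str, float | None]
    folds: list[dict] = field(default_factory=list, repr=False)
    leakage_flag: bool = False
    config: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Assert fold bookkeeping: training rows never include the test subject."""
        for fold in self.folds:
            if set(fold["train_rows"]) & set(fold["test_rows"]):
                raise AssertionError(
                    f"fold {fold['subject_id']}: train/test rows overlap")


def _majority(labels: Sequence[str]) -> str:
    pos = sum(1 for lab in labels if lab == POSITIVE_LABEL)
    return POSITIVE_LABEL if pos > len(labels) / 2 else NEGATIVE_LABEL


def _split_table(table: pd.DataFrame):
    meta = ("subject_id", "segment", "group")
    feature_cols = [c for c in table.columns if c not in meta]
    subjects = list(dict.fromkeys(table["subject_id"]))
    for sid in subjects:
        if int((table["subject_id"] == sid).sum()) != 3:
            raise ValueError(f"subject {sid} does not have exactly 3 segment rows")
    X = table[feature_cols].to_numpy(dtype=float)
    y = table["group"].to_numpy()
    return subjects, X, y, feature_cols


def loocv_vote(table: pd.DataFrame, clf: ClassifierSpec | None = None,
               red: ReductionSpec | None = None) -> CvReport:
    """Leave-one-subject-out cross-validation with 3-segment label voting."""
    clf = clf or ClassifierSpec()
    red = red or ReductionSpec()
    subjects, X, y, _ = _split_table(table)
    sid_col = table["subject_id"].to_numpy()

    joint = red.mode == "joint"
    if joint:
        Xr = reduce_features(X, red)
        lo, hi = fit_minmax(Xr)
        Xn_joint = apply_minmax(Xr, lo, hi)

    per_subject = []
    folds = []
    tp = fp = fn = tn = 0
    for sid in subjects:
        test = np.flatnonzero(sid_col == sid)
        train = np.flatnonzero(sid_col != sid)
        if joint:
            Xtr, Xte = Xn_joint[train], Xn_joint[test]
        else:
            if red.method == "tsne":
                # t-SNE cannot embed unseen rows; a train-fit linear
                # projection of matching dimension stands in.
                proj = PCA(n_components=red.n_dims, random_state=red.seed)
                Xtr_r = proj.fit_transform(X[train])
                Xte_r = proj.transform(X[test])
            else:
                Xtr_r, Xte_r = X[train], X[test]
            lo, hi = fit_minmax(Xtr_r)
            Xtr = apply_minmax(Xtr_r, lo, hi)
            Xte = apply_minmax(Xte_r, lo, hi)
        model = clf.build()
        model.fit(Xtr, y[train])
        seg_labels = list(model.predict(Xte))
        voted = _majority(seg_labels)
        true = y[test][0]
        per_subject.append({
            "subject_id": sid,
            "true_group": true,
            "segment_labels": seg_labels,
            "voted_label": voted,
        })
        folds.append({"subject_id": sid,
                      "train_rows": train.tolist(),
                      "test_rows": test.tolist()})
        if true == POSITIVE_LABEL:
            tp += voted == POSITIVE_LABEL
            fn += voted != POSITIVE_LABEL
        else:
            tn += voted == NEGATIVE_LABEL
            fp += voted != NEGATIVE_LABEL

    confusion = {"TP": int(tp), "FP": int(fp), "FN": int(fn), "TN": int(tn)}
    report = CvReport(
        per_subject=per_subject,
        confusion=confusion,
        metrics=compute_metrics(tp, fp, fn, tn),
        folds=folds,
        leakage_flag=bool(joint),
        config={"classifier": clf.__dict__, "reduction": red.__dict__},
    )
    report.validate()
    return report


def feature_importance(table: pd.DataFrame, columns: list[str] | None = None,
                       seed: int = 0, n_estimators: int = 50
                       ) -> list[tuple[str, float]]:
    """Gradient-boosted-trees gain importance per feature, descending.

    Trains an XGBoost classifier on all rows (CI = 1) and reports the gain
    importance of each column; deterministic under a fixed seed.
    """
    from xgboost import XGBClassifier

    meta = ("subject_id", "segment", "group")
    cols = columns or [c for c in table.columns if c not in meta]
    y = (table["group"] == POSITIVE_LABEL).to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("feature importance needs both classes present")
    X = table[cols].to_numpy(dtype=float)
    model = XGBClassifier(
        n_estimators=n_estimators, max_depth=3, learning_rate=0.3,
        importance_type="gain", random_state=seed, n_jobs=1,
        tree_method="exact", eval_metric="logloss",
    )
    model.fit(X, y)
    scores = model.feature_importances_
    order = np.argsort(-scores, kind="stable")
    return [(cols[i], float(scores[i])) for i in order]
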