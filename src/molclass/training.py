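"""In-silico construction of the linear classifier from expression data.

Pipeline: differential-expression screen (|log2 fold change| >= 2, i.e. a
fourfold disparity) -> random-forest importance ranking (permutation-based
Mean Decrease Accuracy, impurity-based Mean Decrease Gini as tiebreaker) ->
class-weighted linear SVM over the top-k panels (k = 1..10, with the
positive-class misclassification penalty twice the negative's, favoring
cancer sensitivity) -> selection of the highest validation-AUC panel,
smallest panel winning ties -> export of weights on the classifier's nM
input scale, rounded to one decimal.

Everything is seed-deterministic: the same seed yields a bit-for-bit
identical serialized classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .compiler import InputScale, LinearClassifierSpec
from .crn import ValidationError

__all__ = [
    "ExpressionMatrix",
    "PanelModel",
    "differential_expression",
    "rank_features",
    "train_panels",
    "select_classifier",
    "split_train_validation",
    "train_classifier",
]


@dataclass
class ExpressionMatrix:
    """Samples × miRNA log2-scale expression with binary class labels."""

    values: pd.DataFrame  # index: sample ids, columns: feature ids
    labels: pd.Series  # aligned with values.index
    positive_class: str = "HCC"
    negative_class: str = "healthy"

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.values.index)
        if self.values.isna().any().any() or self.labels.isna().any():
            raise ValidationError("expression matrix contains missing values")
        classes = set(self.labels.unique())
        if not classes <= {self.positive_class, self.negative_class}:
            raise ValidationError(f"unexpected class labels {classes}")

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    @property
    def y(self) -> np.ndarray:
        return (self.labels == self.positive_class).to_numpy(int)

    def subset(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[sample_ids],
            self.labels.loc[sample_ids],
            self.positive_class,
            self.negative_class,
        )

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "label", self.labels)
        out.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(
        cls,
        path,
        positive_class: str = "HCC",
        negative_class: str = "healthy",
        label_column: str = "label",
    ) -> "ExpressionMatrix":
        df = pd.read_csv(path, index_col=0)
        if label_column not in df.columns:
            raise ValidationError(f"expression CSV lacks a {label_column!r} column")
        labels = df[label_column].astype(str)
        values = df.drop(columns=[label_column]).astype(float)
        values.index.name = None
        labels.index.name = None
        return cls(values, labels, positive_class, negative_class)


@dataclass
class PanelModel:
    """A linear SVM trained on a k-feature panel, weights in nM input space."""

    features: tuple[str, ...]
    weights: tuple[float, ...]  # one-decimal, nM input space
    bias: float
    k: int
    auc_train: float
    auc_validation: float
    weights_unrounded: tuple[float, ...] = field(default=(), repr=False)
    auc_validation_unrounded: float = float("nan")

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 10:
            raise ValidationError("panel size k must be between 1 and 10")


def differential_expression(
    matrix: ExpressionMatrix, threshold: float = 2.0
) -> pd.DataFrame:
    """Per-feature log2 fold change (positive-class mean − negative-class mean).

    Features with |log2FC| >= ``threshold`` (fourfold by default) are
    retained; direction is 'up' (higher in the positive class) or 'down'.
    """
    y = matrix.y
    if y.min() == y.max():
        raise ValidationError("both classes must be represented")
    pos_mean = matrix.values[y == 1].mean(axis=0)
    neg_mean = matrix.values[y == 0].mean(axis=0)
    fc = pos_mean - neg_mean
    out = pd.DataFrame(
        {
            "log2_fold_change": fc,
            "direction": np.where(fc >= 0, "up", "down"),
            "retained": fc.abs() >= threshold,
        }
    )
    out.index.name = "feature"
    return out


def rank_features(
    matrix: ExpressionMatrix,
    retained,
    seed: int,
    n_estimators: int = 500,
    n_repeats: int = 10,
) -> pd.DataFrame:
    """Random-forest importance ranking of the retained features.

    Mean Decrease Accuracy is the permutation importance of each feature
    (accuracy scoring); Mean Decrease Gini is the forest's impurity-based
    importance, used as the tiebreaker.  Deterministic given the seed.
    """
    retained = list(retained)
    if not retained:
        raise ValidationError("retained feature set is empty")
    X = matrix.values[retained].to_numpy()
    y = matrix.y
    rng = np.random.default_rng(seed)
    rf_seed, perm_seed = (int(s) for s in rng.integers(0, 2**31 - 1, 2))
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=rf_seed, n_jobs=1
    )
    forest.fit(X, y)
    perm = permutation_importance(
        forest, X, y, n_repeats=n_repeats, random_state=perm_seed, scoring="accuracy"
    )
    df = pd.DataFrame(
        {
            "mean_decrease_accuracy": perm.importances_mean,
            "mean_decrease_gini": forest.feature_importances_,
        },
        index=pd.Index(retained, name="feature"),
    )
    return df.sort_values(
        ["mean_decrease_accuracy", "mean_decrease_gini"],
        ascending=False,
        kind="mergesort",
    )


def split_train_validation(
    matrix: ExpressionMatrix, seed: int, validation_fraction: float = 0.5
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Stratified 50/50 train/validation split (seeded)."""
    train_idx, val_idx = train_test_split(
        matrix.values.index,
        test_size=validation_fraction,
        random_state=seed % (2**31),
        stratify=matrix.labels,
    )
    return matrix.subset(train_idx), matrix.subset(val_idx)


def _input_scale_from_matrix(matrix: ExpressionMatrix) -> InputScale:
    lo = float(matrix.values.min().min())
    hi = float(matrix.values.max().max())
    if hi <= lo:
        hi = lo + 1.0
    return InputScale(x_min=lo, x_max=hi)


def _round_weights(weights: np.ndarray, bias: float, target_max: float = 2.5):
    """Rescale (w, b) jointly so max|w| = ``target_max``, round w to 0.1.

    Joint rescaling leaves the decision boundary unchanged; the target
    magnitude keeps one-decimal rounding from destroying small weights.
    """
    scale = target_max / np.max(np.abs(weights))
    w = weights * scale
    b = bias * scale
    w_rounded = np.round(w, 1) + 0.0  # normalize -0.0
    return w, b, w_rounded


def _auc(weights, bias, X, y) -> float:
    scores = X @ np.asarray(weights) + bias
    return float(roc_auc_score(y, scores))


def train_panels(
    matrix_train: ExpressionMatrix,
    ranking: pd.DataFrame,
    matrix_validation: ExpressionMatrix,
    k_range=range(1, 11),
    class_penalty_ratio: float = 2.0,
    C: float = 1.0,
    seed: int = 0,
    input_scale: InputScale | None = None,
) -> list[PanelModel]:
    """Linear-kernel SVMs over the top-k ranked panels.

    The positive-class misclassification penalty is ``class_penalty_ratio``
    times the negative's.  Features are standardized for the fit; weights
    are mapped back to the classifier's nM input space (shared affine scale)
    and rounded to one decimal after the fit.  AUCs are reported for both
    splits, with the rounded weights.
    """
    y_tr, y_val = matrix_train.y, matrix_validation.y
    if y_tr.min() == y_tr.max() or y_val.min() == y_val.max():
        raise ValidationError("degenerate single-class split")
    ranked = list(ranking.index)
    if input_scale is None:
        input_scale = _input_scale_from_matrix(matrix_train)
    a = input_scale.slope

    panels = []
    for k in k_range:
        if k > len(ranked):
            break
        feats = ranked[:k]
        X_tr = matrix_train.values[feats].to_numpy()
        X_val = matrix_validation.values[feats].to_numpy()
        mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
        sd[sd == 0] = 1.0
        svm = SVC(
            kernel="linear",
            C=C,
            class_weight={1: class_penalty_ratio, 0: 1.0},
            random_state=seed % (2**31),
        )
        svm.fit((X_tr - mu) / sd, y_tr)
        w_std = svm.coef_.ravel()
        b_std = float(svm.intercept_[0])
        # undo standardization: score on raw log2 expression x
        w_x = w_std / sd
        b_x = b_std - float(np.dot(w_std, mu / sd))
        # to input space u = a·x + m (shared affine scale):
        # Σ w_x x + b_x = Σ (w_x/a) u + (b_x − (m/a) Σ w_x)
        w_u = w_x / a
        b_u = b_x - (input_scale.intercept / a) * float(w_x.sum())
        w_u, b_u, w_rounded = _round_weights(w_u, b_u)

        keep = w_rounded != 0.0
        if not keep.any():
            continue
        feats_kept = tuple(np.asarray(feats)[keep])
        U_tr = input_scale.to_nM(X_tr[:, keep])
        U_val = input_scale.to_nM(X_val[:, keep])
        panels.append(
            PanelModel(
                features=feats_kept,
                weights=tuple(w_rounded[keep]),
                bias=b_u,
                k=k,
                auc_train=_auc(w_rounded[keep], b_u, U_tr, y_tr),
                auc_validation=_auc(w_rounded[keep], b_u, U_val, y_val),
                weights_unrounded=tuple(w_u[keep]),
                auc_validation_unrounded=_auc(w_u[keep], b_u, U_val, y_val),
            )
        )
    if not panels:
        raise ValidationError("no trainable panel (all weights rounded to zero)")
    return panels


def select_classifier(
    panels: list[PanelModel],
    input_scale: InputScale | None = None,
    positive_class: str = "HCC",
    negative_class: str = "healthy",
) -> LinearClassifierSpec:
    """Highest validation AUC wins; ties broken toward the smaller panel."""
    if not panels:
        raise ValidationError("no panels to select from")
    best = max(panels, key=lambda p: (p.auc_validation, -p.k))
    return LinearClassifierSpec(
        features=best.features,
        weights=best.weights,
        bias=best.bias,
        positive_class=positive_class,
        negative_class=negative_class,
        input_scale=input_scale,
    )


def train_classifier(
    matrix: ExpressionMatrix,
    seed: int,
    de_threshold: float = 2.0,
    k_range=range(1, 11),
    class_penalty_ratio: float = 2.0,
) -> tuple[LinearClassifierSpec, list[PanelModel], pd.DataFrame]:
    """End-to-end: DE screen -> RF ranking -> SVM panels -> selected spec."""
    train, val = split_train_validation(matrix, seed)
    de = differential_expression(train, de_threshold)
    retained = list(de.index[de["retained"]])
    if not retained:
        raise ValidationError("no differentially expressed features retained")
    ranking = rank_features(train, retained, seed)
    scale = _input_scale_from_matrix(train)
    panels = train_panels(
        train,
        ranking,
        val,
        k_range=k_range,
        class_penalty_ratio=class_penalty_ratio,
        seed=seed,
        input_scale=scale,
    )
    spec = select_classifier(
        panels, scale, matrix.positive_class, matrix.negative_class
    )
    return spec, panels, ranking
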