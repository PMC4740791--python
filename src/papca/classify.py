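"""Tissue staging with a homogeneous-cubic-kernel support vector machine.

Liver condition (normal / steatosis / fibrosis) is staged from PASA
features — slope and midband-fit at 700, 1220 and 1370 nm — using a C-type
soft-margin SVM with the homogeneous third-order polynomial kernel

    K(u, v) = (γ ⟨u, v⟩)³ .

Multi-class decisions are one-vs-one with majority vote; ties fall to the
lowest class index and are recorded.  Slope and midband features are min–max
normalized to [0, 1] per parameter type.  Performance is assessed by
stratified 3-fold cross-validation: with 12 specimens per condition, each
cycle trains on 24 specimens (2 groups × 4 × 3 conditions) and tests on the
held-out 12, and the per-cycle accuracies are averaged.

The underlying quadratic program is solved by scikit-learn's ``SVC`` (with
``kernel='poly', coef0=0, degree=3``, which is exactly the kernel above);
voting, normalization, fold construction and reporting are defined here.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

#: default feature-group layout for the 6-feature PASA vector:
#: columns 0–2 are slopes, 3–5 midband-fits
SLOPE_MID_GROUPS = ((0, 1, 2), (3, 4, 5))

DEFAULT_C_GRID = tuple(2.0**k for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**k for k in range(-15, 4, 2))


def poly3_kernel(u: np.ndarray, v: np.ndarray, gamma: float) -> float:
    """Homogeneous cubic kernel ``(γ ⟨u, v⟩)³`` of two feature vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("u and v must be 1-D vectors of equal length")
    return float((gamma * np.dot(u, v)) ** 3)


def poly3_gram(X: np.ndarray, Y: np.ndarray | None = None, gamma: float = 1.0) -> np.ndarray:
    """Gram matrix of :func:`poly3_kernel` between the rows of X and Y."""
    X = np.asarray(X, dtype=float)
    Y = X if Y is None else np.asarray(Y, dtype=float)
    return (gamma * (X @ Y.T)) ** 3


@dataclass(frozen=True)
class SVMConfig:
    """Staging-classifier settings."""

    C: float = 10.0
    gamma: float = 1.0 / 6.0
    degree: int = 3
    normalization: str = "train-fold"  # or "global"

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError("C must be positive")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if self.normalization not in ("train-fold", "global"):
            raise ValueError("normalization must be 'train-fold' or 'global'")


class TypedMinMaxScaler(TransformerMixin, BaseEstimator):
    """Min–max normalization shared within feature groups.

    Slopes and midband-fits are physically different quantities; each group
    of columns is rescaled by one affine map computed from all values of
    that group in the fitting set, so fitted values land in [0, 1] while
    relative differences among same-type features are preserved.  Held-out
    values are mapped by the same transform without clipping; a constant
    group maps to 0.
    """

    def __init__(self, groups: Sequence[Sequence[int]] = SLOPE_MID_GROUPS):
        self.groups = groups

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        mins, scales = [], []
        for cols in self.groups:
            block = X[:, list(cols)]
            lo, hi = float(block.min()), float(block.max())
            mins.append(lo)
            scales.append(1.0 / (hi - lo) if hi > lo else 0.0)
        self.group_min_ = np.array(mins)
        self.group_scale_ = np.array(scales)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "group_min_")
        X = check_array(X, dtype=float)
        out = X.astype(float).copy()
        for g, cols in enumerate(self.groups):
            cols = list(cols)
            out[:, cols] = (X[:, cols] - self.group_min_[g]) * self.group_scale_[g]
        return out


class PolySVC(ClassifierMixin, BaseEstimator):
    """C-type SVM with the homogeneous cubic kernel, one-vs-one voting.

    Pairwise machines are trained by scikit-learn's ``SVC``; prediction
    re-implements the majority vote so the tie rule is explicit: a tied vote
    goes to the lowest class index.  ``tie_count_`` records how many of the
    most recent predictions were tie-broken.
    """

    def __init__(self, C: float = 10.0, gamma: float = 1.0 / 6.0, degree: int = 3):
        self.C = C
        self.gamma = gamma
        self.degree = degree

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes to train the classifier")
        self.svc_ = SVC(
            C=self.C,
            kernel="poly",
            degree=self.degree,
            gamma=self.gamma,
            coef0=0.0,
            decision_function_shape="ovo",
        )
        self.svc_.fit(X, y_enc)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "svc_")
        X = check_array(X, dtype=float)
        return np.atleast_2d(self.svc_.decision_function(X))

    def predict(self, X):
        check_is_fitted(self, "svc_")
        X = check_array(X, dtype=float)
        n_classes = self.classes_.size
        dec = self.decision_function(X)
        if n_classes == 2:
            # single machine; positive decision favors the second class
            idx = (dec.ravel() > 0).astype(int)
            self.tie_count_ = 0
            return self.classes_[idx]
        votes = np.zeros((X.shape[0], n_classes), dtype=int)
        for col, (i, j) in enumerate(combinations(range(n_classes), 2)):
            d = dec[:, col]
            # sklearn ovo: a positive decision favors the first class of the
            # pair; a zero decision falls to the lower class index
            votes[d >= 0, i] += 1
            votes[d < 0, j] += 1
        top = votes.max(axis=1, keepdims=True)
        ties = (votes == top).sum(axis=1) > 1
        self.tie_count_ = int(np.sum(ties))
        return self.classes_[np.argmax(votes, axis=1)]


@dataclass
class CVCycle:
    """One train/test cycle of the 3-fold procedure."""

    test_group: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    train_pred: np.ndarray
    test_pred: np.ndarray
    train_true: np.ndarray
    test_true: np.ndarray
    train_accuracy: float
    test_accuracy: float
    tie_broken: int


@dataclass
class CVReport:
    """Per-cycle predictions and accuracies plus cross-cycle means."""

    fold_assignment: np.ndarray
    cycles: list[CVCycle]
    mean_train_accuracy: float
    mean_test_accuracy: float
    config: SVMConfig
    seed: int

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "seed": int(self.seed),
            "fold_assignment": self.fold_assignment.tolist(),
            "mean_train_accuracy": self.mean_train_accuracy,
            "mean_test_accuracy": self.mean_test_accuracy,
            "cycles": [
                {
                    "test_group": c.test_group,
                    "train_idx": c.train_idx.tolist(),
                    "test_idx": c.test_idx.tolist(),
                    "train_pred": np.asarray(c.train_pred).tolist(),
                    "test_pred": np.asarray(c.test_pred).tolist(),
                    "train_true": np.asarray(c.train_true).tolist(),
                    "test_true": np.asarray(c.test_true).tolist(),
                    "train_accuracy": c.train_accuracy,
                    "test_accuracy": c.test_accuracy,
                    "tie_broken": c.tie_broken,
                }
                for c in self.cycles
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def minmax_normalize(
    train_features: np.ndarray,
    other_features: np.ndarray | None = None,
    groups: Sequence[Sequence[int]] = SLOPE_MID_GROUPS,
):
    """Fit a per-type min–max transform on ``train_features`` and apply it.

    Returns ``(train_scaled, other_scaled, scaler)``; ``other_scaled`` is
    None when no held-out features are given.  Held-out values outside the
    fitting range map outside [0, 1] — the transform is affine, not clipped.
    """
    scaler = TypedMinMaxScaler(groups=groups).fit(train_features)
    train_scaled = scaler.transform(train_features)
    other_scaled = None if other_features is None else scaler.transform(other_features)
    return train_scaled, other_scaled, scaler


def _stratified_groups(labels: np.ndarray, n_groups: int, rng: np.random.Generator) -> np.ndarray:
    classes, counts = np.unique(labels, return_counts=True)
    if np.unique(counts).size != 1 or counts[0] % n_groups != 0:
        raise ValueError(
            f"per-class counts {dict(zip(classes.tolist(), counts.tolist()))} must be "
            f"equal and divisible by {n_groups}"
        )
    per_group = counts[0] // n_groups
    assignment = np.empty(labels.size, dtype=int)
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        for g in range(n_groups):
            assignment[idx[g * per_group : (g + 1) * per_group]] = g + 1
    return assignment


def threefold_cv(
    features: np.ndarray,
    labels: Sequence,
    config: SVMConfig | None = None,
    seed: int = 0,
    groups: Sequence[Sequence[int]] | None = None,
) -> CVReport:
    """Stratified 3-fold cross-validation of the staging SVM.

    Specimens are randomly divided (seeded) into three groups with equal
    per-class counts; each group serves once as the test set while the other
    two train the machine.  Normalization is fit on the training folds by
    default (``config.normalization='global'`` fits it on all specimens
    instead, mirroring a pre-normalized feature table).
    """
    config = config or SVMConfig()
    X = check_array(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    if groups is None:
        groups = _default_groups(X.shape[1])
    rng = np.random.default_rng(seed)
    assignment = _stratified_groups(y, 3, rng)

    global_scaler = None
    if config.normalization == "global":
        global_scaler = TypedMinMaxScaler(groups=groups).fit(X)

    cycles = []
    for g in (1, 2, 3):
        test_idx = np.flatnonzero(assignment == g)
        train_idx = np.flatnonzero(assignment != g)
        if global_scaler is not None:
            scaler = global_scaler
        else:
            scaler = TypedMinMaxScaler(groups=groups).fit(X[train_idx])
        Xtr = scaler.transform(X[train_idx])
        Xte = scaler.transform(X[test_idx])
        clf = PolySVC(C=config.C, gamma=config.gamma, degree=config.degree)
        clf.fit(Xtr, y[train_idx])
        train_pred = clf.predict(Xtr)
        test_pred = clf.predict(Xte)
        cycles.append(
            CVCycle(
                test_group=g,
                train_idx=train_idx,
                test_idx=test_idx,
                train_pred=train_pred,
                test_pred=test_pred,
                train_true=y[train_idx],
                test_true=y[test_idx],
                train_accuracy=float(np.mean(train_pred == y[train_idx])),
                test_accuracy=float(np.mean(test_pred == y[test_idx])),
                tie_broken=clf.tie_count_,
            )
        )
    return CVReport(
        fold_assignment=assignment,
        cycles=cycles,
        mean_train_accuracy=float(np.mean([c.train_accuracy for c in cycles])),
        mean_test_accuracy=float(np.mean([c.test_accuracy for c in cycles])),
        config=config,
        seed=int(seed),
    )


def _default_groups(n_features: int) -> tuple[tuple[int, ...], ...]:
    # 6-feature vectors are (3 slopes, 3 midbands); otherwise all columns
    # form one parameter type
    if n_features == 6:
        return SLOPE_MID_GROUPS
    return (tuple(range(n_features)),)


def grid_search(
    features: np.ndarray,
    labels: Sequence,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    seed: int = 0,
    normalization: str = "train-fold",
    criterion: str = "mean-test",
) -> SVMConfig:
    """Exhaustive (C, γ) search over exponential grids.

    Candidates are ranked by mean cross-validated testing accuracy
    (``criterion='mean-test'``; ``'mean-train'`` ranks by training accuracy
    instead).  Ties resolve to the smallest C, then the smallest γ, so the
    least-capacity machine wins among equals.
    """
    if len(C_grid) == 0 or len(gamma_grid) == 0:
        raise ValueError("C_grid and gamma_grid must be non-empty")
    if criterion not in ("mean-test", "mean-train"):
        raise ValueError("criterion must be 'mean-test' or 'mean-train'")
    best = None
    best_score = -np.inf
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            config = SVMConfig(C=C, gamma=gamma, normalization=normalization)
            report = threefold_cv(features, labels, config, seed=seed)
            score = (
                report.mean_test_accuracy
                if criterion == "mean-test"
                else report.mean_train_accuracy
            )
            if score > best_score:  # strict: earlier (smaller C, gamma) wins ties
                best_score = score
                best = config
    return best


def accuracy_table(
    per_cycle_predictions: Mapping[str, Sequence[Sequence]],
    truths: Sequence[Sequence] | Sequence,
) -> pd.DataFrame:
    """Per-cycle and mean accuracies in the worked-example table layout.

    ``per_cycle_predictions`` maps a feature-set name (e.g. ``'slope'``,
    ``'mid'``, ``'both'``) to its list of per-cycle predicted label arrays;
    ``truths`` is either one label array shared by all cycles or a list of
    per-cycle arrays.  The output holds one row per (feature set, cycle)
    plus a mean row per feature set, with the fraction correct as a
    percentage and as an ``"x/n"`` count string.
    """
    rows = []
    for name, cycles in per_cycle_predictions.items():
        truths_per_cycle = (
            truths
            if len(truths) == len(cycles) and not np.isscalar(truths[0])
            and len(np.shape(truths[0])) > 0
            else [truths] * len(cycles)
        )
        pct = []
        for k, (pred, true) in enumerate(zip(cycles, truths_per_cycle), start=1):
            pred = np.asarray(pred)
            true = np.asarray(true)
            if pred.shape != true.shape:
                raise ValueError(
                    f"{name} cycle {k}: {pred.size} predictions vs {true.size} truths"
                )
            n_correct = int(np.sum(pred == true))
            acc = 100.0 * n_correct / true.size
            pct.append(acc)
            rows.append(
                {
                    "feature_set": name,
                    "cycle": str(k),
                    "n_correct": n_correct,
                    "n_total": int(true.size),
                    "accuracy_pct": acc,
                    "display": f"{acc:.1f}% ({n_correct}/{true.size})",
                }
            )
        mean_acc = float(np.mean(pct))
        rows.append(
            {
                "feature_set": name,
                "cycle": "mean",
                "n_correct": None,
                "n_total": None,
                "accuracy_pct": mean_acc,
                "display": f"{mean_acc:.1f}%",
            }
        )
    return pd.DataFrame(rows)
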