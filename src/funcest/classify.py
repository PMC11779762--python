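"""Linear separation of function types in log-hyperparameter space.

Expert raters label each drawn function as linear, quadratic, cubic,
data-tracking, or unclassifiable. Because cubic and data-tracking drawings
occupy the same region of parameter space, the two are merged before
analysis and unclassifiable rows are dropped. A linear classifier then
separates linear drawings from the rest: linear functions live at large
length scales and small noise variances, data-tracking functions at small
length scales and large noise variances, so a 2-D boundary on
(log length scale, log noise variance) already does most of the work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

from .exceptions import DegenerateLabelsError, InvalidArgumentError

__all__ = [
    "VALID_LABELS",
    "FEATURE_NAMES",
    "LinearBoundary",
    "prepare_labels",
    "fit_linear_boundary",
    "apply_boundary",
]

VALID_LABELS = ("linear", "quadratic", "cubic", "data_tracking", "unclassifiable")

#: Canonical feature columns, in order.
FEATURE_NAMES = ("log_length_scale", "log_signal_var", "log_noise_var")


@dataclass(frozen=True)
class LinearBoundary:
    """A linear decision rule over named log-hyperparameter features.

    ``score = weights . point + bias``; a non-negative score is the
    ``positive_label`` side (data-tracking/quadratic), a negative score the
    linear side. Exact zeros break toward ``positive_label``.
    """

    features: tuple
    weights: np.ndarray
    bias: float
    positive_label: str = "data_tracking"
    training_accuracy: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "features", tuple(self.features))
        if self.weights.size != len(self.features):
            raise InvalidArgumentError("one weight per feature required")
        if np.all(self.weights == 0):
            raise InvalidArgumentError("at least one weight must be nonzero")


def prepare_labels(labels: pd.DataFrame) -> pd.DataFrame:
    """Merge cubic into data_tracking and drop unclassifiable rows.

    Expects a ``label`` column drawn from :data:`VALID_LABELS`; the
    remaining classes are {linear, quadratic, data_tracking}.
    """
    if "label" not in labels.columns:
        raise InvalidArgumentError("labels table needs a 'label' column")
    bad = set(labels["label"]) - set(VALID_LABELS)
    if bad:
        raise InvalidArgumentError(f"unknown labels: {sorted(bad)}")
    out = labels[labels["label"] != "unclassifiable"].copy()
    out["label"] = out["label"].replace({"cubic": "data_tracking"})
    if out.empty:
        raise DegenerateLabelsError("no classifiable rows remain")
    return out.reset_index(drop=True)


def fit_linear_boundary(
    features: pd.DataFrame,
    labels,
    feature_subset: tuple | None = None,
    positive_label: str = "data_tracking",
) -> LinearBoundary:
    """Fit a linear-vs-rest boundary on the chosen feature subset.

    The separator is an L2-regularized squared-hinge margin classifier
    trained deterministically in the primal; the regularization is applied
    to the mean loss, so the fitted rule (and its apparent accuracy) is
    invariant to duplicating every row. ``labels`` may be any array-like of
    class names; every non-"linear" row is the positive class.

    Returns the boundary with apparent (training-set) accuracy.
    """
    subset = tuple(feature_subset) if feature_subset is not None else FEATURE_NAMES
    missing = [f for f in subset if f not in features.columns]
    if missing:
        raise InvalidArgumentError(f"features table lacks columns {missing}")
    X = features.loc[:, list(subset)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise InvalidArgumentError("features must be finite")
    y = np.asarray([lab != "linear" for lab in np.asarray(labels)], dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("need both a linear and a non-linear class")
    # C = 1/n puts unit regularization against the *mean* squared-hinge loss;
    # the large intercept_scaling leaves the bias effectively unregularized
    # so the fitted rule never scores below the majority-class rate.
    clf = LinearSVC(
        C=1.0 / len(y),
        loss="squared_hinge",
        dual=False,
        tol=1e-10,
        intercept_scaling=100.0,
    )
    clf.fit(X, y)
    acc = float(clf.score(X, y))
    return LinearBoundary(
        features=subset,
        weights=clf.coef_.ravel(),
        bias=float(clf.intercept_[0]),
        positive_label=positive_label,
        training_accuracy=acc,
    )


def apply_boundary(boundary: LinearBoundary, point) -> tuple[str, float]:
    """Evaluate the boundary at a point; returns (label, score).

    ``point`` is a mapping of feature name to value, or an array ordered as
    ``boundary.features``. Score zero breaks toward the positive label.
    """
    if isinstance(point, dict):
        missing = [f for f in boundary.features if f not in point]
        if missing:
            raise InvalidArgumentError(f"point lacks features {missing}")
        vec = np.array([point[f] for f in boundary.features], dtype=float)
    else:
        vec = np.asarray(point, dtype=float).ravel()
        if vec.size != len(boundary.features):
            raise InvalidArgumentError(
                f"point must have {len(boundary.features)} values"
            )
    score = float(boundary.weights @ vec + boundary.bias)
    label = boundary.positive_label if score >= 0 else "linear"
    return label, score
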