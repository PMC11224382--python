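"""Classical-ML comparison models on flattened features.

Four classifiers — decision tree, random forest, AdaBoost (staged additive
stumps), and K-nearest neighbours — fitted on row-major flattened features of
the RGB (1386), hyperspectral (462) or fused (1848) representation.  Defaults:
entropy-criterion tree, 100-tree forest, 50 depth-2 AdaBoost trees, KNN with
k = 5 and Euclidean distance; all overridable via keyword arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .errors import PodfusionError, ShapeError
from .fusion import FusedSample

BASELINE_NAMES = ("decision_tree", "random_forest", "adaboost", "knn")


@dataclass
class FeatureTable:
    """n x d flattened feature matrix with labels and a source tag."""

    matrix: np.ndarray
    labels: np.ndarray
    source: str = "fusion"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.labels.size:
            raise ShapeError(
                f"feature matrix {self.matrix.shape} does not align with {self.labels.size} labels"
            )
        if not np.isfinite(self.matrix).all():
            raise ShapeError("feature matrix contains non-finite values")


def flatten(samples, labels: np.ndarray | None = None, source: str = "fusion") -> FeatureTable:
    """Row-major flatten of homogeneous samples into a feature table.

    Accepts a list of fused samples (label comes from each sample) or an
    array of per-sample tensors plus a label vector.  The row-major order
    matches the fusion module's channel-last layout, so a flattened fused
    row has length 22*21*4 = 1848.
    """
    if len(samples) and isinstance(samples[0], FusedSample):
        arrays = [s.tensor for s in samples]
        labels = np.array([s.label for s in samples], dtype=int)
    else:
        arrays = [np.asarray(s) for s in samples]
        if labels is None:
            raise PodfusionError("labels required when samples are raw arrays")
    shape0 = arrays[0].shape
    if any(a.shape != shape0 for a in arrays):
        raise ShapeError("ragged sample shapes cannot be flattened into one table")
    matrix = np.stack([a.reshape(-1) for a in arrays])
    return FeatureTable(matrix=matrix, labels=np.asarray(labels, dtype=int), source=source)


def fit_baseline(name: str, table: FeatureTable, seed: int = 0, **params):
    """Fit one named baseline on a feature table; returns the fitted estimator."""
    if np.unique(table.labels).size < 2:
        raise PodfusionError("baseline fitting needs at least two classes")
    if name == "decision_tree":
        model = DecisionTreeClassifier(criterion="entropy", random_state=seed, **params)
    elif name == "random_forest":
        params.setdefault("n_estimators", 100)
        model = RandomForestClassifier(criterion="entropy", random_state=seed, **params)
    elif name == "adaboost":
        # depth-2 base trees: a single-split stump is not better than random
        # across 4 classes, which the staged additive (SAMME) scheme requires
        params.setdefault("n_estimators", 50)
        params.setdefault("estimator", DecisionTreeClassifier(max_depth=2))
        model = AdaBoostClassifier(random_state=seed, **params)
    elif name == "knn":
        params.setdefault("n_neighbors", 5)
        if params["n_neighbors"] > table.labels.size:
            raise PodfusionError("KNN needs k <= number of training samples")
        model = KNeighborsClassifier(metric="euclidean", **params)
    else:
        raise PodfusionError(f"unsupported baseline {name!r}; choose from {BASELINE_NAMES}")
    return model.fit(table.matrix, table.labels)
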