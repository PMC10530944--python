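"""Classifier adapters for benchmarking against the hybrid pipeline.

Each adapter wraps an established implementation behind the minimal
``fit(X, y)`` / ``predict(X)`` contract that :func:`eigenstep.evaluate.run_baseline`
expects; all receive the same eigenspace scores the hybrid pipeline sees,
so comparisons isolate the value of the stepwise selection + dense network
stage.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier


class MajorityClassAdapter:
    """Predicts the most frequent training class; the chance-level floor."""

    def fit(self, X, y):
        values, counts = np.unique(np.asarray(y), return_counts=True)
        self.majority_ = values[np.argmax(counts)]
        return self

    def predict(self, X):
        return np.full(len(X), self.majority_, dtype=np.int64)


class KNNAdapter:
    def __init__(self, n_neighbors: int = 1):
        self._model = KNeighborsClassifier(n_neighbors=n_neighbors)

    def fit(self, X, y):
        self._model.fit(X, y)
        return self

    def predict(self, X):
        return self._model.predict(X)


class DecisionTreeAdapter:
    def __init__(self, seed: int = 0):
        self._model = DecisionTreeClassifier(random_state=seed)

    def fit(self, X, y):
        self._model.fit(X, y)
        return self

    def predict(self, X):
        return self._model.predict(X)


class RandomForestAdapter:
    def __init__(self, n_estimators: int = 100, seed: int = 0):
        self._model = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed
        )

    def fit(self, X, y):
        self._model.fit(X, y)
        return self

    def predict(self, X):
        return self._model.predict(X)


class SVMAdapter:
    def __init__(self, seed: int = 0):
        self._model = SVC(kernel="rbf", random_state=seed)

    def fit(self, X, y):
        self._model.fit(X, y)
        return self

    def predict(self, X):
        return self._model.predict(X)


BASELINES = {
    "majority": MajorityClassAdapter,
    "knn": KNNAdapter,
    "decision_tree": DecisionTreeAdapter,
    "random_forest": RandomForestAdapter,
    "svm": SVMAdapter,
}
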