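"""Boosting with random undersampling for imbalanced binary tasks.

SAMME-style AdaBoost over shallow decision trees where, at every boosting
iteration, the majority class is randomly undersampled to the minority
class size before the tree is fitted.  The per-iteration undersampling is
the defining trait of the RUSBoost family; weight updates follow discrete
AdaBoost.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    def __init__(self, n_estimators: int = 50, max_depth: int = 2,
                 learning_rate: float = 1.0, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, yi = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("RUSBoostClassifier is binary")
        n = len(y)
        rng = np.random.default_rng(self.random_state)
        w = np.full(n, 1.0 / n)
        self.estimators_, self.estimator_weights_ = [], []
        counts = np.bincount(yi, minlength=2)
        minority = int(np.argmin(counts))
        for m in range(self.n_estimators):
            # random undersampling of the majority class, weight-proportional
            keep = np.flatnonzero(yi == minority).tolist()
            maj = np.flatnonzero(yi != minority)
            p = w[maj] / w[maj].sum()
            take = min(len(maj), max(counts[minority], 2))
            keep += rng.choice(maj, size=take, replace=False, p=p).tolist()
            keep = np.asarray(keep)

            tree = DecisionTreeClassifier(
                max_depth=self.max_depth, random_state=int(rng.integers(2**31))
            )
            tree.fit(X[keep], yi[keep], sample_weight=w[keep] * n)
            pred = tree.predict(X)
            err = float(np.sum(w[pred != yi]))
            if err >= 0.5:
                continue
            err = max(err, 1e-10)
            alpha = self.learning_rate * 0.5 * np.log((1 - err) / err)
            w *= np.exp(alpha * (2.0 * (pred != yi) - 1.0))
            w /= w.sum()
            self.estimators_.append(tree)
            self.estimator_weights_.append(alpha)
        if not self.estimators_:  # all weak learners failed: fit one plain tree
            tree = DecisionTreeClassifier(max_depth=self.max_depth,
                                          random_state=self.random_state)
            tree.fit(X, yi)
            self.estimators_ = [tree]
            self.estimator_weights_ = [1.0]
        self.estimator_weights_ = np.asarray(self.estimator_weights_)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        score = np.zeros(len(X))
        for tree, a in zip(self.estimators_, self.estimator_weights_):
            score += a * (2.0 * tree.predict(X) - 1.0)
        return score / self.estimator_weights_.sum()

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def predict_proba(self, X):
        s = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-4.0 * s))  # squashed margin in [0, 1]
        return np.column_stack([1 - p1, p1])

    @property
    def feature_importances_(self):
        check_is_fitted(self, "estimators_")
        imp = np.zeros(self.estimators_[0].n_features_in_)
        for tree, a in zip(self.estimators_, self.estimator_weights_):
            imp += a * tree.feature_importances_
        total = imp.sum()
        return imp / total if total > 0 else imp
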