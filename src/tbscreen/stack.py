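"""Stacked meta-model over the twelve one-vs-one base scores.

The six pairwise models emit two complementary probabilities each; the
twelve scores form the meta-model's input for both class schemes (the
three-class scheme merges moderate and severe into one target label but
reuses the same base scores).  Training rows feed the meta-learner their
out-of-bag base scores so the stack never sees in-bag leakage; unseen rows
use full-bag scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.ensemble import RandomForestClassifier

from tbscreen.ovo import OvoBundle


@dataclass
class ClassScheme:
    name: str  # 'three' or 'four'
    classes: tuple
    merge_map: dict

    @staticmethod
    def four() -> "ClassScheme":
        classes = ("non", "mild", "moderate", "severe")
        return ClassScheme("four", classes, {c: c for c in classes})

    @staticmethod
    def three() -> "ClassScheme":
        return ClassScheme(
            "three",
            ("non", "mild", "moderate_severe"),
            {"non": "non", "mild": "mild",
             "moderate": "moderate_severe", "severe": "moderate_severe"},
        )

    @staticmethod
    def by_name(name: str) -> "ClassScheme":
        if name == "three":
            return ClassScheme.three()
        if name == "four":
            return ClassScheme.four()
        raise ValueError(f"unknown scheme {name!r}")

    def map_labels(self, labels: pd.Series) -> pd.Series:
        return labels.map(self.merge_map)


def default_meta_candidates(scheme: ClassScheme, seed: int = 0) -> dict:
    """Candidate meta-learners; MLP depths/learning rates are scheme-specific.

    Three-class default: two hidden layers, learning rate 7.06e-2.
    Four-class default: three hidden layers, learning rate 5.14e-3.
    Hidden widths (16, 16[, 8]) are a configuration choice.
    """
    if scheme.name == "three":
        mlp = MLPClassifier(hidden_layer_sizes=(16, 16), learning_rate_init=7.06e-2,
                            max_iter=600, early_stopping=True,
                            validation_fraction=0.15, random_state=seed)
    else:
        mlp = MLPClassifier(hidden_layer_sizes=(16, 16, 8), learning_rate_init=5.14e-3,
                            max_iter=600, early_stopping=True,
                            validation_fraction=0.15, random_state=seed)
    return {
        "mlp": mlp,
        "logreg": LogisticRegression(max_iter=2000),
        "rbfsvm": SVC(kernel="rbf", probability=True, random_state=seed),
        "polysvm": SVC(kernel="poly", degree=3, probability=True, random_state=seed),
        "rf": RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1),
    }


def build_meta_features(bundle: OvoBundle, values: pd.DataFrame,
                        labels: pd.Series | None = None) -> np.ndarray:
    """The 12-column meta design matrix.

    Pass ``labels`` for training rows to obtain leakage-controlled OOB
    scores; omit it for unseen rows (full-bag scores).
    """
    if labels is not None:
        scores, _ = bundle.oob_pair_scores(values, labels)
        return scores
    return bundle.predict_pair_scores(values)


@dataclass
class MetaModel:
    scheme: ClassScheme
    learner: object
    candidate_log: dict = field(default_factory=dict)
    training_meta: dict = field(default_factory=dict)

    def predict_proba(self, bundle: OvoBundle, values: pd.DataFrame) -> pd.DataFrame:
        """Class probabilities for unseen rows (full-bag meta features)."""
        meta_X = build_meta_features(bundle, values)
        return self.predict_proba_from_scores(meta_X, index=values.index)

    def predict_proba_from_scores(self, meta_X: np.ndarray,
                                  index=None) -> pd.DataFrame:
        probs = self.learner.predict_proba(np.asarray(meta_X, dtype=float))
        cols = list(self.learner.classes_)
        out = pd.DataFrame(probs, columns=cols, index=index)
        # fixed scheme column order, absent classes as zero columns
        for c in self.scheme.classes:
            if c not in out.columns:
                out[c] = 0.0
        return out[list(self.scheme.classes)]

    def predict(self, bundle: OvoBundle, values: pd.DataFrame) -> pd.Series:
        probs = self.predict_proba(bundle, values)
        return probs.idxmax(axis=1)


def train_meta(
    meta_X: np.ndarray,
    labels: pd.Series,
    scheme: ClassScheme,
    candidates: dict | None = None,
    seed: int = 0,
    cv_folds: int = 3,
) -> MetaModel:
    """Fit candidate meta-learners and keep the best by CV balanced accuracy.

    ``labels`` must already be mapped through the scheme's merge map (raw
    severities are mapped automatically).  With a single candidate the CV
    selection step is skipped.
    """
    y = scheme.map_labels(labels) if set(labels) - set(scheme.classes) else labels
    y = y.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("meta training needs at least two classes present")
    X = np.asarray(meta_X, dtype=float)
    if X.shape[1] % 2:
        raise ValueError("meta design width must be even (paired task scores)")
    cands = candidates if candidates is not None else default_meta_candidates(scheme, seed)

    log = {}
    if len(cands) == 1:
        name, est = next(iter(cands.items()))
        best = (0.0, name, est)
    else:
        best = None
        min_class = np.bincount(pd.factorize(y)[0]).min()
        folds = max(2, min(cv_folds, min_class))
        for name, est in cands.items():
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            scores = []
            try:
                for tr, te in skf.split(X, y):
                    from sklearn.base import clone

                    m = clone(est)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        m.fit(X[tr], y[tr])
                    scores.append(balanced_accuracy_score(y[te], m.predict(X[te])))
                score = float(np.mean(scores))
            except Exception as exc:  # noqa: BLE001
                warnings.warn(f"meta candidate {name} failed: {exc}")
                score = 0.0
            log[name] = score
            if best is None or score > best[0]:
                best = (score, name, est)
    score, name, est = best
    from sklearn.base import clone

    learner = clone(est)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        learner.fit(X, y)
    return MetaModel(
        scheme=scheme,
        learner=learner,
        candidate_log=log,
        training_meta={"winner": name, "cv_balanced_accuracy": score, "seed": seed},
    )
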