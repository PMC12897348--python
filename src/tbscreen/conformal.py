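"""Split conformal prediction over a probabilistic multi-class model.

A calibration set held out from training provides nonconformity scores
s(x, y) = 1 - p(y | x); the threshold is the ceil((1 - alpha)(n + 1))-th
smallest score of the calibration multiset augmented with +infinity.  Under
exchangeability of calibration and test rows, the resulting prediction
sets contain the true label with probability at least 1 - alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def calibration_split(labels: pd.Series, holdout: float = 0.2, seed: int = 0):
    """Class-stratified disjoint (fit_ids, calib_ids) split of training rows.

    Per-class calibration counts are nearest-integer, half up, of
    ``holdout`` times the class size (capped to leave at least one fit row).
    """
    if not (0 < holdout < 1):
        raise ValueError("holdout must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    calib: list = []
    for cls in labels.unique():
        ids = labels.index[labels == cls].to_numpy()
        n_cal = min(int(np.floor(holdout * len(ids) + 0.5)), len(ids) - 1)
        if n_cal < 1:
            warnings.warn(f"class {cls!r} too small for calibration; none held out")
            continue
        calib += rng.choice(ids, size=n_cal, replace=False).tolist()
    calib_set = set(calib)
    fit_ids = [i for i in labels.index if i not in calib_set]
    calib_ids = [i for i in labels.index if i in calib_set]
    return fit_ids, calib_ids


def nonconformity(prob: float) -> float:
    """Nonconformity of a label with predicted probability ``prob``: 1 - prob."""
    return 1.0 - prob


def fit_threshold(calib_scores, alpha: float) -> float:
    """Finite-sample quantile threshold q_hat.

    The ceil((1 - alpha)(n + 1))-th smallest element of the calibration
    scores augmented with +infinity; +infinity when the rank exceeds n.
    """
    scores = np.sort(np.asarray(calib_scores, dtype=float))
    n = len(scores)
    if n < 1:
        raise ValueError("need at least one calibration score")
    rank = int(np.ceil((1.0 - alpha) * (n + 1)))
    if rank > n:
        return np.inf
    if rank < 1:
        rank = 1
    return float(scores[rank - 1])


@dataclass
class ConformalCalibration:
    alpha: float
    calib_scores: np.ndarray
    q_hat: float
    n_calib: int

    @staticmethod
    def fit(probs: pd.DataFrame, truths: pd.Series, alpha: float) -> "ConformalCalibration":
        """Calibrate from per-row class probabilities and true labels."""
        scores = np.array(
            [nonconformity(probs.loc[i, truths.loc[i]]) for i in probs.index]
        )
        return ConformalCalibration(
            alpha=alpha, calib_scores=scores,
            q_hat=fit_threshold(scores, alpha), n_calib=len(scores),
        )


@dataclass
class PredictionSet:
    subject_id: object
    labels: list
    scores: dict
    q_used: float

    def __contains__(self, label) -> bool:
        return label in self.labels

    def __len__(self) -> int:
        return len(self.labels)


def predict_set(probs_row: pd.Series, q_hat: float,
                subject_id=None) -> PredictionSet:
    """All labels whose nonconformity 1 - p(y|x) is at most q_hat.

    The set may be empty when every score exceeds q_hat; no forced top-1
    fallback is applied, preserving the coverage guarantee.
    """
    scores = {y: nonconformity(p) for y, p in probs_row.items()}
    labels = [y for y, s in scores.items() if s <= q_hat]
    return PredictionSet(subject_id=subject_id, labels=labels, scores=scores,
                         q_used=q_hat)


def predict_sets(probs: pd.DataFrame, q_hat: float) -> list[PredictionSet]:
    return [predict_set(probs.loc[i], q_hat, subject_id=i) for i in probs.index]


def coverage(sets: list, truths) -> float:
    """Fraction of rows whose true label lies in the prediction set."""
    truths = list(truths)
    if len(sets) != len(truths):
        raise ValueError("sets and truths must align")
    return float(np.mean([t in s.labels for s, t in zip(sets, truths)]))


def avg_set_size(sets: list) -> float:
    if not sets:
        raise ValueError("need at least one prediction set")
    return float(np.mean([len(s) for s in sets]))


def sets_to_frame(sets: list, classes) -> pd.DataFrame:
    """0/1 set-membership matrix (rows = subjects, columns = classes)."""
    return pd.DataFrame(
        [[int(c in s.labels) for c in classes] for s in sets],
        index=[s.subject_id for s in sets], columns=list(classes),
    )


def sets_to_long(sets: list) -> pd.DataFrame:
    rows = []
    for s in sets:
        for label, score in s.scores.items():
            rows.append(dict(subject_id=s.subject_id, label=label,
                             included=int(label in s.labels), score=score))
    return pd.DataFrame(rows)
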