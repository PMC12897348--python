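"""One-vs-one bagged base models with out-of-bag validation.

Four severity classes yield six pairwise binary tasks.  Each task's model
is a bagged ensemble of the winning candidate family from a seeded
Bayesian (Gaussian-process expected-improvement) hyperparameter search
scored by out-of-bag balanced accuracy.  Every bag member records its
bootstrap row set, so OOB predictions for a training row only ever use
members that excluded it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from tbscreen.cohort import SEVERITY_RANK
from tbscreen.rusboost import RUSBoostClassifier

#: reduced candidate zoo: the families named for the framework, searchable
CANDIDATE_SPACES = {
    "logreg": {"C": (1e-3, 1e3, "log")},
    "linsvm": {"C": (1e-3, 1e3, "log")},
    "rbfsvm": {"C": (1e-2, 1e3, "log"), "gamma": (1e-4, 1e1, "log")},
    "rf": {"n_estimators": (20, 200, "int"), "max_depth": (2, 10, "int")},
    "mlp": {"alpha": (1e-5, 1e-1, "log"), "learning_rate_init": (1e-4, 1e-1, "log")},
    "rusboost": {"n_estimators": (10, 80, "int"), "max_depth": (1, 4, "int")},
}

DEFAULT_CANDIDATES = tuple(CANDIDATE_SPACES)


def build_estimator(family: str, params: dict, seed: int):
    if family == "logreg":
        return LogisticRegression(C=params.get("C", 1.0), max_iter=2000)
    if family == "linsvm":
        return SVC(kernel="linear", C=params.get("C", 1.0), probability=True,
                   random_state=seed)
    if family == "rbfsvm":
        return SVC(kernel="rbf", C=params.get("C", 1.0),
                   gamma=params.get("gamma", "scale"), probability=True,
                   random_state=seed)
    if family == "rf":
        return RandomForestClassifier(
            n_estimators=int(params.get("n_estimators", 100)),
            max_depth=int(params.get("max_depth", 5)),
            random_state=seed, n_jobs=1)
    if family == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(16,), alpha=params.get("alpha", 1e-4),
            learning_rate_init=params.get("learning_rate_init", 1e-3),
            max_iter=400, random_state=seed)
    if family == "rusboost":
        return RUSBoostClassifier(
            n_estimators=int(params.get("n_estimators", 40)),
            max_depth=int(params.get("max_depth", 2)), random_state=seed)
    raise ValueError(f"unknown candidate family {family!r}")


@dataclass
class BinaryTask:
    pair: tuple  # (lower-severity class, higher-severity class)
    ids: list = field(default_factory=list)
    features: list = field(default_factory=list)


def enumerate_tasks(classes) -> list[BinaryTask]:
    """All unordered class pairs, ordered canonically by severity rank."""
    cls = sorted(set(classes), key=lambda c: SEVERITY_RANK.get(c, 99))
    if len(cls) < 2:
        raise ValueError("need at least two classes")
    return [BinaryTask(pair=p) for p in combinations(cls, 2)]


class BaggedEnsemble:
    """B bootstrap-trained clones of one estimator with stored bag indices."""

    def __init__(self, base_estimator, B: int = 50, seed: int = 0):
        self.base_estimator = base_estimator
        self.B = B
        self.seed = seed
        self.members_: list = []
        self.bootstrap_indices_: list = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedEnsemble":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n = len(y)
        rng = np.random.default_rng(self.seed)
        self.members_, self.bootstrap_indices_ = [], []
        self.n_rows_ = n
        classes = np.unique(y)
        for b in range(self.B):
            for _ in range(50):  # redraw until both classes present
                idx = rng.integers(n, size=n)
                if len(np.unique(y[idx])) == len(classes):
                    break
            est = clone(self.base_estimator)
            if hasattr(est, "random_state"):
                est.random_state = int(rng.integers(2**31))
            est.fit(X[idx], y[idx])
            self.members_.append(est)
            self.bootstrap_indices_.append(np.unique(idx))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs = np.mean([m.predict_proba(np.asarray(X, dtype=float))
                         for m in self.members_], axis=0)
        return probs

    def oob_proba(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-training-row probability using only members that excluded it.

        Returns (probs, covered): rows never excluded by any member get the
        full-bag probability and ``covered=False``.
        """
        X = np.asarray(X, dtype=float)
        n = len(X)
        member_probs = np.stack([m.predict_proba(X) for m in self.members_])
        in_bag = np.zeros((self.B, n), dtype=bool)
        for b, idx in enumerate(self.bootstrap_indices_):
            in_bag[b, idx] = True
        out = np.empty((n, member_probs.shape[2]))
        covered = np.zeros(n, dtype=bool)
        for i in range(n):
            oob = ~in_bag[:, i]
            if oob.any():
                out[i] = member_probs[oob, i].mean(axis=0)
                covered[i] = True
            else:
                out[i] = member_probs[:, i].mean(axis=0)
        if (~covered).mean() > 0.01:
            warnings.warn(
                f"{(~covered).sum()} of {n} rows lack OOB members; increase B"
            )
        return out, covered


# ---------------------------------------------------------------------------
# seeded Bayesian hyperparameter search
# ---------------------------------------------------------------------------

def _sample_params(space: dict, rng) -> dict:
    out = {}
    for name, (lo, hi, kind) in space.items():
        if kind == "int":
            out[name] = int(rng.integers(lo, hi + 1))
        elif kind == "log":
            out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            out[name] = float(rng.uniform(lo, hi))
    return out


def _encode(params: dict, space: dict) -> np.ndarray:
    v = []
    for name, (lo, hi, kind) in space.items():
        x = params[name]
        if kind == "log":
            v.append((np.log(x) - np.log(lo)) / (np.log(hi) - np.log(lo)))
        else:
            v.append((x - lo) / (hi - lo))
    return np.asarray(v)


def gp_search(score_fn, space: dict, budget: int, seed: int):
    """Maximize ``score_fn(params)`` with GP expected improvement."""
    rng = np.random.default_rng(seed)
    history = []
    n_init = max(min(budget // 2, 5), 1)
    for _ in range(min(n_init, budget)):
        p = _sample_params(space, rng)
        history.append((p, score_fn(p)))
    while len(history) < budget:
        Xh = np.stack([_encode(p, space) for p, _ in history])
        yh = np.array([s for _, s in history])
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5), alpha=1e-4, normalize_y=True,
            random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(Xh, yh)
        cands = [_sample_params(space, rng) for _ in range(64)]
        Xc = np.stack([_encode(p, space) for p in cands])
        mu, sd = gp.predict(Xc, return_std=True)
        best = yh.max()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - best) / np.maximum(sd, 1e-9)
        from scipy.stats import norm
        ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
        p = cands[int(np.argmax(ei))]
        history.append((p, score_fn(p)))
    best_p, best_s = max(history, key=lambda h: h[1])
    return best_p, best_s, history


def train_base(
    X: np.ndarray,
    y: np.ndarray,
    candidates=DEFAULT_CANDIDATES,
    B: int = 50,
    budget: int = 25,
    seed: int = 0,
):
    """Search candidate families and return the best bagged ensemble.

    For each family a seeded GP search over its space is scored by OOB
    balanced accuracy of a bagged version; the best family's ensemble is
    refitted and returned together with the search log.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("train_base expects a binary task")
    if len(candidates) == 1 and budget <= 1:
        # degenerate search: fit the single family at its default parameters
        family = candidates[0]
        ensemble = BaggedEnsemble(build_estimator(family, {}, seed), B=B,
                                  seed=seed).fit(X, y)
        return ensemble, {"winner": family, "winner_params": {},
                          "winner_oob_balanced_accuracy": None, "search": []}

    log = []
    best = None
    for fi, family in enumerate(candidates):
        space = CANDIDATE_SPACES[family]

        def score_fn(params, family=family):
            try:
                est = build_estimator(family, params, seed)
                bag = BaggedEnsemble(est, B=B, seed=seed).fit(X, y)
                probs, _ = bag.oob_proba(X)
                pred = bag.members_[0].classes_[np.argmax(probs, axis=1)]
                return balanced_accuracy_score(y, pred)
            except Exception as exc:  # noqa: BLE001 - candidate may fail to converge
                warnings.warn(f"candidate {family} failed: {exc}")
                return 0.0

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params, score, hist = gp_search(score_fn, space, budget, seed + fi)
        log.append({"family": family, "best_params": params, "oob_balanced_accuracy": score})
        if best is None or score > best[0]:
            best = (score, family, params)
    score, family, params = best
    ensemble = BaggedEnsemble(build_estimator(family, params, seed), B=B,
                              seed=seed).fit(X, y)
    return ensemble, {"winner": family, "winner_params": params,
                      "winner_oob_balanced_accuracy": score, "search": log}


# ---------------------------------------------------------------------------
# the six-model bundle
# ---------------------------------------------------------------------------

class OvoBundle:
    """Six pairwise bagged models sharing a training table."""

    def __init__(self, candidates=DEFAULT_CANDIDATES, B: int = 50,
                 budget: int = 25, seed: int = 0):
        self.candidates = candidates
        self.B = B
        self.budget = budget
        self.seed = seed
        self.tasks_: list[BinaryTask] = []
        self.models_: dict = {}
        self.search_log_: dict = {}
        self.oob_metrics_: dict = {}

    def fit(self, values: pd.DataFrame, labels: pd.Series,
            feature_sets: dict | None = None) -> "OvoBundle":
        """Train all pairwise models.

        ``feature_sets`` maps a class pair to its selected feature list;
        when omitted every task uses all columns.
        """
        self.tasks_ = enumerate_tasks(labels.unique())
        for t_i, task in enumerate(self.tasks_):
            a, b = task.pair
            ids = labels.index[labels.isin(task.pair)]
            feats = (feature_sets or {}).get(task.pair, list(values.columns))
            task.ids = list(ids)
            task.features = list(feats)
            X = values.loc[ids, feats].to_numpy(dtype=float)
            y = (labels.loc[ids] == b).to_numpy().astype(int)
            ensemble, log = train_base(
                X, y, candidates=self.candidates, B=self.B,
                budget=self.budget, seed=self.seed + 1000 * t_i)
            self.models_[task.pair] = ensemble
            self.search_log_[task.pair] = log
            probs, covered = ensemble.oob_proba(X)
            pred = (probs[:, 1] > 0.5).astype(int)
            self.oob_metrics_[task.pair] = {
                "oob_accuracy": float(np.mean(pred == y)),
                "oob_balanced_accuracy": float(balanced_accuracy_score(y, pred)),
                "oob_coverage": float(covered.mean()),
            }
        return self

    @property
    def pairs(self) -> list[tuple]:
        return [t.pair for t in self.tasks_]

    def predict_pair_scores(self, values: pd.DataFrame) -> np.ndarray:
        """Full-bag scores: (n, 2*tasks) with per-task [P(lower), P(higher)]."""
        cols = []
        for task in self.tasks_:
            missing = [f for f in task.features if f not in values.columns]
            if missing:
                raise ValueError(f"rows lack features {missing[:3]}...")
            X = values.loc[:, task.features].to_numpy(dtype=float)
            p = self.models_[task.pair].predict_proba(X)
            cols.append(p[:, [0, 1]])
        return np.hstack(cols)

    def oob_pair_scores(self, values: pd.DataFrame,
                        labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
        """OOB scores for training rows (leakage control for stacking).

        Rows outside a task's class pair get the full-bag score for that
        task (their label never entered its training).  Returns
        ``(scores, covered)`` with ``covered`` the per-row all-task OOB flag.
        """
        n = len(values)
        out = np.empty((n, 2 * len(self.tasks_)))
        covered = np.ones(n, dtype=bool)
        pos = {sid: i for i, sid in enumerate(values.index)}
        for t_i, task in enumerate(self.tasks_):
            X_all = values.loc[:, task.features].to_numpy(dtype=float)
            full = self.models_[task.pair].predict_proba(X_all)
            out[:, 2 * t_i: 2 * t_i + 2] = full
            in_task = [sid for sid in values.index if sid in set(task.ids)]
            if in_task:
                rows = [pos[sid] for sid in in_task]
                # align with the ensemble's training order
                order = [task.ids.index(sid) for sid in in_task]
                X_task = values.loc[task.ids, task.features].to_numpy(dtype=float)
                probs, cov = self.models_[task.pair].oob_proba(X_task)
                out[rows, 2 * t_i: 2 * t_i + 2] = probs[order]
                covered[rows] &= cov[order]
        return out, covered
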