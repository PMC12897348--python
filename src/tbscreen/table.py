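"""Tabular feature container and preparation steps.

Holds the subjects-by-features table with an explicit missingness mask,
and implements severity-stratified k-NN imputation, adaptive (mutual-
information-guided) normalization, and the three-stage feature-selection
pipeline (univariate t-test filter -> Shapley-value ranking -> recursive
feature elimination with a boosted, undersampled ensemble).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import balanced_accuracy_score

from tbscreen.shapley import sampling_shapley
from tbscreen.rusboost import RUSBoostClassifier

ANTHROPOMETRIC_COLUMNS = ("age", "sex", "bmi", "nc", "mps")

#: preference order used to break mutual-information ties between scalers
NORM_SCHEME_ORDER = ("zscore", "robust", "meanrange", "minmax")


@dataclass
class FeatureTable:
    """Subjects x named features with missingness mask and provenance.

    ``values`` holds NaN exactly where ``mask`` is True; after
    :func:`stratified_knn_impute` the mask is all-False.  ``family`` maps
    each column to its provenance (``anthropometric`` or an acoustic
    feature family); ``norm_meta`` is populated by
    :func:`adaptive_normalize` and re-usable on held-out rows.
    """

    values: pd.DataFrame
    labels: pd.Series
    family: dict[str, str]
    mask: pd.DataFrame | None = None
    norm_meta: dict[str, dict] | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = self.values.isna()
        if not self.values.index.equals(self.labels.index):
            raise ValueError("values and labels must share an index")
        if not self.values.columns.is_unique:
            raise ValueError("feature names must be unique")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def anthropometric_names(self) -> list[str]:
        return [c for c in self.values.columns if self.family.get(c) == "anthropometric"]

    @property
    def acoustic_names(self) -> list[str]:
        return [c for c in self.values.columns if self.family.get(c) != "anthropometric"]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            values=self.values.copy(),
            labels=self.labels.copy(),
            family=dict(self.family),
            mask=self.mask.copy(),
            norm_meta=None if self.norm_meta is None else json.loads(json.dumps(self.norm_meta)),
        )

    def subset_rows(self, ids) -> "FeatureTable":
        ids = list(ids)
        return FeatureTable(
            values=self.values.loc[ids].copy(),
            labels=self.labels.loc[ids].copy(),
            family=dict(self.family),
            mask=self.mask.loc[ids].copy(),
            norm_meta=None if self.norm_meta is None else json.loads(json.dumps(self.norm_meta)),
        )

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out["severity"] = self.labels
        out.to_csv(path, index_label="subject_id")


@dataclass
class SelectionReport:
    """Audit trail of the three-stage selection for one binary task."""

    stage1_kept: list[str]
    stage2_ranking: list[str]
    stage2_scores: dict[str, float]
    final_selected: list[str]
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.final_selected) <= set(self.stage2_ranking) <= set(self.stage1_kept):
            raise ValueError("selection stages must be nested")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "stage1_kept": self.stage1_kept,
                    "stage2_ranking": self.stage2_ranking,
                    "stage2_scores": self.stage2_scores,
                    "final_selected": self.final_selected,
                    "thresholds": self.thresholds,
                },
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def stratified_knn_impute(table: FeatureTable, k: int = 3) -> FeatureTable:
    """Impute missing cells with severity-stratified k-NN (default k=3).

    Each missing cell is replaced by the mean of that column over the k
    nearest complete donors *within the same severity stratum*; distance is
    Euclidean over the stratum's complete, standardized columns.  Strata
    with at most ``k`` usable donors fall back to the stratum column mean
    (with a warning), and to the global column mean as a last resort.
    """
    out = table.copy()
    vals = out.values
    for sev in out.labels.unique():
        idx = out.labels.index[out.labels == sev]
        block = vals.loc[idx]
        miss = block.isna()
        if not miss.to_numpy().any():
            continue
        # standardize on observed entries for the distance metric
        mu = block.mean()
        sd = block.std(ddof=0).replace(0.0, 1.0)
        z = (block - mu) / sd
        for col in block.columns[miss.any(axis=0)]:
            donors = idx[~miss[col]]
            recipients = idx[miss[col]]
            if len(donors) == 0:
                warnings.warn(f"no donors for {col!r} in stratum {sev!r}; using global mean")
                vals.loc[recipients, col] = vals[col].mean()
                continue
            if len(donors) <= k:
                warnings.warn(
                    f"stratum {sev!r} has only {len(donors)} donors for {col!r}; "
                    "falling back to stratum mean"
                )
                vals.loc[recipients, col] = block.loc[donors, col].mean()
                continue
            # distance on columns observed for the recipient, complete in donors
            for r in recipients:
                usable = [
                    c
                    for c in block.columns
                    if c != col and not miss.loc[r, c] and not miss.loc[donors, c].any()
                ]
                if not usable:
                    vals.loc[r, col] = block.loc[donors, col].mean()
                    continue
                d = np.sqrt(((z.loc[donors, usable] - z.loc[r, usable]) ** 2).sum(axis=1))
                nearest = d.nsmallest(k).index
                vals.loc[r, col] = block.loc[nearest, col].mean()
    out.mask = vals.isna()
    if out.mask.to_numpy().any():  # pragma: no cover - defensive
        raise RuntimeError("imputation left missing cells")
    return out


# ---------------------------------------------------------------------------
# adaptive normalization
# ---------------------------------------------------------------------------

def _scheme_params(x: np.ndarray, scheme: str) -> dict:
    if scheme == "zscore":
        return {"center": float(np.mean(x)), "scale": float(np.std(x, ddof=0))}
    if scheme == "minmax":
        return {"center": float(np.min(x)), "scale": float(np.max(x) - np.min(x))}
    if scheme == "meanrange":
        return {"center": float(np.mean(x)), "scale": float(np.max(x) - np.min(x))}
    if scheme == "robust":
        q1, q3 = np.percentile(x, [25, 75])
        return {"center": float(np.median(x)), "scale": float(q3 - q1)}
    raise ValueError(f"unknown scheme {scheme!r}")


def apply_scheme(x: np.ndarray, meta: dict) -> np.ndarray:
    scale = meta["scale"] if meta["scale"] != 0 else 1.0
    return (np.asarray(x, dtype=float) - meta["center"]) / scale


def mutual_information(x, y, bins: int = 10, binning: str = "quantile") -> float:
    """Plug-in mutual information (bits) between a scalar column and labels.

    ``x`` is discretized into ``bins`` equal-frequency bins by default
    (``binning='uniform'`` switches to equal width); MI is the plug-in
    estimate from the resulting joint counts.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    n = len(x)
    if n < 2:
        return 0.0
    if binning == "quantile":
        edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)))
    else:
        edges = np.linspace(np.min(x), np.max(x), bins + 1)
    if len(edges) < 2:
        return 0.0
    xb = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    _, yb = np.unique(y, return_inverse=True)
    joint = np.zeros((len(edges) - 1, yb.max() + 1))
    np.add.at(joint, (xb, yb), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(np.nansum(terms))


def adaptive_normalize(
    table: FeatureTable,
    bins: int = 10,
    binning: str = "quantile",
    fit_meta: dict | None = None,
) -> FeatureTable:
    """Per-column scaling chosen to maximize MI with the severity label.

    For each column, z-score, min-max, mean-range and robust (median/IQR)
    scalings are fitted; the scheme whose scaled column carries maximal
    mutual information with the class label is kept.  Ties are broken by a
    fixed preference order.  Pass ``fit_meta`` (a previous ``norm_meta``) to
    re-apply training-time transforms to held-out rows without refitting.
    """
    if table.mask.to_numpy().any():
        raise ValueError("normalize requires an imputed table")
    out = table.copy()
    if fit_meta is not None:
        meta = fit_meta
        for col in out.values.columns:
            m = meta.get(col)
            if m is None or m.get("scheme") == "constant":
                continue
            out.values[col] = apply_scheme(out.values[col].to_numpy(), m)
        out.norm_meta = json.loads(json.dumps(meta))
        return out

    meta: dict[str, dict] = {}
    y = out.labels.to_numpy()
    for col in out.values.columns:
        x = out.values[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            meta[col] = {"scheme": "constant"}
            continue
        best = None
        for scheme in NORM_SCHEME_ORDER:
            p = _scheme_params(x, scheme)
            if p["scale"] == 0:
                continue
            mi = mutual_information(apply_scheme(x, p), y, bins=bins, binning=binning)
            if best is None or mi > best[0] + 1e-12:
                best = (mi, scheme, p)
        mi, scheme, p = best
        meta[col] = {"scheme": scheme, "mi_bits": mi, **p}
        out.values[col] = apply_scheme(x, p)
    out.norm_meta = meta
    return out


# ---------------------------------------------------------------------------
# three-stage selection
# ---------------------------------------------------------------------------

def ttest_filter(table: FeatureTable, task_labels: pd.Series, alpha: float = 0.05,
                 columns: list[str] | None = None) -> list[str]:
    """Stage 1: keep acoustic features with Welch t-test p < alpha.

    ``task_labels`` is a binary series over the table's rows (one-vs-one
    task).  Zero-variance-in-both-groups features yield an undefined test
    and are treated as p = 1 (removed).
    """
    groups = task_labels.unique()
    if len(groups) != 2:
        raise ValueError("ttest_filter needs binary task labels")
    a_idx = task_labels.index[task_labels == groups[0]]
    b_idx = task_labels.index[task_labels == groups[1]]
    kept = []
    cols = columns if columns is not None else table.acoustic_names
    for col in cols:
        a = table.values.loc[a_idx, col].to_numpy(dtype=float)
        b = table.values.loc[b_idx, col].to_numpy(dtype=float)
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
        if np.isfinite(p) and p < alpha:
            kept.append(col)
    return kept


def shap_rank(
    table: FeatureTable,
    task_labels: pd.Series,
    kept: list[str],
    seed: int = 0,
    n_permutations: int = 16,
    n_estimators: int = 100,
) -> tuple[list[str], dict[str, float]]:
    """Stage 2: rank stage-1 features by mean |Shapley| attribution.

    A random-forest ensemble is fitted on the kept features and per-row
    Shapley values of its positive-class probability are estimated with a
    seeded sampling (permutation) estimator; features are ordered by the
    mean absolute attribution over training rows, descending.
    """
    if not kept:
        raise ValueError("stage-1 output is empty")
    X = table.values.loc[:, kept].to_numpy(dtype=float)
    y = (task_labels == sorted(task_labels.unique())[-1]).to_numpy().astype(int)
    model = RandomForestClassifier(
        n_estimators=n_estimators, max_depth=4, random_state=seed, n_jobs=1
    )
    model.fit(X, y)

    def f(data: np.ndarray) -> np.ndarray:
        return model.predict_proba(data)[:, 1]

    phi = sampling_shapley(f, X, n_permutations=n_permutations, seed=seed)
    score = np.abs(phi).mean(axis=0)
    order = np.argsort(-score, kind="stable")
    ranking = [kept[i] for i in order]
    return ranking, {kept[i]: float(score[i]) for i in order}


def rfe_select(
    table: FeatureTable,
    task_labels: pd.Series,
    ranking: list[str],
    target_k: int = 30,
    seed: int = 0,
    cv_folds: int = 3,
    stage1_kept: list[str] | None = None,
    stage2_scores: dict[str, float] | None = None,
) -> SelectionReport:
    """Stage 3: recursive elimination with an undersampled boosted ensemble.

    Starting from the ranked list, the weakest feature (lowest importance in
    a boosted shallow-tree ensemble trained with per-iteration random
    undersampling of the majority class) is dropped one at a time; each
    visited subset is scored by stratified ``cv_folds``-fold CV balanced
    accuracy for the audit trail.  The subset of size ``target_k`` is
    returned, with the five anthropometric features appended afterwards
    (they are exempt from elimination).
    """
    y = (task_labels == sorted(task_labels.unique())[-1]).to_numpy().astype(int)
    current = list(ranking)
    if len(current) < target_k:
        warnings.warn(
            f"only {len(current)} ranked features (< target {target_k}); keeping all"
        )
        selected = list(current)
        cv_log = {}
    else:
        rng = np.random.default_rng(seed)
        cv_log = {}
        while len(current) > target_k:
            X = table.values.loc[:, current].to_numpy(dtype=float)
            clf = RUSBoostClassifier(
                n_estimators=30, max_depth=2, random_state=int(rng.integers(2**31))
            )
            clf.fit(X, y)
            cv_log[len(current)] = _cv_balanced_accuracy(X, y, seed, cv_folds)
            weakest = int(np.argmin(clf.feature_importances_))
            current.pop(weakest)
        selected = list(current)

    anthro = table.anthropometric_names
    final = selected + [a for a in anthro if a not in selected]
    return SelectionReport(
        stage1_kept=list(stage1_kept) if stage1_kept is not None else list(ranking),
        stage2_ranking=list(ranking),
        stage2_scores=dict(stage2_scores or {}),
        final_selected=selected,
        thresholds={
            "target_k": target_k,
            "anthropometric_appended": final[len(selected):],
            "cv_balanced_accuracy": cv_log,
        },
    )


def _cv_balanced_accuracy(X: np.ndarray, y: np.ndarray, seed: int, folds: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        clf = RUSBoostClassifier(n_estimators=20, max_depth=2, random_state=seed)
        clf.fit(X[tr], y[tr])
        scores.append(balanced_accuracy_score(y[te], clf.predict(X[te])))
    return float(np.mean(scores))


def select_features(
    table: FeatureTable,
    task_labels: pd.Series,
    alpha: float = 0.05,
    target_k: int = 30,
    seed: int = 0,
    shap_permutations: int = 16,
) -> SelectionReport:
    """Run the full three-stage pipeline for one one-vs-one task."""
    kept = ttest_filter(table, task_labels, alpha=alpha)
    if not kept:
        warnings.warn("t-test filter removed everything; falling back to all acoustic features")
        kept = table.acoustic_names
    ranking, scores = shap_rank(table, task_labels, kept, seed=seed,
                                n_permutations=shap_permutations)
    report = rfe_select(
        table, task_labels, ranking, target_k=target_k, seed=seed,
        stage1_kept=kept, stage2_scores=scores,
    )
    report.thresholds["alpha"] = alpha
    return report
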