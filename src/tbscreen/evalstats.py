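"""Evaluation metrics, repeated-trial aggregation, and paired model comparison.

Accuracy, macro-averaged sensitivity/specificity and one-vs-rest AUC are
reported in percent; classifier pairs are compared on per-sample
correctness with a paired t-test, a Wilcoxon signed-rank test, an exact
McNemar test, Cohen's d (paired form), Cliff's delta, and a Bonferroni
correction over the comparison family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix, roc_auc_score


@dataclass
class EvaluationReport:
    confusion: pd.DataFrame
    accuracy: float  # percent
    macro_sensitivity: float
    macro_specificity: float
    per_class: pd.DataFrame
    auc_per_class: dict = field(default_factory=dict)
    n: int = 0
    ci95: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "n": self.n,
            "per_class": self.per_class.to_dict(orient="index"),
            "auc_per_class": self.auc_per_class,
            "confusion": self.confusion.to_dict(orient="index"),
            "ci95": self.ci95,
        }


def confusion_and_metrics(preds, truths, classes, scores: pd.DataFrame | None = None
                          ) -> EvaluationReport:
    """Confusion matrix plus accuracy and macro sensitivity/specificity (%).

    ``classes`` fixes row/column order.  Per-class sensitivity is
    TP/(TP+FN), specificity TN/(TN+FP); macro values are unweighted means
    over classes present in the truths (absent classes are excluded with a
    warning).  One-vs-rest AUC per class is added when a probability frame
    ``scores`` (columns = classes) is supplied.
    """
    preds = np.asarray(preds)
    truths = np.asarray(truths)
    if len(preds) != len(truths):
        raise ValueError("preds and truths must align")
    classes = list(classes)
    cm = confusion_matrix(truths, preds, labels=classes)
    cm_df = pd.DataFrame(cm, index=classes, columns=classes)
    n = cm.sum()
    acc = 100.0 * np.trace(cm) / n

    rows = {}
    sens_list, spec_list = [], []
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = n - tp - fn - fp
        if tp + fn == 0:
            warnings.warn(f"class {c!r} absent from truths; excluded from macro")
            rows[c] = {"sensitivity": np.nan, "specificity": 100.0 * tn / (tn + fp)
                       if tn + fp else np.nan}
            continue
        sens = 100.0 * tp / (tp + fn)
        spec = 100.0 * tn / (tn + fp) if tn + fp else np.nan
        rows[c] = {"sensitivity": sens, "specificity": spec}
        sens_list.append(sens)
        if np.isfinite(spec):
            spec_list.append(spec)

    auc = {}
    if scores is not None:
        for c in classes:
            y_bin = (truths == c).astype(int)
            if 0 < y_bin.sum() < len(y_bin):
                auc[c] = float(roc_auc_score(y_bin, scores[c].to_numpy()))
    return EvaluationReport(
        confusion=cm_df,
        accuracy=float(acc),
        macro_sensitivity=float(np.mean(sens_list)) if sens_list else np.nan,
        macro_specificity=float(np.mean(spec_list)) if spec_list else np.nan,
        per_class=pd.DataFrame(rows).T,
        auc_per_class=auc,
        n=int(n),
    )


def mean_sd_over_folds(values) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator) of fold metrics."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two fold values")
    return float(values.mean()), float(values.std(ddof=1))


def bootstrap_ci(samples, B: int = 1000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Non-parametric percentile bootstrap interval of the mean."""
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    rng = np.random.default_rng(seed)
    means = rng.choice(samples, size=(B, len(samples)), replace=True).mean(axis=1)
    lo = (1 - level) / 2
    return (float(np.quantile(means, lo)), float(np.quantile(means, 1 - lo)))


def repeated_trials(run_fn, seeds, ci_level: float = 0.95) -> pd.DataFrame:
    """Run ``run_fn(seed) -> dict`` per seed; aggregate mean and bootstrap CI.

    Returns the per-trial records; mean/CI per metric are attached in
    ``frame.attrs['aggregate']``.
    """
    records = [dict(seed=s, **run_fn(s)) for s in seeds]
    frame = pd.DataFrame(records)
    agg = {}
    for col in frame.columns:
        if col == "seed" or not np.issubdtype(frame[col].dtype, np.number):
            continue
        vals = frame[col].to_numpy(dtype=float)
        entry = {"mean": float(vals.mean())}
        if len(vals) >= 2:
            entry["sd"] = float(vals.std(ddof=1))
            entry["ci95"] = bootstrap_ci(vals, level=ci_level)
        agg[col] = entry
    frame.attrs["aggregate"] = agg
    return frame


def learning_curve(train_labels: pd.Series, fit_eval_fn,
                   fractions=(0.2, 0.4, 0.6, 0.8, 1.0),
                   seeds=(0,)) -> pd.DataFrame:
    """Metrics vs stratified training-set fraction on a fixed test set.

    ``fit_eval_fn(subset_ids, seed) -> dict`` trains on the subset and
    evaluates on the caller's fixed test set.  Fractions that would empty a
    class are skipped with a warning.
    """
    records = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        for frac in fractions:
            subset = []
            skip = False
            for cls in train_labels.unique():
                ids = train_labels.index[train_labels == cls].to_numpy()
                n_take = int(round(frac * len(ids)))
                if n_take < 1:
                    warnings.warn(f"fraction {frac} empties class {cls!r}; skipped")
                    skip = True
                    break
                subset += rng.choice(ids, size=n_take, replace=False).tolist()
            if skip:
                continue
            metrics = fit_eval_fn(subset, seed)
            records.append(dict(fraction=frac, seed=seed, n_train=len(subset),
                                **metrics))
    return pd.DataFrame(records)


@dataclass
class ComparisonRow:
    pair: str
    p_ttest: float
    p_wilcoxon: float
    p_mcnemar: float
    mean_delta_accuracy: float
    cohens_d: float
    cliffs_delta: float
    p_bonferroni: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "pair", "p_ttest", "p_wilcoxon", "p_mcnemar",
            "mean_delta_accuracy", "cohens_d", "cliffs_delta",
            "p_bonferroni", "degenerate")}


def cliffs_delta(a, b) -> float:
    """Dominance effect size: (#(a > b) - #(a < b)) / (n_a * n_b)."""
    a = np.asarray(a, dtype=float)[:, None]
    b = np.asarray(b, dtype=float)[None, :]
    return float(((a > b).sum() - (a < b).sum()) / (a.size * b.size))


def mcnemar_exact(correct_a, correct_b) -> float:
    """Exact (binomial) two-sided McNemar p-value on discordant pairs."""
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    n01 = int(np.sum(a & ~b))
    n10 = int(np.sum(~a & b))
    m = n01 + n10
    if m == 0:
        return 1.0
    p = 2.0 * stats.binom.cdf(min(n01, n10), m, 0.5)
    if n01 == n10:
        p -= stats.binom.pmf(n01, m, 0.5)  # central term counted twice
    return float(min(p, 1.0))


def compare_classifiers(correct_a, correct_b, pair: str = "A vs B",
                        m_comparisons: int = 1) -> ComparisonRow:
    """Paired significance tests and effect sizes on correctness vectors.

    ``correct_a``/``correct_b`` are aligned binary per-sample correctness
    indicators.  Degenerate all-zero differences yield p = 1 with a flag.
    Bonferroni multiplies the t-test p by ``m_comparisons`` (capped at 1).
    """
    a = np.asarray(correct_a, dtype=float)
    b = np.asarray(correct_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("correctness vectors must align")
    if len(a) < 5:
        raise ValueError("need at least 5 paired samples")
    diff = a - b
    degenerate = bool(np.all(diff == 0))
    if degenerate:
        p_t = p_w = 1.0
        d = 0.0
    else:
        p_t = float(stats.ttest_rel(a, b).pvalue)
        nz = diff[diff != 0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_w = float(stats.wilcoxon(nz).pvalue) if len(nz) else 1.0
        sd = diff.std(ddof=1)
        d = float(diff.mean() / sd) if sd > 0 else 0.0
    return ComparisonRow(
        pair=pair,
        p_ttest=p_t,
        p_wilcoxon=p_w,
        p_mcnemar=mcnemar_exact(a.astype(bool), b.astype(bool)),
        mean_delta_accuracy=float(diff.mean()),
        cohens_d=d,
        cliffs_delta=cliffs_delta(a, b),
        p_bonferroni=float(min(1.0, p_t * m_comparisons)),
        degenerate=degenerate,
    )


def bonferroni_threshold(family_alpha: float = 0.05, m: int = 6) -> float:
    """Per-comparison significance threshold alpha / m."""
    return family_alpha / m
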