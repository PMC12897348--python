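"""End-to-end orchestration: cohort -> features -> models -> conformal -> report.

`SeverityScreeningModel` wires the stages together with strict train/test
hygiene: imputation donors, normalization parameters, feature selection,
base-model training and conformal calibration all see training rows only;
held-out rows are transformed with the stored parameters and never consult
each other.
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from tbscreen import conformal as cp
from tbscreen.cohort import (
    CohortSpec,
    generate_cohort,
    generate_feature_cohort,
    write_cohort,
    inject_missingness,
)
from tbscreen.evalstats import (
    compare_classifiers,
    confusion_and_metrics,
    bonferroni_threshold,
)
from tbscreen.features import extract_features
from tbscreen.ovo import OvoBundle, DEFAULT_CANDIDATES
from tbscreen.stack import ClassScheme, build_meta_features, train_meta
from tbscreen.table import (
    FeatureTable,
    adaptive_normalize,
    select_features,
    stratified_knn_impute,
)
from tbscreen.partition import stratified_split


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    scheme: str = "four"
    seed: int = 0
    alpha: float = 0.05
    n_trials: int = 25
    test_fraction: float = 0.15
    calib_holdout: float = 0.2
    # cohort
    class_sizes: dict | None = None
    effect_size: float = 1.0
    missing_rate: float = 0.0
    cohort_mode: str = "audio"  # 'audio' | 'feature'
    # tabular prep
    knn_k: int = 3
    selection: str = "full"  # 'full' | 'none'
    target_k: int = 30
    shap_permutations: int = 16
    ttest_alpha: float = 0.05
    # models
    base_candidates: tuple = DEFAULT_CANDIDATES
    bag_members: int = 50
    search_budget: int = 25
    meta_candidates: str = "default"  # 'default' | 'logreg'
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("three", "four"):
            raise ValueError("scheme must be 'three' or 'four'")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.selection not in ("full", "none"):
            raise ValueError("selection must be 'full' or 'none'")
        if self.cohort_mode not in ("audio", "feature"):
            raise ValueError("cohort_mode must be 'audio' or 'feature'")

    @staticmethod
    def fast(**overrides) -> "RunConfig":
        """Desk-scale configuration: logistic base family, small bags."""
        base = dict(
            base_candidates=("logreg",), bag_members=10, search_budget=1,
            meta_candidates="logreg", selection="none", cohort_mode="feature",
        )
        base.update(overrides)
        return RunConfig(**base)

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "base_candidates" in raw:
            raw["base_candidates"] = tuple(raw["base_candidates"])
        return RunConfig(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["base_candidates"] = list(d["base_candidates"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    def cohort_spec(self) -> CohortSpec:
        kw = dict(acoustic_effect_size=self.effect_size,
                  missing_rate=self.missing_rate, seed=self.seed)
        if self.class_sizes is not None:
            kw["class_sizes"] = dict(self.class_sizes)
        return CohortSpec(**kw)


def make_table(config: RunConfig) -> FeatureTable:
    """Generate the configured cohort and return its raw feature table."""
    spec = config.cohort_spec()
    if config.cohort_mode == "feature":
        return generate_feature_cohort(spec)
    subjects = generate_cohort(spec)
    table = extract_features(subjects)
    if config.missing_rate > 0:
        table = inject_missingness(table, config.missing_rate, seed=config.seed)
    return table


def impute_holdout(test_table: FeatureTable, train_imputed: FeatureTable,
                   k: int = 3) -> FeatureTable:
    """k-NN impute held-out rows from training donors only.

    The held-out severity stratum is unknown at prediction time, so donors
    are all (complete) training rows; each held-out row is transformed
    independently of the other held-out rows.
    """
    out = test_table.copy()
    if not out.mask.to_numpy().any():
        return out
    donors = train_imputed.values
    mu = donors.mean()
    sd = donors.std(ddof=0).replace(0.0, 1.0)
    z_donors = (donors - mu) / sd
    for rid in out.values.index:
        row = out.values.loc[rid]
        missing_cols = row.index[row.isna()]
        if len(missing_cols) == 0:
            continue
        usable = [c for c in out.values.columns
                  if c not in missing_cols and np.isfinite(row[c])]
        z_row = (row[usable] - mu[usable]) / sd[usable]
        d = np.sqrt(((z_donors[usable] - z_row) ** 2).sum(axis=1))
        nearest = d.nsmallest(k).index
        for c in missing_cols:
            out.values.loc[rid, c] = donors.loc[nearest, c].mean()
    out.mask = out.values.isna()
    return out


class SeverityScreeningModel:
    """The full screener: imputation/normalization, selection, OvO bundle,
    stacked meta-model and split conformal calibration."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.scheme = ClassScheme.by_name(config.scheme)

    # -- training ----------------------------------------------------------
    def fit(self, table: FeatureTable, train_ids: list) -> "SeverityScreeningModel":
        cfg = self.config
        train = table.subset_rows(train_ids)
        train = stratified_knn_impute(train, k=cfg.knn_k)
        self.train_imputed_ = train
        train = adaptive_normalize(train)
        self.norm_meta_ = train.norm_meta

        # per-task feature selection
        self.selection_reports_ = {}
        feature_sets = None
        if cfg.selection == "full":
            feature_sets = {}
            from tbscreen.ovo import enumerate_tasks

            for t_i, task in enumerate(enumerate_tasks(train.labels.unique())):
                ids = train.labels.index[train.labels.isin(task.pair)]
                sub = train.subset_rows(ids)
                report = select_features(
                    sub, sub.labels, alpha=cfg.ttest_alpha,
                    target_k=cfg.target_k, seed=cfg.seed + 17 * t_i,
                    shap_permutations=cfg.shap_permutations)
                self.selection_reports_[task.pair] = report
                feature_sets[task.pair] = (
                    report.final_selected + report.thresholds["anthropometric_appended"])

        # conformal calibration split (calibration rows never touch fitting)
        fit_ids, calib_ids = cp.calibration_split(
            train.labels, holdout=cfg.calib_holdout, seed=cfg.seed)
        self.fit_ids_, self.calib_ids_ = fit_ids, calib_ids
        fit_tbl = train.subset_rows(fit_ids)

        self.bundle_ = OvoBundle(
            candidates=cfg.base_candidates, B=cfg.bag_members,
            budget=cfg.search_budget, seed=cfg.seed,
        ).fit(fit_tbl.values, fit_tbl.labels, feature_sets=feature_sets)

        meta_X = build_meta_features(self.bundle_, fit_tbl.values, fit_tbl.labels)
        scheme_labels = self.scheme.map_labels(fit_tbl.labels)
        cands = None
        if cfg.meta_candidates == "logreg":
            from sklearn.linear_model import LogisticRegression

            cands = {"logreg": LogisticRegression(max_iter=2000)}
        self.meta_ = train_meta(meta_X, scheme_labels, self.scheme,
                                candidates=cands, seed=cfg.seed)

        calib_tbl = train.subset_rows(calib_ids)
        calib_probs = self.meta_.predict_proba(self.bundle_, calib_tbl.values)
        self.calibration_ = cp.ConformalCalibration.fit(
            calib_probs, self.scheme.map_labels(calib_tbl.labels), cfg.alpha)
        self.train_table_ = train
        return self

    # -- inference ---------------------------------------------------------
    def transform(self, table: FeatureTable, ids: list) -> FeatureTable:
        """Impute + normalize held-out rows with stored training parameters."""
        sub = table.subset_rows(ids)
        sub = impute_holdout(sub, self.train_imputed_, k=self.config.knn_k)
        return adaptive_normalize(sub, fit_meta=self.norm_meta_)

    def predict_proba(self, table: FeatureTable, ids: list) -> pd.DataFrame:
        sub = self.transform(table, ids)
        return self.meta_.predict_proba(self.bundle_, sub.values)

    def predict_sets(self, table: FeatureTable, ids: list,
                     alpha: float | None = None) -> list:
        probs = self.predict_proba(table, ids)
        if alpha is None or alpha == self.calibration_.alpha:
            q = self.calibration_.q_hat
        else:
            q = cp.fit_threshold(self.calibration_.calib_scores, alpha)
        return cp.predict_sets(probs, q)

    def evaluate(self, table: FeatureTable, ids: list) -> dict:
        probs = self.predict_proba(table, ids)
        preds = probs.idxmax(axis=1)
        truths = self.scheme.map_labels(table.labels.loc[ids])
        report = confusion_and_metrics(preds, truths, self.scheme.classes,
                                       scores=probs)
        sets = cp.predict_sets(probs, self.calibration_.q_hat)
        return {
            "report": report,
            "coverage": cp.coverage(sets, truths),
            "avg_set_size": cp.avg_set_size(sets),
            "prediction_sets": sets,
            "per_sample_correct": (preds.to_numpy() == truths.to_numpy()).astype(int),
            "probs": probs,
        }


def run_trial(config: RunConfig, seed: int | None = None,
              table: FeatureTable | None = None) -> dict:
    """One full split/train/evaluate trial; returns scalar metrics + model."""
    cfg = dataclasses.replace(config, seed=config.seed if seed is None else seed)
    if table is None:
        table = make_table(cfg)
    manifest = _manifest_from_table(table)
    train_ids, test_ids = stratified_split(
        manifest, test_fraction=cfg.test_fraction, seed=cfg.seed)
    model = SeverityScreeningModel(cfg).fit(table, train_ids)
    ev = model.evaluate(table, test_ids)
    rep = ev["report"]
    return {
        "accuracy": rep.accuracy,
        "macro_sensitivity": rep.macro_sensitivity,
        "macro_specificity": rep.macro_specificity,
        "coverage": ev["coverage"],
        "avg_set_size": ev["avg_set_size"],
        "n_test": rep.n,
        "model": model,
        "evaluation": ev,
        "table": table,
        "train_ids": train_ids,
        "test_ids": test_ids,
    }


def _manifest_from_table(table: FeatureTable) -> pd.DataFrame:
    m = table.values[["age", "bmi", "nc", "mps"]].copy()
    # distance/balancing uses observed values; missing stays NaN
    m["sex"] = table.values["sex"].map(lambda v: "M" if v == 1.0 else
                                       ("F" if v == 0.0 else np.nan))
    m["severity"] = table.labels
    return m


# ---------------------------------------------------------------------------
# CLI-facing runners
# ---------------------------------------------------------------------------

def run_simulate(config: RunConfig, out_dir) -> str:
    """Write a synthetic cohort (WAVs + manifest + spec) to ``out_dir``."""
    spec = config.cohort_spec()
    subjects = generate_cohort(spec)
    return write_cohort(subjects, out_dir, spec=spec)


def run_full(config: RunConfig, out_dir) -> dict:
    """Execute the whole pipeline once and persist reports."""
    os.makedirs(out_dir, exist_ok=True)
    config.to_yaml(os.path.join(out_dir, "config.yaml"))
    res = run_trial(config)
    rep = res["evaluation"]["report"]
    summary = {
        "scheme": config.scheme,
        "seed": config.seed,
        "accuracy": rep.accuracy,
        "macro_sensitivity": rep.macro_sensitivity,
        "macro_specificity": rep.macro_specificity,
        "coverage": res["coverage"],
        "avg_set_size": res["avg_set_size"],
        "per_class": rep.per_class.to_dict(orient="index"),
        "auc_per_class": rep.auc_per_class,
        "n_train": len(res["train_ids"]),
        "n_test": len(res["test_ids"]),
        "conformal": {
            "alpha": config.alpha,
            "q_hat": res["model"].calibration_.q_hat,
            "n_calib": res["model"].calibration_.n_calib,
        },
    }
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    sets = res["evaluation"]["prediction_sets"]
    cp.sets_to_long(sets).to_csv(os.path.join(out_dir, "prediction_sets.csv"),
                                 index=False)
    cp.sets_to_frame(sets, res["model"].scheme.classes).to_csv(
        os.path.join(out_dir, "set_map.csv"))
    pd.DataFrame({
        "subject_id": res["test_ids"],
        "correct": res["evaluation"]["per_sample_correct"],
    }).to_csv(os.path.join(out_dir, "per_sample.csv"), index=False)
    return summary


def run_compare(per_sample_csvs: list, out_csv) -> pd.DataFrame:
    """Pairwise comparison rows across runs' per-sample correctness files."""
    vecs = {}
    for path in per_sample_csvs:
        frame = pd.read_csv(path)
        vecs[path] = frame.set_index("subject_id")["correct"]
    names = list(vecs)
    index0 = vecs[names[0]].index
    for n in names[1:]:
        if not vecs[n].index.equals(index0):
            raise ValueError("per-sample files are not aligned on subjects")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    rows = []
    for a, b in pairs:
        row = compare_classifiers(vecs[a].to_numpy(), vecs[b].to_numpy(),
                                  pair=f"{a} vs {b}", m_comparisons=len(pairs))
        rows.append(row.to_dict())
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = bonferroni_threshold(0.05, len(pairs))
    if out_csv:
        out.to_csv(out_csv, index=False)
        with open(str(out_csv) + ".meta.json", "w") as fh:
            json.dump({"bonferroni_threshold": out.attrs["bonferroni_threshold"],
                       "m_comparisons": len(pairs)}, fh)
    return out
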