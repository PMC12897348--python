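"""Cohort partitioning: stratified train/test split and joint-stratified k-fold.

Small severity classes make plain stratified k-fold unable to keep both the
severity histogram and clinically important anthropometric thresholds (age
>=50, BMI >=35, NC >40, sex, Mallampati grade) balanced across folds; the
joint-stratified assignment here balances both with a greedy rarity-first
heuristic under a hard per-severity fold-size constraint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tbscreen.cohort import SEVERITIES, SEVERITY_RANK

#: factor name -> (column, threshold callable); MPS is kept categorical
FACTOR_NAMES = ("age_ge_50", "bmi_ge_35", "nc_gt_40", "sex_male",
                "mps_1", "mps_2", "mps_3", "mps_4")


def binarize_factors(row) -> dict:
    """Binary anthropometric indicators used for balancing.

    Boundaries follow the printed intervals: age >= 50, BMI >= 35,
    NC > 40 (so NC == 40 falls in the lower arm), sex male; the Mallampati
    score stays categorical (one indicator per grade).  Missing values map
    to NaN and are excluded from balancing for that subject.
    """
    def ind(cond, value):
        return np.nan if pd.isna(value) else float(cond)

    sex = row["sex"]
    sex_male = np.nan if pd.isna(sex) else float(sex == "M" or sex == 1 or sex == 1.0)
    out = {
        "age_ge_50": ind(row["age"] >= 50, row["age"]),
        "bmi_ge_35": ind(row["bmi"] >= 35, row["bmi"]),
        "nc_gt_40": ind(row["nc"] > 40, row["nc"]),
        "sex_male": sex_male,
    }
    for g in (1, 2, 3, 4):
        out[f"mps_{g}"] = ind(row["mps"] == g, row["mps"])
    return out


def _factor_frame(manifest: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {sid: binarize_factors(row) for sid, row in manifest.iterrows()}
    ).T


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(
    manifest: pd.DataFrame,
    test_fraction: float = 0.15,
    seed: int = 0,
    refine_iters: int = 200,
) -> tuple[list, list]:
    """85/15-style severity-stratified train/test split.

    ``manifest`` is indexed by subject_id with columns severity, age, sex,
    bmi, nc, mps.  Per-severity test counts are nearest-integer (half up)
    of ``test_fraction`` times the class size; within class the draw is
    seeded, then a greedy swap refinement reduces train/test discrepancy in
    age/BMI/NC means and sex/MPS proportions.
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    test_ids: list = []
    for sev in manifest["severity"].unique():
        ids = manifest.index[manifest["severity"] == sev].to_numpy()
        if len(ids) < 2:
            warnings.warn(f"class {sev!r} too small to split; all to train")
            continue
        n_test = min(_round_half_up(test_fraction * len(ids)), len(ids) - 1)
        test_ids += rng.choice(ids, size=n_test, replace=False).tolist()

    # numeric design for the discrepancy objective (factors + scaled continuous)
    factors = _factor_frame(manifest)
    cont = manifest[["age", "bmi", "nc"]].astype(float)
    scale = cont.std(ddof=0).replace(0, 1)
    design = np.column_stack([factors.to_numpy(dtype=float),
                              (cont / scale).to_numpy()])
    ids = manifest.index.to_numpy()
    pos = {sid: i for i, sid in enumerate(ids)}
    sev_codes = manifest["severity"].to_numpy()

    in_test = np.zeros(len(ids), dtype=bool)
    in_test[[pos[i] for i in test_ids]] = True

    def discrepancy(mask: np.ndarray) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            te = np.nanmean(design[mask], axis=0)
            tr = np.nanmean(design[~mask], axis=0)
        return float(np.nansum(np.abs(te - tr)))

    best = discrepancy(in_test)
    for _ in range(refine_iters):
        sev = sev_codes[int(rng.integers(len(ids)))]
        te_c = np.flatnonzero(in_test & (sev_codes == sev))
        tr_c = np.flatnonzero(~in_test & (sev_codes == sev))
        if not len(te_c) or not len(tr_c):
            continue
        a = te_c[int(rng.integers(len(te_c)))]
        b = tr_c[int(rng.integers(len(tr_c)))]
        cand = in_test.copy()
        cand[a], cand[b] = False, True
        val = discrepancy(cand)
        if val < best:
            in_test, best = cand, val
    train_ids = [sid for sid, t in zip(ids, in_test) if not t]
    test_ids = [sid for sid, t in zip(ids, in_test) if t]
    return train_ids, test_ids


@dataclass
class FoldAssignment:
    n_folds: int
    assignment: dict  # subject_id -> fold index
    strata_audit: pd.DataFrame

    def fold_ids(self, fold: int) -> list:
        return [s for s, f in self.assignment.items() if f == fold]


def imbalance_objective(assignment: dict, manifest: pd.DataFrame,
                        n_folds: int, severity_weight: float = 10.0) -> float:
    """Weighted fold-imbalance: severity counts (weight 10) + factor proportions."""
    factors = _factor_frame(manifest)
    total = 0.0
    global_counts = manifest["severity"].value_counts(normalize=True)
    global_factors = factors.mean()
    for f in range(n_folds):
        ids = [s for s, ff in assignment.items() if ff == f]
        if not ids:
            total += severity_weight * 2
            continue
        sub = manifest.loc[ids]
        props = sub["severity"].value_counts(normalize=True)
        for sev in global_counts.index:
            total += severity_weight * abs(props.get(sev, 0.0) - global_counts[sev])
        fm = factors.loc[ids].mean()
        total += float(np.nansum(np.abs(fm - global_factors)))
    return total


def joint_stratified_kfold(manifest: pd.DataFrame, k: int = 3,
                           seed: int = 0) -> FoldAssignment:
    """Greedy joint severity x anthropometric stratified fold assignment.

    Subjects are processed in order of the rarity of their (severity x
    binary-factor-pattern) cell; each is placed in the eligible fold
    minimizing the imbalance objective.  A hard constraint keeps every
    severity's fold counts within +-1 of n_c/k (relaxed with a warning when
    k exceeds the class size).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    factors = _factor_frame(manifest)

    # rarity of the joint cell
    pattern = factors.fillna(-1).astype(int).astype(str).agg("".join, axis=1)
    cell = manifest["severity"].astype(str) + "|" + pattern
    cell_counts = cell.value_counts()
    order = sorted(
        manifest.index,
        key=lambda s: (cell_counts[cell[s]], rng.random()),
    )

    class_sizes = manifest["severity"].value_counts()
    for sev, n_c in class_sizes.items():
        if k > n_c:
            warnings.warn(
                f"k={k} exceeds class {sev!r} size {n_c}; per-class balance relaxed"
            )

    quota_base = {sev: n // k for sev, n in class_sizes.items()}
    quota_extra = {sev: n % k for sev, n in class_sizes.items()}
    counts = {sev: np.zeros(k, dtype=int) for sev in class_sizes.index}
    extras_used = {sev: 0 for sev in class_sizes.index}

    fold_factor_sum = np.zeros((k, factors.shape[1]))
    fold_factor_n = np.zeros((k, factors.shape[1]))
    global_factors = factors.mean().to_numpy()

    assignment: dict = {}
    for sid in order:
        sev = manifest.loc[sid, "severity"]
        base = quota_base[sev]
        eligible = []
        for f in range(k):
            c = counts[sev][f]
            if c < base:
                eligible.append(f)
            elif c == base and extras_used[sev] < quota_extra[sev]:
                eligible.append(f)
        if not eligible:
            eligible = list(range(k))
        fv = factors.loc[sid].to_numpy()
        best_f, best_cost = None, None
        for f in eligible:
            s = fold_factor_sum.copy()
            n = fold_factor_n.copy()
            obs = ~np.isnan(fv)
            s[f, obs] += fv[obs]
            n[f, obs] += 1
            with np.errstate(invalid="ignore", divide="ignore"):
                means = np.where(n > 0, s / np.maximum(n, 1), global_factors)
            cost = float(np.abs(means - global_factors).sum())
            # mild preference for filling emptier folds first
            cost += 0.01 * counts[sev][f]
            if best_cost is None or cost < best_cost - 1e-12:
                best_f, best_cost = f, cost
        f = best_f
        if counts[sev][f] == quota_base[sev]:
            extras_used[sev] += 1
        counts[sev][f] += 1
        obs = ~np.isnan(fv)
        fold_factor_sum[f, obs] += fv[obs]
        fold_factor_n[f, obs] += 1
        assignment[sid] = f

    # Local refinement: within-class cross-fold swaps that reduce the total
    # factor-mean deviation.  Swapping same-severity subjects keeps every
    # per-class fold quota intact by construction.
    X = factors.to_numpy()
    obs_mask = ~np.isnan(X)
    Xz = np.where(obs_mask, X, 0.0)
    fold_of = np.array([assignment[s] for s in manifest.index])
    S = np.zeros((k, X.shape[1]))
    N = np.zeros((k, X.shape[1]))
    for f in range(k):
        rows = fold_of == f
        S[f] = Xz[rows].sum(axis=0)
        N[f] = obs_mask[rows].sum(axis=0)

    def _total_dev(s, n):
        with np.errstate(invalid="ignore", divide="ignore"):
            m = s / n
        return float(np.nansum(np.abs(m - global_factors)))

    best = _total_dev(S, N)
    sev_codes = manifest["severity"].to_numpy()
    idx_all = np.arange(len(manifest))
    for _ in range(3):
        improved = False
        for sev in class_sizes.index:
            members = idx_all[sev_codes == sev].copy()
            rng.shuffle(members)
            for ii, a in enumerate(members):
                for b in members[ii + 1:]:
                    f_a, f_b = fold_of[a], fold_of[b]
                    if f_a == f_b:
                        continue
                    S2, N2 = S.copy(), N.copy()
                    for row, src, dst in ((a, f_a, f_b), (b, f_b, f_a)):
                        S2[src] -= Xz[row]
                        N2[src] -= obs_mask[row]
                        S2[dst] += Xz[row]
                        N2[dst] += obs_mask[row]
                    val = _total_dev(S2, N2)
                    if val < best - 1e-12:
                        S, N, best = S2, N2, val
                        fold_of[a], fold_of[b] = f_b, f_a
                        improved = True
        if not improved:
            break
    assignment = {sid: int(f) for sid, f in zip(manifest.index, fold_of)}

    audit_rows = []
    for f in range(k):
        ids = [s for s, ff in assignment.items() if ff == f]
        row = {"fold": f, "n": len(ids)}
        sub = manifest.loc[ids]
        for sev in SEVERITIES:
            row[f"n_{sev}"] = int((sub["severity"] == sev).sum())
        for name in FACTOR_NAMES:
            row[name] = float(np.nanmean(factors.loc[ids][name])) if ids else np.nan
        audit_rows.append(row)
    audit = pd.DataFrame(audit_rows).set_index("fold")
    return FoldAssignment(n_folds=k, assignment=assignment, strata_audit=audit)
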