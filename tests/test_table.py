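"""Tabular preparation: imputation, normalization, selection oracles."""

import numpy as np
import pandas as pd
import pytest

from tbscreen.table import (
    ANTHROPOMETRIC_COLUMNS,
    FeatureTable,
    SelectionReport,
    adaptive_normalize,
    apply_scheme,
    mutual_information,
    rfe_select,
    select_features,
    shap_rank,
    stratified_knn_impute,
    ttest_filter,
)
from tbscreen.rusboost import RUSBoostClassifier
from tbscreen.shapley import sampling_shapley


def _toy_table(values, labels, families=None):
    frame = pd.DataFrame(values)
    frame.index = [f"s{i}" for i in range(len(frame))]
    lab = pd.Series(labels, index=frame.index, name="severity")
    fam = families or {c: "synthetic" for c in frame.columns}
    return FeatureTable(values=frame, labels=lab, family=fam)


class TestFeatureTable:
    def test_mask_tracks_nan(self):
        t = _toy_table({"a": [1.0, np.nan], "b": [2.0, 3.0]}, ["non", "non"])
        assert t.mask.loc["s1", "a"]
        assert not t.mask.loc["s0", "a"]

    def test_index_mismatch_raises(self):
        frame = pd.DataFrame({"a": [1.0]}, index=["x"])
        lab = pd.Series(["non"], index=["y"])
        with pytest.raises(ValueError):
            FeatureTable(values=frame, labels=lab, family={"a": "synthetic"})

    def test_subset_rows(self):
        t = _toy_table({"a": [1.0, 2.0, 3.0]}, ["non", "mild", "non"])
        sub = t.subset_rows(["s2", "s0"])
        assert list(sub.values.index) == ["s2", "s0"]
        assert list(sub.labels) == ["non", "non"]

    def test_family_partition(self):
        fam = {"a": "synthetic", "age": "anthropometric"}
        t = _toy_table({"a": [1.0], "age": [40.0]}, ["non"], fam)
        assert t.anthropometric_names == ["age"]
        assert t.acoustic_names == ["a"]


class TestKnnImpute:
    def test_brute_force_oracle(self):
        """One missing cell; with k=2 the imputed value is the mean of the
        target column over the two nearest (standardized-distance) complete
        donors in the same stratum, computed here by hand."""
        vals = {
            "x": [0.0, 1.0, 2.0, 10.0, np.nan, 5.0, 6.0, 7.0, 8.0],
            "y": [0.0, 1.0, 2.0, 10.0, 1.5, 50.0, 60.0, 70.0, 80.0],
        }
        labels = ["non"] * 5 + ["mild"] * 4
        t = _toy_table(vals, labels)
        out = stratified_knn_impute(t, k=2)

        # oracle: within the 'non' stratum, standardize on observed data
        block = t.values.loc[["s0", "s1", "s2", "s3", "s4"]]
        mu, sd = block.mean(), block.std(ddof=0).replace(0.0, 1.0)
        z = (block - mu) / sd
        d = ((z.loc[["s0", "s1", "s2", "s3"], "y"] - z.loc["s4", "y"]) ** 2
             ) ** 0.5
        nearest = d.nsmallest(2).index
        expected = block.loc[nearest, "x"].mean()
        assert out.values.loc["s4", "x"] == pytest.approx(expected)
        assert not out.mask.to_numpy().any()

    def test_stratum_restriction(self):
        """Donors come only from the same severity stratum even when the
        other stratum has closer rows."""
        vals = {"x": [np.nan, 4.0, 8.0, 12.0, 16.0, 20.0,
                      1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
                "y": [0.0, 0.1, 0.2, 5.0, 6.0, 7.0,
                      0.0, 0.0, 0.0, 0.0, 0.0, 0.0]}
        labels = ["non"] * 6 + ["mild"] * 6
        out = stratified_knn_impute(_toy_table(vals, labels), k=3)
        # all candidate donors are 'non' rows with x in {4..20}: the result
        # can never be the mild-stratum value 1.0
        assert out.values.loc["s0", "x"] >= 4.0

    def test_small_stratum_falls_back_to_stratum_mean(self):
        vals = {"x": [np.nan, 4.0, 8.0], "y": [0.0, 1.0, 2.0]}
        t = _toy_table(vals, ["non", "non", "non"])
        with pytest.warns(UserWarning, match="falling back to stratum mean"):
            out = stratified_knn_impute(t, k=3)
        assert out.values.loc["s0", "x"] == pytest.approx(6.0)

    def test_no_donors_uses_global_mean(self):
        vals = {"x": [np.nan, np.nan, 3.0, 5.0], "y": [0.0, 1.0, 2.0, 3.0]}
        t = _toy_table(vals, ["non", "non", "mild", "mild"])
        with pytest.warns(UserWarning):
            out = stratified_knn_impute(t, k=1)
        assert out.values.loc["s0", "x"] == pytest.approx(4.0)

    def test_complete_table_unchanged(self, feature_cohort):
        out = stratified_knn_impute(feature_cohort)
        pd.testing.assert_frame_equal(out.values, feature_cohort.values)


class TestMutualInformation:
    def test_hand_computed_joint(self):
        """Perfectly separated continuous groups with 2 bins give exactly
        1 bit; the plug-in value matches the hand-built joint table."""
        x = np.concatenate([np.linspace(0, 1, 20), np.linspace(10, 11, 20)])
        y = np.array([0] * 20 + [1] * 20)
        assert mutual_information(x, y, bins=2) == pytest.approx(1.0,
                                                                 abs=1e-9)

    def test_independent_is_zero(self):
        # x bins split each class exactly in half: plug-in MI is exactly 0
        x = np.array([0.0, 1.0, 2.0, 3.0] * 10)
        y = np.array([0, 0, 1, 1, 1, 1, 0, 0] * 5)
        # joint counts are uniform by construction
        mi = mutual_information(x, y, bins=2)
        assert mi == pytest.approx(0.0, abs=1e-9)

    def test_nonnegative_random(self, rng):
        for _ in range(10):
            x = rng.standard_normal(60)
            y = rng.integers(0, 3, 60)
            assert mutual_information(x, y) >= -1e-12

    def test_degenerate(self):
        assert mutual_information(np.ones(1), np.ones(1)) == 0.0
        assert mutual_information(np.ones(50), np.arange(50) % 2) == 0.0


class TestAdaptiveNormalize:
    def test_transform_matches_meta(self, feature_cohort):
        out = adaptive_normalize(stratified_knn_impute(feature_cohort))
        col = out.acoustic_names[0]
        meta = out.norm_meta[col]
        raw = feature_cohort.values[col].to_numpy(dtype=float)
        np.testing.assert_allclose(out.values[col].to_numpy(),
                                   apply_scheme(raw, meta))

    def test_scheme_maximizes_mi(self, feature_cohort):
        """Every stored scheme's MI is at least that of plain z-scoring."""
        from tbscreen.table import _scheme_params
        out = adaptive_normalize(stratified_knn_impute(feature_cohort))
        y = out.labels.to_numpy()
        for col in out.acoustic_names[:10]:
            meta = out.norm_meta[col]
            raw = feature_cohort.values[col].to_numpy(dtype=float)
            z = apply_scheme(raw, _scheme_params(raw, "zscore"))
            assert meta["mi_bits"] >= mutual_information(z, y) - 1e-9

    def test_constant_column_flagged(self):
        t = _toy_table({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]},
                       ["non", "mild", "non"])
        out = adaptive_normalize(t)
        assert out.norm_meta["a"]["scheme"] == "constant"
        np.testing.assert_array_equal(out.values["a"], t.values["a"])

    def test_reuse_on_holdout(self, feature_cohort):
        train = adaptive_normalize(stratified_knn_impute(feature_cohort))
        held = feature_cohort.subset_rows(feature_cohort.values.index[:5])
        out = adaptive_normalize(held, fit_meta=train.norm_meta)
        col = held.acoustic_names[0]
        np.testing.assert_allclose(
            out.values[col].to_numpy(),
            apply_scheme(held.values[col].to_numpy(), train.norm_meta[col]))

    def test_requires_imputed(self):
        t = _toy_table({"a": [1.0, np.nan]}, ["non", "mild"])
        with pytest.raises(ValueError):
            adaptive_normalize(t)


class TestTtestFilter:
    def test_keeps_informative_drops_noise(self, rng):
        n = 40
        y = np.array(["a"] * 20 + ["b"] * 20)
        vals = {
            "informative": np.concatenate([rng.normal(0, 1, 20),
                                           rng.normal(4, 1, 20)]),
            "noise": rng.standard_normal(n),
            "constant": np.zeros(n),
        }
        t = _toy_table(vals, ["non"] * n)
        kept = ttest_filter(t, pd.Series(y, index=t.values.index))
        assert "informative" in kept
        assert "constant" not in kept

    def test_nonbinary_raises(self, feature_cohort):
        with pytest.raises(ValueError):
            ttest_filter(feature_cohort, feature_cohort.labels)


class TestShapley:
    def test_linear_model_oracle(self, rng):
        """With a single background row, permutation Shapley values of a
        linear model are exactly w_j * (x_j - b_j) for every permutation."""
        w = np.array([2.0, -1.0, 0.5])

        def f(data):
            return data @ w

        X = rng.standard_normal((6, 3))
        bg = rng.standard_normal((1, 3))
        phi = sampling_shapley(f, X, background=bg, n_permutations=8, seed=0)
        expected = (X - bg[0]) * w
        np.testing.assert_allclose(phi, expected, atol=1e-9)

    def test_efficiency_property(self, rng):
        """Per-permutation telescoping: attributions sum exactly to
        f(x) - f(background) for any model when the background is fixed."""
        def f(data):
            return np.sin(data).sum(axis=1)

        X = rng.standard_normal((4, 3))
        bg = rng.standard_normal((1, 3))
        phi = sampling_shapley(f, X, background=bg, n_permutations=16,
                               seed=0)
        total = phi.sum(axis=1)
        expected = f(X) - f(bg)[0]
        np.testing.assert_allclose(total, expected, atol=1e-9)


class TestRusboost:
    def test_learns_imbalanced_separable(self, rng):
        n_maj, n_min = 80, 12
        X = np.vstack([rng.normal(0, 1, (n_maj, 3)),
                       rng.normal(3, 1, (n_min, 3))])
        y = np.array([0] * n_maj + [1] * n_min)
        clf = RUSBoostClassifier(n_estimators=30, random_state=0).fit(X, y)
        pred = clf.predict(X)
        # minority recall must be high despite the 80:12 imbalance
        assert (pred[y == 1] == 1).mean() > 0.8
        proba = clf.predict_proba(X)
        assert proba.shape == (len(y), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        imp = clf.feature_importances_
        assert imp.shape == (3,)
        assert np.all(imp >= 0)


class TestSelection:
    def test_report_nesting_enforced(self):
        with pytest.raises(ValueError):
            SelectionReport(stage1_kept=["a"], stage2_ranking=["a", "b"],
                            stage2_scores={}, final_selected=["b"])

    def test_three_stage_nesting_and_append(self, feature_cohort):
        table = adaptive_normalize(stratified_knn_impute(feature_cohort))
        pair = ("non", "severe")
        mask = table.labels.isin(pair)
        sub = table.subset_rows(table.labels.index[mask])
        task = sub.labels
        report = select_features(sub, task, target_k=10, seed=0,
                                 shap_permutations=4)
        assert len(report.final_selected) == 10
        assert set(report.final_selected) <= set(report.stage2_ranking)
        assert set(report.stage2_ranking) <= set(report.stage1_kept)
        appended = report.thresholds["anthropometric_appended"]
        assert set(appended) == set(ANTHROPOMETRIC_COLUMNS)
        assert len(report.final_selected) + len(appended) == 15

    def test_anthropometrics_never_filtered(self, feature_cohort):
        table = adaptive_normalize(stratified_knn_impute(feature_cohort))
        kept = ttest_filter(
            table.subset_rows(table.labels.index[
                table.labels.isin(("non", "severe"))]),
            table.labels[table.labels.isin(("non", "severe"))])
        assert not set(kept) & set(ANTHROPOMETRIC_COLUMNS)

    def test_short_ranking_keeps_all(self, feature_cohort):
        table = adaptive_normalize(stratified_knn_impute(feature_cohort))
        pair = ("non", "severe")
        sub = table.subset_rows(table.labels.index[table.labels.isin(pair)])
        ranking = sub.acoustic_names[:4]
        with pytest.warns(UserWarning, match="keeping all"):
            report = rfe_select(sub, sub.labels, ranking, target_k=30)
        assert report.final_selected == ranking

    def test_shap_rank_orders_by_attribution(self, rng):
        """A strongly informative column outranks pure noise."""
        n = 60
        y = pd.Series(["a"] * 30 + ["b"] * 30,
                      index=[f"s{i}" for i in range(n)])
        vals = {"signal": np.r_[rng.normal(0, 1, 30), rng.normal(5, 1, 30)],
                "noise1": rng.standard_normal(n),
                "noise2": rng.standard_normal(n)}
        t = _toy_table(vals, ["non"] * n)
        ranking, scores = shap_rank(t, y, ["signal", "noise1", "noise2"],
                                    seed=0, n_permutations=8)
        assert ranking[0] == "signal"
        assert scores["signal"] > scores["noise1"]
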