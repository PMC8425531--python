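"""Two-step boosted classification: selection, pairwise, multiclass."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from repeatsig.align import AlignedMatrix
from repeatsig.classify import (
    BoostedFeatureSelector,
    ClassifierConfig,
    TwoStepBoostedClassifier,
    report_metrics,
    select_features,
    train_multiclass,
    train_pairwise,
)

FAST = ClassifierConfig(rng_seed=0)


def matrix_from(X, y, prefix="chr1"):
    ids = [f"s{i:03d}" for i in range(len(X))]
    regions = [f"{prefix}:{i}-{i + 10}" for i in range(X.shape[1] // 2)]
    cols = [f"{r}_{s}" for r in regions for s in ("m", "d")]
    return AlignedMatrix(
        reference_regions=regions,
        values=pd.DataFrame(
            X, index=pd.Index(ids, name="sample_id"), columns=cols
        ),
        labels=pd.Series(list(y), index=ids, name="class"),
    )


class TestFeatureSelection:
    def test_single_signal_column_ranks_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, size=(60, 20))
        y = np.array(["a"] * 30 + ["b"] * 30)
        X[y == "b", 7] += 10.0
        sel = BoostedFeatureSelector(n_top_features=5, random_state=0).fit(X, y)
        assert sel.ranking_[0] == 7
        assert 7 in sel.selected_features_

    def test_permuted_labels_give_chance_overlap(self):
        """Features selected under permuted labels overlap the real
        selection no more than expected by chance (hypergeometric)."""
        rng = np.random.default_rng(1)
        n, d, k = 80, 60, 15
        X = rng.normal(0, 1, size=(n, d))
        y = np.array(["a"] * 40 + ["b"] * 40)
        X[y == "b", :k] += 1.5
        real = set(
            BoostedFeatureSelector(n_top_features=k, random_state=0)
            .fit(X, y).selected_features_
        )
        perm = set(
            BoostedFeatureSelector(n_top_features=k, random_state=0)
            .fit(X, rng.permutation(y)).selected_features_
        )
        overlap = len(real & perm)
        # P(overlap >= observed) under hypergeometric null
        pval = stats.hypergeom.sf(overlap - 1, d, k, k)
        assert pval > 0.01

    def test_select_features_reports_at_most_top_k(self, labeled_matrix):
        ranked = select_features(labeled_matrix, config=FAST)
        assert ranked.selected.sum() <= FAST.n_top_features
        assert list(ranked.importance) == sorted(ranked.importance, reverse=True)

    def test_small_class_raises_stratification_error(self):
        X = np.zeros((6, 4))
        y = np.array(["a"] * 4 + ["b"] * 2)
        with pytest.raises(ValueError, match="n_folds"):
            BoostedFeatureSelector().fit(X, y)


class TestPairwise:
    def test_pair_count_law(self, labeled_matrix):
        reports = train_pairwise(labeled_matrix, config=FAST)
        assert len(reports) == 3  # 3 classes -> 3 pairs

    def test_separable_classes_reach_auc_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 0.1, size=(48, 10))
        y = np.array(["a"] * 24 + ["b"] * 24)
        X[:, 0] = np.where(y == "b", 5.0, 0.0)  # one exactly separating column
        (report,) = train_pairwise(matrix_from(X, y), config=FAST)
        assert report.auc == pytest.approx([1.0] * 4)

    def test_planted_class_dominates(self, labeled_matrix):
        reports = train_pairwise(labeled_matrix, config=FAST)
        by_pair = {frozenset((r.class_a, r.class_b)): r for r in reports}
        assert by_pair[frozenset(("gamma", "alpha"))].mean_auc > 0.9
        assert by_pair[frozenset(("gamma", "beta"))].mean_auc > 0.9

    def test_deterministic_given_seed(self, labeled_matrix):
        r1 = train_pairwise(labeled_matrix, config=FAST)
        r2 = train_pairwise(labeled_matrix, config=FAST)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.auc, b.auc)
            assert a.selected_features == b.selected_features

    def test_out_of_fold_hygiene(self, labeled_matrix):
        """Every sample's validation prediction comes from the fold that
        held it out, and folds partition the samples."""
        clf = TwoStepBoostedClassifier(random_state=0).fit(
            labeled_matrix.values.to_numpy(),
            labeled_matrix.labels.to_numpy(),
        )
        seen = np.concatenate([val for _, val in clf.folds_])
        assert sorted(seen) == list(range(labeled_matrix.values.shape[0]))
        for train_idx, val_idx in clf.folds_:
            assert set(train_idx).isdisjoint(val_idx)


class TestMulticlass:
    def test_probability_rows_sum_to_one(self, labeled_matrix):
        report = train_multiclass(labeled_matrix, config=FAST)
        np.testing.assert_allclose(
            report.proba_profile.sum(axis=1), 1.0, atol=1e-9
        )

    def test_planted_class_dominates_its_confusion_row(self, labeled_matrix):
        report = train_multiclass(labeled_matrix, config=FAST)
        row = report.confusion.loc["gamma"]
        assert row["gamma"] == row.max()

    def test_needs_three_classes(self):
        X = np.zeros((16, 4))
        y = np.array(["a"] * 8 + ["b"] * 8)
        with pytest.raises(ValueError, match="three"):
            train_multiclass(matrix_from(X, y), config=FAST)


class TestReportMetrics:
    def test_mean_and_sd_of_auc(self, labeled_matrix):
        reports = train_pairwise(labeled_matrix, config=FAST)
        reports[0].auc = np.array([0.8, 0.9, 1.0, 0.9])
        summary = report_metrics(reports)["summary"]
        row = summary.iloc[0]
        assert row.mean_auc == pytest.approx(0.90)
        assert row.sd_auc == pytest.approx(0.0816, abs=1e-4)

    def test_seriation_matrix_shape(self, labeled_matrix):
        reports = train_pairwise(labeled_matrix, config=FAST)
        grid = report_metrics(reports)["seriation"]["auc"]
        assert grid.shape == (3, 3)
        assert grid.isna().to_numpy().diagonal().all()
        pd.testing.assert_frame_equal(grid, grid.T)

    def test_missing_roc_data_rejected(self, labeled_matrix):
        reports = train_pairwise(labeled_matrix, config=FAST)
        reports[0].roc_points = []
        with pytest.raises(ValueError, match="ROC"):
            report_metrics(reports)
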