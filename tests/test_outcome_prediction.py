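import numpy as np
import pandas as pd
import pytest

from oracles import auc_pair_oracle, mic_exhaustive_oracle
from tdcsgraph.outcome_prediction import (
    FEATURE_NAMES,
    FeatureMatrix,
    build_feature_matrix,
    change_rate,
    mic,
    nested_cv_svm,
    rank_features_mic,
    roc_auc,
    sfs_select,
)

# small hyperparameter grid keeps the SVM tests fast; the default
# powers-of-two grid is exercised once in the pipeline test
SMALL_GRID = {"svc__C": [1.0, 10.0, 100.0], "svc__gamma": [0.01, 0.1, 1.0]}


def make_fm(X, y, subjects=None):
    X = pd.DataFrame(np.asarray(X, dtype=float))
    X.columns = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=bool)
    if subjects is None:
        subjects = np.array([f"s{i}" for i in range(len(y))])
    return FeatureMatrix(X=X, y=y, subjects=np.asarray(subjects))


class TestChangeRate:
    @pytest.mark.parametrize("pre,post,expected", [
        (2.0, 1.0, -0.5), (1.5, 1.5, 0.0), (1.25, 1.5, 0.2),
    ])
    def test_relative_change(self, pre, post, expected):
        assert change_rate(pre, post) == pytest.approx(expected)

    def test_zero_pre_rejected(self):
        with pytest.raises(ValueError):
            change_rate(0.0, 1.0)


class TestMic:
    def test_noiseless_monotone_relationship_is_one(self):
        x = np.linspace(0, 1, 20)
        assert mic(x, x**3) == pytest.approx(1.0)

    def test_constant_input_is_zero(self):
        assert mic(np.ones(20), np.arange(20.0)) == 0.0
        assert mic(np.arange(20.0), np.ones(20)) == 0.0

    def test_self_mic_is_one(self, rng):
        # exactly 1 needs a balanced 2x2 grid, hence an even sample count;
        # at odd n the best split is 1 point off balance
        x = rng.standard_normal(16)
        assert mic(x, x) == pytest.approx(1.0)

    def test_self_mic_near_one_odd_n(self, rng):
        x = rng.standard_normal(15)
        assert mic(x, x) == pytest.approx(1.0, abs=0.02)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(3):
            x = rng.standard_normal(25)
            y = rng.standard_normal(25)
            m = mic(x, y)
            assert 0.0 <= m <= 1.0
            assert m == pytest.approx(mic(y, x), abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_partition_oracle_tiny_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        if seed % 3 == 0:  # exercise ties
            x = np.round(x)
        assert mic(x, y) == pytest.approx(
            mic_exhaustive_oracle(x, y), abs=1e-9
        )

    def test_binary_label_against_oracle(self, rng):
        x = rng.standard_normal(10)
        y = (rng.random(10) < 0.5).astype(float)
        if np.ptp(y) == 0:
            y[0] = 1 - y[0]
        assert mic(x, y) == pytest.approx(
            mic_exhaustive_oracle(x, y), abs=1e-9
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mic([1, 2, 3], [1, 2, 3])


class TestRankFeatures:
    def test_label_copy_ranked_first(self, rng):
        y = np.array([0, 1] * 10, dtype=bool)
        X = np.column_stack([
            rng.standard_normal(20),
            y.astype(float),
            rng.standard_normal(20),
        ])
        fm = make_fm(X, y)
        assert rank_features_mic(fm)[0] == "f1"

    def test_single_feature(self, rng):
        fm = make_fm(rng.standard_normal((10, 1)), [0, 1] * 5)
        assert rank_features_mic(fm) == ["f0"]

    def test_row_permutation_invariant(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.random(20) < 0.5
        y[:2] = [True, False]
        fm = make_fm(X, y)
        perm = rng.permutation(20)
        fm_p = make_fm(X[perm], y[perm])
        assert rank_features_mic(fm) == rank_features_mic(fm_p)


class TestSfsSelect:
    def test_separating_feature_wins_alone(self, rng):
        n = 40
        y = np.array([False, True] * (n // 2))
        X = np.column_stack([
            np.where(y, 1.0, -1.0) + 0.05 * rng.standard_normal(n),
            rng.standard_normal(n),
            rng.standard_normal(n),
        ])
        fm = make_fm(X, y)
        selected = sfs_select(fm, ["f0", "f1", "f2"], group_aware=False, seed=0)
        assert selected == ["f0"]

    def test_constant_evaluator_ties_favor_fewest(self, rng):
        fm = make_fm(rng.standard_normal((10, 3)), [0, 1] * 5)
        assert sfs_select(fm, ["f2", "f0", "f1"], evaluator=lambda f: 0.5) == ["f2"]

    def test_identical_features_collapse_to_one(self, rng):
        col = rng.standard_normal(20)
        fm = make_fm(np.column_stack([col, col, col]), [0, 1] * 10)
        selected = sfs_select(fm, ["f0", "f1", "f2"], group_aware=False, seed=0)
        assert len(selected) == 1

    def test_empty_ranking_rejected(self, rng):
        fm = make_fm(rng.standard_normal((10, 1)), [0, 1] * 5)
        with pytest.raises(ValueError):
            sfs_select(fm, [])


class TestRocAuc:
    def test_perfect_ranking(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_auc([0.5] * 6, [True, False] * 3)
        assert auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = np.round(rng.standard_normal(n), 1)  # force some ties
        labels = rng.random(n) < 0.5
        labels[:2] = [True, False]
        points, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(auc_pair_oracle(scores, labels), abs=1e-12)
        # ROC curve is monotone non-decreasing
        assert np.all(np.diff(points[:, 0]) >= 0)
        assert np.all(np.diff(points[:, 1]) >= 0)


def separable_cohort(rng, n_subjects=12, windows=5, noise=0.1):
    """Feature matrix where responders and non-responders separate."""
    subjects, rows, labels = [], [], []
    for s in range(n_subjects):
        responder = s < n_subjects // 2
        for _ in range(windows):
            center = 1.0 if responder else -1.0
            rows.append([
                center + noise * rng.standard_normal(),
                0.5 * center + noise * rng.standard_normal(),
                rng.standard_normal(),
                rng.standard_normal(),
            ])
            subjects.append(f"s{s:02d}")
            labels.append(responder)
    return make_fm(rows, labels, subjects)


class TestNestedCvSvm:
    def test_deterministic_per_seed(self, rng):
        fm = separable_cohort(rng, noise=0.8)
        a = nested_cv_svm(fm, seed=4, param_grid=SMALL_GRID)
        b = nested_cv_svm(fm, seed=4, param_grid=SMALL_GRID)
        assert a.to_dict() == b.to_dict()

    def test_separable_cohort_high_accuracy(self):
        accs = []
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            fm = separable_cohort(rng)
            rep = nested_cv_svm(fm, seed=seed, param_grid=SMALL_GRID)
            accs.append(rep.acc_mean)
        assert np.mean(accs) >= 0.95

    def test_shuffled_labels_give_chance_auc(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            X = rng.standard_normal((40, 4))
            subjects = np.repeat([f"s{i}" for i in range(20)], 2)
            # balanced random subject labels, constant within subject
            y = np.repeat(rng.permutation([True, False] * 10), 2)
            fm = make_fm(X, y, subjects)
            rep = nested_cv_svm(fm, seed=seed, param_grid=SMALL_GRID,
                                run_sfs=False)
            aucs.append(rep.pooled_auc)
        assert 0.35 < np.mean(aucs) < 0.65

    def test_single_class_rejected(self, rng):
        fm = make_fm(rng.standard_normal((10, 2)), [True] * 10)
        with pytest.raises(ValueError):
            nested_cv_svm(fm)

    def test_tiny_minority_class_rejected(self, rng):
        fm = make_fm(rng.standard_normal((10, 2)), [True] + [False] * 9)
        with pytest.raises(ValueError, match="class"):
            nested_cv_svm(fm)

    def test_report_metrics_in_range(self, rng):
        fm = separable_cohort(rng, noise=1.5)
        rep = nested_cv_svm(fm, seed=1, param_grid=SMALL_GRID)
        for v in (rep.acc_mean, rep.sn_mean, rep.sp_mean, rep.pooled_auc):
            assert 0.0 <= v <= 1.0
        assert len(rep.fold_acc) == 5
        assert all(len(f) >= 1 for f in rep.selected_features)

    def test_paper_mode_uses_sample_level_splits(self, rng):
        fm = separable_cohort(rng, noise=0.5)
        rep = nested_cv_svm(fm, seed=2, paper_mode=True, param_grid=SMALL_GRID)
        assert not rep.group_aware


class TestBuildFeatureMatrix:
    @staticmethod
    def measure_table():
        rows = []
        values = {
            ("sub-a", "pre"): 2.0, ("sub-a", "post"): 1.0,
            ("sub-b", "pre"): 1.25, ("sub-b", "post"): 1.5,
            ("sub-c", "pre"): 1.0, ("sub-c", "post"): 1.0,
        }
        for (subject, cond), v in values.items():
            for measure, scope in [("C_net", "global"), ("L_net", "global"),
                                   ("E_net", "global"), ("L_local", "site")]:
                rows.append({
                    "subject_id": subject, "condition": cond,
                    "window_index": 0, "density": 0.3,
                    "measure": measure, "scope": scope, "value": v,
                })
        return pd.DataFrame(rows)

    GROUPS = {
        "sub-a": "active_responder",
        "sub-b": "active_nonresponder",
        "sub-c": "sham",
    }

    def test_change_rates_and_labels(self):
        fm = build_feature_matrix(self.measure_table(), self.GROUPS, 0.3)
        assert list(fm.X.columns) == list(FEATURE_NAMES)
        assert len(fm.X) == 2  # sham excluded
        assert fm.y.tolist() == [True, False]
        assert fm.X.iloc[0]["C_net"] == pytest.approx(-0.5)
        assert fm.X.iloc[1]["C_net"] == pytest.approx(0.2)

    def test_wrong_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            build_feature_matrix(self.measure_table(), self.GROUPS, 0.4)

    def test_nonfinite_rates_excluded_with_warning(self):
        table = self.measure_table()
        table.loc[
            (table.subject_id == "sub-a") & (table.condition == "pre")
            & (table.measure == "L_net"), "value"
        ] = np.inf
        with pytest.warns(RuntimeWarning, match="sub-a"):
            fm = build_feature_matrix(table, self.GROUPS, 0.3)
        assert len(fm.X) == 1

    def test_nonfinite_rates_error_mode(self):
        table = self.measure_table()
        table.loc[
            (table.subject_id == "sub-a") & (table.condition == "pre")
            & (table.measure == "L_net"), "value"
        ] = np.inf
        with pytest.raises(ValueError, match="sub-a"):
            build_feature_matrix(table, self.GROUPS, 0.3, on_nonfinite="error")
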