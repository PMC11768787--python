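import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from protonet.evaluation import (
    FoldResult,
    compute_metrics,
    duration_agreement,
    evaluate_fold,
    icc_2_1,
    learning_curve,
    loso_folds,
    pearson_ci,
    run_loso,
    select_threshold,
    stratified_metrics,
    train_baselines,
)
from protonet.features import FeatureTable


class TestLosoFolds:
    def test_one_fold_per_subject_each_held_out_once(self, easy_table):
        folds = list(loso_folds(easy_table))
        subjects = set(easy_table.frame["subject_id"])
        assert len(folds) == len(subjects)
        assert {s for s, _, _ in folds} == subjects

    def test_train_and_test_partition_rows(self, easy_table):
        for subject, train, test in loso_folds(easy_table):
            assert set(test.frame["subject_id"]) == {subject}
            assert subject not in set(train.frame["subject_id"])
            assert len(train.frame) + len(test.frame) == len(easy_table.frame)

    def test_held_out_prototypes_stay_out_of_training(self, easy_table):
        subject, train, test = next(iter(loso_folds(easy_table)))
        proto = test.frame["prototype"]
        assert proto.any()  # the held-out subject does have prototype rows
        assert subject not in set(train.frame["subject_id"])

    def test_single_subject_rejected(self, easy_table):
        one = easy_table.select(
            (easy_table.frame["subject_id"] == easy_table.frame["subject_id"].iloc[0]).to_numpy()
        )
        with pytest.raises(ValueError):
            list(loso_folds(one))


class TestSelectThreshold:
    def test_perfect_separation_keeps_full_sensitivity(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.uniform(0, 0.4, 1000), rng.uniform(0.6, 1.0, 100)])
        labels = np.concatenate([np.zeros(1000, int), np.ones(100, int)])
        thr, info = select_threshold(scores, labels, return_info=True)
        assert info["sensitivity"] == 1.0
        assert 0.945 < info["specificity"] < 0.955

    def test_degenerate_scores_fall_back_with_flag(self):
        scores = np.concatenate([np.zeros(1000), np.ones(50)])
        labels = scores.astype(int)
        thr, info = select_threshold(scores, labels, return_info=True)
        assert info["fallback"]
        assert info["specificity"] == 1.0
        assert info["sensitivity"] == 1.0

    def test_gaussian_mixture_threshold_matches_analytic_quantile(self):
        """On a large N(0,1) / N(2,1) score mixture the threshold lands at
        the analytic 95% specificity quantile of the negatives."""
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.normal(0, 1, 50_000), rng.normal(2, 1, 50_000)])
        labels = np.concatenate([np.zeros(50_000, int), np.ones(50_000, int)])
        thr = select_threshold(scores, labels)
        assert thr == pytest.approx(spstats.norm.ppf(0.95), abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_threshold(np.ones(10), np.ones(10, int))


class TestComputeMetrics:
    def test_perfect_scores_give_unit_metrics(self):
        labels = np.array([0, 0, 1, 1])
        scores = labels.astype(float)
        assert compute_metrics(scores, labels, 0.5) == (1.0, 1.0, 1.0)

    def test_auroc_equals_bruteforce_discordant_pairs(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 200)
        scores = rng.normal(size=200) + labels  # ties unlikely
        _, _, auroc = compute_metrics(scores, labels, 0.0)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auroc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_label_independent_scores_have_half_auroc(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 100_000)
        scores = rng.normal(size=100_000)
        _, _, auroc = compute_metrics(scores, labels, 0.0)
        assert auroc == pytest.approx(0.5, abs=0.01)

    def test_absent_class_yields_nan(self):
        sens, spec, auroc = compute_metrics(np.ones(5), np.ones(5, int), 0.5)
        assert np.isnan(spec) and np.isnan(auroc) and sens == 1.0


class TestBaselines:
    @staticmethod
    def _gaussian_classes(n0, n1, seed=0):
        rng = np.random.default_rng(seed)
        X = np.concatenate(
            [rng.normal(0, 1, (n0, 2)), rng.normal(2.0, 1, (n1, 2))]
        )
        y = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
        return X, y

    def test_separable_data_trains_to_high_auroc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        X = np.concatenate([rng.normal(0, 0.3, (100, 2)), rng.normal(4, 0.3, (100, 2))])
        y = np.repeat([0, 1], 100)
        for clf in train_baselines(X, y, seed=0).values():
            assert roc_auc_score(y, clf.predict_proba(X)[:, 1]) >= 0.99

    def test_class_weighting_recovers_balanced_boundary(self):
        """Under 99:1 imbalance with inverse-frequency weights the logistic
        boundary stays near the balanced Gaussian midpoint (x = 1)."""
        X, y = self._gaussian_classes(9900, 100, seed=5)
        logistic = train_baselines(X, y, seed=0)["logistic"]
        w, b = logistic.coef_[0], logistic.intercept_[0]
        # boundary crossing along the (1,1) class-difference direction;
        # the balanced LDA midpoint sits at t = 1
        t_boundary = -b / (w[0] + w[1])
        assert t_boundary == pytest.approx(1.0, abs=0.1)

    def test_forest_is_deterministic_given_seed(self):
        X, y = self._gaussian_classes(200, 200, seed=6)
        f1 = train_baselines(X, y, seed=3)["random_forest"]
        f2 = train_baselines(X, y, seed=3)["random_forest"]
        np.testing.assert_array_equal(
            f1.predict_proba(X)[:, 1], f2.predict_proba(X)[:, 1]
        )


def _fold(subject, sens_cells=None, spec_cells=None, **kw):
    base = dict(
        subject_id=subject,
        threshold=0.5,
        sensitivity=0.8,
        specificity=0.9,
        auroc=0.85,
        sensitivity_by_subclass=sens_cells or {},
        specificity_by_subclass=spec_cells or {},
        predicted_tremor_s=100.0,
        true_tremor_s=120.0,
        n_test_windows=50,
    )
    base.update(kw)
    return FoldResult(**base)


class TestStratifiedMetrics:
    def test_absent_subclass_cell_is_absent_not_zero(self):
        folds = [
            _fold("a", sens_cells={"T1": 1.0}),
            _fold("b", sens_cells={"T2": 0.5}),
        ]
        out = stratified_metrics(folds)
        assert out["sensitivity"]["T1"]["n_folds"] == 1
        assert "T3" not in out["sensitivity"]

    def test_aggregation_matches_hand_computation(self):
        folds = [
            _fold("a", sens_cells={"T1": 1.0}, spec_cells={"N1": 0.9}),
            _fold("b", sens_cells={"T1": 0.5}, spec_cells={"N1": 0.7}),
            _fold("c", sens_cells={"T1": 0.75}),
        ]
        out = stratified_metrics(folds)
        cell = out["sensitivity"]["T1"]
        assert cell["mean"] == pytest.approx(0.75)
        assert cell["sd"] == pytest.approx(np.std([1.0, 0.5, 0.75]))
        assert cell["n_folds"] == 3
        assert out["specificity"]["N1"]["mean"] == pytest.approx(0.8)

    def test_all_correct_predictions_give_unit_cells(self, easy_table):
        subject, train, test = next(iter(loso_folds(easy_table)))
        # oracle classifier: use the true labels as scores
        pred = test.y.astype(bool)
        from protonet.evaluation import _fold_stratified

        sens, spec = _fold_stratified(test, pred)
        assert all(v == 1.0 for v in sens.values())
        assert all(v == 1.0 for v in spec.values())


class TestLearningCurve:
    def test_full_duration_reproduces_standard_fold_auroc(self, easy_table):
        df = learning_curve(easy_table, durations_min=(10_000.0,), model="logistic")
        rep = run_loso(easy_table, model="logistic", compute_agreement=False)
        full = {
            f.subject_id: f.auroc for f in rep.folds if not np.isnan(f.auroc)
        }
        for row in df.itertuples():
            assert row.auroc == pytest.approx(full[row.subject_id], abs=1e-12)

    def test_cumulative_samples_nest(self, easy_table):
        df = learning_curve(
            easy_table, durations_min=(1.0, 2.0, 5.0), model="logistic"
        )
        counts = df.groupby(["subject_id", "duration_min"])["n_windows"].first()
        for subject in counts.index.get_level_values(0).unique():
            sizes = counts[subject].sort_index().to_numpy()
            assert np.all(np.diff(sizes) >= 0)

    def test_auroc_does_not_collapse_with_more_data(self, easy_table):
        df = learning_curve(
            easy_table, durations_min=(1.0, 8.0), model="logistic", seeds=(0, 1, 2)
        )
        means = df.groupby("duration_min")["auroc"].mean()
        assert means[8.0] >= means[1.0] - 0.02


class TestAgreement:
    def test_identity_has_unit_pearson_and_icc(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 8.0])
        out = duration_agreement(x, x)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["icc"] == pytest.approx(1.0)

    def test_constant_offset_keeps_pearson_but_lowers_icc(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 8.0])
        out = duration_agreement(x + 2.0, x)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["icc"] < 1.0

    def test_icc_matches_pingouin_two_way_absolute_single(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        x = rng.normal(10, 3, 12)
        y = x + rng.normal(0.5, 1.0, 12)
        icc, ci = icc_2_1(x, y, confidence=0.95)
        df = pd.DataFrame(
            {
                "targets": np.tile(np.arange(12), 2),
                "raters": np.repeat(["a", "b"], 12),
                "scores": np.concatenate([x, y]),
            }
        )
        ref = pingouin.intraclass_corr(
            df, targets="targets", raters="raters", ratings="scores"
        ).set_index("Type")
        row = ref.loc["ICC(A,1)"] if "ICC(A,1)" in ref.index else ref.loc["ICC2"]
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        lo, hi = row[[c for c in ("CI95", "CI95%") if c in ref.columns][0]]
        assert ci[0] == pytest.approx(lo, abs=0.01)  # pingouin rounds to 2 dp
        assert ci[1] == pytest.approx(hi, abs=0.01)

    def test_constant_input_gives_nan_pearson(self):
        r, ci = pearson_ci(np.ones(8), np.arange(8.0))
        assert np.isnan(r)


class TestEvaluateFold:
    def test_fold_safe_normalization_excludes_test_subject(self, easy_table):
        """Training z-score statistics must be reproducible from the training
        rows alone (no leakage from the held-out subject)."""
        from protonet.features import zscore_fit_apply

        subject, train, test = next(iter(loso_folds(easy_table)))
        train_z = zscore_fit_apply(train)
        mean, sd = train_z.stats
        np.testing.assert_allclose(mean, train.X.mean(axis=0), atol=1e-12)
        recomputed_with_test = easy_table.X.mean(axis=0)
        assert not np.allclose(mean, recomputed_with_test, atol=1e-12)

    def test_logistic_fold_produces_valid_metrics(self, easy_table):
        subject, train, test = next(
            (s, tr, te)
            for s, tr, te in loso_folds(easy_table)
            if te.y.sum() > 0
        )
        fold = evaluate_fold(subject, train, test, model="logistic", seed=0)
        assert 0.0 <= fold.specificity <= 1.0
        assert 0.0 <= fold.auroc <= 1.0
        assert fold.true_tremor_s == test.y.sum() * 2.0
        assert set(fold.sensitivity_by_subclass) <= {f"T{i}" for i in range(1, 8)}

    def test_run_loso_aggregates_recomputable_from_folds(self, easy_table):
        rep = run_loso(easy_table, model="logistic", compute_agreement=True)
        specs = [f.specificity for f in rep.folds if not np.isnan(f.specificity)]
        assert rep.aggregates["specificity"][0] == pytest.approx(np.mean(specs))
        aurocs = [f.auroc for f in rep.folds if not np.isnan(f.auroc)]
        assert rep.aggregates["auroc"][0] == pytest.approx(np.mean(aurocs))
        assert rep.aggregates["n_folds"] == len(rep.folds)
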