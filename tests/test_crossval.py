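import numpy as np
import pytest

from panelfuse.crossval import (
    CVScheme,
    MultivariateConfig,
    PipelineRecipe,
    PrefilterConfig,
    cv_performance,
    cv_probabilities,
    fit_pipeline,
    nested_cv,
    one_se_select,
    predict_pipeline,
)
from panelfuse.data_model import LabelSet, OmicsMatrix
from panelfuse.feature_selection import SelectionConfig
from panelfuse.imputation import ImputeConfig
from panelfuse.learners import LearnerSpec
from panelfuse.metrics import auc
from conftest import make_two_class_matrix


@pytest.fixture(scope="module")
def signal():
    return make_two_class_matrix(seed=31, n_features=60, n_pos=8, n_neg=12,
                                 shift=3.0, n_shifted=10)


def _recipe(kind="svm_linear", **kwargs) -> PipelineRecipe:
    defaults = dict(
        learner=LearnerSpec(kind, seed=0),
        prefilter=PrefilterConfig(kind="ecmr"),
        selection=SelectionConfig(top_k=8),
    )
    defaults.update(kwargs)
    return PipelineRecipe(**defaults)


class TestCVScheme:
    def test_loo_folds(self, signal):
        matrix, labels = signal
        folds = list(CVScheme("loo").splits(labels, matrix.sample_ids))
        assert len(folds) == matrix.n_samples
        for _, train_ids, test_ids in folds:
            assert len(test_ids) == 1
            assert len(train_ids) == matrix.n_samples - 1
            assert set(train_ids) | set(test_ids) == set(matrix.sample_ids)

    def test_stratified_kfold_coverage_per_repeat(self, signal):
        matrix, labels = signal
        scheme = CVScheme("kfold", k=4, repeats=3, seed=5)
        seen: dict[int, list[str]] = {}
        for rep, _, test_ids in scheme.splits(labels, matrix.sample_ids):
            seen.setdefault(rep, []).extend(test_ids)
        assert sorted(seen) == [0, 1, 2]
        for rep, ids in seen.items():
            # every sample held out exactly once per repeat
            assert sorted(ids) == sorted(matrix.sample_ids)

    def test_stratified_folds_keep_both_classes_in_train(self, signal):
        matrix, labels = signal
        for _, train_ids, _ in CVScheme("kfold", k=4).splits(labels, matrix.sample_ids):
            sub = labels.subset(train_ids)
            assert sub.n_pos > 0 and sub.n_neg > 0

    def test_k_larger_than_n_rejected(self, signal):
        matrix, labels = signal
        with pytest.raises(ValueError, match="exceeds"):
            list(CVScheme("kfold", k=100).splits(labels, matrix.sample_ids))

    def test_invalid_kind(self):
        with pytest.raises(ValueError, match="unknown CV kind"):
            CVScheme("bootstrap")


class TestFitPredict:
    def test_stage_counts_recorded(self, signal):
        matrix, labels = signal
        fit = fit_pipeline(_recipe(), matrix, labels)
        stages = dict(fit.stage_counts)
        assert stages["input"] == 60
        # with 60 distinct ECMRs the median is interpolated between the 30th
        # and 31st order statistics, so exactly 30 lie strictly above it
        assert stages["ecmr_prefilter"] == 30
        assert stages["univariate"] == 8
        assert stages["panel"] == 8

    def test_multivariate_stage_cuts_panel(self, signal):
        matrix, labels = signal
        recipe = _recipe(selection=SelectionConfig(top_k=12),
                         multivariate=MultivariateConfig(importance="svm", top_m=5))
        fit = fit_pipeline(recipe, matrix, labels)
        assert len(fit.panel) == 5

    def test_frozen_panel_skips_selection(self, signal):
        matrix, labels = signal
        from panelfuse.data_model import FeaturePanel

        frozen = FeaturePanel(matrix.feature_ids[:4],
                              {f: 0.0 for f in matrix.feature_ids[:4]})
        fit = fit_pipeline(_recipe(frozen_panel=frozen), matrix, labels)
        assert fit.panel.feature_ids == matrix.feature_ids[:4]

    def test_predict_covers_test_samples(self, signal):
        matrix, labels = signal
        train_ids = matrix.sample_ids[:-4]
        test_ids = matrix.sample_ids[-4:]
        fit = fit_pipeline(_recipe(), matrix.subset_samples(train_ids),
                           labels.subset(train_ids))
        probs = predict_pipeline(fit, matrix.subset_samples(test_ids))
        assert sorted(probs.probabilities) == sorted(test_ids)


class TestCvProbabilities:
    def test_loo_produces_one_model_per_sample(self, signal):
        matrix, labels = signal
        probs, details = cv_probabilities(_recipe(), matrix, labels,
                                          CVScheme("loo"), return_details=True)
        assert len(details) == matrix.n_samples
        assert sorted(probs.probabilities) == sorted(matrix.sample_ids)
        assert probs.origin == "cv_heldout"

    def test_deterministic(self, signal):
        matrix, labels = signal
        p1 = cv_probabilities(_recipe(), matrix, labels, CVScheme("loo"))
        p2 = cv_probabilities(_recipe(), matrix, labels, CVScheme("loo"))
        assert p1.probabilities == p2.probabilities

    def test_sample_order_invariance(self, signal):
        # solver iteration order introduces tiny float differences, so
        # probabilities agree approximately and the ranking (AUC) exactly
        matrix, labels = signal
        perm = list(np.random.default_rng(1).permutation(matrix.sample_ids))
        p1 = cv_probabilities(_recipe(), matrix, labels, CVScheme("loo"))
        p2 = cv_probabilities(_recipe(), matrix.subset_samples(perm), labels,
                              CVScheme("loo"))
        for s in matrix.sample_ids:
            assert p2.probabilities[s] == pytest.approx(p1.probabilities[s],
                                                        abs=1e-4)
        assert auc(p1, labels) == pytest.approx(auc(p2, labels), abs=1e-9)

    def test_heldout_sample_never_in_fold_selection(self, signal):
        # leakage guard: each fold's pipeline must be fit without the held-out
        # sample, so its stage outputs must match a manual refit on the
        # training subset alone
        matrix, labels = signal
        recipe = _recipe()
        probs, details = cv_probabilities(recipe, matrix, labels,
                                          CVScheme("loo"), return_details=True)
        _, test_ids, fold_fit = details[0]
        heldout = test_ids[0]
        assert heldout not in fold_fit.train_matrix.sample_ids
        train_ids = [s for s in matrix.sample_ids if s != heldout]
        manual = fit_pipeline(recipe, matrix.subset_samples(train_ids),
                              labels.subset(train_ids))
        assert manual.panel.feature_ids == fold_fit.panel.feature_ids
        manual_p = predict_pipeline(manual, matrix.subset_samples([heldout]))
        assert manual_p.probabilities[heldout] == pytest.approx(
            probs.probabilities[heldout], abs=1e-12)

    def test_leakage_is_detectable(self, signal):
        # mutating the held-out sample must not change its fold's panel:
        # if it did, information would be leaking into selection
        matrix, labels = signal
        recipe = _recipe()
        _, details = cv_probabilities(recipe, matrix, labels, CVScheme("loo"),
                                      return_details=True)
        _, test_ids, fold_fit = details[0]
        corrupted = matrix.values.copy()
        col = matrix.sample_ids.index(test_ids[0])
        corrupted[:, col] += 1e6
        m2 = OmicsMatrix(list(matrix.feature_ids), list(matrix.sample_ids),
                         corrupted)
        _, details2 = cv_probabilities(recipe, m2, labels, CVScheme("loo"),
                                       return_details=True)
        assert details2[0][2].panel.feature_ids == fold_fit.panel.feature_ids

    def test_fold_losing_a_class_rejected(self):
        # with a single positive sample, its LOO fold has no positives left
        matrix, labels = make_two_class_matrix(seed=1, n_features=10,
                                               n_pos=1, n_neg=8)
        with pytest.raises(ValueError, match="lost a whole class"):
            cv_probabilities(_recipe(selection=SelectionConfig(top_k=3)),
                             matrix, labels, CVScheme("loo"))


class TestOneSeSelect:
    def test_simpler_model_within_one_se_wins(self):
        # B is simpler and within 1 SE of A's best mean -> B
        cands = [("A", 2, 0.93, 0.05), ("B", 1, 0.90, 0.04)]
        assert one_se_select(cands) == "B"

    def test_outside_one_se_keeps_best(self):
        cands = [("A", 2, 0.93, 0.01), ("B", 1, 0.90, 0.04)]
        assert one_se_select(cands) == "A"

    def test_zero_se_degenerates_to_best(self):
        cands = [("A", 2, 0.93, 0.0), ("B", 1, 0.90, 0.0)]
        assert one_se_select(cands) == "A"

    def test_input_validation(self):
        with pytest.raises(ValueError, match="empty"):
            one_se_select([])
        with pytest.raises(ValueError, match="non-negative"):
            one_se_select([("A", 1, 0.9, -0.1)])


class TestNestedCv:
    def test_degenerate_grid_matches_plain_cv(self, signal):
        matrix, labels = signal
        recipe = _recipe("lda", selection=SelectionConfig(top_k=8),
                         tuning_grid={"lda_n_features": [5]})
        nested_p, chosen = nested_cv(recipe, matrix, labels,
                                     CVScheme("loo"), CVScheme("kfold", k=3, seed=0))
        assert all(s.lda_n_features == 5 for s in chosen)
        plain = cv_probabilities(
            _recipe("lda", learner=LearnerSpec("lda", lda_n_features=5, seed=0),
                    selection=SelectionConfig(top_k=8)),
            matrix, labels, CVScheme("loo"))
        for s in matrix.sample_ids:
            assert nested_p.probabilities[s] == pytest.approx(
                plain.probabilities[s], abs=1e-12)

    def test_grid_tuning_chooses_per_fold(self, signal):
        matrix, labels = signal
        recipe = _recipe("elastic_net",
                         tuning_grid={"en_lambda": [0.01, 1.0]},
                         criterion="min_misclassification")
        probs, chosen = nested_cv(recipe, matrix, labels,
                                  CVScheme("loo"),
                                  CVScheme("kfold", k=3, seed=1))
        assert len(chosen) == matrix.n_samples
        assert all(s.en_lambda in (0.01, 1.0) for s in chosen)
        assert auc(probs, labels) > 0.7  # strong signal must survive tuning

    def test_infeasible_grid_points_dropped(self, signal):
        matrix, labels = signal  # 20 samples -> 19 train in LOO
        recipe = _recipe("lda", selection=SelectionConfig(top_k=25),
                         tuning_grid={"lda_n_features": [5, 500]})
        _, chosen = nested_cv(recipe, matrix, labels, CVScheme("loo"),
                              CVScheme("kfold", k=3, seed=0))
        assert all(s.lda_n_features == 5 for s in chosen)


def test_cv_performance_summary(signal):
    matrix, labels = signal
    probs = cv_probabilities(_recipe(), matrix, labels, CVScheme("loo"))
    perf = cv_performance(probs, labels)
    assert perf.auc == pytest.approx(auc(probs, labels))
    assert 0.0 <= perf.misclassification_error <= 1.0
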