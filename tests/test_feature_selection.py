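import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelfuse.data_model import LabelSet, OmicsMatrix, Scale
from panelfuse.feature_selection import (
    SelectionConfig,
    absolute_count_filter,
    bh_adjust,
    detection_filter,
    ecmr,
    ecmr_prefilter,
    fold_change,
    moderated_t,
    multivariate_rank,
    svm_squared_weights,
    univariate_select,
)
from conftest import make_two_class_matrix


class TestEcmr:
    def test_linear_interpolation_quantiles(self):
        # q(.25) = 25.75, q(.75) = 75.25 under h = (n-1)p + 1
        assert ecmr(np.arange(1.0, 101.0), 0.5) == pytest.approx(49.5, abs=1e-12)

    def test_constant_vector_zero(self):
        assert ecmr(np.full(10, 3.3), 0.2) == 0.0

    def test_iqr_special_case(self):
        # balanced classes: ECMR reduces to the inter-quartile range
        assert ecmr(np.array([2.0, 4.0, 6.0, 8.0]), 0.5) == pytest.approx(3.0, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ecmr(np.array([1.0]), 0.5)
        with pytest.raises(ValueError):
            ecmr(np.array([1.0, 2.0]), 0.6)
        with pytest.raises(ValueError):
            ecmr(np.array([1.0, np.nan, 2.0]), 0.5)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=60),
           st.floats(0.01, 0.5))
    def test_translation_and_scale_equivariance(self, xs, f1):
        x = np.array(xs)
        a, b = 2.5, -7.0
        assert ecmr(a * x + b, f1) == pytest.approx(a * ecmr(x, f1), abs=1e-8, rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 80))
    def test_equals_iqr_at_half(self, seed, n):
        x = np.random.default_rng(seed).normal(size=n)
        q75, q25 = np.percentile(x, [75, 25], method="linear")
        assert ecmr(x, 0.5) == pytest.approx(q75 - q25, abs=1e-12)


class TestEcmrPrefilter:
    @staticmethod
    def _matrix_with_distinct_ecmrs(n_features: int, n_samples: int = 8):
        # feature i is i * linspace: ECMRs strictly increase with i
        base = np.linspace(0.0, 1.0, n_samples)
        values = np.outer(np.arange(1, n_features + 1, dtype=float), base)
        fids = [f"f{i:05d}" for i in range(n_features)]
        sids = [f"s{j}" for j in range(n_samples)]
        labels = LabelSet({s: ("positive" if j < n_samples // 2 else "negative")
                           for j, s in enumerate(sids)})
        return OmicsMatrix(fids, sids, values), labels

    @pytest.mark.parametrize("n,q,expected", [
        (4, 0.5, 2),      # ECMRs 1..4: strictly above median 2.5 keeps 2
        (100, 0.75, 25),  # top quartile
        (101, 0.5, 50),   # odd n: ceil(n/2) - 1
        (2000, 0.5, 1000),
    ])
    def test_strictly_above_rule_counts(self, n, q, expected):
        matrix, labels = self._matrix_with_distinct_ecmrs(n)
        panel = ecmr_prefilter(matrix, labels, q=q)
        assert len(panel) == expected

    def test_panel_ordered_by_descending_ecmr(self):
        matrix, labels = self._matrix_with_distinct_ecmrs(10)
        panel = ecmr_prefilter(matrix, labels, q=0.5)
        scores = [panel.scores[f] for f in panel.feature_ids]
        assert scores == sorted(scores, reverse=True)
        # highest-variation features survive
        assert panel.feature_ids[0] == "f00009"


class TestDetectionFilter:
    def test_boundary_at_min_rate(self):
        # 24/32 observed is exactly 0.75 -> retained; 23/32 -> removed
        values = np.ones((2, 32))
        values[0, :8] = np.nan
        values[1, :9] = np.nan
        m = OmicsMatrix(["kept", "dropped"], [f"s{i}" for i in range(32)],
                        values, scale=Scale.RATIO)
        panel = detection_filter(m, min_rate=0.75)
        assert panel.feature_ids == ["kept"]

    def test_complete_matrix_keeps_all(self, small_matrix):
        assert len(detection_filter(small_matrix)) == small_matrix.n_features


class TestAbsoluteCountFilter:
    def test_count_threshold(self):
        m = OmicsMatrix(["f1"], ["a", "b", "c"], np.array([[5.0, 5.0, 9.0]]))
        assert len(absolute_count_filter(m, 8.0, 1)) == 1
        with pytest.raises(ValueError, match="retained no features"):
            absolute_count_filter(m, 8.0, 2)

    def test_threshold_below_minimum_keeps_all(self, small_matrix):
        panel = absolute_count_filter(small_matrix, -100.0, small_matrix.n_samples)
        assert len(panel) == small_matrix.n_features


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_value(self):
        np.testing.assert_allclose(bh_adjust([1.0]), [1.0])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40),
           st.integers(0, 2**31 - 1))
    def test_permutation_equivariance_and_bounds(self, ps, seed):
        p = np.array(ps)
        adj = bh_adjust(p)
        assert (adj <= 1 + 1e-12).all() and (adj >= 0).all()
        perm = np.random.default_rng(seed).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)
        # monotone in p-rank after step-up
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestFoldChange:
    def test_log2_scale(self):
        m = OmicsMatrix(["f1"], ["a", "b"], np.array([[8.0, 7.0]]))
        labels = LabelSet({"a": "positive", "b": "negative"})
        assert fold_change(m, labels)[0] == pytest.approx(2.0)

    def test_ratio_scale_symmetric_and_cutoff(self):
        m = OmicsMatrix(["f1", "f2"], ["a", "b"],
                        np.array([[1.15, 1.0], [1.0, 1.15]]), scale=Scale.RATIO)
        labels = LabelSet({"a": "positive", "b": "negative"})
        fc = fold_change(m, labels)
        assert fc[0] == pytest.approx(1.15)
        assert fc[1] == pytest.approx(1.15)  # direction-symmetric
        assert (fc >= 1.15).all()

    def test_equal_means_give_one(self):
        m = OmicsMatrix(["f1"], ["a", "b"], np.array([[3.0, 3.0]]))
        labels = LabelSet({"a": "positive", "b": "negative"})
        assert fold_change(m, labels)[0] == pytest.approx(1.0)

    def test_nonpositive_ratio_mean_rejected(self):
        m = OmicsMatrix(["f1"], ["a", "b"], np.array([[-1.0, 1.0]]), scale=Scale.RATIO)
        labels = LabelSet({"a": "positive", "b": "negative"})
        with pytest.raises(ValueError, match="fold change undefined"):
            fold_change(m, labels)


class TestModeratedT:
    def test_d0_zero_recovers_ordinary_t(self):
        from scipy import stats as sps

        matrix, labels = make_two_class_matrix(seed=3)
        st_ = moderated_t(matrix, labels, d0=0)
        y = labels.y(matrix.sample_ids)
        pos = matrix.values[:, y == 1]
        neg = matrix.values[:, y == 0]
        t_ref, p_ref = sps.ttest_ind(pos, neg, axis=1, equal_var=True)
        np.testing.assert_allclose(st_.t, t_ref, atol=1e-10)
        np.testing.assert_allclose(st_.p, p_ref, atol=1e-10)

    def test_identical_class_means_give_zero_t(self):
        values = np.array([[1.0, 2.0, 1.0, 2.0], [1.0, 1.0, 2.0, 2.0]])
        m = OmicsMatrix(["same", "diff"], ["a", "b", "c", "d"], values)
        labels = LabelSet({"a": "positive", "b": "positive",
                           "c": "negative", "d": "negative"})
        st_ = moderated_t(m, labels, d0=0)
        assert st_.t[0] == pytest.approx(0.0, abs=1e-12)
        assert st_.p[0] == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_oracle(self):
        # independent re-derivation of the shrinkage formulas at fixed prior
        matrix, labels = make_two_class_matrix(seed=7, n_features=20)
        d0, s0 = 4.0, 1.3
        st_ = moderated_t(matrix, labels, d0=d0, s0_2=s0)
        from scipy import stats as sps

        y = labels.y(matrix.sample_ids)
        pos, neg = matrix.values[:, y == 1], matrix.values[:, y == 0]
        n1, n2 = pos.shape[1], neg.shape[1]
        d = n1 + n2 - 2
        s2 = (pos.var(axis=1, ddof=1) * (n1 - 1) + neg.var(axis=1, ddof=1) * (n2 - 1)) / d
        s2t = (d0 * s0 + d * s2) / (d0 + d)
        t = (pos.mean(axis=1) - neg.mean(axis=1)) / np.sqrt(s2t * (1 / n1 + 1 / n2))
        p = 2 * sps.t.sf(np.abs(t), d0 + d)
        np.testing.assert_allclose(st_.t, t, atol=1e-10)
        np.testing.assert_allclose(st_.p, p, atol=1e-10)

    def test_matches_limma_reference(self):
        # limma's eBayes on the same matrix is the independent reference for
        # the estimated variance prior and the moderated statistics
        matrix, labels = make_two_class_matrix(seed=42, n_features=40)
        st_ = moderated_t(matrix, labels)
        with tempfile.TemporaryDirectory() as td:
            xp = Path(td) / "x.txt"
            np.savetxt(xp, matrix.values)
            y = labels.y(matrix.sample_ids)
            script = f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.table("{xp}"))
            design <- cbind(1, c({','.join(map(str, y))}))
            fit <- eBayes(lmFit(x, design))
            write.table(cbind(fit$df.prior, fit$s2.prior, fit$t[,2], fit$p.value[,2]),
                        "{td}/out.txt", row.names=FALSE, col.names=FALSE)
            """
            subprocess.run(["Rscript", "-e", script], check=True,
                           capture_output=True)
            ref = np.loadtxt(Path(td) / "out.txt")
        assert st_.d0 == pytest.approx(ref[0, 0], rel=1e-5)
        assert st_.s0_2 == pytest.approx(ref[0, 1], rel=1e-5)
        np.testing.assert_allclose(st_.t, ref[:, 2], atol=1e-6)
        np.testing.assert_allclose(st_.p, ref[:, 3], atol=1e-6)

    def test_requires_two_per_class(self):
        m = OmicsMatrix(["f1"], ["a", "b", "c"], np.array([[1.0, 2.0, 3.0]]))
        labels = LabelSet({"a": "positive", "b": "negative", "c": "negative"})
        with pytest.raises(ValueError, match="at least 2"):
            moderated_t(m, labels)


class TestUnivariateSelect:
    @staticmethod
    def _stats(n: int = 100, seed: int = 1, shift: float = 2.0):
        matrix, labels = make_two_class_matrix(seed=seed, n_features=n,
                                               n_shifted=n // 2, shift=shift)
        return moderated_t(matrix, labels)

    def test_max_panel_truncates(self):
        # shift=4 makes >50 features pass FDR 0.05; max_panel cuts to 50
        stats = self._stats(100, shift=4.0)
        assert (stats.fdr <= 0.05).sum() > 50
        panel = univariate_select(stats, SelectionConfig(fdr_cut=0.05, max_panel=50))
        assert len(panel) == 50

    def test_min_panel_extends_with_next_best(self):
        stats = self._stats(200)
        cfg = SelectionConfig(fdr_cut=1e-12, min_panel=50)  # almost nothing passes
        panel = univariate_select(stats, cfg)
        assert len(panel) == 50

    def test_top_k_mode(self):
        stats = self._stats(60)
        panel = univariate_select(stats, SelectionConfig(top_k=3))
        assert len(panel) == 3
        fdrs = [stats.fdr[stats.feature_ids.index(f)] for f in panel.feature_ids]
        assert fdrs == sorted(fdrs)

    def test_size_bounds_invariant(self):
        stats = self._stats(80)
        for fdr_cut in (0.001, 0.05, 0.5):
            cfg = SelectionConfig(fdr_cut=fdr_cut, fc_cut=1.1,
                                  min_panel=10, max_panel=40)
            panel = univariate_select(stats, cfg)
            assert 10 <= len(panel) <= 40


class TestMultivariateRank:
    def test_svm_importance_prefers_separating_feature(self):
        # feature A separates perfectly, feature B is noise
        values = np.array([
            [1.0, 1.2, 0.9, 1.1, -1.0, -1.1, -0.9, -1.2],
            [0.3, -0.2, 0.1, -0.1, 0.2, -0.3, 0.1, -0.1],
        ])
        sids = [f"s{i}" for i in range(8)]
        m = OmicsMatrix(["A", "B"], sids, values)
        labels = LabelSet({s: ("positive" if i < 4 else "negative")
                           for i, s in enumerate(sids)})
        from panelfuse.data_model import FeaturePanel

        panel = FeaturePanel(["B", "A"], {"A": 0.0, "B": 0.0}, stage="univariate")
        ranked = multivariate_rank(m, labels, panel, svm_squared_weights, top_m=2)
        assert ranked.feature_ids[0] == "A"
        assert ranked.scores["A"] > ranked.scores["B"]

    def test_all_equal_importance_keeps_order(self, small_matrix, small_labels):
        from panelfuse.data_model import FeaturePanel

        panel = FeaturePanel(["f2", "f3", "f1"], {f: 0.0 for f in "f1 f2 f3".split()},
                             stage="univariate")
        ranked = multivariate_rank(small_matrix, small_labels, panel,
                                   lambda X, y: np.ones(X.shape[1]), top_m=3)
        assert ranked.feature_ids == ["f2", "f3", "f1"]

    def test_top_m_equal_panel_size_keeps_membership(self, small_matrix, small_labels):
        from panelfuse.data_model import FeaturePanel

        panel = FeaturePanel(["f1", "f2", "f3"], {f: 0.0 for f in "f1 f2 f3".split()})
        ranked = multivariate_rank(small_matrix, small_labels, panel,
                                   svm_squared_weights, top_m=3)
        assert set(ranked.feature_ids) == set(panel.feature_ids)
        with pytest.raises(ValueError, match="exceeds panel size"):
            multivariate_rank(small_matrix, small_labels, panel,
                              svm_squared_weights, top_m=4)
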