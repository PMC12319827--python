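"""Feature classes, normalization order, and leakage-freedom."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scpredict import (
    CorrelationEdgeSelector,
    GlobalMinMaxScaler,
    PipelineFeatures,
    devectorize_upper,
    extract_rcp,
    fit_pca,
    log10_transform,
    project,
    vectorize_upper,
)


def _sym(n, rng):
    m = rng.normal(size=(n, n))
    m = m + m.T
    np.fill_diagonal(m, 0.0)
    return m


class TestVectorize:
    def test_enumeration_order(self):
        m = np.array([[0, 1.0, 2.0], [1.0, 0, 3.0], [2.0, 3.0, 0]])
        assert np.array_equal(vectorize_upper(m), [1.0, 2.0, 3.0])

    def test_length_for_70_regions(self):
        rng = np.random.default_rng(0)
        assert vectorize_upper(_sym(70, rng)).size == 2415

    def test_asymmetric_rejected(self):
        m = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            vectorize_upper(m)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=15), st.integers(0, 10_000))
    def test_roundtrip(self, n, seed):
        m = _sym(n, np.random.default_rng(seed))
        assert np.allclose(devectorize_upper(vectorize_upper(m), n), m)


class TestLog10:
    def test_values(self):
        out = log10_transform(np.array([1000.0, 0.0, 1.0, 10.0]))
        assert np.array_equal(out, [3.0, 0.0, 0.0, 1.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            log10_transform(np.array([-1.0]))


class TestGlobalMinMax:
    def test_global_extremes_and_scaling(self):
        X = np.array([[2.0, 5.0], [7.0, 10.0]])
        sc = GlobalMinMaxScaler().fit(X)
        assert (sc.train_min_, sc.train_max_) == (2.0, 10.0)
        out = sc.transform(np.array([[6.0, 2.0], [10.0, 12.0]]))
        assert np.allclose(out, [[0.5, 0.0], [1.0, 1.25]])  # no clipping

    def test_shape_independent_of_layout(self):
        vals = np.array([1.0, 3.0, 4.0, 9.0])
        a = GlobalMinMaxScaler().fit(vals.reshape(4, 1))
        b = GlobalMinMaxScaler().fit(vals.reshape(2, 2))
        assert (a.train_min_, a.train_max_) == (b.train_min_, b.train_max_)

    def test_training_values_land_in_unit_interval(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 7)) * 40
        out = GlobalMinMaxScaler().fit(X).transform(X)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_training_matrix_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            GlobalMinMaxScaler().fit(np.full((3, 2), 5.0))


class TestCorrelationEdgeSelector:
    def test_toy_table_selects_exact_edge(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([y, np.full(4, 2.0), [0.1, -0.3, 0.2, 0.0]])
        sel = CorrelationEdgeSelector(k=1).fit(X, y)
        assert list(sel.selected_indices_) == [0]
        assert sel.correlations_[1] == 0.0  # constant edge

    def test_full_k_orders_by_absolute_correlation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        sel = CorrelationEdgeSelector(k=8).fit(X, y)
        r = np.abs(sel.correlations_)
        assert np.all(np.diff(r[sel.selected_indices_]) <= 1e-15)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(4, 50), st.integers(1, 20))
    def test_agrees_with_brute_force(self, seed, n, k):
        rng = np.random.default_rng(seed)
        n_edges = max(k, 3)
        X = rng.normal(size=(n, n_edges))
        y = rng.normal(size=n)
        sel = CorrelationEdgeSelector(k=k).fit(X, y)
        brute = np.array([np.corrcoef(X[:, j], y)[0, 1] for j in range(n_edges)])
        order = sorted(range(n_edges), key=lambda j: (-abs(brute[j]), j))
        assert list(sel.selected_indices_) == order[:k]

    def test_signed_ranking_variant(self):
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([-y, y * 0.5 + np.array([0, 0.1, -0.1, 0.1, 0])])
        assert list(
            CorrelationEdgeSelector(k=1, ranking="signed").fit(X, y).selected_indices_
        ) == [1]
        assert list(
            CorrelationEdgeSelector(k=1, ranking="absolute").fit(X, y).selected_indices_
        ) == [0]

    def test_k_out_of_range_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError):
            CorrelationEdgeSelector(k=4).fit(X, np.arange(5.0))


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=6)
        X = np.outer(rng.normal(size=15), direction)
        basis = fit_pca(X, 1)
        assert basis.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_training_mean_projects_to_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 5))
        basis = fit_pca(X, 3)
        assert np.allclose(project(basis, X.mean(axis=0)[None, :]), 0.0, atol=1e-12)

    def test_full_rank_reconstruction_and_variance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 4))
        basis = fit_pca(X, 4)
        rec = project(basis, X) @ basis.components_ + basis.mean_
        assert np.allclose(rec, X, atol=1e-10)
        assert basis.explained_variance_.sum() == pytest.approx(
            np.var(X, axis=0, ddof=1).sum()
        )

    def test_k_beyond_rank_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.random.default_rng(0).normal(size=(5, 10)), 6)


class TestExtractRcp:
    def test_row_extraction_keeps_self_connection_zero(self):
        m = np.array([[0, 1.0, 2.0], [1.0, 0, 3.0], [2.0, 3.0, 0]])
        assert np.array_equal(extract_rcp(m, 1), [1.0, 0.0, 3.0])

    def test_row_equals_column(self):
        rng = np.random.default_rng(5)
        m = _sym(6, rng)
        assert np.array_equal(extract_rcp(m, 2), m[:, 2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            extract_rcp(np.zeros((3, 3)), 3)


def _population(rng, n, R):
    mats = np.stack([_sym(R, rng) for _ in range(n)])
    return mats


class TestBuildOrderOfOperations:
    def test_corr_normalizer_sees_only_selected_columns(self):
        """The min-max pair comes from the selected training edges alone."""
        n, R = 14, 4  # 6 edges
        rng = np.random.default_rng(0)
        train, test = np.arange(12), np.arange(12, 14)
        y = np.zeros(n)
        y[train] = np.linspace(0.0, 1.0, 12)
        edges = rng.uniform(0.2, 0.8, size=(n, 6))
        edges[train, 0] = np.linspace(0.1, 0.9, 12)        # correlated with y
        edges[train, 1] = np.linspace(0.9, 0.1, 12)        # anti-correlated
        edges[train, 2] = rng.uniform(0, 100, size=12)     # wide unselected span
        edges[train, 3] = 0.0
        mats = np.stack([devectorize_upper(e, R) for e in edges])
        feats = PipelineFeatures(mats, "FA", "corr")
        xtr, _, state = feats.build(train, test, y[train], 2)
        assert set(state["selector"].selected_indices_) == {0, 1}
        assert state["scaler"].train_min_ == pytest.approx(0.1)
        assert state["scaler"].train_max_ == pytest.approx(0.9)

    def test_pca_normalizer_fitted_on_full_edge_matrix(self):
        rng = np.random.default_rng(1)
        mats = _population(rng, 20, 6)
        feats = PipelineFeatures(mats, "FA", "pca")
        train, test = np.arange(15), np.arange(15, 20)
        _, _, state = feats.build(train, test, None, 3)
        iu = np.triu_indices(6, 1)
        train_edges = mats[train][:, iu[0], iu[1]]
        assert state["scaler"].train_min_ == train_edges.min()
        assert state["scaler"].train_max_ == train_edges.max()

    def test_whole_brain_feature_count(self):
        rng = np.random.default_rng(2)
        mats = _population(rng, 8, 3)
        feats = PipelineFeatures(mats, "FA", "whole-brain")
        xtr, xte, _ = feats.build(np.arange(6), np.arange(6, 8))
        assert xtr.shape == (6, 3) and xte.shape == (2, 3)

    def test_nos_log_transform_applied_before_anything(self):
        mats = np.zeros((3, 3, 3))
        mats[:, 0, 1] = mats[:, 1, 0] = [1.0, 10.0, 100.0]
        mats[:, 0, 2] = mats[:, 2, 0] = [5.0, 5.0, 10.0]
        feats = PipelineFeatures(mats, "NOS", "whole-brain")
        assert np.allclose(feats._edges[:, 0], [0.0, 1.0, 2.0])

    def test_overlapping_indices_rejected(self):
        mats = _population(np.random.default_rng(3), 6, 4)
        feats = PipelineFeatures(mats, "FA", "whole-brain")
        with pytest.raises(ValueError, match="overlap"):
            feats.build(np.arange(4), np.arange(3, 6))


class TestLeakageFreedom:
    """Mutating test-set data leaves every fitted transformer bit-identical."""

    @pytest.mark.parametrize("feature_class,param", [
        ("corr", 4), ("pca", 3), ("whole-brain", None), ("rcp", 2),
    ])
    def test_test_set_mutation_invisible_to_fit(self, feature_class, param):
        rng = np.random.default_rng(7)
        mats = _population(rng, 25, 8)
        y = rng.normal(size=25)
        train, test = np.arange(18), np.arange(18, 25)

        mutated = mats.copy()
        mutated[test] = _population(np.random.default_rng(99), 7, 8)

        state_a = PipelineFeatures(mats, "FA", feature_class).build(
            train, test, y[train], param
        )[2]
        state_b = PipelineFeatures(mutated, "FA", feature_class).build(
            train, test, y[train], param
        )[2]
        for key in state_a:
            a, b = state_a[key], state_b[key]
            if key == "scaler":
                assert a.train_min_ == b.train_min_
                assert a.train_max_ == b.train_max_
            elif key == "selector":
                assert np.array_equal(a.selected_indices_, b.selected_indices_)
                assert np.array_equal(a.correlations_, b.correlations_)
            elif key == "pca":
                assert np.array_equal(a.components_, b.components_)
                assert np.array_equal(a.mean_, b.mean_)

    def test_test_target_mutation_invisible_to_selection(self):
        rng = np.random.default_rng(8)
        mats = _population(rng, 20, 6)
        y = rng.normal(size=20)
        y2 = y.copy()
        y2[15:] += 100.0  # only test-set targets change
        train, test = np.arange(15), np.arange(15, 20)
        feats = PipelineFeatures(mats, "FA", "corr")
        sel_a = feats.build(train, test, y[train], 3)[2]["selector"]
        sel_b = feats.build(train, test, y2[train], 3)[2]["selector"]
        assert np.array_equal(sel_a.selected_indices_, sel_b.selected_indices_)
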