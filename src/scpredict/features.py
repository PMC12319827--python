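"""Feature classes and normalization for connectome-based prediction.

Four feature classes are supported: the vectorized upper triangle of the
connectome (``whole-brain``), the k edges most correlated with the target
over training subjects (``corr``), the first k principal components of the
normalized connectome (``pca``), and single regional connectivity profiles
— rows of the connectome (``rcp``).

All data-dependent fitting (the global min-max normalizer, the edge
ranking, the PCA basis) is restricted to training subjects; fitted state
is bit-identical under any change to test-set data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

FEATURE_CLASSES: tuple[str, ...] = ("whole-brain", "corr", "pca", "rcp")


def vectorize_upper(connectome) -> np.ndarray:
    """Upper triangle (without diagonal) in fixed row-major i<j order.

    Accepts a Connectome or a symmetric square matrix; returns a vector of
    length R(R-1)/2.
    """
    m = np.asarray(getattr(connectome, "matrix", connectome), dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("connectome must be a square matrix")
    if not np.allclose(m, m.T):
        raise ValueError("connectome must be symmetric")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def devectorize_upper(vec: np.ndarray, n_rois: int) -> np.ndarray:
    """Rebuild the symmetric zero-diagonal matrix from its edge vector."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != n_rois * (n_rois - 1) // 2:
        raise ValueError("edge vector length does not match n_rois")
    m = np.zeros((n_rois, n_rois))
    iu = np.triu_indices(n_rois, k=1)
    m[iu] = vec
    return m + m.T


def log10_transform(features: np.ndarray) -> np.ndarray:
    """log10 of all values > 0; zeros stay 0 (for streamline counts).

    Note log10(1) = 0 collides with untouched zeros; on integer counts
    this only merges the 0- and 1-streamline bins.
    """
    x = np.asarray(features, dtype=float)
    if (x < 0).any():
        raise ValueError("log10 transform requires nonnegative values")
    return np.where(x > 0, np.log10(np.maximum(x, 1e-300)), 0.0)


class GlobalMinMaxScaler(TransformerMixin, BaseEstimator):
    """Min-max scaling with ONE global (min, max) pair over all entries.

    x_norm = (x - train_min) / (train_max - train_min), where train_min and
    train_max are the single smallest and largest values over the entire
    training matrix — not per column. Training values land in [0, 1]; test
    values outside the training range are not clipped.

    Parameters
    ----------
    per_feature : bool, default False
        Column-wise (min, max) pairs instead of one global pair.

    Attributes
    ----------
    train_min_, train_max_ : float or (n_features,) arrays when per_feature.
    """

    def __init__(self, per_feature: bool = False):
        self.per_feature = per_feature

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=True, dtype=float)
        if self.per_feature:
            self.train_min_ = X.min(axis=0)
            self.train_max_ = X.max(axis=0)
            if np.any(self.train_max_ <= self.train_min_):
                raise ValueError("degenerate normalization: constant feature column")
        else:
            self.train_min_ = float(X.min())
            self.train_max_ = float(X.max())
            if self.train_max_ <= self.train_min_:
                raise ValueError("degenerate normalization: all training values equal")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "train_min_")
        X = check_array(X, ensure_2d=True, dtype=float)
        return (X - self.train_min_) / (self.train_max_ - self.train_min_)


class CorrelationEdgeSelector(TransformerMixin, BaseEstimator):
    """Select the k features most correlated with the target on training data.

    Per-feature Pearson correlation with the target is computed over
    training subjects only; features are ranked by absolute correlation
    descending (``ranking='signed'`` ranks by signed value instead), ties
    broken by ascending feature index, and the top k kept. Constant
    features get correlation 0.

    Attributes
    ----------
    correlations_ : (n_features,) training correlations.
    selected_indices_ : (k,) column indices in rank order.
    """

    def __init__(self, k: int = 10, ranking: str = "absolute"):
        self.k = k
        self.ranking = ranking

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if X.shape[0] < 3:
            raise ValueError("edge selection needs at least 3 training subjects")
        if not 1 <= self.k <= X.shape[1]:
            raise ValueError(f"k={self.k} outside 1..{X.shape[1]} features")
        if self.ranking not in ("absolute", "signed"):
            raise ValueError("ranking must be 'absolute' or 'signed'")
        xc = X - X.mean(axis=0)
        yc = y - y.mean()
        sx = xc.std(axis=0)
        sy = yc.std()
        r = np.zeros(X.shape[1])
        ok = (sx > 0) & (sy > 0)
        if sy > 0:
            r[ok] = (xc[:, ok] * yc[:, None]).mean(axis=0) / (sx[ok] * sy)
        self.correlations_ = r
        score = np.abs(r) if self.ranking == "absolute" else r
        # stable rank: descending score, ties by ascending index
        order = np.lexsort((np.arange(X.shape[1]), -score))
        self.selected_indices_ = order[: self.k]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_indices_")
        X = check_array(X, dtype=float)
        return X[:, self.selected_indices_]


def fit_global_minmax(train_features: np.ndarray) -> GlobalMinMaxScaler:
    """Fit the global min-max normalizer on a training feature matrix."""
    return GlobalMinMaxScaler().fit(np.asarray(train_features, dtype=float))

def apply_minmax(normalizer: GlobalMinMaxScaler, features: np.ndarray) -> np.ndarray:
    return normalizer.transform(np.asarray(features, dtype=float))

def select_corr_edges(
    train_features: np.ndarray, train_targets: np.ndarray, k: int,
    ranking: str = "absolute",
) -> CorrelationEdgeSelector:
    """Fit the top-k correlated-edge selector on training data only."""
    return CorrelationEdgeSelector(k=k, ranking=ranking).fit(
        train_features, train_targets
    )

def fit_pca(train_features_normalized: np.ndarray, k: int) -> PCA:
    """PCA basis (k orthonormal components, training mean) fit on training data."""
    x = np.asarray(train_features_normalized, dtype=float)
    if k > min(x.shape[0] - 1, x.shape[1]):
        raise ValueError("k exceeds the available PCA rank")
    return PCA(n_components=k, svd_solver="full").fit(x)

def project(basis: PCA, features: np.ndarray) -> np.ndarray:
    """Scores: center by the training mean, project on the components."""
    return basis.transform(np.asarray(features, dtype=float))


def extract_rcp(connectome, roi_index: int) -> np.ndarray:
    """One regional connectivity profile: the full row of the connectome.

    ``roi_index`` is 0-based. The zero self-connection entry is kept, so
    the vector has length R.
    """
    m = np.asarray(getattr(connectome, "matrix", connectome), dtype=float)
    if not 0 <= roi_index < m.shape[0]:
        raise ValueError(f"roi_index {roi_index} outside 0..{m.shape[0] - 1}")
    return m[roi_index].copy()


@dataclass
class PipelineFeatures:
    """Per-pipeline feature substrate with leakage-free fold-wise building.

    Precomputes the target-independent part once (log10 transform of NOS
    weights, edge vectorization); per-fold building then fits the
    normalizer / edge selector / PCA basis on training subjects only.

    The order of operations matches the prediction protocol: for the PCA
    class the normalizer is fit on the full vectorized connectome of the
    training set before the PCA; for whole-brain, corr and rcp the features
    are extracted/selected first and the normalizer is fit on the selected
    training columns only.
    """

    matrices: np.ndarray  # (n_subjects, R, R)
    weighting: str
    feature_class: str
    ranking: str = "absolute"
    per_feature_norm: bool = False
    _edges: np.ndarray = field(init=False, repr=False)
    _rows: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        mats = np.asarray(self.matrices, dtype=float)
        if mats.ndim != 3 or mats.shape[1] != mats.shape[2]:
            raise ValueError("matrices must be (n_subjects, R, R)")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.weighting.upper() == "NOS":
            mats = log10_transform(mats)
        self._rows = mats
        iu = np.triu_indices(mats.shape[1], k=1)
        self._edges = mats[:, iu[0], iu[1]]

    @property
    def n_subjects(self) -> int:
        return self._rows.shape[0]

    @property
    def n_rois(self) -> int:
        return self._rows.shape[1]

    @property
    def n_edges(self) -> int:
        return self._edges.shape[1]

    def default_param(self):
        """Feature-selection parameter for classes that need none."""
        return None

    def build(
        self,
        train_idx: np.ndarray,
        test_idx: np.ndarray,
        y_train: np.ndarray | None = None,
        param: int | None = None,
    ) -> tuple[np.ndarray, np.ndarray, dict[str, Any]]:
        """Train/test feature matrices plus the fitted transformer state.

        ``param`` is the feature-selection case: k for corr/pca, the
        0-based region index for rcp, ignored (None) for whole-brain.
        """
        train_idx = np.asarray(train_idx, dtype=np.int64)
        test_idx = np.asarray(test_idx, dtype=np.int64)
        if np.intersect1d(train_idx, test_idx).size:
            raise ValueError("train and test indices overlap")
        state: dict[str, Any] = {}

        if self.feature_class == "whole-brain":
            xtr, xte = self._edges[train_idx], self._edges[test_idx]
        elif self.feature_class == "corr":
            if y_train is None:
                raise ValueError("corr feature class needs training targets")
            sel = CorrelationEdgeSelector(k=int(param), ranking=self.ranking).fit(
                self._edges[train_idx], np.asarray(y_train, dtype=float)
            )
            state["selector"] = sel
            xtr = sel.transform(self._edges[train_idx])
            xte = sel.transform(self._edges[test_idx])
        elif self.feature_class == "pca":
            scaler = GlobalMinMaxScaler(per_feature=self.per_feature_norm).fit(
                self._edges[train_idx]
            )
            state["scaler"] = scaler
            basis = fit_pca(scaler.transform(self._edges[train_idx]), int(param))
            state["pca"] = basis
            return (
                basis.transform(scaler.transform(self._edges[train_idx])),
                basis.transform(scaler.transform(self._edges[test_idx])),
                state,
            )
        else:  # rcp
            xtr = self._rows[train_idx, int(param), :]
            xte = self._rows[test_idx, int(param), :]

        scaler = GlobalMinMaxScaler(per_feature=self.per_feature_norm).fit(xtr)
        state["scaler"] = scaler
        return scaler.transform(xtr), scaler.transform(xte), state


def build_features(
    feature_class: str,
    matrices: np.ndarray,
    train_indices: np.ndarray,
    test_indices: np.ndarray,
    train_targets: np.ndarray | None = None,
    weighting: str = "NOS",
    param: int | None = None,
    ranking: str = "absolute",
) -> tuple[np.ndarray, np.ndarray, dict[str, Any]]:
    """One-shot feature building (thin wrapper over PipelineFeatures)."""
    feats = PipelineFeatures(matrices, weighting, feature_class, ranking=ranking)
    return feats.build(train_indices, test_indices, train_targets, param)
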