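"""Repeated nested 5-fold cross-validation for connectome pipelines.

The outer loop estimates out-of-sample accuracy (Pearson r between
predicted and observed targets, averaged over the 5 test folds); the
inner loop chooses the ridge regularization alpha — and optionally the
feature-selection case — by mean inner-fold correlation. The whole
procedure is repeated over independent random splits (100 by default) to
yield a distribution of prediction results; split schemes are a pure
function of (n_subjects, master seed), so they are consistent across
pipelines run on the same subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CVDistribution
from .features import PipelineFeatures
from .ridge import DEFAULT_ALPHA_GRID, RidgeRegressor, pearson_r, ridge_predict_path

N_FOLDS = 5
N_REPEATS = 100


@dataclass(frozen=True)
class SplitScheme:
    """Outer and inner fold assignments for every repeat.

    ``outer[r, s]`` is subject s's outer fold (0..4) in repeat r;
    ``inner[r, f, s]`` is the inner fold (0..4) of subject s within the
    training set of outer fold f, or -1 when s belongs to the test fold.
    Per-repeat child seeds are spawned from the master seed keyed by the
    repeat index, so extending n_repeats never perturbs earlier repeats.
    """

    n_subjects: int
    master_seed: int
    outer: np.ndarray
    inner: np.ndarray

    @property
    def n_repeats(self) -> int:
        return self.outer.shape[0]

    @property
    def n_folds(self) -> int:
        return self.inner.shape[1]


def _fold_ids(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random partition into n_folds near-equal folds (sizes differ by <= 1)."""
    ids = np.repeat(np.arange(n_folds), np.diff(np.linspace(0, n, n_folds + 1).astype(int)))
    return ids[rng.permutation(n)]


def make_splits(
    n_subjects: int,
    master_seed: int,
    n_repeats: int = N_REPEATS,
    n_folds: int = N_FOLDS,
) -> SplitScheme:
    """Repeated outer/inner fold assignments, reproducible from the seed."""
    if n_subjects < 10:
        raise ValueError("need at least 10 subjects for nested 5-fold CV")
    outer = np.empty((n_repeats, n_subjects), dtype=np.int8)
    inner = np.empty((n_repeats, n_folds, n_subjects), dtype=np.int8)
    for r in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([int(master_seed), r]))
        outer[r] = _fold_ids(n_subjects, n_folds, rng)
        for f in range(n_folds):
            train = np.flatnonzero(outer[r] != f)
            inner[r, f] = -1
            inner[r, f, train] = _fold_ids(train.size, n_folds, rng)
    return SplitScheme(n_subjects, int(master_seed), outer, inner)


def inner_select(
    feats: PipelineFeatures,
    y: np.ndarray,
    subjects: np.ndarray,
    inner_fold_ids: np.ndarray,
    alpha_grid=DEFAULT_ALPHA_GRID,
    feature_params=None,
    scoring: str = "pearson",
):
    """Grid search over (feature case, alpha) by mean inner-fold score.

    For every combination: fit on 4 inner folds, score the held-out inner
    fold, average over the 5 folds. Ties are broken toward larger alpha,
    then the smaller (earlier) feature parameter. ``feature_params=None``
    is alpha-only mode using the feature class's fixed case.

    Returns (alpha*, feature_param*, score matrix of shape
    (n_params, n_alphas)).
    """
    alphas = np.asarray(alpha_grid, dtype=float)
    if alphas.size == 0:
        raise ValueError("empty alpha grid")
    params = list(feature_params) if feature_params is not None else [
        feats.default_param()
    ]
    if len(params) == 0:
        raise ValueError("empty feature grid")
    subjects = np.asarray(subjects, dtype=np.int64)
    fold_ids = np.asarray(inner_fold_ids)
    y = np.asarray(y, dtype=float)

    folds = np.unique(fold_ids[fold_ids >= 0])
    scores = np.zeros((len(params), alphas.size))
    for f in folds:
        tr = subjects[fold_ids[subjects] != f]
        te = subjects[fold_ids[subjects] == f]
        for ip, p in enumerate(params):
            xtr, xte, _ = feats.build(tr, te, y[tr], p)
            preds = ridge_predict_path(xtr, y[tr], xte, alphas)
            for ia in range(alphas.size):
                if scoring == "pearson":
                    scores[ip, ia] += pearson_r(preds[ia], y[te])
                elif scoring == "neg_mse":
                    scores[ip, ia] += -float(np.mean((preds[ia] - y[te]) ** 2))
                else:
                    raise ValueError(f"unknown scoring {scoring!r}")
    scores /= folds.size

    # argmax with ties -> larger alpha, then smaller feature parameter index
    best_ip, best_ia = 0, 0
    best = -np.inf
    for ip in range(len(params)):
        for ia in range(alphas.size):
            s = scores[ip, ia]
            if s > best or (s == best and ip == best_ip and alphas[ia] > alphas[best_ia]):
                best, best_ip, best_ia = s, ip, ia
    return float(alphas[best_ia]), params[best_ip], scores


def run_nested_cv(
    feats: PipelineFeatures,
    y: np.ndarray,
    outer_fold_ids: np.ndarray,
    inner_fold_ids: np.ndarray,
    alpha_grid=DEFAULT_ALPHA_GRID,
    feature_params=None,
    fixed_param=None,
    scoring: str = "pearson",
) -> float:
    """One repeat of the nested CV: mean test-fold correlation.

    For each outer fold, hyperparameters are chosen by ``inner_select`` on
    the outer-training subjects, the model is refit on the full training
    set and scored on the held-out fold; the 5 fold correlations are
    averaged into a single prediction result.
    """
    y = np.asarray(y, dtype=float)
    outer_fold_ids = np.asarray(outer_fold_ids)
    rs = []
    for f in range(int(outer_fold_ids.max()) + 1):
        te = np.flatnonzero(outer_fold_ids == f)
        tr = np.flatnonzero(outer_fold_ids != f)
        params = feature_params if feature_params is not None else [fixed_param]
        alpha, param, _ = inner_select(
            feats, y, tr, inner_fold_ids[f], alpha_grid, params, scoring=scoring,
        )
        xtr, xte, _ = feats.build(tr, te, y[tr], param)
        model = RidgeRegressor(alpha=alpha).fit(xtr, y[tr])
        rs.append(pearson_r(model.predict(xte), y[te]))
    return float(np.mean(rs))


def run_repeated(
    feats: PipelineFeatures,
    y: np.ndarray,
    scheme: SplitScheme,
    alpha_grid=DEFAULT_ALPHA_GRID,
    feature_params=None,
    fixed_param=None,
    pipeline_id: str = "",
    scoring: str = "pearson",
) -> CVDistribution:
    """Nested CV over every repeat of the split scheme -> result distribution."""
    if scheme.n_subjects != feats.n_subjects or scheme.n_subjects != len(y):
        raise ValueError("split scheme does not match the data")
    values = np.array([
        run_nested_cv(
            feats, y, scheme.outer[r], scheme.inner[r], alpha_grid,
            feature_params=feature_params, fixed_param=fixed_param, scoring=scoring,
        )
        for r in range(scheme.n_repeats)
    ])
    return CVDistribution(values, pipeline_id)


def permutation_baseline(
    feats: PipelineFeatures,
    y: np.ndarray,
    scheme: SplitScheme,
    perm_seed: int,
    alpha_grid=DEFAULT_ALPHA_GRID,
    feature_params=None,
    fixed_param=None,
    pipeline_id: str = "",
) -> CVDistribution:
    """Null distribution: targets shuffled between subjects, once per repeat.

    The CV splits are reused unchanged; only the target-to-subject
    assignment is permuted (with a repeat-specific permutation derived from
    ``perm_seed``), breaking any real connectome-target association while
    preserving the target's marginal distribution.
    """
    y = np.asarray(y, dtype=float)
    values = np.empty(scheme.n_repeats)
    for r in range(scheme.n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([int(perm_seed), r, 0xBE]))
        y_perm = y[rng.permutation(y.size)]
        values[r] = run_nested_cv(
            feats, y_perm, scheme.outer[r], scheme.inner[r], alpha_grid,
            feature_params=feature_params, fixed_param=fixed_param,
        )
    return CVDistribution(values, pipeline_id or "permutation")
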