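"""Pipeline enumeration, sweep execution and summary statistics.

A "pipeline" is one cell of the benchmarking design: (parcellation x
connectome weighting x subject group x feature class x target). Each cell
is evaluated under repeated nested cross-validation, for every feature-
selection case of its feature class, yielding one accuracy distribution
per case. Summaries cover Cohen's d between condition distributions, the
fraction of results above an accuracy threshold, the post-hoc "best of all
cases" protocol, and the audit quantifying how much that post-hoc
selection inflates accuracy relative to selecting the case inside the
inner cross-validation loop.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import TRAITS, WEIGHTINGS, CVDistribution
from .crossval import SplitScheme, permutation_baseline, run_repeated
from .features import FEATURE_CLASSES, PipelineFeatures
from .ridge import DEFAULT_ALPHA_GRID

# fixed feature-count cases for the corr and pca classes; the parcellation's
# region count is appended as the 19th case
FEATURE_K_GRID: tuple[int, ...] = (
    1, 2, 3, 4, 5, 10, 15, 20, 30, 40, 50, 60, 70, 80, 90, 100, 150, 200,
)
SUBJECT_GROUPS: tuple[str, ...] = ("mixed", "female", "male")
PROMISING_THRESHOLD = 0.2  # accuracy regarded as a promising prediction


@dataclass(frozen=True)
class PipelineConfig:
    """One cell of the benchmarking design."""

    parcellation: str
    weighting: str
    group: str
    feature_class: str
    target: str

    @property
    def pipeline_id(self) -> str:
        return "|".join(
            (self.parcellation, self.weighting, self.group, self.feature_class,
             self.target)
        )


@dataclass(frozen=True)
class ConfigSpace:
    """Factor levels of the sweep; the full design is their Cartesian product."""

    parcellations: tuple[str, ...]
    weightings: tuple[str, ...] = WEIGHTINGS
    groups: tuple[str, ...] = SUBJECT_GROUPS
    feature_classes: tuple[str, ...] = FEATURE_CLASSES
    targets: tuple[str, ...] = TRAITS

    def __post_init__(self) -> None:
        for name in ("parcellations", "weightings", "groups", "feature_classes",
                     "targets"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"empty factor list: {name}")

    @property
    def n_pipelines(self) -> int:
        return (
            len(self.parcellations) * len(self.weightings) * len(self.groups)
            * len(self.feature_classes) * len(self.targets)
        )


def enumerate_pipelines(space: ConfigSpace) -> list[PipelineConfig]:
    """Deterministic lexicographic enumeration of the full design."""
    return [
        PipelineConfig(*combo)
        for combo in itertools.product(
            space.parcellations, space.weightings, space.groups,
            space.feature_classes, space.targets,
        )
    ]


def feature_grid_for(
    feature_class: str, n_rois: int, n_available: int | None = None
) -> list:
    """Feature-selection cases for one feature class.

    corr/pca: the fixed k grid with the region count appended, deduplicated
    and capped at the available feature count; rcp: one case per region
    (0-based indices); whole-brain: a single case (None).
    """
    if n_rois < 2:
        raise ValueError("n_rois must be >= 2")
    if feature_class == "whole-brain":
        return [None]
    if feature_class == "rcp":
        return list(range(n_rois))
    if feature_class in ("corr", "pca"):
        cap = n_available if n_available is not None else n_rois * (n_rois - 1) // 2
        grid = [min(k, cap) for k in (*FEATURE_K_GRID, n_rois)]
        seen: list[int] = []
        for k in grid:
            if k not in seen:
                seen.append(k)
        return seen
    raise ValueError(f"unknown feature class {feature_class!r}")


def best_of_selection(
    distributions: list[CVDistribution],
) -> tuple[int, CVDistribution]:
    """Post-hoc best feature-selection case: the largest repeat-mean accuracy.

    Ties break toward the smallest case index. The returned distribution is
    an optimistic upper bound — the case was chosen on the very test
    results being reported.
    """
    if len(distributions) == 0:
        raise ValueError("need at least one feature-selection case")
    means = np.array([d.mean for d in distributions])
    best = int(np.argmax(means))  # argmax takes the first maximum
    return best, distributions[best]


def cohens_d(dist_a, dist_b) -> float:
    """Standardized mean difference with the pooled standard deviation."""
    a = np.asarray(getattr(dist_a, "values", dist_a), dtype=float)
    b = np.asarray(getattr(dist_b, "values", dist_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both distributions need at least 2 values")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def fraction_above(
    result_table: pd.DataFrame,
    threshold: float = PROMISING_THRESHOLD,
    group_by: str | list[str] = "weighting",
    value_col: str = "r",
) -> pd.Series:
    """Per-condition share of results with accuracy strictly above threshold."""
    if len(result_table) == 0:
        raise ValueError("empty result table")
    return result_table.groupby(group_by, sort=True)[value_col].apply(
        lambda v: float((v > threshold).mean())
    )


@dataclass(frozen=True)
class OptimismReport:
    """Post-hoc vs in-loop feature selection on identical data and splits."""

    mean_posthoc: float
    mean_inner: float
    gap: float
    ci_low: float
    ci_high: float
    best_case: int
    per_case_means: np.ndarray
    posthoc: CVDistribution
    inner: CVDistribution


def optimism_audit(
    feats: PipelineFeatures,
    y: np.ndarray,
    scheme: SplitScheme,
    feature_params,
    alpha_grid=DEFAULT_ALPHA_GRID,
    n_boot: int = 2000,
    boot_seed: int = 0,
) -> OptimismReport:
    """Measure selection-induced optimism for one feature class.

    Protocol A runs one accuracy distribution per feature-selection case
    and keeps the best repeat-mean (post-hoc selection, using the test
    results themselves); protocol B selects the case inside the inner CV
    loop together with alpha. Both consume identical folds, so the gap
    mean(A) - mean(B) is paired per repeat; its confidence interval is a
    seeded percentile bootstrap over the repeat-level differences.
    """
    feature_params = list(feature_params)
    per_case = [
        run_repeated(feats, y, scheme, alpha_grid, fixed_param=p,
                     pipeline_id=f"case={p}")
        for p in feature_params
    ]
    best_idx, best_dist = best_of_selection(per_case)
    inner_dist = run_repeated(
        feats, y, scheme, alpha_grid, feature_params=feature_params,
        pipeline_id="inner-select",
    )
    diffs = best_dist.values - inner_dist.values
    rng = np.random.default_rng(np.random.SeedSequence([int(boot_seed), 0xB007]))
    boots = np.array([
        diffs[rng.integers(0, diffs.size, diffs.size)].mean() for _ in range(n_boot)
    ])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return OptimismReport(
        mean_posthoc=best_dist.mean,
        mean_inner=inner_dist.mean,
        gap=best_dist.mean - inner_dist.mean,
        ci_low=float(lo),
        ci_high=float(hi),
        best_case=best_idx,
        per_case_means=np.array([d.mean for d in per_case]),
        posthoc=best_dist,
        inner=inner_dist,
    )


def run_pipeline_cases(
    pipeline: PipelineConfig,
    matrices: np.ndarray,
    y: np.ndarray,
    scheme: SplitScheme,
    alpha_grid=DEFAULT_ALPHA_GRID,
    permute_seed: int | None = None,
) -> list[CVDistribution]:
    """All feature-selection cases of one pipeline on prepared data.

    ``matrices``/``y`` must already be restricted to the pipeline's subject
    group. With ``permute_seed`` the permutation baseline is run instead.
    """
    feats = PipelineFeatures(matrices, pipeline.weighting, pipeline.feature_class)
    if pipeline.feature_class == "pca":
        # PCA rank is bounded by the smallest inner-training set minus 1
        n = len(y)
        outer_train = n - -(-n // scheme.n_folds)
        inner_train = outer_train - -(-outer_train // scheme.n_folds)
        cap = min(feats.n_edges, inner_train - 1)
    else:
        cap = feats.n_edges
    cases = feature_grid_for(pipeline.feature_class, feats.n_rois, n_available=cap)
    out = []
    for case in cases:
        pid = f"{pipeline.pipeline_id}|case={case}"
        if permute_seed is None:
            out.append(run_repeated(feats, y, scheme, alpha_grid,
                                    fixed_param=case, pipeline_id=pid))
        else:
            out.append(permutation_baseline(feats, y, scheme, permute_seed,
                                            alpha_grid, fixed_param=case,
                                            pipeline_id=pid))
    return out


def sweep_results_frame(
    case_distributions: dict[PipelineConfig, list[CVDistribution]],
) -> pd.DataFrame:
    """Tidy results: one row per (pipeline, feature-selection case, repeat)."""
    rows = []
    for cfg, dists in case_distributions.items():
        for case_idx, dist in enumerate(dists):
            for rep, r in enumerate(dist.values):
                rows.append(
                    (cfg.parcellation, cfg.weighting, cfg.group,
                     cfg.feature_class, cfg.target, case_idx, rep, float(r))
                )
    return pd.DataFrame(
        rows,
        columns=["parcellation", "weighting", "group", "feature_class",
                 "target", "selection_case", "repeat", "r"],
    )
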