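"""Shared data containers for connectome-based prediction.

The objects here are deliberately thin: a labelled voxel grid, scalar maps on
that grid, voxel-path streamlines, the region-by-region connectome, the
subject cohort with its questionnaire-derived trait scores, and the
distribution of cross-validated prediction accuracies for one pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

TRAITS: tuple[str, ...] = ("O", "C", "E", "A", "N")
N_ITEMS_PER_TRAIT = 12
MAX_ITEM_SCORE = 4
MAX_TRAIT_SCORE = N_ITEMS_PER_TRAIT * MAX_ITEM_SCORE  # 48
WEIGHTINGS: tuple[str, ...] = ("NOS", "FA", "MD")


@dataclass(frozen=True)
class LabelVolume:
    """3D integer parcellation: 0 = background, 1..R = region labels."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("label volume must be a 3D array")
        if labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        object.__setattr__(self, "labels", labels.astype(np.int32))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_rois(self) -> int:
        return int(self.labels.max())

    def roi_sizes(self) -> np.ndarray:
        """Voxel count per label 1..R."""
        return np.bincount(self.labels.ravel(), minlength=self.n_rois + 1)[1:]

    def validate(self) -> None:
        """Every label in 1..R must be non-empty."""
        if self.n_rois < 1:
            raise ValueError("parcellation has no labelled voxels")
        if (self.roi_sizes() == 0).any():
            raise ValueError("parcellation has empty labels")


@dataclass(frozen=True)
class ScalarVolume:
    """Voxelwise scalar map (e.g. FA in [0,1], MD in mm^2/s) on a 3D grid."""

    values: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError("scalar volume must be a 3D array")
        if not np.isfinite(values).all():
            raise ValueError("scalar volume contains non-finite values")
        if self.kind.upper() == "FA" and (values.min() < 0 or values.max() > 1):
            raise ValueError("FA values must lie in [0, 1]")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class StreamlineSet:
    """Ordered voxel paths on a common grid.

    Each streamline is an (L, 3) integer array of voxel coordinates with
    L >= 2; the grid shape is carried for bounds checking.
    """

    paths: tuple[np.ndarray, ...]
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        paths = tuple(np.asarray(p, dtype=np.int64) for p in self.paths)
        for p in paths:
            if p.ndim != 2 or p.shape[1] != 3:
                raise ValueError("each streamline must be an (L, 3) array")
            if p.shape[0] < 2:
                raise ValueError("streamlines must visit at least 2 voxels")
            if (p < 0).any() or (p >= np.asarray(self.grid_shape)).any():
                raise ValueError("streamline coordinates out of bounds")
        object.__setattr__(self, "paths", paths)
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self):
        return iter(self.paths)


@dataclass(frozen=True)
class Connectome:
    """Symmetric zero-diagonal R x R structural connectivity matrix."""

    matrix: np.ndarray
    weighting: str
    parcellation_id: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("connectome matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("connectome matrix must be symmetric")
        if np.abs(np.diag(m)).max(initial=0.0) != 0.0:
            raise ValueError("connectome diagonal (self-connections) must be zero")
        if self.weighting == "NOS":
            if (m < 0).any() or not np.array_equal(m, np.round(m)):
                raise ValueError("NOS entries must be nonnegative integers")
        if self.weighting == "FA" and (m.min() < 0 or m.max() > 1):
            raise ValueError("FA edge weights must lie in [0, 1]")
        if self.weighting == "MD" and m.min() < 0:
            raise ValueError("MD edge weights must be nonnegative")
        object.__setattr__(self, "matrix", m)

    @property
    def size(self) -> int:
        return self.matrix.shape[0]


# reversal mask for inversely keyed questionnaire items: fixed, arbitrary,
# shared by every trait (the real inventory's keying is not public here)
REVERSED_ITEMS: tuple[int, ...] = (2, 5, 8, 11)


def score_items(item_responses: np.ndarray) -> np.ndarray:
    """Trait totals from raw item responses, reversing inversely keyed items.

    Parameters
    ----------
    item_responses : (n_subjects, n_traits, 12) integers in 0..4
        Raw Likert responses as recorded.

    Returns
    -------
    (n_subjects, n_traits) integer totals, each in [0, 48].
    """
    items = np.asarray(item_responses)
    if items.min() < 0 or items.max() > MAX_ITEM_SCORE:
        raise ValueError("item responses must be integers in 0..4")
    keyed = items.copy()
    keyed[..., list(REVERSED_ITEMS)] = MAX_ITEM_SCORE - keyed[..., list(REVERSED_ITEMS)]
    return keyed.sum(axis=-1)


@dataclass(frozen=True)
class Cohort:
    """Subjects with sex, questionnaire items, trait totals and a cognition score."""

    subject_ids: tuple[str, ...]
    sex: np.ndarray  # array of "F"/"M"
    item_responses: np.ndarray  # (n, 5, 12) ints in 0..4
    trait_scores: np.ndarray  # (n, 5) ints in [0, 48]
    cognition: np.ndarray  # (n,) floats

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        sex = np.asarray(self.sex)
        items = np.asarray(self.item_responses, dtype=np.int64)
        scores = np.asarray(self.trait_scores, dtype=np.int64)
        cog = np.asarray(self.cognition, dtype=float)
        if sex.shape != (n,) or items.shape != (n, len(TRAITS), N_ITEMS_PER_TRAIT):
            raise ValueError("cohort field shapes inconsistent")
        if scores.shape != (n, len(TRAITS)) or cog.shape != (n,):
            raise ValueError("cohort field shapes inconsistent")
        if not set(np.unique(sex)) <= {"F", "M"}:
            raise ValueError("sex labels must be 'F' or 'M'")
        if scores.min() < 0 or scores.max() > MAX_TRAIT_SCORE:
            raise ValueError("trait scores must lie in [0, 48]")
        if not np.array_equal(score_items(items), scores):
            raise ValueError("trait scores must equal reversal-corrected item sums")
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "sex", sex)
        object.__setattr__(self, "item_responses", items)
        object.__setattr__(self, "trait_scores", scores)
        object.__setattr__(self, "cognition", cog)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def target(self, name: str) -> np.ndarray:
        """Prediction target vector: one of the five traits or 'cognition'."""
        if name == "cognition":
            return self.cognition.astype(float)
        if name in TRAITS:
            return self.trait_scores[:, TRAITS.index(name)].astype(float)
        raise KeyError(f"unknown target {name!r}")

    def group_indices(self, group: str) -> np.ndarray:
        """Subject indices for a subject group: mixed, female or male."""
        if group == "mixed":
            return np.arange(self.n_subjects)
        if group == "female":
            return np.flatnonzero(self.sex == "F")
        if group == "male":
            return np.flatnonzero(self.sex == "M")
        raise KeyError(f"unknown subject group {group!r}")

    def with_target(self, name: str, values: np.ndarray) -> "Cohort":
        """Copy of the cohort with one target column replaced.

        Replacing a trait rewrites its item responses so the invariant
        "score equals reversal-corrected item sum" still holds: the new
        total is spread greedily over the 12 items.
        """
        values = np.asarray(values)
        if values.shape != (self.n_subjects,):
            raise ValueError("replacement target has wrong length")
        if name == "cognition":
            return replace(self, cognition=values.astype(float))
        if name not in TRAITS:
            raise KeyError(f"unknown target {name!r}")
        totals = values.astype(np.int64)
        if totals.min() < 0 or totals.max() > MAX_TRAIT_SCORE:
            raise ValueError("trait totals must lie in [0, 48]")
        t = TRAITS.index(name)
        items = self.item_responses.copy()
        items[:, t, :] = _spread_total(totals)
        # store reversed items back in raw (as-recorded) form
        items[:, t, list(REVERSED_ITEMS)] = (
            MAX_ITEM_SCORE - items[:, t, list(REVERSED_ITEMS)]
        )
        scores = self.trait_scores.copy()
        scores[:, t] = totals
        return replace(self, item_responses=items, trait_scores=scores)

    @property
    def frame(self) -> pd.DataFrame:
        """Tidy per-subject table (subject_id, sex, O, C, E, A, N, cognition)."""
        data = {"subject_id": list(self.subject_ids), "sex": self.sex}
        for i, t in enumerate(TRAITS):
            data[t] = self.trait_scores[:, i]
        data["cognition"] = self.cognition
        return pd.DataFrame(data)


def _spread_total(totals: np.ndarray) -> np.ndarray:
    """Distribute integer totals in [0,48] over 12 items, each in 0..4."""
    n = totals.shape[0]
    items = np.zeros((n, N_ITEMS_PER_TRAIT), dtype=np.int64)
    remaining = totals.copy()
    for j in range(N_ITEMS_PER_TRAIT):
        take = np.minimum(remaining, MAX_ITEM_SCORE)
        items[:, j] = take
        remaining -= take
    return items


@dataclass(frozen=True)
class CVDistribution:
    """Per-repeat mean test correlations for one pipeline (one value per split)."""

    values: np.ndarray
    pipeline_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("distribution must be a non-empty 1D array")
        if (np.abs(v) > 1 + 1e-12).any():
            raise ValueError("prediction accuracies must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def n_repeats(self) -> int:
        return self.values.size
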