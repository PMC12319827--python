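"""Seeded generators for every input the prediction pipelines consume.

The generators emulate the statistical properties of a diffusion-MRI
connectome study without simulating diffusion physics: a connected
parcellation on a voxel grid, anticorrelated FA/MD scalar maps,
straight-line streamline paths, a population of symmetric zero-diagonal
connectomes (right-skewed integer streamline counts plus two coupled,
bounded microstructural weightings), a cohort with Likert-item trait
scores and a continuous cognition composite, and targets with a planted
linear edge signal of configurable variance explained.

Every generator is a pure function of its arguments including the seed:
identical calls produce bit-identical outputs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .containers import (
    MAX_ITEM_SCORE,
    MAX_TRAIT_SCORE,
    N_ITEMS_PER_TRAIT,
    TRAITS,
    Cohort,
    Connectome,
    LabelVolume,
    ScalarVolume,
    StreamlineSet,
    score_items,
)

_NEIGHBORS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic benchmark dataset.

    Parameters
    ----------
    grid_shape : voxel grid of the synthetic brain volume.
    n_rois : parcellation granularity R.
    n_subjects : cohort size.
    fa_md_coupling : in [0, 1]; fraction of shared latent variance between
        the FA- and MD-weighted edges of one subject. 0.95 emulates the
        near-unity correlation between microstructural weightings seen in
        real connectomes.
    nos_log_mean, nos_log_sd : mean and SD of the log10 streamline-count
        distribution across edges and subjects. The marginal is a rounded
        log-normal, i.e. heavily right-skewed nonnegative integers.
    effect_r2 : population variance of the target explained by the planted
        edge signal (0 = null data).
    seed : master seed for all randomness.
    """

    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_rois: int = 20
    n_subjects: int = 100
    fa_md_coupling: float = 0.95
    nos_log_mean: float = 1.0
    nos_log_sd: float = 0.8
    effect_r2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) < 1 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be three positive integers")
        if self.n_rois < 1 or self.n_subjects < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.fa_md_coupling <= 1.0:
            raise ValueError("fa_md_coupling must lie in [0, 1]")
        if not 0.0 <= self.effect_r2 <= 1.0:
            raise ValueError("effect_r2 must lie in [0, 1]")
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))


def _foreground_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoid 'brain' mask inscribed in the grid."""
    axes = [np.arange(s, dtype=float) for s in grid_shape]
    grids = np.meshgrid(*axes, indexing="ij")
    d2 = sum(
        ((g - (s - 1) / 2.0) / (s / 2.0)) ** 2 for g, s in zip(grids, grid_shape)
    )
    return d2 <= 1.0


def make_parcellation(
    grid_shape: tuple[int, int, int], n_rois: int, seed: int
) -> LabelVolume:
    """Grow a connected parcellation from random seed voxels.

    Foreground is an ellipsoid mask; each region is grown by multi-source
    breadth-first search over 6-connectivity, so every label forms a
    connected region and every foreground voxel carries exactly one label.
    """
    mask = _foreground_mask(grid_shape)
    fg = np.argwhere(mask)
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    if n_rois > fg.shape[0]:
        raise ValueError(
            f"n_rois={n_rois} exceeds the {fg.shape[0]} foreground voxels"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9A5C]))
    seeds = fg[rng.choice(fg.shape[0], size=n_rois, replace=False)]

    labels = np.zeros(grid_shape, dtype=np.int32)
    queue: deque[tuple[int, int, int]] = deque()
    for r, v in enumerate(seeds, start=1):
        labels[tuple(v)] = r
        queue.append(tuple(v))
    shape = np.asarray(grid_shape)
    while queue:
        v = queue.popleft()
        lab = labels[v]
        for d in _NEIGHBORS:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if (0 <= w[0] < shape[0] and 0 <= w[1] < shape[1] and 0 <= w[2] < shape[2]
                    and mask[w] and labels[w] == 0):
                labels[w] = lab
                queue.append(w)
    vol = LabelVolume(labels)
    vol.validate()
    return vol


def make_scalar_volumes(
    label_volume: LabelVolume, seed: int, md_noise_sd: float = 1e-4
) -> tuple[ScalarVolume, ScalarVolume]:
    """Voxelwise FA and MD maps with a negative FA-MD correlation.

    FA is Beta(4,4)-distributed in [0, 1]; MD (mm^2/s) is a decreasing
    affine function of FA plus Gaussian noise, floored at a small positive
    value, so the voxelwise Pearson correlation is strongly negative.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFA]))
    shape = label_volume.shape
    fa = rng.beta(4.0, 4.0, size=shape)
    md = 1.2e-3 - 0.8e-3 * fa + rng.normal(0.0, md_noise_sd, size=shape)
    md = np.maximum(md, 1e-6)
    return ScalarVolume(fa, kind="FA"), ScalarVolume(md, kind="MD")


def _rasterize(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Straight-line voxel path from a to b (inclusive), duplicates merged."""
    steps = int(np.abs(b - a).max())
    pts = np.rint(np.linspace(a, b, steps + 1)).astype(np.int64)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = (pts[1:] != pts[:-1]).any(axis=1)
    return pts[keep]


def make_streamlines(
    label_volume: LabelVolume, n_streamlines: int, seed: int
) -> StreamlineSet:
    """Straight-line streamlines between random labelled voxels.

    Endpoints are drawn from the labelled (foreground) voxels, distinct so
    every path visits at least 2 voxels. Geometry is a rasterized segment:
    sufficient to exercise the endpoint and per-voxel averaging rules of
    connectome construction, where curvature is irrelevant.
    """
    if n_streamlines < 0:
        raise ValueError("n_streamlines must be >= 0")
    fg = np.argwhere(label_volume.labels > 0)
    if fg.shape[0] == 0:
        raise ValueError("label volume has no foreground voxels")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x57]))
    paths = []
    for _ in range(n_streamlines):
        i = rng.integers(fg.shape[0])
        j = rng.integers(fg.shape[0])
        while (fg[j] == fg[i]).all():
            j = rng.integers(fg.shape[0])
        paths.append(_rasterize(fg[i], fg[j]))
    return StreamlineSet(tuple(paths), label_volume.shape)


def make_cohort(n_subjects: int, balanced_sex: bool, seed: int) -> Cohort:
    """Cohort with Likert-item trait scores and a cognition composite.

    Each trait total is the reversal-corrected sum of 12 items in 0..4;
    per-subject item response probabilities vary (Beta-distributed), which
    yields overdispersed integer totals in [0, 48]. Cognition is a
    continuous composite (mean 100, SD 15). With ``balanced_sex`` the two
    sexes are exactly equally frequent (requires even n).
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if balanced_sex and n_subjects % 2:
        raise ValueError("balanced sexes require an even number of subjects")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))
    if balanced_sex:
        sex = np.array(["F", "M"] * (n_subjects // 2))
        rng.shuffle(sex)
    else:
        sex = np.where(rng.random(n_subjects) < 0.5, "F", "M")

    # intended (keyed) item contributions; stored responses re-reverse the
    # inversely keyed items so raw data look like as-recorded Likert answers
    p = rng.beta(4.0, 4.0, size=(n_subjects, len(TRAITS)))
    keyed = rng.binomial(
        MAX_ITEM_SCORE, p[..., None], size=(n_subjects, len(TRAITS), N_ITEMS_PER_TRAIT)
    )
    from .containers import REVERSED_ITEMS

    items = keyed.copy()
    items[..., list(REVERSED_ITEMS)] = MAX_ITEM_SCORE - items[..., list(REVERSED_ITEMS)]
    scores = score_items(items)
    cognition = rng.normal(100.0, 15.0, size=n_subjects)
    ids = tuple(f"sub-{i:04d}" for i in range(n_subjects))
    return Cohort(ids, sex, items, scores, cognition)


@dataclass(frozen=True)
class SCPopulation:
    """Per-subject connectome triplets as dense arrays.

    ``nos``, ``fa`` and ``md`` are (n_subjects, R, R) stacks of symmetric
    zero-diagonal matrices sharing one edge-support mask per subject.
    """

    nos: np.ndarray
    fa: np.ndarray
    md: np.ndarray
    parcellation_id: str = ""

    def __post_init__(self) -> None:
        for name in ("nos", "fa", "md"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.ndim != 3 or a.shape[1] != a.shape[2]:
                raise ValueError("population arrays must be (n, R, R)")
            object.__setattr__(self, name, a)

    @property
    def n_subjects(self) -> int:
        return self.nos.shape[0]

    @property
    def n_rois(self) -> int:
        return self.nos.shape[1]

    def matrices(self, weighting: str) -> np.ndarray:
        key = weighting.lower()
        if key not in ("nos", "fa", "md"):
            raise KeyError(f"unknown weighting {weighting!r}")
        return getattr(self, key)

    def connectome(self, subject: int, weighting: str) -> Connectome:
        return Connectome(
            self.matrices(weighting)[subject], weighting.upper(), self.parcellation_id
        )


def _sym_from_upper(vec: np.ndarray, n_rois: int) -> np.ndarray:
    iu = np.triu_indices(n_rois, k=1)
    m = np.zeros(vec.shape[:-1] + (n_rois, n_rois))
    m[..., iu[0], iu[1]] = vec
    m[..., iu[1], iu[0]] = vec
    return m


def simulate_connectomes(
    cohort: Cohort, n_rois: int, config: GeneratorConfig
) -> SCPopulation:
    """Population of NOS/FA/MD-weighted connectomes with latent coupling.

    log10(NOS) per edge is an edge-level population mean plus a subject
    deviation, rounded to integers (so weak edges drop to 0 and the
    marginal is right-skewed). FA and MD share a latent edge factor with
    weight ``fa_md_coupling``; both carry edge-level structure so the
    population has principal components. FA is clipped to [0, 1]; MD is
    positive wherever an edge exists; absent edges are 0 in all three.
    """
    if n_rois < 2:
        raise ValueError("connectomes need n_rois >= 2")
    n = cohort.n_subjects
    n_edges = n_rois * (n_rois - 1) // 2
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x5C]))

    sd_edge = config.nos_log_sd * np.sqrt(0.7)
    sd_subj = config.nos_log_sd * np.sqrt(0.3)
    log_nos = (
        config.nos_log_mean
        + rng.normal(0.0, sd_edge, size=n_edges)
        + rng.normal(0.0, sd_subj, size=(n, n_edges))
    )
    nos = np.rint(10.0 ** log_nos)
    support = nos > 0

    rho = config.fa_md_coupling

    def latent() -> np.ndarray:
        # edge-level structure (shared across subjects) + subject deviation
        return np.sqrt(0.4) * rng.normal(size=n_edges) + np.sqrt(0.6) * rng.normal(
            size=(n, n_edges)
        )

    shared, u_fa, u_md = latent(), latent(), latent()
    lat_fa = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * u_fa
    lat_md = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * u_md
    fa = np.clip(0.45 + 0.12 * lat_fa, 0.0, 1.0)
    md = np.maximum(0.8e-3 + 0.12e-3 * lat_md, 1e-6)

    nos[~support] = 0.0
    fa[~support] = 0.0
    md[~support] = 0.0
    return SCPopulation(
        _sym_from_upper(nos, n_rois),
        _sym_from_upper(fa, n_rois),
        _sym_from_upper(md, n_rois),
        parcellation_id=f"synth{n_rois}",
    )


def planted_edge_features(
    population: SCPopulation, weighting: str = "NOS"
) -> np.ndarray:
    """Edge feature matrix (n_subjects, n_edges) the signal is planted on.

    NOS edges are log10-transformed (zeros kept at 0), matching the
    transform the prediction pipeline applies, so a planted linear signal
    is linear in the model's feature space.
    """
    mats = population.matrices(weighting)
    iu = np.triu_indices(population.n_rois, k=1)
    x = mats[:, iu[0], iu[1]]
    if weighting.upper() == "NOS":
        x = np.where(x > 0, np.log10(np.maximum(x, 1e-300)), 0.0)
    return x


def plant_signal(
    population: SCPopulation,
    cohort: Cohort,
    target_name: str,
    signal_edges: np.ndarray,
    effect_r2: float,
    seed: int,
    weighting: str = "NOS",
    discretize: bool = True,
    return_info: bool = False,
):
    """Replace one target with a planted linear function of chosen edges.

    The signal is a random-weight linear combination of the named
    upper-triangle edge values, standardized over the cohort; the new
    target is sqrt(effect_r2) * signal + sqrt(1 - effect_r2) * noise with
    standardized independent noise, so the population variance explained
    equals ``effect_r2``. Trait targets are mapped affinely (sample range
    onto [0, 48], hence correlation-preserving) and rounded to integers;
    cognition stays continuous on its 100 +/- 15 scale.

    Returns the modified cohort; with ``return_info=True`` also the
    standardized signal combination (for recovery checks). With
    ``discretize=False`` a trait target is left continuous: it cannot be
    written back through the integer item-response invariant, so the raw
    target array is returned instead of a cohort.
    """
    if not 0.0 <= effect_r2 <= 1.0:
        raise ValueError("effect_r2 must lie in [0, 1]")
    signal_edges = np.asarray(signal_edges, dtype=np.int64)
    if signal_edges.size == 0:
        raise ValueError("signal_edges must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x516]))
    x = planted_edge_features(population, weighting)[:, signal_edges]
    w = rng.normal(size=signal_edges.size)
    s = x @ w
    sd = s.std()
    if sd == 0:
        raise ValueError("signal combination is constant over the cohort")
    s = (s - s.mean()) / sd

    e = rng.normal(size=cohort.n_subjects)
    e = (e - e.mean()) / e.std()
    z = np.sqrt(effect_r2) * s + np.sqrt(1.0 - effect_r2) * e

    if target_name == "cognition":
        target = 100.0 + 15.0 * z
    else:
        span = z.max() - z.min()
        if span == 0:
            target = np.full_like(z, MAX_TRAIT_SCORE / 2.0)
        else:
            target = (z - z.min()) / span * MAX_TRAIT_SCORE
        if not discretize:
            return (target, s) if return_info else target
        target = np.rint(target)
    new = cohort.with_target(target_name, target)
    return (new, s) if return_info else new


@dataclass(frozen=True)
class BenchmarkData:
    """One fully generated study: parcellation, maps, cohort, connectomes."""

    config: GeneratorConfig
    label_volume: LabelVolume
    fa_volume: ScalarVolume
    md_volume: ScalarVolume
    cohort: Cohort
    population: SCPopulation
    signal_edges: np.ndarray


def generate_benchmark(
    config: GeneratorConfig,
    target_name: str = "O",
    n_signal_edges: int = 10,
) -> BenchmarkData:
    """End-to-end dataset under the study conditions in ``config``.

    Plants a linear signal of variance explained ``config.effect_r2`` on
    ``n_signal_edges`` randomly chosen edges into ``target_name`` (the
    other targets stay null).
    """
    vol = make_parcellation(config.grid_shape, config.n_rois, config.seed)
    fa_vol, md_vol = make_scalar_volumes(vol, config.seed)
    cohort = make_cohort(config.n_subjects, config.n_subjects % 2 == 0, config.seed)
    pop = simulate_connectomes(cohort, config.n_rois, config)
    n_edges = config.n_rois * (config.n_rois - 1) // 2
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xED]))
    edges = rng.choice(n_edges, size=min(n_signal_edges, n_edges), replace=False)
    if config.effect_r2 > 0:
        cohort = plant_signal(
            pop, cohort, target_name, edges, config.effect_r2, config.seed
        )
    return BenchmarkData(config, vol, fa_vol, md_vol, cohort, pop, edges)
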