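"""Construct NOS-, FA- and MD-weighted connectomes from streamlines.

The weighting rules: the NOS edge weight between two regions is the raw
count of streamlines whose endpoints fall in those regions (no
normalization by region size); the microstructural FA/MD edge weight is
the mean over those streamlines of each streamline's mean scalar value
over the distinct voxels it passes through. Streamlines with an endpoint
in background are discarded; self-connections contribute only to the
diagonal, which is set to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import Connectome, LabelVolume, ScalarVolume, StreamlineSet

logger = logging.getLogger(__name__)


def endpoint_rois(
    streamline: np.ndarray, label_volume: LabelVolume
) -> tuple[int, int] | None:
    """Region labels of a streamline's first and last voxel.

    Returns ``None`` when either endpoint lies in background (label 0).
    A streamline may begin and end in the same region; the resulting
    self-connection lands on the diagonal and is zeroed by the builders.
    """
    path = np.asarray(streamline, dtype=np.int64)
    if (path < 0).any() or (path >= np.asarray(label_volume.shape)).any():
        raise ValueError("streamline coordinates out of bounds")
    a = int(label_volume.labels[tuple(path[0])])
    b = int(label_volume.labels[tuple(path[-1])])
    if a == 0 or b == 0:
        return None
    return a, b


@dataclass(frozen=True)
class EndpointTally:
    """Bookkeeping of how streamlines were assigned during a build."""

    n_streamlines: int
    n_background: int
    n_self: int

    @property
    def n_counted(self) -> int:
        return self.n_streamlines - self.n_background - self.n_self


def _pair_assignments(
    streamline_set: StreamlineSet, label_volume: LabelVolume
) -> tuple[list[tuple[int, int, int]], EndpointTally]:
    """(streamline index, roi_i, roi_j) for counted streamlines, i <= j 0-based."""
    pairs: list[tuple[int, int, int]] = []
    n_background = n_self = 0
    for idx, path in enumerate(streamline_set):
        rois = endpoint_rois(path, label_volume)
        if rois is None:
            n_background += 1
            continue
        a, b = rois
        if a == b:
            n_self += 1
            continue
        i, j = sorted((a - 1, b - 1))
        pairs.append((idx, i, j))
    tally = EndpointTally(len(streamline_set), n_background, n_self)
    if n_background:
        logger.info("discarded %d streamlines with background endpoints", n_background)
    return pairs, tally


def build_nos(
    streamline_set: StreamlineSet,
    label_volume: LabelVolume,
    return_tally: bool = False,
):
    """NOS-weighted connectome: raw streamline counts between region pairs.

    Counts are not normalized by region size. Unordered endpoint pairs are
    pooled before counting, so the matrix is symmetric by construction.
    """
    label_volume.validate()
    R = label_volume.n_rois
    if R < 2:
        raise ValueError("connectome construction needs at least 2 regions")
    m = np.zeros((R, R))
    pairs, tally = _pair_assignments(streamline_set, label_volume)
    for _, i, j in pairs:
        m[i, j] += 1
        m[j, i] += 1
    sc = Connectome(m, "NOS")
    return (sc, tally) if return_tally else sc


def streamline_mean_scalar(
    streamline: np.ndarray, scalar_volume: ScalarVolume
) -> float:
    """Mean scalar value over the distinct voxels a streamline passes through.

    A voxel revisited by the path is counted once.
    """
    path = np.asarray(streamline, dtype=np.int64)
    if (path < 0).any() or (path >= np.asarray(scalar_volume.shape)).any():
        raise ValueError("streamline coordinates out of bounds")
    voxels = np.unique(path, axis=0)
    return float(scalar_volume.values[voxels[:, 0], voxels[:, 1], voxels[:, 2]].mean())


def build_microstructural(
    streamline_set: StreamlineSet,
    label_volume: LabelVolume,
    scalar_volume: ScalarVolume,
    weighting_tag: str,
) -> Connectome:
    """FA- or MD-weighted connectome.

    Edge (i, j) is the mean of the per-streamline mean scalar over all
    streamlines whose endpoints fall in regions i and j; pairs with no
    streamline stay 0.
    """
    label_volume.validate()
    if label_volume.shape != scalar_volume.shape:
        raise ValueError("label and scalar volumes must share a grid")
    R = label_volume.n_rois
    if R < 2:
        raise ValueError("connectome construction needs at least 2 regions")
    sums = np.zeros((R, R))
    counts = np.zeros((R, R))
    pairs, _ = _pair_assignments(streamline_set, label_volume)
    for idx, i, j in pairs:
        v = streamline_mean_scalar(streamline_set.paths[idx], scalar_volume)
        sums[i, j] += v
        counts[i, j] += 1
    m = np.zeros((R, R))
    hit = counts > 0
    m[hit] = sums[hit] / counts[hit]
    m = m + m.T  # (i, j) stored once with i < j
    return Connectome(m, weighting_tag.upper())


def build_all(
    streamline_set: StreamlineSet,
    label_volume: LabelVolume,
    fa_volume: ScalarVolume,
    md_volume: ScalarVolume,
) -> dict[str, Connectome]:
    """All three weightings from one streamline set."""
    return {
        "NOS": build_nos(streamline_set, label_volume),
        "FA": build_microstructural(streamline_set, label_volume, fa_volume, "FA"),
        "MD": build_microstructural(streamline_set, label_volume, md_volume, "MD"),
    }
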