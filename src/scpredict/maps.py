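"""Voxelwise prediction brain maps from regional connectivity profiles.

Each region's cross-validated prediction accuracy (the repeat-mean of its
RCP pipeline) is painted onto all voxels of that region; maps from
different parcellations of the same grid are then averaged voxelwise to a
parcellation-consensus map. Background voxels stay unassigned (NaN) and
are excluded from all statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CVDistribution, LabelVolume
from .ridge import pearson_r


@dataclass(frozen=True)
class PredictionMap:
    """Voxel grid of mean prediction accuracy; unassigned voxels are NaN."""

    values: np.ndarray
    target: str = ""
    weighting: str = ""
    group: str = ""
    parcellation_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("prediction map must be a 3D volume")
        assigned = v[np.isfinite(v)]
        if assigned.size and (np.abs(assigned) > 1 + 1e-12).any():
            raise ValueError("assigned map values must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def foreground_mean(self) -> float:
        return float(np.nanmean(self.values))


def rcp_map(
    rcp_means, label_volume: LabelVolume, **metadata
) -> PredictionMap:
    """Single-parcellation map: region i's accuracy on all voxels of region i.

    ``rcp_means`` holds one repeat-mean accuracy per region, ordered by
    0-based region index (CVDistribution entries are reduced to their
    mean). A missing region is an error.
    """
    means = [
        d.mean if isinstance(d, CVDistribution) else float(d) for d in rcp_means
    ]
    vol = label_volume
    vol.validate()
    if len(means) != vol.n_rois:
        raise ValueError(
            f"need one accuracy per region: got {len(means)} for {vol.n_rois} regions"
        )
    lut = np.concatenate(([np.nan], np.asarray(means, dtype=float)))
    values = lut[vol.labels]
    return PredictionMap(
        values, parcellation_ids=(metadata.pop("parcellation_id", ""),), **metadata
    )


def average_maps(maps: list[PredictionMap]) -> PredictionMap:
    """Voxelwise mean across parcellation maps sharing one grid.

    A voxel's average uses only the maps in which it is assigned; voxels
    assigned in no map stay unassigned.
    """
    if len(maps) == 0:
        raise ValueError("need at least one map")
    shape = maps[0].values.shape
    if any(m.values.shape != shape for m in maps):
        raise ValueError("all maps must share one voxel grid")
    stack = np.stack([m.values for m in maps])
    counts = np.isfinite(stack).sum(axis=0)
    totals = np.nansum(stack, axis=0)
    mean = np.full(shape, np.nan)
    np.divide(totals, counts, out=mean, where=counts > 0)
    ids = tuple(pid for m in maps for pid in m.parcellation_ids)
    first = maps[0]
    return PredictionMap(
        mean, target=first.target, weighting=first.weighting, group=first.group,
        parcellation_ids=ids,
    )


def correlate_maps(
    map_a: PredictionMap, map_b: PredictionMap, zero_negatives: bool = False,
    return_degenerate: bool = False,
):
    """Pearson correlation between two maps over their assigned voxels.

    Both maps must share the grid and the assigned-voxel mask. With
    ``zero_negatives`` every negative value in BOTH maps is replaced by 0
    before correlating (the variant restricting the comparison to regions
    that predicted successfully). A constant map makes the correlation
    undefined: the convention is 0 with a degeneracy flag.
    """
    if map_a.values.shape != map_b.values.shape:
        raise ValueError("maps must share one voxel grid")
    if not np.array_equal(map_a.mask, map_b.mask):
        raise ValueError("maps must share the assigned-voxel mask")
    a = map_a.values[map_a.mask]
    b = map_b.values[map_b.mask]
    if zero_negatives:
        a = np.maximum(a, 0.0)
        b = np.maximum(b, 0.0)
    return pearson_r(a, b, return_degenerate=return_degenerate)
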