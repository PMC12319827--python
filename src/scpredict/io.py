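"""Plain-text readers and writers for the pipeline's on-disk formats.

Volumes are stored as whitespace-delimited text with a shape header (or
NIfTI when the filename ends in .nii/.nii.gz and nibabel is available);
streamlines as one semicolon-separated voxel path per line; connectomes as
delimited square matrices with a JSON sidecar carrying the weighting tag;
cohorts as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    TRAITS,
    Cohort,
    Connectome,
    LabelVolume,
    ScalarVolume,
    StreamlineSet,
    score_items,
)


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def write_volume(array: np.ndarray, path) -> None:
    path = Path(path)
    array = np.asarray(array)
    if _is_nifti(path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float64), np.eye(4)), path)
        return
    flat = array.reshape(array.shape[0], -1)
    header = f"shape={array.shape[0]},{array.shape[1]},{array.shape[2]}"
    fmt = "%d" if np.issubdtype(array.dtype, np.integer) else "%.10g"
    np.savetxt(path, flat, fmt=fmt, header=header)


def read_volume(path) -> np.ndarray:
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        return np.asarray(nib.load(path).dataobj)
    with open(path) as fh:
        header = fh.readline()
    shape = tuple(int(s) for s in header.split("shape=")[1].split(","))
    return np.loadtxt(path, skiprows=1).reshape(shape)


def write_label_volume(vol: LabelVolume, path) -> None:
    write_volume(vol.labels, path)


def read_label_volume(path) -> LabelVolume:
    return LabelVolume(np.rint(read_volume(path)).astype(np.int32))


def write_scalar_volume(vol: ScalarVolume, path) -> None:
    write_volume(vol.values, path)


def read_scalar_volume(path, kind: str = "") -> ScalarVolume:
    return ScalarVolume(read_volume(path), kind=kind)


def write_streamlines(streamlines: StreamlineSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# grid={','.join(str(s) for s in streamlines.grid_shape)}\n")
        for p in streamlines:
            fh.write(";".join(",".join(str(c) for c in v) for v in p) + "\n")


def read_streamlines(path) -> StreamlineSet:
    with open(path) as fh:
        header = fh.readline()
        grid = tuple(int(s) for s in header.split("grid=")[1].split(","))
        paths = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            paths.append(
                np.array([[int(c) for c in v.split(",")] for v in line.split(";")])
            )
    return StreamlineSet(tuple(paths), grid)


def write_connectome(sc: Connectome, path) -> None:
    """Delimited square matrix plus a JSON sidecar with the weighting tag."""
    path = Path(path)
    np.savetxt(path, sc.matrix, fmt="%.10g")
    sidecar = {
        "weighting": sc.weighting,
        "parcellation_id": sc.parcellation_id,
        "n_rois": sc.size,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_connectome(path) -> Connectome:
    path = Path(path)
    matrix = np.loadtxt(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return Connectome(matrix, meta["weighting"], meta.get("parcellation_id", ""))


def write_cohort(cohort: Cohort, path, items_path=None) -> None:
    """Cohort table as CSV; optionally the raw item responses alongside."""
    cohort.frame.to_csv(path, index=False)
    if items_path is not None:
        flat = cohort.item_responses.reshape(cohort.n_subjects, -1)
        cols = [f"{t}_item{j:02d}" for t in TRAITS for j in range(flat.shape[1] // 5)]
        pd.DataFrame(flat, columns=cols).assign(
            subject_id=list(cohort.subject_ids)
        ).to_csv(items_path, index=False)


def read_cohort(path, items_path=None) -> Cohort:
    frame = pd.read_csv(path)
    n = len(frame)
    scores = frame[list(TRAITS)].to_numpy(dtype=np.int64)
    if items_path is not None:
        items_frame = pd.read_csv(items_path)
        items = (
            items_frame.drop(columns=["subject_id"])
            .to_numpy(dtype=np.int64)
            .reshape(n, len(TRAITS), -1)
        )
    else:
        # reconstruct item responses consistent with the stored totals
        from .containers import Cohort as _C

        zero_items = np.zeros((n, 5, 12), dtype=np.int64)
        tmp = _C(
            tuple(frame["subject_id"].astype(str)),
            frame["sex"].to_numpy(),
            zero_items,
            score_items(zero_items),
            frame["cognition"].to_numpy(dtype=float),
        )
        for i, t in enumerate(TRAITS):
            tmp = tmp.with_target(t, scores[:, i])
        return tmp
    return Cohort(
        tuple(frame["subject_id"].astype(str)),
        frame["sex"].to_numpy(),
        items,
        scores,
        frame["cognition"].to_numpy(dtype=float),
    )
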