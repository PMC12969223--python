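"""Condition-block extraction, gray-matter masking and normalization.

Each subject's 4-D series is cut into the labeled condition blocks, masked
to gray matter, and z-normalized per voxel within each (subject, condition)
block.  Blocks are thereby "aliased as different subjects": clustering sees
a pool of independently normalized blocks, which keeps centroids readable
as local z statistics and prevents cross-condition leakage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

_TIMING_COLUMNS = ("subject", "condition", "start_volume", "end_volume")


@dataclass
class FrameMatrix:
    """Frames x in-mask voxels, with per-frame provenance.

    ``frame_index`` has one row per frame with columns subject, condition and
    position (0-based index within its block).  ``mask_voxel_ids`` are flat
    C-order indices into the image grid, enabling re-embedding of centroid
    maps into NIfTI space.
    """

    data: np.ndarray
    frame_index: pd.DataFrame
    mask_voxel_ids: np.ndarray
    grid_shape: tuple[int, int, int]
    affine: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def blocks(self):
        """Iterate (subject, condition, row indices) per block, in order."""
        for (subject, condition), idx in self.frame_index.groupby(
                ["subject", "condition"], sort=False).groups.items():
            yield subject, condition, np.asarray(idx)

    def save(self, path: str | Path) -> None:
        """Persist as a compressed array bundle plus a JSON index sidecar."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), data=self.data,
                            mask_voxel_ids=self.mask_voxel_ids, affine=self.affine)
        sidecar = {
            "grid_shape": list(self.grid_shape),
            "frame_index": self.frame_index.to_dict(orient="list"),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "FrameMatrix":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            data=arrays["data"],
            frame_index=pd.DataFrame(sidecar["frame_index"]),
            mask_voxel_ids=arrays["mask_voxel_ids"],
            grid_shape=tuple(sidecar["grid_shape"]),
            affine=arrays["affine"],
        )


def zscore_block(block: np.ndarray) -> np.ndarray:
    """Per-voxel z-normalization of a (frames, voxels) block.

    Zero-variance voxels map to 0 everywhere (flagged by the caller); the
    operation is idempotent.
    """
    mean = block.mean(axis=0)
    sd = block.std(axis=0)
    out = np.zeros_like(block, dtype=np.float64)
    nz = sd > 0
    out[:, nz] = (block[:, nz] - mean[nz]) / sd[nz]
    return out


def _as_image(img) -> nib.Nifti1Image:
    if isinstance(img, (str, Path)):
        return nib.load(str(img))
    return img


def extract_blocks(images: dict[str, "nib.Nifti1Image | str | Path"],
                   timing: pd.DataFrame,
                   mask_img: "nib.Nifti1Image | str | Path") -> FrameMatrix:
    """Cut labeled condition blocks out of each subject's series.

    Only frames inside the half-open [start_volume, end_volume) intervals are
    retained; voxels outside the binary mask are dropped; each block is
    z-normalized independently per voxel.
    """
    missing = [c for c in _TIMING_COLUMNS if c not in timing.columns]
    if missing:
        raise InputError(f"timing table lacks columns: {missing}")
    mask_img = _as_image(mask_img)
    mask = np.asarray(mask_img.dataobj) > 0
    if not mask.any():
        raise InputError("mask is empty")
    mask_voxel_ids = np.flatnonzero(mask.ravel())

    rows = []
    index_rows = []
    n_zero_variance = 0
    for subject, sub_timing in timing.groupby("subject", sort=False):
        if subject not in images:
            raise InputError(f"no image provided for subject {subject!r}")
        img = _as_image(images[subject])
        if img.shape[:3] != mask.shape:
            raise InputError(f"image grid {img.shape[:3]} does not match mask {mask.shape}")
        n_vol = img.shape[3]
        intervals = sorted((int(r.start_volume), int(r.end_volume))
                           for r in sub_timing.itertuples())
        for (s0, e0), (s1, _) in zip(intervals, intervals[1:]):
            if s1 < e0:
                raise InputError(f"overlapping timing intervals for subject {subject!r}")
        series = np.asarray(img.dataobj).reshape(-1, n_vol)[mask_voxel_ids]
        for row in sub_timing.itertuples():
            start, end = int(row.start_volume), int(row.end_volume)
            if not (0 <= start < end <= n_vol):
                raise InputError(
                    f"timing interval [{start}, {end}) out of range for subject "
                    f"{subject!r} with {n_vol} volumes")
            block = series[:, start:end].T.astype(np.float64)
            normalized = zscore_block(block)
            n_zero_variance += int((block.std(axis=0) == 0).sum())
            rows.append(normalized)
            for pos in range(end - start):
                index_rows.append((row.subject, row.condition, pos))
    if n_zero_variance:
        logger.info("zero-variance voxels set to 0 in %d voxel-block pairs", n_zero_variance)
    return FrameMatrix(
        data=np.vstack(rows),
        frame_index=pd.DataFrame(index_rows, columns=["subject", "condition", "position"]),
        mask_voxel_ids=mask_voxel_ids,
        grid_shape=mask.shape,
        affine=np.asarray(mask_img.affine),
    )


def pool_frames(matrices: list[FrameMatrix]) -> FrameMatrix:
    """Row-concatenate FrameMatrices sharing the same mask, keeping provenance."""
    if not matrices:
        raise InputError("nothing to pool")
    first = matrices[0]
    for m in matrices[1:]:
        if (m.grid_shape != first.grid_shape
                or not np.array_equal(m.mask_voxel_ids, first.mask_voxel_ids)):
            raise InputError("FrameMatrices use different masks; cannot pool")
    return FrameMatrix(
        data=np.vstack([m.data for m in matrices]),
        frame_index=pd.concat([m.frame_index for m in matrices], ignore_index=True),
        mask_voxel_ids=first.mask_voxel_ids,
        grid_shape=first.grid_shape,
        affine=first.affine,
    )
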