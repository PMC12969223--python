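"""Spatial labeling of CAPs against a 7-network parcellation, and
edge-artifact detection.

Each CAP centroid (a z-map over in-mask voxels) is correlated with the
binary indicator map of each reference network: +1 means the network
coincides with positive coactivation, -1 with codeactivation.  A CAP whose
strongest voxels concentrate on the one-voxel boundary shell of the mask is
flagged as a likely motion/susceptibility artifact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .consensus import CAPSet
from .errors import InputError
from .synthetic import boundary_shell

ARTIFACT_SCORE_THRESHOLD = 0.5
TOP_FRACTION = 0.1


@dataclass
class SimilarityTable:
    rho: pd.DataFrame          # CAP (1-based index) x network correlations
    best_network: pd.Series    # per CAP, argmax over networks of rho


def _mask_and_ids(mask_img) -> tuple[np.ndarray, np.ndarray]:
    mask = np.asarray(mask_img.dataobj) > 0
    return mask, np.flatnonzero(mask.ravel())


def spatial_similarity(caps: CAPSet, atlas_img, lookup: pd.DataFrame,
                       mask_img) -> SimilarityTable:
    """Pearson correlation of each centroid with each network indicator,
    across in-mask voxels.  Constant centroids or empty networks give NaN."""
    mask, mask_ids = _mask_and_ids(mask_img)
    if caps.centroids.shape[1] != mask_ids.size:
        raise InputError("centroid length does not match mask voxel count")
    atlas = np.asarray(atlas_img.dataobj).ravel()[mask_ids]
    networks = list(lookup["network"])
    labels = list(lookup["label"])
    rho = np.full((caps.k, len(networks)), np.nan)
    for j, label in enumerate(labels):
        indicator = (atlas == label).astype(float)
        if indicator.sum() == 0 or indicator.std() == 0:
            continue
        for c in range(caps.k):
            centroid = caps.centroids[c]
            if centroid.std() == 0:
                continue
            rho[c, j] = np.corrcoef(centroid, indicator)[0, 1]
    rho_df = pd.DataFrame(rho, index=pd.RangeIndex(1, caps.k + 1, name="cap"),
                          columns=networks)
    best = rho_df.apply(lambda row: row.idxmax() if row.notna().any() else pd.NA, axis=1)
    return SimilarityTable(rho=rho_df, best_network=best)


def artifact_scores(caps: CAPSet, mask_img, top_fraction: float = TOP_FRACTION) -> np.ndarray:
    """Fraction of each centroid's top-|z| voxels lying on the mask boundary.

    The top set is the ``top_fraction`` (default decile) of in-mask voxels by
    absolute z, so the score is invariant to sign and affine rescaling of the
    centroid.
    """
    mask, mask_ids = _mask_and_ids(mask_img)
    if caps.centroids.shape[1] != mask_ids.size:
        raise InputError("centroid length does not match mask voxel count")
    shell = boundary_shell(mask).ravel()[mask_ids]
    scores = np.empty(caps.k)
    for c in range(caps.k):
        a = np.abs(caps.centroids[c])
        cutoff = np.quantile(a, 1 - top_fraction)
        top = a >= cutoff
        scores[c] = shell[top].mean() if top.any() else 0.0
    return scores


def flag_artifacts(scores: np.ndarray, threshold: float = ARTIFACT_SCORE_THRESHOLD) -> np.ndarray:
    """Boolean per-CAP exclusion flags."""
    return np.asarray(scores) > threshold


def caps_to_nifti(caps: CAPSet, mask_img) -> list[nib.Nifti1Image]:
    """Re-embed centroid z-maps into the image grid, one NIfTI per CAP."""
    mask, mask_ids = _mask_and_ids(mask_img)
    images = []
    for c in range(caps.k):
        vol = np.zeros(mask.shape, dtype=np.float32)
        vol.ravel()[mask_ids] = caps.centroids[c]
        images.append(nib.Nifti1Image(vol.reshape(mask.shape), np.asarray(mask_img.affine)))
    return images


def save_cap_maps(caps: CAPSet, mask_img, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for c, img in enumerate(caps_to_nifti(caps, mask_img), start=1):
        path = outdir / f"cap-{c:02d}_zmap.nii"
        nib.save(img, path)
        paths.append(path)
    return paths
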