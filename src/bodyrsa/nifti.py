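"""Optional real-data I/O: NIfTI volumes and ROI masks.

The synthetic pipeline works on abstract voxel arrays; these helpers
map 4-D NIfTI time series and 3-D masks onto that representation so
real per-run data can be fed through the same GLM/RSA/decoding path.
The mask convention is nonzero = included; the affine is honored for
mm <-> voxel conversion when building sphere masks.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["load_bold", "load_roi_mask", "sphere_mask", "save_voxel_map"]


def load_bold(path: str | Path, mask: np.ndarray | None = None) -> np.ndarray:
    """Load a 4-D NIfTI run as voxels x volumes.

    With a 3-D boolean ``mask``, only in-mask voxels are returned (in
    C order of the mask's True positions).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected 4-D BOLD image, got shape {data.shape}")
    if mask is None:
        return data.reshape(-1, data.shape[-1]).astype(float)
    if mask.shape != data.shape[:3]:
        raise ValueError("mask shape does not match image grid")
    return data[mask].astype(float)


def load_roi_mask(path: str | Path) -> np.ndarray:
    """Load a 3-D NIfTI mask; nonzero voxels are included."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D mask, got shape {data.shape}")
    return data != 0


def sphere_mask(
    shape: tuple[int, int, int],
    affine: np.ndarray,
    center_mm: tuple[float, float, float],
    radius_mm: float = 8.0,
) -> np.ndarray:
    """Boolean sphere mask on an image grid (inclusive boundary).

    Voxel centers are mapped to mm through the affine; a voxel is
    included when its center lies within ``radius_mm`` of the target.
    """
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).reshape(-1, 4)
    mm = vox @ affine.T
    d2 = ((mm[:, :3] - np.asarray(center_mm)) ** 2).sum(axis=1)
    return (d2 <= radius_mm**2 + 1e-9).reshape(shape)


def save_voxel_map(
    values: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    path: str | Path,
) -> None:
    """Write per-voxel values back into mask positions as a 3-D NIfTI."""
    vol = np.zeros(mask.shape, dtype=float)
    vol[mask] = values
    nib.save(nib.Nifti1Image(vol, affine), str(path))
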