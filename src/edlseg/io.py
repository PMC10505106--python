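"""NIfTI I/O helpers (channel-first arrays <-> .nii/.nii.gz volumes).

Channel-first arrays are stored with the channel axis last in the NIfTI
file (the common convention for multi-channel volumes) and restored to
channel-first on load when ``n_channels`` metadata or an explicit flag says
so.  Uncertainty maps are written as float32 single-channel volumes.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_nifti", "load_nifti", "save_uncertainty"]


def save_nifti(array: np.ndarray, path, channel_first: bool | None = None) -> None:
    """Write an array as NIfTI; channel-first input is moved to channel-last."""
    array = np.asarray(array)
    if channel_first is None:
        channel_first = array.ndim >= 3
    data = np.moveaxis(array, 0, -1) if channel_first and array.ndim >= 3 else array
    img = nib.Nifti1Image(np.ascontiguousarray(data), affine=np.eye(4))
    nib.save(img, str(path))


def load_nifti(path, channel_first: bool = True) -> np.ndarray:
    """Read a NIfTI volume; multi-channel data comes back channel-first."""
    data = np.asarray(nib.load(str(path)).dataobj)
    if channel_first and data.ndim >= 3:
        data = np.moveaxis(data, -1, 0)
    return data


def save_uncertainty(u: np.ndarray, path) -> None:
    """Write an uncertainty map as a float32 single-channel volume."""
    arr = np.asarray(u, dtype=np.float32)
    nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))
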