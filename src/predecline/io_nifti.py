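"""Thin NIfTI-1 read/write helpers (nibabel-backed)."""

from __future__ import annotations

import numpy as np
import nibabel as nib

__all__ = ["write_volume", "read_volume", "write_volume_pair"]


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_volume_pair(pair, directory) -> None:
    """Write a subject's baseline/follow-up/label volumes as NIfTI-1."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    affine = np.diag([pair.voxel_size] * 3 + [1.0])
    write_volume(pair.baseline, affine, d / f"{pair.subject_id}_baseline.nii")
    write_volume(pair.followup, affine, d / f"{pair.subject_id}_followup.nii")
    img = nib.Nifti1Image(pair.labels.astype(np.int16), affine)
    nib.save(img, str(d / f"{pair.subject_id}_labels.nii"))
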