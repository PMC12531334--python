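"""NIfTI and tabular I/O with atomic writes.

Volumes are exchanged as NIfTI-1 with an identity-scaled affine recorded
from the grid's voxel size; cohort masks are validated binary and
shape-consistent. Real lesion deposits follow the naming convention
``lesion{id}_{age}_{sex}.nii.gz`` with NA for missing fields.
"""

from __future__ import annotations

import os
import re
import tempfile
import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .synth import GridSpec

_LESION_NAME = re.compile(
    r"^lesion(?P<id>[^_]+)_(?P<age>[^_]+)_(?P<sex>[^_.]+)\.nii(\.gz)?$"
)


def atomic_write(path: str, writer) -> None:
    """Write via a temp file in the destination directory, then rename."""
    d = os.path.dirname(os.path.abspath(path)) or "."
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.remove(tmp)


def write_volume(volume: np.ndarray, spec: GridSpec, path: str) -> None:
    arr = np.asarray(volume)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, spec.affine)
    d = os.path.dirname(os.path.abspath(path)) or "."
    os.makedirs(d, exist_ok=True)
    suffix = ".nii.gz" if path.endswith(".gz") else ".nii"
    fd, tmp = tempfile.mkstemp(dir=d, suffix=suffix)
    os.close(fd)
    try:
        nib.save(img, tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.remove(tmp)


def read_volume(path: str) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(path)
    return np.asanyarray(img.dataobj), img.affine


def read_mask_nifti(path: str, tol: float = 1e-6) -> np.ndarray:
    """Load a NIfTI volume and validate it is binary within tolerance."""
    data, _ = read_volume(path)
    data = np.asarray(data, dtype=float)
    rounded = np.round(data)
    if np.abs(data - rounded).max() > tol or not np.isin(rounded, (0, 1)).all():
        bad = data[np.abs(data - rounded) > tol]
        example = bad.flat[0] if bad.size else data[~np.isin(rounded, (0, 1))].flat[0]
        raise ValueError(f"{path}: non-binary value {example!r} in lesion mask")
    return rounded.astype(bool)


def read_cohort_masks(paths) -> list[tuple[str, np.ndarray]]:
    """Load a cohort of binary masks, enforcing one shared grid."""
    out = []
    ref_shape, ref_path = None, None
    for p in paths:
        mask = read_mask_nifti(p)
        if ref_shape is None:
            ref_shape, ref_path = mask.shape, p
        elif mask.shape != ref_shape:
            raise ValueError(
                f"shape mismatch: {ref_path} is {ref_shape} but {p} is {mask.shape}"
            )
        out.append((os.path.basename(p), mask))
    return out


@dataclass(frozen=True)
class LesionMeta:
    patient_id: str
    age: int | None
    sex: str | None


def parse_lesion_filename(name: str) -> LesionMeta:
    """Parse ``lesion{id}_{age}_{sex}.nii.gz``; NA fields become None;
    non-conforming names fall back to an id-only record with a warning."""
    m = _LESION_NAME.match(name)
    if m is None:
        warnings.warn(f"filename {name!r} does not follow the deposit convention")
        stem = re.sub(r"\.nii(\.gz)?$", "", name)
        return LesionMeta(stem, None, None)
    age = None if m["age"].upper() == "NA" else int(m["age"])
    sex = None if m["sex"].upper() == "NA" else m["sex"]
    return LesionMeta(m["id"], age, sex)


def write_records_tsv(records, path: str) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id, "network": r.network_id,
                "r_A": r.r_A, "r_B": r.r_B, "s": r.s, "tau": r.tau,
                "rep_kind": r.rep_kind,
            }
            for r in records
        ]
    )
    atomic_write(path, lambda tmp: df.to_csv(tmp, sep="\t", index=False))
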