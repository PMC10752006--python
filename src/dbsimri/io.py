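"""File formats: NIfTI-1 volumes, FSL-style bval/bvec text, cohort output.

Gradient tables follow the FSL convention: a whitespace-delimited
``bval`` row of K values (s/mm2) and a 3 x K ``bvec`` matrix of
direction components.  b-values below 10 s/mm2 are treated as b = 0
references, whose direction rows may be zero vectors.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np

from .schemes import B0_THRESHOLD, GradientScheme
from .phantom import Cohort

__all__ = [
    "read_dwi",
    "read_mask",
    "read_bvals_bvecs",
    "write_dwi",
    "write_mask",
    "write_bvals_bvecs",
    "write_maps",
    "write_cohort",
]


def read_bvals_bvecs(bval_path, bvec_path) -> GradientScheme:
    """Parse FSL-style gradient tables into a GradientScheme."""
    try:
        bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    except ValueError as exc:
        raise ValueError(f"non-numeric bval file {bval_path}: {exc}") from None
    try:
        bvecs = np.loadtxt(bvec_path, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric bvec file {bvec_path}: {exc}") from None
    if bvecs.shape[0] != 3 and bvecs.shape[1] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (3, bvals.size):
        raise ValueError(
            f"bvec shape {bvecs.shape} incompatible with {bvals.size} b-values"
        )
    directions = bvecs.T.astype(float).copy()
    weighted = bvals >= B0_THRESHOLD
    norms = np.linalg.norm(directions, axis=1)
    if np.any(norms[weighted] == 0):
        raise ValueError("zero direction vector at a diffusion-weighted entry")
    directions[weighted] /= norms[weighted, None]
    directions[~weighted] = 0.0
    return GradientScheme(directions, bvals)


def read_dwi(dwi_path, bval_path, bvec_path) -> tuple[nib.Nifti1Image, GradientScheme]:
    """Load a 4-D DWI NIfTI together with its gradient scheme.

    The scheme length must equal the 4th image dimension.
    """
    img = nib.load(os.fspath(dwi_path))
    if img.ndim != 4:
        raise ValueError(f"{dwi_path}: expected a 4-D DWI volume, got {img.ndim}-D")
    scheme = read_bvals_bvecs(bval_path, bvec_path)
    n_vols = img.shape[3]
    if n_vols != len(scheme):
        raise ValueError(
            f"{dwi_path} has {n_vols} volumes but the gradient table has "
            f"{len(scheme)} entries"
        )
    return img, scheme


def read_mask(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a binary mask NIfTI; returns (bool array, affine)."""
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    return data.astype(bool), img.affine


def write_dwi(path, data: np.ndarray, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64),
                             affine if affine is not None else np.eye(4)), path)
    return path


def write_mask(path, mask: np.ndarray, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8),
                             affine if affine is not None else np.eye(4)), path)
    return path


def write_bvals_bvecs(scheme: GradientScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvalues[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.8f")


def write_maps(maps: dict[str, np.ndarray], outdir, affine=None, prefix: str = "") -> list[Path]:
    """Write one NIfTI per metric map; the metric name is in the filename."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in maps.items():
        p = outdir / f"{prefix}{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64),
                                 affine if affine is not None else np.eye(4)), p)
        paths.append(p)
    return paths


def _voxel_affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_cohort(cohort: Cohort, outdir) -> Path:
    """Write a simulated cohort to disk: per-scan DWI + mask NIfTIs, the
    shared gradient tables, and the ground-truth table as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bvals_bvecs(cohort.scheme, outdir / "cohort.bval", outdir / "cohort.bvec")
    aff = _voxel_affine(cohort.spec.voxel_size)
    for s in cohort.scans:
        stem = f"{s.animal}_{s.eye}_day{s.day:02d}"
        write_dwi(outdir / f"{stem}_dwi.nii", s.dwi, aff)
        write_mask(outdir / f"{stem}_mask.nii", s.mask, aff)
    cohort.truth_table.to_csv(outdir / "ground_truth.csv", index=False)
    return outdir
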