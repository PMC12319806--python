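"""File I/O: NIfTI volumes, FSL bvals/bvecs, TCK tractograms, edge tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import AcquisitionScheme

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_scheme",
    "load_scheme",
    "save_edges_csv",
    "load_edges_csv",
    "write_phantom_dataset",
]


def save_nifti(data, affine, path) -> None:
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float))
    nib.save(img, str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_scheme(scheme: AcquisitionScheme, bvals_path, bvecs_path) -> None:
    """FSL convention: one row of b-values; bvecs as 3 rows of N columns."""
    np.savetxt(str(bvals_path), scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(str(bvecs_path), scheme.bvecs.T, fmt="%.9g")


def load_scheme(bvals_path, bvecs_path) -> AcquisitionScheme:
    bvals = np.loadtxt(str(bvals_path)).ravel()
    bvecs = np.loadtxt(str(bvecs_path))
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    return AcquisitionScheme(bvals, bvecs)


def save_edges_csv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(str(path), index=False)


def load_edges_csv(path) -> pd.DataFrame:
    return pd.read_csv(str(path))


def write_phantom_dataset(out_dir, streamlines, truth, parcellation, calib_roi,
                          scheme, dwi) -> None:
    """Write a complete phantom dataset: NIfTI volumes (RAS affine), TCK
    streamlines (world mm), FSL gradient text files, and a JSON ground-truth
    sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = truth.affine
    save_nifti(dwi, aff, out / "dwi.nii.gz")
    for name in ("mvf", "avf", "icvf", "isovf", "fa", "g", "mtsat"):
        save_nifti(getattr(truth, name), aff, out / f"{name}.nii.gz")
    save_nifti(parcellation.astype(np.int32), aff, out / "parcellation.nii.gz")
    save_nifti(calib_roi.astype(np.uint8), aff, out / "calib_roi.nii.gz")
    streamlines.save_tck(out / "streamlines.tck")
    save_scheme(scheme, out / "bvals", out / "bvecs")
    sidecar = {
        "axon_csa": truth.axon_csa.tolist(),
        "myelin_csa": truth.myelin_csa.tolist(),
        "bundle_id": truth.bundle_id.tolist(),
        "edges": truth.edges.to_dict(orient="records"),
        "voxel_size": truth.voxel_size,
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
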