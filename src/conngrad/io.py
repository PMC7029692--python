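"""File I/O: NIfTI volumes, .npz containers for matrices/fingerprints, TSV tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import BinaryMask, SeedROI, VolumeGrid, roi_from_mask
from .roi_geometry import FingerprintSet
from .similarity import SimilarityMatrix
from .spectral import ReorderingResult


def load_volume(path) -> tuple[np.ndarray, VolumeGrid]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    grid = VolumeGrid(tuple(data.shape[:3]), img.affine)
    return data, grid


def save_volume(path, data: np.ndarray, grid: VolumeGrid) -> None:
    img = nib.Nifti1Image(np.asarray(data), np.asarray(grid.affine))
    nib.save(img, str(path))


def load_mask(path) -> BinaryMask:
    data, grid = load_volume(path)
    return BinaryMask(grid, data > 0)


def save_mask(path, mask: BinaryMask) -> None:
    save_volume(path, mask.values.astype(np.uint8), mask.grid)


def load_seed_roi(path) -> SeedROI:
    return roi_from_mask(load_mask(path))


def save_similarity(path, sim: SimilarityMatrix) -> None:
    np.savez(
        path,
        values=sim.values,
        mode=np.array(sim.mode),
        self_similarity=np.array(sim.self_similarity),
        roi_voxels=sim.roi.voxels,
        roi_shape=np.array(sim.roi.grid.shape),
        roi_affine=sim.roi.grid.affine,
    )


def load_similarity(path) -> SimilarityMatrix:
    with np.load(path, allow_pickle=False) as z:
        grid = VolumeGrid(tuple(int(s) for s in z["roi_shape"]), z["roi_affine"])
        roi = SeedROI(grid, z["roi_voxels"])
        return SimilarityMatrix(
            roi, z["values"], mode=str(z["mode"]), self_similarity=float(z["self_similarity"])
        )


def save_fingerprints(path, fp: FingerprintSet) -> None:
    extra = {}
    if fp.target_grid is not None:
        extra = {
            "target_shape": np.array(fp.target_grid.shape),
            "target_affine": fp.target_grid.affine,
        }
    np.savez(
        path,
        values=fp.values,
        targets=fp.targets,
        kind=np.array(fp.kind),
        roi_voxels=fp.roi.voxels,
        roi_shape=np.array(fp.roi.grid.shape),
        roi_affine=fp.roi.grid.affine,
        **extra,
    )


def load_fingerprints(path) -> FingerprintSet:
    with np.load(path, allow_pickle=False) as z:
        grid = VolumeGrid(tuple(int(s) for s in z["roi_shape"]), z["roi_affine"])
        roi = SeedROI(grid, z["roi_voxels"])
        tgrid = None
        if "target_shape" in z:
            tgrid = VolumeGrid(tuple(int(s) for s in z["target_shape"]), z["target_affine"])
        return FingerprintSet(roi, z["targets"], z["values"], str(z["kind"]), target_grid=tgrid)


def save_reordering(path, res: ReorderingResult) -> None:
    np.savez(
        path,
        eigenvalues=res.eigenvalues,
        fiedler=res.fiedler,
        permutation=res.permutation,
        lambda2=np.array(res.lambda2),
    )


def load_reordering(path) -> ReorderingResult:
    with np.load(path, allow_pickle=False) as z:
        return ReorderingResult(
            eigenvalues=z["eigenvalues"],
            fiedler=z["fiedler"],
            permutation=z["permutation"],
            lambda2=float(z["lambda2"]),
        )


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
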