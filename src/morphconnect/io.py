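"""File I/O: NIfTI volumes, GIFTI surfaces/vertex maps, CSV and YAML."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .mesh import SurfaceMesh

__all__ = [
    "save_volume",
    "load_volume",
    "save_mesh_gifti",
    "load_mesh_gifti",
    "save_vertex_map_gifti",
    "load_vertex_map_gifti",
    "load_config",
    "save_config",
]


def save_volume(data: np.ndarray, path, voxel_size_mm: float = 1.0) -> None:
    """Write a 3-D array as NIfTI-1 with an isotropic diagonal affine."""
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_mesh_gifti(mesh: SurfaceMesh, path) -> None:
    img = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(
                mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            ),
            nib.gifti.GiftiDataArray(
                mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            ),
        ]
    )
    nib.save(img, str(path))


def load_mesh_gifti(path) -> SurfaceMesh:
    img = nib.load(str(path))
    verts = faces = None
    for da in img.darrays:
        if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            verts = np.asarray(da.data, float)
        elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            faces = np.asarray(da.data, int)
    if verts is None or faces is None:
        raise ValueError(f"{path} lacks a pointset/triangle pair")
    return SurfaceMesh(verts, faces)


def save_vertex_map_gifti(values: np.ndarray, path) -> None:
    img = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(
                np.asarray(values, dtype=np.float32), intent="NIFTI_INTENT_NONE"
            )
        ]
    )
    nib.save(img, str(path))


def load_vertex_map_gifti(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.darrays[0].data, float)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
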