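"""Readers/writers, dataset manifests and provenance logging.

Formats: TIFF/OME-TIFF for images and masks, PLY/OBJ for meshes, NPZ/CSV
for point clouds and embeddings, YAML for configuration, JSON/CSV for
reports. Every artifact-producing run writes a plain-text run log with the
config hash, seeds and package version so outputs can be regenerated
bit-exactly in deterministic mode.
"""

from __future__ import annotations

import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh
import yaml

__all__ = [
    "read_image",
    "write_image",
    "read_mesh",
    "write_mesh",
    "load_manifest",
    "save_pointcloud",
    "load_pointcloud",
    "write_run_log",
]

DEFAULT_VOXEL_SIZE = (1.0, 1.0, 1.0)


def read_image(path):
    """Read a 3D single-channel TIFF/OME-TIFF.

    Returns ``(voxels, voxel_size)`` with voxels in ZYX order and voxel
    size in micrometres (ZYX). Falls back to (1, 1, 1) with a warning when
    no resolution metadata is present.
    """
    path = Path(path)
    if path.suffix.lower() not in {".tif", ".tiff"}:
        raise ValueError(
            f"unsupported image format {path.suffix!r}; expected TIFF or "
            "OME-TIFF"
        )
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        voxel_size = _voxel_size_from_metadata(tf)
    if arr.ndim != 3:
        raise ValueError(
            f"expected a 3D single-channel stack, got shape {arr.shape}; "
            "select a channel before loading"
        )
    if voxel_size is None:
        warnings.warn(
            f"{path.name}: no voxel-size metadata; defaulting to (1, 1, 1)",
            stacklevel=2,
        )
        voxel_size = DEFAULT_VOXEL_SIZE
    return arr, tuple(voxel_size)


def _voxel_size_from_metadata(tf):
    try:
        ome = tf.ome_metadata
    except Exception:
        ome = None
    if ome:
        import re

        sizes = {}
        for axis in ("Z", "Y", "X"):
            m = re.search(rf'PhysicalSize{axis}="([0-9.eE+-]+)"', ome)
            if m:
                sizes[axis] = float(m.group(1))
        if len(sizes) == 3:
            return (sizes["Z"], sizes["Y"], sizes["X"])
    return None


def write_image(path, voxels, voxel_size=None):
    """Write a 3D array as OME-TIFF with physical voxel sizes."""
    voxels = np.asarray(voxels)
    meta = None
    if voxel_size is not None:
        z, y, x = voxel_size
        meta = {
            "axes": "ZYX",
            "PhysicalSizeZ": z,
            "PhysicalSizeY": y,
            "PhysicalSizeX": x,
        }
    tifffile.imwrite(path, voxels, metadata=meta, ome=voxel_size is not None)


def read_mesh(path) -> trimesh.Trimesh:
    """Read a PLY or OBJ mesh (quads triangulated deterministically)."""
    path = Path(path)
    if path.suffix.lower() not in {".ply", ".obj"}:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")
    mesh = trimesh.load(path, force="mesh", process=False)
    if mesh.is_empty or len(mesh.faces) == 0:
        raise ValueError(f"{path.name}: empty mesh")
    if not mesh.is_watertight:
        warnings.warn(f"{path.name}: mesh is not watertight", stacklevel=2)
    return mesh


def write_mesh(path, mesh):
    """Write a mesh; PLY is binary little-endian with float64 vertices
    (bit-exact round trips), other suffixes go through trimesh export."""
    path = Path(path)
    if path.suffix.lower() != ".ply":
        mesh.export(path)
        return
    vertices = np.ascontiguousarray(mesh.vertices, dtype="<f8")
    faces = np.ascontiguousarray(mesh.faces, dtype="<i4")
    header = (
        "ply\nformat binary_little_endian 1.0\n"
        f"element vertex {len(vertices)}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {len(faces)}\n"
        "property list uchar int vertex_indices\nend_header\n"
    )
    face_block = np.empty(
        len(faces), dtype=[("n", "u1"), ("idx", "<i4", (3,))]
    )
    face_block["n"] = 3
    face_block["idx"] = faces
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(vertices.tobytes())
        fh.write(face_block.tobytes())


def load_manifest(path, validate_paths: bool = True) -> pd.DataFrame:
    """Load a dataset manifest CSV and validate it.

    Requires unique ids; when ``validate_paths`` is set, every referenced
    file must exist relative to the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError("manifest must have an 'id' column")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate manifest ids: {dupes[:5]}")
    if validate_paths:
        root = path.parent
        for col in df.columns:
            if not col.endswith("_path"):
                continue
            for p in df[col].dropna():
                if p and not (root / p).exists():
                    raise FileNotFoundError(
                        f"manifest references missing file {p!r}"
                    )
    return df


def save_pointcloud(path, points, **metadata):
    """NPZ point cloud with float64 coordinates plus metadata keys."""
    np.savez(path, points=np.asarray(points, dtype=np.float64), **metadata)


def load_pointcloud(path):
    with np.load(path) as z:
        points = z["points"]
        meta = {k: z[k] for k in z.files if k != "points"}
    return points, meta


def write_run_log(out_dir, command: str, config: dict, seed: int):
    """Plain-text provenance log next to the outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = {
        "command": command,
        "seed": seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config,
    }
    with open(out_dir / "run_log.yaml", "a") as fh:
        fh.write(yaml.safe_dump([log], sort_keys=False))
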