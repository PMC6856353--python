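"""Readers and writers for the formats the pipeline touches.

Per-vertex scalar overlays: FreeSurfer curv, MGH/MGZ, GIFTI functional files,
or delimited text.  Meshes: FreeSurfer binary surface or GIFTI.  Cluster
tables and phenotype tables: TSV.  All writers round-trip losslessly for
their own output (within float32 precision for the binary overlay formats).
Vertex indices are 0-based everywhere; hemispheres are separate meshes.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .mapping import Cluster, ClusterTable
from .mesh import SurfaceMesh

_TEXT_EXT = {".tsv", ".txt", ".csv"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".mgh", ".mgz"):
        return "mgh"
    if suffix == ".gii":
        return "gifti"
    if suffix in _TEXT_EXT:
        return "tsv"
    return "curv"


def _check_length(n: int, mesh: SurfaceMesh | None, path) -> None:
    if mesh is not None and n != mesh.n_vertices:
        raise ValueError(
            f"{path}: overlay has {n} vertices but the mesh has "
            f"{mesh.n_vertices}"
        )


def read_vertex_data(path, fmt: str | None = None, mesh: SurfaceMesh | None = None):
    """Read a per-vertex vector/matrix.

    Returns an ndarray (vertices first axis) for curv/MGH/GIFTI, and a
    DataFrame (header labels preserved) for delimited text.  When ``mesh`` is
    given the vertex count is validated against it.
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "curv":
        data = np.asarray(nib.freesurfer.io.read_morph_data(str(path)))
    elif fmt == "mgh":
        img = nib.load(str(path))
        arr = np.asarray(img.get_fdata())
        data = arr.reshape(arr.shape[0], -1)
        if data.shape[1] == 1:
            data = data[:, 0]
    elif fmt == "gifti":
        img = nib.load(str(path))
        cols = [np.asarray(d.data) for d in img.darrays]
        data = cols[0] if len(cols) == 1 else np.column_stack(cols)
    elif fmt == "tsv":
        data = pd.read_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown vertex-data format {fmt!r}")
    n = len(data)
    _check_length(n, mesh, path)
    return data


def write_vertex_data(data, path, fmt: str | None = None) -> Path:
    """Write a per-vertex vector/matrix in the requested format."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "tsv":
        df = data if isinstance(data, pd.DataFrame) else pd.DataFrame(np.asarray(data))
        df.to_csv(path, sep="\t", index=False)
        return path
    arr = np.asarray(data, dtype=np.float32)
    if fmt == "curv":
        if arr.ndim != 1:
            raise ValueError("curv holds a single per-vertex scalar")
        nib.freesurfer.io.write_morph_data(str(path), arr)
    elif fmt == "mgh":
        if arr.ndim == 1:
            vol = arr.reshape(arr.shape[0], 1, 1)
        else:
            vol = arr.reshape(arr.shape[0], 1, 1, arr.shape[1])
        nib.save(nib.MGHImage(vol, np.eye(4)), str(path))
    elif fmt == "gifti":
        cols = [arr] if arr.ndim == 1 else [arr[:, j] for j in range(arr.shape[1])]
        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(c.astype(np.float32), intent="NIFTI_INTENT_NONE")
            for c in cols
        ])
        nib.save(img, str(path))
    else:
        raise ValueError(f"unknown vertex-data format {fmt!r}")
    return path


def read_surface(path, fmt: str | None = None, hemisphere: str = "lh") -> SurfaceMesh:
    """Read a triangulated surface (FreeSurfer geometry or GIFTI)."""
    path = Path(path)
    fmt = fmt or ("gifti" if path.suffix.lower() == ".gii" else "freesurfer")
    if fmt == "freesurfer":
        coords, faces = nib.freesurfer.io.read_geometry(str(path))
    elif fmt == "gifti":
        img = nib.load(str(path))
        coords = faces = None
        for d in img.darrays:
            if d.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                coords = np.asarray(d.data)
            elif d.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                faces = np.asarray(d.data)
        if coords is None or faces is None:
            raise ValueError(f"{path}: GIFTI file lacks pointset/triangle arrays")
    else:
        raise ValueError(f"unknown surface format {fmt!r}")
    return SurfaceMesh(np.asarray(coords, float), np.asarray(faces, int), hemisphere)


def write_surface(mesh: SurfaceMesh, path, fmt: str | None = None) -> Path:
    path = Path(path)
    fmt = fmt or ("gifti" if path.suffix.lower() == ".gii" else "freesurfer")
    if fmt == "freesurfer":
        nib.freesurfer.io.write_geometry(str(path), mesh.vertex_coords,
                                         mesh.triangles)
    elif fmt == "gifti":
        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(mesh.vertex_coords.astype(np.float32),
                                     intent="NIFTI_INTENT_POINTSET"),
            nib.gifti.GiftiDataArray(mesh.triangles.astype(np.int32),
                                     intent="NIFTI_INTENT_TRIANGLE"),
        ])
        nib.save(img, str(path))
    else:
        raise ValueError(f"unknown surface format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

CLUSTER_COLUMNS = ["Cluster", "COG X", "COG Y", "COG Z",
                   "Number of vertices", "sign", "replicated"]


def write_cluster_table(table: ClusterTable, path) -> Path:
    """Write a cluster table as TSV (COG coordinates in mm, 2 decimals)."""
    path = Path(path)
    df = table.to_frame()
    for c in ("COG X", "COG Y", "COG Z"):
        df[c] = df[c].astype(float).round(2)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_cluster_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CLUSTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: cluster table lacks columns {sorted(missing)}")
    return df


def write_phenotype_table(df: pd.DataFrame, path) -> Path:
    """Phenotype table contract: family_id, twin, zygosity (+ sex, covariates,
    item/score columns), one row per individual."""
    for col in ("family_id", "twin", "zygosity"):
        if col not in df.columns:
            raise ValueError(f"phenotype table lacks column {col!r}")
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_phenotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("family_id", "twin", "zygosity"):
        if col not in df.columns:
            raise ValueError(f"{path}: phenotype table lacks column {col!r}")
    return df


def write_expression_matrix(matrix, path) -> Path:
    matrix.to_frame().to_csv(Path(path), sep="\t", index=True, index_label="gene")
    return Path(path)


def read_expression_matrix(path):
    from .expression import ExpressionMatrix

    df = pd.read_csv(path, sep="\t", index_col="gene")
    return ExpressionMatrix.from_frame(df)
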