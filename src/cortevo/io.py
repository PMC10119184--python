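"""File formats: surface meshes (OFF/PLY), vertex-field tables, correspondences.

Vertex indices are 0-based both internally and in all emitted files.
Vertex fields travel as headered comma-separated text with the vertex index
in the first column; correspondence files store one row per source vertex
(target face id plus three barycentric weights).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import trimesh

from .mesh import BarycentricAttachment, SurfaceMesh, VertexField

__all__ = [
    "read_mesh", "write_mesh",
    "read_vertex_fields", "write_vertex_fields",
    "read_correspondence", "write_correspondence",
]


def read_mesh(path: str, hemisphere: str = "left") -> SurfaceMesh:
    """Load an OFF or PLY surface (ASCII, or binary little-endian PLY)."""
    tm = trimesh.load(path, process=False, force="mesh")
    return SurfaceMesh(np.asarray(tm.vertices, dtype=float),
                       np.asarray(tm.faces, dtype=np.int64), hemisphere)


def write_mesh(mesh: SurfaceMesh, path: str) -> None:
    """Write a surface as ASCII OFF or PLY, chosen by file extension."""
    ext = os.path.splitext(path)[1].lower()
    tm = mesh.to_trimesh()
    if ext == ".off":
        tm.export(path)
    elif ext == ".ply":
        tm.export(path, encoding="ascii")
    else:
        raise ValueError(f"unsupported mesh format: {ext}")


def write_vertex_fields(fields: dict[str, VertexField] | dict[str, np.ndarray],
                        path: str) -> None:
    cols = {}
    n = None
    for name, f in fields.items():
        vals = f.values if isinstance(f, VertexField) else np.asarray(f, dtype=float)
        if vals.ndim == 1:
            cols[name] = vals
        else:
            for c in range(vals.shape[1]):
                cols[f"{name}_{c}"] = vals[:, c]
        n = len(vals)
    df = pd.DataFrame({"vertex": np.arange(n), **cols})
    df.to_csv(path, index=False)


def read_vertex_fields(path: str) -> dict[str, VertexField]:
    df = pd.read_csv(path)
    if "vertex" not in df.columns:
        raise ValueError("vertex-field file must have a 'vertex' index column")
    df = df.sort_values("vertex")
    return {c: VertexField(df[c].to_numpy(), c) for c in df.columns if c != "vertex"}


def write_correspondence(att: BarycentricAttachment, path: str) -> None:
    df = pd.DataFrame({
        "source_vertex": np.arange(len(att.face_ids)),
        "target_face": att.face_ids,
        "w0": att.weights[:, 0], "w1": att.weights[:, 1], "w2": att.weights[:, 2],
    })
    df.to_csv(path, index=False)


def read_correspondence(path: str) -> BarycentricAttachment:
    df = pd.read_csv(path).sort_values("source_vertex")
    return BarycentricAttachment(df["target_face"].to_numpy(np.int64),
                                 df[["w0", "w1", "w2"]].to_numpy(float))
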