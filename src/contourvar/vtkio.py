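"""Minimal legacy-VTK polydata writer (ASCII) for surface meshes.

Only what the SD-map export needs: triangle meshes with optional per-vertex
scalar channels. PLY export goes through trimesh; this covers the VTK side.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_vtk_polydata"]


def write_vtk_polydata(
    vertices: np.ndarray,
    faces: np.ndarray,
    path: str | Path,
    point_scalars: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a triangle mesh as legacy VTK polydata (version 4.2, ASCII)."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    lines = [
        "# vtk DataFile Version 4.2",
        "surface mesh",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(vertices)} float",
    ]
    lines += [" ".join(f"{c:.6f}" for c in v) for v in vertices]
    lines.append(f"POLYGONS {len(faces)} {4 * len(faces)}")
    lines += ["3 " + " ".join(str(i) for i in f) for f in faces]
    if point_scalars:
        lines.append(f"POINT_DATA {len(vertices)}")
        for name, values in point_scalars.items():
            values = np.asarray(values, dtype=float)
            if len(values) != len(vertices):
                raise ValueError(
                    f"scalar channel {name!r} has {len(values)} values for "
                    f"{len(vertices)} vertices"
                )
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.6f}" for v in values]
    Path(path).write_text("\n".join(lines) + "\n")
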