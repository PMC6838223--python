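"""Minimal legacy-ASCII VTK writers for visualization interchange.

Two artifact kinds are supported: centerlines as POLYDATA polylines and
displacement/strain vector fields as STRUCTURED_POINTS with point-data
vectors.  Files follow the VTK legacy format version 2.0 and open directly in
ParaView/3D Slicer.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .centerline import Centerline
from .core import VectorField


def write_centerline_vtk(cl: Centerline, path: str | Path) -> None:
    """Write a centerline as a legacy-ASCII VTK polyline.

    Branch labels, when present, are written as a per-point scalar array.
    """
    pts = np.asarray(cl.points, dtype=float)
    n = len(pts)
    lines = [
        "# vtk DataFile Version 2.0",
        "aortic centerline",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} float",
    ]
    lines += [f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}" for p in pts]
    lines.append(f"LINES 1 {n + 1}")
    lines.append(" ".join([str(n)] + [str(i) for i in range(n)]))
    if cl.branch_labels is not None:
        lines += [
            f"POINT_DATA {n}",
            "SCALARS branch int 1",
            "LOOKUP_TABLE default",
        ]
        lines += [str(int(b)) for b in cl.branch_labels]
    Path(path).write_text("\n".join(lines) + "\n")


def write_structured_vector_field(fieldv: VectorField, path: str | Path,
                                  name: str = "displacement") -> None:
    """Write a vector field as legacy-ASCII VTK STRUCTURED_POINTS.

    Vector components are world-millimeter displacements; the lattice origin
    and spacing are carried through so the glyphs land in scanner coordinates.
    """
    nx, ny, nz = fieldv.vectors.shape[:3]
    sx, sy, sz = fieldv.spacing
    ox, oy, oz = fieldv.origin
    lines = [
        "# vtk DataFile Version 2.0",
        f"{name} field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {ox:.6g} {oy:.6g} {oz:.6g}",
        f"SPACING {sx:.6g} {sy:.6g} {sz:.6g}",
        f"POINT_DATA {nx * ny * nz}",
        f"VECTORS {name} float",
    ]
    # VTK structured points iterate x fastest, z slowest
    flat = np.transpose(fieldv.vectors, (2, 1, 0, 3)).reshape(-1, 3)
    lines += [f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g}" for v in flat]
    Path(path).write_text("\n".join(lines) + "\n")
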