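"""Minimal legacy-ASCII VTK STRUCTURED_POINTS writer for field export.

Only the subset needed to dump 2D/3D scalar fields on uniform grids for
inspection in ParaView; not a general VTK library.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np

__all__ = ["write_structured_points"]


def write_structured_points(
    path: Union[str, Path],
    fields: dict[str, np.ndarray],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> None:
    """Write scalar fields on a uniform grid as legacy ASCII VTK.

    All fields must share a shape (nx, ny) or (nx, ny, nz); values are
    written in VTK's x-fastest order.
    """
    if not fields:
        raise ValueError("no fields to write")
    shapes = {np.asarray(v).shape for v in fields.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must share one shape")
    shape = shapes.pop()
    if len(shape) == 2:
        shape = (*shape, 1)
    nx, ny, nz = shape
    lines = [
        "# vtk DataFile Version 3.0",
        "pillarmps field export",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {origin[0]:g} {origin[1]:g} {origin[2]:g}",
        f"SPACING {spacing[0]:g} {spacing[1]:g} {spacing[2]:g}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, arr in fields.items():
        a = np.asarray(arr, dtype=float).reshape(nx, ny, nz)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # x varies fastest in VTK
        flat = a.transpose(2, 1, 0).ravel()
        lines.extend(" ".join(f"{v:.6g}" for v in flat[i:i + 9])
                     for i in range(0, flat.size, 9))
    Path(path).write_text("\n".join(lines) + "\n")
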