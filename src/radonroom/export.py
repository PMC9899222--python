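"""Plain-text field export: legacy-ASCII VTK structured points and CSV
point probes.

The legacy VTK format is written directly (it is a simple self-describing
text format); cell-centred fields are exported as POINT_DATA on the
cell-centre lattice so any VTK-aware viewer renders them without
conversion.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .room import Grid
from .transport import sample_at


def write_vtk_structured(path, grid: Grid,
                         scalars: dict[str, np.ndarray] | None = None,
                         vectors: dict[str, tuple] | None = None) -> Path:
    """Write cell-centred fields to a legacy-ASCII VTK file.

    ``scalars`` maps name -> (nx, ny, nz) array; ``vectors`` maps name ->
    three cell-centred component arrays.
    """
    path = Path(path)
    scalars = scalars or {}
    vectors = vectors or {}
    nx, ny, nz = grid.shape
    x, y, z = grid.cell_centers
    lines = [
        "# vtk DataFile Version 3.0",
        "radonroom field export",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {x[0]:.9g} {y[0]:.9g} {z[0]:.9g}",
        f"SPACING {grid.dx:.9g} {grid.dy:.9g} {grid.dz:.9g}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, arr in scalars.items():
        arr = np.asarray(arr)
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        # VTK expects x varying fastest
        flat = arr.transpose(2, 1, 0).ravel()
        lines.extend(" ".join(f"{v:.6g}" for v in flat[i:i + 9])
                     for i in range(0, flat.size, 9))
    for name, comps in vectors.items():
        cx, cy, cz = (np.asarray(c) for c in comps)
        lines.append(f"VECTORS {name} float")
        stacked = np.stack([cx.transpose(2, 1, 0).ravel(),
                            cy.transpose(2, 1, 0).ravel(),
                            cz.transpose(2, 1, 0).ravel()], axis=1)
        lines.extend(" ".join(f"{v:.6g}" for v in row) for row in stacked)
    path.write_text("\n".join(lines) + "\n")
    return path


def probe_csv(path, field, grid: Grid, points: pd.DataFrame) -> Path:
    """Sample a field at labelled points and write a CSV probe table.

    ``points`` needs columns point, x_m, y_m, z_m.
    """
    path = Path(path)
    pts = points[["x_m", "y_m", "z_m"]].to_numpy(dtype=float)
    out = points.copy()
    out["concentration_bq_m3"] = sample_at(field, grid, pts)
    out.to_csv(path, index=False)
    return path
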