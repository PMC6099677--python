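"""StDev*Coeff contour fields and volumetric export (OpenDX, Gaussian cube).

The display statistic behind CoMFA/CoMSIA contour maps is the product of
each retained column's PLS coefficient and its training-set standard
deviation: large positive voxels mark lattice regions where increasing the
field raises predicted activity ("favored"), large negative voxels the
opposite.  Columns removed by the pre-fit filter carry value 0.  Contour
levels default to the 80th (favored) and 20th (disfavored) percentiles of
the nonzero voxel values, with linear interpolation between order
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fields import GridSpec
from .pls import PLSModelSummary

__all__ = [
    "ContourField",
    "stdev_coeff_field",
    "threshold_levels",
    "export_volumetric",
    "read_volumetric",
    "BOHR_PER_ANGSTROM",
]

#: 1 Å in bohr (CODATA a0 = 0.529177210903 Å)
BOHR_PER_ANGSTROM = 1.0 / 0.529177210903


@dataclass
class ContourField:
    field_type: str
    values: np.ndarray  # one scalar per grid point
    favored_level: float | None = None
    disfavored_level: float | None = None


def stdev_coeff_field(
    model: PLSModelSummary, n_grid_points: int, field_type: str
) -> ContourField:
    """Per-voxel coefficient × training-sd for one field type.

    ``n_grid_points`` is the lattice size of the descriptor grid; voxels
    whose columns were filtered out before the fit get 0.
    """
    known = set(model.retained_field_types.tolist())
    if field_type not in known:
        raise ValueError(f"unknown field type {field_type!r}; model has {sorted(known)}")
    values = np.zeros(n_grid_points)
    sel = model.retained_field_types == field_type
    idx = model.retained_grid_indices[sel].astype(int)
    values[idx] = model.coefficients[sel] * model.retained_column_sd[sel]
    return ContourField(field_type=field_type, values=values)


def threshold_levels(
    field: ContourField, favored_pct: float = 80.0, disfavored_pct: float = 20.0
) -> tuple[float, float]:
    """Percentiles of the nonzero voxel values (linear interpolation)."""
    if not 0 <= disfavored_pct < favored_pct <= 100:
        raise ValueError("need 0 <= disfavored_pct < favored_pct <= 100")
    nonzero = field.values[field.values != 0]
    if nonzero.size == 0:
        raise ValueError("all-zero contour field: no levels to compute")
    favored = float(np.percentile(nonzero, favored_pct))
    disfavored = float(np.percentile(nonzero, disfavored_pct))
    field.favored_level = favored
    field.disfavored_level = disfavored
    return favored, disfavored


def export_volumetric(
    field: ContourField, grid: GridSpec, path: str | Path, fmt: str = "dx"
) -> Path:
    """Write the contour field as OpenDX (.dx) or Gaussian cube (.cube).

    Cube origins/spacings are converted to bohr per the format standard.
    """
    path = Path(path)
    if field.values.size != grid.n_points:
        raise ValueError(
            f"field has {field.values.size} voxels but grid has {grid.n_points} points"
        )
    data = field.values.reshape(grid.dims)
    if fmt == "dx":
        from gridData import Grid

        g = Grid(data, origin=np.array(grid.origin), delta=grid.spacing)
        g.export(str(path), file_format="dx")
    elif fmt == "cube":
        _write_cube(data, grid, path)
    else:
        raise ValueError(f"unknown volumetric format {fmt!r}")
    return path


def _write_cube(data: np.ndarray, grid: GridSpec, path: Path) -> None:
    b = BOHR_PER_ANGSTROM
    nx, ny, nz = grid.dims
    lines = ["qsar3d contour field", "StDev*Coeff lattice (lengths in bohr)"]
    ox, oy, oz = (c * b for c in grid.origin)
    lines.append(f"{1:5d} {ox:12.6f} {oy:12.6f} {oz:12.6f}")
    lines.append(f"{nx:5d} {grid.spacing * b:12.6f} {0.0:12.6f} {0.0:12.6f}")
    lines.append(f"{ny:5d} {0.0:12.6f} {grid.spacing * b:12.6f} {0.0:12.6f}")
    lines.append(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {grid.spacing * b:12.6f}")
    # one placeholder atom (cube files require >= 1 atom record)
    lines.append(f"{1:5d} {0.0:12.6f} {0.0:12.6f} {0.0:12.6f} {0.0:12.6f}")
    vals = data.reshape(nx * ny * nz)  # C order: z fastest, matching cube layout
    for start in range(0, vals.size, 6):
        chunk = vals[start : start + 6]
        lines.append(" ".join(f"{v: .5E}" for v in chunk))
    path.write_text("\n".join(lines) + "\n")


def read_volumetric(path: str | Path, fmt: str | None = None):
    """Read a .dx or .cube file back; returns (values_3d, origin_Å, spacing_Å)."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "dx":
        from gridData import Grid

        g = Grid(str(path))
        return np.asarray(g.grid), np.asarray(g.origin, dtype=float), float(g.delta[0])
    if fmt == "cube":
        lines = path.read_text().splitlines()
        natoms = int(lines[2].split()[0])
        origin = np.array([float(v) for v in lines[2].split()[1:4]]) / BOHR_PER_ANGSTROM
        dims, spacing = [], None
        for ax in range(3):
            parts = lines[3 + ax].split()
            dims.append(int(parts[0]))
            step = float(parts[1 + ax]) / BOHR_PER_ANGSTROM
            spacing = step if spacing is None else spacing
        body = " ".join(lines[6 + natoms :]).split()
        values = np.array([float(v) for v in body]).reshape(dims)
        return values, origin, float(spacing)
    raise ValueError(f"unknown volumetric format {fmt!r}")
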