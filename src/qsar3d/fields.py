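"""Lattice construction and CoMFA / CoMSIA molecular-field descriptors.

CoMFA probes every point of a cubic lattice (2 Å spacing by default) with an
sp3-carbon-like probe (radius 1.52 Å, charge +1) and records the
Lennard-Jones 6-12 steric energy and the Coulomb electrostatic energy with a
distance-dependent dielectric, both truncated at ±30 kcal/mol.  CoMSIA
replaces the hard potentials with Gaussian similarity indices
``A_k(q) = −Σ_i w_probe,k · w_ik · exp(−α r_iq²)`` (attenuation α = 0.3)
evaluated for five atomic property sets: steric (r_vdW³), electrostatic
(partial charge), hydrophobic (atomic logP contribution) and hydrogen-bond
donor / acceptor flags.

The grid origin is snapped down to integer multiples of the spacing so that
rigidly translating an entire aligned dataset (by lattice-commensurate or
arbitrary shifts, thanks to the shared frame) reproduces identical columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structures import Molecule

__all__ = [
    "GridSpec",
    "ProbeSpec",
    "FieldBlock",
    "DescriptorMatrix",
    "COMFA_FIELDS",
    "COMSIA_FIELDS",
    "build_grid",
    "comfa_fields",
    "comsia_fields",
    "assemble_descriptors",
    "comfa_probe",
    "comsia_probe",
]

#: Coulomb constant, kcal·Å/(mol·e²)
COULOMB_CONSTANT = 332.0636
#: LJ well depth of the sp3 carbon probe, kcal/mol
PROBE_EPSILON = 0.107
#: minimum distance guard for the Coulomb kernel, Å
MIN_DISTANCE = 1e-6

#: 6-12 well depths per element, kcal/mol (Tripos-style parameterization)
LJ_EPSILON: dict[str, float] = {
    "H": 0.042, "C": 0.107, "N": 0.095, "O": 0.116, "F": 0.109,
    "P": 0.314, "S": 0.314, "Cl": 0.314, "Br": 0.434, "I": 0.623,
    "B": 0.095, "Si": 0.402, "Se": 0.434,
}

COMFA_FIELDS = ("comfa_steric", "comfa_electrostatic")
COMSIA_FIELDS = (
    "comsia_steric",
    "comsia_electrostatic",
    "comsia_hydrophobic",
    "comsia_donor",
    "comsia_acceptor",
)


@dataclass(frozen=True)
class GridSpec:
    """Cubic lattice: minimum corner, spacing and points per axis."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < 2 for d in self.dims):
            raise ValueError("grid needs at least 2 points per axis")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice points, shape (n_points, 3); z varies fastest."""
        axes = [
            self.origin[k] + self.spacing * np.arange(self.dims[k]) for k in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass(frozen=True)
class ProbeSpec:
    vdw_radius: float
    charge: float = 1.0
    hydrophobicity: float = 1.0
    donor_weight: float = 1.0
    acceptor_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError("probe radius must be positive")


def comfa_probe() -> ProbeSpec:
    """sp3 carbon probe: radius 1.52 Å, charge +1."""
    return ProbeSpec(vdw_radius=1.52, charge=1.0)


def comsia_probe() -> ProbeSpec:
    """Similarity probe: radius 1 Å, all property weights +1."""
    return ProbeSpec(vdw_radius=1.0, charge=1.0)


@dataclass
class FieldBlock:
    """n_molecules × n_grid_points block of one field type."""

    field_type: str
    values: np.ndarray
    units: str
    mask: np.ndarray | None = None  # True where the raw value was masked pre-imputation

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("FieldBlock values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.field_type}: non-finite field values")


@dataclass
class DescriptorMatrix:
    """Column-concatenated field blocks with per-column metadata."""

    X: np.ndarray
    field_types: np.ndarray  # (p,) str, field type per column
    grid_indices: np.ndarray  # (p,) int, lattice point index per column
    row_ids: list[str]

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.field_types) or self.X.shape[1] != len(self.grid_indices):
            raise ValueError("column metadata length mismatch")
        if self.X.shape[0] != len(self.row_ids):
            raise ValueError("row id length mismatch")

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def block_columns(self, field_type: str) -> np.ndarray:
        return np.flatnonzero(self.field_types == field_type)

    def block_names(self) -> list[str]:
        seen: list[str] = []
        for ft in self.field_types:
            if ft not in seen:
                seen.append(ft)
        return seen

    def select_rows(self, idx: Sequence[int]) -> "DescriptorMatrix":
        idx = list(idx)
        return DescriptorMatrix(
            X=self.X[idx],
            field_types=self.field_types,
            grid_indices=self.grid_indices,
            row_ids=[self.row_ids[i] for i in idx],
        )

    def select_columns(self, cols: np.ndarray) -> "DescriptorMatrix":
        return DescriptorMatrix(
            X=self.X[:, cols],
            field_types=self.field_types[cols],
            grid_indices=self.grid_indices[cols],
            row_ids=list(self.row_ids),
        )


# ---------------------------------------------------------------------------

def build_grid(
    molecules: Sequence[Molecule], spacing: float = 2.0, padding: float = 4.0
) -> GridSpec:
    """Lattice enclosing the union bounding box of all molecules plus padding.

    The origin is snapped down to integer multiples of the spacing so that
    lattice-commensurate translations of the whole dataset yield the same
    columns.
    """
    if not molecules:
        raise ValueError("build_grid needs at least one molecule")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if padding < 0:
        raise ValueError("padding must be non-negative")
    coords = np.vstack([m.coords for m in molecules])
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    origin = np.floor(lo / spacing) * spacing
    dims = np.maximum(np.ceil((hi - origin) / spacing).astype(int) + 1, 2)
    return GridSpec(origin=tuple(origin), spacing=spacing, dims=tuple(int(d) for d in dims))


def _distances(mol: Molecule, points: np.ndarray) -> np.ndarray:
    """(n_atoms, n_points) Euclidean distances."""
    diff = mol.coords[:, None, :] - points[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


def comfa_fields(
    molecules: Sequence[Molecule],
    grid: GridSpec,
    probe: ProbeSpec | None = None,
    cutoff: float = 30.0,
) -> tuple[FieldBlock, FieldBlock]:
    """CoMFA steric (LJ 6-12) and electrostatic (Coulomb) blocks, kcal/mol.

    Both are truncated to ±cutoff.  At points where the steric energy hits
    the cutoff the electrostatic value is meaningless (inside the van der
    Waals envelope); those entries are masked and imputed with the column
    mean over the unmasked molecules (the mask is kept on the block).
    """
    if probe is None:
        probe = comfa_probe()
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    points = grid.points()
    n, m = len(molecules), grid.n_points
    steric = np.zeros((n, m))
    electro = np.zeros((n, m))
    for i, mol in enumerate(molecules):
        radii = np.array([a.vdw_radius for a in mol.atoms])
        charges = np.array([a.partial_charge for a in mol.atoms])
        if np.any(radii <= 0):
            raise ValueError(f"{mol.id}: atoms missing van der Waals radii")
        eps = np.array(
            [np.sqrt(LJ_EPSILON.get(a.element, PROBE_EPSILON) * PROBE_EPSILON) for a in mol.atoms]
        )
        r = np.maximum(_distances(mol, points), MIN_DISTANCE)
        rm = (radii + probe.vdw_radius)[:, None]  # LJ minimum-energy distance
        frac6 = (rm / r) ** 6
        steric[i] = np.sum(eps[:, None] * (frac6 * frac6 - 2.0 * frac6), axis=0)
        electro[i] = np.sum(COULOMB_CONSTANT * charges[:, None] * probe.charge / (r * r), axis=0)
    steric_clipped = np.clip(steric, -cutoff, cutoff)
    mask = steric >= cutoff
    electro = np.clip(electro, -cutoff, cutoff)
    # impute masked electrostatic entries with the column mean of unmasked rows
    imputed = electro.copy()
    if mask.any():
        masked_cols = np.flatnonzero(mask.any(axis=0))
        for j in masked_cols:
            keep = ~mask[:, j]
            fill = electro[keep, j].mean() if keep.any() else 0.0
            imputed[mask[:, j], j] = fill
    sb = FieldBlock("comfa_steric", steric_clipped, units="kcal/mol")
    eb = FieldBlock("comfa_electrostatic", imputed, units="kcal/mol", mask=mask)
    return sb, eb


def _comsia_weights(mol: Molecule, field_type: str) -> np.ndarray:
    if field_type == "comsia_steric":
        return np.array([a.vdw_radius**3 for a in mol.atoms])
    if field_type == "comsia_electrostatic":
        return np.array([a.partial_charge for a in mol.atoms])
    if field_type == "comsia_hydrophobic":
        return np.array([a.hydrophobicity for a in mol.atoms])
    if field_type == "comsia_donor":
        return np.array([1.0 if a.is_donor else 0.0 for a in mol.atoms])
    if field_type == "comsia_acceptor":
        return np.array([1.0 if a.is_acceptor else 0.0 for a in mol.atoms])
    raise ValueError(f"unknown CoMSIA field {field_type!r}")


def _probe_weight(probe: ProbeSpec, field_type: str) -> float:
    return {
        "comsia_steric": probe.vdw_radius**3,
        "comsia_electrostatic": probe.charge,
        "comsia_hydrophobic": probe.hydrophobicity,
        "comsia_donor": probe.donor_weight,
        "comsia_acceptor": probe.acceptor_weight,
    }[field_type]


def comsia_fields(
    molecules: Sequence[Molecule],
    grid: GridSpec,
    probe: ProbeSpec | None = None,
    alpha: float = 0.3,
) -> tuple[FieldBlock, ...]:
    """The five CoMSIA similarity-index blocks (unitless, no cutoff).

    Value for property k at point q: ``−Σ_i w_probe,k · w_ik · exp(−α·r_iq²)``
    with r in Å.
    """
    if probe is None:
        probe = comsia_probe()
    if alpha <= 0:
        raise ValueError("attenuation factor alpha must be positive")
    points = grid.points()
    n, m = len(molecules), grid.n_points
    values = {ft: np.zeros((n, m)) for ft in COMSIA_FIELDS}
    for i, mol in enumerate(molecules):
        r2 = np.sum((mol.coords[:, None, :] - points[None, :, :]) ** 2, axis=2)
        gauss = np.exp(-alpha * r2)
        for ft in COMSIA_FIELDS:
            w = _comsia_weights(mol, ft)
            values[ft][i] = -_probe_weight(probe, ft) * (w @ gauss)
    return tuple(FieldBlock(ft, values[ft], units="similarity") for ft in COMSIA_FIELDS)


def assemble_descriptors(
    blocks: Sequence[FieldBlock], row_ids: Sequence[str]
) -> DescriptorMatrix:
    """Concatenate field blocks column-wise, keeping per-column metadata."""
    blocks = list(blocks)
    if not blocks:
        raise ValueError("assemble_descriptors needs at least one block")
    n = blocks[0].values.shape[0]
    if any(b.values.shape[0] != n for b in blocks):
        raise ValueError("field blocks disagree on row count")
    if len(row_ids) != n:
        raise ValueError("row_ids length does not match block rows")
    X = np.hstack([b.values for b in blocks])
    field_types = np.concatenate(
        [np.full(b.values.shape[1], b.field_type, dtype=object) for b in blocks]
    )
    grid_indices = np.concatenate([np.arange(b.values.shape[1]) for b in blocks])
    return DescriptorMatrix(
        X=X, field_types=field_types, grid_indices=grid_indices, row_ids=list(row_ids)
    )


def export_field_dx(block_row: np.ndarray, grid: GridSpec, path) -> None:
    """Write one molecule's field (a single block row) as an OpenDX file."""
    from gridData import Grid

    values = np.asarray(block_row, dtype=float).reshape(grid.dims)
    g = Grid(values, origin=np.array(grid.origin), delta=grid.spacing)
    g.export(str(path), file_format="dx")
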