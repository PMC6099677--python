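"""Aligned small-molecule structures, activities and train/test bookkeeping.

The modelling pipeline operates on a set of pre-aligned 3D structures
(common coordinate frame, coordinates in Å) with per-atom physicochemical
properties — partial charge, van der Waals radius, an atomic hydrophobicity
(logP) contribution and hydrogen-bond donor/acceptor flags — plus one
activity value per molecule, expressed as pEC50 = −log10(EC50 in mol/L).

Structure input goes through RDKit (SDF V2000 and TRIPOS MOL2); property
assignment uses Gasteiger–Marsili charges and Ghose–Crippen atomic logP
contributions, with van der Waals radii from the Bondi compilation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Molecule",
    "ActivityRecord",
    "AlignedDataset",
    "BONDI_RADII",
    "read_structures",
    "read_activities",
    "assign_atom_properties",
    "ec50_to_pec50",
    "kabsch_align",
    "split_train_test",
    "write_manifest",
]

#: Bondi van der Waals radii, Å.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "B": 1.92, "Si": 2.10, "Se": 1.90,
}


@dataclass
class Atom:
    """One atom of an aligned molecule with the properties the field kernels need."""

    element: str
    position: np.ndarray  # (3,), Å
    partial_charge: float = 0.0  # elementary charge units
    vdw_radius: float = 0.0  # Å; 0.0 means "not yet assigned"
    hydrophobicity: float = 0.0  # atomic logP contribution, unitless
    is_donor: bool = False
    is_acceptor: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")


@dataclass
class Molecule:
    """An aligned molecule: an id plus an ordered list of atoms.

    ``rdkit_mol`` optionally keeps the RDKit connection table around so that
    bonding-dependent property schemes (Gasteiger, Crippen, H-bond rules) can
    run; it does not take part in equality.
    """

    id: str
    atoms: list[Atom]
    name: str | None = None
    rdkit_mol: object | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.id!r} has no atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def translated(self, shift: Sequence[float]) -> "Molecule":
        shift = np.asarray(shift, dtype=float)
        atoms = [replace(a, position=a.position + shift) for a in self.atoms]
        return Molecule(id=self.id, atoms=atoms, name=self.name, rdkit_mol=self.rdkit_mol)


@dataclass
class ActivityRecord:
    molecule_id: str
    pec50: float
    ec50: float | None = None  # µM

    def __post_init__(self) -> None:
        if self.ec50 is not None:
            implied = ec50_to_pec50(self.ec50)
            if abs(implied - self.pec50) > 1e-3:
                raise ValueError(
                    f"{self.molecule_id}: pEC50 {self.pec50} inconsistent with "
                    f"EC50 {self.ec50} µM (implies {implied:.4f})"
                )


@dataclass
class AlignedDataset:
    """Aligned molecules + activities + train/test roles, one of each per molecule."""

    molecules: list[Molecule]
    activities: dict[str, ActivityRecord]
    roles: dict[str, str]

    def __post_init__(self) -> None:
        ids = [m.id for m in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValueError("molecule ids are not unique")
        for mid in ids:
            if mid not in self.activities:
                raise ValueError(f"molecule {mid!r} has no activity record")
            if self.roles.get(mid) not in ("train", "test"):
                raise ValueError(f"molecule {mid!r} has no valid role")

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.molecules]

    def subset(self, role: str) -> list[Molecule]:
        return [m for m in self.molecules if self.roles[m.id] == role]

    def y(self, role: str | None = None) -> np.ndarray:
        mols = self.molecules if role is None else self.subset(role)
        return np.array([self.activities[m.id].pec50 for m in mols])


# ---------------------------------------------------------------------------
# structure input

_ATOM_PROPS_TAG = "atom_properties"


def _element_radius(element: str) -> float:
    try:
        return BONDI_RADII[element]
    except KeyError:
        raise ValueError(f"unknown element {element!r}: no van der Waals radius on file")


def _mol_from_rdkit(rdmol, index: int, default_id: str | None = None) -> Molecule:
    from rdkit import Chem

    if rdmol.GetNumConformers() == 0:
        raise ValueError(f"record {index}: no 3D coordinates")
    conf = rdmol.GetConformer()
    atoms = []
    for i, a in enumerate(rdmol.GetAtoms()):
        p = conf.GetAtomPosition(i)
        charge = 0.0
        if a.HasProp("_TriposPartialCharge"):
            charge = a.GetDoubleProp("_TriposPartialCharge")
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                position=np.array([p.x, p.y, p.z]),
                partial_charge=charge,
                vdw_radius=_element_radius(a.GetSymbol()),
            )
        )
    mol_id = default_id
    if rdmol.HasProp("_Name") and rdmol.GetProp("_Name").strip():
        mol_id = rdmol.GetProp("_Name").strip()
    if not mol_id:
        mol_id = f"mol_{index}"
    mol = Molecule(id=mol_id, atoms=atoms, rdkit_mol=rdmol)
    # per-atom property block written by qsar3d.synthetic.write_structures
    if rdmol.HasProp(_ATOM_PROPS_TAG):
        lines = rdmol.GetProp(_ATOM_PROPS_TAG).strip().splitlines()
        if len(lines) != len(atoms):
            raise ValueError(f"record {index}: atom_properties length mismatch")
        for atom, line in zip(mol.atoms, lines):
            q, r, h, d, acc = line.split()
            atom.partial_charge = float(q)
            atom.vdw_radius = float(r)
            atom.hydrophobicity = float(h)
            atom.is_donor = bool(int(d))
            atom.is_acceptor = bool(int(acc))
    return mol


def read_structures(path: str | Path, fmt: str | None = None) -> list[Molecule]:
    """Read aligned molecules from an SDF (V2000) or TRIPOS MOL2 file.

    Coordinates are taken as Å.  MOL2 partial charges, when present, are
    retained verbatim on the atoms.  Records that fail to parse raise a
    ``ValueError`` naming the record index.
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("sdf", "mol2"):
        raise ValueError(f"unsupported format {fmt!r} (expected 'sdf' or 'mol2')")

    molecules: list[Molecule] = []
    if fmt == "sdf":
        try:
            supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        except OSError as exc:
            raise ValueError(f"cannot parse {path} as SDF: {exc}")
        for i, rdmol in enumerate(supplier):
            if rdmol is None:
                raise ValueError(f"unparseable SDF record at index {i} in {path}")
            molecules.append(_mol_from_rdkit(rdmol, i))
    else:
        text = path.read_text()
        chunks = text.split("@<TRIPOS>MOLECULE")
        blocks = ["@<TRIPOS>MOLECULE" + c for c in chunks[1:]]
        for i, block in enumerate(blocks):
            rdmol = Chem.MolFromMol2Block(block, sanitize=False, removeHs=False)
            if rdmol is None:
                raise ValueError(f"unparseable MOL2 record at index {i} in {path}")
            name = block.splitlines()[1].strip() or None
            molecules.append(_mol_from_rdkit(rdmol, i, default_id=name))
    if not molecules:
        raise ValueError(f"no molecule records found in {path}")
    return molecules


def read_activities(path: str | Path) -> tuple[dict[str, ActivityRecord], dict[str, str]]:
    """Read an activity table (CSV with columns id, ec50_uM or pec50, role optional)."""
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError("activity table needs an 'id' column")
    records: dict[str, ActivityRecord] = {}
    roles: dict[str, str] = {}
    for _, row in df.iterrows():
        mid = str(row["id"])
        ec50 = float(row["ec50_uM"]) if "ec50_uM" in df.columns and pd.notna(row.get("ec50_uM")) else None
        if "pec50" in df.columns and pd.notna(row.get("pec50")):
            pec50 = float(row["pec50"])
        elif ec50 is not None:
            pec50 = ec50_to_pec50(ec50)
        else:
            raise ValueError(f"{mid}: neither pec50 nor ec50_uM given")
        records[mid] = ActivityRecord(molecule_id=mid, pec50=pec50, ec50=ec50)
        if "role" in df.columns and pd.notna(row.get("role")):
            roles[mid] = str(row["role"])
    return records, roles


# ---------------------------------------------------------------------------
# property assignment

# Nitrogen acceptor exclusions: quaternary/positively charged N and nitro N
# have no available lone pair.


def assign_atom_properties(molecule: Molecule, charge_method: str = "gasteiger") -> Molecule:
    """Populate partial charges, radii, hydrophobicity and H-bond flags.

    ``charge_method='gasteiger'`` computes Gasteiger–Marsili charges from the
    RDKit connection table; ``'input'`` keeps charges already on the atoms
    (e.g. from a MOL2 charges column).  Hydrophobicity uses Ghose–Crippen
    atomic logP contributions.  Donor rule: any H bonded to N/O/S; the flag is
    carried on the heavy atom and on its hydrogens.  Acceptor rule: N or O
    with an available lone pair (quaternary and nitro nitrogens excluded).
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem, rdMolDescriptors

    if charge_method not in ("gasteiger", "input"):
        raise ValueError(f"unknown charge_method {charge_method!r}")
    rdmol = molecule.rdkit_mol
    if rdmol is None:
        raise ValueError(
            f"molecule {molecule.id!r} carries no connection table; "
            "read it from SDF/MOL2 or attach an RDKit mol"
        )
    rdmol = Chem.Mol(rdmol)
    try:
        Chem.SanitizeMol(rdmol)
    except Exception as exc:  # pragma: no cover - depends on input chemistry
        raise ValueError(f"molecule {molecule.id!r}: cannot sanitize for {charge_method}: {exc}")

    n = rdmol.GetNumAtoms()
    if n != len(molecule.atoms):
        raise ValueError(f"molecule {molecule.id!r}: atom count mismatch with connection table")

    if charge_method == "gasteiger":
        AllChem.ComputeGasteigerCharges(rdmol)
        charges = [a.GetDoubleProp("_GasteigerCharge") for a in rdmol.GetAtoms()]
        if not all(math.isfinite(c) for c in charges):
            raise ValueError(f"molecule {molecule.id!r}: Gasteiger charges did not converge")
    else:
        charges = [a.partial_charge for a in molecule.atoms]

    crippen = rdMolDescriptors._CalcCrippenContribs(rdmol)

    donors = [False] * n
    acceptors = [False] * n
    for a in rdmol.GetAtoms():
        i = a.GetIdx()
        sym = a.GetSymbol()
        if sym in ("N", "O", "S") and a.GetTotalNumHs(includeNeighbors=True) > 0:
            donors[i] = True
            for nb in a.GetNeighbors():
                if nb.GetSymbol() == "H":
                    donors[nb.GetIdx()] = True
        if sym in ("N", "O"):
            has_lone_pair = True
            if sym == "N":
                if a.GetFormalCharge() > 0 or a.GetTotalDegree() >= 4:
                    has_lone_pair = False
                # nitro nitrogen: N bonded to two oxygens with one double bond
                o_nb = [nb for nb in a.GetNeighbors() if nb.GetSymbol() == "O"]
                if len(o_nb) >= 2 and any(
                    rdmol.GetBondBetweenAtoms(i, nb.GetIdx()).GetBondTypeAsDouble() == 2.0
                    for nb in o_nb
                ):
                    has_lone_pair = False
            acceptors[i] = has_lone_pair

    atoms = []
    for i, atom in enumerate(molecule.atoms):
        atoms.append(
            replace(
                atom,
                partial_charge=float(charges[i]),
                vdw_radius=_element_radius(atom.element),
                hydrophobicity=float(crippen[i][0]),
                is_donor=donors[i],
                is_acceptor=acceptors[i],
            )
        )
    return Molecule(id=molecule.id, atoms=atoms, name=molecule.name, rdkit_mol=rdmol)


# ---------------------------------------------------------------------------
# activities

def ec50_to_pec50(ec50_um):
    """Convert EC50 in µM to pEC50 = −log10(EC50 in mol/L) = 6 − log10(EC50 µM)."""
    ec50_um = np.asarray(ec50_um, dtype=float)
    if np.any(ec50_um <= 0):
        raise ValueError("EC50 must be positive")
    out = 6.0 - np.log10(ec50_um)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# rigid alignment

def kabsch_align(
    mobile: Molecule, reference: Molecule, atom_map: Sequence[tuple[int, int]]
) -> tuple[Molecule, float]:
    """Rigid (rotation + translation) superposition of ``mobile`` onto ``reference``.

    ``atom_map`` lists (mobile_index, reference_index) pairs; at least three
    non-collinear pairs are required.  Returns the transformed molecule and
    the RMSD over the mapped pairs, in Å.
    """
    pairs = list(atom_map)
    if len(pairs) < 3:
        raise ValueError("kabsch_align needs at least 3 mapped atom pairs")
    P = np.array([mobile.atoms[i].position for i, _ in pairs])  # mobile
    Q = np.array([reference.atoms[j].position for _, j in pairs])  # reference
    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
    # collinearity check: rank of the centered mobile points
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2:
        raise ValueError("mapped atom pairs are collinear")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1))))
    atoms = [replace(a, position=R @ a.position + t) for a in mobile.atoms]
    aligned = Molecule(id=mobile.id, atoms=atoms, name=mobile.name, rdkit_mol=mobile.rdkit_mol)
    return aligned, rmsd


# ---------------------------------------------------------------------------
# train/test split

def split_train_test(
    dataset: Sequence[tuple[str, float]],
    train_fraction: float,
    strategy: str = "stratified_random",
    seed: int = 0,
    manual_test_ids: Iterable[str] | None = None,
    bin_edges: Sequence[float] = (4.0, 6.0, 8.0),
) -> dict[str, str]:
    """Assign each (id, pEC50) pair a 'train' or 'test' role.

    ``stratified_random`` bins activities (default bins [4,6) and [6,8) log
    units, values outside clamped to the nearest bin) and draws test
    compounds proportionally from each bin with a seeded RNG.  ``manual``
    takes an explicit test-id list.
    """
    items = list(dataset)
    n = len(items)
    if n < 4:
        raise ValueError("need at least 4 compounds to split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    ids = [i for i, _ in items]
    n_train = int(round(train_fraction * n))
    n_test = n - n_train
    if n_test < 1 or n_train < 1:
        raise ValueError("split leaves an empty set")

    if strategy == "manual":
        if manual_test_ids is None:
            raise ValueError("manual strategy needs manual_test_ids")
        test = set(str(i) for i in manual_test_ids)
        unknown = test - set(ids)
        if unknown:
            raise ValueError(f"manual test list names unknown ids: {sorted(unknown)}")
        return {i: ("test" if i in test else "train") for i in ids}

    if strategy != "stratified_random":
        raise ValueError(f"unknown strategy {strategy!r}")

    edges = np.asarray(bin_edges, dtype=float)
    y = np.array([v for _, v in items])
    binned = np.clip(np.digitize(y, edges[1:-1]), 0, len(edges) - 2)
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    # proportional allocation, largest bins first; remainders go to the
    # bins with the largest fractional part
    bins = sorted(set(binned))
    quotas = {b: n_test * np.sum(binned == b) / n for b in bins}
    alloc = {b: int(np.floor(q)) for b, q in quotas.items()}
    remainder = n_test - sum(alloc.values())
    for b in sorted(bins, key=lambda b: quotas[b] - alloc[b], reverse=True)[:remainder]:
        alloc[b] += 1
    for b in bins:
        members = np.flatnonzero(binned == b)
        take = min(alloc[b], len(members))
        test_idx.extend(rng.choice(members, size=take, replace=False))
    # top up if a bin was too small
    while len(test_idx) < n_test:
        pool = [i for i in range(n) if i not in test_idx]
        test_idx.append(int(rng.choice(pool)))
    test = {ids[i] for i in test_idx}
    return {i: ("test" if i in test else "train") for i in ids}


def write_manifest(dataset: AlignedDataset, path: str | Path) -> pd.DataFrame:
    """Write the normalized dataset manifest (id, pEC50, role) as CSV."""
    df = pd.DataFrame(
        {
            "id": dataset.ids,
            "pec50": [dataset.activities[i].pec50 for i in dataset.ids],
            "role": [dataset.roles[i] for i in dataset.ids],
        }
    )
    df.to_csv(path, index=False)
    return df
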