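"""PDB parsing and distance-based binding-pocket extraction.

The pocket is defined as all residues with any atom within a cutoff
(default 10 A = 1 nm) of any atom of a reference bound ligand.  The pocket
is then converted into a featurizable pseudo-molecule with bonds inferred
from interatomic distances, so the same embedding machinery that handles
ligands can embed the pocket.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from scipy.spatial.distance import cdist

from .chem_features import (
    DEFAULT_RADII,
    EmbeddingTable,
    FeatureVector,
    embed_molecule,
    mol_to_sentence,
)
from .errors import ConfigError, PDBParseError, VScreenError

# residue names never treated as reference ligands
DEFAULT_HET_EXCLUDE = frozenset(
    {"HOH", "WAT", "DOD", "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE",
     "SO4", "PO4", "GOL", "EDO", "ACT", "DMS", "PEG"}
)

# single-bond covalent radii in Angstrom (Cordero et al. values, abridged)
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20, "B": 0.84,
}
BOND_TOLERANCE = 0.45  # Angstrom added to the radius sum


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    altloc: str
    res_name: str
    chain: str
    res_number: int
    icode: str
    x: float
    y: float
    z: float
    occupancy: float
    element: str
    is_het: bool

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.res_number, self.icode)

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Structure:
    """Parsed protein structure plus its HET groups."""

    atoms: list[AtomRecord]
    het_groups: dict[tuple[str, str, int], list[AtomRecord]]
    source_id: str = ""

    def residues(self) -> dict[tuple[str, int, str], list[AtomRecord]]:
        out: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out


@dataclass(frozen=True)
class PocketConfig:
    radius: float = 10.0  # Angstrom; 1 nm as in the distance-cutoff definition
    selection_unit: str = "residue"

    def __post_init__(self):
        if self.radius <= 0:
            raise ConfigError("pocket radius must be > 0")
        if self.selection_unit not in ("residue", "atom"):
            raise ConfigError(f"unknown selection unit {self.selection_unit!r}")


@dataclass
class PocketStructure:
    residues: list[tuple[str, int, str]]
    atoms: list[AtomRecord]
    source: str = ""

    def __len__(self) -> int:
        return len(self.residues)


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    if len(line) < 54:
        raise PDBParseError(f"truncated ATOM/HETATM record at line {lineno}", lineno)
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip() or "A"
        res_number = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip() if len(line) >= 60 else ""
        occupancy = float(occ_field) if occ_field else 1.0
    except ValueError as exc:
        raise PDBParseError(f"malformed fixed-width field at line {lineno}: {exc}", lineno)
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        # fall back to the atom-name convention: first alphabetic character
        stripped = name.lstrip("0123456789")
        element = stripped[:1].upper()
    if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
        raise PDBParseError(f"non-finite coordinates at line {lineno}", lineno)
    return AtomRecord(
        serial=serial, name=name, altloc=altloc, res_name=res_name, chain=chain,
        res_number=res_number, icode=icode, x=x, y=y, z=z, occupancy=occupancy,
        element=element, is_het=line.startswith("HETATM"),
    )


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom: highest occupancy, ties by altloc letter."""
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.chain, a.res_number, a.icode, a.res_name, a.name)
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (a.occupancy, b.altloc) > (b.occupancy, a.altloc):
                best[key] = a
    return [best[k] for k in order]


def parse_structure(
    pdb_text: str,
    source_id: str = "",
    het_exclude: frozenset[str] = DEFAULT_HET_EXCLUDE,
) -> Structure:
    """Parse fixed-column PDB text into a Structure.

    ATOM records populate the protein; HETATM records (minus water and
    common buffer components) populate het_groups keyed by
    (residue_name, chain, residue_number).  Only the first MODEL of a
    multi-model file is read.
    """
    protein: list[AtomRecord] = []
    het: list[AtomRecord] = []
    in_model = 0
    n_records = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            in_model += 1
            if in_model > 1:
                break
        elif rec == "ENDMDL":
            break
        elif rec == "ATOM  ":
            n_records += 1
            protein.append(_parse_atom_line(line, lineno))
        elif rec == "HETATM":
            n_records += 1
            a = _parse_atom_line(line, lineno)
            if a.res_name not in het_exclude:
                het.append(a)
    if n_records == 0:
        raise PDBParseError("no ATOM or HETATM records with coordinates found")
    protein = _resolve_altlocs(protein)
    het = _resolve_altlocs(het)
    het_groups: dict[tuple[str, str, int], list[AtomRecord]] = {}
    for a in het:
        het_groups.setdefault((a.res_name, a.chain, a.res_number), []).append(a)
    return Structure(atoms=protein, het_groups=het_groups, source_id=source_id)


def extract_pocket(
    structure: Structure,
    ligand_id: tuple[str, str, int],
    cfg: PocketConfig = PocketConfig(),
) -> PocketStructure:
    """Select all residues with any atom within cfg.radius of any ligand atom."""
    if ligand_id not in structure.het_groups:
        raise KeyError(f"ligand {ligand_id} not found; have {sorted(structure.het_groups)}")
    lig_atoms = structure.het_groups[ligand_id]
    if not lig_atoms:
        raise ConfigError(f"ligand {ligand_id} has no atoms")
    lig_xyz = np.array([[a.x, a.y, a.z] for a in lig_atoms])

    residues = structure.residues()
    kept_keys: list[tuple[str, int, str]] = []
    kept_atoms: list[AtomRecord] = []
    for key in sorted(residues):
        atoms = residues[key]
        xyz = np.array([[a.x, a.y, a.z] for a in atoms])
        if cdist(xyz, lig_xyz).min() <= cfg.radius:
            kept_keys.append(key)
            kept_atoms.extend(atoms)
    src = f"{structure.source_id}:{ligand_id[0]}_{ligand_id[1]}{ligand_id[2]}"
    return PocketStructure(residues=kept_keys, atoms=kept_atoms, source=src)


def pocket_to_molecule(pocket: PocketStructure) -> Chem.Mol:
    """Build a (possibly disconnected) molecular graph from the pocket atoms.

    Heavy atoms only; single bonds are placed between atom pairs whose
    distance is at most the sum of their covalent radii plus 0.45 A.
    Deterministic for a fixed pocket.
    """
    heavy = [a for a in pocket.atoms if a.element != "H"]
    if not heavy:
        raise ConfigError("pocket has no heavy atoms")
    for a in heavy:
        if a.element not in COVALENT_RADII:
            raise VScreenError(
                f"unrecognized element {a.element!r} for atom {a.serial} {a.name}"
            )
    rw = Chem.RWMol()
    for a in heavy:
        atom = Chem.Atom(a.element.capitalize())
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    xyz = np.array([[a.x, a.y, a.z] for a in heavy])
    radii = np.array([COVALENT_RADII[a.element] for a in heavy])
    dist = cdist(xyz, xyz)
    cut = radii[:, None] + radii[None, :] + BOND_TOLERANCE
    n = len(heavy)
    for i in range(n):
        for j in range(i + 1, n):
            if 0.4 < dist[i, j] <= cut[i, j]:
                rw.AddBond(i, j, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.GetSSSR(mol)
    return mol


def featurize_pocket(
    pocket: PocketStructure,
    table: EmbeddingTable,
    radii: Sequence[int] = DEFAULT_RADII,
    aggregation: str = "sum",
) -> FeatureVector:
    """Pocket -> pseudo-molecule -> sentence -> aggregated embedding."""
    mol = pocket_to_molecule(pocket)
    sent = mol_to_sentence(mol, radii=radii, source_id=pocket.source)
    return embed_molecule(sent, table, aggregation=aggregation)
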