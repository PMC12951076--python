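"""Structure I/O: PDB/Mol2/SDF readers, training manifests, core records.

The canonical in-memory model is heavy-atom only: hydrogens are stripped
on input because every atom taxonomy used downstream is defined over
heavy atoms. Waters are dropped; other HETATM records (metals, cofactors)
are kept and fall into the undefined protein type during typing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_WATER_NAMES = {"HOH", "WAT", "DOD"}

# Sybyl bond order vocabulary kept verbatim ("1","2","3","ar","am","du","un","nc")
BondTuple = tuple[int, int, str]


class StructureError(ValueError):
    """Raised for unreadable or contract-violating structure input."""


@dataclass
class AtomRecord:
    """One heavy atom with its residue context.

    Positions are in Angstrom. ``sybyl_type`` is populated verbatim for
    Mol2 input and left ``None`` otherwise (SDF ligands get their types
    inferred later by the typing layer).
    """

    atom_index: int
    atom_name: str
    element: str
    sybyl_type: Optional[str]
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    is_hetero: bool = False
    icode: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(
                f"atom {self.atom_name}: position must be a finite 3-vector"
            )

    @property
    def residue_id(self) -> tuple[str, int, str, str]:
        """(chain, seq, icode, residue_name) — the residue identity key."""
        return (self.chain_id, self.residue_seq, self.icode, self.residue_name)


@dataclass
class Structure:
    """An ordered heavy-atom list with optional connectivity."""

    atoms: list[AtomRecord]
    bonds: list[BondTuple] = field(default_factory=list)
    source_path: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for a, b, _ in self.bonds:
            if not (0 <= a < n and 0 <= b < n):
                raise StructureError(f"bond ({a},{b}) references invalid atom index")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def neighbors(self, i: int) -> list[tuple[int, str]]:
        out = []
        for a, b, order in self.bonds:
            if a == i:
                out.append((b, order))
            elif b == i:
                out.append((a, order))
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly moved copy (used by invariance tests and pose tools)."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        atoms = []
        for a in self.atoms:
            moved = AtomRecord(
                atom_index=a.atom_index, atom_name=a.atom_name, element=a.element,
                sybyl_type=a.sybyl_type, residue_name=a.residue_name,
                residue_seq=a.residue_seq, chain_id=a.chain_id,
                position=rotation @ a.position + translation,
                is_hetero=a.is_hetero, icode=a.icode,
            )
            atoms.append(moved)
        return Structure(atoms=atoms, bonds=list(self.bonds),
                         source_path=self.source_path)


@dataclass
class ComplexRecord:
    """Receptor structure plus one ligand pose and an optional affinity.

    Affinity is in pK units (-log10 of Kd or Ki in molar); larger means
    tighter binding.
    """

    receptor: Structure
    ligand: Structure
    affinity: Optional[float] = None
    complex_id: str = ""

    def __post_init__(self) -> None:
        if len(self.receptor) < 1 or len(self.ligand) < 1:
            raise StructureError("receptor and ligand must each have >= 1 atom")
        if self.affinity is not None and self.affinity < 0:
            raise StructureError("affinity (pK) must be non-negative")


def _is_hydrogen(element: str) -> bool:
    return element.upper() in {"H", "D", "T"}


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file into the canonical heavy-atom representation.

    First model only. Alternate locations are resolved to the
    highest-occupancy conformer (ties: first encountered). Waters are
    dropped; all other HETATM records are kept.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]
    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES:
                continue
            is_het = res.het_flag == "H"
            # resolve altlocs per atom name: highest occupancy, first wins ties
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in res:
                if _is_hydrogen(atom.element.name):
                    continue
                if atom.name not in best:
                    best[atom.name] = atom
                    order.append(atom.name)
                elif atom.occ > best[atom.name].occ:
                    best[atom.name] = atom
            for name in order:
                atom = best[name]
                atoms.append(AtomRecord(
                    atom_index=len(atoms),
                    atom_name=name,
                    element=atom.element.name,
                    sybyl_type=None,
                    residue_name=res.name,
                    residue_seq=res.seqid.num,
                    chain_id=chain.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    is_hetero=is_het,
                    icode=(res.seqid.icode or "").strip(),
                ))
    if not atoms:
        raise StructureError(f"{path}: zero heavy atoms after filtering")
    return Structure(atoms=atoms, source_path=str(path))


def read_mol2(path: str | Path) -> Structure:
    """Read a Tripos Mol2 file, keeping Sybyl atom types verbatim.

    Only the first molecule is read. Hydrogens are dropped; bonds are
    remapped onto the heavy-atom index space and bonds to hydrogens are
    discarded.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise StructureError(f"cannot read Mol2 file {path}: {exc}") from exc

    sections: dict[str, list[str]] = {}
    current: Optional[str] = None
    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if line.startswith("@<TRIPOS>"):
            current = line[len("@<TRIPOS>"):].strip().upper()
            if current in sections:  # second molecule: stop at repeats
                break
            sections[current] = []
            continue
        if current is not None and line.strip() and not line.startswith("#"):
            sections[current].append(line)

    if "ATOM" not in sections:
        raise StructureError(f"{path}: missing @<TRIPOS>ATOM section")

    declared_atoms = None
    if sections.get("MOLECULE"):
        mol_lines = sections["MOLECULE"]
        if len(mol_lines) >= 2:
            counts = mol_lines[1].split()
            if counts:
                try:
                    declared_atoms = int(counts[0])
                except ValueError:
                    pass
    if declared_atoms is not None and declared_atoms != len(sections["ATOM"]):
        raise StructureError(
            f"{path}: header declares {declared_atoms} atoms, "
            f"ATOM section has {len(sections['ATOM'])}"
        )

    atoms: list[AtomRecord] = []
    index_map: dict[int, int] = {}  # mol2 atom id -> heavy atom index
    for line in sections["ATOM"]:
        parts = line.split()
        if len(parts) < 6:
            raise StructureError(f"{path}: malformed ATOM line: {line!r}")
        mol2_id = int(parts[0])
        name = parts[1]
        try:
            xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
        except ValueError as exc:
            raise StructureError(f"{path}: bad coordinates in {line!r}") from exc
        sybyl = parts[5]
        element = sybyl.split(".")[0].capitalize()
        if _is_hydrogen(element):
            continue
        subst_name = parts[7] if len(parts) > 7 else "LIG"
        res_name = subst_name.rstrip("0123456789") or "LIG"
        index_map[mol2_id] = len(atoms)
        atoms.append(AtomRecord(
            atom_index=len(atoms),
            atom_name=name,
            element=element,
            sybyl_type=sybyl,
            residue_name=res_name,
            residue_seq=int(parts[6]) if len(parts) > 6 else 1,
            chain_id="",
            position=xyz,
            is_hetero=True,
        ))
    if not atoms:
        raise StructureError(f"{path}: zero heavy atoms after filtering")

    bonds: list[BondTuple] = []
    for line in sections.get("BOND", []):
        parts = line.split()
        if len(parts) < 4:
            continue
        a, b, order = int(parts[1]), int(parts[2]), parts[3]
        if a in index_map and b in index_map:
            bonds.append((index_map[a], index_map[b], order))
    return Structure(atoms=atoms, bonds=bonds, source_path=str(path))


def read_sdf(path: str | Path) -> Structure:
    """Read the first molecule of an SDF (V2000) file via RDKit.

    Sybyl types are left unset; the typing layer infers them from
    element, bond orders and aromaticity.
    """
    from rdkit import Chem

    path = Path(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    mol = next((m for m in supplier if m is not None), None)
    if mol is None:
        raise StructureError(f"{path}: no parseable molecule")
    conf = mol.GetConformer()
    atoms: list[AtomRecord] = []
    index_map: dict[int, int] = {}
    for rd_atom in mol.GetAtoms():
        element = rd_atom.GetSymbol()
        if _is_hydrogen(element):
            continue
        pos = conf.GetAtomPosition(rd_atom.GetIdx())
        index_map[rd_atom.GetIdx()] = len(atoms)
        atoms.append(AtomRecord(
            atom_index=len(atoms),
            atom_name=f"{element}{len(atoms) + 1}",
            element=element,
            sybyl_type=None,
            residue_name="LIG",
            residue_seq=1,
            chain_id="",
            position=np.array([pos.x, pos.y, pos.z]),
            is_hetero=True,
        ))
    if not atoms:
        raise StructureError(f"{path}: zero heavy atoms after filtering")
    bonds: list[BondTuple] = []
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a not in index_map or b not in index_map:
            continue
        if bond.GetIsAromatic():
            order = "ar"
        else:
            order = {1.0: "1", 2.0: "2", 3.0: "3"}.get(bond.GetBondTypeAsDouble(), "1")
        bonds.append((index_map[a], index_map[b], order))
    return Structure(atoms=atoms, bonds=bonds, source_path=str(path))


def read_ligand(path: str | Path) -> Structure:
    """Dispatch on extension: .mol2 -> read_mol2, .sdf/.sd -> read_sdf."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".mol2":
        return read_mol2(path)
    if suffix in {".sdf", ".sd", ".mol"}:
        return read_sdf(path)
    raise StructureError(f"unsupported ligand format: {path}")


@dataclass
class ManifestEntry:
    """One training-manifest row; paths already resolved."""

    complex_id: str
    receptor_path: Path
    ligand_path: Path
    affinity: Optional[float]


_MANIFEST_COLUMNS = ["complex_id", "receptor_path", "ligand_path", "affinity"]


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read a tab-separated training manifest.

    Required header: complex_id, receptor_path, ligand_path, affinity.
    Relative paths are resolved against the manifest's directory.
    Affinity may be empty (unweighted training only).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"complex_id": str})
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise StructureError(f"{path}: manifest missing columns {missing}")
    dupes = df["complex_id"][df["complex_id"].duplicated()].tolist()
    if dupes:
        raise StructureError(f"{path}: duplicate complex_id values {sorted(set(dupes))}")
    base = path.parent
    entries: list[ManifestEntry] = []
    for row in df.itertuples(index=False):
        aff_raw = getattr(row, "affinity")
        if pd.isna(aff_raw) or (isinstance(aff_raw, str) and not aff_raw.strip()):
            affinity = None
        else:
            try:
                affinity = float(aff_raw)
            except (TypeError, ValueError) as exc:
                raise StructureError(
                    f"{path}: non-numeric affinity {aff_raw!r} "
                    f"for complex {row.complex_id}") from exc
        entries.append(ManifestEntry(
            complex_id=str(row.complex_id),
            receptor_path=(base / str(row.receptor_path)).resolve(),
            ligand_path=(base / str(row.ligand_path)).resolve(),
            affinity=affinity,
        ))
    return entries


def load_complex(entry: ManifestEntry) -> ComplexRecord:
    """Materialize one manifest entry into a ComplexRecord."""
    return ComplexRecord(
        receptor=read_pdb(entry.receptor_path),
        ligand=read_ligand(entry.ligand_path),
        affinity=entry.affinity,
        complex_id=entry.complex_id,
    )


def load_manifest_complexes(path: str | Path) -> list[ComplexRecord]:
    return [load_complex(e) for e in read_manifest(path)]
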