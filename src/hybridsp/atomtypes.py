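"""Atom taxonomies for the statistical potentials.

Three schemes:

* ``ligand_sybyl23`` — 23 Sybyl heavy-atom types for ligand atoms.
* ``protein_residue100`` — residue-dependent protein types: each of the
  19 non-glycine standard residues contributes two backbone slots
  (BB1 = {N, CA}, BB2 = {C, O}) and three side-chain slots (side-chain
  heavy atoms partitioned by increasing bond distance from CA into
  three contiguous near-equal groups); glycine contributes its four
  atoms individually; one UNDEF slot absorbs everything else (metals,
  halogens, cofactors, non-standard residues, terminal OXT).
  19*5 + 4 + 1 = 100 labels.
* ``protein_sybyl`` — a Sybyl-style atom-atom protein scheme (fixed
  per-residue lookup) for DrugScore-style atom-atom potentials.

All mappers are total functions: unrecognized atoms land on a fallback
label, never raise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from hybridsp.structio import AtomRecord, Structure

logger = logging.getLogger(__name__)

UNDEF = "UNDEF"

#: 23 Sybyl heavy-atom labels used for ligand atoms (config-overridable).
LIGAND_SYBYL_LABELS: tuple[str, ...] = (
    "C.1", "C.2", "C.3", "C.ar",
    "N.1", "N.2", "N.3", "N.4", "N.ar", "N.am", "N.pl3",
    "O.2", "O.3", "O.co2",
    "S.2", "S.3", "S.o", "S.o2",
    "P.3",
    "F", "Cl", "Br", "I",
)

STANDARD_RESIDUES: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

_BACKBONE_BB1 = {"N", "CA"}
_BACKBONE_BB2 = {"C", "O"}

# element -> fallback ligand label for Sybyl types with no tabulated mapping
_ELEMENT_FALLBACK = {
    "C": "C.3", "N": "N.3", "O": "O.3", "S": "S.3", "P": "P.3",
    "F": "F", "Cl": "Cl", "Br": "Br", "I": "I",
}
_GENERIC_FALLBACK = "C.3"


def _data_path(name: str) -> Path:
    return Path(str(resources.files("hybridsp").joinpath("data", name)))


def _read_tsv_rows(path: Path) -> list[list[str]]:
    rows = []
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def load_residue_topology(path: Optional[Path] = None) -> dict[str, list[str]]:
    """Residue -> side-chain heavy atoms ordered by bond distance from CA."""
    path = path or _data_path("residue_topology.tsv")
    topo: dict[str, list[str]] = {}
    for row in _read_tsv_rows(path):
        res = row[0]
        atoms = row[1].split(",") if len(row) > 1 and row[1] else []
        topo[res] = atoms
    return topo


def load_sybyl_fallback(path: Optional[Path] = None) -> dict[str, str]:
    path = path or _data_path("sybyl_fallback.tsv")
    return {row[0]: row[1] for row in _read_tsv_rows(path)}


def load_protein_sybyl_table(path: Optional[Path] = None) -> dict[tuple[str, str], str]:
    path = path or _data_path("protein_sybyl.tsv")
    return {(row[0], row[1]): row[2] for row in _read_tsv_rows(path)}


def _sidechain_slots(atoms: list[str]) -> dict[str, int]:
    """Partition ordered side-chain atoms into 3 contiguous near-equal groups.

    Returns atom name -> slot index (0-based: SC1, SC2, SC3). Residues
    with fewer than 3 side-chain atoms populate leading slots only.
    """
    if not atoms:
        return {}
    groups = np.array_split(np.arange(len(atoms)), 3)
    slot_of: dict[str, int] = {}
    for slot, idx in enumerate(groups):
        for i in idx:
            slot_of[atoms[int(i)]] = slot
    return slot_of


@dataclass(frozen=True)
class TypeScheme:
    """A named, ordered label vocabulary with a total atom -> label mapper."""

    scheme_id: str
    labels: tuple[str, ...]
    mapper: Callable[[AtomRecord], str]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"{self.scheme_id}: duplicate labels")

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def __call__(self, atom: AtomRecord) -> str:
        return self.mapper(atom)


def _build_residue100_labels(topology: dict[str, list[str]]) -> tuple[
        tuple[str, ...], dict[tuple[str, str], str]]:
    labels: list[str] = []
    atom_to_label: dict[tuple[str, str], str] = {}
    for res in STANDARD_RESIDUES:
        if res == "GLY":
            for name in ("N", "CA", "C", "O"):
                label = f"GLY:{name}"
                labels.append(label)
                atom_to_label[(res, name)] = label
            continue
        labels.append(f"{res}:BB1")
        labels.append(f"{res}:BB2")
        for name in _BACKBONE_BB1:
            atom_to_label[(res, name)] = f"{res}:BB1"
        for name in _BACKBONE_BB2:
            atom_to_label[(res, name)] = f"{res}:BB2"
        slots = _sidechain_slots(topology.get(res, []))
        for k in range(3):
            labels.append(f"{res}:SC{k + 1}")
        for atom_name, slot in slots.items():
            atom_to_label[(res, atom_name)] = f"{res}:SC{slot + 1}"
    labels.append(UNDEF)
    return tuple(labels), atom_to_label


_TOPOLOGY = load_residue_topology()
_RESIDUE100_LABELS, _RESIDUE100_MAP = _build_residue100_labels(_TOPOLOGY)
_SYBYL_FALLBACK = load_sybyl_fallback()
_PROTEIN_SYBYL_TABLE = load_protein_sybyl_table()
_BACKBONE_SYBYL = {"N": "N.am", "CA": "C.3", "C": "C.2", "O": "O.2", "OXT": "O.co2"}


def _map_sybyl_label(sybyl: str, element: str) -> str:
    """Map an arbitrary Sybyl type string onto the 23-label vocabulary."""
    if sybyl in LIGAND_SYBYL_LABELS:
        return sybyl
    if sybyl in _SYBYL_FALLBACK:
        return _SYBYL_FALLBACK[sybyl]
    elem = element.capitalize()
    if elem in _ELEMENT_FALLBACK:
        return _ELEMENT_FALLBACK[elem]
    logger.warning("unknown Sybyl type %r (element %s): mapping to %s",
                   sybyl, element, _GENERIC_FALLBACK)
    return _GENERIC_FALLBACK


def ligand_type_of(atom: AtomRecord, structure: Optional[Structure] = None) -> str:
    """Map a ligand heavy atom to one of the 23 Sybyl labels.

    Uses the verbatim Mol2 type when present; otherwise infers one from
    element and connectivity (``structure`` supplies the bonds).
    """
    sybyl = atom.sybyl_type
    if sybyl is None:
        sybyl = infer_sybyl_type(atom, structure)
    return _map_sybyl_label(sybyl, atom.element)


def infer_sybyl_type(atom: AtomRecord, structure: Optional[Structure]) -> str:
    """Infer a Sybyl type from element + bond orders (SDF ligands).

    Heuristic: aromatic flag beats bond order; carboxylate oxygens are
    detected from a carbon bearing two oxygens with at least one
    double/aromatic C-O bond. Without connectivity, saturated types are
    assumed.
    """
    elem = atom.element.capitalize()
    if elem in {"F", "Cl", "Br", "I", "P"}:
        return "P.3" if elem == "P" else elem
    if structure is None:
        return _ELEMENT_FALLBACK.get(elem, _GENERIC_FALLBACK)
    neigh = structure.neighbors(atom.atom_index)
    orders = [o for _, o in neigh]
    aromatic = "ar" in orders
    if elem == "C":
        if aromatic:
            return "C.ar"
        if "3" in orders:
            return "C.1"
        if "2" in orders:
            return "C.2"
        return "C.3"
    if elem == "N":
        if aromatic:
            return "N.ar"
        if "3" in orders:
            return "N.1"
        if "am" in orders or _bonded_to_carbonyl(atom, structure):
            return "N.am"
        if "2" in orders:
            return "N.2"
        if len(neigh) >= 4:
            return "N.4"
        return "N.3"
    if elem == "O":
        if _is_carboxylate_oxygen(atom, structure):
            return "O.co2"
        if "2" in orders or aromatic:
            return "O.2"
        return "O.3"
    if elem == "S":
        n_oxy = sum(1 for j, _ in neigh if structure.atoms[j].element == "O")
        if n_oxy >= 2:
            return "S.o2"
        if n_oxy == 1:
            return "S.o"
        if "2" in orders:
            return "S.2"
        return "S.3"
    return _ELEMENT_FALLBACK.get(elem, _GENERIC_FALLBACK)


def _bonded_to_carbonyl(atom: AtomRecord, structure: Structure) -> bool:
    for j, order in structure.neighbors(atom.atom_index):
        nb = structure.atoms[j]
        if nb.element != "C" or order not in {"1", "am"}:
            continue
        for k, korder in structure.neighbors(j):
            if structure.atoms[k].element == "O" and korder == "2":
                return True
    return False


def _is_carboxylate_oxygen(atom: AtomRecord, structure: Structure) -> bool:
    for j, _ in structure.neighbors(atom.atom_index):
        carbon = structure.atoms[j]
        if carbon.element != "C":
            continue
        oxy_bonds = [(k, o) for k, o in structure.neighbors(j)
                     if structure.atoms[k].element == "O"]
        if len(oxy_bonds) == 2 and any(o in {"2", "ar"} for _, o in oxy_bonds):
            return True
    return False


def protein_type_of(atom: AtomRecord) -> str:
    """Map a receptor heavy atom to one of the 100 residue-dependent labels."""
    return _RESIDUE100_MAP.get((atom.residue_name, atom.atom_name), UNDEF)


def protein_sybyl_type_of(atom: AtomRecord) -> str:
    """Map a receptor heavy atom to the Sybyl-style atom-atom scheme."""
    if atom.residue_name in STANDARD_RESIDUES:
        if atom.atom_name in _BACKBONE_SYBYL:
            return _BACKBONE_SYBYL[atom.atom_name]
        sybyl = _PROTEIN_SYBYL_TABLE.get((atom.residue_name, atom.atom_name))
        if sybyl is not None:
            return sybyl
    # metals, cofactors, non-standard residues: element-based fallback
    elem = atom.element.capitalize()
    return _ELEMENT_FALLBACK.get(elem, UNDEF)


_SCHEMES: dict[str, TypeScheme] = {
    "ligand_sybyl23": TypeScheme(
        scheme_id="ligand_sybyl23",
        labels=LIGAND_SYBYL_LABELS,
        mapper=ligand_type_of,
    ),
    "protein_residue100": TypeScheme(
        scheme_id="protein_residue100",
        labels=_RESIDUE100_LABELS,
        mapper=protein_type_of,
    ),
    "protein_sybyl": TypeScheme(
        scheme_id="protein_sybyl",
        labels=LIGAND_SYBYL_LABELS + (UNDEF,),
        mapper=protein_sybyl_type_of,
    ),
}


def get_scheme(scheme_id: str) -> TypeScheme:
    try:
        return _SCHEMES[scheme_id]
    except KeyError:
        raise KeyError(
            f"unknown scheme {scheme_id!r}; known: {sorted(_SCHEMES)}") from None


def enumerate_types(scheme_id: str) -> tuple[str, ...]:
    """Stable, documented label ordering for a scheme."""
    return get_scheme(scheme_id).labels


def ligand_labels_of(structure: Structure) -> list[str]:
    return [ligand_type_of(a, structure) for a in structure.atoms]


def protein_labels_of(structure: Structure, scheme_id: str = "protein_residue100") -> list[str]:
    scheme = get_scheme(scheme_id)
    return [scheme(a) for a in structure.atoms]
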