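"""Shared fixtures: tiny hand-built structures and planted ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from hybridsp.structio import AtomRecord, Structure, ComplexRecord


def pdb_line(serial: int, name: str, resname: str, chain: str, seq: int,
             x: float, y: float, z: float, occ: float = 1.00,
             altloc: str = " ", element: str = "", hetatm: bool = False) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    element = element or name[0]
    name_field = f" {name:<3}" if len(name) < 4 else name
    return (f"{record}{serial:>5} {name_field}{altloc}{resname:>3} {chain}"
            f"{seq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2}")


def make_atom(index: int, name: str, element: str, res: str, seq: int,
              pos, sybyl: str | None = None, chain: str = "A") -> AtomRecord:
    return AtomRecord(
        atom_index=index, atom_name=name, element=element, sybyl_type=sybyl,
        residue_name=res, residue_seq=seq, chain_id=chain,
        position=np.asarray(pos, dtype=float))


def single_pair_complex(distance: float, lig_type: str = "C.3",
                        rec_res: str = "GLY", rec_atom: str = "CA") -> ComplexRecord:
    """One ligand atom at the origin, one receptor atom at ``distance``."""
    elem = lig_type.split(".")[0].capitalize()
    lig = Structure([make_atom(0, f"{elem}1", elem, "LIG", 1, [0, 0, 0], lig_type)])
    rec = Structure([make_atom(0, rec_atom, rec_atom[0], rec_res, 1,
                               [distance, 0, 0])])
    return ComplexRecord(receptor=rec, ligand=lig, complex_id="pair")


@pytest.fixture
def gly_pdb(tmp_path):
    """One glycine with backbone + 3 hydrogens: 4 heavy atoms expected."""
    lines = [
        pdb_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0, element="N"),
        pdb_line(2, "CA", "GLY", "A", 1, 1.458, 0.0, 0.0, element="C"),
        pdb_line(3, "C", "GLY", "A", 1, 2.0, 1.4, 0.0, element="C"),
        pdb_line(4, "O", "GLY", "A", 1, 1.3, 2.4, 0.0, element="O"),
        pdb_line(5, "H", "GLY", "A", 1, -0.5, 0.8, 0.0, element="H"),
        pdb_line(6, "HA2", "GLY", "A", 1, 1.8, -0.9, 0.0, element="H"),
        pdb_line(7, "HA3", "GLY", "A", 1, 1.2, 0.3, 1.0, element="H"),
    ]
    path = tmp_path / "gly.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


@pytest.fixture
def benzene_mol2(tmp_path):
    """Benzene with explicit hydrogens: 6 heavy atoms, 6 aromatic bonds."""
    import math
    atom_lines, bond_lines = [], []
    for k in range(6):
        a = 2 * math.pi * k / 6
        atom_lines.append(
            f"{k + 1:>7} C{k + 1:<7} {1.39 * math.cos(a):>9.4f} "
            f"{1.39 * math.sin(a):>9.4f} {0.0:>9.4f} C.ar     1 BNZ1 0.0000")
        bond_lines.append(f"{k + 1:>6} {k + 1:>5} {(k + 1) % 6 + 1:>5} ar")
    for k in range(6):
        a = 2 * math.pi * k / 6
        atom_lines.append(
            f"{k + 7:>7} H{k + 1:<7} {2.49 * math.cos(a):>9.4f} "
            f"{2.49 * math.sin(a):>9.4f} {0.0:>9.4f} H        1 BNZ1 0.0000")
        bond_lines.append(f"{k + 7:>6} {k + 1:>5} {k + 7:>5} 1")
    text = "\n".join(
        ["@<TRIPOS>MOLECULE", "benzene", "12 12 0 0 0", "SMALL", "NO_CHARGES",
         "", "@<TRIPOS>ATOM"] + atom_lines + ["@<TRIPOS>BOND"] + bond_lines)
    path = tmp_path / "benzene.mol2"
    path.write_text(text + "\n")
    return path
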