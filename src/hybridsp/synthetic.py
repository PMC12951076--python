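"""Self-contained synthetic fixtures: planted potentials and sampled
complexes written as valid PDB + Mol2.

The generator plants a smooth per-pair well potential W*(r) on the
standard radial grid and samples pocket-atom distances from the binned
Boltzmann density p_k proportional to r_k^2 * exp(-W*(r_k)) * dr
(inverse-transform over bins, uniform within a bin), so the sampled
histogram is an exact multinomial draw of the model being recovered.
Pocket pseudo-residues carry real residue names and complete backbone
atom sets, so typing and local-frame construction exercise the full
production paths; no attempt is made at realistic covalent geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

from hybridsp import atomtypes
from hybridsp.potentials import (
    ContactHistogram,
    PotentialTable,
    R0_DEFAULT,
    RC_DEFAULT,
    DR_DEFAULT,
    bin_midpoints,
)
from hybridsp.structio import AtomRecord, Structure

#: atoms written per pseudo-residue type (backbone + short side chains)
_FIXTURE_RESIDUE_ATOMS: dict[str, list[tuple[str, str]]] = {
    "GLY": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")],
    "ALA": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")],
    "SER": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"),
            ("OG", "O")],
}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic ensemble; ``seed`` fixes all randomness.

    ``ligand_size`` defaults to 1 so that every ligand-pocket distance is
    drawn exactly from the planted density (additional ligand atoms would
    contribute contacts at unplanted distances).
    """

    n_complexes: int = 200
    residues_per_pocket: dict[str, int] = field(
        default_factory=lambda: {"GLY": 8, "ALA": 8, "SER": 8})
    ligand_size: int = 1
    ligand_labels: tuple[str, ...] = ("C.3",)
    affinity_range: tuple[float, float] = (2.0, 11.0)
    seed: int = 0
    planted: Optional[PotentialTable] = None  # None = uniform (W* = 0)

    def __post_init__(self) -> None:
        if self.n_complexes < 0 or self.ligand_size < 1:
            raise ValueError("sizes must be >= 1 (n_complexes >= 0)")
        for res in self.residues_per_pocket:
            if res not in _FIXTURE_RESIDUE_ATOMS:
                raise ValueError(f"unsupported fixture residue {res}")

    @property
    def pocket_protein_labels(self) -> tuple[str, ...]:
        labels = []
        for res, count in self.residues_per_pocket.items():
            if count <= 0:
                continue
            for name, _ in _FIXTURE_RESIDUE_ATOMS[res]:
                atom = AtomRecord(0, name, "C", None, res, 1, "A",
                                  np.zeros(3))
                lbl = atomtypes.protein_type_of(atom)
                if lbl not in labels:
                    labels.append(lbl)
        return tuple(labels)


def make_planted_potential(seed: int,
                           lig_labels: Sequence[str],
                           prot_labels: Sequence[str],
                           well_depth_range: tuple[float, float] = (0.5, 1.5),
                           well_sigma: float = 0.5,
                           ) -> PotentialTable:
    """Plant a smooth Gaussian-well profile per selected type pair.

    W*(r) = -depth * exp(-(r - center)^2 / (2 sigma^2)) with a random
    center in [2.5, 5.0] Angstrom and depth drawn from
    ``well_depth_range``; all other pairs are zero. Reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    scheme_l = atomtypes.get_scheme("ligand_sybyl23")
    scheme_p = atomtypes.get_scheme("protein_residue100")
    r_mid = bin_midpoints(R0_DEFAULT, RC_DEFAULT, DR_DEFAULT)
    delta_w = np.zeros((len(scheme_l.labels), len(scheme_p.labels), len(r_mid)))
    lo, hi = well_depth_range
    for ll in lig_labels:
        for pl in prot_labels:
            center = rng.uniform(2.5, 5.0)
            depth = rng.uniform(lo, hi)
            profile = -depth * np.exp(-((r_mid - center) ** 2) / (2 * well_sigma**2))
            delta_w[scheme_l.index_of(ll), scheme_p.index_of(pl)] = profile
    return PotentialTable(
        lig_scheme="ligand_sybyl23", prot_scheme="protein_residue100",
        r0=R0_DEFAULT, rc=RC_DEFAULT, dr=DR_DEFAULT, delta_w=delta_w,
        provenance=f"planted:seed={seed}")


def _pair_bin_probs(planted: Optional[PotentialTable], li: int, pj: int,
                    r_mid: np.ndarray, dr: float) -> np.ndarray:
    w = planted.delta_w[li, pj] if planted is not None else np.zeros_like(r_mid)
    p = r_mid**2 * np.exp(-w) * dr
    return p / p.sum()


def expected_histogram(planted: Optional[PotentialTable],
                       total_pairs_per_type_pair: float,
                       lig_labels: Optional[Sequence[str]] = None,
                       prot_labels: Optional[Sequence[str]] = None,
                       ) -> ContactHistogram:
    """Noise-free oracle: counts set to exact expectations T * p_k.

    With ``lig_labels``/``prot_labels`` given, only those pairs are
    populated (matching the pair support of a sampled fixture ensemble).
    """
    scheme_l = atomtypes.get_scheme("ligand_sybyl23")
    scheme_p = atomtypes.get_scheme("protein_residue100")
    lig_labels = tuple(lig_labels or scheme_l.labels)
    prot_labels = tuple(prot_labels or scheme_p.labels)
    hist = ContactHistogram(lig_scheme="ligand_sybyl23",
                            prot_scheme="protein_residue100")
    r_mid = bin_midpoints(hist.r0, hist.rc, hist.dr)
    for ll in lig_labels:
        li = scheme_l.index_of(ll)
        for pl in prot_labels:
            pj = scheme_p.index_of(pl)
            p = _pair_bin_probs(planted, li, pj, r_mid, hist.dr)
            hist.counts[li, pj] = total_pairs_per_type_pair * p
    return hist


def _sample_distance(rng: np.random.Generator, probs: np.ndarray,
                     r0: float, dr: float) -> float:
    k = int(rng.choice(len(probs), p=probs))
    return r0 + (k + rng.uniform()) * dr


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def build_complex_structures(spec: FixtureSpec, rng: np.random.Generator,
                             lig_label: str
                             ) -> tuple[Structure, Structure]:
    """One pocket + ligand pair with distances drawn from the planted model.

    The ligand probe atom sits at the origin; extra ligand atoms (if any)
    are packed within 0.8 Angstrom of it. Every pocket atom is placed
    independently at a sampled distance from the probe in a random
    direction.
    """
    scheme_l = atomtypes.get_scheme("ligand_sybyl23")
    scheme_p = atomtypes.get_scheme("protein_residue100")
    r_mid = bin_midpoints(R0_DEFAULT, RC_DEFAULT, DR_DEFAULT)
    li = scheme_l.index_of(lig_label)

    lig_atoms = []
    for i in range(spec.ligand_size):
        pos = np.zeros(3) if i == 0 else 0.8 * _random_direction(rng) * rng.uniform()
        elem = lig_label.split(".")[0].capitalize()
        lig_atoms.append(AtomRecord(
            atom_index=i, atom_name=f"{elem}{i + 1}", element=elem,
            sybyl_type=lig_label, residue_name="LIG", residue_seq=1,
            chain_id="", position=pos, is_hetero=True))
    bonds = [(i, i + 1, "1") for i in range(spec.ligand_size - 1)]
    ligand = Structure(atoms=lig_atoms, bonds=bonds)

    rec_atoms: list[AtomRecord] = []
    seq = 0
    for res, count in spec.residues_per_pocket.items():
        for _ in range(count):
            seq += 1
            for name, elem in _FIXTURE_RESIDUE_ATOMS[res]:
                probe = AtomRecord(0, name, elem, None, res, seq, "A", np.zeros(3))
                pj = scheme_p.index_of(atomtypes.protein_type_of(probe))
                probs = _pair_bin_probs(spec.planted, li, pj, r_mid, DR_DEFAULT)
                d = _sample_distance(rng, probs, R0_DEFAULT, DR_DEFAULT)
                pos = d * _random_direction(rng)
                rec_atoms.append(AtomRecord(
                    atom_index=len(rec_atoms), atom_name=name, element=elem,
                    sybyl_type=None, residue_name=res, residue_seq=seq,
                    chain_id="A", position=pos))
    receptor = Structure(atoms=rec_atoms)
    return receptor, ligand


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a fixture receptor as PDB (via gemmi)."""
    st = gemmi.Structure()
    st.name = "fixture"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    current_key = None
    res = None
    for atom in structure.atoms:
        key = (atom.residue_seq, atom.icode, atom.residue_name)
        if key != current_key:
            if res is not None:
                chain.add_residue(res)
            res = gemmi.Residue()
            res.name = atom.residue_name
            res.seqid = gemmi.SeqId(atom.residue_seq, atom.icode or " ")
            current_key = key
        g_atom = gemmi.Atom()
        g_atom.name = atom.atom_name
        g_atom.element = gemmi.Element(atom.element)
        g_atom.pos = gemmi.Position(*atom.position)
        g_atom.occ = 1.0
        res.add_atom(g_atom)
    if res is not None:
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    Path(path).write_text(st.make_pdb_string())


def write_mol2(structure: Structure, path: str | Path,
               mol_name: str = "LIG") -> None:
    """Write a fixture ligand as Tripos Mol2."""
    lines = ["@<TRIPOS>MOLECULE", mol_name,
             f"{len(structure.atoms)} {len(structure.bonds)} 0 0 0",
             "SMALL", "NO_CHARGES", "", "@<TRIPOS>ATOM"]
    for i, atom in enumerate(structure.atoms, start=1):
        sybyl = atom.sybyl_type or atom.element
        x, y, z = atom.position
        lines.append(f"{i:>7} {atom.atom_name:<8} {x:>9.4f} {y:>9.4f} "
                     f"{z:>9.4f} {sybyl:<8} 1 LIG1 0.0000")
    lines.append("@<TRIPOS>BOND")
    for n, (a, b, order) in enumerate(structure.bonds, start=1):
        lines.append(f"{n:>6} {a + 1:>5} {b + 1:>5} {order}")
    Path(path).write_text("\n".join(lines) + "\n")


def sample_complexes(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Generate the ensemble on disk; returns the manifest path.

    Layout: ``<out>/complexes/<id>_rec.pdb``, ``<id>_lig.mol2`` and a
    tab-separated ``manifest.tsv`` (complex_id, receptor_path,
    ligand_path, affinity). All files re-read cleanly through the
    structure I/O layer.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows = ["complex_id\treceptor_path\tligand_path\taffinity"]
    struct_dir = out_dir / "complexes"
    if spec.n_complexes > 0:
        struct_dir.mkdir(exist_ok=True)
    lo, hi = spec.affinity_range
    for i in range(spec.n_complexes):
        cid = f"syn{i:04d}"
        lig_label = spec.ligand_labels[i % len(spec.ligand_labels)]
        receptor, ligand = build_complex_structures(spec, rng, lig_label)
        rec_path = struct_dir / f"{cid}_rec.pdb"
        lig_path = struct_dir / f"{cid}_lig.mol2"
        write_pdb(receptor, rec_path)
        write_mol2(ligand, lig_path, mol_name=cid)
        affinity = rng.uniform(lo, hi)
        rows.append(f"{cid}\tcomplexes/{cid}_rec.pdb\t"
                    f"complexes/{cid}_lig.mol2\t{affinity:.4f}")
    manifest = out_dir / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest


def sample_complex_records(spec: FixtureSpec) -> list:
    """In-memory variant of :func:`sample_complexes` (no file I/O)."""
    from hybridsp.structio import ComplexRecord

    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.affinity_range
    records = []
    for i in range(spec.n_complexes):
        lig_label = spec.ligand_labels[i % len(spec.ligand_labels)]
        receptor, ligand = build_complex_structures(spec, rng, lig_label)
        records.append(ComplexRecord(
            receptor=receptor, ligand=ligand,
            affinity=float(rng.uniform(lo, hi)), complex_id=f"syn{i:04d}"))
    return records
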