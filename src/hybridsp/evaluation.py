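"""Docking-power and screening-power metrics, plus interaction consensus.

Docking power: fraction of targets whose best-scored pose is within
2 Angstrom RMSD of the crystal pose. Screening power: enrichment factor
at a top fraction and AUROC, with lower score = better everywhere.

The interaction-consensus analysis detects protein-ligand interactions
(hydrophobic, hydrogen bond, pi-pi stacking, weak hydrogen bond, salt
bridge, cation-pi, halogen bond) under documented geometric thresholds
and counts a (receptor atom, interaction type, role) triple once iff it
occurs with all five top-scored compounds of a target.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from hybridsp.structio import ComplexRecord, Structure

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Pose / screen containers
# ---------------------------------------------------------------------------

@dataclass
class PoseSet:
    """Scored docking poses for one target; poses share the crystal's
    atom count and ordering (RMSD is computed without superposition)."""

    target_id: str
    crystal: Structure
    poses: list[tuple[str, Structure, float]]
    crystal_score: Optional[float] = None  # used when include_crystal is set

    def __post_init__(self) -> None:
        for pose_id, st, _ in self.poses:
            if len(st) != len(self.crystal):
                raise ValueError(
                    f"{self.target_id}/{pose_id}: pose atom count "
                    f"{len(st)} != crystal {len(self.crystal)}")


@dataclass
class ScreenSet:
    """Scored screening entries for one target (lower score = better)."""

    target_id: str
    entries: list[tuple[str, float, bool]]  # (compound_id, score, is_active)

    @property
    def n_actives(self) -> int:
        return sum(1 for _, _, a in self.entries if a)


def rmsd(a: Structure, b: Structure) -> float:
    """Heavy-atom RMSD over corresponding atoms, no superposition."""
    if len(a) != len(b):
        raise ValueError(f"atom count mismatch: {len(a)} vs {len(b)}")
    diff = a.coords - b.coords
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def docking_success_rate(pose_sets: Sequence[PoseSet], threshold: float = 2.0,
                         top_n: int = 1, include_crystal: bool = False) -> float:
    """Fraction of targets whose top_n best-scoring poses contain one
    within ``threshold`` RMSD of the crystal. Score ties are broken by
    stable input order; include_crystal adds the crystal itself as a
    zero-RMSD candidate with its own score."""
    if not pose_sets:
        raise ValueError("no pose sets")
    successes = 0
    for ps in pose_sets:
        candidates: list[tuple[float, float]] = []  # (score, rmsd)
        for _, st, score in ps.poses:
            candidates.append((score, rmsd(st, ps.crystal)))
        if include_crystal:
            # unscored crystal defaults to the best pose score and is
            # inserted first, so the stable tie-break favors it
            crystal_score = ps.crystal_score
            if crystal_score is None:
                crystal_score = min((s for s, _ in candidates), default=0.0)
            candidates.insert(0, (crystal_score, 0.0))
        if not candidates:
            raise ValueError(f"{ps.target_id}: empty pose set")
        order = sorted(range(len(candidates)), key=lambda i: candidates[i][0])
        top = order[:top_n]
        if min(candidates[i][1] for i in top) < threshold:
            successes += 1
    return successes / len(pose_sets)


def enrichment_factor(screen: ScreenSet, fraction: float) -> float:
    """EF = (actives in top ceil(fraction*N) / ceil(fraction*N)) / (actives/N)."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    n = len(screen.entries)
    n_act = screen.n_actives
    if n_act == 0:
        raise ValueError(f"{screen.target_id}: no actives")
    m = math.ceil(fraction * n)
    order = sorted(range(n), key=lambda i: screen.entries[i][1])
    hits = sum(1 for i in order[:m] if screen.entries[i][2])
    return (hits / m) / (n_act / n)


def auroc(screen: ScreenSet) -> float:
    """AUROC via the Mann-Whitney statistic with midranks for ties.

    Equals the probability that a random active outscores (scores lower
    than) a random decoy, counting ties as half.
    """
    scores = np.array([s for _, s, _ in screen.entries], dtype=float)
    actives = np.array([a for _, _, a in screen.entries], dtype=bool)
    n_act = int(actives.sum())
    n_dec = len(scores) - n_act
    if n_act == 0 or n_dec == 0:
        raise ValueError(f"{screen.target_id}: need >= 1 active and >= 1 decoy")
    ranks = rankdata(scores)  # ascending: rank 1 = best (lowest) score
    u_worse = float(ranks[actives].sum()) - n_act * (n_act + 1) / 2.0
    return 1.0 - u_worse / (n_act * n_dec)


def screening_success_rate(screens: Sequence[ScreenSet], fraction: float) -> float:
    """Fraction of targets with >= 1 active inside the top fraction."""
    if not screens:
        raise ValueError("no screen sets")
    successes = 0
    for sc in screens:
        n = len(sc.entries)
        m = math.ceil(fraction * n)
        order = sorted(range(n), key=lambda i: sc.entries[i][1])
        if any(sc.entries[i][2] for i in order[:m]):
            successes += 1
    return successes / len(screens)


# ---------------------------------------------------------------------------
# Interaction detection
# ---------------------------------------------------------------------------

INTERACTION_TYPES = ("hydrophobic", "hbond", "pi_pi", "weak_hbond",
                     "salt_bridge", "cation_pi", "halogen_bond")

#: type -> roles the receptor atom may take in a record of that type
VALID_ROLES: dict[str, set[str]] = {
    "hydrophobic": {"nonpolar"},
    "hbond": {"donor", "acceptor"},
    "weak_hbond": {"donor", "acceptor", "nonpolar"},
    "salt_bridge": {"cation", "acceptor"},
    "pi_pi": {"pi_system"},
    "cation_pi": {"cation", "pi_system"},
    "halogen_bond": {"acceptor"},
}


@dataclass(frozen=True)
class InteractionRecord:
    """One detected protein-ligand interaction; role describes the
    receptor atom's part in it."""

    interaction_type: str
    chain_id: str
    residue_name: str
    residue_seq: int
    atom_name: str
    ligand_atom: int
    role: str

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES[self.interaction_type]:
            raise ValueError(
                f"invalid role {self.role} for {self.interaction_type}")

    @property
    def receptor_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.atom_name)


@dataclass
class InteractionThresholds:
    """Geometric cutoffs (Angstrom / degrees); conventional defaults."""

    hbond_dist: float = 3.5
    weak_hbond_dist: float = 3.6
    hydrophobic_dist: float = 4.0
    salt_bridge_dist: float = 4.0
    pi_pi_centroid_dist: float = 5.5
    pi_pi_parallel_max_deg: float = 30.0
    pi_pi_tshape_range_deg: tuple[float, float] = (60.0, 90.0)
    cation_pi_dist: float = 6.0
    halogen_dist: float = 3.5
    halogen_angle_min_deg: float = 140.0


# Per-residue receptor role tables (heavy-atom, hydrogen-free convention).
_DONOR_ATOMS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
_ACCEPTOR_ATOMS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}
_NONPOLAR_C: dict[str, set[str]] = {
    "ALA": {"CB"}, "ARG": {"CB", "CG"}, "ASN": {"CB"}, "ASP": {"CB"},
    "CYS": {"CB"}, "GLN": {"CB", "CG"}, "GLU": {"CB", "CG"},
    "ILE": {"CB", "CG1", "CG2", "CD1"}, "LEU": {"CB", "CG", "CD1", "CD2"},
    "LYS": {"CB", "CG", "CD"}, "MET": {"CB", "CG", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "PRO": {"CB", "CG"}, "THR": {"CG2"},
    "TRP": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "VAL": {"CB", "CG1", "CG2"}, "HIS": {"CB"},
}
_CATION_ATOMS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
}
_CARBOXYLATE_O: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
}
#: aromatic ring atom sets; pi interactions are attributed to the ring's
#: anchor atom (first listed, CG)
_RING_ATOMS: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]],
}

_LIG_DONOR_TYPES = {"N.3", "N.4", "N.am", "N.pl3", "O.3"}
_LIG_ACCEPTOR_TYPES = {"O.2", "O.3", "O.co2", "N.ar", "N.2", "N.1", "N.3"}
_HALOGEN_ELEMENTS = {"Cl", "Br", "I"}


def _ring_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit plane: returns (centroid, unit normal)."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid)
    return centroid, vt[2]


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = abs(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(min(1.0, c)))


def _ligand_rings(ligand: Structure) -> list[list[int]]:
    """Aromatic rings from connectivity: cycles in the subgraph of
    aromatic bonds (order 'ar'), falling back to rings of C.ar atoms."""
    import networkx as nx

    g = nx.Graph()
    for a, b, order in ligand.bonds:
        if order == "ar":
            g.add_edge(a, b)
    rings = []
    for cycle in nx.cycle_basis(g):
        if 5 <= len(cycle) <= 6:
            rings.append(sorted(cycle))
    return rings


def _ligand_roles(ligand: Structure) -> dict[int, set[str]]:
    from hybridsp.atomtypes import ligand_type_of

    roles: dict[int, set[str]] = {}
    for atom in ligand.atoms:
        label = ligand_type_of(atom, ligand)
        r: set[str] = set()
        if label in _LIG_DONOR_TYPES:
            r.add("donor")
        if label in _LIG_ACCEPTOR_TYPES:
            r.add("acceptor")
        if label == "N.4":
            r.add("cation")
        if label == "O.co2":
            r.add("anion")
        if label.startswith("C"):
            bonded_hetero = any(
                ligand.atoms[j].element in {"N", "O"}
                for j, _ in ligand.neighbors(atom.atom_index))
            if not bonded_hetero:
                r.add("nonpolar")
            r.add("carbon")
        if atom.element in _HALOGEN_ELEMENTS:
            bonded_c = any(ligand.atoms[j].element == "C"
                           for j, _ in ligand.neighbors(atom.atom_index))
            if bonded_c or not ligand.bonds:
                r.add("halogen")
        if atom.element in {"N", "O"}:
            r.add("polar")
        roles[atom.atom_index] = r
    return roles


def detect_interactions(complex_: ComplexRecord,
                        thresholds: Optional[InteractionThresholds] = None
                        ) -> list[InteractionRecord]:
    """Detect protein-ligand interactions under geometric thresholds.

    Records are deterministic for identical inputs and invariant under
    rigid motion of the whole complex. Ring-dependent types (pi-pi,
    ligand-side cation-pi) require ligand connectivity; without bonds
    they are skipped with a warning.
    """
    th = thresholds or InteractionThresholds()
    receptor, ligand = complex_.receptor, complex_.ligand
    lig_roles = _ligand_roles(ligand)
    lig_xyz = ligand.coords
    records: list[InteractionRecord] = []

    def add(kind: str, rec_atom, lig_idx: int, role: str) -> None:
        records.append(InteractionRecord(
            interaction_type=kind, chain_id=rec_atom.chain_id,
            residue_name=rec_atom.residue_name, residue_seq=rec_atom.residue_seq,
            atom_name=rec_atom.atom_name, ligand_atom=lig_idx, role=role))

    # pairwise atom-atom interactions
    for rec in receptor.atoms:
        res, name = rec.residue_name, rec.atom_name
        is_bb_n = name == "N" and res != "PRO"
        is_bb_o = name in {"O", "OXT"}
        donor = is_bb_n or name in _DONOR_ATOMS.get(res, set())
        acceptor = is_bb_o or name in _ACCEPTOR_ATOMS.get(res, set())
        nonpolar = name in _NONPOLAR_C.get(res, set())
        cation = name in _CATION_ATOMS.get(res, set())
        carboxylate = is_bb_o and name == "OXT" or name in _CARBOXYLATE_O.get(res, set())
        is_carbon = rec.element == "C"
        is_no = rec.element in {"N", "O"}
        d_all = np.linalg.norm(lig_xyz - rec.position, axis=1)
        for li, d in enumerate(d_all):
            if d > 6.5:
                continue
            lr = lig_roles[li]
            if donor and "acceptor" in lr and d <= th.hbond_dist:
                add("hbond", rec, li, "donor")
            if acceptor and "donor" in lr and d <= th.hbond_dist:
                add("hbond", rec, li, "acceptor")
            if nonpolar and "nonpolar" in lr and d <= th.hydrophobic_dist:
                add("hydrophobic", rec, li, "nonpolar")
            if is_carbon and "polar" in lr and d <= th.weak_hbond_dist:
                add("weak_hbond", rec, li, "nonpolar")
            if is_no and acceptor and "carbon" in lr and d <= th.weak_hbond_dist:
                add("weak_hbond", rec, li, "acceptor")
            if cation and "anion" in lr and d <= th.salt_bridge_dist:
                add("salt_bridge", rec, li, "cation")
            if carboxylate and "cation" in lr and d <= th.salt_bridge_dist:
                add("salt_bridge", rec, li, "acceptor")
            if is_no and acceptor and "halogen" in lr and d <= th.halogen_dist:
                # C-X...A angle check
                carbon = next((j for j, _ in ligand.neighbors(li)
                               if ligand.atoms[j].element == "C"), None)
                if carbon is None and ligand.bonds:
                    continue
                if carbon is not None:
                    v1 = lig_xyz[carbon] - lig_xyz[li]
                    v2 = rec.position - lig_xyz[li]
                    cosang = float(np.dot(v1, v2) /
                                   (np.linalg.norm(v1) * np.linalg.norm(v2)))
                    ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                    if ang < th.halogen_angle_min_deg:
                        continue
                add("halogen_bond", rec, li, "acceptor")

    # ring-based interactions
    if not ligand.bonds:
        if len(ligand) >= 5:  # smaller ligands cannot contain a ring anyway
            logger.warning("ligand has no connectivity: ring-dependent "
                           "interaction types disabled")
        lig_rings: list[list[int]] = []
    else:
        lig_rings = _ligand_rings(ligand)

    rec_rings: list[tuple[object, np.ndarray, np.ndarray]] = []
    by_res: dict[tuple, dict[str, object]] = {}
    for a in receptor.atoms:
        by_res.setdefault((a.chain_id, a.residue_seq, a.icode, a.residue_name),
                          {})[a.atom_name] = a
    for (chain, seq, icode, res), atoms in by_res.items():
        for ring_names in _RING_ATOMS.get(res, []):
            if all(n in atoms for n in ring_names):
                pts = np.array([atoms[n].position for n in ring_names])
                centroid, normal = _ring_plane(pts)
                rec_rings.append((atoms[ring_names[0]], centroid, normal))

    for ring in lig_rings:
        l_centroid, l_normal = _ring_plane(lig_xyz[ring])
        anchor_lig = ring[0]
        for rec_atom, centroid, normal in rec_rings:
            dist = float(np.linalg.norm(centroid - l_centroid))
            if dist <= th.pi_pi_centroid_dist:
                ang = _angle_deg(normal, l_normal)
                lo, hi = th.pi_pi_tshape_range_deg
                if ang <= th.pi_pi_parallel_max_deg or lo <= ang <= hi:
                    add("pi_pi", rec_atom, anchor_lig, "pi_system")
        # receptor cation vs ligand ring
        for rec in receptor.atoms:
            if rec.atom_name in _CATION_ATOMS.get(rec.residue_name, set()):
                if np.linalg.norm(rec.position - l_centroid) <= th.cation_pi_dist:
                    add("cation_pi", rec, anchor_lig, "cation")

    # ligand cation vs receptor ring
    for li, roles in lig_roles.items():
        if "cation" not in roles:
            continue
        for rec_atom, centroid, _ in rec_rings:
            if np.linalg.norm(lig_xyz[li] - centroid) <= th.cation_pi_dist:
                add("cation_pi", rec_atom, li, "pi_system")

    return records


def common_interactions(top_complexes: Sequence[ComplexRecord],
                        thresholds: Optional[InteractionThresholds] = None
                        ) -> list[tuple[tuple[str, int, str], str, str]]:
    """Unanimity consensus over the top five scored compounds of a target.

    A (receptor atom, interaction type, role) triple is counted once iff
    it appears in the interaction records of all five complexes. Output
    sorted by (chain, residue, atom name, type, role).
    """
    if len(top_complexes) != 5:
        raise ValueError("consensus analysis requires exactly 5 complexes")
    first = top_complexes[0].receptor
    for c in top_complexes[1:]:
        r = c.receptor
        if len(r) != len(first) or any(
                a.atom_name != b.atom_name or a.residue_seq != b.residue_seq
                for a, b in zip(r.atoms, first.atoms)):
            raise ValueError("all 5 complexes must share one receptor")
    triple_sets = []
    for c in top_complexes:
        recs = detect_interactions(c, thresholds)
        triple_sets.append({(r.receptor_key, r.interaction_type, r.role)
                            for r in recs})
    common = set.intersection(*triple_sets)
    return sorted(common, key=lambda t: (t[0][0], t[0][1], t[0][2], t[1], t[2]))
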