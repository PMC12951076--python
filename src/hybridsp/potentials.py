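"""Statistical-potential derivation from protein-ligand contact statistics.

The distance-dependent potential follows the classical pair-distribution
construction: per type pair (i, j), the local density rho_ij(r) =
N_ij(r) / (4 pi r^2 dr) is compared with the bulk density over the whole
interaction shell, g_ij(r) = rho_ij(r) / rho_bulk; the reference state
g(r) is the average of g_ij(r) over all included type pairs, and the
potential of mean force is the inverse Boltzmann transform

    dW_ij(r) = -ln[ g_ij(r) / g(r) ]    (k_B T units, k_B T = 1).

Contacts are counted on [r0, rc) = [2, 6) Angstrom in 0.2 Angstrom bins.
Training can weight each complex's contact counts by its binding
affinity, p = exp((A - A_mean) / A_mean), which up-weights tight binders.

An orientation-dependent atom-residue variant bins each ligand atom's
position in a local residue frame (r, cos theta, phi) and applies the
same inverse-Boltzmann construction with the 3D volume element
r^2 dr dcos(theta) dphi.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial import cKDTree

from hybridsp import atomtypes
from hybridsp.structio import ComplexRecord, Structure, read_manifest, load_complex

logger = logging.getLogger(__name__)

R0_DEFAULT = 2.0
RC_DEFAULT = 6.0
DR_DEFAULT = 0.2
CAP_DEFAULT = 10.0

DR_ORIENT_DEFAULT = 0.5
N_COS_DEFAULT = 6
N_PHI_DEFAULT = 8


def affinity_weight(affinity: float, affinity_mean: float) -> float:
    """Contact-count weight p = exp((A - A_mean) / A_mean).

    Strictly increasing in A; equals 1 at the mean affinity.
    """
    if affinity_mean <= 0:
        raise ValueError("affinity_mean must be positive")
    if affinity < 0:
        raise ValueError("affinity (pK) must be non-negative")
    return math.exp((affinity - affinity_mean) / affinity_mean)


def _n_bins(r0: float, rc: float, dr: float) -> int:
    return int(round((rc - r0) / dr))


def bin_midpoints(r0: float, rc: float, dr: float) -> np.ndarray:
    k = np.arange(_n_bins(r0, rc, dr))
    return r0 + (k + 0.5) * dr


def bin_edges(r0: float, rc: float, dr: float) -> np.ndarray:
    return np.linspace(r0, rc, _n_bins(r0, rc, dr) + 1)


def radial_bin_of(d: np.ndarray, r0: float, rc: float, dr: float) -> np.ndarray:
    """Half-open binning [lo, hi) on exact edges; callers must pre-filter
    to r0 <= d < rc. digitize keeps edge values (e.g. d = 3.0) in the bin
    they open, which floor((d - r0)/dr) does not guarantee in floats."""
    return np.digitize(d, bin_edges(r0, rc, dr)) - 1


@dataclass
class ContactHistogram:
    """(Possibly affinity-weighted) pair counts per type pair per radial bin.

    ``counts[i, j, k]`` holds the accumulated weight for ligand label i,
    protein label j, radial bin k covering [r0 + k*dr, r0 + (k+1)*dr).
    """

    lig_scheme: str
    prot_scheme: str
    r0: float = R0_DEFAULT
    rc: float = RC_DEFAULT
    dr: float = DR_DEFAULT
    counts: np.ndarray = None  # type: ignore[assignment]
    weighted: bool = False
    n_complexes: int = 0
    affinity_mean: Optional[float] = None

    def __post_init__(self) -> None:
        nl = len(atomtypes.enumerate_types(self.lig_scheme))
        npr = len(atomtypes.enumerate_types(self.prot_scheme))
        nb = _n_bins(self.r0, self.rc, self.dr)
        if self.counts is None:
            self.counts = np.zeros((nl, npr, nb), dtype=float)
        else:
            self.counts = np.asarray(self.counts, dtype=float)
            if self.counts.shape != (nl, npr, nb):
                raise ValueError(
                    f"counts shape {self.counts.shape} != ({nl}, {npr}, {nb})")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]


@dataclass
class PotentialTable:
    """Distance-dependent potential grid dW_ij(r) in k_B T units.

    Lower is better. ``clash_policy`` controls sub-r0 contacts when
    scoring: ("first_bin", None) charges the pair's innermost bin;
    ("constant", value) charges a fixed penalty.
    """

    lig_scheme: str
    prot_scheme: str
    r0: float
    rc: float
    dr: float
    delta_w: np.ndarray
    clash_policy: tuple[str, Optional[float]] = ("first_bin", None)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.delta_w = np.asarray(self.delta_w, dtype=float)
        nl = len(atomtypes.enumerate_types(self.lig_scheme))
        npr = len(atomtypes.enumerate_types(self.prot_scheme))
        nb = _n_bins(self.r0, self.rc, self.dr)
        if self.delta_w.shape != (nl, npr, nb):
            raise ValueError(
                f"delta_w shape {self.delta_w.shape} != ({nl}, {npr}, {nb})")
        if not np.all(np.isfinite(self.delta_w)):
            raise ValueError("delta_w must be finite everywhere")

    @property
    def lig_labels(self) -> tuple[str, ...]:
        return atomtypes.enumerate_types(self.lig_scheme)

    @property
    def prot_labels(self) -> tuple[str, ...]:
        return atomtypes.enumerate_types(self.prot_scheme)


@dataclass
class AccumulationReport:
    """Side report from contact accumulation."""

    in_range_pairs: int = 0
    clashes: int = 0
    total_weight: float = 0.0


def _pair_labels(complex_: ComplexRecord, lig_scheme: str, prot_scheme: str
                 ) -> tuple[np.ndarray, np.ndarray]:
    lig = atomtypes.get_scheme(lig_scheme)
    prot = atomtypes.get_scheme(prot_scheme)
    lig_idx = np.array(
        [lig.index_of(atomtypes.ligand_type_of(a, complex_.ligand))
         for a in complex_.ligand.atoms], dtype=int)
    prot_idx = np.array([prot.index_of(prot(a)) for a in complex_.receptor.atoms],
                        dtype=int)
    return lig_idx, prot_idx


def accumulate_contacts(complex_: ComplexRecord, weight: float,
                        hist: ContactHistogram) -> AccumulationReport:
    """Add one complex's ligand-receptor contacts into the histogram.

    Every (ligand atom, receptor atom) pair with r0 <= d < rc adds
    ``weight`` to its (ligand label, protein label, bin) cell. Pairs
    below r0 are reported as clashes; pairs at or beyond rc are ignored.
    Neighbor search uses a k-d tree; equivalence with the naive
    all-pairs loop is property-tested.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    if len(complex_.ligand) == 0 or len(complex_.receptor) == 0:
        raise ValueError("empty structure")
    lig_idx, prot_idx = _pair_labels(complex_, hist.lig_scheme, hist.prot_scheme)
    lig_xyz = complex_.ligand.coords
    rec_xyz = complex_.receptor.coords
    tree = cKDTree(rec_xyz)
    report = AccumulationReport()
    neighborhoods = tree.query_ball_point(lig_xyz, hist.rc)
    for li, rec_ids in enumerate(neighborhoods):
        if not rec_ids:
            continue
        rec_ids = np.asarray(rec_ids, dtype=int)
        d = np.linalg.norm(rec_xyz[rec_ids] - lig_xyz[li], axis=1)
        clash = d < hist.r0
        report.clashes += int(clash.sum())
        in_range = (~clash) & (d < hist.rc)
        bins = np.clip(radial_bin_of(d[in_range], hist.r0, hist.rc, hist.dr),
                       0, hist.n_bins - 1)
        np.add.at(hist.counts, (lig_idx[li], prot_idx[rec_ids[in_range]], bins),
                  weight)
        report.in_range_pairs += int(in_range.sum())
    report.total_weight = weight * report.in_range_pairs
    hist.n_complexes += 1
    return report


def derive_potential(hist: ContactHistogram, *, pseudocount: float = 0.0,
                     min_pair_total: float = 1.0, cap: float = CAP_DEFAULT,
                     clash_policy: tuple[str, Optional[float]] = ("first_bin", None),
                     provenance: str = "") -> PotentialTable:
    """Inverse-Boltzmann derivation of dW_ij(r) from a contact histogram.

    Pairs whose total raw count is below ``min_pair_total`` are excluded
    from the reference average and assigned dW = 0. The reference g(r)
    averages g_ij(r) over the included pairs only. Energies are clipped
    to [-cap, +cap]; bins where the reference itself vanishes get +cap.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if not np.any(hist.counts > 0):
        raise ValueError("histogram has no counts")
    counts = hist.counts
    raw_totals = counts.sum(axis=2)
    included = raw_totals >= max(min_pair_total, np.finfo(float).tiny)
    if not np.any(included):
        raise ValueError("all type pairs fall below min_pair_total")

    r_mid = bin_midpoints(hist.r0, hist.rc, hist.dr)
    shell = 4.0 * np.pi * r_mid**2 * hist.dr          # per-bin volume
    total_vol = (4.0 * np.pi / 3.0) * (hist.rc**3 - hist.r0**3)

    n = counts + pseudocount
    totals = n.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = n / shell[None, None, :]
        rho_bulk = totals / total_vol
        g = rho / rho_bulk[:, :, None]
    g[~included] = 0.0
    g = np.nan_to_num(g, nan=0.0, posinf=0.0)

    g_ref = g[included].mean(axis=0)                   # reference state per bin
    zero_ref = g_ref <= 0
    if np.any(zero_ref):
        logger.warning("reference g(r) is zero in %d bin(s); dW set to +cap",
                       int(zero_ref.sum()))

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = g / g_ref[None, None, :]
    pos = included[:, :, None] & ~zero_ref[None, None, :]
    delta_w = np.where(pos & (ratio > 0), -np.log(np.where(ratio > 0, ratio, 1.0)),
                       np.where(pos, cap, 0.0))
    if np.any(zero_ref):
        delta_w = np.where(included[:, :, None] & zero_ref[None, None, :],
                           cap, delta_w)
    delta_w[~included] = 0.0
    delta_w = np.clip(delta_w, -cap, cap)
    return PotentialTable(
        lig_scheme=hist.lig_scheme, prot_scheme=hist.prot_scheme,
        r0=hist.r0, rc=hist.rc, dr=hist.dr, delta_w=delta_w,
        clash_policy=clash_policy, provenance=provenance,
    )


ManifestLike = Union[str, Path, Sequence[ComplexRecord]]


def _resolve_complexes(manifest: ManifestLike) -> tuple[list[ComplexRecord], str]:
    if isinstance(manifest, (str, Path)):
        path = Path(manifest)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
        return [load_complex(e) for e in read_manifest(path)], f"manifest:{path.name}:{digest}"
    return list(manifest), f"in-memory:{len(list(manifest))} complexes"


def train_distance_potential(manifest: ManifestLike,
                             lig_scheme: str = "ligand_sybyl23",
                             prot_scheme: str = "protein_residue100",
                             weighted: bool = False,
                             *, pseudocount: float = 0.0,
                             min_pair_total: float = 1.0,
                             cap: float = CAP_DEFAULT,
                             r0: float = R0_DEFAULT, rc: float = RC_DEFAULT,
                             dr: float = DR_DEFAULT,
                             ) -> tuple[PotentialTable, ContactHistogram]:
    """Train a distance-dependent potential from a manifest or complex list.

    In weighted mode every complex must carry an affinity; A_mean is the
    manifest mean and each complex contributes with weight
    exp((A - A_mean)/A_mean).
    """
    complexes, source = _resolve_complexes(manifest)
    if not complexes:
        raise ValueError("empty manifest")
    affinity_mean = None
    if weighted:
        affs = [c.affinity for c in complexes]
        if any(a is None for a in affs):
            missing = [c.complex_id for c in complexes if c.affinity is None]
            raise ValueError(f"weighted training requires affinities; missing for {missing}")
        affinity_mean = float(np.mean([float(a) for a in affs]))
    hist = ContactHistogram(lig_scheme=lig_scheme, prot_scheme=prot_scheme,
                            r0=r0, rc=rc, dr=dr, weighted=weighted,
                            affinity_mean=affinity_mean)
    for c in complexes:
        w = affinity_weight(float(c.affinity), affinity_mean) if weighted else 1.0
        accumulate_contacts(c, w, hist)
    provenance = (f"{source}; weighted={weighted}; A_mean={affinity_mean}; "
                  f"alpha={pseudocount}; M={min_pair_total}; cap={cap}")
    table = derive_potential(hist, pseudocount=pseudocount,
                             min_pair_total=min_pair_total, cap=cap,
                             provenance=provenance)
    return table, hist


# ---------------------------------------------------------------------------
# Orientation-dependent atom-residue potential
# ---------------------------------------------------------------------------

def build_local_frame(a1: np.ndarray, a2: np.ndarray, a3: np.ndarray,
                      tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed orthonormal frame from three non-collinear points.

    Origin at a1; x along a1->a2; z normal to the (a1, a2, a3) plane;
    y completes the right-handed triad. Returns (origin, axes) with
    axes rows (x, y, z).
    """
    a1, a2, a3 = (np.asarray(p, float) for p in (a1, a2, a3))
    v1 = a2 - a1
    n1 = np.linalg.norm(v1)
    if n1 < tol:
        raise ValueError("degenerate frame: coincident anchor atoms")
    x = v1 / n1
    z_raw = np.cross(x, a3 - a1)
    nz = np.linalg.norm(z_raw)
    if nz < tol:
        raise ValueError("degenerate frame: collinear anchor atoms")
    z = z_raw / nz
    y = np.cross(z, x)
    return a1, np.vstack([x, y, z])


# Residues whose side chains have >= 3 heavy atoms get a CB-first frame.
_SC_FRAME_RESIDUES = tuple(
    res for res, atoms in sorted(atomtypes.load_residue_topology().items())
    if len(atoms) >= 3)

FRAME_LABELS: tuple[str, ...] = tuple(
    [f"{res}:bb" for res in atomtypes.STANDARD_RESIDUES]
    + [f"{res}:sc" for res in _SC_FRAME_RESIDUES])


def residue_frames(receptor: Structure) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Enumerate local frames: backbone (N, CA, C) per standard residue,
    plus a side-chain frame from the first three side-chain heavy atoms
    where the residue has them. Degenerate frames are skipped."""
    topo = atomtypes.load_residue_topology()
    by_res: dict[tuple, dict[str, np.ndarray]] = {}
    res_names: dict[tuple, str] = {}
    for a in receptor.atoms:
        key = (a.chain_id, a.residue_seq, a.icode)
        by_res.setdefault(key, {})[a.atom_name] = a.position
        res_names[key] = a.residue_name
    frames = []
    for key in by_res:
        res = res_names[key]
        if res not in atomtypes.STANDARD_RESIDUES:
            continue
        atoms = by_res[key]
        if all(n in atoms for n in ("N", "CA", "C")):
            try:
                origin, axes = build_local_frame(atoms["N"], atoms["CA"], atoms["C"])
                frames.append((f"{res}:bb", origin, axes))
            except ValueError:
                logger.warning("degenerate backbone frame for %s %s", res, key)
        sc = topo.get(res, [])
        if len(sc) >= 3 and all(n in atoms for n in sc[:3]):
            try:
                origin, axes = build_local_frame(
                    atoms[sc[0]], atoms[sc[1]], atoms[sc[2]])
                frames.append((f"{res}:sc", origin, axes))
            except ValueError:
                logger.warning("degenerate side-chain frame for %s %s", res, key)
    return frames


@dataclass
class OrientationHistogram:
    """Counts over (ligand label, frame label, r bin, cos-theta bin, phi bin)."""

    lig_scheme: str = "ligand_sybyl23"
    frame_labels: tuple[str, ...] = FRAME_LABELS
    r0: float = R0_DEFAULT
    rc: float = RC_DEFAULT
    dr: float = DR_ORIENT_DEFAULT
    n_cos: int = N_COS_DEFAULT
    n_phi: int = N_PHI_DEFAULT
    counts: np.ndarray = None  # type: ignore[assignment]
    weighted: bool = False
    n_complexes: int = 0
    affinity_mean: Optional[float] = None

    def __post_init__(self) -> None:
        nl = len(atomtypes.enumerate_types(self.lig_scheme))
        nf = len(self.frame_labels)
        nr = _n_bins(self.r0, self.rc, self.dr)
        shape = (nl, nf, nr, self.n_cos, self.n_phi)
        if self.counts is None:
            self.counts = np.zeros(shape, dtype=float)
        else:
            self.counts = np.asarray(self.counts, dtype=float)
            if self.counts.shape != shape:
                raise ValueError(f"counts shape {self.counts.shape} != {shape}")

    @property
    def n_r_bins(self) -> int:
        return self.counts.shape[2]


@dataclass
class OrientationTable:
    """Orientation-dependent potential grid, k_B T units, lower better."""

    lig_scheme: str
    frame_labels: tuple[str, ...]
    r0: float
    rc: float
    dr: float
    n_cos: int
    n_phi: int
    delta_w: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.delta_w = np.asarray(self.delta_w, dtype=float)
        if not np.all(np.isfinite(self.delta_w)):
            raise ValueError("delta_w must be finite everywhere")

    @property
    def n_r_bins(self) -> int:
        return self.delta_w.shape[2]


def _spherical_bins(local: np.ndarray, hist: OrientationHistogram
                    ) -> Optional[tuple[int, int, int]]:
    r = float(np.linalg.norm(local))
    if not (hist.r0 <= r < hist.rc):
        return None
    rb = min(int(radial_bin_of(np.array([r]), hist.r0, hist.rc, hist.dr)[0]),
             hist.n_r_bins - 1)
    cos_t = float(np.clip(local[2] / r, -1.0, 1.0))
    cb = min(int((cos_t + 1.0) / (2.0 / hist.n_cos)), hist.n_cos - 1)
    phi = math.atan2(local[1], local[0])  # atan2(0, 0) = 0: poles land in bin of phi=0
    pb = min(int((phi + math.pi) / (2.0 * math.pi / hist.n_phi)), hist.n_phi - 1)
    return rb, cb, pb


def accumulate_orientation(complex_: ComplexRecord, weight: float,
                           hist: OrientationHistogram) -> int:
    """Bin each in-range ligand atom in every residue frame's spherical
    coordinates; returns the number of increments made."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    lig_scheme = atomtypes.get_scheme(hist.lig_scheme)
    lig_idx = [lig_scheme.index_of(atomtypes.ligand_type_of(a, complex_.ligand))
               for a in complex_.ligand.atoms]
    frame_index = {lbl: i for i, lbl in enumerate(hist.frame_labels)}
    lig_xyz = complex_.ligand.coords
    tree = cKDTree(lig_xyz)
    n_increments = 0
    for label, origin, axes in residue_frames(complex_.receptor):
        fi = frame_index.get(label)
        if fi is None:
            continue
        for li in tree.query_ball_point(origin, hist.rc):
            local = axes @ (lig_xyz[li] - origin)
            binned = _spherical_bins(local, hist)
            if binned is None:
                continue
            rb, cb, pb = binned
            hist.counts[lig_idx[li], fi, rb, cb, pb] += weight
            n_increments += 1
    hist.n_complexes += 1
    return n_increments


def derive_orientation_potential(hist: OrientationHistogram, *,
                                 pseudocount: float = 0.0,
                                 min_pair_total: float = 1.0,
                                 cap: float = CAP_DEFAULT,
                                 provenance: str = "") -> OrientationTable:
    """Inverse-Boltzmann derivation with the 3D volume element
    r^2 dr dcos(theta) dphi; reference is the per-cell mean over
    included (ligand label, frame label) pairs."""
    if not np.any(hist.counts > 0):
        raise ValueError("empty orientation histogram")
    counts = hist.counts
    raw_totals = counts.sum(axis=(2, 3, 4))
    included = raw_totals >= max(min_pair_total, np.finfo(float).tiny)
    if not np.any(included):
        raise ValueError("all pairs below min_pair_total")

    r_mid = bin_midpoints(hist.r0, hist.rc, hist.dr)
    d_cos = 2.0 / hist.n_cos
    d_phi = 2.0 * math.pi / hist.n_phi
    cell_vol = (r_mid**2 * hist.dr * d_cos * d_phi)[:, None, None]  # (nr,1,1)
    total_vol = ((hist.rc**3 - hist.r0**3) / 3.0) * 2.0 * 2.0 * math.pi

    n = counts + pseudocount
    totals = n.sum(axis=(2, 3, 4))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = n / cell_vol[None, None, ...]
        g = rho / (totals / total_vol)[:, :, None, None, None]
    g[~included] = 0.0
    g = np.nan_to_num(g, nan=0.0, posinf=0.0)

    g_ref = g[included].mean(axis=0)
    zero_ref = g_ref <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = g / g_ref[None, None, ...]
    pos = included[:, :, None, None, None] & ~zero_ref[None, None, ...]
    delta_w = np.where(pos & (ratio > 0), -np.log(np.where(ratio > 0, ratio, 1.0)),
                       np.where(pos, cap, 0.0))
    if np.any(zero_ref):
        mask = included[:, :, None, None, None] & zero_ref[None, None, ...]
        delta_w = np.where(mask, cap, delta_w)
    delta_w[~included] = 0.0
    delta_w = np.clip(delta_w, -cap, cap)
    return OrientationTable(
        lig_scheme=hist.lig_scheme, frame_labels=hist.frame_labels,
        r0=hist.r0, rc=hist.rc, dr=hist.dr, n_cos=hist.n_cos, n_phi=hist.n_phi,
        delta_w=delta_w, provenance=provenance,
    )


def train_orientation_potential(manifest: ManifestLike, weighted: bool = False,
                                *, pseudocount: float = 0.0,
                                min_pair_total: float = 1.0,
                                cap: float = CAP_DEFAULT) -> OrientationTable:
    complexes, source = _resolve_complexes(manifest)
    if not complexes:
        raise ValueError("empty manifest")
    affinity_mean = None
    if weighted:
        if any(c.affinity is None for c in complexes):
            raise ValueError("weighted training requires affinities for all complexes")
        affinity_mean = float(np.mean([float(c.affinity) for c in complexes]))
    hist = OrientationHistogram(weighted=weighted, affinity_mean=affinity_mean)
    for c in complexes:
        w = affinity_weight(float(c.affinity), affinity_mean) if weighted else 1.0
        accumulate_orientation(c, w, hist)
    return derive_orientation_potential(
        hist, pseudocount=pseudocount, min_pair_total=min_pair_total, cap=cap,
        provenance=f"{source}; weighted={weighted}; A_mean={affinity_mean}")


# ---------------------------------------------------------------------------
# Table serialization (tab-separated, '#' key=value header, absent rows = 0)
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_table(table: Union[PotentialTable, OrientationTable],
                path: str | Path) -> None:
    """Write a potential table; zero entries are omitted. Deterministic:
    identical tables serialize to identical bytes."""
    path = Path(path)
    lines: list[str] = []
    if isinstance(table, PotentialTable):
        lines.append("# kind=distance")
        lines.append(f"# lig_scheme={table.lig_scheme}")
        lines.append(f"# prot_scheme={table.prot_scheme}")
        for key in ("r0", "rc", "dr"):
            lines.append(f"# {key}={_fmt(getattr(table, key))}")
        cp_kind, cp_val = table.clash_policy
        lines.append(f"# clash_policy={cp_kind}"
                     + (f":{_fmt(cp_val)}" if cp_val is not None else ""))
        lines.append(f"# provenance={table.provenance}")
        lines.append("ligand_label\tprotein_label\tbin\tr_mid\tdelta_w")
        r_mid = bin_midpoints(table.r0, table.rc, table.dr)
        ligs, prots = table.lig_labels, table.prot_labels
        for i, j, k in zip(*np.nonzero(table.delta_w)):
            lines.append(f"{ligs[i]}\t{prots[j]}\t{k}\t{_fmt(r_mid[k])}\t"
                         f"{_fmt(table.delta_w[i, j, k])}")
    else:
        lines.append("# kind=orientation")
        lines.append(f"# lig_scheme={table.lig_scheme}")
        lines.append(f"# frame_labels={','.join(table.frame_labels)}")
        for key in ("r0", "rc", "dr"):
            lines.append(f"# {key}={_fmt(getattr(table, key))}")
        lines.append(f"# n_cos={table.n_cos}")
        lines.append(f"# n_phi={table.n_phi}")
        lines.append(f"# provenance={table.provenance}")
        lines.append("ligand_label\tframe_label\tr_bin\tcos_bin\tphi_bin\tr_mid\tdelta_w")
        r_mid = bin_midpoints(table.r0, table.rc, table.dr)
        ligs = atomtypes.enumerate_types(table.lig_scheme)
        for i, f, rb, cb, pb in zip(*np.nonzero(table.delta_w)):
            lines.append(
                f"{ligs[i]}\t{table.frame_labels[f]}\t{rb}\t{cb}\t{pb}\t"
                f"{_fmt(r_mid[rb])}\t{_fmt(table.delta_w[i, f, rb, cb, pb])}")
    path.write_text("\n".join(lines) + "\n")


def read_table(path: str | Path) -> Union[PotentialTable, OrientationTable]:
    """Read a serialized potential table (distance or orientation)."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val
        elif line.strip():
            rows.append(line.split("\t"))
    if not rows:
        raise ValueError(f"{path}: no table body")
    rows = rows[1:]  # drop column header
    kind = meta.get("kind", "distance")
    r0, rc, dr = (float(meta[k]) for k in ("r0", "rc", "dr"))
    if kind == "distance":
        lig_scheme = meta["lig_scheme"]
        prot_scheme = meta["prot_scheme"]
        ligs = atomtypes.enumerate_types(lig_scheme)
        prots = atomtypes.enumerate_types(prot_scheme)
        li = {l: i for i, l in enumerate(ligs)}
        pj = {p: j for j, p in enumerate(prots)}
        delta_w = np.zeros((len(ligs), len(prots), _n_bins(r0, rc, dr)))
        for row in rows:
            delta_w[li[row[0]], pj[row[1]], int(row[2])] = float(row[4])
        cp = meta.get("clash_policy", "first_bin")
        if ":" in cp:
            cp_kind, cp_val = cp.split(":")
            clash_policy: tuple[str, Optional[float]] = (cp_kind, float(cp_val))
        else:
            clash_policy = (cp, None)
        return PotentialTable(lig_scheme=lig_scheme, prot_scheme=prot_scheme,
                              r0=r0, rc=rc, dr=dr, delta_w=delta_w,
                              clash_policy=clash_policy,
                              provenance=meta.get("provenance", ""))
    frame_labels = tuple(meta["frame_labels"].split(","))
    lig_scheme = meta["lig_scheme"]
    ligs = atomtypes.enumerate_types(lig_scheme)
    li = {l: i for i, l in enumerate(ligs)}
    fi = {f: i for i, f in enumerate(frame_labels)}
    n_cos, n_phi = int(meta["n_cos"]), int(meta["n_phi"])
    delta_w = np.zeros((len(ligs), len(frame_labels), _n_bins(r0, rc, dr),
                        n_cos, n_phi))
    for row in rows:
        delta_w[li[row[0]], fi[row[1]], int(row[2]), int(row[3]), int(row[4])] = \
            float(row[6])
    return OrientationTable(lig_scheme=lig_scheme, frame_labels=frame_labels,
                            r0=r0, rc=rc, dr=dr, n_cos=n_cos, n_phi=n_phi,
                            delta_w=delta_w, provenance=meta.get("provenance", ""))
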