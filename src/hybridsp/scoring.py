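"""Score complexes with single potentials or the weighted hybrid model.

The hybrid score is a plain weighted sum of component potentials,

    total = a * atom_residue_weighted + b * atom_atom + c * orientation,

with task-specific presets: dk (docking) = (0.4, 0.5, 0.1),
scr (screening) = (0.6, 0.2, 0.2), bl (balanced) = (0.5, 0.3, 0.2).
Lower scores are better everywhere; components declared higher-better
are negated at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial import cKDTree

from hybridsp import atomtypes
from hybridsp.potentials import (
    OrientationTable,
    PotentialTable,
    _spherical_bins,
    radial_bin_of,
    read_table,
    residue_frames,
)
from hybridsp.structio import ComplexRecord

logger = logging.getLogger(__name__)

#: Hybrid weights (a, b, c) over (atom-residue weighted, atom-atom, orientation).
PRESETS: dict[str, tuple[float, float, float]] = {
    "dk": (0.4, 0.5, 0.1),
    "scr": (0.6, 0.2, 0.2),
    "bl": (0.5, 0.3, 0.2),
}


def score_distance(complex_: ComplexRecord, table: PotentialTable
                   ) -> tuple[float, int]:
    """Sum dW over all in-range ligand-receptor pairs.

    Pairs closer than r0 are clashes, charged per the table's clash
    policy (default: the pair's innermost-bin value). Returns
    (energy in k_B T, clash count).
    """
    lig = atomtypes.get_scheme(table.lig_scheme)
    prot = atomtypes.get_scheme(table.prot_scheme)
    lig_idx = np.array(
        [lig.index_of(atomtypes.ligand_type_of(a, complex_.ligand))
         for a in complex_.ligand.atoms], dtype=int)
    prot_idx = np.array([prot.index_of(prot(a)) for a in complex_.receptor.atoms],
                        dtype=int)
    lig_xyz = complex_.ligand.coords
    rec_xyz = complex_.receptor.coords
    tree = cKDTree(rec_xyz)
    n_bins = table.delta_w.shape[2]
    cp_kind, cp_val = table.clash_policy
    energy = 0.0
    clashes = 0
    for li, rec_ids in enumerate(tree.query_ball_point(lig_xyz, table.rc)):
        if not rec_ids:
            continue
        rec_ids = np.asarray(rec_ids, dtype=int)
        d = np.linalg.norm(rec_xyz[rec_ids] - lig_xyz[li], axis=1)
        clash = d < table.r0
        clashes += int(clash.sum())
        if cp_kind == "constant":
            energy += float(cp_val) * int(clash.sum())
        else:  # first_bin
            energy += float(table.delta_w[lig_idx[li], prot_idx[rec_ids[clash]], 0].sum())
        in_range = (~clash) & (d < table.rc)
        bins = np.clip(
            radial_bin_of(d[in_range], table.r0, table.rc, table.dr),
            0, n_bins - 1)
        energy += float(
            table.delta_w[lig_idx[li], prot_idx[rec_ids[in_range]], bins].sum())
    return energy, clashes


def score_orientation(complex_: ComplexRecord, table: OrientationTable) -> float:
    """Sum orientation dW over every (residue frame, in-range ligand atom)."""
    lig = atomtypes.get_scheme(table.lig_scheme)
    lig_idx = [lig.index_of(atomtypes.ligand_type_of(a, complex_.ligand))
               for a in complex_.ligand.atoms]
    frame_index = {lbl: i for i, lbl in enumerate(table.frame_labels)}
    frames = residue_frames(complex_.receptor)
    if not frames:
        logger.warning("no residue frames constructible; orientation score is 0")
        return 0.0
    lig_xyz = complex_.ligand.coords
    tree = cKDTree(lig_xyz)
    energy = 0.0
    for label, origin, axes in frames:
        fi = frame_index.get(label)
        if fi is None:
            continue
        for li in tree.query_ball_point(origin, table.rc):
            binned = _spherical_bins(axes @ (lig_xyz[li] - origin), table)
            if binned is None:
                continue
            rb, cb, pb = binned
            energy += float(table.delta_w[lig_idx[li], fi, rb, cb, pb])
    return energy


AnyTable = Union[PotentialTable, OrientationTable]


@dataclass
class HybridComponent:
    """One weighted component: an in-memory table or a table file path."""

    table: Union[AnyTable, str, Path]
    weight: float
    label: str = ""
    sense: str = "lower_better"  # or "higher_better": negated at scoring

    def resolve(self) -> AnyTable:
        if isinstance(self.table, (str, Path)):
            path = Path(self.table)
            if not path.exists():
                raise FileNotFoundError(f"component table not found: {path}")
            return read_table(path)
        return self.table


@dataclass
class HybridModel:
    """Ordered weighted components implementing the hybrid summation."""

    components: list[HybridComponent]
    preset_name: str = "custom"

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("hybrid model needs >= 1 component")
        if not all(np.isfinite(c.weight) for c in self.components):
            raise ValueError("weights must be finite")

    @classmethod
    def from_tables(cls, tables: Sequence[AnyTable], preset: str) -> "HybridModel":
        """Build a model from component tables and a named weight preset."""
        weights = PRESETS[preset]
        if len(tables) != len(weights):
            raise ValueError(f"preset {preset} expects {len(weights)} components")
        labels = ("atom_residue_w", "atom_atom", "orientation")
        comps = [HybridComponent(t, w, label=l)
                 for t, w, l in zip(tables, weights, labels)]
        return cls(components=comps, preset_name=preset)


@dataclass
class ScoreResult:
    """Total hybrid score with per-component breakdown (lower is better)."""

    complex_id: str
    total: float
    per_component: dict[str, tuple[float, float]] = field(default_factory=dict)
    clash_count: int = 0


def _score_component(complex_: ComplexRecord, table: AnyTable) -> tuple[float, int]:
    if isinstance(table, PotentialTable):
        return score_distance(complex_, table)
    return score_orientation(complex_, table), 0


def score_hybrid(complex_: ComplexRecord, model: HybridModel) -> ScoreResult:
    """Weighted sum of component scores; total = sum(weight * raw)."""
    total = 0.0
    per_component: dict[str, tuple[float, float]] = {}
    clash_count = 0
    for k, comp in enumerate(model.components):
        table = comp.resolve()
        raw, clashes = _score_component(complex_, table)
        if comp.sense == "higher_better":
            raw = -raw
        weighted = comp.weight * raw
        total += weighted
        label = comp.label or f"component_{k}"
        per_component[label] = (raw, weighted)
        clash_count += clashes
    return ScoreResult(complex_id=complex_.complex_id, total=total,
                       per_component=per_component, clash_count=clash_count)
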