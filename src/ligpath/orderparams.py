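"""Clamshell-closure order parameters (xi1, xi2, xi12) and the glycan-D2
minimum-distance order parameter.

xi1 and xi2 are mass-weighted center-of-mass distances between pairs of
backbone residue groups spanning the clamshell mouth; xi12 = (xi1+xi2)/2 is
the 1-D closure projection. The glycan-D2 order parameter is the minimum
heavy-atom distance between a glycan and the bottom-lobe CA atoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    OrderParameterGroups,
    SelectionError,
    Topology,
    Trajectory,
    pairwise_distances,
    resolve_selection,
)

__all__ = [
    "D2_LOBE_PRESETS",
    "OrderParameterSeries",
    "center_of_mass",
    "xi_pair",
    "xi12",
    "glycan_d2",
    "compute_series",
]

#: Bottom-lobe (D2) residue-range presets, overridable in config.
D2_LOBE_PRESETS = {
    "GluN1": ((537, 544), (663, 754)),
    "GluN2A": ((533, 539), (661, 757)),
}


def center_of_mass(xyz: np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    """Mass-weighted centroid; geometric when masses are omitted."""
    xyz = np.atleast_2d(np.asarray(xyz, dtype=np.float64))
    if masses is None:
        return xyz.mean(axis=0)
    masses = np.asarray(masses, dtype=np.float64)
    return (xyz * masses[:, None]).sum(axis=0) / masses.sum()


def _group_atoms(topology: Topology, resids: tuple[int, ...]) -> list[int]:
    spec = "resid " + " ".join(str(r) for r in resids) + " and backbone and protein"
    ids = resolve_selection(topology, spec)
    return sorted(ids)


def xi_pair(
    frame_xyz: np.ndarray,
    topology: Topology,
    groups: OrderParameterGroups,
    mass_weighted: bool = True,
) -> tuple[float, float]:
    """Compute (xi1, xi2) for one frame from backbone residue groups."""
    out = []
    for resids_a, resids_b in ((groups.xi1_a, groups.xi1_b), (groups.xi2_a, groups.xi2_b)):
        ids_a = _group_atoms(topology, resids_a)
        ids_b = _group_atoms(topology, resids_b)
        if not ids_a or not ids_b:
            raise SelectionError("order-parameter group resolved to no atoms")
        ma = topology.masses(ids_a) if mass_weighted else None
        mb = topology.masses(ids_b) if mass_weighted else None
        ca = center_of_mass(frame_xyz[topology.indices(ids_a)], ma)
        cb = center_of_mass(frame_xyz[topology.indices(ids_b)], mb)
        out.append(float(np.linalg.norm(ca - cb)))
    return out[0], out[1]


def xi12(xi1: float, xi2: float):
    """1-D closure projection: the arithmetic mean of xi1 and xi2."""
    return (np.asarray(xi1) + np.asarray(xi2)) / 2.0


def glycan_d2(glycan_xyz: np.ndarray, d2_ca_xyz: np.ndarray) -> float:
    """Minimum heavy-atom distance between a glycan and D2-lobe CA atoms."""
    glycan_xyz = np.atleast_2d(glycan_xyz)
    d2_ca_xyz = np.atleast_2d(d2_ca_xyz)
    if glycan_xyz.size == 0 or d2_ca_xyz.size == 0:
        raise SelectionError("glycan-D2 order parameter needs non-empty atom sets")
    return float(pairwise_distances(glycan_xyz, d2_ca_xyz).min())


@dataclass
class OrderParameterSeries:
    """Per-frame order-parameter table with CSV export."""

    table: pd.DataFrame  # columns: frame, time_ns, xi1, xi2, xi12, glycan_*...

    def to_csv(self, path, **meta) -> None:
        with open(path, "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
            self.table.to_csv(fh, index=False)


def compute_series(
    traj: Trajectory,
    subunit: str,
    mass_weighted: bool = True,
    d2_resid_ranges: tuple[tuple[int, int], ...] | None = None,
) -> OrderParameterSeries:
    """Compute xi1/xi2/xi12 (and per-glycan D2 distances) for every frame.

    ``subunit`` keys into ``topology.op_groups``; D2-lobe residue ranges
    default to the named preset for the subunit when available.
    """
    top = traj.topology
    if subunit not in top.op_groups:
        raise SelectionError(f"no order-parameter groups for subunit {subunit!r}")
    groups = top.op_groups[subunit]

    if d2_resid_ranges is None and subunit in D2_LOBE_PRESETS:
        d2_resid_ranges = D2_LOBE_PRESETS[subunit]
    d2_idx = None
    if d2_resid_ranges is not None and top.glycan_atoms:
        resid_tokens = " ".join(f"{lo}-{hi}" for lo, hi in d2_resid_ranges)
        try:
            d2_ids = resolve_selection(top, f"resid {resid_tokens} and calpha and protein")
            d2_idx = top.indices(d2_ids)
        except SelectionError:
            d2_idx = None

    glycan_idx = {
        name: top.indices([i for i in ids if top.atom(i).is_heavy])
        for name, ids in top.glycan_atoms.items()
    }

    rows = []
    for f in range(traj.n_frames):
        xyz = traj.coordinates[f]
        x1, x2 = xi_pair(xyz, top, groups, mass_weighted=mass_weighted)
        row = {
            "frame": f,
            "time_ns": float(traj.frame_times[f]),
            "xi1": x1,
            "xi2": x2,
            "xi12": float(xi12(x1, x2)),
        }
        if d2_idx is not None:
            for name, gidx in glycan_idx.items():
                row[f"glycan_d2_{name}"] = glycan_d2(xyz[gidx], xyz[d2_idx])
        rows.append(row)
    return OrderParameterSeries(table=pd.DataFrame(rows))
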