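"""Structure/trajectory I/O and artifact serialization.

Coordinate formats (PDB, DCD, XTC) are delegated to MDAnalysis. The full
Topology — which carries selection metadata no coordinate format can hold
(ligand copies, docking quadruples, lobes, order-parameter groups) — round
trips through a JSON sidecar. Selection overrides are read from YAML.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import yaml

from .core import (
    AtomRecord,
    DockingAtoms,
    OrderParameterGroups,
    Topology,
    Trajectory,
)

__all__ = [
    "topology_to_dict",
    "topology_from_dict",
    "write_topology_json",
    "read_topology_json",
    "write_pdb",
    "write_trajectory",
    "read_trajectory",
    "load_selection_config",
]


def topology_to_dict(top: Topology) -> dict:
    return {
        "atoms": [
            [a.atom_id, a.name, a.element, a.residue_id, a.residue_name, a.chain_id]
            for a in top.atoms
        ],
        "ligand_copies": [list(c) for c in top.ligand_copies],
        "ligand_ref_atom": list(top.ligand_ref_atom),
        "docking_atoms": [list(d.as_tuple()) for d in top.docking_atoms],
        "lobe_D1": {k: sorted(v) for k, v in top.lobe_D1.items()},
        "lobe_D2": {k: sorted(v) for k, v in top.lobe_D2.items()},
        "op_groups": {
            k: {
                "xi1_a": list(g.xi1_a),
                "xi1_b": list(g.xi1_b),
                "xi2_a": list(g.xi2_a),
                "xi2_b": list(g.xi2_b),
            }
            for k, g in top.op_groups.items()
        },
        "glycan_atoms": {k: list(v) for k, v in top.glycan_atoms.items()},
        "box": list(top.box) if top.box is not None else None,
    }


def topology_from_dict(d: dict) -> Topology:
    return Topology(
        atoms=[AtomRecord(*row) for row in d["atoms"]],
        ligand_copies=[list(c) for c in d.get("ligand_copies", [])],
        ligand_ref_atom=list(d.get("ligand_ref_atom", [])),
        docking_atoms=[DockingAtoms(*q) for q in d.get("docking_atoms", [])],
        lobe_D1={k: frozenset(v) for k, v in d.get("lobe_D1", {}).items()},
        lobe_D2={k: frozenset(v) for k, v in d.get("lobe_D2", {}).items()},
        op_groups={
            k: OrderParameterGroups(
                xi1_a=tuple(g["xi1_a"]),
                xi1_b=tuple(g["xi1_b"]),
                xi2_a=tuple(g["xi2_a"]),
                xi2_b=tuple(g["xi2_b"]),
            )
            for k, g in d.get("op_groups", {}).items()
        },
        glycan_atoms={k: list(v) for k, v in d.get("glycan_atoms", {}).items()},
        box=tuple(d["box"]) if d.get("box") else None,
    )


def write_topology_json(top: Topology, path, **meta) -> None:
    payload = topology_to_dict(top)
    if meta:
        payload["_meta"] = meta
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)


def read_topology_json(path) -> Topology:
    with open(path) as fh:
        return topology_from_dict(json.load(fh))


def _mda_universe(top: Topology, coordinates: np.ndarray):
    import MDAnalysis as mda

    n = top.n_atoms
    resids_seq: list[int] = []
    res_index = []
    seen: dict[tuple[str, int], int] = {}
    for a in top.atoms:
        key = (a.chain_id, a.residue_id)
        if key not in seen:
            seen[key] = len(seen)
            resids_seq.append(a.residue_id)
        res_index.append(seen[key])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=n,
            n_residues=len(seen),
            atom_resindex=np.array(res_index),
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in top.atoms])
        u.add_TopologyAttr("elements", [a.element for a in top.atoms])
        u.add_TopologyAttr("resids", np.array(resids_seq))
        resnames = [None] * len(seen)
        segids = [None] * len(seen)
        for a in top.atoms:
            i = seen[(a.chain_id, a.residue_id)]
            resnames[i] = a.residue_name
            segids[i] = a.chain_id
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("chainIDs", [a.chain_id for a in top.atoms])
        u.atoms.positions = np.asarray(coordinates, dtype=np.float32)
        if top.box is not None:
            u.dimensions = [*top.box, 90.0, 90.0, 90.0]
    return u


def write_pdb(top: Topology, coordinates: np.ndarray, path) -> None:
    """Write one frame as PDB (for molecular viewers)."""
    u = _mda_universe(top, coordinates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write trajectory coordinates as DCD (or any MDAnalysis format)."""
    import MDAnalysis as mda

    u = _mda_universe(traj.topology, traj.coordinates[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.topology.n_atoms) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coordinates[f].astype(np.float32)
                w.write(u.atoms)


def read_trajectory(topology_json, traj_path, dt_ns: float | None = None,
                    frame_times=None) -> Trajectory:
    """Load a Trajectory from a topology JSON plus a DCD/XTC file."""
    import MDAnalysis as mda

    top = read_topology_json(topology_json)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = _mda_universe(top, np.zeros((top.n_atoms, 3)))
        u.load_new(str(traj_path))
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory],
                          dtype=np.float64)
    n = coords.shape[0]
    if frame_times is not None:
        times = np.asarray(frame_times, dtype=np.float64)
    else:
        times = (dt_ns if dt_ns else 1.0) * np.arange(n)
    return Trajectory(coordinates=coords, frame_times=times, topology=top)


def load_selection_config(path) -> dict:
    """Read a YAML key-value selection/parameter override file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("selection config must be a mapping")
    return data
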