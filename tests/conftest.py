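import numpy as np
import pytest

from ligpath.chains import detect_chains, split_chain
from ligpath.core import AtomRecord, Topology, Trajectory
from ligpath.synthetic import make_toy_receptor, simulate_binding


@pytest.fixture(scope="session")
def receptor():
    return make_toy_receptor(seed=11, n_residues=36, n_ligand_copies=3)


@pytest.fixture(scope="session")
def guided_sim(receptor):
    return simulate_binding(receptor, n_frames=500, seed=11, mode="guided")


@pytest.fixture(scope="session")
def guided_chains(receptor, guided_sim):
    traj, _ = guided_sim
    return {
        c: detect_chains(traj, c) for c in range(len(receptor.topology.ligand_copies))
    }


@pytest.fixture(scope="session")
def guided_pathways(guided_sim, guided_chains):
    traj, _ = guided_sim
    out = []
    for chains in guided_chains.values():
        for ch in chains:
            out.extend(split_chain(ch, traj))
    return out


def make_point_topology(n_ligand_atoms=1, n_protein_atoms=1):
    """Minimal topology: polar single-atom ligand + polar protein atoms."""
    atoms = [
        AtomRecord(i, "O", "O", 100 + i, "PRT", "A") for i in range(n_protein_atoms)
    ]
    lig_ids = []
    for j in range(n_ligand_atoms):
        aid = n_protein_atoms + j
        name = "CA" if j == 0 else f"O{j}"
        el = "O"
        atoms.append(AtomRecord(aid, name, el, 900, "LIG", "L"))
        lig_ids.append(aid)
    return Topology(
        atoms=atoms,
        ligand_copies=[lig_ids],
        ligand_ref_atom=[lig_ids[0]],
        box=(100.0, 100.0, 100.0),
    )


@pytest.fixture
def point_topology():
    return make_point_topology()


def trajectory_from_ligand_distances(distances, dt=1.0):
    """Trajectory where a 1-atom ligand sits `d` A from a protein atom at
    the origin, one frame per entry."""
    top = make_point_topology()
    n = len(distances)
    coords = np.zeros((n, 2, 3))
    for f, d in enumerate(distances):
        coords[f, 1] = [d, 0.0, 0.0]
    return Trajectory(
        coordinates=coords, frame_times=dt * np.arange(n), topology=top
    )
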