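"""Synthetic-data generators with known ground truth.

Every stage of the toolkit can be exercised without external downloads:

* :func:`make_toy_receptor` builds a two-lobed point-cloud "protein" with a
  docking-arginine mimic (NH1/NH2 sites), polar/apolar atom flags, an
  optional glycan chain, and serine-like ligand copies in an orthorhombic
  box.
* :func:`simulate_binding` emits a trajectory in which ligand copies
  perform reflected random walks in bulk and scripted association /
  docking / dissociation episodes whose frame indices are recorded in a
  :class:`GroundTruthLog`. The script is constructed so the 6 A / 10 A /
  4 A detection criteria flip exactly at the planned frames, and the
  generator re-verifies this against the emitted coordinates before
  returning.
* :func:`sample_umbrella` draws exact Boltzmann samples from an analytic
  2-D potential plus harmonic umbrella biases (direct Gaussian where the
  total potential is quadratic, rejection sampling otherwise).
* :func:`simulate_association_events` is a lightweight memoryless
  association-event generator for kinetics parameter-recovery tests.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import (
    AtomRecord,
    DockingAtoms,
    OrderParameterGroups,
    Topology,
    Trajectory,
    pairwise_distances,
)
from .free_energy import KB_KCAL, UmbrellaWindow
from .kinetics import BindingEventRecord, KineticsInput

__all__ = [
    "GenerationError",
    "ToyReceptor",
    "PlantedEvent",
    "GroundTruthLog",
    "make_toy_receptor",
    "simulate_binding",
    "sample_umbrella",
    "simulate_association_events",
    "harmonic_2d",
    "double_well_x",
]


class GenerationError(RuntimeError):
    """Raised when a generator produces geometry violating its contract."""


# serine-like rigid ligand template (A, relative to CA); OT1-OT2 = 2.2 A to
# match the NH1-NH2 spacing of the docking mimic so the docked pose is exact
_LIG_ATOMS = ("N", "CA", "CB", "OG", "OT1", "OT2")
_LIG_ELEMENTS = ("N", "C", "C", "O", "O", "O")
_LIG_OFFSETS = np.array(
    [
        [1.45, 0.0, 0.0],  # N
        [0.00, 0.0, 0.0],  # CA
        [-0.75, 1.30, 0.0],  # CB
        [-0.20, 2.50, 0.6],  # OG
        [1.10, -1.00, 0.0],  # OT1
        [-1.10, -1.00, 0.0],  # OT2
    ]
)
_NH_SEP = 2.2  # NH1-NH2 spacing of the docking mimic


@dataclass
class ToyReceptor:
    topology: Topology
    coordinates: np.ndarray  # (n_atoms, 3) reference structure
    center: np.ndarray
    radius: float  # hull radius of the protein point cloud
    rails: list[list[int]]  # residue-id rails, one per pathway template
    docking_residue: int


@dataclass
class PlantedEvent:
    """One scripted association episode in the ground-truth log."""

    ligand_copy: int
    start: int  # first associated frame
    end: int  # last associated frame
    terminated: bool
    dock_start: int | None = None
    dock_end: int | None = None
    template_id: int | None = None
    mechanism: str = "guided"

    @property
    def docked(self) -> bool:
        return self.dock_start is not None


@dataclass
class GroundTruthLog:
    """Event record of a synthetic binding simulation.

    ``events[c]`` lists the planted episodes of ligand copy ``c`` in frame
    order; intervals are non-overlapping per copy by construction.
    """

    events: dict[int, list[PlantedEvent]]
    n_frames: int
    dt_ns: float
    mode: str
    planted_rate_per_ns: float
    seed: int

    def association_intervals(self, copy: int) -> list[tuple[int, int, bool]]:
        return [(e.start, e.end, e.terminated) for e in self.events.get(copy, [])]

    def docking_intervals(self, copy: int) -> list[tuple[int, int]]:
        return [
            (e.dock_start, e.dock_end)
            for e in self.events.get(copy, [])
            if e.docked
        ]

    def docked_frames(self, copy: int) -> frozenset[int]:
        out: set[int] = set()
        for s, e in self.docking_intervals(copy):
            out.update(range(s, e + 1))
        return frozenset(out)

    def to_json(self, path) -> None:
        payload = {
            "n_frames": self.n_frames,
            "dt_ns": self.dt_ns,
            "mode": self.mode,
            "planted_rate_per_ns": self.planted_rate_per_ns,
            "seed": self.seed,
            "events": {
                str(c): [asdict(e) for e in evs] for c, evs in sorted(self.events.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruthLog":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            events={
                int(c): [PlantedEvent(**e) for e in evs]
                for c, evs in d["events"].items()
            },
            n_frames=d["n_frames"],
            dt_ns=d["dt_ns"],
            mode=d["mode"],
            planted_rate_per_ns=d["planted_rate_per_ns"],
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# receptor
# ---------------------------------------------------------------------------

def make_toy_receptor(
    seed: int = 0,
    n_residues: int = 40,
    lobe_radius: float = 10.0,
    lobe_offset: float = 6.0,
    n_ligand_copies: int = 3,
    with_glycan: bool = True,
    box: tuple[float, float, float] = (140.0, 110.0, 110.0),
    n_templates: int = 2,
) -> ToyReceptor:
    """Deterministic two-lobed point-cloud receptor with a docking site.

    Residues are scattered on two spherical shells (the D1 lobe above, the
    D2 lobe below); each residue carries backbone N/CA/C atoms and every
    third residue a polar sidechain oxygen. A docking residue protrudes on
    the +x axis bearing NH1/NH2 nitrogen sites spaced to accept the ligand
    carboxyl exactly. Pathway-template "rails" are residue sequences in
    distinct angular sectors used by guided-mode simulation.
    """
    if n_residues < 10:
        raise GenerationError("need at least 10 residues")
    rng = np.random.default_rng(seed)
    box = tuple(float(b) for b in box)
    center = np.array(box) / 2.0
    if min(box) < 2 * (lobe_radius + lobe_offset) + 40:
        raise GenerationError("box too small for the receptor plus bulk margin")

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    aid = 0

    def add_atom(name, element, resid, resname, chain, pos):
        nonlocal aid
        atoms.append(AtomRecord(aid, name, element, resid, resname, chain))
        coords.append(np.asarray(pos, dtype=np.float64))
        aid += 1
        return aid - 1

    n_d1 = n_residues // 2
    n_d2 = n_residues - n_d1
    d1_ids, d2_ids = [], []
    residue_base: dict[int, np.ndarray] = {}

    def place_lobe(n, z_sign, id_start, id_list):
        # quasi-uniform shell points, biased to the outer hemisphere
        for i in range(n):
            u = rng.uniform(-0.3, 1.0) * z_sign
            phi = rng.uniform(0, 2 * np.pi)
            s = np.sqrt(max(1 - u * u, 0.0))
            base = center + np.array([0, 0, z_sign * lobe_offset]) + lobe_radius * np.array(
                [s * np.cos(phi), s * np.sin(phi), u]
            )
            resid = id_start + i
            id_list.append(resid)
            residue_base[resid] = base
            add_atom("N", "N", resid, "GLY", "A", base + [-1.2, 0, 0])
            add_atom("CA", "C", resid, "GLY", "A", base)
            add_atom("C", "C", resid, "GLY", "A", base + [1.2, 0, 0])
            if i % 3 == 0:
                add_atom("OG", "O", resid, "GLY", "A", base + [0, 0.9, 0.9])

    place_lobe(n_d1, +1, 401, d1_ids)
    place_lobe(n_d2, -1, 601, d2_ids)

    # docking residue on the +x axis, protruding from the hull
    dock_resid = 500
    dock_base = center + np.array([lobe_radius + lobe_offset + 2.0, 0.0, 0.0])
    residue_base[dock_resid] = dock_base
    add_atom("N", "N", dock_resid, "ARG", "A", dock_base + [-1.2, 0, 0])
    add_atom("CA", "C", dock_resid, "ARG", "A", dock_base)
    add_atom("C", "C", dock_resid, "ARG", "A", dock_base + [1.2, 0, 0])
    nh1 = add_atom("NH1", "N", dock_resid, "ARG", "A", dock_base + [1.8, +_NH_SEP / 2, 0])
    nh2 = add_atom("NH2", "N", dock_resid, "ARG", "A", dock_base + [1.8, -_NH_SEP / 2, 0])

    glycans: dict[str, list[int]] = {}
    if with_glycan:
        anchor = residue_base[d1_ids[0]]
        out = (anchor - center) / np.linalg.norm(anchor - center)
        gids = []
        for g in range(5):
            el = "O" if g % 2 else "C"
            gids.append(
                add_atom(f"G{g+1}", el, 801, "MAN", "G", anchor + out * (2.0 + 1.5 * g))
            )
        glycans["G801"] = gids

    # order-parameter groups: one D1/D2 residue pair per order parameter
    op = OrderParameterGroups(
        xi1_a=(d1_ids[0], d1_ids[1]),
        xi1_b=(d2_ids[0], d2_ids[1]),
        xi2_a=(d1_ids[2], d1_ids[3]),
        xi2_b=(d2_ids[2], d2_ids[3]),
    )

    # rails: candidate residues far enough from the docking NH sites that a
    # ligand tracking them can never satisfy the docking criterion
    nh_mid = dock_base + np.array([1.8, 0, 0])
    candidates = [
        r
        for r in d1_ids + d2_ids
        if np.linalg.norm(residue_base[r] - nh_mid) >= 13.0
    ]
    if len(candidates) < 2 * n_templates:
        raise GenerationError("too few residues for pathway rails; increase n_residues")
    az = {r: np.arctan2(*(residue_base[r] - center)[[1, 0]]) for r in candidates}
    rails: list[list[int]] = []
    for t in range(n_templates):
        lo = -np.pi + 2 * np.pi * t / n_templates
        hi = -np.pi + 2 * np.pi * (t + 1) / n_templates
        sector = [r for r in candidates if lo <= az[r] < hi]
        sector.sort(key=lambda r: -np.linalg.norm(residue_base[r] - nh_mid))
        rails.append(sector[:6])
    if any(len(r) < 3 for r in rails):
        raise GenerationError("degenerate rail geometry; increase n_residues")

    # ligand copies, parked in far bulk corners initially
    ligand_copies: list[list[int]] = []
    ref_atoms: list[int] = []
    docking: list[DockingAtoms] = []
    for c in range(n_ligand_copies):
        start = center + np.array(
            [
                (-1) ** c * (box[0] / 2 - 18.0),
                (-1) ** (c // 2) * (box[1] / 2 - 18.0),
                (c % 3 - 1) * (box[2] / 2 - 18.0) * 0.5,
            ]
        )
        ids = []
        for name, el, off in zip(_LIG_ATOMS, _LIG_ELEMENTS, _LIG_OFFSETS):
            ids.append(add_atom(name, el, 900 + c, "SER", "L", start + off))
        ligand_copies.append(ids)
        ref_atoms.append(ids[_LIG_ATOMS.index("CA")])
        docking.append(
            DockingAtoms(
                nh1=nh1, nh2=nh2, ot1=ids[_LIG_ATOMS.index("OT1")], ot2=ids[_LIG_ATOMS.index("OT2")]
            )
        )

    topology = Topology(
        atoms=atoms,
        ligand_copies=ligand_copies,
        ligand_ref_atom=ref_atoms,
        docking_atoms=docking,
        lobe_D1={"A": frozenset(d1_ids)},
        lobe_D2={"A": frozenset(d2_ids)},
        op_groups={"A": op},
        glycan_atoms=glycans,
        box=box,
    )
    coords = np.array(coords)
    prot_idx = topology.indices(topology.protein_atom_ids)
    radius = float(np.linalg.norm(coords[prot_idx] - center, axis=1).max())
    return ToyReceptor(
        topology=topology,
        coordinates=coords,
        center=center,
        radius=radius,
        rails=rails,
        docking_residue=dock_resid,
    )


# ---------------------------------------------------------------------------
# binding simulation
# ---------------------------------------------------------------------------

def _rail_point(receptor: ToyReceptor, coords: np.ndarray, resid: int, target: float) -> np.ndarray:
    """CA position on the outward radial of ``resid`` such that the minimum
    ligand-polar to residue-polar distance equals ``target`` A."""
    top = receptor.topology
    res_polar = [
        a.atom_id
        for a in top.atoms
        if a.residue_id == resid and a.is_polar and a.atom_id not in top.ligand_atom_ids
    ]
    p = coords[top.atom_index(res_polar[0])]
    u = p - receptor.center
    u = u / np.linalg.norm(u)
    polar_offsets = _LIG_OFFSETS[[0, 3, 4, 5]]  # N, OG, OT1, OT2

    def min_dist(r):
        return np.linalg.norm(u * r + polar_offsets, axis=1).min()

    lo, hi = 0.0, 30.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < target:
            lo = mid
        else:
            hi = mid
    return p + u * (0.5 * (lo + hi))


def _free_approach_point(receptor: ToyReceptor, coords: np.ndarray) -> np.ndarray:
    """CA position on the +x axis outside the docking site such that the
    minimum ligand-polar to docking-residue-polar distance is 5.0 A.

    Because the MINIMUM polar pair distance is 5.0, no NH-OT pair can be
    within 4 A, so the docking criterion is guaranteed false here while the
    6 A association criterion holds; the only contacted residue is the
    docking residue itself (free-diffusion signature).
    """
    top = receptor.topology
    targets = np.array(
        [
            coords[top.atom_index(a.atom_id)]
            for a in top.atoms
            if a.residue_id == receptor.docking_residue and a.is_polar
        ]
    )
    u = np.array([1.0, 0.0, 0.0])
    anchor = targets.mean(axis=0)
    polar_offsets = _LIG_OFFSETS[[0, 3, 4, 5]]

    def min_dist(r):
        pts = anchor + u * r + polar_offsets
        return pairwise_distances(pts, targets).min()

    lo, hi = 0.0, 30.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < 5.0:
            lo = mid
        else:
            hi = mid
    return anchor + u * (0.5 * (lo + hi))


def _docked_pose(receptor: ToyReceptor, coords: np.ndarray, copy: int) -> np.ndarray:
    """Rigid placement with OT1 2.8 A outside NH1 and OT2 2.8 A outside NH2."""
    top = receptor.topology
    dk = top.docking_atoms[copy]
    nh1 = coords[top.atom_index(dk.nh1)]
    nh2 = coords[top.atom_index(dk.nh2)]
    out = np.array([1.0, 0.0, 0.0])
    t1 = nh1 + out * 2.8
    t2 = nh2 + out * 2.8
    # local frame: OT1->OT2 axis and the CA direction off the carboxyl midpoint
    l1, l2 = _LIG_OFFSETS[4], _LIG_OFFSETS[5]
    m_local = 0.5 * (l1 + l2)
    e1l = (l2 - l1) / np.linalg.norm(l2 - l1)
    e2l = np.array([0.0, 1.0, 0.0])  # from carboxyl toward CA/body
    e3l = np.cross(e1l, e2l)
    m_t = 0.5 * (t1 + t2)
    e1t = (t2 - t1) / np.linalg.norm(t2 - t1)
    e2t = out  # body points away from the protein
    e2t = e2t - e1t * (e2t @ e1t)
    e2t = e2t / np.linalg.norm(e2t)
    e3t = np.cross(e1t, e2t)
    R = np.column_stack([e1t, e2t, e3t]) @ np.column_stack([e1l, e2l, e3l]).T
    return (R @ (_LIG_OFFSETS - m_local).T).T + m_t


def _bulk_step(pos, rng, center, keepout, box, margin=6.0, sigma=2.5):
    step = rng.normal(0.0, sigma, 3)
    new = pos + step
    new = np.clip(new, margin, np.asarray(box) - margin)
    d = new - center
    r = np.linalg.norm(d)
    if r < keepout:
        new = center + d / max(r, 1e-9) * keepout
        new = np.clip(new, margin, np.asarray(box) - margin)
    return new


def simulate_binding(
    receptor: ToyReceptor,
    n_frames: int = 600,
    dt: float = 1.0,
    seed: int = 0,
    mode: str = "guided",
    assoc_rate_per_ns: float = 0.02,
    p_dock: float = 0.6,
    p_unbind: float = 0.85,
    mean_dock_frames: int = 8,
    verify: bool = True,
) -> tuple[Trajectory, GroundTruthLog]:
    """Scripted-diffusion binding trajectory with exact ground truth.

    Each ligand copy alternates between a reflected random walk in bulk
    (kept > 10.5 A from every protein heavy atom, so no chain can start or
    survive there) and scripted episodes: guided approaches track a rail of
    surface residues at 5 A (association triggers at the first rail frame),
    may enter the exact docked pose (both carboxyl oxygens 2.8 A from the
    NH sites), and exit via a rail frame back to bulk. Free-mode episodes
    touch a single rail residue before docking. With probability
    ``1 - p_unbind`` a docked copy stays docked to the trajectory end
    (unterminated chain). Waiting times are geometric with per-frame
    probability ``assoc_rate_per_ns * dt`` (memoryless).

    The emitted coordinates are re-checked frame-by-frame against the
    association (6 A), dissociation (10 A) and docking (4 A) criteria; any
    disagreement with the planted log raises :class:`GenerationError`.
    """
    if n_frames <= 0 or dt <= 0:
        raise ValueError("n_frames and dt must be positive")
    if mode not in ("guided", "free"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    top = receptor.topology
    base = receptor.coordinates
    box = np.asarray(top.box)
    n_copies = len(top.ligand_copies)
    if box.prod() < n_copies * 27_000.0:  # ~30 A cube of bulk per copy
        raise GenerationError("box too small for the requested ligand copies")
    keepout = receptor.radius + 14.0
    p_assoc = min(assoc_rate_per_ns * dt, 0.5)

    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    events: dict[int, list[PlantedEvent]] = {c: [] for c in range(n_copies)}

    for c in range(n_copies):
        lig_idx = top.indices(top.ligand_copies[c])
        # sorted(ids) aligns with _LIG_OFFSETS order because atoms were added
        # in template order with increasing ids
        pos = base[lig_idx[_LIG_ATOMS.index("CA")]].copy()
        f = 0
        while f < n_frames:
            # bulk phase
            if rng.uniform() >= p_assoc:
                pos = _bulk_step(pos, rng, receptor.center, keepout, box)
                coords[f, lig_idx] = pos + _LIG_OFFSETS
                f += 1
                continue
            # plan an episode
            if mode == "guided":
                template = int(rng.integers(len(receptor.rails)))
                approach = [
                    _rail_point(receptor, base, resid, 5.0)
                    for resid in receptor.rails[template]
                ]
            else:
                template = None
                approach = [_free_approach_point(receptor, base)]
            docked = rng.uniform() < p_dock
            frames_needed = len(approach) + (1 if docked else 0) + 1
            if f + frames_needed + 2 > n_frames:
                # not enough room to finish cleanly; idle in bulk instead
                pos = _bulk_step(pos, rng, receptor.center, keepout, box)
                coords[f, lig_idx] = pos + _LIG_OFFSETS
                f += 1
                continue

            start = f
            for ca in approach:
                coords[f, lig_idx] = ca + _LIG_OFFSETS
                f += 1
            dock_start = dock_end = None
            if docked:
                n_dock = 1 + rng.geometric(1.0 / max(mean_dock_frames, 1))
                pose = _docked_pose(receptor, base, c)
                dock_start = f
                while f < n_frames and n_dock > 0:
                    coords[f, lig_idx] = pose
                    f += 1
                    n_dock -= 1
                dock_end = f - 1
                if f >= n_frames or rng.uniform() >= p_unbind:
                    # stay docked to the trajectory end: unterminated chain
                    while f < n_frames:
                        coords[f, lig_idx] = pose
                        f += 1
                    events[c].append(
                        PlantedEvent(
                            ligand_copy=c,
                            start=start,
                            end=n_frames - 1,
                            terminated=False,
                            dock_start=dock_start,
                            dock_end=n_frames - 1,
                            template_id=template,
                            mechanism=mode,
                        )
                    )
                    break
                # exit via one approach frame so the last docked frame is
                # not the chain end
                coords[f, lig_idx] = approach[-1] + _LIG_OFFSETS
                f += 1
            end = f - 1
            # a chain only terminates if a beyond-10-A frame actually follows;
            # when the trajectory ends on the exit frame it stays open
            events[c].append(
                PlantedEvent(
                    ligand_copy=c,
                    start=start,
                    end=end,
                    terminated=f < n_frames,
                    dock_start=dock_start,
                    dock_end=dock_end,
                    template_id=template,
                    mechanism=mode,
                )
            )
            # dissociate: jump back to a fresh bulk position
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            pos = receptor.center + u * (keepout + 6.0)
            pos = np.clip(pos, 6.0, box - 6.0)
            if np.linalg.norm(pos - receptor.center) < keepout:
                pos = receptor.center + u * keepout
            if f < n_frames:
                coords[f, lig_idx] = pos + _LIG_OFFSETS
                f += 1

    times = dt * np.arange(n_frames)
    traj = Trajectory(coordinates=coords, frame_times=times, topology=top)
    log = GroundTruthLog(
        events=events,
        n_frames=n_frames,
        dt_ns=dt,
        mode=mode,
        planted_rate_per_ns=assoc_rate_per_ns,
        seed=seed,
    )
    if verify:
        _verify_log(traj, log)
    return traj, log


def _verify_log(traj: Trajectory, log: GroundTruthLog) -> None:
    """Literal frame-by-frame re-check of the planted log against the
    emitted coordinates (independent of the detection module)."""
    top = traj.topology
    prot = sorted(top.protein_atom_ids)
    ipp = top.indices([i for i in prot if top.atom(i).is_polar and top.atom(i).is_heavy])
    iph = top.indices([i for i in prot if top.atom(i).is_heavy])
    for c, lig in enumerate(top.ligand_copies):
        ilp = top.indices([i for i in lig if top.atom(i).is_polar and top.atom(i).is_heavy])
        ilh = top.indices([i for i in lig if top.atom(i).is_heavy])
        dk = top.docking_atoms[c]
        i1, i2, i3, i4 = (top.atom_index(i) for i in dk.as_tuple())
        intervals = []
        docked = set()
        start = None
        for f in range(traj.n_frames):
            xyz = traj.coordinates[f]
            amin = pairwise_distances(xyz[ilp], xyz[ipp]).min()
            dmin = pairwise_distances(xyz[ilh], xyz[iph]).min()
            if start is None:
                if amin <= 6.0:
                    start = f
            elif dmin > 10.0:
                intervals.append((start, f - 1, True))
                start = f if amin <= 6.0 else None
            if start is not None:
                d11 = np.linalg.norm(xyz[i1] - xyz[i3])
                d22 = np.linalg.norm(xyz[i2] - xyz[i4])
                d12 = np.linalg.norm(xyz[i1] - xyz[i4])
                d21 = np.linalg.norm(xyz[i2] - xyz[i3])
                if (d11 <= 4.0 and d22 <= 4.0) or (d12 <= 4.0 and d21 <= 4.0):
                    docked.add(f)
        if start is not None:
            intervals.append((start, traj.n_frames - 1, False))
        if intervals != log.association_intervals(c):
            raise GenerationError(
                f"copy {c}: planted intervals {log.association_intervals(c)} "
                f"!= observed {intervals}"
            )
        if docked != set(log.docked_frames(c)):
            raise GenerationError(
                f"copy {c}: planted docked frames disagree with coordinates"
            )


# ---------------------------------------------------------------------------
# umbrella sampling
# ---------------------------------------------------------------------------

def harmonic_2d(kx: float, ky: float, x0: float = 0.0, y0: float = 0.0):
    """Analytic 2-D harmonic potential 0.5*kx*(x-x0)^2 + 0.5*ky*(y-y0)^2."""

    def U(x, y):
        return 0.5 * kx * (x - x0) ** 2 + 0.5 * ky * (y - y0) ** 2

    U.quadratic = (kx, ky, x0, y0)
    return U


def double_well_x(barrier: float = 2.0, x0: float = 1.0, ky: float = 2.0):
    """2-D double well: ``barrier*((x/x0)^2-1)^2 + 0.5*ky*y^2``.

    Minima at (+-x0, 0) with value 0; saddle at (0, 0) with the planted
    barrier height (kcal/mol).
    """

    def U(x, y):
        return barrier * ((np.asarray(x) / x0) ** 2 - 1.0) ** 2 + 0.5 * ky * np.asarray(y) ** 2

    U.barrier = barrier
    U.minima = ((-x0, 0.0), (x0, 0.0))
    U.saddle = (0.0, 0.0)
    return U


def sample_umbrella(
    potential,
    centers,
    k: float,
    n_per_window: int,
    temperature: float = 300.0,
    seed: int = 0,
    support: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> list[UmbrellaWindow]:
    """Exact Boltzmann samples from ``potential`` + harmonic biases.

    When the total potential is quadratic (``potential`` is None or carries
    a ``quadratic`` tag) samples are drawn directly from the resulting
    Gaussian. Otherwise rejection sampling with a uniform proposal over
    ``support`` is used; the support must cover the distribution (density
    at its edge should be negligible) and an acceptance rate below 1e-4
    raises an error suggesting a narrower support.
    """
    rng = np.random.default_rng(seed)
    kT = KB_KCAL * temperature
    windows: list[UmbrellaWindow] = []
    for w, (cx, cy) in enumerate(centers):
        if potential is None:
            sx = sy = np.sqrt(kT / k)
            samples = np.column_stack(
                [rng.normal(cx, sx, n_per_window), rng.normal(cy, sy, n_per_window)]
            )
        elif hasattr(potential, "quadratic"):
            kx, ky, x0, y0 = potential.quadratic
            ktx, kty = kx + k, ky + k
            mx = (kx * x0 + k * cx) / ktx
            my = (ky * y0 + k * cy) / kty
            samples = np.column_stack(
                [
                    rng.normal(mx, np.sqrt(kT / ktx), n_per_window),
                    rng.normal(my, np.sqrt(kT / kty), n_per_window),
                ]
            )
        else:
            if support is None:
                raise ValueError("rejection sampling needs an explicit support")
            (xlo, xhi), (ylo, yhi) = support
            gx = np.linspace(xlo, xhi, 201)
            gy = np.linspace(ylo, yhi, 201)
            X, Y = np.meshgrid(gx, gy, indexing="ij")
            E = potential(X, Y) + 0.5 * k * ((X - cx) ** 2 + (Y - cy) ** 2)
            log_max = (-E / kT).max()
            out = []
            n_drawn = 0
            n_kept = 0
            while n_kept < n_per_window:
                m = max(4 * (n_per_window - n_kept), 1000)
                xs = rng.uniform(xlo, xhi, m)
                ys = rng.uniform(ylo, yhi, m)
                e = potential(xs, ys) + 0.5 * k * ((xs - cx) ** 2 + (ys - cy) ** 2)
                accept = np.log(rng.uniform(size=m)) < (-e / kT) - log_max
                n_drawn += m
                n_kept += int(accept.sum())
                out.append(np.column_stack([xs[accept], ys[accept]]))
                if n_drawn > 10_000 and n_kept / n_drawn < 1e-4:
                    raise GenerationError(
                        "rejection acceptance below 1e-4; narrow the support"
                    )
            samples = np.vstack(out)[:n_per_window]
        windows.append(
            UmbrellaWindow(
                center=(float(cx), float(cy)),
                k=k,
                samples=samples,
                temperature=temperature,
                window_id=f"w{w}",
            )
        )
    return windows


# ---------------------------------------------------------------------------
# kinetics events
# ---------------------------------------------------------------------------

def simulate_association_events(
    kon: float,
    concentration_M: float,
    sites: int = 1,
    n_events: int = 1000,
    mean_residence_ns: float = 50.0,
    seed: int = 0,
) -> KineticsInput:
    """Memoryless association-event series with a planted kon.

    Bulk waiting times are exponential with per-site rate
    ``kon * concentration * sites`` (per second); residence times are
    exponential with the given mean. The kon estimator applied to the
    returned input recovers the planted value within sampling error.
    """
    rng = np.random.default_rng(seed)
    rate = kon * concentration_M * sites
    waits_s = rng.exponential(1.0 / rate, n_events)
    residence_ns = rng.exponential(mean_residence_ns, n_events)
    events = [
        BindingEventRecord(
            ligand_copy=0, chain_id=i, residence_time_ns=float(residence_ns[i]), success=True
        )
        for i in range(n_events)
    ]
    return KineticsInput(
        events=events,
        bulk_times_s=[float(waits_s.sum())],
        concentrations_M=[concentration_M],
        sites=[sites],
    )
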