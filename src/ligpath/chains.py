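"""Binding-chain detection, docking classification and pathway splitting.

A binding chain is one continuous ligand-protein association episode. It
starts at the first frame where any polar ligand heavy atom comes within
``assoc_cutoff`` (default 6 A) of any polar protein heavy atom and persists
until the ligand diffuses beyond ``dissoc_cutoff`` (default 10 A) from the
protein. The two cutoffs form a hysteresis band: a ligand oscillating
between 6 and 10 A neither starts a new chain nor ends a live one.

Chains containing at least one docked frame (carboxyl engaging the docking
arginine, either orientation) are split into a binding pathway (association
start -> first docked frame) and, when the chain later dissociates, a
time-reversed unbinding pathway (last docked frame -> dissociation).
Chains that never dock are discarded.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .core import (
    AssociationState,
    Topology,
    TopologyError,
    Trajectory,
    pairwise_distances,
)

__all__ = [
    "BindingChain",
    "Pathway",
    "CensusResult",
    "chains_from_profiles",
    "detect_chains",
    "is_docked",
    "split_chain",
    "classify_mechanism",
    "association_census",
    "association_states",
]


@dataclass
class BindingChain:
    """One ligand-protein association episode."""

    ligand_copy: int
    start_frame: int
    end_frame: int
    per_frame_contacts: list[frozenset[int]]
    docked_frames: frozenset[int]
    terminated: bool
    chain_id: int = 0

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError("start_frame must be <= end_frame")
        if len(self.per_frame_contacts) != self.n_frames:
            raise ValueError("per_frame_contacts must cover every chain frame")
        bad = [f for f in self.docked_frames if not self.start_frame <= f <= self.end_frame]
        if bad:
            raise ValueError(f"docked frames outside chain span: {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    @property
    def frames(self) -> range:
        return range(self.start_frame, self.end_frame + 1)

    @property
    def docked(self) -> bool:
        return bool(self.docked_frames)

    def docking_episodes(self) -> list[tuple[int, int]]:
        """Maximal contiguous runs of docked frames as (start, end) pairs."""
        if not self.docked_frames:
            return []
        frames = sorted(self.docked_frames)
        episodes = []
        start = prev = frames[0]
        for f in frames[1:]:
            if f != prev + 1:
                episodes.append((start, prev))
                start = f
            prev = f
        episodes.append((start, prev))
        return episodes

    def contact_residues(self) -> frozenset[int]:
        out: set[int] = set()
        for s in self.per_frame_contacts:
            out |= s
        return frozenset(out)


@dataclass
class Pathway:
    """Ordered ligand reference-point trace from association to docking.

    For ``direction == "unbinding-reversed"`` the stored order is the
    time-reversed dissociation segment so all pathways share one
    directionality.
    """

    chain_id: int
    ligand_copy: int
    direction: str  # "binding" | "unbinding-reversed"
    trace: np.ndarray
    frames: list[int]
    contact_residues: Counter = field(default_factory=Counter)
    mechanism: str | None = None

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=np.float64)
        if self.trace.ndim != 2 or self.trace.shape[1] != 3:
            raise ValueError("trace must have shape (n_points, 3)")
        if len(self.frames) != len(self.trace):
            raise ValueError("trace and frames lengths differ")
        if len(self.frames) < 1:
            raise ValueError("pathway needs at least one frame")
        if self.direction not in ("binding", "unbinding-reversed"):
            raise ValueError(f"bad direction {self.direction!r}")

    @property
    def path_id(self) -> str:
        tag = "b" if self.direction == "binding" else "u"
        return f"c{self.ligand_copy}-ch{self.chain_id}-{tag}"

    def distinct_residues(self) -> frozenset[int]:
        return frozenset(self.contact_residues)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def chains_from_profiles(
    assoc_min: np.ndarray,
    dissoc_min: np.ndarray,
    assoc_cutoff: float = 6.0,
    dissoc_cutoff: float = 10.0,
) -> list[tuple[int, int, bool]]:
    """Hysteresis state machine over per-frame minimum-distance profiles.

    ``assoc_min[f]`` is the minimum polar-ligand to polar-protein heavy-atom
    distance at frame ``f``; ``dissoc_min[f]`` the minimum over all heavy
    atoms. Returns ``(start_frame, end_frame, terminated)`` triples; a chain
    still alive at the final frame has ``terminated=False``.
    """
    if assoc_cutoff >= dissoc_cutoff:
        raise ValueError(
            f"assoc_cutoff ({assoc_cutoff}) must be < dissoc_cutoff ({dissoc_cutoff})"
        )
    assoc_min = np.asarray(assoc_min, dtype=np.float64)
    dissoc_min = np.asarray(dissoc_min, dtype=np.float64)
    if assoc_min.shape != dissoc_min.shape or assoc_min.ndim != 1:
        raise ValueError("profiles must be 1-D arrays of equal length")
    if assoc_min.size == 0:
        raise ValueError("empty trajectory")

    chains: list[tuple[int, int, bool]] = []
    start: int | None = None
    for f in range(assoc_min.size):
        if start is None:
            if assoc_min[f] <= assoc_cutoff:
                start = f
        else:
            if dissoc_min[f] > dissoc_cutoff:
                chains.append((start, f - 1, True))
                start = f if assoc_min[f] <= assoc_cutoff else None
    if start is not None:
        chains.append((start, assoc_min.size - 1, False))
    return chains


def is_docked(
    nh1: np.ndarray,
    nh2: np.ndarray,
    ot1: np.ndarray,
    ot2: np.ndarray,
    dock_cutoff: float = 4.0,
) -> bool:
    """Evaluate the two-orientation arginine-carboxyl docking criterion.

    True iff (NH1-OT1 <= cutoff AND NH2-OT2 <= cutoff) or the swapped
    pairing holds, covering the crystallographic and flipped poses.
    """
    d = lambda a, b: float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))
    cond1 = d(nh1, ot1) <= dock_cutoff and d(nh2, ot2) <= dock_cutoff
    cond2 = d(nh1, ot2) <= dock_cutoff and d(nh2, ot1) <= dock_cutoff
    return cond1 or cond2


def _distance_profiles(traj: Trajectory, copy: int, use_pbc: bool):
    """Per-frame (polar-polar min, all-heavy min) profiles plus index caches."""
    top = traj.topology
    lig_ids = top.ligand_copies[copy]
    lig_polar = [i for i in lig_ids if top.atom(i).is_polar and top.atom(i).is_heavy]
    lig_heavy = [i for i in lig_ids if top.atom(i).is_heavy]
    prot_ids = sorted(top.protein_atom_ids)
    prot_polar = [i for i in prot_ids if top.atom(i).is_polar and top.atom(i).is_heavy]
    prot_heavy = [i for i in prot_ids if top.atom(i).is_heavy]
    if not lig_polar or not prot_polar:
        raise TopologyError("association criterion needs polar heavy atoms on both sides")

    box = top.box if use_pbc else None
    ilp = top.indices(lig_polar)
    ilh = top.indices(lig_heavy)
    ipp = top.indices(prot_polar)
    iph = top.indices(prot_heavy)
    n = traj.n_frames
    assoc = np.empty(n)
    dissoc = np.empty(n)
    for f in range(n):
        xyz = traj.coordinates[f]
        assoc[f] = pairwise_distances(xyz[ilp], xyz[ipp], box=box).min()
        dissoc[f] = pairwise_distances(xyz[ilh], xyz[iph], box=box).min()
    return assoc, dissoc, (ilp, ilh, ipp, iph)


def detect_chains(
    traj: Trajectory,
    copy: int,
    assoc_cutoff: float = 6.0,
    dissoc_cutoff: float = 10.0,
    dock_cutoff: float = 4.0,
    contact_cutoff: float | None = None,
    use_pbc: bool = False,
) -> list[BindingChain]:
    """Detect all binding chains of one ligand copy.

    ``contact_cutoff`` (default: ``assoc_cutoff``) is the polar-polar
    distance under which a protein residue is recorded as contacted for the
    residue-profiling statistics. Docking is evaluated at every chain frame.
    """
    if assoc_cutoff >= dissoc_cutoff:
        raise ValueError(
            f"assoc_cutoff ({assoc_cutoff}) must be < dissoc_cutoff ({dissoc_cutoff})"
        )
    if contact_cutoff is None:
        contact_cutoff = assoc_cutoff
    top = traj.topology
    assoc, dissoc, (ilp, _ilh, ipp, _iph) = _distance_profiles(traj, copy, use_pbc)
    spans = chains_from_profiles(assoc, dissoc, assoc_cutoff, dissoc_cutoff)

    prot_polar_resids = np.array(
        [top.atoms[i].residue_id for i in ipp], dtype=np.int64
    )
    box = top.box if use_pbc else None
    if copy < len(top.docking_atoms):
        dk = top.docking_atoms[copy]
        dock_idx = tuple(top.atom_index(i) for i in dk.as_tuple())
    else:
        dock_idx = None

    chains: list[BindingChain] = []
    for k, (start, end, terminated) in enumerate(spans):
        contacts: list[frozenset[int]] = []
        docked: set[int] = set()
        for f in range(start, end + 1):
            xyz = traj.coordinates[f]
            dmat = pairwise_distances(xyz[ilp], xyz[ipp], box=box)
            near = dmat.min(axis=0) <= contact_cutoff
            contacts.append(frozenset(prot_polar_resids[near].tolist()))
            if dock_idx is not None:
                i1, i2, i3, i4 = dock_idx
                if is_docked(xyz[i1], xyz[i2], xyz[i3], xyz[i4], dock_cutoff):
                    docked.add(f)
        chains.append(
            BindingChain(
                ligand_copy=copy,
                start_frame=start,
                end_frame=end,
                per_frame_contacts=contacts,
                docked_frames=frozenset(docked),
                terminated=terminated,
                chain_id=k,
            )
        )
    return chains


# ---------------------------------------------------------------------------
# splitting and classification
# ---------------------------------------------------------------------------

def _contact_counter(chain: BindingChain, frames) -> Counter:
    c: Counter = Counter()
    for f in frames:
        for r in chain.per_frame_contacts[f - chain.start_frame]:
            c[r] += 1
    return c


def split_chain(chain: BindingChain, traj: Trajectory) -> list[Pathway]:
    """Split a docked chain into binding / unbinding pathways.

    Never-docked chains yield nothing. The binding pathway runs from the
    chain start through the FIRST docked frame. The unbinding pathway runs
    from the LAST docked frame through the chain end, stored time-reversed;
    it is omitted for unterminated chains and when the last docked frame is
    the chain end. Intermediate undock/redock excursions spawn no extra
    pathways.
    """
    if not chain.docked_frames:
        return []
    top = traj.topology
    ref = top.ligand_ref_atom[chain.ligand_copy]
    ref_idx = top.atom_index(ref)
    first_dock = min(chain.docked_frames)
    last_dock = max(chain.docked_frames)

    out: list[Pathway] = []
    b_frames = list(range(chain.start_frame, first_dock + 1))
    out.append(
        Pathway(
            chain_id=chain.chain_id,
            ligand_copy=chain.ligand_copy,
            direction="binding",
            trace=traj.coordinates[b_frames, ref_idx, :],
            frames=b_frames,
            contact_residues=_contact_counter(chain, b_frames),
        )
    )
    if chain.terminated and last_dock < chain.end_frame:
        u_frames = list(range(chain.end_frame, last_dock - 1, -1))
        out.append(
            Pathway(
                chain_id=chain.chain_id,
                ligand_copy=chain.ligand_copy,
                direction="unbinding-reversed",
                trace=traj.coordinates[u_frames, ref_idx, :],
                frames=u_frames,
                contact_residues=_contact_counter(chain, u_frames),
            )
        )
    return out


def classify_mechanism(
    path: Pathway,
    min_distinct_residues: int = 3,
    docking_site_residues: frozenset[int] = frozenset(),
) -> str:
    """Label a pathway ``guided`` or ``free``.

    ``free`` iff the number of distinct surface residues contacted (docking
    site residues excluded) is below ``min_distinct_residues``. The exact
    rule is a configurable stand-in; see the emitted metadata.
    """
    surface = path.distinct_residues() - docking_site_residues
    return "free" if len(surface) < min_distinct_residues else "guided"


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------

@dataclass
class CensusResult:
    """Association/docking counts for one ligand copy (or pooled copies)."""

    n_associations: int
    n_docked: int
    n_docking_episodes: int
    per_residue: dict[int, tuple[int, int]]  # residue -> (associations, successes)
    duration_us: float

    @property
    def success_fraction(self) -> float | None:
        if self.n_associations == 0:
            return None
        return self.n_docked / self.n_associations

    @property
    def associations_per_us(self) -> float:
        return self.n_associations / self.duration_us

    @property
    def docked_per_us(self) -> float:
        return self.n_docked / self.duration_us

    def residue_success_probability(self) -> dict[int, float]:
        """Conditional probability an association touching a residue docks.

        Residues never contacted are absent (undefined, not zero).
        """
        return {
            r: s / n for r, (n, s) in self.per_residue.items() if n > 0
        }


def association_census(
    traj: Trajectory,
    chains: list[BindingChain],
) -> CensusResult:
    """Count associations, docked associations and per-residue successes.

    An "association" is one chain; docking-episode counts are also reported
    because the two conventions differ when a chain undocks and redocks.
    Rates are normalised per microsecond of trajectory.
    """
    duration_us = traj.duration_ns / 1000.0
    if duration_us <= 0:
        raise ValueError("trajectory duration is zero; cannot normalise rates")
    per_residue: dict[int, list[int]] = {}
    n_docked = 0
    n_episodes = 0
    for chain in chains:
        success = chain.docked
        n_docked += int(success)
        n_episodes += len(chain.docking_episodes())
        for r in chain.contact_residues():
            cell = per_residue.setdefault(r, [0, 0])
            cell[0] += 1
            cell[1] += int(success)
    return CensusResult(
        n_associations=len(chains),
        n_docked=n_docked,
        n_docking_episodes=n_episodes,
        per_residue={r: (n, s) for r, (n, s) in per_residue.items()},
        duration_us=duration_us,
    )


def association_states(traj: Trajectory, chains: list[BindingChain]) -> np.ndarray:
    """Per-frame AssociationState array for one ligand copy."""
    states = np.full(traj.n_frames, int(AssociationState.BULK), dtype=np.int8)
    for chain in chains:
        states[chain.start_frame : chain.end_frame + 1] = int(AssociationState.ASSOCIATED)
        for f in chain.docked_frames:
            states[f] = int(AssociationState.DOCKED)
    return states
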