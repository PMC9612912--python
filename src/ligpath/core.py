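"""Core domain model: atoms, topologies, trajectories and selections.

Unit conventions used throughout the package:

* distances in angstroms (A)
* times in nanoseconds (ns); kinetic outputs convert to seconds explicitly
* energies in kcal/mol, temperatures in kelvin
* frame indices are 0-based

Periodic minimum-image handling is OFF by default (the solute is assumed
whole and centered); pass ``box`` to the distance helpers to enable
orthorhombic minimum-image distances.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "AtomRecord",
    "AssociationState",
    "DockingAtoms",
    "OrderParameterGroups",
    "Topology",
    "Trajectory",
    "SelectionError",
    "TopologyError",
    "resolve_selection",
    "is_polar_element",
    "min_pairwise_distance",
    "pairwise_distances",
    "DEFAULT_POLAR_ELEMENTS",
    "BACKBONE_NAMES",
    "ATOMIC_MASSES",
]

#: Elements whose heavy atoms count as polar for the association criterion.
#: Sulfur is included by decision; override per call where supported.
DEFAULT_POLAR_ELEMENTS = frozenset({"N", "O", "S"})

#: Backbone atom names used for backbone selections and order parameters.
BACKBONE_NAMES = frozenset({"N", "CA", "C"})

#: Standard atomic masses (amu) for the elements this package encounters.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}


class SelectionError(ValueError):
    """Raised when a selection expression cannot be resolved."""


class TopologyError(ValueError):
    """Raised when a topology violates a structural invariant."""


def is_polar_element(element: str, polar_elements=DEFAULT_POLAR_ELEMENTS) -> bool:
    """Return True when ``element`` is a polar heavy-atom element.

    Carbon and hydrogen are never polar; the default polar set is
    {N, O, S} and is configurable.
    """
    return element.upper() in polar_elements


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a topology.

    ``residue_id`` preserves the numbering of the source topology verbatim
    (author/Uniprot-style numbering is never renumbered).
    """

    atom_id: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    chain_id: str = "A"

    @property
    def is_polar(self) -> bool:
        return is_polar_element(self.element)

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


class AssociationState(enum.IntEnum):
    """Ligand state per frame: bulk, surface-associated, or docked."""

    BULK = 0
    ASSOCIATED = 1
    DOCKED = 2


@dataclass(frozen=True)
class DockingAtoms:
    """Atom ids of the docking criterion quadruple for one ligand copy."""

    nh1: int
    nh2: int
    ot1: int
    ot2: int

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.nh1, self.nh2, self.ot1, self.ot2)


@dataclass(frozen=True)
class OrderParameterGroups:
    """Residue-id ranges defining the two clamshell-closure distances.

    Each of the four entries is a tuple of residue ids whose backbone
    atoms form one center-of-mass group; xi1 = |COM(xi1_a) - COM(xi1_b)|
    and likewise for xi2.
    """

    xi1_a: tuple[int, ...]
    xi1_b: tuple[int, ...]
    xi2_a: tuple[int, ...]
    xi2_b: tuple[int, ...]


@dataclass
class Topology:
    """Atom table plus the named selections every analysis stage shares."""

    atoms: list[AtomRecord]
    ligand_copies: list[list[int]] = field(default_factory=list)
    ligand_ref_atom: list[int] = field(default_factory=list)
    docking_atoms: list[DockingAtoms] = field(default_factory=list)
    lobe_D1: dict[str, frozenset[int]] = field(default_factory=dict)
    lobe_D2: dict[str, frozenset[int]] = field(default_factory=dict)
    op_groups: dict[str, OrderParameterGroups] = field(default_factory=dict)
    glycan_atoms: dict[str, list[int]] = field(default_factory=dict)
    box: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise TopologyError("atom_id values must be unique within a topology")
        self._by_id = {a.atom_id: a for a in self.atoms}
        lig = set()
        for copy in self.ligand_copies:
            overlap = lig.intersection(copy)
            if overlap:
                raise TopologyError(f"ligand copies share atoms: {sorted(overlap)}")
            lig.update(copy)
        self._ligand_atom_ids = frozenset(lig)
        for d in self.docking_atoms:
            for aid in d.as_tuple():
                if aid not in self._by_id:
                    raise TopologyError(f"docking atom id {aid} not in topology")

    # -- lookups ---------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom(self, atom_id: int) -> AtomRecord:
        try:
            return self._by_id[atom_id]
        except KeyError:
            raise TopologyError(f"no atom with id {atom_id}") from None

    @property
    def ligand_atom_ids(self) -> frozenset[int]:
        return self._ligand_atom_ids

    @property
    def protein_atom_ids(self) -> frozenset[int]:
        """All non-ligand atoms (glycans count as part of the protein)."""
        return frozenset(a.atom_id for a in self.atoms if a.atom_id not in self._ligand_atom_ids)

    def atom_index(self, atom_id: int) -> int:
        """Row index of ``atom_id`` in the coordinate array."""
        if not hasattr(self, "_index_of"):
            self._index_of = {a.atom_id: i for i, a in enumerate(self.atoms)}
        return self._index_of[atom_id]

    def indices(self, atom_ids) -> np.ndarray:
        return np.array([self.atom_index(i) for i in sorted(atom_ids)], dtype=np.intp)

    def masses(self, atom_ids) -> np.ndarray:
        return np.array(
            [ATOMIC_MASSES[self.atom(i).element.upper()] for i in sorted(atom_ids)]
        )

    def residue_ids(self) -> frozenset[int]:
        return frozenset(a.residue_id for a in self.atoms)

    def atom_names(self) -> frozenset[str]:
        return frozenset(a.name for a in self.atoms)


@dataclass
class Trajectory:
    """Coordinate stream (frames x atoms x 3, in A) over a fixed topology."""

    coordinates: np.ndarray
    frame_times: np.ndarray
    topology: Topology

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate array has {self.coordinates.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if len(self.frame_times) != self.coordinates.shape[0]:
            raise ValueError("frame_times length must match the number of frames")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def duration_ns(self) -> float:
        """Total simulated time, counting one timestep per frame."""
        if self.n_frames < 2:
            return 0.0
        dt = np.diff(self.frame_times)
        return float(np.sum(dt) + dt[-1])

    def frame_durations_ns(self) -> np.ndarray:
        """Per-frame time credit (ns); the last frame inherits the last step."""
        if self.n_frames < 2:
            return np.zeros(self.n_frames)
        dt = np.diff(self.frame_times)
        return np.append(dt, dt[-1])


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def pairwise_distances(xyz_a: np.ndarray, xyz_b: np.ndarray, box=None) -> np.ndarray:
    """All-pairs Euclidean distances, optionally orthorhombic minimum-image."""
    xyz_a = np.atleast_2d(np.asarray(xyz_a, dtype=np.float64))
    xyz_b = np.atleast_2d(np.asarray(xyz_b, dtype=np.float64))
    if box is None:
        return cdist(xyz_a, xyz_b)
    box = np.asarray(box, dtype=np.float64)
    delta = xyz_a[:, None, :] - xyz_b[None, :, :]
    delta -= box * np.round(delta / box)
    return np.sqrt(np.sum(delta * delta, axis=-1))


def min_pairwise_distance(xyz_a: np.ndarray, xyz_b: np.ndarray, box=None) -> float:
    """Minimum distance between two point sets (A)."""
    return float(pairwise_distances(xyz_a, xyz_b, box=box).min())


# ---------------------------------------------------------------------------
# selection mini-language
# ---------------------------------------------------------------------------

_RESID_RANGE = re.compile(r"^(-?\d+)[-:](-?\d+)$")


def _parse_resid_tokens(tokens: list[str], topology: Topology) -> set[int]:
    wanted: set[int] = set()
    for tok in tokens:
        m = _RESID_RANGE.match(tok)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            wanted.update(range(lo, hi + 1))
        else:
            try:
                wanted.add(int(tok))
            except ValueError:
                raise SelectionError(f"bad residue token {tok!r}") from None
    present = topology.residue_ids()
    missing = {r for r in wanted if r not in present}
    # ranges may legitimately skip gaps, but a selection matching nothing at
    # all is always an error
    if wanted and not (wanted & present):
        raise SelectionError(f"no residues match {' '.join(tokens)!r}")
    if missing == wanted:
        raise SelectionError(f"unknown residues {sorted(missing)}")
    return wanted


def resolve_selection(topology: Topology, spec: str, allow_empty: bool = False) -> frozenset[int]:
    """Resolve a selection expression to an ordered atom-id set.

    The expression is a sequence of clauses joined by ``and``; supported
    clauses are::

        resid 485-486 690        residue ids (ranges with - or :)
        name N CA C              atom names
        chain A B                chain labels
        backbone                 atoms named N, CA, C
        calpha                   atoms named CA
        polar                    polar heavy atoms (N/O/S)
        heavy                    non-hydrogen atoms
        protein                  non-ligand atoms
        ligand 0                 atoms of ligand copy 0
        glycan NAME              atoms of a named glycan
        all                      every atom

    Resolution is deterministic and independent of atom storage order.
    An empty result raises :class:`SelectionError` unless ``allow_empty``.
    """
    clauses = [c.strip() for c in re.split(r"\band\b", spec) if c.strip()]
    if not clauses:
        raise SelectionError("empty selection expression")
    selected = {a.atom_id for a in topology.atoms}
    for clause in clauses:
        parts = clause.split()
        kw, args = parts[0].lower(), parts[1:]
        if kw == "resid":
            if not args:
                raise SelectionError("resid clause needs residue ids")
            resids = _parse_resid_tokens(args, topology)
            keep = {a.atom_id for a in topology.atoms if a.residue_id in resids}
        elif kw == "name":
            if not args:
                raise SelectionError("name clause needs atom names")
            known = topology.atom_names()
            unknown = [n for n in args if n not in known]
            if len(unknown) == len(args):
                raise SelectionError(f"unknown atom name(s) {unknown}")
            keep = {a.atom_id for a in topology.atoms if a.name in set(args)}
        elif kw == "chain":
            keep = {a.atom_id for a in topology.atoms if a.chain_id in set(args)}
            if not keep:
                raise SelectionError(f"unknown chain(s) {args}")
        elif kw == "backbone":
            keep = {a.atom_id for a in topology.atoms if a.is_backbone}
        elif kw == "calpha":
            keep = {a.atom_id for a in topology.atoms if a.name == "CA"}
        elif kw == "polar":
            keep = {a.atom_id for a in topology.atoms if a.is_polar and a.is_heavy}
        elif kw == "heavy":
            keep = {a.atom_id for a in topology.atoms if a.is_heavy}
        elif kw == "protein":
            keep = set(topology.protein_atom_ids)
        elif kw == "ligand":
            if len(args) != 1:
                raise SelectionError("ligand clause needs exactly one copy index")
            try:
                copy = int(args[0])
                keep = set(topology.ligand_copies[copy])
            except (ValueError, IndexError):
                raise SelectionError(f"unknown ligand copy {args[0]!r}") from None
        elif kw == "glycan":
            if len(args) != 1 or args[0] not in topology.glycan_atoms:
                raise SelectionError(f"unknown glycan {' '.join(args)!r}")
            keep = set(topology.glycan_atoms[args[0]])
        elif kw == "all":
            keep = {a.atom_id for a in topology.atoms}
        else:
            raise SelectionError(f"unknown selection keyword {kw!r}")
        selected &= keep
    if not selected and not allow_empty:
        raise SelectionError(f"selection {spec!r} matched no atoms")
    return frozenset(selected)
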