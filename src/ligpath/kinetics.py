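"""Association rate constant (kon) estimation from unbiased trajectories.

The estimator is

    kon = N_b / sum_i( t_i * L_i * s_i )

with N_b the number of association events surviving the residence-time
threshold, t_i the bulk-solvent time of ligand copy i (seconds), L_i the
free-ligand concentration (molar) and s_i the number of identical binding
sites. Reported per threshold: the zero threshold gives the upper bound
("all events included"); higher thresholds give lower bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import AssociationState, Trajectory
from .chains import BindingChain, association_states

__all__ = [
    "AVOGADRO",
    "BindingEventRecord",
    "KineticsInput",
    "KonReport",
    "bulk_time",
    "residence_time_ns",
    "free_concentration",
    "kon_estimate",
    "kinetics_from_chains",
]

AVOGADRO = 6.02214076e23
_A3_TO_L = 1e-27  # cubic angstroms to liters


@dataclass
class BindingEventRecord:
    ligand_copy: int
    chain_id: int
    residence_time_ns: float  # time in the associated-or-docked state
    success: bool  # chain reached the docked state

    def __post_init__(self) -> None:
        if self.residence_time_ns < 0:
            raise ValueError("residence time must be >= 0")


@dataclass
class KineticsInput:
    """Everything the kon estimator consumes.

    One (t_i, L_i, s_i) term per ligand copy / trajectory segment; terms
    from independent trajectories may simply be concatenated (the estimator
    is additive in both numerator and denominator).
    """

    events: list[BindingEventRecord]
    bulk_times_s: list[float]
    concentrations_M: list[float]
    sites: list[int]
    residence_basis: str = "associated"  # or "docked"; recorded in reports

    def __post_init__(self) -> None:
        if not len(self.bulk_times_s) == len(self.concentrations_M) == len(self.sites):
            raise ValueError("bulk_times_s, concentrations_M and sites must align")
        if any(t < 0 for t in self.bulk_times_s):
            raise ValueError("bulk times must be >= 0")
        if any(c <= 0 for c in self.concentrations_M):
            raise ValueError("concentrations must be > 0")
        if any(s < 1 for s in self.sites):
            raise ValueError("site counts must be >= 1")

    def denominator(self) -> float:
        return float(
            sum(
                t * c * s
                for t, c, s in zip(self.bulk_times_s, self.concentrations_M, self.sites)
            )
        )

    @staticmethod
    def concatenate(parts: list["KineticsInput"]) -> "KineticsInput":
        return KineticsInput(
            events=[e for p in parts for e in p.events],
            bulk_times_s=[t for p in parts for t in p.bulk_times_s],
            concentrations_M=[c for p in parts for c in p.concentrations_M],
            sites=[s for p in parts for s in p.sites],
            residence_basis=parts[0].residence_basis if parts else "associated",
        )


def bulk_time(traj: Trajectory, chains: list[BindingChain]) -> float:
    """Time one ligand copy spends in bulk solvent, in seconds.

    Total trajectory time minus time in the ASSOCIATED or DOCKED states.
    """
    states = association_states(traj, chains)
    dur = traj.frame_durations_ns()
    in_bulk = states == int(AssociationState.BULK)
    return float(dur[in_bulk].sum()) * 1e-9


def residence_time_ns(
    traj: Trajectory, chain: BindingChain, basis: str = "associated"
) -> float:
    """Residence time of one chain: associated-or-docked (default) or
    docked-only time, in ns."""
    dur = traj.frame_durations_ns()
    if basis == "associated":
        return float(dur[chain.start_frame : chain.end_frame + 1].sum())
    if basis == "docked":
        if not chain.docked_frames:
            return 0.0
        return float(dur[sorted(chain.docked_frames)].sum())
    raise ValueError(f"unknown residence basis {basis!r}")


def free_concentration(
    traj: Trajectory,
    states_per_copy: np.ndarray,
    frame_range: slice | None = None,
    constant: float | None = None,
) -> float:
    """Free-agonist concentration (molar) over a frame range.

    Mean number of BULK-state copies divided by Avogadro's number times the
    box volume. ``states_per_copy`` has shape (n_copies, n_frames). Pass
    ``constant`` to bypass the computation (nominal-concentration mode).
    """
    if constant is not None:
        return float(constant)
    if traj.topology.box is None:
        raise ValueError("box dimensions unknown; supply a constant concentration")
    states = np.asarray(states_per_copy)
    if frame_range is not None:
        states = states[:, frame_range]
    n_free = (states == int(AssociationState.BULK)).sum(axis=0).mean()
    lx, ly, lz = traj.topology.box
    volume_l = lx * ly * lz * _A3_TO_L
    conc = float(n_free / (AVOGADRO * volume_l))
    if conc == 0.0:
        warnings.warn("no free ligand copies in range; kon is undefined at L=0")
    return conc


@dataclass
class KonReport:
    """kon estimates per residence threshold plus the inputs that made them."""

    estimates: dict[float, float]  # threshold_ns -> kon (1/M/s)
    n_events: dict[float, int]
    denominator_Ms: float
    residence_basis: str
    thresholds_ns: list[float] = field(default_factory=list)

    @property
    def upper_bound(self) -> float:
        return self.estimates[min(self.estimates)]

    @property
    def lower_bound(self) -> float:
        return self.estimates[max(self.estimates)]


def kon_estimate(
    inputs: KineticsInput,
    residence_thresholds_ns: tuple[float, ...] = (0.0, 100.0),
) -> KonReport:
    """Estimate kon at each residence-time threshold.

    Events with residence time strictly below a threshold are dropped from
    N_b for that threshold; the denominator is threshold-independent.
    Raising the threshold can therefore never increase the estimate.
    """
    denom = inputs.denominator()
    if denom <= 0:
        raise ValueError("kon denominator is zero (no bulk time recorded)")
    estimates: dict[float, float] = {}
    counts: dict[float, int] = {}
    for thr in sorted(set(residence_thresholds_ns)):
        if thr == 0.0:
            nb = len(inputs.events)
        else:
            nb = sum(1 for e in inputs.events if e.residence_time_ns > thr)
        counts[thr] = nb
        if nb == 0:
            warnings.warn(f"no events above residence threshold {thr} ns; kon = 0")
        estimates[thr] = nb / denom
    return KonReport(
        estimates=estimates,
        n_events=counts,
        denominator_Ms=denom,
        residence_basis=inputs.residence_basis,
        thresholds_ns=sorted(set(residence_thresholds_ns)),
    )


def kinetics_from_chains(
    traj: Trajectory,
    chains_per_copy: dict[int, list[BindingChain]],
    sites: int = 1,
    concentration_M: float | None = None,
    count_all_associations: bool = False,
    residence_basis: str = "associated",
) -> KineticsInput:
    """Build a KineticsInput from detected chains.

    By default only docked ("successful") chains count as association
    events for N_b; set ``count_all_associations`` to count every chain.
    Free concentration is computed from the box and bulk-state occupancy
    unless a nominal constant is supplied.
    """
    all_states = np.vstack(
        [association_states(traj, chains_per_copy.get(c, []))
         for c in sorted(chains_per_copy)]
    )
    conc = free_concentration(traj, all_states, constant=concentration_M)
    events: list[BindingEventRecord] = []
    bulk: list[float] = []
    for copy in sorted(chains_per_copy):
        chains = chains_per_copy[copy]
        bulk.append(bulk_time(traj, chains))
        for ch in chains:
            if not count_all_associations and not ch.docked:
                continue
            events.append(
                BindingEventRecord(
                    ligand_copy=copy,
                    chain_id=ch.chain_id,
                    residence_time_ns=residence_time_ns(traj, ch, residence_basis),
                    success=ch.docked,
                )
            )
    return KineticsInput(
        events=events,
        bulk_times_s=bulk,
        concentrations_M=[conc] * len(bulk),
        sites=[sites] * len(bulk),
        residence_basis=residence_basis,
    )
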