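"""Residue contact statistics: fractional occurrence, overlap coefficients
and agonist comparisons."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

__all__ = [
    "ContactProfile",
    "OCProfileResult",
    "overlap_coefficient",
    "profile_from_pathways",
    "cluster_oc_profile",
    "fractional_occurrence",
    "compare_agonists",
]


@dataclass
class ContactProfile:
    """Per-residue contact counts within one scope (cluster or agonist).

    ``pathway_counts`` counts pathways contacting each residue (primary
    statistic); ``frame_counts`` counts contact frames (also emitted since
    either convention is defensible — see output metadata). Fractional
    occurrence normalises by the most contacted residue, so it is invariant
    under uniform scaling of counts and the top residue is exactly 1.0.
    """

    scope: str
    pathway_counts: dict[int, int] = field(default_factory=dict)
    frame_counts: dict[int, int] = field(default_factory=dict)
    count_basis: str = "pathway"  # which counts feed fractional occurrence

    def counts(self) -> dict[int, int]:
        return self.pathway_counts if self.count_basis == "pathway" else self.frame_counts

    def fractional(self) -> dict[int, float]:
        counts = self.counts()
        if not counts:
            raise ValueError(f"profile {self.scope!r} is empty")
        top = max(counts.values())
        return {r: c / top for r, c in counts.items()}


def profile_from_pathways(pathways, scope: str, count_basis: str = "pathway") -> ContactProfile:
    """Aggregate pathway contact multisets into a ContactProfile."""
    pc: dict[int, int] = {}
    fc: dict[int, int] = {}
    for p in pathways:
        for r, nframes in p.contact_residues.items():
            pc[r] = pc.get(r, 0) + 1
            fc[r] = fc.get(r, 0) + nframes
    return ContactProfile(scope=scope, pathway_counts=pc, frame_counts=fc, count_basis=count_basis)


def overlap_coefficient(A, B) -> float:
    """Szymkiewicz-Simpson overlap coefficient |A&B| / min(|A|, |B|).

    1.0 whenever one set contains the other; undefined (error) for empty
    sets. Chosen over Jaccard because pathway lengths vary widely and many
    incidental contacts would otherwise dilute the similarity.
    """
    A, B = set(A), set(B)
    if not A or not B:
        raise ValueError("overlap coefficient is undefined for empty sets")
    return len(A & B) / min(len(A), len(B))


@dataclass
class OCProfileResult:
    cluster_means: dict[int, float]
    cluster_pair_counts: dict[int, int]
    global_mean: float
    below_global: list[int]  # clusters whose mean OC < global mean


def cluster_oc_profile(pathways_by_cluster: dict[int, list]) -> OCProfileResult:
    """Pairwise overlap coefficients within clusters vs the global mean.

    The global mean is the mean OC over ALL pathway pairs regardless of
    cluster, so it is independent of the partition. Clusters whose mean
    falls below the global mean carry the "random contacts" signature.
    Pathways with empty contact sets are excluded with a warning.
    """
    kept: dict[int, list] = {}
    for cid, paths in pathways_by_cluster.items():
        ok = [p for p in paths if p.distinct_residues()]
        if len(ok) < len(paths):
            warnings.warn(
                f"cluster {cid}: dropped {len(paths) - len(ok)} pathway(s) with "
                "empty contact sets from OC statistics"
            )
        kept[cid] = ok
    all_paths = [p for paths in kept.values() for p in paths]
    if len(all_paths) < 2:
        raise ValueError("need at least two pathways with contacts")
    all_ocs = [
        overlap_coefficient(a.distinct_residues(), b.distinct_residues())
        for a, b in itertools.combinations(all_paths, 2)
    ]
    global_mean = sum(all_ocs) / len(all_ocs)

    cluster_means: dict[int, float] = {}
    pair_counts: dict[int, int] = {}
    for cid, paths in kept.items():
        pairs = list(itertools.combinations(paths, 2))
        pair_counts[cid] = len(pairs)
        if pairs:
            ocs = [
                overlap_coefficient(a.distinct_residues(), b.distinct_residues())
                for a, b in pairs
            ]
            cluster_means[cid] = sum(ocs) / len(ocs)
    below = sorted(c for c, m in cluster_means.items() if m < global_mean)
    return OCProfileResult(
        cluster_means=cluster_means,
        cluster_pair_counts=pair_counts,
        global_mean=global_mean,
        below_global=below,
    )


def fractional_occurrence(
    profile: ContactProfile,
    label_threshold: float = 0.2,
    display_threshold: float = 0.1,
) -> dict[str, object]:
    """Partition residues into labeled / displayed-only / hidden tiers.

    Residues at >= ``label_threshold`` fractional occurrence (relative to
    the most contacted residue in scope) are labeled; those at
    >= ``display_threshold`` are additionally displayed; the rest are
    hidden.
    """
    fractions = profile.fractional()
    labeled = {r for r, f in fractions.items() if f >= label_threshold}
    displayed_only = {
        r for r, f in fractions.items() if display_threshold <= f < label_threshold
    }
    hidden = set(fractions) - labeled - displayed_only
    return {
        "fractions": fractions,
        "labeled": labeled,
        "displayed_only": displayed_only,
        "displayed": labeled | displayed_only,
        "hidden": hidden,
    }


def compare_agonists(
    profile_x: ContactProfile,
    profile_y: ContactProfile,
    fold_threshold: float = 10.0,
    pseudo_count: float = 0.01,
) -> dict[str, list[dict]]:
    """Residues distinguishing two agonists by fractional-occurrence ratio.

    A residue is flagged for X when its fractional occurrence in X exceeds
    ``fold_threshold`` times that in Y (and symmetrically for Y). Residues
    absent from one profile take ``pseudo_count`` as their fraction and are
    annotated ``absent_in_other``.
    """
    fx = profile_x.fractional()
    fy = profile_y.fractional()
    flagged_x: list[dict] = []
    flagged_y: list[dict] = []
    for r in sorted(set(fx) | set(fy)):
        x = fx.get(r)
        y = fy.get(r)
        x_eff = pseudo_count if x is None else x
        y_eff = pseudo_count if y is None else y
        if x is not None and x_eff / y_eff > fold_threshold:
            flagged_x.append(
                {"residue": r, "ratio": x_eff / y_eff, "absent_in_other": y is None}
            )
        if y is not None and y_eff / x_eff > fold_threshold:
            flagged_y.append(
                {"residue": r, "ratio": y_eff / x_eff, "absent_in_other": x is None}
            )
    return {profile_x.scope: flagged_x, profile_y.scope: flagged_y}
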