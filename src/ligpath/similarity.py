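"""Pathway similarity analysis: weighted-average Hausdorff distances,
hierarchical clustering and per-cluster occupancy densities.

The path metric is the weighted-average Hausdorff distance

    dH_wavg(A, B) = 1/2 [ dH_sum(A|B)/|A| + dH_sum(B|A)/|B| ]

where dH_sum(A|B) is the one-sided summed nearest-neighbour distance from
every point of A to B and |A|, |B| are frame counts. The frame-count
normalisation removes the temporal component: duplicating every point of a
path leaves the metric unchanged, as does reversing a path in time.

Note: dH_wavg satisfies non-negativity, symmetry and identity of
indiscernibles on point sets, but the triangle inequality is NOT
guaranteed; Ward linkage on such a matrix is the field's convention and is
applied here with that caveat (complete linkage is offered as well).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

__all__ = [
    "PathDistanceMatrix",
    "ClusterAssignment",
    "OccupancyGrid",
    "hausdorff_sum",
    "wavg_hausdorff",
    "distance_matrix",
    "cluster_paths",
    "occupancy_density",
    "write_opendx",
]


def _points(path) -> np.ndarray:
    # Pathway objects carry an (n, 3) ``trace`` array; raw arrays/sequences
    # are used directly (note ndarray.trace is a method, hence the check)
    tr = getattr(path, "trace", None)
    raw = tr if tr is not None and not callable(tr) else path
    pts = np.asarray(raw, dtype=np.float64)
    pts = np.atleast_2d(pts)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("a path must be an (n, 3) point sequence")
    if pts.shape[0] == 0:
        raise ValueError("empty path")
    return pts


def hausdorff_sum(A, B) -> float:
    """One-sided summed Hausdorff distance from path A to path B (A)."""
    a, b = _points(A), _points(B)
    return float(cdist(a, b).min(axis=1).sum())


def wavg_hausdorff(A, B) -> float:
    """Weighted-average Hausdorff distance between two paths (A).

    Symmetric by construction and independent of each path's frame count.
    """
    a, b = _points(A), _points(B)
    d = cdist(a, b)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


@dataclass
class PathDistanceMatrix:
    path_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.path_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match path_ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def distance_matrix(paths, path_ids=None) -> PathDistanceMatrix:
    """Full symmetric dH_wavg matrix over a list of paths."""
    n = len(paths)
    if n < 2:
        raise ValueError("need at least two paths")
    if path_ids is None:
        path_ids = [getattr(p, "path_id", str(i)) for i, p in enumerate(paths)]
    if len(set(path_ids)) != len(path_ids):
        raise ValueError("path ids must be unique")
    pts = [_points(p) for p in paths]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = cdist(pts[i], pts[j])
            values[i, j] = values[j, i] = 0.5 * (
                d.min(axis=1).mean() + d.min(axis=0).mean()
            )
    return PathDistanceMatrix(list(path_ids), values)


@dataclass
class ClusterAssignment:
    """Hierarchical clustering result over a path distance matrix."""

    path_ids: list[str]
    linkage_tree: np.ndarray  # scipy linkage matrix (n-1, 4)
    labels: dict[str, int]
    cut_spec: dict

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.labels.values():
            out[c] = out.get(c, 0) + 1
        return out

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for pid in self.path_ids:  # preserve input order
            out.setdefault(self.labels[pid], []).append(pid)
        return out

    def dendrogram_records(self) -> list[dict]:
        """Merge list (pair indices + height + size) for JSON export."""
        return [
            {
                "left": int(a),
                "right": int(b),
                "height": float(h),
                "size": int(s),
            }
            for a, b, h, s in self.linkage_tree
        ]


def cluster_paths(
    matrix: PathDistanceMatrix,
    method: str = "ward",
    n_clusters: int | None = None,
    height: float | None = None,
) -> ClusterAssignment:
    """Agglomerative clustering on a precomputed dH_wavg matrix.

    ``method`` is ``ward`` (default) or ``complete``. Cut either at a
    cluster count or a merge-height threshold; exactly one must be given.
    Deterministic for a fixed matrix and cut.
    """
    if method not in ("ward", "complete"):
        raise ValueError(f"unsupported linkage {method!r}")
    if (n_clusters is None) == (height is None):
        raise ValueError("specify exactly one of n_clusters or height")
    n = len(matrix.path_ids)
    if n_clusters is not None and not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}]")
    tree = linkage(matrix.condensed(), method=method)
    if n_clusters is not None:
        flat = fcluster(tree, t=n_clusters, criterion="maxclust")
        cut = {"n_clusters": n_clusters}
    else:
        flat = fcluster(tree, t=height, criterion="distance")
        cut = {"height": height}
    labels = {pid: int(c) for pid, c in zip(matrix.path_ids, flat)}
    return ClusterAssignment(
        path_ids=list(matrix.path_ids),
        linkage_tree=tree,
        labels=labels,
        cut_spec={"method": method, **cut},
    )


@dataclass
class OccupancyGrid:
    """Voxel counts of trace points on a regular orthogonal grid."""

    origin: np.ndarray
    spacing: float
    counts: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    def total(self) -> int:
        return int(self.counts.sum())


def occupancy_density(paths, spacing: float, origin=None, shape=None, metadata=None) -> OccupancyGrid:
    """Bin all trace points of ``paths`` onto a voxel grid.

    The grid (origin/shape) is derived from the data extent unless given
    explicitly, which lets grids from different clusters share one frame of
    reference. Count conservation: the grid total equals the number of
    points that fall inside the grid (all of them for an auto-extent grid).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    pts = np.vstack([_points(p) for p in paths])
    if origin is None:
        origin = np.floor(pts.min(axis=0) / spacing) * spacing
    origin = np.asarray(origin, dtype=np.float64)
    if shape is None:
        shape = tuple(np.floor((pts.max(axis=0) - origin) / spacing).astype(int) + 1)
    idx = np.floor((pts - origin) / spacing).astype(int)
    counts = np.zeros(shape, dtype=np.int64)
    inside = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    np.add.at(counts, tuple(idx[inside].T), 1)
    return OccupancyGrid(origin=origin, spacing=spacing, counts=counts, metadata=metadata or {})


def write_opendx(grid: OccupancyGrid, path) -> None:
    """Write an occupancy grid as an OpenDX scalar field (text)."""
    nx, ny, nz = grid.shape
    ox, oy, oz = grid.origin
    s = grid.spacing
    with open(path, "w") as fh:
        fh.write(f"# ligpath occupancy grid {grid.metadata}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {s:.6f} 0 0\ndelta 0 {s:.6f} 0\ndelta 0 0 {s:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        flat = grid.counts.astype(float).ravel(order="C")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.1f}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
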