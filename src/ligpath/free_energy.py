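"""Free-energy surfaces: histogram PMFs, 2-D WHAM unbiasing of umbrella
windows, block-averaged uncertainties and low-energy conformer extraction.

All free energies are in kcal/mol and are min-zeroed over sampled bins
(the additive gauge is fixed by the minimum). Unsampled bins carry +inf,
never zero. Histogram PMF errors use 5 contiguous blocks by default;
WHAM errors use 10 blocks per window. Blocks that do not sample a bin are
omitted from that bin's error estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "KB_KCAL",
    "UmbrellaWindow",
    "PMFGrid",
    "WhamConvergenceError",
    "histogram_pmf",
    "wham2d",
    "low_energy_conformers",
    "conditional_pmf",
]

#: Boltzmann constant in kcal/(mol K).
KB_KCAL = 0.0019872041


class WhamConvergenceError(RuntimeError):
    pass


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic bias center, force constant, samples.

    The bias is ``0.5*k*((x1-c1)^2 + (x2-c2)^2)`` — independent harmonic
    terms with the same force constant on each order parameter.
    """

    center: tuple[float, float]
    k: float  # kcal/mol/A^2
    samples: np.ndarray  # (n, 2) order-parameter pairs
    temperature: float = 300.0
    window_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.shape[1] != 2:
            raise ValueError("samples must be (n, 2)")
        if self.samples.shape[0] == 0:
            raise ValueError("window has no samples")
        if self.k < 0:
            raise ValueError("force constant must be >= 0")

    def bias_energy(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        d = pts - np.asarray(self.center)
        return 0.5 * self.k * (d * d).sum(axis=1)


@dataclass
class PMFGrid:
    """Binned free-energy surface (1-D or 2-D).

    ``F`` is min-zeroed over sampled bins; unsampled bins are +inf and are
    excluded from the min shift. ``std`` is NaN where no block estimate is
    available.
    """

    edges: tuple[np.ndarray, ...]
    F: np.ndarray
    std: np.ndarray
    counts: np.ndarray
    kT: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sampled = np.isfinite(self.F)
        if sampled.any() and not np.isclose(self.F[sampled].min(), 0.0, atol=1e-10):
            raise ValueError("PMF must be min-zeroed over sampled bins")
        if np.any(self.std[np.isfinite(self.std)] < 0):
            raise ValueError("std must be non-negative")

    @property
    def ndim(self) -> int:
        return len(self.edges)

    def centers(self) -> tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)

    @property
    def sampled(self) -> np.ndarray:
        return np.isfinite(self.F)

    def bin_index(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map points to bin indices; second return flags in-range points."""
        values = np.atleast_2d(np.asarray(values, dtype=np.float64))
        if values.shape[1] != self.ndim:
            values = values.reshape(-1, self.ndim)
        idx = []
        ok = np.ones(values.shape[0], dtype=bool)
        for d, e in enumerate(self.edges):
            i = np.digitize(values[:, d], e) - 1
            i = np.where(np.isclose(values[:, d], e[-1]), len(e) - 2, i)
            ok &= (i >= 0) & (i < len(e) - 1)
            idx.append(np.clip(i, 0, len(e) - 2))
        return tuple(idx), ok


def _edges_1d(values: np.ndarray, bin_width: float, vrange=None) -> np.ndarray:
    if vrange is None:
        lo = np.floor(values.min() / bin_width) * bin_width
        hi = np.ceil(values.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
    else:
        lo, hi = vrange
    n = int(round((hi - lo) / bin_width))
    n = max(n, 1)
    return lo + bin_width * np.arange(n + 1)


def _pmf_from_counts(counts: np.ndarray, kT: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        F = -kT * np.log(counts / counts.sum())
    F[counts == 0] = np.inf
    F -= F[np.isfinite(F)].min()
    return F


def histogram_pmf(
    series: np.ndarray,
    bin_width: float = 0.2,
    temperature: float = 310.0,
    n_blocks: int = 5,
    vrange: tuple[float, float] | None = None,
    weights: np.ndarray | None = None,
) -> PMFGrid:
    """1-D Boltzmann-inversion PMF with block-averaged errors.

    ``F(bin) = -kT ln p(bin)``, min-zeroed. The standard deviation per bin
    comes from PMFs of ``n_blocks`` contiguous blocks; blocks that do not
    sample a bin are omitted from that bin's error. Optional per-sample
    ``weights`` support reweighting (used by the single-window WHAM check).
    """
    series = np.asarray(series, dtype=np.float64).ravel()
    if series.size == 0:
        raise ValueError("empty series")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    kT = KB_KCAL * temperature
    edges = _edges_1d(series, bin_width, vrange)
    if weights is None:
        weights = np.ones_like(series)
    counts, _ = np.histogram(series, bins=edges, weights=weights)
    raw_counts, _ = np.histogram(series, bins=edges)
    F = _pmf_from_counts(counts, kT)

    std = np.full_like(F, np.nan)
    if n_blocks >= 2 and series.size >= n_blocks:
        block_F = []
        for vals, w in zip(
            np.array_split(series, n_blocks), np.array_split(weights, n_blocks)
        ):
            if vals.size == 0:
                continue
            c, _ = np.histogram(vals, bins=edges, weights=w)
            block_F.append(_pmf_from_counts(c, kT))
        if block_F:
            B = np.array(block_F)
            finite = np.isfinite(B)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                n_ok = finite.sum(axis=0)
                masked = np.where(finite, B, np.nan)
                std = np.nanstd(masked, axis=0, ddof=1)
            std[n_ok < 2] = np.nan
    return PMFGrid(
        edges=(edges,),
        F=F,
        std=std,
        counts=raw_counts,
        kT=kT,
        metadata={"bin_width": bin_width, "temperature": temperature, "n_blocks": n_blocks},
    )


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

def _wham_solve(
    H: np.ndarray,  # (L, B) histogram counts per window over flat bins
    log_c: np.ndarray,  # (L, B) -bias/kT at bin centers
    tol: float,
    max_iter: int,
    kT: float,
    f_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Self-consistent WHAM iteration in log space.

    Returns (logP over bins, window free energies F_l in kcal/mol).
    """
    L, B = H.shape
    N_l = H.sum(axis=1)
    log_N = np.log(np.where(N_l > 0, N_l, 1.0))
    H_b = H.sum(axis=0)
    sampled = H_b > 0
    with np.errstate(divide="ignore"):
        log_H = np.log(H_b)

    F_l = np.zeros(L) if f_init is None else np.asarray(f_init, dtype=np.float64).copy()
    for _ in range(int(max_iter)):
        # logP_b = log H_b - logsumexp_l [ log N_l + (F_l + kT*log_c_lb)/kT ]
        log_den = logsumexp(log_N[:, None] + F_l[:, None] / kT + log_c, axis=0)
        logP = np.where(sampled, log_H - log_den, -np.inf)
        F_new = -kT * logsumexp(logP[None, :] + log_c, axis=1)
        delta = np.max(np.abs(F_new - F_l - (F_new[0] - F_l[0])))
        F_l = F_new
        if delta < tol:
            break
    else:
        raise WhamConvergenceError(
            f"WHAM did not converge in {max_iter} iterations (residual {delta:.3g})"
        )
    return logP, F_l


def _window_overlap_connected(H: np.ndarray) -> bool:
    """Check whether windows form one connected component via shared bins."""
    L = H.shape[0]
    sampled = H > 0
    parent = list(range(L))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(L):
        for j in range(i + 1, L):
            if np.any(sampled[i] & sampled[j]):
                pi, pj = find(i), find(j)
                parent[pi] = pj
    return len({find(i) for i in range(L)}) == 1


def wham2d(
    windows: list[UmbrellaWindow],
    bin_width: tuple[float, float] = (0.25, 0.25),
    vrange: tuple[tuple[float, float], tuple[float, float]] | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    n_blocks: int = 10,
    f_init: np.ndarray | None = None,
) -> PMFGrid:
    """Unbias 2-D umbrella windows with the weighted histogram analysis
    method.

    Window free-energy constants are iterated to self-consistency
    (``|dF| < tol`` kcal/mol, gauge-fixed); the result is invariant to a
    constant added to the initial constants. Per-bin standard deviations
    come from ``n_blocks`` contiguous blocks of every window's trajectory,
    each unbiased independently. Non-overlapping window histograms trigger
    a convergence warning with a disconnected-region report.
    """
    if not windows:
        raise ValueError("need at least one window")
    temps = {w.temperature for w in windows}
    if len(temps) > 1:
        raise ValueError(f"windows have inconsistent temperatures: {sorted(temps)}")
    kT = KB_KCAL * windows[0].temperature

    all_samples = np.vstack([w.samples for w in windows])
    edges_x = _edges_1d(all_samples[:, 0], bin_width[0], vrange[0] if vrange else None)
    edges_y = _edges_1d(all_samples[:, 1], bin_width[1], vrange[1] if vrange else None)
    cx = 0.5 * (edges_x[1:] + edges_x[:-1])
    cy = 0.5 * (edges_y[1:] + edges_y[:-1])
    centers = np.stack(np.meshgrid(cx, cy, indexing="ij"), axis=-1).reshape(-1, 2)
    nx, ny = len(cx), len(cy)

    def histo(w_samples: np.ndarray) -> np.ndarray:
        h, _, _ = np.histogram2d(
            w_samples[:, 0], w_samples[:, 1], bins=(edges_x, edges_y)
        )
        return h.reshape(-1)

    H = np.array([histo(w.samples) for w in windows])
    log_c = np.array([-w.bias_energy(centers) / kT for w in windows])

    if len(windows) > 1 and not _window_overlap_connected(H):
        warnings.warn(
            "umbrella window histograms do not form a single overlapping "
            "region; the relative free energies of disconnected regions "
            "are undetermined"
        )

    logP, F_l = _wham_solve(H, log_c, tol, max_iter, kT, f_init)
    F = np.full(nx * ny, np.inf)
    finite = np.isfinite(logP)
    F[finite] = -kT * logP[finite]
    F[finite] -= F[finite].min()

    # block errors: unbias block j of every window, j = 0..n_blocks-1
    std = np.full(nx * ny, np.nan)
    if n_blocks >= 2:
        block_F = []
        for j in range(n_blocks):
            Hj = np.array(
                [histo(np.array_split(w.samples, n_blocks)[j]) for w in windows]
            )
            if Hj.sum() == 0:
                continue
            live = Hj.sum(axis=1) > 0  # windows with samples in this block
            try:
                logPj, _ = _wham_solve(
                    Hj[live], log_c[live], max(tol, 1e-6), max_iter, kT
                )
            except WhamConvergenceError:
                continue
            Fj = np.full(nx * ny, np.inf)
            fin = np.isfinite(logPj)
            Fj[fin] = -kT * logPj[fin]
            if fin.any():
                Fj[fin] -= Fj[fin].min()
            block_F.append(Fj)
        if block_F:
            B = np.array(block_F)
            fin = np.isfinite(B)
            n_ok = fin.sum(axis=0)
            masked = np.where(fin, B, np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                std = np.nanstd(masked, axis=0, ddof=1)
            std[n_ok < 2] = np.nan

    counts = H.sum(axis=0).reshape(nx, ny).astype(np.int64)
    return PMFGrid(
        edges=(edges_x, edges_y),
        F=F.reshape(nx, ny),
        std=std.reshape(nx, ny),
        counts=counts,
        kT=kT,
        metadata={
            "method": "wham2d",
            "bin_width": bin_width,
            "temperature": windows[0].temperature,
            "n_windows": len(windows),
            "n_blocks": n_blocks,
            "window_free_energies": [float(f - F_l[0]) for f in F_l],
        },
    )


def low_energy_conformers(
    pmf: PMFGrid, values: np.ndarray, threshold: float = 1.0
) -> np.ndarray:
    """Indices of frames whose order-parameter bin has F <= threshold.

    Intended to feed bound-state residue-contact profiling. Returns an
    empty array (with a warning) when no bin is at or below the threshold.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim == 1:
        values = values[:, None]
    idx, ok = pmf.bin_index(values)
    F_at = pmf.F[idx]
    keep = ok & np.isfinite(F_at) & (F_at <= threshold)
    if not np.any(keep):
        warnings.warn(f"no frames fall in bins with F <= {threshold} kcal/mol")
    return np.nonzero(keep)[0]


def conditional_pmf(
    series: np.ndarray,
    condition: np.ndarray,
    condition_name: str = "condition",
    **hist_kwargs,
) -> tuple[PMFGrid, PMFGrid]:
    """Histogram PMFs of ``series`` for frames satisfying / failing a
    boolean predicate, on a shared bin grid so the two are comparable.

    An empty satisfying stratum is an error naming the predicate; an empty
    failing stratum returns ``None`` in the second slot (a degenerate
    always-true predicate reproduces the unconditioned PMF).
    """
    series = np.asarray(series, dtype=np.float64).ravel()
    condition = np.asarray(condition, dtype=bool).ravel()
    if series.shape != condition.shape:
        raise ValueError("series and condition must have the same length")
    if not condition.any():
        raise ValueError(f"no frames satisfy predicate {condition_name!r}")
    bw = hist_kwargs.pop("bin_width", 0.2)
    vrange = hist_kwargs.pop("vrange", None)
    if vrange is None:
        edges = _edges_1d(series, bw)
        vrange = (edges[0], edges[-1])
    pmf_true = histogram_pmf(series[condition], bin_width=bw, vrange=vrange, **hist_kwargs)
    pmf_true.metadata["stratum"] = f"{condition_name}=True"
    if condition.all():
        warnings.warn(f"predicate {condition_name!r} holds on every frame")
        return pmf_true, None
    pmf_false = histogram_pmf(series[~condition], bin_width=bw, vrange=vrange, **hist_kwargs)
    pmf_false.metadata["stratum"] = f"{condition_name}=False"
    return pmf_true, pmf_false
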