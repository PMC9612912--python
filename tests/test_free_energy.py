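import numpy as np
import pytest

from ligpath.free_energy import (
    KB_KCAL,
    PMFGrid,
    UmbrellaWindow,
    conditional_pmf,
    histogram_pmf,
    low_energy_conformers,
    wham2d,
)
from ligpath.synthetic import harmonic_2d, sample_umbrella

T = 300.0
KT = KB_KCAL * T


class TestHistogramPMF:
    def test_uniform_is_flat(self):
        rng = np.random.default_rng(0)
        samples = rng.uniform(0, 10, 100_000)
        pmf = histogram_pmf(samples, bin_width=0.2, temperature=T)
        inner = slice(1, -1)  # edge bins are half-filled by the uniform range
        ok = np.isfinite(pmf.F[inner]) & np.isfinite(pmf.std[inner])
        # flatness relative to the mean level (min-zeroing shifts all bins)
        dev = np.abs(pmf.F[inner][ok] - pmf.F[inner][ok].mean())
        assert np.all(dev <= 3 * pmf.std[inner][ok] + 1e-9)

    def test_harmonic_boltzmann_recovery(self):
        # exact Boltzmann samples from U = 0.5*kappa*x^2 are Gaussian with
        # variance kT/kappa
        kappa = 2.0
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, np.sqrt(KT / kappa), 200_000)
        pmf = histogram_pmf(x, bin_width=0.1, temperature=T)
        centers = pmf.centers()[0]
        analytic = 0.5 * kappa * centers**2
        analytic -= analytic.min()
        sel = np.isfinite(pmf.F) & (pmf.F < 3.0)
        rms = np.sqrt(np.mean((pmf.F[sel] - analytic[sel]) ** 2))
        assert rms < 0.1

    def test_single_sample(self):
        pmf = histogram_pmf(np.array([1.23]), bin_width=0.2, temperature=T, n_blocks=1)
        assert np.sum(np.isfinite(pmf.F)) == 1
        assert pmf.F[np.isfinite(pmf.F)][0] == 0.0

    def test_unsampled_bins_are_inf_not_zero(self):
        pmf = histogram_pmf(
            np.array([0.1, 0.1, 5.1]), bin_width=0.2, temperature=T,
            vrange=(0.0, 6.0), n_blocks=1,
        )
        assert np.isinf(pmf.F).any()
        assert np.isfinite(pmf.F).sum() == 2

    def test_empty_series_error(self):
        with pytest.raises(ValueError):
            histogram_pmf(np.array([]))

    def test_block_std_shrinks_with_samples(self):
        rng = np.random.default_rng(5)
        small = histogram_pmf(rng.normal(0, 1, 2_000), temperature=T)
        big = histogram_pmf(rng.normal(0, 1, 200_000), temperature=T)

        def med_std(p):
            s = p.std[np.isfinite(p.std) & np.isfinite(p.F) & (p.F < 2)]
            return np.median(s)

        assert med_std(big) < med_std(small)


class TestWham2D:
    def test_single_window_zero_bias_equals_histogram(self):
        rng = np.random.default_rng(2)
        samples = np.column_stack([rng.normal(0, 1, 20_000), rng.normal(0, 1, 20_000)])
        w = UmbrellaWindow(center=(0.0, 0.0), k=0.0, samples=samples, temperature=T)
        grid = wham2d([w], bin_width=(0.25, 0.25), n_blocks=0)
        # marginal consistency against the 2-D raw histogram PMF
        counts = grid.counts
        with np.errstate(divide="ignore"):
            F_ref = -KT * np.log(counts / counts.sum())
        F_ref[counts == 0] = np.inf
        F_ref -= F_ref[np.isfinite(F_ref)].min()
        sel = np.isfinite(grid.F)
        np.testing.assert_allclose(grid.F[sel], F_ref[sel], atol=1e-6)

    def test_single_biased_window_matches_reweighting(self):
        # closed form: unbiasing one window multiplies counts by
        # exp(+bias/kT), i.e. F = -kT ln(counts) - bias (up to a constant)
        rng = np.random.default_rng(3)
        k = 5.0
        samples = np.column_stack(
            [rng.normal(1.0, np.sqrt(KT / k), 50_000),
             rng.normal(-1.0, np.sqrt(KT / k), 50_000)]
        )
        w = UmbrellaWindow(center=(1.0, -1.0), k=k, samples=samples, temperature=T)
        grid = wham2d([w], bin_width=(0.2, 0.2), n_blocks=0)
        cx, cy = grid.centers()
        X, Y = np.meshgrid(cx, cy, indexing="ij")
        bias = 0.5 * k * ((X - 1.0) ** 2 + (Y + 1.0) ** 2)
        with np.errstate(divide="ignore"):
            F_ref = -KT * np.log(grid.counts / grid.counts.sum()) - bias
        F_ref[grid.counts == 0] = np.inf
        F_ref -= F_ref[np.isfinite(F_ref)].min()
        sel = np.isfinite(grid.F)
        np.testing.assert_allclose(grid.F[sel], F_ref[sel], atol=1e-5)

    def test_gauge_invariance(self):
        U = harmonic_2d(2.0, 2.0)
        wins = sample_umbrella(
            U, [(-1.0, 0.0), (0.0, 0.0), (1.0, 0.0)], k=5.0,
            n_per_window=4000, temperature=T, seed=4,
        )
        g0 = wham2d(wins, bin_width=(0.2, 0.2), n_blocks=0)
        g1 = wham2d(wins, bin_width=(0.2, 0.2), n_blocks=0,
                    f_init=np.full(3, 7.5))
        sel = np.isfinite(g0.F)
        np.testing.assert_allclose(g0.F[sel], g1.F[sel], atol=1e-5)

    def test_harmonic_recovery(self):
        kappa = 3.0
        U = harmonic_2d(kappa, kappa)
        centers = [(x, 0.0) for x in np.linspace(-1.5, 1.5, 7)]
        wins = sample_umbrella(U, centers, k=10.0, n_per_window=5000,
                               temperature=T, seed=6)
        grid = wham2d(wins, bin_width=(0.2, 0.2), n_blocks=0)
        cx, cy = grid.centers()
        iy = np.argmin(np.abs(cy))
        F = grid.F[:, iy]
        ref = 0.5 * kappa * cx**2
        sel = np.isfinite(F) & (ref < 2.5)
        assert np.sqrt(np.mean((F[sel] - (ref[sel] - ref[sel].min())) ** 2)) < 0.12

    def test_temperature_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        s = rng.normal(0, 1, (100, 2))
        w1 = UmbrellaWindow((0, 0), 1.0, s, temperature=300.0)
        w2 = UmbrellaWindow((0, 0), 1.0, s, temperature=310.0)
        with pytest.raises(ValueError):
            wham2d([w1, w2])

    def test_disconnected_windows_warn(self):
        rng = np.random.default_rng(1)
        w1 = UmbrellaWindow((0, 0), 50.0,
                            np.column_stack([rng.normal(0, 0.05, 500),
                                             rng.normal(0, 0.05, 500)]),
                            temperature=T)
        w2 = UmbrellaWindow((30, 30), 50.0,
                            np.column_stack([rng.normal(30, 0.05, 500),
                                             rng.normal(30, 0.05, 500)]),
                            temperature=T)
        with pytest.warns(UserWarning, match="overlap"):
            wham2d([w1, w2], bin_width=(0.5, 0.5), n_blocks=0)


def _grid_from_F(F, edges_x, kT=KT):
    F = np.asarray(F, dtype=float)
    return PMFGrid(
        edges=(np.asarray(edges_x),),
        F=F - F[np.isfinite(F)].min(),
        std=np.zeros_like(F),
        counts=np.ones_like(F, dtype=np.int64),
        kT=kT,
    )


class TestLowEnergyConformers:
    def test_threshold_zero_gives_minimum_bin(self):
        grid = _grid_from_F([2.0, 0.0, 1.5], [0.0, 1.0, 2.0, 3.0])
        frames = np.array([0.5, 1.5, 2.5, 1.2])
        sel = low_energy_conformers(grid, frames, threshold=0.0)
        assert sel.tolist() == [1, 3]

    def test_threshold_above_max_selects_all(self):
        grid = _grid_from_F([2.0, 0.0, 1.5], [0.0, 1.0, 2.0, 3.0])
        frames = np.array([0.5, 1.5, 2.5])
        sel = low_energy_conformers(grid, frames, threshold=10.0)
        assert sel.tolist() == [0, 1, 2]

    def test_two_basin_selection(self):
        # basins at 0 and 0.8 with a 2.0 barrier between them
        grid = _grid_from_F([0.0, 2.0, 0.8], [0.0, 1.0, 2.0, 3.0])
        frames = np.array([0.2, 1.5, 2.9, 0.9])
        sel = low_energy_conformers(grid, frames, threshold=1.0)
        assert sel.tolist() == [0, 2, 3]

    def test_empty_selection_warns(self):
        grid = _grid_from_F([0.0, 2.0], [0.0, 1.0, 2.0])
        with pytest.warns(UserWarning):
            sel = low_energy_conformers(grid, np.array([1.5]), threshold=0.5)
        assert sel.size == 0

    def test_2d_frame_selection(self):
        rng = np.random.default_rng(9)
        samples = np.column_stack([rng.normal(0, 0.5, 5000), rng.normal(0, 0.5, 5000)])
        w = UmbrellaWindow((0, 0), 0.0, samples, temperature=T)
        grid = wham2d([w], bin_width=(0.25, 0.25), n_blocks=0)
        sel = low_energy_conformers(grid, samples, threshold=0.5)
        r = np.linalg.norm(samples, axis=1)
        assert 0 < sel.size < len(samples)
        assert r[sel].mean() < r.mean()  # low-F frames cluster near the mode


class TestConditionalPMF:
    def test_always_true_reproduces_unconditioned(self):
        rng = np.random.default_rng(11)
        series = rng.normal(5, 1, 5000)
        with pytest.warns(UserWarning):
            p_true, p_false = conditional_pmf(
                series, np.ones(5000, bool), temperature=T
            )
        ref = histogram_pmf(series, bin_width=0.2, temperature=T)
        sel = np.isfinite(ref.F)
        np.testing.assert_allclose(p_true.F[sel], ref.F[sel], atol=1e-12)
        assert p_false is None

    def test_planted_correlation(self):
        # glycan distance small iff xi12 below the cut
        rng = np.random.default_rng(12)
        xi = rng.uniform(10, 20, 20_000)
        closed = xi < 14.0
        glycan = np.where(closed, rng.normal(4, 0.5, xi.size),
                          rng.normal(12, 0.5, xi.size))
        p_closed, p_open = conditional_pmf(
            glycan, closed, condition_name="closed", temperature=T
        )
        centers = p_closed.centers()[0]
        min_closed = centers[np.nanargmin(np.where(np.isfinite(p_closed.F), p_closed.F, np.nan))]
        min_open = centers[np.nanargmin(np.where(np.isfinite(p_open.F), p_open.F, np.nan))]
        assert min_closed < min_open

    def test_swapped_predicate_swaps_outputs(self):
        rng = np.random.default_rng(13)
        series = rng.normal(0, 1, 4000)
        cond = series > 0
        a_true, a_false = conditional_pmf(series, cond, temperature=T)
        b_true, b_false = conditional_pmf(series, ~cond, temperature=T)
        np.testing.assert_allclose(
            a_true.F[np.isfinite(a_true.F)], b_false.F[np.isfinite(b_false.F)]
        )

    def test_empty_true_stratum_errors(self):
        with pytest.raises(ValueError, match="mypred"):
            conditional_pmf(np.arange(5.0), np.zeros(5, bool), condition_name="mypred")
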