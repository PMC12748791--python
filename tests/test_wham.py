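"""WHAM: exact small cases, likelihood oracle, bootstrap behavior."""

import numpy as np
import pytest

from elevatorfep.beus import BEUSRun, ExchangeLog, UmbrellaWindow
from elevatorfep.common import kt
from elevatorfep.wham import (WHAMError, bootstrap_pmf,
                              integrated_autocorrelation_time, pmf_estimate,
                              wham_solve)

KT = kt(310.0)
BETA = 1.0 / KT


def gaussian_counts(k_land, k_bias, centers, bins, n_per_window):
    """Expected (noise-free) histogram counts for harmonic land + biases.

    The biased density of window i is the exact Gaussian
    N(mu_i, s2) with s2 = kT/(k_land + k_bias), mu_i = k_bias*c_i/(k_land+k_bias).
    """
    k_tot = k_land + k_bias
    s2 = KT / k_tot
    mids = 0.5 * (bins[:-1] + bins[1:])
    width = np.diff(bins)
    counts = np.empty((len(centers), len(mids)))
    for i, c in enumerate(centers):
        mu = k_bias * c / k_tot
        p = np.exp(-(mids - mu) ** 2 / (2 * s2))
        counts[i] = n_per_window * p / p.sum() * (width / width)
    return counts, mids


def analytic_window_free_energies(k_land, k_bias, centers):
    """f_i = -kT ln ∫ exp(-beta(k_land x²/2 + k_bias (x-c)²/2)) dx, rel f_0."""
    k_tot = k_land + k_bias
    f = 0.5 * (k_land * k_bias / k_tot) * np.asarray(centers) ** 2
    return f - f[0]


class TestWhamSolve:
    def test_single_window_degenerate_case(self):
        counts = np.array([[10.0, 40.0, 10.0]])
        bias = np.zeros_like(counts)
        f, p, _ = wham_solve(counts, bias, 310.0)
        assert f[0] == 0.0
        assert np.allclose(p, counts[0] / counts.sum())

    def test_two_identical_windows_equal_free_energy(self):
        counts = np.array([[5.0, 20.0, 5.0], [5.0, 20.0, 5.0]])
        bias = np.tile(np.array([1.0, 0.0, 1.0]), (2, 1))
        f, _, _ = wham_solve(counts, bias, 310.0)
        assert f[1] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("method", ["lbfgs", "direct"])
    def test_harmonic_landscape_matches_gaussian_closed_form(self, method):
        # noise-free expected counts: WHAM must recover the analytic window
        # free energies up to binning error
        k_land, k_bias = 2.0, 8.0
        centers = np.linspace(-1.5, 1.5, 7)
        bins = np.linspace(-3.2, 3.2, 321)
        counts, mids = gaussian_counts(k_land, k_bias, centers, bins, 10000)
        bias = 0.5 * k_bias * (mids[None, :] - centers[:, None]) ** 2
        f, _, _ = wham_solve(counts, bias, 310.0, method=method)
        expected = analytic_window_free_energies(k_land, k_bias, centers)
        assert np.abs(f - expected).max() < 1e-3

    def test_shift_invariance_of_pmf(self):
        k_land, k_bias = 2.0, 8.0
        centers = np.linspace(-1.0, 1.0, 5)
        bins = np.linspace(-2.5, 2.5, 161)
        counts, mids = gaussian_counts(k_land, k_bias, centers, bins, 5000)
        bias = 0.5 * k_bias * (mids[None, :] - centers[:, None]) ** 2
        _, p1, _ = wham_solve(counts, bias, 310.0)
        _, p2, _ = wham_solve(counts, bias + 7.3, 310.0)
        pmf1 = -KT * np.log(p1)
        pmf2 = -KT * np.log(p2)
        assert np.allclose(pmf1 - pmf1.min(), pmf2 - pmf2.min(), atol=1e-6)

    def test_direct_iteration_residual_monotone(self):
        k_land, k_bias = 2.0, 8.0
        centers = np.linspace(-1.0, 1.0, 5)
        bins = np.linspace(-2.5, 2.5, 101)
        counts, mids = gaussian_counts(k_land, k_bias, centers, bins, 5000)
        bias = 0.5 * k_bias * (mids[None, :] - centers[:, None]) ** 2
        _, _, resid = wham_solve(counts, bias, 310.0, method="direct",
                                 tol=1e-8)
        assert np.all(np.diff(resid) <= 1e-12)

    def test_disconnected_windows_rejected(self):
        counts = np.array([[10.0, 0.0, 0.0], [0.0, 0.0, 10.0]])
        bias = np.zeros_like(counts)
        with pytest.raises(WHAMError, match="disconnected"):
            wham_solve(counts, bias, 310.0)

    def test_brute_force_likelihood_oracle_small_problem(self):
        # 3 windows / 12 bins: grid-search the WHAM likelihood over
        # (f_1, f_2) and compare the maximizer with the solver
        k_land, k_bias = 1.5, 5.0
        centers = np.array([-0.8, 0.0, 0.8])
        bins = np.linspace(-2.2, 2.2, 13)
        counts, mids = gaussian_counts(k_land, k_bias, centers, bins, 3000)
        bias = 0.5 * k_bias * (mids[None, :] - centers[:, None]) ** 2
        n_i = counts.sum(axis=1)
        n_b = counts.sum(axis=0)

        def neg_loglik(f):
            denom = (n_i[:, None] * np.exp(BETA * (f[:, None] - bias))).sum(0)
            return (n_b * np.log(denom)).sum() - BETA * (n_i * f).sum()

        grid = np.linspace(-0.5, 1.5, 81)
        best, best_val = None, np.inf
        for f1 in grid:
            for f2 in grid:
                v = neg_loglik(np.array([0.0, f1, f2]))
                if v < best_val:
                    best, best_val = (f1, f2), v
        f, _, _ = wham_solve(counts, bias, 310.0)
        assert f[1] == pytest.approx(best[0], abs=0.025)
        assert f[2] == pytest.approx(best[1], abs=0.025)


def _synthetic_run(n_per_window, seed=0, k=8.0, centers=None):
    """BEUSRun whose samples are exact Gaussian draws (flat landscape)."""
    rng = np.random.default_rng(seed)
    if centers is None:
        centers = np.linspace(0.0, 3.0, 10)
    sig = np.sqrt(KT / k)
    windows = [UmbrellaWindow(i, i / (len(centers) - 1), [c], k)
               for i, c in enumerate(centers)]
    samples = [rng.normal(c, sig, (n_per_window, 1)) for c in centers]
    return BEUSRun(windows=windows, samples=samples, exchange_log=ExchangeLog())


class TestPmfEstimate:
    def test_flat_potential_profile_is_flat(self):
        run = _synthetic_run(4000, seed=1)
        prof = bootstrap_pmf(run, bins=60, n_boot=40, seed=2, min_count=100)
        ok = np.isfinite(prof.values) & (prof.sd > 0)
        dev = prof.values[ok] - np.median(prof.values[ok])
        assert np.all(np.abs(dev) < 3.5 * np.maximum(prof.sd[ok], 0.02))

    def test_sparse_bins_reported_as_gaps(self):
        run = _synthetic_run(50, seed=3, centers=np.array([0.0, 0.6, 1.2]))
        with pytest.warns(UserWarning, match="gaps"):
            prof = pmf_estimate(run, bins=np.linspace(-0.6, 1.8, 97),
                                min_count=5)
        assert np.isnan(prof.values).any()

    def test_double_well_barrier_recovered(self, double_well):
        # end-to-end: BEUS sampling + WHAM vs the analytic profile
        from elevatorfep.beus import run_beus, seed_windows
        from elevatorfep.toy_systems import analytic_pmf
        centers = np.linspace(-2.6, 2.6, 16)[:, None]
        wins = seed_windows(centers, 16, k=10.0)
        run = run_beus(double_well, wins, exchange_interval=100, n_sweeps=400,
                       dt=0.002, seed=5)
        prof = pmf_estimate(run, bins=70, temperature=310.0, min_count=100)
        ref = analytic_pmf(double_well, prof.bins)
        ok = np.isfinite(prof.values)
        err = prof.values[ok] - ref.values[ok]
        err -= err.mean()
        assert prof.barrier() == pytest.approx(5.0, abs=0.3)
        assert np.abs(err).max() < 0.3

    def test_coupled_vs_base_barrier_difference(self):
        # the substrate analog on the 1D well: recovered barriers differ by
        # the planted 3 kcal/mol
        from elevatorfep.beus import run_beus, seed_windows
        from elevatorfep.toy_systems import make_double_well
        barriers = {}
        for delta in (0.0, 3.0):
            m = make_double_well(5.0, 4.0, coupling_delta=delta)
            wins = seed_windows(np.linspace(-2.6, 2.6, 16)[:, None], 16, 10.0)
            run = run_beus(m, wins, exchange_interval=100, n_sweeps=400,
                           dt=0.002, seed=8)
            barriers[delta] = pmf_estimate(run, bins=70, min_count=100).barrier()
        assert barriers[0.0] - barriers[3.0] == pytest.approx(3.0, abs=0.3)


class TestBootstrap:
    def test_zero_variance_samples_zero_sd(self):
        # every window reports the identical constant sample: nothing varies
        # under resampling, so the bootstrap SD must vanish
        windows = [UmbrellaWindow(i, i / 3, [1.0], 5.0) for i in range(4)]
        samples = [np.full((100, 1), 1.0) for _ in range(4)]
        run = BEUSRun(windows=windows, samples=samples,
                      exchange_log=ExchangeLog())
        with pytest.warns(UserWarning):
            prof = bootstrap_pmf(run, bins=np.linspace(0.5, 1.5, 5), n_boot=25,
                                 seed=1, min_count=1)
        ok = np.isfinite(prof.values)
        assert np.allclose(prof.sd[ok], 0.0, atol=1e-9)

    def test_sd_shrinks_as_inverse_sqrt_samples(self):
        # block bootstrap within windows: SD ~ n^-1/2 across four
        # sample-size doublings (well-sampled central bins)
        bins = np.linspace(-0.5, 3.5, 41)
        sds = []
        sizes = (500, 1000, 2000, 4000, 8000)
        for n in sizes:
            run = _synthetic_run(n, seed=12345)
            prof = bootstrap_pmf(run, bins=bins, n_boot=100, seed=7,
                                 mode="block", block_length=25)
            central = (prof.bins > 0.2) & (prof.bins < 2.8)
            sds.append(np.nanmean(prof.sd[central]))
        slope = np.polyfit(np.log(sizes), np.log(sds), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.12)

    def test_bootstrap_mean_consistent_with_point_estimate(self):
        run = _synthetic_run(2000, seed=9)
        prof, resamples = bootstrap_pmf(run, bins=40, n_boot=60, seed=3,
                                        return_resamples=True)
        boot_mean = np.nanmean(resamples, axis=0)
        ok = np.isfinite(prof.values) & (prof.sd > 1e-12)
        within = np.abs(boot_mean[ok] - prof.values[ok]) <= prof.sd[ok]
        assert within.mean() >= 0.9

    def test_few_resamples_warns(self):
        run = _synthetic_run(200, seed=2)
        with pytest.warns(UserWarning, match="bootstrap"):
            bootstrap_pmf(run, bins=30, n_boot=10, seed=1)


def test_integrated_autocorrelation_time_of_ou_series():
    # AR(1) with coefficient a has IACT = (1+a)/(1-a)
    rng = np.random.default_rng(4)
    a = 0.8
    x = np.empty(200000)
    x[0] = 0.0
    noise = rng.normal(0, 1, len(x))
    for i in range(1, len(x)):
        x[i] = a * x[i - 1] + noise[i]
    tau = integrated_autocorrelation_time(x)
    assert tau == pytest.approx((1 + a) / (1 - a), rel=0.15)
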