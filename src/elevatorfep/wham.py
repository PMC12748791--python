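"""Weighted histogram analysis method (WHAM) with bootstrap errors.

Combines the biased per-window histograms of a BEUS run into an unbiased
free-energy profile along the path coordinate (or the CV itself in 1D).
The window free energies f_i solve the standard self-consistent equations

    p_b = ( Σ_i n_ib ) / ( Σ_i N_i exp(beta (f_i - U_ib)) )
    f_i = -kT ln Σ_b p_b exp(-beta U_ib)

iterated until max|Δf| < tol with f_0 = 0.  Uncertainties come from
bootstrap resampling across windows (block bootstrap within windows is
available as an option).
"""

from __future__ import annotations

import warnings

import numpy as np

from .common import PMFProfile, kt, spawn_seeds
from .beus import BEUSRun, project_to_path

__all__ = ["wham_solve", "pmf_estimate", "bootstrap_pmf",
           "integrated_autocorrelation_time"]


class WHAMError(RuntimeError):
    pass


def _check_connected(counts: np.ndarray) -> None:
    """Windows must form a connected chain through shared occupied bins."""
    k = len(counts)
    occupied = counts > 0
    adj = [[j for j in range(k) if j != i and np.any(occupied[i] & occupied[j])]
           for i in range(k)]
    seen = {0}
    stack = [0]
    while stack:
        for j in adj[stack.pop()]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    if len(seen) != k:
        missing = sorted(set(range(k)) - seen)
        raise WHAMError(f"histogram graph is disconnected: windows {missing} "
                        "share no occupied bins with window 0's component")


def _direct_update(f, log_ni, n_b, bias, beta):
    """One self-consistent WHAM iteration; returns (f_new, log_p)."""
    a = log_ni[:, None] + beta * (f[:, None] - bias)
    amax = a.max(axis=0)
    denom = amax + np.log(np.exp(a - amax).sum(axis=0))
    with np.errstate(divide="ignore"):
        log_p = np.where(n_b > 0, np.log(np.maximum(n_b, 1e-300)) - denom, -np.inf)
    b = log_p[None, :] - beta * bias
    bmax = b.max(axis=1)
    f_new = -(bmax + np.log(np.exp(b - bmax[:, None]).sum(axis=1))) / beta
    return f_new - f_new[0], log_p


def wham_solve(counts: np.ndarray, bias_energies: np.ndarray,
               temperature: float, tol: float = 1e-6, max_iter: int = 100000,
               check_connectivity: bool = True, f0: np.ndarray | None = None,
               method: str = "lbfgs"):
    """Solve the WHAM equations.

    ``counts``: (K, B) histogram counts per window; ``bias_energies``:
    (K, B) bias energy of window i evaluated at bin center b, kcal/mol.
    ``method='lbfgs'`` minimizes the convex WHAM log-likelihood directly
    (fast); ``method='direct'`` uses classic self-consistent iteration,
    whose residual decreases monotonically.  Either way the solution is
    polished by direct iteration until max|Δf| < tol.  Returns (f (K,)
    window free energies with f[0] = 0, p (B,) unbiased bin probabilities,
    residual history of the polishing iterations).
    """
    counts = np.asarray(counts, dtype=float)
    bias = np.asarray(bias_energies, dtype=float)
    if counts.shape != bias.shape:
        raise ValueError("counts and bias_energies must have identical shape")
    if check_connectivity and len(counts) > 1:
        _check_connected(counts)
    beta = 1.0 / kt(temperature)
    n_i = counts.sum(axis=1)
    n_b = counts.sum(axis=0)
    k = len(counts)
    f = np.zeros(k) if f0 is None else np.asarray(f0, dtype=float).copy()
    f = f - f[0]
    log_ni = np.where(n_i > 0, np.log(np.maximum(n_i, 1e-300)), -np.inf)

    if method == "lbfgs" and k > 1:
        from scipy.optimize import minimize

        def objective(x):
            ff = np.concatenate([[0.0], x])
            a = log_ni[:, None] + beta * (ff[:, None] - bias)
            amax = a.max(axis=0)
            lse = amax + np.log(np.exp(a - amax).sum(axis=0))
            obj = float((n_b * lse).sum() - beta * (n_i * ff).sum())
            w = np.exp(a - lse[None, :])          # (K, B) window weights
            grad = beta * ((n_b[None, :] * w).sum(axis=1) - n_i)
            return obj, grad[1:]

        res = minimize(objective, f[1:], jac=True, method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9})
        f = np.concatenate([[0.0], res.x])
    elif method not in ("lbfgs", "direct"):
        raise ValueError("method must be 'lbfgs' or 'direct'")

    resid = []
    for _ in range(int(max_iter)):
        f_new, log_p = _direct_update(f, log_ni, n_b, bias, beta)
        r = float(np.abs(f_new - f).max())
        resid.append(r)
        f = f_new
        if r < tol:
            p = np.exp(log_p)
            return f, p / p.sum(), np.array(resid)
    raise WHAMError(f"WHAM did not converge in {max_iter} iterations; "
                    f"last residual {resid[-1]:.3g} kcal/mol")


def _window_histograms(run: BEUSRun, bins: np.ndarray, stride: int = 1):
    """Histogram each window's samples on common bins of the path coordinate
    (or the raw CV in 1D), plus bias energies at bin centers."""
    edges = np.asarray(bins, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    k = len(run.windows)
    counts = np.empty((k, len(centers)))
    bias = np.empty((k, len(centers)))
    one_d = len(run.windows[0].center) == 1 and run.path is None
    if one_d:
        coords = centers[:, None]
    else:
        if run.path is None:
            raise ValueError("a path polyline is required for multi-D runs")
        from .beus import path_point
        coords = path_point(run.path, centers)
    for i, (w, samp) in enumerate(zip(run.windows, run.samples)):
        samp = samp[::stride]
        if one_d:
            vals = samp[:, 0]
        else:
            vals = project_to_path(samp, run.path)
        counts[i], _ = np.histogram(vals, bins=edges)
        bias[i] = w.bias_energy(coords)
    return counts, bias, centers


def pmf_estimate(run: BEUSRun, bins: np.ndarray | int = 100,
                 temperature: float | None = None, tol: float = 1e-6,
                 max_iter: int = 100000, min_count: int = 5,
                 stride: int = 1) -> PMFProfile:
    """Unbiased PMF from a BEUS run, zero at its minimum.

    ``bins`` may be explicit edges or a bin count over the sampled range.
    Bins inside the sampled range with fewer than ``min_count`` total
    samples are reported as gaps (NaN), never interpolated silently.
    """
    from .common import DEFAULT_TEMPERATURE
    temperature = DEFAULT_TEMPERATURE if temperature is None else temperature
    if np.isscalar(bins):
        one_d = len(run.windows[0].center) == 1 and run.path is None
        if one_d:
            allv = np.concatenate([s[:, 0] for s in run.samples if len(s)])
        else:
            allv = np.concatenate([project_to_path(s, run.path)
                                   for s in run.samples if len(s)])
        bins = np.linspace(allv.min(), allv.max(), int(bins) + 1)
    counts, bias, centers = _window_histograms(run, bins, stride=stride)
    f, p, _ = wham_solve(counts, bias, temperature, tol=tol, max_iter=max_iter)
    total = counts.sum(axis=0)
    with np.errstate(divide="ignore"):
        pmf = -kt(temperature) * np.log(p)
    pmf[total < min_count] = np.nan
    if np.any(np.isnan(pmf[(total > 0)])):
        warnings.warn("bins with sparse sampling reported as gaps (NaN)")
    pmf = pmf - np.nanmin(pmf)
    return PMFProfile(bins=centers, values=pmf)


def bootstrap_pmf(run: BEUSRun, bins: np.ndarray | int = 100, n_boot: int = 50,
                  seed: int = 0, temperature: float | None = None,
                  mode: str = "window", block_length: int | None = None,
                  min_count: int = 5, stride: int = 1,
                  return_resamples: bool = False):
    """PMF with per-bin bootstrap SD.

    ``mode='window'`` resamples whole windows with replacement (the default,
    matching how per-window sampling noise dominates BEUS error bars);
    ``mode='block'`` resamples decorrelated blocks within each window.
    """
    from .common import DEFAULT_TEMPERATURE
    temperature = DEFAULT_TEMPERATURE if temperature is None else temperature
    if n_boot < 20:
        warnings.warn("fewer than 20 bootstrap resamples: SDs will be noisy")
    if len(run.windows) < 8 and mode == "window":
        warnings.warn("window bootstrap with <8 windows is unreliable")
    point = pmf_estimate(run, bins=bins, temperature=temperature,
                         min_count=min_count, stride=stride)
    edges = np.concatenate([
        [point.bins[0] - 0.5 * (point.bins[1] - point.bins[0])],
        0.5 * (point.bins[:-1] + point.bins[1:]),
        [point.bins[-1] + 0.5 * (point.bins[-1] - point.bins[-2])]])
    counts, bias, centers = _window_histograms(run, edges, stride=stride)
    n_win = len(run.windows)
    rng_seeds = spawn_seeds(seed, n_boot)
    profiles = np.full((n_boot, len(centers)), np.nan)
    f_point, _, _ = wham_solve(counts, bias, temperature)
    for b in range(n_boot):
        rng = np.random.default_rng(rng_seeds[b])
        if mode == "window":
            pick = rng.integers(0, n_win, n_win)
            c = counts[pick]
            u = bias[pick]
            f_init = f_point[pick] - f_point[pick][0]
        elif mode == "block":
            f_init = f_point
            if block_length is None:
                block_length = max(len(run.samples[0]) // 20, 1)
            c = np.empty_like(counts)
            u = bias
            for i, samp in enumerate(run.samples):
                nblk = max(len(samp) // block_length, 1)
                blocks = [samp[j * block_length:(j + 1) * block_length]
                          for j in range(nblk)]
                take = rng.integers(0, nblk, nblk)
                vals = np.concatenate([blocks[t] for t in take])
                if run.path is not None:
                    vv = project_to_path(vals, run.path)
                else:
                    vv = vals[:, 0]
                c[i], _ = np.histogram(vv, bins=edges)
        else:
            raise ValueError("mode must be 'window' or 'block'")
        try:
            _, p, _ = wham_solve(c, u, temperature, check_connectivity=False,
                                 f0=f_init)
        except WHAMError:
            continue
        with np.errstate(divide="ignore"):
            prof = -kt(temperature) * np.log(p)
        prof[c.sum(axis=0) < min_count] = np.nan
        profiles[b] = prof - np.nanmin(prof)
    sd = np.nanstd(profiles, axis=0, ddof=1)
    out = PMFProfile(bins=point.bins, values=point.values, sd=sd)
    if return_resamples:
        return out, profiles
    return out


def integrated_autocorrelation_time(series: np.ndarray, max_lag: int | None = None) -> float:
    """IACT in sampling intervals, by the initial-positive-sequence sum.

    Useful for choosing a decorrelation stride (block decimation) before
    histogramming.
    """
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    n = len(x)
    if n < 4 or np.allclose(x, 0):
        return 1.0
    if max_lag is None:
        max_lag = n // 4
    var = float(x @ x) / n
    tau = 1.0
    for lag in range(1, max_lag):
        c = float(x[:-lag] @ x[lag:]) / ((n - lag) * var)
        if c <= 0:
            break
        tau += 2.0 * c
    return float(tau)
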