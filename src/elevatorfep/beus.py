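"""Stage 3 — bias-exchange umbrella sampling (BEUS) along the refined path.

The refined string is segmented into umbrella windows at equal arc length;
each window restrains the system to its center (a point in normalized CV
space, or a scalar for a 1D landscape) with a harmonic bias.  At regular
intervals, restraint *centers* of adjacent windows are swapped by a
Metropolis criterion, alternating even/odd pairs — enhancing diffusion of
replicas along the path without perturbing the per-window equilibrium.
Samples are tagged by the center that was active when they were recorded,
which is what the WHAM stage needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .common import spawn_seeds
from .smwst import StringPath, polyline_arc_length, resample_polyline
from .toy_systems import PotentialModel

__all__ = ["UmbrellaWindow", "ExchangeLog", "BEUSRun", "seed_windows",
           "exchange_decision", "run_beus", "histogram_overlap",
           "project_to_path"]


@dataclass
class UmbrellaWindow:
    """One umbrella window: a harmonic bias centered on the path."""

    index: int
    s_center: float
    center: np.ndarray          # (D,) CV-space image of the center
    k: float

    def __post_init__(self):
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        if self.k <= 0:
            raise ValueError("force constant must be positive")

    def bias_energy(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        d = x - self.center
        if d.ndim == 1:
            return 0.5 * self.k * float(d @ d)
        return 0.5 * self.k * (d ** 2).sum(axis=-1)


@dataclass
class ExchangeLog:
    """Record of every swap attempt."""

    sweeps: list = field(default_factory=list)
    pairs: list = field(default_factory=list)
    deltas: list = field(default_factory=list)
    accepted: list = field(default_factory=list)
    draws: list = field(default_factory=list)

    def append(self, sweep, pair, delta, accepted, draw):
        self.sweeps.append(sweep)
        self.pairs.append(pair)
        self.deltas.append(delta)
        self.accepted.append(accepted)
        self.draws.append(draw)

    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted)) if self.accepted else float("nan")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# sweep\twin_i\twin_j\tdelta\taccepted\tdraw\n")
            for s, (i, j), d, a, u in zip(self.sweeps, self.pairs, self.deltas,
                                          self.accepted, self.draws):
                fh.write(f"{s}\t{i}\t{j}\t{d:.8g}\t{int(a)}\t{u:.8g}\n")


@dataclass
class BEUSRun:
    """Per-window CV samples plus bias parameters and the exchange log."""

    windows: list
    samples: list               # per window: (n_samples, D) arrays
    exchange_log: ExchangeLog
    path: np.ndarray | None = None   # polyline used for s-projection
    seed: int = 0

    @property
    def n_samples_total(self) -> int:
        return int(sum(len(s) for s in self.samples))


def seed_windows(path, n_windows: int, k: float) -> list[UmbrellaWindow]:
    """Windows at equal arc length along the refined path.

    ``path`` is a StringPath or an (N, D) polyline; initial configurations
    are the window centers themselves (nearest string images).
    """
    if n_windows < 2:
        raise ValueError("need at least 2 windows")
    pts = path.images if isinstance(path, StringPath) else np.asarray(path, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    centers = resample_polyline(pts, n_windows)
    s = np.linspace(0.0, 1.0, n_windows)
    return [UmbrellaWindow(index=i, s_center=float(s[i]), center=centers[i], k=k)
            for i in range(n_windows)]


def exchange_decision(window_i: UmbrellaWindow, window_j: UmbrellaWindow,
                      value_i, value_j, temperature: float, u: float):
    """Metropolis decision for swapping the centers of adjacent windows.

    Delta = beta * [U_i(x_j) + U_j(x_i) - U_i(x_i) - U_j(x_j)];
    accept iff u < min(1, exp(-Delta)).
    """
    from .common import kt
    beta = 1.0 / kt(temperature)
    delta = beta * (window_i.bias_energy(value_j) + window_j.bias_energy(value_i)
                    - window_i.bias_energy(value_i) - window_j.bias_energy(value_j))
    delta = float(delta)
    accept = bool(u < min(1.0, np.exp(-delta)))
    return accept, delta


def run_beus(model: PotentialModel, windows: list[UmbrellaWindow],
             exchange_interval: int = 100, n_sweeps: int = 100,
             dt: float = 2e-4, seed: int = 0, friction: float = 1.0,
             sample_stride: int = 5, equil_steps: int = 200,
             exchange: bool = True, path: np.ndarray | None = None) -> BEUSRun:
    """Interleave propagation and center-exchange sweeps.

    Each sweep propagates every replica for ``exchange_interval`` steps
    under its current center, recording samples every ``sample_stride``
    steps into the window owning that center, then attempts swaps over
    alternating even/odd adjacent pairs (center-swap semantics).  A single
    window, or ``exchange=False``, reduces to plain umbrella sampling.
    """
    n_win = len(windows)
    d = len(windows[0].center)
    k = np.array([w.k for w in windows], dtype=float)[:, None]  # follows the held center
    centers = np.array([w.center for w in windows])     # row r = center held by replica r
    win_of_replica = np.arange(n_win)                   # which window's center replica r holds
    x = centers.copy()
    rng = np.random.default_rng(seed)
    mu, kT = 1.0 / friction, model.kt
    noise = np.sqrt(2.0 * mu * kT * dt)
    guard = float(model.params.get("domain_guard", 1e6))
    beta = 1.0 / kT

    samples: list[list[np.ndarray]] = [[] for _ in range(n_win)]
    log = ExchangeLog()

    def propagate(steps, record):
        nonlocal x
        for step in range(steps):
            f = -model.gradient(x) - k * (x - centers)
            x = x + mu * dt * f + noise * rng.standard_normal(x.shape)
            if np.abs(x).max() > guard:
                raise RuntimeError("BEUS replica diverged; reduce dt")
            if record and (step + 1) % sample_stride == 0:
                for r in range(n_win):
                    samples[win_of_replica[r]].append(x[r].copy())

    propagate(equil_steps, record=False)
    low_acc_warned = False
    n_acc = n_att = 0
    for sweep in range(n_sweeps):
        propagate(exchange_interval, record=True)
        if not exchange or n_win < 2:
            continue
        replica_of_win = np.argsort(win_of_replica)
        start = sweep % 2
        for wi in range(start, n_win - 1, 2):
            ri, rj = replica_of_win[wi], replica_of_win[wi + 1]
            win_i, win_j = windows[wi], windows[wi + 1]
            u = float(rng.random())
            accept, delta = exchange_decision(win_i, win_j, x[ri], x[rj],
                                              model.temperature, u)
            log.append(sweep, (wi, wi + 1), delta, accept, u)
            n_att += 1
            if accept:
                n_acc += 1
                win_of_replica[ri], win_of_replica[rj] = (win_of_replica[rj],
                                                          win_of_replica[ri])
                centers[ri], centers[rj] = win_j.center, win_i.center
                k[ri, 0], k[rj, 0] = win_j.k, win_i.k
                replica_of_win = np.argsort(win_of_replica)
        if (not low_acc_warned) and n_att >= 100 and n_acc / n_att < 0.01:
            warnings.warn("swap acceptance below 1%; window spacing or force "
                          "constant gives poor overlap")
            low_acc_warned = True

    sample_arrays = [np.array(s) if s else np.empty((0, d)) for s in samples]
    return BEUSRun(windows=windows, samples=sample_arrays, exchange_log=log,
                   path=path, seed=seed)


def project_to_path(samples: np.ndarray, path: np.ndarray) -> np.ndarray:
    """Normalized arc-length coordinate s of each sample by nearest-point
    projection onto a piecewise-linear path.

    Samples lying beyond the path endpoints are projected onto the linear
    extension of the terminal segments (s < 0 or s > 1), so basin
    populations are not artificially piled onto the end bins.
    """
    pts = np.asarray(path, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    a, b = pts[:-1], pts[1:]
    ab = b - a
    seg_len2 = (ab ** 2).sum(axis=1)
    seg_len2[seg_len2 == 0] = 1.0
    arc = polyline_arc_length(pts)
    total = arc[-1]
    # (n_samples, n_segments) projections
    t = ((x[:, None, :] - a[None]) * ab[None]).sum(axis=2) / seg_len2[None]
    t_cl = np.clip(t, 0.0, 1.0)
    proj = a[None] + t_cl[..., None] * ab[None]
    d2 = ((proj - x[:, None, :]) ** 2).sum(axis=2)
    best = d2.argmin(axis=1)
    idx = np.arange(len(x))
    t_best = t_cl[idx, best]
    # unclamp on the terminal segments
    first, last = best == 0, best == len(a) - 1
    t_best = np.where(first & (t[idx, best] < 0), t[idx, best], t_best)
    t_best = np.where(last & (t[idx, best] > 1), t[idx, best], t_best)
    s_abs = arc[best] + t_best * np.sqrt(seg_len2[best])
    return s_abs / total


def path_point(path: np.ndarray, s) -> np.ndarray:
    """CV-space point at normalized arc length s, with linear extrapolation
    beyond the endpoints (inverse of :func:`project_to_path` on the path)."""
    pts = np.asarray(path, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    arc = polyline_arc_length(pts)
    s_nodes = arc / arc[-1]
    s = np.atleast_1d(np.asarray(s, dtype=float))
    out = np.column_stack([np.interp(s, s_nodes, pts[:, j])
                           for j in range(pts.shape[1])])
    lo, hi = s < 0, s > 1
    if lo.any():
        d0 = (pts[1] - pts[0]) / (s_nodes[1] - s_nodes[0])
        out[lo] = pts[0] + np.outer(s[lo], d0)
    if hi.any():
        d1 = (pts[-1] - pts[-2]) / (s_nodes[-1] - s_nodes[-2])
        out[hi] = pts[-1] + np.outer(s[hi] - 1.0, d1)
    return out


def histogram_overlap(run: BEUSRun, bins: np.ndarray,
                      coordinate: int | str = 0, threshold: float = 0.05):
    """Pairwise Σ_b min(p_i, p_j) overlap matrix of window histograms.

    ``coordinate`` selects a CV index, or "s" to project onto the run's
    path.  Returns (matrix, list of adjacent pairs below ``threshold``).
    """
    n = len(run.windows)
    hists = []
    for s in run.samples:
        if len(s) == 0:
            raise ValueError("empty window: no samples to histogram")
        vals = project_to_path(s, run.path) if coordinate == "s" else s[:, coordinate]
        h, _ = np.histogram(vals, bins=bins)
        hists.append(h / h.sum())
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            mat[i, j] = np.minimum(hists[i], hists[j]).sum()
    poor = [(i, i + 1) for i in range(n - 1) if mat[i, i + 1] < threshold]
    return mat, poor
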