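"""Stage 2 — string method with swarms of trajectories (SMwST).

The driven transition trace is resampled into N equidistant images in
normalized CV space.  Each refinement cycle anchors M replicas to every
image with a harmonic restraint, releases them for a short free stage, and
moves each image by the mean replica drift; the string is then smoothed and
reparametrized to equal arc length with fixed endpoints.  Iterating drives
the string toward the minimum free-energy path (MFEP), whose
zero-temperature limit is also computed here by an entirely independent
route (saddle search + steepest-descent integration) for validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .common import spawn_seeds
from .toy_systems import PotentialModel

__all__ = ["StringPath", "SwarmConfig", "initialize_string", "run_swarm_cycle",
           "run_smwst", "smooth_string", "reparametrize_string",
           "string_convergence", "mean_string", "steepest_descent_mfep",
           "polyline_arc_length", "resample_polyline", "point_polyline_distance"]


# --------------------------------------------------------------------------
# Polyline helpers
# --------------------------------------------------------------------------

def polyline_arc_length(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length along a polyline, starting at 0."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """n points at equal arc length along a piecewise-linear curve."""
    arc = polyline_arc_length(points)
    if arc[-1] <= 0:
        raise ValueError("degenerate (zero-length) curve")
    targets = np.linspace(0.0, arc[-1], n)
    out = np.empty((n, points.shape[1]))
    for j in range(points.shape[1]):
        out[:, j] = np.interp(targets, arc, points[:, j])
    return out


def point_polyline_distance(point: np.ndarray, polyline: np.ndarray) -> float:
    """Euclidean distance from a point to a piecewise-linear curve."""
    p = np.asarray(point, dtype=float)
    a, b = polyline[:-1], polyline[1:]
    ab = b - a
    denom = (ab ** 2).sum(axis=1)
    denom[denom == 0] = 1.0
    t = np.clip(((p - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.sqrt(((proj - p) ** 2).sum(axis=1)).min())


# --------------------------------------------------------------------------
# String containers
# --------------------------------------------------------------------------

@dataclass
class StringPath:
    """Ordered images in normalized CV space with per-cycle history."""

    images: np.ndarray
    cycle: int = 0
    history: list = field(default_factory=list)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if len(self.images) < 3:
            raise ValueError("a string needs at least 3 images")

    @property
    def n_images(self) -> int:
        return len(self.images)

    def arc_length(self) -> float:
        return float(polyline_arc_length(self.images)[-1])

    def write_tsv(self, path) -> None:
        """Persist the full history, one tab-separated block per cycle."""
        with open(path, "w") as fh:
            fh.write("# cycle\timage\t" +
                     "\t".join(f"cv{i}" for i in range(self.images.shape[1])) + "\n")
            for c, imgs in enumerate(self.history + [self.images]):
                for i, row in enumerate(imgs):
                    fh.write(f"{c}\t{i}\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


@dataclass
class SwarmConfig:
    """Protocol constants for one SMwST run.

    Defaults reproduce the protocol shape of the workflow this package
    emulates: 32 images, 24 swarm replicas per image, 200 cycles, with a
    restrained anchoring stage followed by a free drift stage each cycle
    (toy time units stand in for the 10 ps + 10 ps stages).
    """

    n_replicas: int = 24
    t_restrained: float = 4e-3
    t_free: float = 2e-3
    k_restraint: float = 1000.0
    smoothing: float = 0.1
    n_cycles: int = 200
    dt: float = 2e-4
    seed: int = 0
    drift_statistic: str = "mean"   # or "median", robust option

    def __post_init__(self):
        if self.n_replicas < 1:
            raise ValueError("need at least one replica per image")
        if not (0.0 <= self.smoothing < 1.0):
            raise ValueError("smoothing weight must be in [0, 1)")
        if self.t_restrained <= 0 or self.t_free <= 0:
            raise ValueError("stage durations must be positive")


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def initialize_string(cv_series: np.ndarray, n_images: int = 32,
                      smooth_window: int = 11) -> StringPath:
    """Images at equal arc length along a (smoothed) driven CV trace.

    The raw trace is lightly smoothed with a moving average before
    resampling; traces that backtrack in arc length are handled by the
    resampling itself (a warning is emitted).
    """
    series = np.asarray(cv_series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    if smooth_window > 1 and len(series) > 2 * smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        sm = np.column_stack([
            np.convolve(series[:, j], kernel, mode="valid")
            for j in range(series.shape[1])])
        sm = np.vstack([series[:1], sm, series[-1:]])
    else:
        sm = series
    seg = np.linalg.norm(np.diff(sm, axis=0), axis=1)
    if np.any(seg <= 0):
        warnings.warn("CV trace is not strictly monotone in arc length; "
                      "resampling by arc length")
        keep = np.concatenate([[True], seg > 0])
        sm = sm[keep]
    return StringPath(images=resample_polyline(sm, n_images))


def smooth_string(string: StringPath, s: float) -> StringPath:
    """Neighbor-average smoothing of interior images; endpoints untouched.

    x_i <- (1-s) x_i + (s/2)(x_{i-1} + x_{i+1}).
    """
    if not (0.0 <= s < 1.0):
        raise ValueError("smoothing weight must be in [0, 1)")
    img = string.images.copy()
    img[1:-1] = (1.0 - s) * img[1:-1] + 0.5 * s * (img[:-2] + img[2:])
    return StringPath(images=img, cycle=string.cycle, history=string.history)


def reparametrize_string(string: StringPath) -> StringPath:
    """Redistribute images to equal arc length; endpoints fixed."""
    img = resample_polyline(string.images, string.n_images)
    return StringPath(images=img, cycle=string.cycle, history=string.history)


def run_swarm_cycle(string: StringPath, model: PotentialModel,
                    cfg: SwarmConfig, rng: np.random.Generator | None = None,
                    fixed_endpoints: bool = True):
    """One SMwST cycle; returns (updated string, diagnostics dict).

    Per image: M replicas are restrained to the image center for
    ``t_restrained``, then run free for ``t_free``; the image moves by the
    swarm-mean (or median) drift, then smoothing and reparametrization are
    applied.  Diverged replicas are dropped and counted; >50% dropped for
    any image is an error.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_img, d = string.images.shape
    m = cfg.n_replicas
    mu, kT = 1.0, model.kt
    dt = cfg.dt
    guard = float(model.params.get("domain_guard", 1e6))

    centers = np.repeat(string.images, m, axis=0)       # (n_img*m, d)
    x = centers.copy()
    noise = np.sqrt(2.0 * mu * kT * dt)
    n_res = max(int(round(cfg.t_restrained / dt)), 1)
    n_free = max(int(round(cfg.t_free / dt)), 1)
    for _ in range(n_res):
        f = -model.gradient(x) - cfg.k_restraint * (x - centers)
        x = x + mu * dt * f + noise * rng.standard_normal(x.shape)
    for _ in range(n_free):
        x = x - mu * dt * model.gradient(x) + noise * rng.standard_normal(x.shape)

    disp = (x - centers).reshape(n_img, m, d)
    ok = np.all(np.abs(x.reshape(n_img, m, d)) <= guard, axis=2)
    dropped = int((~ok).sum())
    if np.any(ok.sum(axis=1) < m / 2):
        raise RuntimeError("more than half of the swarm replicas diverged")
    if cfg.drift_statistic == "median":
        drift = np.array([np.median(disp[i][ok[i]], axis=0) for i in range(n_img)])
    else:
        drift = np.array([disp[i][ok[i]].mean(axis=0) for i in range(n_img)])

    new = string.images + drift
    if fixed_endpoints:
        new[0], new[-1] = string.images[0], string.images[-1]
    updated = StringPath(images=new, cycle=string.cycle + 1,
                         history=string.history + [string.images.copy()])
    updated = smooth_string(updated, cfg.smoothing)
    updated = reparametrize_string(updated)
    diag = {"rms_drift": float(np.sqrt((drift ** 2).sum(axis=1).mean())),
            "drift": drift, "dropped_replicas": dropped}
    return updated, diag


def run_smwst(string: StringPath, model: PotentialModel, cfg: SwarmConfig,
              fixed_endpoints: bool = True) -> StringPath:
    """Run ``cfg.n_cycles`` refinement cycles with per-cycle child seeds."""
    seeds = spawn_seeds(cfg.seed, cfg.n_cycles)
    s = string
    for c in range(cfg.n_cycles):
        s, _ = run_swarm_cycle(s, model, cfg,
                               rng=np.random.default_rng(seeds[c]),
                               fixed_endpoints=fixed_endpoints)
    return s


def string_convergence(history: list[np.ndarray], threshold: float | None = None,
                       window: int = 10):
    """Per-cycle RMS image displacement between consecutive strings.

    Returns (rms series, converged_cycle) where converged_cycle is the first
    cycle index after which the RMS stays below ``threshold`` for ``window``
    consecutive cycles (None if never, or if no threshold given).
    """
    if len(history) < 2:
        raise ValueError("need at least two cycles of history")
    arr = np.asarray(history, dtype=float)
    disp = np.diff(arr, axis=0)
    rms = np.sqrt((disp ** 2).sum(axis=2).mean(axis=1))
    converged_cycle = None
    if threshold is not None:
        below = rms < threshold
        for i in range(len(below) - window + 1):
            if below[i:i + window].all():
                converged_cycle = i + 1
                break
    return rms, converged_cycle


def mean_string(history: list[np.ndarray], last_k: int = 50) -> np.ndarray:
    """Cycle-averaged string over the trailing ``last_k`` cycles.

    Averaging the converged portion suppresses the finite-swarm image
    jitter (the standard way converged strings are reported).
    """
    arr = np.asarray(history[-last_k:], dtype=float)
    return arr.mean(axis=0)


# --------------------------------------------------------------------------
# Independent zero-temperature MFEP oracle
# --------------------------------------------------------------------------

def steepest_descent_mfep(model: PotentialModel, n_points: int = 200,
                          ds: float = 1e-3) -> np.ndarray:
    """Zero-temperature MFEP by saddle search + steepest descent.

    Finds the index-1 saddle by minimizing |grad U|² from the construction's
    saddle guess, then integrates dx/dl = -grad U / |grad U| from tiny
    displacements along the unstable Hessian direction down to each basin.
    Shares no code with the swarm iteration; used to validate it.
    """
    from scipy.optimize import minimize

    guess = np.asarray(model.params["saddle"], dtype=float)

    def gsq(x):
        g = np.asarray(model.gradient(x), dtype=float)
        return float(g @ g)

    res = minimize(gsq, guess, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-18, "maxiter": 20000})
    saddle = res.x
    d = len(saddle)
    # numeric Hessian
    h = 1e-5
    hess = np.empty((d, d))
    for i in range(d):
        e = np.zeros(d)
        e[i] = h
        hess[:, i] = (np.asarray(model.gradient(saddle + e))
                      - np.asarray(model.gradient(saddle - e))) / (2 * h)
    hess = 0.5 * (hess + hess.T)
    w, v = np.linalg.eigh(hess)
    unstable = v[:, np.argmin(w)]

    def descend(x0):
        # fixed-step normalized-gradient descent, halving the step on
        # energy overshoot so the path terminates cleanly at the minimum
        pts = [x0.copy()]
        x = x0.copy()
        step = ds
        e = float(model.energy(x))
        for _ in range(200000):
            g = np.asarray(model.gradient(x), dtype=float)
            norm = np.linalg.norm(g)
            if norm < 1e-9 or step < 1e-8:
                break
            xn = x - step * g / norm
            en = float(model.energy(xn))
            if en >= e:
                step *= 0.5
                continue
            x, e = xn, en
            pts.append(x.copy())
        return np.array(pts)

    eps = 10 * ds
    branch_a = descend(saddle - eps * unstable)[::-1]
    branch_b = descend(saddle + eps * unstable)
    path = np.vstack([branch_a, saddle[None, :], branch_b])
    # orient from first basin to last
    basins = np.atleast_2d(model.params["basins"]).astype(float)
    if np.linalg.norm(path[0] - basins[0]) > np.linalg.norm(path[-1] - basins[0]):
        path = path[::-1]
    return resample_polyline(path, n_points)
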