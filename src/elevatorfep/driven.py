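"""Stage 1 — steered transitions along the elevator CVs.

A moving harmonic restraint drags the system from the OF basin to the IF
basin under one of three protocols (rotation first, translation first, or
both simultaneously), followed by a release stage in which the force
constants ramp linearly to zero.  The nonequilibrium work accumulated by
each moving restraint is integrated on the fly; comparing mean work across
protocols identifies the most efficient drive (simultaneous, for a
landscape whose saddle lies on the diagonal of CV space).

All dynamics run on the normalized-CV landscapes of
:mod:`elevatorfep.toy_systems`; positions ARE the CV values there, so the
restraints act directly on the coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .common import spawn_seeds
from .toy_systems import PotentialModel, Trajectory

__all__ = ["DriveProtocol", "DrivenResult", "run_smd", "compare_protocols",
           "release_and_equilibrate", "relaxation_time"]

MODES = ("rotation_then_translation", "translation_then_rotation", "simultaneous")


def relaxation_time(model: PotentialModel, friction: float = 1.0,
                    mass: float = 1.0) -> float:
    """Basin relaxation time 1/(mu * k_curv) from numeric curvature at the
    first basin minimum (ps)."""
    x0 = np.atleast_2d(model.params["basins"])[0].astype(float)
    h = 1e-4
    d = len(x0)
    curv = 0.0
    for i in range(d):
        e = np.zeros(d)
        e[i] = h
        curv = max(curv, (float(model.energy(x0 + e)) - 2 * float(model.energy(x0))
                          + float(model.energy(x0 - e))) / h ** 2)
    mu = 1.0 / (friction * mass)
    return 1.0 / (mu * curv)


@dataclass
class DriveProtocol:
    """Schedule for driving both CVs from their OF to their IF values.

    ``mode`` selects the ordering; sequential modes split the drive time
    50/50 between the two CVs.  ``k`` is per normalized CV unit squared.
    ``duration`` defaults (in :func:`run_smd`) to 500 basin relaxation
    times, with the release stage half the drive — mirroring the 2:1
    drive/release ratio of the workflow this emulates.
    """

    mode: str = "simultaneous"
    duration: float | None = None
    release_duration: float | None = None
    k: float = 500.0
    dt: float = 2e-4
    tolerance_frac: float = 0.05

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("duration must be positive")

    def center_schedule(self, n_steps: int, start: np.ndarray,
                        target: np.ndarray) -> np.ndarray:
        """Per-step restraint centers, shape (n_steps + 1, D)."""
        frac = np.linspace(0.0, 1.0, n_steps + 1)
        d = len(start)
        centers = np.empty((n_steps + 1, d))
        if self.mode == "simultaneous":
            prog = np.tile(frac[:, None], (1, d))
        else:
            # CV index 0 = translation (u), 1 = rotation (v)
            first = 1 if self.mode == "rotation_then_translation" else 0
            second = 1 - first
            prog = np.zeros((n_steps + 1, d))
            prog[:, first] = np.clip(2 * frac, 0, 1)
            prog[:, second] = np.clip(2 * frac - 1, 0, 1)
        for i in range(d):
            centers[:, i] = start[i] + prog[:, i] * (target[i] - start[i])
        return centers


@dataclass
class DrivenResult:
    """Output of one steered run (possibly many replicas)."""

    cv_series: np.ndarray          # (T, n_reps, D) recorded positions
    times: np.ndarray
    centers: np.ndarray            # (T, D) restraint centers at record times
    work: np.ndarray               # (T, n_reps, D) cumulative per-CV work
    final_cv: np.ndarray           # (n_reps, D) after release
    converged: np.ndarray          # (n_reps,) bool, end of drive vs target
    release_series: np.ndarray | None = None
    seed: int = 0

    @property
    def total_work(self) -> np.ndarray:
        """Final accumulated work per replica (summed over CVs), kcal/mol."""
        return self.work[-1].sum(axis=1)


def _drive_loop(model, x, centers, k_vec, dt, friction, rng, stride, k_ramp=None):
    """Core SMD loop: harmonic restraint with per-step centers (and optional
    per-step force-constant ramp); trapezoid work accumulation per CV."""
    mu = 1.0 / friction
    kT = model.kt
    noise = np.sqrt(2.0 * mu * kT * dt)
    guard = float(model.params.get("domain_guard", 1e6))
    n_steps = len(centers) - 1
    n, d = x.shape
    w = np.zeros((n, d))
    recs, works = [x.copy()], [w.copy()]
    for step in range(n_steps):
        kk = k_vec if k_ramp is None else k_vec * k_ramp[step]
        f = -model.gradient(x) - kk * (x - centers[step])
        xn = x + mu * dt * f
        if noise > 0:
            xn = xn + noise * rng.standard_normal(x.shape)
        if np.abs(xn).max() > guard:
            raise RuntimeError(f"driven trajectory diverged at step {step}; dt={dt:g}")
        dc = centers[step + 1] - centers[step]
        dev0 = centers[step] - x
        dev1 = centers[step + 1] - xn
        w = w + kk * 0.5 * (dev0 + dev1) * dc
        x = xn
        if (step + 1) % stride == 0:
            recs.append(x.copy())
            works.append(w.copy())
    return x, w, np.array(recs), np.array(works)


def run_smd(model: PotentialModel, protocol: DriveProtocol, seed: int = 0,
            n_reps: int = 1, friction: float = 1.0, stride: int = 20,
            start: np.ndarray | None = None,
            target: np.ndarray | None = None) -> DrivenResult:
    """Drive the system from the OF basin to the IF basin.

    After the drive, force constants ramp linearly to zero over the release
    stage with centers held at the target.  Non-convergence (drive endpoint
    further than ``tolerance_frac`` of the OF→IF span from the target) is
    reported per replica in ``converged``, never silently.
    """
    basins = np.atleast_2d(model.params["basins"]).astype(float)
    start = basins[0] if start is None else np.asarray(start, dtype=float)
    target = basins[-1] if target is None else np.asarray(target, dtype=float)
    d = len(start)

    duration = protocol.duration
    if duration is None:
        duration = 500.0 * relaxation_time(model, friction)
    release = protocol.release_duration
    if release is None:
        release = 0.5 * duration
    dt = protocol.dt
    n_drive = max(int(round(duration / dt)), 10)
    n_rel = max(int(round(release / dt)), 1)

    rng = np.random.default_rng(seed)
    x = np.tile(start, (n_reps, 1))
    centers = protocol.center_schedule(n_drive, start, target)
    k_vec = np.full(d, float(protocol.k))

    x, w, recs, works = _drive_loop(model, x, centers, k_vec, dt, friction,
                                    rng, stride)
    span = np.linalg.norm(target - start)
    # convergence judged on the time-averaged CVs over the drive tail, so
    # thermal fluctuations of a single end frame do not flag a converged run
    tail = recs[-max(len(recs) // 20, 1):].mean(axis=0)
    converged = np.linalg.norm(tail - target, axis=1) <= protocol.tolerance_frac * span
    if not converged.all():
        warnings.warn(f"{(~converged).sum()}/{n_reps} replicas did not reach "
                      f"the target CVs within {protocol.tolerance_frac:.0%} of the span")

    # release: centers fixed at target, k ramps to zero
    rel_centers = np.tile(target, (n_rel + 1, 1))
    ramp = np.linspace(1.0, 0.0, n_rel)
    x, _w2, rel_recs, _ = _drive_loop(model, x, rel_centers, k_vec, dt, friction,
                                      rng, stride, k_ramp=ramp)
    times = np.arange(len(recs)) * dt * stride
    return DrivenResult(cv_series=recs, times=times,
                        centers=centers[::stride][:len(recs)],
                        work=works, final_cv=x, converged=converged,
                        release_series=rel_recs, seed=seed)


def compare_protocols(model: PotentialModel, protocols=None, n_reps: int = 10,
                      seed: int = 0, **smd_kwargs) -> pd.DataFrame:
    """Mean ± SD of final accumulated work per protocol, ranked by mean.

    Default protocols share one drive duration of 100 basin relaxation
    times: short enough that dissipation (which scales with the dragged
    path length and so distinguishes the protocols) dominates the work,
    long enough that the transition completes.  Rows with any
    non-convergent replica are flagged in ``all_converged``.
    """
    if n_reps < 3:
        raise ValueError("need n_reps >= 3 for a meaningful comparison")
    if protocols is None:
        dur = 100.0 * relaxation_time(model)
        protocols = [DriveProtocol(mode=m, duration=dur) for m in MODES]
    seeds = spawn_seeds(seed, len(protocols))
    rows = []
    for proto, s in zip(protocols, seeds):
        res = run_smd(model, proto, seed=s, n_reps=n_reps, **smd_kwargs)
        wtot = res.total_work
        rows.append({"mode": proto.mode, "mean_work": float(wtot.mean()),
                     "sd_work": float(wtot.std(ddof=1)),
                     "n_reps": n_reps,
                     "all_converged": bool(res.converged.all())})
    df = pd.DataFrame(rows).sort_values("mean_work").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def release_and_equilibrate(model: PotentialModel, result: DrivenResult,
                            duration: float, seed: int = 0,
                            friction: float = 1.0, dt: float | None = None,
                            rep: int = 0):
    """Unbiased continuation after release, with a basin-stability verdict.

    Verdict is "stable" if every frame classifies (nearest basin in
    normalized CV space) into the target (last) basin for the full
    duration; "unstable" otherwise.  duration = 0 returns "stable"
    vacuously with a warning.
    """
    from .toy_systems import propagate_langevin

    if dt is None:
        dt = 2e-4
    basins = np.atleast_2d(model.params["basins"]).astype(float)
    start = result.final_cv[rep]
    if duration <= 0:
        warnings.warn("zero-duration equilibration: verdict is vacuously stable")
        traj = Trajectory(frames=start[None, :], timestep=dt, seed=seed)
        return traj, "stable"
    n_steps = max(int(round(duration / dt)), 1)
    traj = propagate_langevin(model, start, n_steps, dt, friction=friction,
                              seed=seed, stride=max(n_steps // 2000, 1))
    d2 = ((traj.frames[:, None, :] - basins[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    stable = bool(np.all(nearest == len(basins) - 1))
    return traj, ("stable" if stable else "unstable")
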