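"""Synthetic systems with analytic ground truth.

This module generates every input the pipeline consumes in desk-scale mode:

* analytic 1D/2D potential landscapes with two metastable basins separated
  by a barrier of a few kcal/mol, including a tunable saddle-lowering
  "substrate" coupling and a transition-state "confinement" penalty;
* an overdamped (Brownian) Langevin propagator;
* a rigid-body "elevator" bead model of a transporter — a static scaffold
  domain plus a transport domain with outward-facing (OF) and inward-facing
  (IF) reference configurations related by a rigid translation + rotation;
* a two-state telegraph generator for bound/unbound ligand time series with
  known on/off rates.

Every stochastic operation takes an explicit integer seed and is
reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.transform import Rotation

from .common import DEFAULT_TEMPERATURE, KB_KCAL, PMFProfile, kt

__all__ = [
    "PotentialModel",
    "BeadSystem",
    "Trajectory",
    "TelegraphParams",
    "ContactSeries",
    "make_double_well",
    "make_two_basin_2d",
    "propagate_langevin",
    "make_elevator_bead_model",
    "generate_telegraph_binding",
    "analytic_pmf",
    "free_energy_difference",
]


# --------------------------------------------------------------------------
# Potential models
# --------------------------------------------------------------------------

@dataclass
class PotentialModel:
    """An analytic energy landscape over 1 or 2 coordinates.

    ``energy`` maps a coordinate vector (or an ``(n, d)`` batch) to kcal/mol;
    ``gradient`` returns d(energy)/d(coords) in kcal/mol per coordinate unit.
    ``params`` records the named constants of the construction (barrier
    height, basin positions, saddle-lowering coupling delta, ...) so that
    oracles can reason about the model analytically.
    """

    dimensionality: int
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    temperature: float = DEFAULT_TEMPERATURE
    params: dict = field(default_factory=dict)

    @property
    def kt(self) -> float:
        return kt(self.temperature)

    def basin_minima(self) -> np.ndarray:
        """Numerically refined basin minima, seeded from the construction."""
        from scipy.optimize import minimize

        guesses = np.atleast_2d(self.params["basins"])
        out = []
        for g in guesses:
            res = minimize(lambda x: float(self.energy(x)), g,
                           jac=lambda x: np.asarray(self.gradient(x), dtype=float),
                           method="L-BFGS-B")
            out.append(res.x)
        return np.array(out)


def make_double_well(barrier: float, separation: float, asymmetry: float = 0.0,
                     temperature: float = DEFAULT_TEMPERATURE,
                     coupling_delta: float = 0.0) -> PotentialModel:
    """Quartic 1D double well with minima at ±separation/2.

    ``barrier`` is the saddle height above the left minimum (kcal/mol);
    ``asymmetry`` raises the right (IF-like) minimum by that amount;
    ``coupling_delta`` (the "substrate" coupling) lowers the saddle by
    exactly delta by scaling the quartic amplitude — the minima positions
    and energies are untouched and, unlike a localized dip at the barrier
    top, no spurious shoulder maxima appear.  With delta = 0 the model
    reduces exactly to its base form.
    """
    if barrier <= 0 or separation <= 0:
        raise ValueError("barrier and separation must be positive")
    if coupling_delta >= barrier:
        raise ValueError("coupling_delta must be smaller than barrier")
    a = separation / 2.0
    asym, delta = float(asymmetry), float(coupling_delta)
    b_eff = float(barrier) - delta

    def energy(x):
        x = np.asarray(x, dtype=float)
        xx = x[..., 0] if x.ndim and x.shape[-1] == 1 else x
        return b_eff * ((xx / a) ** 2 - 1.0) ** 2 + 0.5 * asym * (xx / a + 1.0)

    def gradient(x):
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim and x.shape[-1] == 1
        xx = x[..., 0] if squeeze else x
        g = 4 * b_eff * xx * ((xx / a) ** 2 - 1.0) / a ** 2 + 0.5 * asym / a
        return g[..., None] if squeeze else g

    return PotentialModel(
        dimensionality=1, energy=energy, gradient=gradient, temperature=temperature,
        params={"kind": "double_well", "barrier": float(barrier),
                "separation": separation, "asymmetry": asym,
                "coupling_delta": delta,
                "basins": np.array([[-a], [a]]), "saddle": np.array([0.0]),
                "domain_guard": 10.0 * separation})


def _two_basin_sw(u, v):
    """Path/transverse coordinates for the 2D model.

    s runs 0 (OF basin at (0,1)) to 1 (IF basin at (1,0)) along the straight
    diagonal; w is the signed transverse offset.
    """
    s = 0.5 * (u + 1.0 - v)
    w = (u + v - 1.0) / np.sqrt(2.0)
    return s, w


def make_two_basin_2d(z_range: float = 8.0, theta_range: float = 19.0,
                      barrier: float = 5.0, coupling_delta: float = 0.0,
                      confinement: float = 0.0, asymmetry: float = 0.0,
                      k_transverse: float = 150.0, valley_amplitude: float = 0.12,
                      temperature: float = DEFAULT_TEMPERATURE) -> PotentialModel:
    """Two-basin 2D landscape in normalized elevator-CV space.

    Coordinates are span-normalized: u = z/z_range, v = theta/theta_range,
    with the OF basin at (u,v)=(0,1) (z=0, theta=theta_range) and the IF
    basin at (1,0) (z=z_range, theta=0).  A curved harmonic valley (center
    w0(s) = valley_amplitude*sin(pi*s)) connects the basins across a quartic
    barrier at s=1/2.

    ``coupling_delta`` (the substrate analog) lowers the saddle by exactly
    delta, and ``confinement`` (the anionic-lipid analog) raises it by
    exactly that amount, both by scaling the quartic amplitude along the
    path — basins and the transverse confinement (hence the vibrational
    entropy entering the free-energy profile) are untouched, so planted
    barrier DIFFERENCES between conditions are exact.  ``asymmetry`` tilts
    the landscape so the IF basin sits higher by ~that amount.
    """
    if z_range <= 0 or theta_range <= 0:
        raise ValueError("ranges must be positive")
    if coupling_delta >= barrier + confinement:
        raise ValueError("coupling_delta must be smaller than the barrier")
    b_eff = float(barrier) + float(confinement) - float(coupling_delta)
    delta, conf, asym = float(coupling_delta), float(confinement), float(asymmetry)
    kt_w = float(k_transverse)
    amp = float(valley_amplitude)

    def _terms(u, v):
        s, w = _two_basin_sw(u, v)
        w0 = amp * np.sin(np.pi * s)
        return s, w, w - w0

    def energy(x):
        x = np.asarray(x, dtype=float)
        u, v = x[..., 0], x[..., 1]
        s, w, e = _terms(u, v)
        return (16.0 * b_eff * s ** 2 * (1.0 - s) ** 2 + 0.5 * kt_w * e ** 2
                + asym * s)

    def gradient(x):
        x = np.asarray(x, dtype=float)
        u, v = x[..., 0], x[..., 1]
        s, w, e = _terms(u, v)
        w0p = amp * np.pi * np.cos(np.pi * s)
        du_ds = (32.0 * b_eff * s * (1.0 - s) * (1.0 - 2.0 * s)
                 - kt_w * e * w0p + asym)
        du_dw = kt_w * e
        gu = 0.5 * du_ds + du_dw / np.sqrt(2.0)
        gv = -0.5 * du_ds + du_dw / np.sqrt(2.0)
        return np.stack([gu, gv], axis=-1)

    saddle_w = amp  # w0 at s = 1/2
    saddle_uv = np.array([0.5 + saddle_w / np.sqrt(2.0), 0.5 + saddle_w / np.sqrt(2.0)])
    return PotentialModel(
        dimensionality=2, energy=energy, gradient=gradient, temperature=temperature,
        params={"kind": "two_basin_2d", "barrier": float(barrier),
                "coupling_delta": delta, "confinement": conf,
                "asymmetry": asym, "effective_barrier": b_eff,
                "k_transverse": kt_w, "valley_amplitude": amp,
                "z_range": float(z_range), "theta_range": float(theta_range),
                "basins": np.array([[0.0, 1.0], [1.0, 0.0]]),
                "saddle": saddle_uv, "domain_guard": 10.0})


def to_physical(model: PotentialModel, x: np.ndarray) -> np.ndarray:
    """Map normalized (u, v) coordinates of a 2D model to (z Å, theta deg)."""
    x = np.asarray(x, dtype=float)
    scale = np.array([model.params["z_range"], model.params["theta_range"]])
    return x * scale


def from_physical(model: PotentialModel, ztheta: np.ndarray) -> np.ndarray:
    ztheta = np.asarray(ztheta, dtype=float)
    scale = np.array([model.params["z_range"], model.params["theta_range"]])
    return ztheta / scale


# --------------------------------------------------------------------------
# Langevin propagator
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Frames of a (possibly biased) Langevin run.

    ``frames`` has shape (T, D); ``bias_record`` (if present) stores the
    instantaneous bias energy per recorded frame.
    """

    frames: np.ndarray
    timestep: float
    seed: int
    times: np.ndarray | None = None
    bias_record: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.times is None:
            self.times = np.arange(len(self.frames)) * self.timestep

    def write_tsv(self, path) -> None:
        from .common import write_timeseries_tsv
        cols = {f"coord{i}": self.frames[:, i] for i in range(self.frames.shape[1])}
        if self.bias_record is not None:
            cols["bias_kcal"] = self.bias_record
        write_timeseries_tsv(path, self.times, cols)


class IntegrationError(RuntimeError):
    pass


def propagate_langevin(model: PotentialModel, start, n_steps: int, dt: float,
                       friction: float = 1.0, seed: int = 0, bias=None,
                       mass: float = 1.0, stride: int = 1) -> Trajectory:
    """Overdamped (Brownian) propagation of a single walker.

    Update rule: x += mu*F*dt + sqrt(2*mu*kT*dt)*xi with mobility
    mu = 1/(friction*mass) and F = -grad U - grad U_bias.  Only
    configurational statistics matter for the estimators built on top, so
    inertia is deliberately dropped.  Deterministic under a fixed seed.
    """
    x = np.array(start, dtype=float).reshape(1, -1)
    frames, biases = _propagate_ensemble(model, x, n_steps, dt, friction, seed,
                                         bias=bias, mass=mass, stride=stride)
    traj = Trajectory(frames=frames[:, 0, :], timestep=dt * stride, seed=seed,
                      bias_record=None if biases is None else biases[:, 0])
    return traj


def _propagate_ensemble(model: PotentialModel, x0: np.ndarray, n_steps: int,
                        dt: float, friction: float, seed: int, bias=None,
                        mass: float = 1.0, stride: int = 1):
    """Vectorized core: propagate an (n_walkers, D) ensemble.

    ``bias`` is either None or an object with ``force(x, step) -> (n, D)``
    and ``energy(x, step) -> (n,)`` methods (step counts applied updates).
    Returns (frames (T, n, D), bias_record or None); frame 0 is the start.
    """
    x = np.array(x0, dtype=float)
    n, d = x.shape
    mu = 1.0 / (friction * mass)
    sqrt_noise = np.sqrt(2.0 * mu * model.kt * dt)
    guard = float(model.params.get("domain_guard", 1e6))
    rng = np.random.default_rng(seed)

    n_rec = n_steps // stride + 1
    frames = np.empty((n_rec, n, d))
    frames[0] = x
    biases = None
    if bias is not None:
        biases = np.empty((n_rec, n))
        biases[0] = bias.energy(x, 0)
    rec = 1
    for step in range(1, n_steps + 1):
        f = -model.gradient(x)
        if bias is not None:
            f = f + bias.force(x, step - 1)
        if sqrt_noise > 0:
            x = x + mu * dt * f + sqrt_noise * rng.standard_normal(x.shape)
        else:
            x = x + mu * dt * f
        if np.abs(x).max() > guard:
            raise IntegrationError(
                f"trajectory diverged beyond |x| = {guard:g} at step {step}; "
                f"dt = {dt:g} is likely too large")
        if step % stride == 0:
            frames[rec] = x
            if biases is not None:
                biases[rec] = bias.energy(x, step)
            rec += 1
    return frames[:rec], None if biases is None else biases[:rec]


# --------------------------------------------------------------------------
# Elevator bead model
# --------------------------------------------------------------------------

@dataclass
class BeadSystem:
    """Rigid-body toy transporter: scaffold beads + transport-domain beads.

    The scaffold (SD) is identical in both reference states; the transport
    domain (TD) in the IF reference is the OF TD rigidly translated along
    the membrane normal (z axis) and rotated about a perpendicular (x) axis.
    """

    scaffold_ref: np.ndarray
    td_of: np.ndarray
    td_if: np.ndarray
    masses: np.ndarray
    translation: float
    rotation: float

    @property
    def n_sd(self) -> int:
        return len(self.scaffold_ref)

    @property
    def n_td(self) -> int:
        return len(self.td_of)

    def frame_of(self) -> np.ndarray:
        return np.vstack([self.scaffold_ref, self.td_of])

    def frame_if(self) -> np.ndarray:
        return np.vstack([self.scaffold_ref, self.td_if])

    def scaffold_indices(self) -> np.ndarray:
        return np.arange(self.n_sd)

    def td_indices(self) -> np.ndarray:
        return np.arange(self.n_sd, self.n_sd + self.n_td)


class DegenerateAxisError(ValueError):
    pass


def make_elevator_bead_model(n_td: int = 10, n_sd: int = 14,
                             translation: float = 8.0, rotation: float = 19.0,
                             seed: int = 0) -> BeadSystem:
    """Build a bead transporter whose OF→IF change is a known rigid motion.

    Defaults mirror the elevator geometry of the transporter this package
    emulates: the transport domain shifts by 8 Å along the membrane normal
    and rotates by 19°.  The TD bead cloud is elongated along y so its first
    principal axis is well defined and perpendicular to the rotation axis
    (x), making the rotation CV recover ``rotation`` exactly by
    construction.
    """
    if n_td < 3:
        raise DegenerateAxisError("need at least 3 transport-domain beads")
    rng = np.random.default_rng(seed)
    # scaffold: ring-like shell around the TD
    ang = np.linspace(0, 2 * np.pi, n_sd, endpoint=False)
    scaffold = np.column_stack([
        9.0 * np.cos(ang), 9.0 * np.sin(ang),
        rng.uniform(-6, 6, n_sd)])
    # TD: anisotropic cloud, long axis along y
    td = rng.normal(0.0, 1.0, (n_td, 3)) * np.array([1.2, 4.0, 1.0])
    td -= td.mean(axis=0)
    cov = np.cov(td.T)
    evals = np.sort(np.linalg.eigvalsh(cov))
    if evals[1] < 1e-9 * evals[2] or evals[2] < 1e-12:
        raise DegenerateAxisError("transport-domain beads are (near-)collinear")
    # orient the principal axis exactly along y so theta is exact by design
    w, vecs = np.linalg.eigh(cov)
    axis = vecs[:, np.argmax(w)]
    target = np.array([0.0, 1.0, 0.0])
    rot_align, _ = Rotation.align_vectors([target], [axis])
    td = td @ rot_align.as_matrix().T

    rot = Rotation.from_euler("x", rotation, degrees=True)
    td_if = td @ rot.as_matrix().T + np.array([0.0, 0.0, float(translation)])
    masses = np.full(n_sd + n_td, 100.0)
    return BeadSystem(scaffold_ref=scaffold, td_of=td, td_if=td_if,
                      masses=masses, translation=float(translation),
                      rotation=float(rotation))


# --------------------------------------------------------------------------
# Telegraph (two-state) binding generator
# --------------------------------------------------------------------------

@dataclass
class TelegraphParams:
    """Two-state bound/unbound kinetics: kon*[C] and koff in 1/ns."""

    kon_times_conc: float
    koff: float
    concentration: float
    duration: float
    dt: float

    def __post_init__(self):
        if self.kon_times_conc <= 0 or self.koff <= 0:
            raise ValueError("rates must be positive")
        if self.dt >= 0.2 / max(self.kon_times_conc, self.koff):
            raise ValueError("dt must be well below 1/max(rate)")

    @property
    def kd_true(self) -> float:
        """True dissociation constant koff/kon in mM."""
        return self.koff / (self.kon_times_conc / self.concentration)


@dataclass
class ContactSeries:
    """Per-frame bound/unbound flags for one or more tracked ligands."""

    times: np.ndarray
    bound: np.ndarray  # (T,) or (T, n_ligands) boolean
    nearest_residue: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.bound = np.asarray(self.bound, dtype=bool)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def generate_telegraph_binding(params: TelegraphParams, seed: int = 0) -> ContactSeries:
    """Sample a two-state Markov chain with exact exponential dwell times.

    Dwells are drawn exactly per state (mean 1/koff bound, 1/(kon*[C])
    unbound), the chain is started from its stationary distribution, and
    the state is then sampled on a regular dt grid.  The exact number of
    simulated transitions is recorded in ``meta['n_transitions']``.
    """
    rng = np.random.default_rng(seed)
    rates = {True: params.koff, False: params.kon_times_conc}
    p_bound = params.kon_times_conc / (params.kon_times_conc + params.koff)
    state = bool(rng.random() < p_bound)
    t, switch_times, switch_states = 0.0, [0.0], [state]
    while t < params.duration:
        t += rng.exponential(1.0 / rates[state])
        state = not state
        switch_times.append(t)
        switch_states.append(state)
    times = np.arange(0.0, params.duration, params.dt)
    idx = np.searchsorted(switch_times, times, side="right") - 1
    bound = np.array(switch_states, dtype=bool)[idx]
    return ContactSeries(times=times, bound=bound,
                         meta={"n_transitions": len(switch_times) - 2,
                               "params": params, "seed": seed})


# --------------------------------------------------------------------------
# Analytic free-energy oracles
# --------------------------------------------------------------------------

def analytic_pmf(model: PotentialModel, grid: np.ndarray) -> PMFProfile:
    """Ground-truth PMF for a toy model.

    1D: energy minus its minimum on the grid.  2D (two-basin model): the
    profile along the path coordinate s, F(s) = -kT ln ∫ exp(-beta U(s,w)) dw
    computed by quadrature over the transverse coordinate.
    """
    grid = np.asarray(grid, dtype=float)
    if model.dimensionality == 1:
        basins = np.atleast_2d(model.params["basins"])
        if grid.min() > basins[:, 0].min() or grid.max() < basins[:, 0].max():
            warnings.warn("grid does not cover the basin minima")
        u = model.energy(grid)
        return PMFProfile(bins=grid, values=u - u.min())
    if model.params.get("kind") != "two_basin_2d":
        raise NotImplementedError("2D analytic PMF implemented for the two-basin model")
    beta = 1.0 / model.kt
    amp = model.params["valley_amplitude"]
    vals = np.empty_like(grid)
    w_half = 6.0 * np.sqrt(model.kt / model.params["k_transverse"]) + abs(amp) + 0.3
    for i, s in enumerate(grid):
        w0 = amp * np.sin(np.pi * s)
        w = np.linspace(w0 - w_half, w0 + w_half, 801)
        # map (s, w) back to (u, v)
        u_c = s + w / np.sqrt(2.0)
        v_c = 1.0 - s + w / np.sqrt(2.0)
        uu = model.energy(np.stack([u_c, v_c], axis=-1))
        vals[i] = -model.kt * np.log(np.trapezoid(np.exp(-beta * (uu - uu.min())), w)) + uu.min()
    return PMFProfile(bins=grid, values=vals - vals.min())


def free_energy_difference(model: PotentialModel) -> float:
    """Analytic ΔF (second basin minus first) by direct quadrature.

    Basins are separated at the saddle location along the first coordinate
    (1D) or path coordinate s = 1/2 (2D two-basin model).
    """
    beta = 1.0 / model.kt
    if model.dimensionality == 1:
        sep = model.params["separation"]
        x = np.linspace(-2.5 * sep, 2.5 * sep, 6001)
        u = model.energy(x)
        bz = np.exp(-beta * (u - u.min()))
        left = x < model.params["saddle"][0]
        fa = -model.kt * np.log(np.trapezoid(bz[left], x[left]))
        fb = -model.kt * np.log(np.trapezoid(bz[~left], x[~left]))
        return float(fb - fa)
    s = np.linspace(-0.3, 1.3, 1601)
    prof = analytic_pmf(model, s)
    bz = np.exp(-beta * prof.values)
    left = s < 0.5
    fa = -model.kt * np.log(np.trapezoid(bz[left], s[left]))
    fb = -model.kt * np.log(np.trapezoid(bz[~left], s[~left]))
    return float(fb - fa)
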