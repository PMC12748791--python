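"""Elevator-transporter collective variables and restraint machinery.

The transition of an elevator transporter is described by two CVs measured
after superposing each frame onto a reference using the scaffold domain:

* ``z`` — signed projection of the transport-domain (TD) center of mass
  onto the OF→IF displacement axis (0 Å at OF, full displacement at IF);
* ``theta`` — angle between the TD's first principal axis and its
  orientation in the IF reference, in [0°, 90°].

COMs, axes and alignments use only the designated (Cα-equivalent)
particles.  Harmonic restraints on these CVs, optionally with a moving
center, provide the biasing forces for the driven and umbrella stages;
``accumulated_work`` integrates the nonequilibrium work done by a moving
restraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DomainSelection", "CVReference", "RestraintSpec", "RigidTransform",
    "align_to_reference", "cv_translation_z", "cv_rotation_theta",
    "bias_energy", "accumulated_work", "rmsd_to_target",
]


@dataclass
class DomainSelection:
    """Index sets for scaffold and transport-domain particles."""

    scaffold: np.ndarray
    td: np.ndarray
    calpha_only: bool = True

    def __post_init__(self):
        self.scaffold = np.asarray(self.scaffold, dtype=int)
        self.td = np.asarray(self.td, dtype=int)
        if len(self.scaffold) == 0 or len(self.td) == 0:
            raise ValueError("both index sets must be non-empty")
        if np.intersect1d(self.scaffold, self.td).size:
            raise ValueError("scaffold and TD index sets must be disjoint")


@dataclass
class CVReference:
    """Anchors of the CV definitions: scaffold reference plus TD endpoints."""

    scaffold_ref: np.ndarray
    td_com_of: np.ndarray
    td_com_if: np.ndarray
    td_axis_if: np.ndarray

    def __post_init__(self):
        self.td_axis_if = np.asarray(self.td_axis_if, dtype=float)
        n = np.linalg.norm(self.td_axis_if)
        if not np.isclose(n, 1.0, atol=1e-8):
            self.td_axis_if = self.td_axis_if / n
        if np.linalg.norm(np.asarray(self.td_com_if) - np.asarray(self.td_com_of)) < 1e-9:
            raise ValueError("OF and IF TD centers of mass coincide")

    @classmethod
    def from_bead_system(cls, system) -> "CVReference":
        sel = DomainSelection(system.scaffold_indices(), system.td_indices())
        axis = principal_axis(system.td_if)
        return cls(scaffold_ref=system.scaffold_ref,
                   td_com_of=system.td_of.mean(axis=0),
                   td_com_if=system.td_if.mean(axis=0),
                   td_axis_if=axis)


@dataclass
class RestraintSpec:
    """Harmonic restraint on one CV, optionally with a moving center.

    ``k`` is in kcal/mol per squared CV unit (Å² for z; the rotation CV is
    restrained in its span-normalized form, so the nominal per-degree
    constant is converted by theta_span²).  ``schedule`` is a piecewise-
    linear center path given as (times_ps, centers); ``center`` is used when
    no schedule is given.
    """

    cv: str
    k: float
    center: float = 0.0
    schedule: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("force constant must be non-negative")
        if self.schedule is not None:
            t, c = self.schedule
            t = np.asarray(t, dtype=float)
            if np.any(np.diff(t) < 0):
                raise ValueError("schedule times must be monotone")
            self.schedule = (t, np.asarray(c, dtype=float))

    def center_at(self, t: float | np.ndarray):
        if self.schedule is None:
            return self.center
        ts, cs = self.schedule
        return np.interp(t, ts, cs)


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class RigidTransform:
    """Proper rigid transform x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def angle_deg(self) -> float:
        c = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))


def _check_noncollinear(coords: np.ndarray) -> None:
    c = coords - coords.mean(axis=0)
    svals = np.linalg.svd(c, compute_uv=False)
    if len(coords) < 3 or svals[1] < 1e-9 * max(svals[0], 1e-12):
        raise DegenerateGeometryError("need >=3 non-collinear particles")


def align_to_reference(frame: np.ndarray, reference: np.ndarray,
                       selection: DomainSelection) -> RigidTransform:
    """Least-squares rigid superposition of a frame's scaffold onto a reference.

    Kabsch algorithm on the scaffold selection; reflection-optimal solutions
    are corrected by flipping the smallest singular direction so a proper
    rotation is always returned.  The transform applies to the whole frame.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mob = frame[selection.scaffold]
    ref = reference[selection.scaffold] if len(reference) > len(selection.scaffold) \
        else reference
    _check_noncollinear(mob)
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    h = (mob - mc).T @ (ref - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    return RigidTransform(rotation=rot, translation=trans)


def principal_axis(coords: np.ndarray) -> np.ndarray:
    """First principal axis (largest-eigenvalue eigenvector) of a particle cloud."""
    c = np.asarray(coords, dtype=float)
    c = c - c.mean(axis=0)
    cov = c.T @ c / len(c)
    w, v = np.linalg.eigh(cov)
    if (w[-1] - w[-2]) < 1e-9 * max(w[-1], 1e-300):
        raise DegenerateGeometryError("top two principal moments are degenerate")
    return v[:, -1]


def cv_translation_z(frame: np.ndarray, refs: CVReference,
                     sel: DomainSelection) -> float:
    """Signed TD translation: projection of TD COM onto the OF→IF axis, Å.

    The frame is first aligned onto the reference using the scaffold.  z is
    0 at the OF reference and |COM_IF − COM_OF| at the IF reference; signed,
    so a monotone drive coordinate exists.
    """
    tf = align_to_reference(frame, refs.scaffold_ref, sel)
    com = tf.apply(np.asarray(frame)[sel.td]).mean(axis=0)
    disp = np.asarray(refs.td_com_if) - np.asarray(refs.td_com_of)
    axis = disp / np.linalg.norm(disp)
    return float((com - refs.td_com_of) @ axis)


def cv_rotation_theta(frame: np.ndarray, refs: CVReference,
                      sel: DomainSelection) -> float:
    """TD rotation: angle (deg) between the frame's TD first principal axis
    and the IF-reference axis, after scaffold alignment.

    The eigenvector sign ambiguity is resolved by requiring a non-negative
    dot product with the reference axis, giving theta in [0°, 90°].
    """
    tf = align_to_reference(frame, refs.scaffold_ref, sel)
    axis = principal_axis(tf.apply(np.asarray(frame)[sel.td]))
    dot = float(axis @ refs.td_axis_if)
    if dot < 0:
        dot = -dot
    return float(np.degrees(np.arccos(np.clip(dot, -1.0, 1.0))))


def bias_energy(r: RestraintSpec, value: float | np.ndarray, t: float = 0.0):
    """Harmonic restraint energy U = 1/2 k (value - center(t))², kcal/mol."""
    c = r.center_at(t)
    return 0.5 * r.k * (np.asarray(value, dtype=float) - c) ** 2


def bias_force(r: RestraintSpec, value, t: float = 0.0):
    """-dU/d(value); the force the propagator applies along the CV."""
    c = r.center_at(t)
    return -r.k * (np.asarray(value, dtype=float) - c)


def accumulated_work(schedule: RestraintSpec, times: np.ndarray,
                     values: np.ndarray):
    """Nonequilibrium work done by a moving harmonic restraint.

    Discretizes W = ∫ (∂U/∂t) dt over the center schedule with the
    trapezoid rule, W += k * mean[(c−x) at both ends] * Δc per interval —
    exact for an instantaneous center jump at fixed x (½kΔc²) and zero for
    perfect tracking.  Returns (cumulative series, final value) in kcal/mol.
    """
    import warnings
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    c = np.asarray(schedule.center_at(times), dtype=float)
    if schedule.schedule is None or np.allclose(c, c[0]):
        warnings.warn("static schedule: accumulated work is identically zero")
        w = np.zeros_like(times)
        return w, 0.0
    dev = c - values
    dc = np.diff(c)
    incr = schedule.k * 0.5 * (dev[:-1] + dev[1:]) * dc
    w = np.concatenate([[0.0], np.cumsum(incr)])
    return w, float(w[-1])


def rmsd_to_target(frame: np.ndarray, target: np.ndarray,
                   sel: DomainSelection) -> float:
    """TD RMSD (Å) to a target structure after scaffold alignment."""
    frame = np.asarray(frame, dtype=float)
    target = np.asarray(target, dtype=float)
    if frame.shape != target.shape:
        raise ValueError("frame and target particle counts differ")
    tf = align_to_reference(frame, target, sel)
    moved = tf.apply(frame)
    diff = moved[sel.td] - target[sel.td]
    return float(np.sqrt((diff ** 2).sum(axis=1).mean()))
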