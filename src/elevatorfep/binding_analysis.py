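"""Anion-binding analytics: contacts, residence times, Kd, ranking, maps.

A ligand is "bound" in a frame when it lies within a cutoff (default 3.5 Å)
of any protein heavy atom.  Maximal runs of constant bound/unbound state
are segmented into events; the dissociation constant follows from the
residence-time ratio

    Kd = (t_unbound_total / t_bound_total) * [ligand]

(equivalently koff/kon with koff = 1/<bound dwell> and
kon = 1/(<unbound dwell> * [ligand])).  Per-residue interaction
probabilities rank the binding residues, and 3D occupancy grids /
1D axis projections map where ligands spend their time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .toy_systems import ContactSeries

__all__ = ["BindingEventTable", "DensityGrid", "detect_contacts",
           "segment_events", "estimate_kd", "rank_residues",
           "residue_contact_table", "accumulate_density", "project_density_z",
           "write_density_map", "read_density_map"]

DEFAULT_CUTOFF = 3.5  # Å, heavy-atom contact criterion


@dataclass
class BindingEventTable:
    """Segmented bound/unbound events tiling a contact series."""

    events: pd.DataFrame          # columns: start, end, state ("bound"/"unbound")
    t_bound_total: float
    t_unbound_total: float

    @property
    def duration(self) -> float:
        return self.t_bound_total + self.t_unbound_total

    def dwell_times(self, state: str) -> np.ndarray:
        ev = self.events
        sel = ev[ev.state == state]
        return (sel.end - sel.start).to_numpy()


@dataclass
class DensityGrid:
    """Voxel occupancy-probability grid (probability per frame per ligand)."""

    origin: np.ndarray
    spacing: np.ndarray
    counts: np.ndarray
    n_frames: int = 0
    n_ligands: int = 1
    overflow: int = 0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.atleast_1d(np.asarray(self.spacing, dtype=float))
        if self.spacing.size == 1:
            self.spacing = np.repeat(self.spacing, 3)
        self.counts = np.asarray(self.counts, dtype=float)

    @property
    def probability(self) -> np.ndarray:
        denom = max(self.n_frames, 1)
        return self.counts / denom


def detect_contacts(ligand_coords: np.ndarray, protein_coords: np.ndarray,
                    cutoff: float = DEFAULT_CUTOFF,
                    times: np.ndarray | None = None,
                    box: np.ndarray | None = None,
                    protein_labels: np.ndarray | None = None) -> ContactSeries:
    """Per-frame bound flags from a distance criterion.

    ``ligand_coords``: (T, 3) or (T, L, 3); ``protein_coords``: (P, 3)
    static or (T, P, 3) per frame.  ``box`` enables orthorhombic
    minimum-image distances (real-trajectory mode); the toy mode is
    non-periodic.  If ``protein_labels`` (P,) residue labels are given, the
    nearest contacting residue per frame/ligand is recorded too.
    """
    lig = np.asarray(ligand_coords, dtype=float)
    prot = np.asarray(protein_coords, dtype=float)
    if lig.ndim == 2:
        lig = lig[:, None, :]
    t_frames, n_lig = lig.shape[:2]
    if prot.ndim == 2:
        prot = np.broadcast_to(prot, (t_frames,) + prot.shape)
    if len(prot) != t_frames:
        raise ValueError("ligand and protein frame counts differ")
    if prot.shape[1] == 0 or n_lig == 0:
        raise ValueError("empty ligand or protein selection")
    bound = np.zeros((t_frames, n_lig), dtype=bool)
    nearest = np.full((t_frames, n_lig), -1, dtype=int) if protein_labels is not None else None
    for t in range(t_frames):
        pc = prot[t]
        if box is not None:
            pc = np.mod(pc, box)
            tree = cKDTree(pc, boxsize=box)
            q = np.mod(lig[t], box)
        else:
            tree = cKDTree(pc)
            q = lig[t]
        dist, idx = tree.query(q)
        bound[t] = dist <= cutoff
        if nearest is not None:
            nearest[t] = np.where(bound[t], idx, -1)
    times = np.arange(t_frames, dtype=float) if times is None else np.asarray(times, dtype=float)
    flags = bound[:, 0] if n_lig == 1 else bound
    near_res = None
    if nearest is not None:
        labels = np.asarray(protein_labels)
        near_res = np.where(nearest >= 0, labels[np.clip(nearest, 0, None)], None)
        if n_lig == 1:
            near_res = near_res[:, 0]
    return ContactSeries(times=times, bound=flags, nearest_residue=near_res,
                         meta={"cutoff": cutoff})


def segment_events(series: ContactSeries, gap_tolerance_frames: int = 0) -> BindingEventTable:
    """Maximal constant-state runs of a contact series.

    ``gap_tolerance_frames`` > 0 merges opposite-state runs shorter than the
    tolerance into their surroundings (default: no merging).  Event times
    tile the series exactly: each frame contributes one sampling interval,
    so t_bound_total + t_unbound_total equals the series duration.
    """
    flags = np.asarray(series.bound, dtype=bool)
    if flags.ndim != 1:
        raise ValueError("segment_events expects a single-ligand series")
    if len(flags) == 0:
        raise ValueError("empty series")
    dt = float(np.median(np.diff(series.times))) if len(series.times) > 1 else 1.0

    if gap_tolerance_frames > 0:
        flags = flags.copy()
        changed = True
        while changed:
            changed = False
            runs = _runs(flags)
            for (i0, i1, state) in runs[1:-1]:
                if i1 - i0 <= gap_tolerance_frames:
                    flags[i0:i1] = ~state
                    changed = True
                    break
    runs = _runs(flags)
    rows = [{"start": series.times[i0],
             "end": series.times[i0] + (i1 - i0) * dt,
             "state": "bound" if state else "unbound"}
            for (i0, i1, state) in runs]
    ev = pd.DataFrame(rows)
    t_bound = float(flags.sum() * dt)
    t_unbound = float((~flags).sum() * dt)
    return BindingEventTable(events=ev, t_bound_total=t_bound,
                             t_unbound_total=t_unbound)


def _runs(flags: np.ndarray):
    """(start_idx, end_idx_exclusive, state) for each maximal run."""
    change = np.flatnonzero(np.diff(flags.astype(int))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(flags)]])
    return [(int(s), int(e), bool(flags[s])) for s, e in zip(starts, ends)]


class UndefinedKdError(ZeroDivisionError):
    pass


def estimate_kd(table: BindingEventTable, concentration: float) -> dict:
    """Dissociation constant from residence times.

    Kd = (t_unbound_total / t_bound_total) * concentration (mM); also
    reports koff = 1/<bound dwell> and kon = 1/(<unbound dwell> * conc).
    """
    if table.t_bound_total <= 0:
        raise UndefinedKdError("no bound time observed: Kd is undefined")
    kd = table.t_unbound_total / table.t_bound_total * concentration
    bound_dwells = table.dwell_times("bound")
    unbound_dwells = table.dwell_times("unbound")
    koff = 1.0 / bound_dwells.mean() if len(bound_dwells) else np.nan
    kon = (1.0 / (unbound_dwells.mean() * concentration)
           if len(unbound_dwells) else np.nan)
    return {"kd": float(kd), "koff": float(koff), "kon": float(kon),
            "n_bound_events": int(len(bound_dwells)),
            "n_unbound_events": int(len(unbound_dwells))}


def residue_contact_table(ligand_coords: np.ndarray, protein_coords: np.ndarray,
                          residue_labels: np.ndarray,
                          cutoff: float = DEFAULT_CUTOFF,
                          box: np.ndarray | None = None) -> pd.DataFrame:
    """Boolean frames × residues contact table for one ligand."""
    lig = np.asarray(ligand_coords, dtype=float)
    prot = np.asarray(protein_coords, dtype=float)
    labels = np.asarray(residue_labels)
    if prot.ndim == 2:
        prot = np.broadcast_to(prot, (len(lig),) + prot.shape)
    uniq = pd.unique(labels)
    out = np.zeros((len(lig), len(uniq)), dtype=bool)
    col = {r: i for i, r in enumerate(uniq)}
    for t in range(len(lig)):
        diff = prot[t] - lig[t][None, :]
        if box is not None:
            diff = (diff + box / 2) % box - box / 2
        d = np.linalg.norm(diff, axis=1)
        for r in pd.unique(labels[d <= cutoff]):
            out[t, col[r]] = True
    return pd.DataFrame(out, columns=uniq)


def rank_residues(contact_tables: dict[str, pd.DataFrame],
                  denominator: str = "all") -> pd.DataFrame:
    """Per-residue, per-species interaction probability, sorted descending.

    ``contact_tables`` maps ligand species name to a frames × residues
    boolean table.  ``denominator='all'`` divides by all frames (the
    fraction-of-frames convention); ``'bound'`` divides by frames with any
    contact.  Residues never contacted are excluded.  Ties are broken by
    residue label.
    """
    rows = []
    for species, table in contact_tables.items():
        denom = len(table) if denominator == "all" else int(table.any(axis=1).sum())
        denom = max(denom, 1)
        frac = table.sum(axis=0) / denom
        for residue, p in frac.items():
            if p > 0:
                rows.append({"residue": residue, "species": species,
                             "probability": float(p)})
    df = pd.DataFrame(rows, columns=["residue", "species", "probability"])
    return (df.sort_values(["probability", "residue"],
                           ascending=[False, True]).reset_index(drop=True))


def accumulate_density(trajectories, origin, spacing, shape,
                       n_ligands: int = 1) -> DensityGrid:
    """Per-voxel visit probability averaged over frames and trajectories.

    ``trajectories`` is an iterable of (T, 3) (or (T, L, 3)) ligand
    positions in a common reference frame (alignment applied upstream).
    Positions outside the grid go to an overflow counter, with a warning.
    """
    origin = np.asarray(origin, dtype=float)
    spacing = np.atleast_1d(np.asarray(spacing, dtype=float))
    if spacing.size == 1:
        spacing = np.repeat(spacing, 3)
    shape = tuple(int(s) for s in shape)
    counts = np.zeros(shape)
    n_frames = overflow = 0
    edges = [origin[i] + spacing[i] * np.arange(shape[i] + 1) for i in range(3)]
    for traj in trajectories:
        pos = np.asarray(traj, dtype=float)
        if pos.ndim == 2:
            pos = pos[:, None, :]
        n_frames += len(pos)
        flat = pos.reshape(-1, 3)
        h, _ = np.histogramdd(flat, bins=edges)
        counts += h
        overflow += len(flat) - int(h.sum())
    if overflow:
        warnings.warn(f"{overflow} ligand positions fell outside the grid "
                      "(counted in the overflow bin)")
    return DensityGrid(origin=origin, spacing=spacing, counts=counts,
                       n_frames=n_frames, n_ligands=n_ligands, overflow=overflow)


def project_density_z(data, axis: int = 2, bins: int = 60,
                      range_: tuple[float, float] | None = None):
    """Normalized 1D probability density along a stated axis, with peaks.

    ``data`` is either a DensityGrid or an (N, 3) position array.  Returns
    (bin_centers, density, peak_locations); density integrates to 1.
    """
    from scipy.signal import find_peaks

    if isinstance(data, DensityGrid):
        other = tuple(i for i in range(3) if i != axis)
        marg = data.counts.sum(axis=other)
        centers = (data.origin[axis]
                   + data.spacing[axis] * (np.arange(data.counts.shape[axis]) + 0.5))
        width = data.spacing[axis]
    else:
        pos = np.asarray(data, dtype=float)
        vals = pos[:, axis] if pos.ndim == 2 else pos
        hist, edges = np.histogram(vals, bins=bins, range=range_)
        centers = 0.5 * (edges[:-1] + edges[1:])
        width = edges[1] - edges[0]
        marg = hist.astype(float)
    total = marg.sum()
    dens = marg / (total * width) if total > 0 else marg
    idx, _ = find_peaks(dens, height=0.1 * dens.max() if dens.max() > 0 else None)
    return centers, dens, centers[idx]


# --------------------------------------------------------------------------
# OpenDX scalar-field I/O
# --------------------------------------------------------------------------

def write_density_map(grid: DensityGrid, path, use_probability: bool = True) -> None:
    """Write the grid as an OpenDX scalar field loadable by molecular viewers."""
    nx, ny, nz = grid.counts.shape
    data = grid.probability if use_probability else grid.counts
    try:
        with open(path, "w") as fh:
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            fh.write("origin " + " ".join(f"{v:.6g}" for v in grid.origin) + "\n")
            fh.write(f"delta {grid.spacing[0]:.6g} 0 0\n")
            fh.write(f"delta 0 {grid.spacing[1]:.6g} 0\n")
            fh.write(f"delta 0 0 {grid.spacing[2]:.6g}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            fh.write(f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n")
            flat = data.ravel(order="C")
            for i in range(0, len(flat), 3):
                fh.write(" ".join(repr(float(v)) for v in flat[i:i + 3]) + "\n")
            fh.write('attribute "dep" string "positions"\n')
            fh.write('object "density" class field\n')
    except OSError as exc:
        raise OSError(f"failed to write OpenDX map to {path}: {exc}") from exc


def read_density_map(path) -> DensityGrid:
    """Read an OpenDX scalar field written by :func:`write_density_map`."""
    origin = np.zeros(3)
    spacing = np.zeros(3)
    shape = None
    values: list[float] = []
    n_items = None
    delta_row = 0
    try:
        with open(path) as fh:
            reading = False
            for line in fh:
                t = line.split()
                if not t:
                    continue
                if reading:
                    if not _is_float(t[0]):
                        reading = False
                        continue
                    values.extend(float(v) for v in t)
                    if len(values) >= n_items:
                        reading = False
                    continue
                if t[:4] == ["object", "1", "class", "gridpositions"]:
                    shape = tuple(int(v) for v in t[-3:])
                elif t[0] == "origin":
                    origin = np.array([float(v) for v in t[1:4]])
                elif t[0] == "delta":
                    spacing[delta_row] = float(t[1 + delta_row])
                    delta_row += 1
                elif t[0] == "object" and "data" in t and "follows" in t:
                    n_items = int(t[t.index("items") + 1])
                    reading = True
    except OSError as exc:
        raise OSError(f"failed to read OpenDX map from {path}: {exc}") from exc
    if shape is None or n_items is None:
        raise ValueError(f"{path} is not a recognizable OpenDX scalar field")
    counts = np.array(values[:n_items]).reshape(shape, order="C")
    return DensityGrid(origin=origin, spacing=spacing, counts=counts,
                       n_frames=1, n_ligands=1)


def _is_float(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
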