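"""Pipeline orchestration: configuration, staging, provenance, comparison.

Runs the full desk-scale analog of the enhanced-sampling workflow —
drive → string refinement (SMwST) → bias-exchange umbrella sampling →
WHAM with bootstrap errors — for one or more landscape conditions (apo,
substrate-coupled, confinement-removed), then compares free-energy
barriers between conditions.  Every stage receives a child seed fanned out
from the global run seed, and the full configuration plus all seeds are
serialized into a run record sufficient to replay the run bit-identically.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beus import run_beus, seed_windows
from .common import PMFProfile, spawn_seeds
from .driven import DriveProtocol, run_smd
from .smwst import (StringPath, SwarmConfig, initialize_string, mean_string,
                    run_smwst)
from .toy_systems import make_two_basin_2d
from .wham import bootstrap_pmf

__all__ = ["PipelineConfig", "RunRecord", "run_pipeline", "run_condition",
           "compare_conditions", "read_structure_selection",
           "DEFAULT_CONDITIONS"]

#: The three study conditions: a bare landscape ("apo") carrying a
#: transition-state confinement penalty (the anionic-lipid analog), the
#: substrate-coupled landscape (saddle lowered by 3 kcal/mol), and the
#: substrate-coupled landscape with the confinement removed (2 kcal/mol
#: lower again).
DEFAULT_CONDITIONS = {
    "apo": {"coupling_delta": 0.0, "confinement": 2.0},
    "substrate": {"coupling_delta": 3.0, "confinement": 2.0},
    "pip2_removed": {"coupling_delta": 3.0, "confinement": 0.0},
}


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown keys in config section '{section}': "
                         f"{sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    system: dict = field(default_factory=dict)
    conditions: dict = field(default_factory=lambda: dict(DEFAULT_CONDITIONS))
    drive: dict = field(default_factory=dict)
    smwst: dict = field(default_factory=dict)
    beus: dict = field(default_factory=dict)
    wham: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str | None = None

    _SYSTEM_KEYS = {"barrier", "asymmetry", "z_range", "theta_range",
                    "k_transverse", "valley_amplitude", "temperature"}
    _COND_KEYS = {"coupling_delta", "confinement"}
    _DRIVE_KEYS = {"mode", "duration", "release_duration", "k", "dt"}
    _SMWST_KEYS = {"n_images", "n_replicas", "n_cycles", "t_restrained",
                   "t_free", "k_restraint", "smoothing", "dt", "average_last"}
    _BEUS_KEYS = {"n_windows", "k", "n_sweeps", "exchange_interval",
                  "sample_stride", "equil_steps", "dt"}
    _WHAM_KEYS = {"bins", "n_boot", "min_count"}

    def __post_init__(self):
        _check_keys("system", self.system, self._SYSTEM_KEYS)
        for name, cond in self.conditions.items():
            _check_keys(f"conditions.{name}", cond, self._COND_KEYS)
        _check_keys("drive", self.drive, self._DRIVE_KEYS)
        _check_keys("smwst", self.smwst, self._SMWST_KEYS)
        _check_keys("beus", self.beus, self._BEUS_KEYS)
        _check_keys("wham", self.wham, self._WHAM_KEYS)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        _check_keys("<top level>", d, {"system", "conditions", "drive", "smwst",
                                       "beus", "wham", "seed", "outdir"})
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunRecord:
    """Provenance of a pipeline run: enough to replay it bit-identically."""

    config: dict
    seed: int
    stage_seeds: dict
    version: str
    started: float
    finished: float | None = None
    outputs: dict = field(default_factory=dict)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _build_model(config: PipelineConfig, condition: dict):
    sys_kw = dict(config.system)
    return make_two_basin_2d(**sys_kw, **condition)


def run_condition(model, config: PipelineConfig, seed: int,
                  outdir: Path | None = None, tag: str = "run") -> dict:
    """Drive → SMwST → BEUS → WHAM for one landscape; returns artifacts."""
    s_drive, s_smwst, s_beus, s_boot = spawn_seeds(seed, 4)

    # --- stage 1: steered transition ------------------------------------
    drive_kw = dict(config.drive)
    proto = DriveProtocol(mode=drive_kw.pop("mode", "simultaneous"), **drive_kw)
    drv = run_smd(model, proto, seed=s_drive)
    if not drv.converged.all():
        raise RuntimeError(f"stage 'drive' failed to converge for {tag}")

    # --- stage 2: string refinement --------------------------------------
    sm_kw = dict(config.smwst)
    n_images = sm_kw.pop("n_images", 32)
    average_last = sm_kw.pop("average_last", 50)
    string = initialize_string(drv.cv_series[:, 0, :], n_images=n_images)
    minima = model.basin_minima()
    imgs = string.images.copy()
    imgs[0], imgs[-1] = minima[0], minima[-1]
    string = StringPath(images=imgs)
    cfg = SwarmConfig(seed=s_smwst, **sm_kw)
    refined = run_smwst(string, model, cfg)
    path = mean_string(refined.history + [refined.images],
                       last_k=min(average_last, cfg.n_cycles))

    # --- stage 3: bias-exchange umbrella sampling -------------------------
    beus_kw = dict(config.beus)
    n_windows = beus_kw.pop("n_windows", 64)
    k_win = beus_kw.pop("k", 36.0 * 8.0 ** 2)
    beus_kw.setdefault("dt", 1e-4)
    beus_kw.setdefault("exchange_interval", 100)
    beus_kw.setdefault("n_sweeps", 1200)
    windows = seed_windows(path, n_windows, k_win)
    run = run_beus(model, windows, seed=s_beus, path=path, **beus_kw)

    # --- stage 4: WHAM + bootstrap ---------------------------------------
    wham_kw = dict(config.wham)
    # common grid across conditions; samples projecting beyond the path
    # endpoints (onto the linear extensions, s<0 or s>1) are excluded rather
    # than piled into the edge bins
    bins = wham_kw.pop("bins", np.linspace(0.0, 1.0, 101))
    pmf = bootstrap_pmf(run, bins=bins, seed=s_boot,
                        temperature=model.temperature,
                        n_boot=wham_kw.pop("n_boot", 40), **wham_kw)

    out = {"driven": drv, "string": refined, "path": path, "beus": run,
           "pmf": pmf, "seeds": {"drive": s_drive, "smwst": s_smwst,
                                 "beus": s_beus, "bootstrap": s_boot}}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pmf.write_tsv(outdir / f"pmf_{tag}.tsv")
        refined.write_tsv(outdir / f"string_{tag}.tsv")
        run.exchange_log.write_tsv(outdir / f"exchange_{tag}.tsv")
        out["files"] = {k: str(outdir / f"{k}_{tag}.tsv")
                        for k in ("pmf", "string", "exchange")}
    return out


def run_pipeline(config: PipelineConfig, outdir=None) -> tuple[RunRecord, dict]:
    """Execute the full pipeline for every configured condition.

    Returns (RunRecord, results) where results maps condition name to the
    per-condition artifact dict plus a ``comparison`` entry (barrier table
    and condition differences) when more than one condition ran.
    """
    outdir = Path(outdir) if outdir is not None else (
        Path(config.outdir) if config.outdir else None)
    record = RunRecord(config=config.to_dict(), seed=config.seed,
                       stage_seeds={}, version=__version__, started=time.time())
    names = list(config.conditions)
    seeds = spawn_seeds(config.seed, len(names))
    results: dict = {}
    for name, s in zip(names, seeds):
        model = _build_model(config, config.conditions[name])
        try:
            results[name] = run_condition(model, config, s, outdir=outdir, tag=name)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failure in condition '{name}': {exc}") from exc
        record.stage_seeds[name] = results[name]["seeds"]
        if outdir is not None:
            record.outputs[name] = results[name].get("files", {})
    if len(names) > 1:
        pmfs = {n: results[n]["pmf"] for n in names}
        cond_table, diff_table = compare_conditions(pmfs)
        results["comparison"] = {"conditions": cond_table, "differences": diff_table}
        if outdir is not None:
            cond_table.to_csv(outdir / "barriers.tsv", sep="\t", index=False)
            diff_table.to_csv(outdir / "barrier_differences.tsv", sep="\t", index=False)
    record.finished = time.time()
    if outdir is not None:
        record.write_json(outdir / "run_record.json")
    return record, results


def compare_conditions(pmfs: dict[str, PMFProfile],
                       pairs: list[tuple[str, str]] | None = None):
    """Barrier table and pairwise barrier differences with bootstrap SDs.

    Barrier = interior maximum minus the starting-basin minimum; basin
    offset = end-basin minimum minus start-basin minimum.  Profiles must be
    on a common grid.  Conditions without an interior maximum are flagged.
    """
    names = list(pmfs)
    grid = pmfs[names[0]].bins
    for n in names[1:]:
        if not np.allclose(pmfs[n].bins, grid):
            raise ValueError("profiles are not on a common grid")
    rows = []
    details = {}
    for n in names:
        p = pmfs[n]
        finite = np.isfinite(p.values)
        span = grid[finite][-1] - grid[finite][0]
        lo = grid[finite][0]
        basin0 = finite & (grid <= lo + 0.25 * span)
        basin1 = finite & (grid >= lo + 0.75 * span)
        interior = finite & (grid > lo + 0.2 * span) & (grid < lo + 0.8 * span)
        # no interior maximum: the global maximum sits in a basin region
        i_glob = np.flatnonzero(finite)[np.argmax(p.values[finite])]
        flagged = not interior.any() or not interior[i_glob]
        i_top = np.flatnonzero(interior)[np.argmax(p.values[interior])] if interior.any() else -1
        i_b0 = np.flatnonzero(basin0)[np.argmin(p.values[basin0])]
        i_b1 = np.flatnonzero(basin1)[np.argmin(p.values[basin1])]
        barrier = float(p.values[i_top] - p.values[i_b0]) if i_top >= 0 else np.nan
        offset = float(p.values[i_b1] - p.values[i_b0])
        sd_b = np.nan
        if p.sd is not None and i_top >= 0:
            sd_b = float(np.hypot(p.sd[i_top], p.sd[i_b0]))
        rows.append({"condition": n, "barrier_kcal": barrier,
                     "basin_offset_kcal": offset, "barrier_sd_kcal": sd_b,
                     "no_interior_maximum": bool(flagged)})
        details[n] = (barrier, sd_b)
    cond_table = pd.DataFrame(rows)
    if pairs is None:
        pairs = [(names[i], names[j]) for i in range(len(names))
                 for j in range(i + 1, len(names))]
    drows = []
    for a, b in pairs:
        (ba, sa), (bb, sb) = details[a], details[b]
        drows.append({"condition_a": a, "condition_b": b,
                      "delta_barrier_kcal": float(ba - bb),
                      "delta_sd_kcal": float(np.hypot(np.nan_to_num(sa),
                                                      np.nan_to_num(sb)))})
    return cond_table, pd.DataFrame(drows)


def read_structure_selection(pdb_path, scaffold_ranges, td_ranges):
    """Cα selections for the scaffold and transport domains of a PDB model.

    Range strings are "CHAIN:FIRST-LAST" with 1-based inclusive residue
    numbers (PDB convention).  Residues missing from a requested range are
    listed in the returned report (and warned about), never silently
    skipped.  Returns (DomainSelection, coords (N,3) Å, report dict).
    """
    import MDAnalysis as mda

    from .colvars import DomainSelection

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(pdb_path))

    def collect(ranges):
        idx, missing = [], []
        for spec in ranges:
            chain, _, span = spec.partition(":")
            first, last = (int(x) for x in span.split("-"))
            for resid in range(first, last + 1):
                sel = u.select_atoms(
                    f"chainID {chain} and resid {resid} and name CA")
                if len(sel) == 0:
                    missing.append(f"{chain}:{resid}")
                else:
                    idx.append(sel.indices[0])
        return idx, missing

    sc_idx, sc_missing = collect(scaffold_ranges)
    td_idx, td_missing = collect(td_ranges)
    missing = sc_missing + td_missing
    if missing:
        warnings.warn("missing residues in selection ranges: " + ", ".join(missing))
    ca = u.select_atoms("name CA")
    coords = u.atoms.positions.astype(float)
    sel = DomainSelection(scaffold=np.array(sc_idx, dtype=int),
                          td=np.array(td_idx, dtype=int))
    report = {"missing_residues": missing,
              "n_scaffold": len(sc_idx), "n_td": len(td_idx),
              "n_calpha_total": len(ca)}
    return sel, coords, report
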