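"""Shared constants, containers and small utilities.

Unit system (package-wide): Å for length, kcal/mol for energy, ps for time,
K for temperature, amu for mass, degrees for angles.  The overdamped
propagator uses the mobility mu = 1/(friction*mass) in Å²·mol/kcal/ps, which
fixes the time unit of the toy dynamics self-consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Boltzmann constant in kcal/mol/K.
KB_KCAL = 1.987204259e-3

#: Simulation temperature used throughout (the transporter systems this
#: package emulates are simulated at body temperature).
DEFAULT_TEMPERATURE = 310.0


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB_KCAL * temperature


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Fan a global run seed out into ``n`` independent child seeds.

    Uses :class:`numpy.random.SeedSequence` spawning (a counter scheme), so
    replica/stage streams are statistically independent and reproducible.
    Returned integers are < 2**31 so they can be logged and re-used anywhere.
    """
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
            for child in ss.spawn(n)]


@dataclass
class PMFProfile:
    """A free-energy profile along a (path) coordinate.

    ``bins`` are bin centers (path coordinate s, or CV units), ``values`` the
    free energy per bin in kcal/mol shifted so the minimum of the sampled
    range is zero, ``sd`` optional bootstrap standard deviations.
    """

    bins: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None = None
    reference: str = "zero-at-minimum"

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)

    def barrier(self, basin_frac: float = 0.25) -> float:
        """Barrier height: interior maximum minus the first-basin minimum.

        ``basin_frac`` bounds the leading fraction of the profile searched
        for the starting-basin minimum.
        """
        finite = np.isfinite(self.values)
        if not finite.any():
            raise ValueError("profile has no finite bins")
        lo, hi = self.bins[finite][0], self.bins[finite][-1]
        span = hi - lo
        basin = finite & (self.bins <= lo + basin_frac * span)
        interior = finite & (self.bins > lo + 0.2 * span) & (self.bins < hi - 0.2 * span)
        if not interior.any():
            raise ValueError("no interior maximum (profile too short)")
        return float(self.values[interior].max() - self.values[basin].min())

    def write_tsv(self, path) -> None:
        sd = self.sd if self.sd is not None else np.full_like(self.values, np.nan)
        with open(path, "w") as fh:
            fh.write("# s\tpmf_kcal\tsd_kcal\n")
            for b, v, s in zip(self.bins, self.values, sd):
                fh.write(f"{b:.8g}\t{v:.8g}\t{s:.8g}\n")

    @classmethod
    def read_tsv(cls, path) -> "PMFProfile":
        data = np.loadtxt(path)
        data = np.atleast_2d(data)
        sd = data[:, 2] if data.shape[1] > 2 else None
        if sd is not None and np.all(np.isnan(sd)):
            sd = None
        return cls(bins=data[:, 0], values=data[:, 1], sd=sd)


def write_timeseries_tsv(path, times: np.ndarray, columns: dict[str, np.ndarray]) -> None:
    """Write a tab-separated time series with a ``#``-prefixed header line."""
    names = ["time_ps"] + list(columns)
    arrays = [np.asarray(times, dtype=float)] + [np.asarray(c, dtype=float) for c in columns.values()]
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(names) + "\n")
        for row in zip(*arrays):
            fh.write("\t".join(f"{x:.10g}" for x in row) + "\n")


def read_timeseries_tsv(path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        header = fh.readline()
    names = header.lstrip("# ").split()
    return names, np.atleast_2d(np.loadtxt(path))
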