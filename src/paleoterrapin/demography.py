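"""Stepwise Ne trajectories: calibration to years, normalization, averaging.

The HMM fit yields a step function of relative Ne against coalescent-scaled
time (units of 2*N0 generations).  Calibration converts to years using the
generation time g (age at maturity plus half the reproductive longevity)
and the per-generation mutation rate mu = d*g/(2*T) from a pairwise genomic
distance d and a divergence time T, via N0 = theta / (4 * mu * bin_size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class CalibrationParams:
    d: float  # pairwise genomic distance, substitutions/site
    T: float  # divergence time, years
    alpha: float  # age at maturity, years
    L: float  # reproductive longevity, years
    g: float = field(init=False)
    mu_per_gen: float = field(init=False)
    mu_per_year: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.d, self.T, self.alpha, self.L) <= 0:
            raise ValueError("all calibration inputs must be positive")
        self.g = self.alpha + self.L / 2.0
        self.mu_per_gen = self.d * self.g / (2.0 * self.T)
        self.mu_per_year = self.d / (2.0 * self.T)


def calibrate(d: float, T: float, alpha: float, L: float) -> CalibrationParams:
    """Generation time and mutation rate from distance/divergence inputs."""
    return CalibrationParams(d=d, T=T, alpha=alpha, L=L)


def mean_pairwise_distance(distances) -> float:
    """Distance to a multi-species sister node: mean of the pairwise values."""
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0 or np.any(d <= 0):
        raise ValueError("need positive distances")
    return float(d.mean())


@dataclass
class DemographicTrajectory:
    """Step function of Ne against time, with optional bootstrap envelope.

    ``times`` are left edges of steps (strictly increasing from 0); in
    "coalescent" units times are in 2*N0 generations and ne is relative to
    N0, in "years" both are absolute.
    """

    times: np.ndarray
    ne: np.ndarray
    units: str = "coalescent"
    theta_per_bin: float | None = None
    bin_size: int = 100
    species: str = ""
    bootstrap: list["DemographicTrajectory"] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ne = np.asarray(self.ne, dtype=float)
        if self.times.shape != self.ne.shape:
            raise ValueError("times and ne must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.ne <= 0):
            raise ValueError("Ne must be positive")

    def value_at(self, t) -> np.ndarray:
        """Step-function value at time(s) t (left-continuous steps)."""
        idx = np.clip(np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1, 0, None)
        return self.ne[idx]

    def mean_ne(self, exclude_recent: int = 4) -> float:
        """Mean Ne over the trajectory, dropping the most recent points.

        The most recent intervals carry few coalescent events and are noisy;
        by default the four earliest-time steps are excluded.
        """
        if exclude_recent >= len(self.ne):
            raise ValueError("nothing left after exclusion")
        return float(self.ne[exclude_recent:].mean())

    def to_frame(self) -> pd.DataFrame:
        rows = [pd.DataFrame({"time": self.times, "ne": self.ne, "replicate_id": -1})]
        for i, rep in enumerate(self.bootstrap):
            rows.append(pd.DataFrame({"time": rep.times, "ne": rep.ne, "replicate_id": i}))
        return pd.concat(rows, ignore_index=True)


def scale_to_years(
    traj: DemographicTrajectory, calib: CalibrationParams, n0: float | None = None
) -> DemographicTrajectory:
    """Convert a coalescent-unit trajectory to years and diploid Ne.

    N0 = theta / (4 * mu_per_gen * bin_size); times scale by 2*N0*g years
    and Ne values by N0.  Bootstrap replicates are scaled with the same
    factors so scaling and resampling commute.
    """
    if traj.units == "years":
        return traj
    if n0 is None:
        if traj.theta_per_bin is None:
            raise ValueError("trajectory lacks theta; pass n0 explicitly")
        n0 = traj.theta_per_bin / (4.0 * calib.mu_per_gen * traj.bin_size)
    # each replicate carries its own theta, so bootstrap and scaling commute
    scaled_boot = [
        scale_to_years(b, calib, n0=None if b.theta_per_bin else n0) for b in traj.bootstrap
    ]
    return DemographicTrajectory(
        times=traj.times * 2.0 * n0 * calib.g,
        ne=traj.ne * n0,
        units="years",
        theta_per_bin=traj.theta_per_bin,
        bin_size=traj.bin_size,
        species=traj.species,
        bootstrap=scaled_boot,
    )


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1]; a constant series maps to 0.5 with a warning."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        warnings.warn("constant trajectory: min-max normalization undefined, using 0.5")
        return np.full_like(values, 0.5)
    return (values - lo) / (hi - lo)


def normalize_and_average(
    trajectories: dict[str, DemographicTrajectory],
    grouping: dict[str, str] | None = None,
    time_window: tuple[float, float] = (1e4, 1e7),
    grid: np.ndarray | None = None,
    mode: str = "minmax",
) -> pd.DataFrame:
    """Per-group mean of normalized trajectories on a common log-time grid.

    Each species' step function (year units) is evaluated on the grid
    restricted to ``time_window``, normalized (``mode="minmax"`` rescales to
    [0, 1]; ``mode="max"`` divides by the maximum, the per-period display
    convention), then averaged within groups.  ``grouping`` maps species to
    group label (default: one "all" group).
    """
    if not trajectories:
        raise ValueError("no trajectories")
    if grid is None:
        grid = np.logspace(np.log10(time_window[0]), np.log10(time_window[1]), 100)
    grid = grid[(grid >= time_window[0]) & (grid <= time_window[1])]
    rows = {}
    for sp, traj in trajectories.items():
        if traj.units != "years":
            raise ValueError(f"trajectory for {sp} must be in years")
        vals = traj.value_at(grid)
        if mode == "minmax":
            rows[sp] = minmax_normalize(vals)
        elif mode == "max":
            rows[sp] = vals / vals.max()
        else:
            raise ValueError("mode must be 'minmax' or 'max'")
    grouping = grouping or {sp: "all" for sp in rows}
    out = []
    for group in sorted(set(grouping.values())):
        members = [rows[sp] for sp in rows if grouping.get(sp) == group]
        if not members:
            raise ValueError(f"group {group} has no trajectories")
        out.append(pd.DataFrame({"group": group, "time": grid, "mean_ne_norm": np.mean(members, axis=0)}))
    return pd.concat(out, ignore_index=True)
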