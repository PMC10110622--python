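"""Cavity hydration analysis.

Occupancy counting in the cavity cylinder, fluctuation statistics (mean,
s.e.m., relative standard deviation), water residence times, axial and
axial-radial density profiles, ion solvation-shell counts, and the
hydration-current correlation.

The cavity boundary is closed: a particle with ``z_lo <= z <= z_hi`` and
``r <= radius`` counts as inside.  Fluctuation statistics use the sample
(n-1) standard deviation; the relative standard deviation rsd = sd/mean is
the dewetting indicator (dewetting-prone cavities fluctuate between wet
and dry states and show large rsd, steadily wetted ones small rsd).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model_core import (
    AtomGroupSpec,
    Frame,
    PoreGeometry,
    minimum_image_distance,
    to_axis_frame,
)


@dataclass
class HydrationSeries:
    times: np.ndarray  # ps
    counts: np.ndarray  # per-frame cavity occupancy

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.counts = np.asarray(self.counts, int)
        if self.times.shape != self.counts.shape:
            raise ValueError("times and counts must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class HydrationStats:
    mean: float
    sd: float
    sem: float
    rsd: float | None  # sd/mean; None when mean == 0 or single frame
    n_frames: int
    defined: bool = True  # False when a single frame makes sd meaningless


@dataclass
class DensityProfile:
    bin_centers: np.ndarray  # z, nm (axis frame)
    density: np.ndarray  # particles / nm^3
    bulk_density: float
    counts: np.ndarray  # raw per-bin tallies (summed over frames)
    bin_width: float
    n_frames: int


@dataclass
class ShellCounts:
    n_first: int
    n_two_shell: int
    r1: float
    r2: float


@dataclass
class Dwell:
    """A maximal run of consecutive in-cavity frames for one particle."""

    particle: int
    duration: float  # ns
    censored: bool  # truncated by trajectory start or end


def in_cavity_mask(frame: Frame, geometry: PoreGeometry, indices) -> np.ndarray:
    z, r = to_axis_frame(frame, geometry, indices)
    return (z >= geometry.z_lo) & (z <= geometry.z_hi) & (r <= geometry.radius)


def count_in_cavity(frame: Frame, geometry: PoreGeometry, group: AtomGroupSpec) -> int:
    """Number of group particles inside the closed cavity cylinder."""
    return int(in_cavity_mask(frame, geometry, group.indices).sum())


def series_stats(counts: Sequence[float]) -> HydrationStats:
    counts = np.asarray(counts, float)
    n = len(counts)
    mean = float(counts.mean()) if n else float("nan")
    if n < 2:
        return HydrationStats(mean=mean, sd=float("nan"), sem=float("nan"),
                              rsd=None, n_frames=n, defined=False)
    sd = float(counts.std(ddof=1))
    sem = sd / np.sqrt(n)
    rsd = sd / mean if mean > 0 else None
    return HydrationStats(mean=mean, sd=sd, sem=sem, rsd=rsd, n_frames=n)


def hydration_series(
    traj: Iterable[Frame],
    geometry: PoreGeometry,
    group: AtomGroupSpec,
) -> tuple[HydrationSeries, HydrationStats]:
    """Per-frame cavity occupancy of ``group`` plus fluctuation statistics."""
    times, counts = [], []
    for frame in traj:
        times.append(frame.time)
        counts.append(count_in_cavity(frame, geometry, group))
    series = HydrationSeries(times=np.array(times), counts=np.array(counts))
    return series, series_stats(series.counts)


def residence_times(
    traj: Iterable[Frame],
    geometry: PoreGeometry,
    group: AtomGroupSpec,
    dt: float,
    gap_tolerance: int = 0,
) -> list[Dwell]:
    """Dwell times (ns) of each group particle in the cavity.

    A dwell is a maximal run of consecutive in-cavity frames; a run of more
    than ``gap_tolerance`` consecutive excursion frames ends it.  Runs
    touching the first or last frame are flagged censored.  ``dt`` is the
    frame spacing in ps; a k-frame dwell lasts k*dt.
    """
    run_start = None  # per-particle index of current run start
    run_len = None
    gap = None
    dwells: list[Dwell] = []
    n_frames = 0
    for fi, frame in enumerate(traj):
        n_frames += 1
        inside = in_cavity_mask(frame, geometry, group.indices)
        if run_len is None:
            n = len(inside)
            run_start = np.full(n, -1)
            run_len = np.zeros(n, dtype=int)
            gap = np.zeros(n, dtype=int)
        for p in range(len(inside)):
            if inside[p]:
                if run_len[p] == 0:
                    run_start[p] = fi
                run_len[p] += 1
                gap[p] = 0
            elif run_len[p] > 0:
                gap[p] += 1
                if gap[p] > gap_tolerance:
                    dwells.append(
                        Dwell(
                            particle=int(group.indices[p]),
                            duration=run_len[p] * dt / 1000.0,
                            censored=run_start[p] == 0,
                        )
                    )
                    run_len[p] = 0
                    gap[p] = 0
    if run_len is not None:
        for p in range(len(run_len)):
            if run_len[p] > 0:  # touched the final frame -> censored
                dwells.append(
                    Dwell(
                        particle=int(group.indices[p]),
                        duration=run_len[p] * dt / 1000.0,
                        censored=True,
                    )
                )
    return dwells


def axial_density_profile(
    traj: Iterable[Frame],
    geometry: PoreGeometry,
    group: AtomGroupSpec,
    bin_width: float = 0.05,
    bulk_slab: tuple[float, float] | None = None,
    z_range: tuple[float, float] | None = None,
) -> DensityProfile:
    """Axial number-density profile inside the cylinder radius.

    Bins span ``z_range`` (default: the cavity bounds) with uniform width;
    density = tally / (n_frames * pi * radius^2 * bin_width).  The bulk
    density is measured in the same cylinder over the disjoint axial slab
    ``bulk_slab`` (z-range in the axis frame).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    z_min, z_max = z_range if z_range is not None else (geometry.z_lo, geometry.z_hi)
    n_bins = max(1, int(round((z_max - z_min) / bin_width)))
    edges = z_min + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    bulk_count = 0.0
    n_frames = 0
    if bulk_slab is not None:
        b_lo, b_hi = bulk_slab
        if not b_hi > b_lo:
            raise ValueError("bulk slab must have positive extent")
        if b_lo < geometry.z_hi and b_hi > geometry.z_lo:
            raise ValueError("bulk slab must be disjoint from the cavity")
    for frame in traj:
        n_frames += 1
        z, r = to_axis_frame(frame, geometry, group.indices)
        radial = r <= geometry.radius
        counts += np.histogram(z[radial], bins=edges)[0]
        if bulk_slab is not None:
            bulk_count += np.sum(radial & (z >= b_lo) & (z <= b_hi))
    if n_frames == 0:
        raise ValueError("trajectory has no frames")
    bin_volume = np.pi * geometry.radius**2 * bin_width
    density = counts / (n_frames * bin_volume)
    if bulk_slab is not None:
        slab_volume = np.pi * geometry.radius**2 * (b_hi - b_lo)
        bulk_density = bulk_count / (n_frames * slab_volume)
    else:
        bulk_density = float("nan")
    return DensityProfile(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        density=density,
        bulk_density=float(bulk_density),
        counts=counts,
        bin_width=bin_width,
        n_frames=n_frames,
    )


def axial_radial_density_map(
    traj: Iterable[Frame],
    geometry: PoreGeometry,
    group: AtomGroupSpec,
    dz: float = 0.05,
    dr: float = 0.05,
    z_range: tuple[float, float] | None = None,
    r_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cylindrically averaged (z, r) density map.

    Returns ``(z_centers, r_centers, density)`` with density normalised by
    the cylindrical shell volume ``pi * (r_out^2 - r_in^2) * dz`` per frame.
    """
    if dz <= 0 or dr <= 0:
        raise ValueError("dz and dr must be positive")
    z_min, z_max = z_range if z_range is not None else (geometry.z_lo, geometry.z_hi)
    r_max = r_max if r_max is not None else geometry.radius
    n_z = max(1, int(round((z_max - z_min) / dz)))
    n_r = max(1, int(round(r_max / dr)))
    z_edges = z_min + dz * np.arange(n_z + 1)
    r_edges = dr * np.arange(n_r + 1)
    tally = np.zeros((n_z, n_r))
    n_frames = 0
    for frame in traj:
        n_frames += 1
        z, r = to_axis_frame(frame, geometry, group.indices)
        tally += np.histogram2d(z, r, bins=(z_edges, r_edges))[0]
    if n_frames == 0:
        raise ValueError("trajectory has no frames")
    shell_volumes = np.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2) * dz
    density = tally / (n_frames * shell_volumes[None, :])
    z_centers = 0.5 * (z_edges[:-1] + z_edges[1:])
    r_centers = 0.5 * (r_edges[:-1] + r_edges[1:])
    return z_centers, r_centers, density


def shell_counts(
    frame: Frame,
    ion_index: int,
    water_oxygens: AtomGroupSpec,
    r1: float = 0.36,
    r2: float = 0.61,
) -> ShellCounts:
    """Waters within the first (``<= r1``) and first+second (``<= r2``)
    solvation shells of one ion, with minimum-image distances.

    Default cutoffs are typical K+ - water-oxygen radial-distribution
    minima (first minimum ~0.36 nm, second ~0.61 nm).
    """
    if not r1 < r2:
        raise ValueError("r1 must be below r2")
    ion = frame.coords[ion_index]
    waters = frame.coords[water_oxygens.indices]
    d = minimum_image_distance(waters, ion, frame.box)
    return ShellCounts(
        n_first=int(np.sum(d <= r1)),
        n_two_shell=int(np.sum(d <= r2)),
        r1=r1,
        r2=r2,
    )


def correlate(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Pearson correlation between two series (e.g. replica currents vs
    replica cavity water counts).  Returns None if either variance is zero.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0 or np.var(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])
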