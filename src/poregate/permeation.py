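"""Ion permeation event detection and current estimation.

A permeation event is a complete pore traversal: an ion must visit the
three axial compartments in order below -> inside -> above (direction +1,
intracellular to extracellular) or above -> inside -> below (-1), where
"inside" requires both the axial bounds and the radial cutoff of the
cavity cylinder.  A below -> above hop with no valid inside frame, or one
whose in-range frames all sit outside the radial cutoff, went around the
protein (or through a periodic image) and is discarded.  Axial jumps of
more than half the box length between consecutive frames are treated as
periodic wraps and reset the ion's state machine, so box-edge recycling
never counts as a traversal.  Partial traversals at the trajectory start
or end are not counted.

The current follows from the net event count: I = (n_up - n_down) * e / T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model_core import (
    ELEMENTARY_CHARGE,
    AtomGroupSpec,
    Frame,
    PoreGeometry,
    to_axis_frame,
)


@dataclass
class PermeationEvent:
    particle_index: int
    direction: int  # +1 lower->upper, -1 upper->lower
    t_enter: float  # ps, first frame inside the cavity
    t_exit: float  # ps, frame completing the traversal

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        if not self.t_enter < self.t_exit:
            raise ValueError("t_enter must precede t_exit")


@dataclass
class CurrentEstimate:
    n_up: int
    n_down: int
    duration: float  # ps
    current: float  # pA


def detect_crossings(
    traj: Iterable[Frame],
    geometry: PoreGeometry,
    ion_group: AtomGroupSpec,
) -> list[PermeationEvent]:
    """Scan the trajectory with a per-ion three-compartment state machine."""
    events: list[PermeationEvent] = []
    origin = None  # per-ion: 0 none, -1 from below, +1 from above
    passed = None
    t_inside = None
    prev_z = None
    for frame in traj:
        z, r = to_axis_frame(frame, geometry, ion_group.indices)
        n = len(z)
        if origin is None:
            origin = np.zeros(n, dtype=int)
            passed = np.zeros(n, dtype=bool)
            t_inside = np.zeros(n)
        box_z = frame.box @ np.abs(geometry.axis_direction)
        for i in range(n):
            if prev_z is not None and abs(z[i] - prev_z[i]) > box_z / 2:
                origin[i] = 0  # periodic wrap: reset, never a traversal
                passed[i] = False
            zi, ri = z[i], r[i]
            if zi < geometry.z_lo:
                if origin[i] == +1 and passed[i]:
                    events.append(
                        PermeationEvent(
                            particle_index=int(ion_group.indices[i]),
                            direction=-1,
                            t_enter=float(t_inside[i]),
                            t_exit=float(frame.time),
                        )
                    )
                origin[i] = -1
                passed[i] = False
            elif zi > geometry.z_hi:
                if origin[i] == -1 and passed[i]:
                    events.append(
                        PermeationEvent(
                            particle_index=int(ion_group.indices[i]),
                            direction=+1,
                            t_enter=float(t_inside[i]),
                            t_exit=float(frame.time),
                        )
                    )
                origin[i] = +1
                passed[i] = False
            elif ri <= geometry.radius:
                if origin[i] != 0 and not passed[i]:
                    passed[i] = True
                    t_inside[i] = frame.time
            else:
                # in the axial range but outside the cylinder: an
                # around-protein path; invalidate until the ion re-enters
                # an outer compartment
                origin[i] = 0
                passed[i] = False
        prev_z = z
    return events


def compute_current(
    events: Sequence[PermeationEvent], duration: float
) -> CurrentEstimate:
    """Current in pA from directional event counts over ``duration`` ps."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_up = sum(1 for e in events if e.direction == +1)
    n_down = sum(1 for e in events if e.direction == -1)
    # e [C] / T [ps]: C/ps = 1e12 A -> 1e24 pA
    current = (n_up - n_down) * ELEMENTARY_CHARGE / duration * 1e24
    return CurrentEstimate(n_up=n_up, n_down=n_down, duration=duration, current=current)


@dataclass
class PooledCurrent:
    mean: float  # pA
    sem: float  # pA (nan when < 2 replicas)
    per_replica: tuple[float, ...]
    defined: bool


def pool_replicas(per_replica: Sequence[CurrentEstimate]) -> PooledCurrent:
    """Arithmetic mean and s.e.m. of replica currents."""
    currents = np.array([c.current for c in per_replica], float)
    if len(currents) == 0:
        raise ValueError("need at least one replica")
    mean = float(currents.mean())
    if len(currents) < 2:
        return PooledCurrent(mean=mean, sem=float("nan"),
                             per_replica=tuple(currents), defined=False)
    sem = float(currents.std(ddof=1) / np.sqrt(len(currents)))
    return PooledCurrent(mean=mean, sem=sem, per_replica=tuple(currents), defined=True)
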