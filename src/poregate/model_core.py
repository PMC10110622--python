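"""Shared data model, physical constants, and pore-geometry resolution.

All coordinates are in nm, times in ps, energies in kJ/mol (reported in
units of kBT where stated), angles in degrees.  The pore is described by a
cylinder: an axis through the channel, axial bounds ``z_lo``/``z_hi``
measured along that axis, and a radial cutoff.  The +axis direction points
from the intracellular (lower) anchor toward the extracellular (upper)
anchor, so "entering the cavity from the intracellular side" means moving
toward increasing z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

AVOGADRO = 6.02214076e23  # 1/mol
ELEMENTARY_CHARGE = 1.602176634e-19  # C
KB_KJ_MOL = 0.00831446261815324  # kJ/(mol K)

#: roles an atom group may declare; analyses dispatch on these labels
GROUP_ROLES = frozenset(
    {
        "water_oxygen",
        "potassium",
        "backbone",
        "calpha",
        "sidechain",
        "lipid_tail_carbon",
        "scaffold",
    }
)


class DegenerateAxisError(ValueError):
    """Raised when the two pore anchors coincide and no axis can be built."""


@dataclass
class Frame:
    """A single trajectory frame: positions, orthorhombic box, time stamp."""

    coords: np.ndarray  # (n, 3) nm
    box: np.ndarray  # (3,) nm, orthorhombic edge lengths
    time: float = 0.0  # ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if self.box.shape != (3,):
            raise ValueError("box must hold 3 orthorhombic edge lengths")
        if not np.all(self.box > 0):
            raise ValueError("all box lengths must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_particles(self) -> int:
        return self.coords.shape[0]


@dataclass
class AtomGroupSpec:
    """A named, ordered particle selection with a semantic role."""

    name: str
    indices: np.ndarray
    role: str

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.role not in GROUP_ROLES:
            raise ValueError(
                f"unknown group role {self.role!r}; expected one of {sorted(GROUP_ROLES)}"
            )
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError(f"group {self.name!r} has duplicate indices")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class PoreGeometry:
    """Cylindrical region defining the central cavity.

    ``z_lo``/``z_hi`` are axial coordinates in the axis frame (projection
    onto ``axis_direction`` relative to the projection of ``axis_origin``).
    """

    axis_origin: np.ndarray
    axis_direction: np.ndarray
    z_lo: float
    z_hi: float
    radius: float

    def __post_init__(self) -> None:
        self.axis_origin = np.asarray(self.axis_origin, dtype=float)
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        norm = np.linalg.norm(self.axis_direction)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise DegenerateAxisError("axis direction has zero length")
            self.axis_direction = self.axis_direction / norm
        if not self.z_lo < self.z_hi:
            raise ValueError("z_lo must be strictly below z_hi")
        if not self.radius > 0:
            raise ValueError("radius must be positive")

    @property
    def length(self) -> float:
        return self.z_hi - self.z_lo

    @property
    def volume(self) -> float:
        """Cylinder volume in nm^3."""
        return np.pi * self.radius**2 * self.length


@dataclass
class Constants:
    """Physical constants bundle; temperature enters only through kBT."""

    temperature: float = 300.0  # K
    e_charge: float = ELEMENTARY_CHARGE  # C
    v_water: float = 0.0299  # nm^3, molecular volume of liquid water at 0.997 g/mL

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.e_charge <= 0 or self.v_water <= 0:
            raise ValueError("all constants must be positive")

    @property
    def kBT(self) -> float:
        """Thermal energy in kJ/mol."""
        return KB_KJ_MOL * self.temperature


@dataclass
class FieldSpec:
    """Constant electric field along the pore axis, as used to mimic a
    transmembrane voltage in channel simulations."""

    E_field: float  # V/nm
    box_length_z: float  # nm

    def __post_init__(self) -> None:
        if self.box_length_z <= 0:
            raise ValueError("box_length_z must be positive")


@dataclass
class ReferenceState:
    """Reference coordinates of a named group (e.g. an open- or closed-state
    average structure) used for RMSD order parameters."""

    label: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        if self.label not in {"open", "closed", "other"}:
            raise ValueError("label must be 'open', 'closed' or 'other'")
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("reference coordinates must be finite")


def resolve_pore_geometry(
    frame: Frame,
    upper_anchor: AtomGroupSpec | np.ndarray,
    lower_anchor: AtomGroupSpec | np.ndarray,
    radius: float,
) -> PoreGeometry:
    """Build the cavity cylinder from two anchor selections.

    The axis runs from the centroid of ``lower_anchor`` (intracellular side,
    the axis origin, z = 0) to the centroid of ``upper_anchor``; z_hi is the
    anchor separation.  Raises :class:`DegenerateAxisError` if the centroids
    coincide.
    """
    lo_idx = lower_anchor.indices if isinstance(lower_anchor, AtomGroupSpec) else np.asarray(lower_anchor, int)
    up_idx = upper_anchor.indices if isinstance(upper_anchor, AtomGroupSpec) else np.asarray(upper_anchor, int)
    if len(lo_idx) == 0 or len(up_idx) == 0:
        raise ValueError("anchor selections must be non-empty")
    lower = frame.coords[lo_idx].mean(axis=0)
    upper = frame.coords[up_idx].mean(axis=0)
    axis = upper - lower
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise DegenerateAxisError("anchor centroids coincide; pore axis undefined")
    direction = axis / norm
    return PoreGeometry(
        axis_origin=lower,
        axis_direction=direction,
        z_lo=0.0,
        z_hi=float(norm),
        radius=float(radius),
    )


def to_axis_frame(
    frame: Frame,
    geometry: PoreGeometry,
    indices: Sequence[int] | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Project particles into the pore-axis frame.

    Returns ``(z, r)``: axial coordinate along the axis (relative to the
    origin's projection) and perpendicular distance to the axis.
    """
    coords = frame.coords if indices is None else frame.coords[np.asarray(indices, int)]
    rel = coords - geometry.axis_origin
    z = rel @ geometry.axis_direction
    perp = rel - np.outer(z, geometry.axis_direction)
    r = np.linalg.norm(perp, axis=1)
    return z, r


def voltage_from_field(spec: FieldSpec) -> float:
    """Transmembrane voltage in mV from a constant field: V = E * L_z."""
    return spec.E_field * spec.box_length_z * 1000.0


def nominal_concentration(
    n_ions: int, n_waters: int, constants: Constants | None = None
) -> float:
    """Nominal ion concentration (mol/L) of a solvated system.

    Approximates the solvent volume as ``n_waters * v_water`` so that
    ``c = (n_ions / n_waters) / (v_water * N_A * 1e-24)``.
    """
    if n_waters <= 0:
        raise ValueError("n_waters must be positive")
    if n_ions < 0:
        raise ValueError("n_ions must be non-negative")
    constants = constants or Constants()
    litres = n_waters * constants.v_water * 1e-24
    return (n_ions / AVOGADRO) / litres


def minimum_image_displacement(dx: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vectors for an orthorhombic box."""
    box = np.asarray(box, float)
    return dx - box * np.round(dx / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image Euclidean distance(s) between points ``a`` and ``b``."""
    d = minimum_image_displacement(np.asarray(a, float) - np.asarray(b, float), box)
    return np.linalg.norm(d, axis=-1)
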