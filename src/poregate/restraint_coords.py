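"""Enforced-(de)wetting machinery.

The chain reaction coordinate measures the hydration of the cavity
cylinder slice by slice: the cylinder is cut into ``n_slices`` axial
slices, each slice gets a smooth occupancy ``n_i`` (a sum of C1
switching-function weights over water oxygens), a saturation function
maps occupancy to a "hydrated" degree ``h_i`` in [0, 1], and the
coordinate is the mean of cumulative products taken along the fill
direction:

    xi = (1/n_slices) * sum_i  prod_{j <= i} h_j .

The sequential product encodes "slice by slice" semantics: a slice only
contributes once every slice before it (from the fill end) is hydrated,
so pulling xi up or down with a harmonic restraint wets or dries the
cavity in order rather than uniformly.  xi is 0 for an empty cylinder,
1 when every slice is saturated, and exactly k/n_slices when the first k
slices (fill order) are saturated and the rest empty.

Functional forms (cosine-ramp switching, smoothstep saturation
S(u) = 3u^2 - 2u^3, sequential product, harmonic restraint) are this
package's concrete realisation; all parameters echo into output metadata.

The dummy-atom repulsion is a flat-bottom half-harmonic from a fixed
site, used to push waters out of a region (e.g. the helix kink) or to
keep lipid tails out of the cavity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    AtomGroupSpec,
    Frame,
    PoreGeometry,
    minimum_image_displacement,
    to_axis_frame,
)


@dataclass
class ChainCoordinateSpec:
    geometry: PoreGeometry
    n_slices: int = 10
    n0: float = 4.0  # saturation occupancy per slice
    ax_ramp: float = 0.05  # nm, axial switching half-width
    rad_ramp: float = 0.05  # nm, radial switching half-width
    k: float = 5000.0  # kJ/mol, restraint force constant
    xi_target: float = 1.0
    fill_direction: str = "from_lower"

    def __post_init__(self) -> None:
        if self.n_slices < 2:
            raise ValueError("need at least 2 slices")
        if self.n0 <= 0 or self.ax_ramp <= 0 or self.rad_ramp <= 0:
            raise ValueError("n0 and ramps must be positive")
        if not 0.0 <= self.xi_target <= 1.0:
            raise ValueError("xi_target must lie in [0, 1]")
        if self.fill_direction not in {"from_lower", "from_upper"}:
            raise ValueError("fill_direction must be 'from_lower' or 'from_upper'")

    @property
    def slice_thickness(self) -> float:
        return (self.geometry.z_hi - self.geometry.z_lo) / self.n_slices

    @property
    def slice_centers(self) -> np.ndarray:
        """Slice centres in ascending axial order."""
        t = self.slice_thickness
        return self.geometry.z_lo + t * (np.arange(self.n_slices) + 0.5)

    def metadata(self) -> dict:
        return {
            "n_slices": self.n_slices,
            "n0": self.n0,
            "ax_ramp_nm": self.ax_ramp,
            "rad_ramp_nm": self.rad_ramp,
            "k_kJ_mol": self.k,
            "xi_target": self.xi_target,
            "fill_direction": self.fill_direction,
            "switching": "cosine-ramp",
            "saturation": "smoothstep 3u^2-2u^3",
            "chain_form": "mean of cumulative products",
        }


@dataclass
class DummyRepulsionSpec:
    site: np.ndarray  # nm
    r_cut: float  # nm
    k_rep: float  # kJ/mol/nm^2
    target_role: str = "water_oxygen"

    def __post_init__(self) -> None:
        self.site = np.asarray(self.site, float)
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")
        if self.k_rep < 0:
            raise ValueError("k_rep must be non-negative")
        if self.target_role not in {"water_oxygen", "lipid_tail_carbon"}:
            raise ValueError("target_role must be water_oxygen or lipid_tail_carbon")


def _plateau_switch(x: np.ndarray, half_width: float, ramp: float):
    """C1 switching function of |x|: 1 for |x| <= half_width, cosine decay
    over [half_width, half_width + ramp], 0 beyond.  Returns (f, df/dx)."""
    ax = np.abs(x)
    f = np.zeros_like(ax)
    df = np.zeros_like(ax)
    f[ax <= half_width] = 1.0
    on_ramp = (ax > half_width) & (ax < half_width + ramp)
    u = (ax[on_ramp] - half_width) / ramp
    f[on_ramp] = 0.5 * (1.0 + np.cos(np.pi * u))
    df[on_ramp] = -0.5 * np.pi / ramp * np.sin(np.pi * u) * np.sign(x[on_ramp])
    return f, df


def _smoothstep(u: np.ndarray):
    """S(u) = 3u^2 - 2u^3 on [0, 1] and its derivative."""
    return 3 * u**2 - 2 * u**3, 6 * u - 6 * u**2


def _occupancies(frame: Frame, spec: ChainCoordinateSpec, waters: AtomGroupSpec,
                 with_grads: bool):
    """Smooth per-slice occupancies; optionally d n_i / d water position."""
    geo = spec.geometry
    idx = waters.indices
    z, r = to_axis_frame(frame, geo, idx)
    rel = frame.coords[idx] - geo.axis_origin
    perp = rel - np.outer(z, geo.axis_direction)
    half = spec.slice_thickness / 2.0
    f_rad, df_rad = _plateau_switch(r, geo.radius, spec.rad_ramp)
    # radial gradient direction: unit perpendicular vector (zero on-axis,
    # where the plateau makes df_rad vanish anyway)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_hat = np.where(r[:, None] > 1e-12, perp / r[:, None], 0.0)
    n = np.zeros(spec.n_slices)
    grads = (
        np.zeros((spec.n_slices, len(idx), 3)) if with_grads else None
    )
    for i, zc in enumerate(spec.slice_centers):
        f_ax, df_ax = _plateau_switch(z - zc, half, spec.ax_ramp)
        w = f_ax * f_rad
        n[i] = w.sum()
        if with_grads:
            grads[i] = (
                df_ax[:, None] * f_rad[:, None] * geo.axis_direction[None, :]
                + f_ax[:, None] * df_rad[:, None] * r_hat
            )
    return n, grads


def slice_occupancies(
    frame: Frame, spec: ChainCoordinateSpec, waters: AtomGroupSpec
) -> np.ndarray:
    """Smooth occupancy n_i per slice, in ascending axial order."""
    n, _ = _occupancies(frame, spec, waters, with_grads=False)
    return n


def _chain_from_occupancies(n: np.ndarray, spec: ChainCoordinateSpec):
    """xi and d xi / d n_i given per-slice occupancies (axial order)."""
    order = (
        np.arange(spec.n_slices)
        if spec.fill_direction == "from_lower"
        else np.arange(spec.n_slices)[::-1]
    )
    u = np.minimum(n[order] / spec.n0, 1.0)
    h, dh = _smoothstep(u)
    dh = np.where(n[order] < spec.n0, dh / spec.n0, 0.0)  # saturated: flat
    m = spec.n_slices
    # cumulative products P_i = prod_{j<=i} h_j and partial derivatives
    P = np.cumprod(h)
    xi = float(P.sum() / m)
    dxi_dn_ordered = np.zeros(m)
    for k in range(m):
        if dh[k] == 0.0:
            continue
        acc = 0.0
        for i in range(k, m):
            prod_except = np.prod(h[:i + 1][np.arange(i + 1) != k])
            acc += prod_except
        dxi_dn_ordered[k] = acc * dh[k] / m
    dxi_dn = np.zeros(m)
    dxi_dn[order] = dxi_dn_ordered
    return xi, dxi_dn


def chain_coordinate(
    frame: Frame, spec: ChainCoordinateSpec, waters: AtomGroupSpec
) -> float:
    """The hydration chain coordinate xi in [0, 1]."""
    n, _ = _occupancies(frame, spec, waters, with_grads=False)
    xi, _ = _chain_from_occupancies(n, spec)
    return xi


def chain_restraint_forces(
    frame: Frame, spec: ChainCoordinateSpec, waters: AtomGroupSpec
) -> tuple[float, np.ndarray]:
    """Harmonic restraint U = 1/2 k (xi - xi_target)^2 and the forces
    -dU/dx on every water oxygen (kJ/mol/nm), via the chain rule through
    the saturation and switching functions.  Waters outside all slice
    ramps receive exactly zero force."""
    n, grads = _occupancies(frame, spec, waters, with_grads=True)
    xi, dxi_dn = _chain_from_occupancies(n, spec)
    energy = 0.5 * spec.k * (xi - spec.xi_target) ** 2
    dU_dxi = spec.k * (xi - spec.xi_target)
    # forces: -dU/dx = -dU/dxi * sum_i dxi/dn_i * dn_i/dx
    dxi_dx = np.tensordot(dxi_dn, grads, axes=(0, 0))  # (n_waters, 3)
    forces = -dU_dxi * dxi_dx
    return float(energy), forces


def dummy_repulsion(
    frame: Frame, spec: DummyRepulsionSpec, targets: AtomGroupSpec
) -> tuple[float, np.ndarray]:
    """Flat-bottom half-harmonic repulsion from a fixed dummy site.

    U(r) = 1/2 k_rep (r_cut - r)^2 for r < r_cut, 0 beyond; the force on
    each target points radially away from the site (minimum image).  A
    target exactly at the site has maximal energy and, the direction being
    undefined, zero force.
    """
    disp = minimum_image_displacement(
        frame.coords[targets.indices] - spec.site, frame.box
    )
    r = np.linalg.norm(disp, axis=1)
    inside = r < spec.r_cut
    energy = 0.5 * spec.k_rep * np.sum((spec.r_cut - r[inside]) ** 2)
    forces = np.zeros_like(disp)
    ok = inside & (r > 1e-12)
    forces[ok] = (
        spec.k_rep * (spec.r_cut - r[ok])[:, None] * disp[ok] / r[ok][:, None]
    )
    return float(energy), forces
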