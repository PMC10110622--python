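"""Toy-pore systems and stochastic trajectories with known ground truth.

The generator emulates, at desk scale, the statistical structure a
channel-MD analysis pipeline assumes: a periodic box of non-interacting
"water" particles and ions diffusing by overdamped Langevin dynamics; an
axial potential bump of tunable height over the cavity region (the
hydrophobic barrier); a constant tilt on ions standing in for the
transmembrane field; optional two-state telegraph modulation of the water
barrier that produces the bimodal wet/dry cavity occupancy of a stochastic
liquid-vapour transition; and a rigid pseudo-tetramer scaffold with open
and closed templates carrying labelled C-alpha, kink backbone O/HN and
side-chain tip sites for the conformational order parameters.

Ground truth (the generating potentials, the quadrature occupancy, the
hidden telegraph state sequence, the templates) is returned alongside
every trajectory so each analysis stage has an exact oracle.

Everything is seeded: the same parameters and seed give bitwise-identical
systems and trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterator

import numpy as np

from .model_core import AtomGroupSpec, Frame, PoreGeometry
from .restraint_coords import _plateau_switch

#: axial half-width of the cosine ramps flanking the barrier plateau (nm)
BARRIER_RAMP = 0.5


@dataclass
class SyntheticPoreParams:
    n_waters: int = 400
    n_ions: int = 12
    box: tuple[float, float, float] = (6.0, 6.0, 9.0)  # nm
    pore_radius: float = 0.8  # nm
    cavity_bounds: tuple[float, float] = (3.5, 5.5)  # nm, absolute z
    water_barrier: float = 0.0  # kBT
    ion_barrier: float = 0.0  # kBT
    field_tilt: float = 0.0  # kBT/nm, on ions, pushing toward +z
    diffusion: float = 0.05  # nm^2/ps
    dt: float = 0.05  # ps
    n_steps: int = 20_000
    save_stride: int = 40
    seed: int = 0
    wetting_mode: str = "off"  # {'off', 'telegraph'}
    k_wet: float = 0.005  # 1/ps, dry -> wet switching rate
    k_dry: float = 0.005  # 1/ps, wet -> dry switching rate
    scaffold: str = "open"  # {'open', 'closed', 'morph'}
    scaffold_morph: float = 0.0  # lambda in [0, 1] when scaffold == 'morph'

    def __post_init__(self) -> None:
        if self.diffusion <= 0 or self.dt <= 0:
            raise ValueError("diffusion and dt must be positive")
        if self.n_steps < 1 or self.save_stride < 1:
            raise ValueError("n_steps and save_stride must be >= 1")
        if self.wetting_mode not in {"off", "telegraph"}:
            raise ValueError("wetting_mode must be 'off' or 'telegraph'")
        if self.wetting_mode == "telegraph" and (self.k_wet <= 0 or self.k_dry <= 0):
            raise ValueError("telegraph rates must be positive")
        if self.scaffold not in {"open", "closed", "morph"}:
            raise ValueError("scaffold must be 'open', 'closed' or 'morph'")
        if not self.cavity_bounds[0] < self.cavity_bounds[1]:
            raise ValueError("cavity_bounds must be increasing")

    @property
    def n_particles(self) -> int:
        return self.n_waters + self.n_ions + N_SCAFFOLD_ATOMS

    def geometry(self) -> PoreGeometry:
        return PoreGeometry(
            axis_origin=np.array([self.box[0] / 2, self.box[1] / 2, 0.0]),
            axis_direction=np.array([0.0, 0.0, 1.0]),
            z_lo=self.cavity_bounds[0],
            z_hi=self.cavity_bounds[1],
            radius=self.pore_radius,
        )

    def detection_geometry(self) -> PoreGeometry:
        """Permeation-detection region: same axial bounds, radius covering
        the whole box cross-section.  The toy box has no protein wall, so
        every axial traversal is a genuine pore passage and the radial
        around-protein guard must not discard it."""
        r_cover = float(np.hypot(self.box[0], self.box[1]) / 2 + 0.1)
        return PoreGeometry(
            axis_origin=np.array([self.box[0] / 2, self.box[1] / 2, 0.0]),
            axis_direction=np.array([0.0, 0.0, 1.0]),
            z_lo=self.cavity_bounds[0],
            z_hi=self.cavity_bounds[1],
            radius=r_cover,
        )


# ---------------------------------------------------------------------------
# scaffold templates

N_CHAINS = 4
SITES_PER_CHAIN = 6  # O297, O298, HN301, HN302, CA304, CZ304(tip)
N_SCAFFOLD_ATOMS = N_CHAINS * SITES_PER_CHAIN

# per-template geometry: C-alpha ring radius, kink O...HN separations,
# side-chain tip polar angles (vs +z) and radial sense (+1 out / -1 in)
_TEMPLATE = {
    "open": dict(
        r_ca=1.5, d_297_301=0.50, d_298_302=0.45,
        tip_theta=(60.0, 90.0, 120.0, 75.0), tip_sense=+1.0,
    ),
    "closed": dict(
        r_ca=1.0, d_297_301=0.20, d_298_302=0.22,
        tip_theta=(150.0, 150.0, 150.0, 150.0), tip_sense=-1.0,
    ),
}


def _template_coords(params: SyntheticPoreParams, which: str) -> np.ndarray:
    """Scaffold coordinates for one template, chain-major site order."""
    t = _TEMPLATE[which]
    cx, cy = params.box[0] / 2, params.box[1] / 2
    zc = 0.5 * (params.cavity_bounds[0] + params.cavity_bounds[1])
    coords = np.zeros((N_SCAFFOLD_ATOMS, 3))
    tip_len = 0.6
    for k in range(N_CHAINS):
        phi = np.pi / 2 * k
        e_r = np.array([np.cos(phi), np.sin(phi), 0.0])
        e_t = np.array([-np.sin(phi), np.cos(phi), 0.0])
        center = np.array([cx, cy, 0.0])
        r_bb = t["r_ca"] + 0.2
        o297 = center + r_bb * e_r + np.array([0, 0, zc + 0.5])
        hn301 = o297 - np.array([0, 0, t["d_297_301"]])
        o298 = center + r_bb * e_r + 0.15 * e_t + np.array([0, 0, zc - 0.1])
        hn302 = o298 - np.array([0, 0, t["d_298_302"]])
        ca = center + t["r_ca"] * e_r + np.array([0, 0, zc])
        theta = np.radians(t["tip_theta"][k])
        v = np.sin(theta) * t["tip_sense"] * e_r + np.cos(theta) * np.array([0, 0, 1.0])
        tip = ca + tip_len * v
        coords[k * SITES_PER_CHAIN: (k + 1) * SITES_PER_CHAIN] = [
            o297, o298, hn301, hn302, ca, tip
        ]
    return coords


def scaffold_coords(params: SyntheticPoreParams) -> np.ndarray:
    if params.scaffold == "morph":
        lam = params.scaffold_morph
        if not 0.0 <= lam <= 1.0:
            raise ValueError("scaffold_morph must lie in [0, 1]")
        return (1 - lam) * _template_coords(params, "open") + lam * _template_coords(
            params, "closed"
        )
    return _template_coords(params, params.scaffold)


def scaffold_site_indices(params: SyntheticPoreParams) -> dict:
    """Index map for the scaffold sites, offset past waters and ions."""
    off = params.n_waters + params.n_ions
    chains = []
    for k in range(N_CHAINS):
        base = off + k * SITES_PER_CHAIN
        chains.append(
            dict(O297=base, O298=base + 1, HN301=base + 2, HN302=base + 3,
                 CA=base + 4, tip=base + 5)
        )
    return dict(chains=chains, offset=off)


# ---------------------------------------------------------------------------
# potentials

def _axial_bump(params: SyntheticPoreParams) -> Callable:
    """Unit-height plateau over the cavity with cosine ramps; returns
    f(z) and f'(z) evaluator."""
    z_lo, z_hi = params.cavity_bounds
    zc = 0.5 * (z_lo + z_hi)
    half = 0.5 * (z_hi - z_lo)

    def f(z: np.ndarray):
        return _plateau_switch(np.asarray(z, float) - zc, half, BARRIER_RAMP)

    return f


@dataclass
class GroundTruth:
    u_water: Callable  # z -> (u, du/dz), kBT units, barrier at full height
    u_ion: Callable  # barrier only (tilt handled separately)
    field_tilt: float
    expected_occupancy: float | None  # quadrature mean cavity water count
    template_open: np.ndarray
    template_closed: np.ndarray
    template_rmsd: float
    wet_states: np.ndarray | None = None  # telegraph state per saved frame


@dataclass
class ToySystem:
    params: SyntheticPoreParams
    frame: Frame
    groups: dict[str, AtomGroupSpec]
    sites: dict
    truth: GroundTruth


class InMemoryTrajectory:
    """Sequence of frames with named groups; satisfies the trajectory
    protocol the analysis modules expect."""

    def __init__(self, frames: list[Frame], dt: float, groups: dict[str, AtomGroupSpec]):
        self.frames = frames
        self.dt = dt  # ps between stored frames
        self.groups = groups

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        return self.n_frames * self.dt

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __reversed__(self) -> Iterator[Frame]:
        return reversed(self.frames)


def analytic_occupancy(params: SyntheticPoreParams) -> float:
    """Expected equilibrium mean cavity water count by quadrature.

    Valid only for untilted waters with wetting off:
    N * A_cav * int_cav exp(-u) / (A_box * int_box exp(-u)).
    """
    if params.wetting_mode != "off":
        raise ValueError("analytic occupancy is defined for wetting_mode='off'")
    bump = _axial_bump(params)
    z_lo, z_hi = params.cavity_bounds
    z_box = np.linspace(0.0, params.box[2], 20001)
    z_cav = np.linspace(z_lo, z_hi, 20001)  # grid aligned to the bounds
    w = lambda z: np.exp(-params.water_barrier * bump(z)[0])
    a_cav = np.pi * params.pore_radius**2
    a_box = params.box[0] * params.box[1]
    num = a_cav * np.trapezoid(w(z_cav), z_cav)
    den = a_box * np.trapezoid(w(z_box), z_box)
    return params.n_waters * num / den


def build_toy_system(params: SyntheticPoreParams) -> ToySystem:
    """Construct the initial frame: scaffold from the template, waters
    placed by rejection sampling from exp(-U_w(z)), ions uniformly."""
    rng = np.random.default_rng(params.seed)
    box = np.asarray(params.box, float)
    bump = _axial_bump(params)
    n_total = params.n_particles
    coords = np.zeros((n_total, 3))
    # waters: x, y uniform; z by rejection from exp(-B_w * bump(z))
    barrier = params.water_barrier if params.wetting_mode == "off" else (
        params.water_barrier if _initial_wet_state(params) == 0 else 0.0
    )
    coords[: params.n_waters, 0] = rng.uniform(0, box[0], params.n_waters)
    coords[: params.n_waters, 1] = rng.uniform(0, box[1], params.n_waters)
    coords[: params.n_waters, 2] = _rejection_sample_z(
        rng, params.n_waters, box[2], lambda z: barrier * bump(z)[0]
    )
    io, ih = params.n_waters, params.n_waters + params.n_ions
    coords[io:ih, 0] = rng.uniform(0, box[0], params.n_ions)
    coords[io:ih, 1] = rng.uniform(0, box[1], params.n_ions)
    coords[io:ih, 2] = _rejection_sample_z(
        rng, params.n_ions, box[2], lambda z: params.ion_barrier * bump(z)[0]
    )
    coords[ih:] = scaffold_coords(params)
    frame = Frame(coords=coords, box=box, time=0.0)

    sites = scaffold_site_indices(params)
    groups = {
        "waters": AtomGroupSpec("waters", np.arange(params.n_waters), "water_oxygen"),
        "ions": AtomGroupSpec("ions", np.arange(io, ih), "potassium"),
        "scaffold": AtomGroupSpec("scaffold", np.arange(ih, n_total), "scaffold"),
        "calpha": AtomGroupSpec(
            "calpha", np.array([c["CA"] for c in sites["chains"]]), "calpha"
        ),
    }
    open_t = _template_coords(params, "open")
    closed_t = _template_coords(params, "closed")
    from .conformation import kabsch_superpose

    _, _, t_rmsd = kabsch_superpose(open_t, closed_t)
    truth = GroundTruth(
        u_water=lambda z: tuple(params.water_barrier * np.asarray(v) for v in bump(z)),
        u_ion=lambda z: tuple(params.ion_barrier * np.asarray(v) for v in bump(z)),
        field_tilt=params.field_tilt,
        expected_occupancy=(
            analytic_occupancy(params) if params.wetting_mode == "off" else None
        ),
        template_open=open_t,
        template_closed=closed_t,
        template_rmsd=t_rmsd,
    )
    return ToySystem(params=params, frame=frame, groups=groups, sites=sites, truth=truth)


def _initial_wet_state(params: SyntheticPoreParams) -> int:
    """Telegraph initial state: 1 (wet) with stationary probability."""
    p_wet = params.k_wet / (params.k_wet + params.k_dry)
    return int(np.random.default_rng(params.seed + 1).random() < p_wet)


def _rejection_sample_z(rng, n: int, box_z: float, u_of_z: Callable) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    for _ in range(10_000):
        need = n - filled
        if need == 0:
            break
        z = rng.uniform(0, box_z, max(need * 2, 16))
        accept = rng.random(len(z)) < np.exp(-u_of_z(z))
        take = z[accept][:need]
        out[filled: filled + len(take)] = take
        filled += len(take)
    if filled < n:
        raise RuntimeError("placement failed: potential rejects nearly all samples")
    return out


def simulate(
    params: SyntheticPoreParams, system: ToySystem | None = None
) -> tuple[InMemoryTrajectory, GroundTruth]:
    """Run overdamped Langevin dynamics and return the stored frames.

    Update per mobile particle: x <- x - D * du/dx * dt + sqrt(2 D dt) * eta
    with u in kBT units.  Waters feel the (possibly telegraph-modulated)
    axial water barrier; ions feel the ion barrier minus the constant tilt.
    All boundaries are periodic; the axial wrap acts as reservoir recycling
    and sustains a steady driven flux.  The scaffold is static.
    """
    system = system or build_toy_system(params)
    sigma = np.sqrt(2 * params.diffusion * params.dt)
    if sigma > BARRIER_RAMP / 2:
        raise ValueError(
            f"unstable step: sqrt(2 D dt) = {sigma:.3f} nm exceeds half the "
            f"barrier ramp width ({BARRIER_RAMP / 2} nm); reduce dt or D"
        )
    rng = np.random.default_rng(params.seed)
    box = np.asarray(params.box, float)
    bump = _axial_bump(params)
    n_mobile = params.n_waters + params.n_ions
    pos = system.frame.coords.copy()
    wet = _initial_wet_state(params)
    p_dry = params.k_dry * params.dt  # wet -> dry per step
    p_wet = params.k_wet * params.dt  # dry -> wet per step

    frames: list[Frame] = []
    wet_states: list[int] = []
    w_slice = slice(0, params.n_waters)
    i_slice = slice(params.n_waters, n_mobile)
    D, dt = params.diffusion, params.dt
    for step in range(1, params.n_steps + 1):
        if params.wetting_mode == "telegraph":
            if wet and rng.random() < p_dry:
                wet = 0
            elif not wet and rng.random() < p_wet:
                wet = 1
            b_w = 0.0 if wet else params.water_barrier
        else:
            b_w = params.water_barrier
        z = pos[:n_mobile, 2]
        _, dbump = bump(z)
        du = np.empty(n_mobile)
        du[: params.n_waters] = b_w * dbump[: params.n_waters]
        du[params.n_waters:] = (
            params.ion_barrier * dbump[params.n_waters:] - params.field_tilt
        )
        noise = rng.standard_normal((n_mobile, 3))
        pos[:n_mobile] += sigma * noise
        pos[:n_mobile, 2] -= D * du * dt
        pos[:n_mobile] %= box  # periodic wrap; axial wrap = reservoir re-entry
        if step % params.save_stride == 0:
            frames.append(
                Frame(coords=pos.copy(), box=box.copy(), time=step * dt)
            )
            wet_states.append(wet)

    truth = replace(
        system.truth, wet_states=np.array(wet_states, dtype=int)
    )
    traj = InMemoryTrajectory(
        frames=frames, dt=params.dt * params.save_stride, groups=system.groups
    )
    return traj, truth


# ---------------------------------------------------------------------------
# file output (PDB topology, XTC / multi-model PDB trajectories)

#: selection config resolving the toy system's groups from its PDB labels
TOY_SELECTION_CONFIG = {
    "waters": {"role": "water_oxygen", "resname": "SOL", "name": "OW"},
    "ions": {"role": "potassium", "resname": "K"},
    "scaffold": {"role": "scaffold", "resname": "SCF"},
    "calpha": {"role": "calpha", "resname": "SCF", "name": "CA"},
}


def _toy_universe(params: SyntheticPoreParams, frame: Frame):
    import MDAnalysis as mda

    n_w, n_i = params.n_waters, params.n_ions
    n_res = n_w + n_i + N_CHAINS * 5
    u = mda.Universe.empty(
        n_atoms=params.n_particles,
        n_residues=n_res,
        n_segments=2 + N_CHAINS,
        atom_resindex=_atom_resindex(params),
        residue_segindex=_residue_segindex(params),
        trajectory=True,
    )
    names = ["OW"] * n_w + ["K"] * n_i
    resnames = ["SOL"] * n_w + ["K"] * n_i
    resids = list(range(1, n_w + n_i + 1))
    for _ in range(N_CHAINS):
        names += ["O", "O", "HN", "HN", "CA", "CZ"]
        resnames += ["SCF"] * 5
        resids += [297, 298, 301, 302, 304]
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr(
        "segids", ["W", "I"] + [chr(ord("A") + k) for k in range(N_CHAINS)]
    )
    u.atoms.positions = frame.coords * 10.0  # nm -> Angstrom
    u.dimensions = [*(frame.box * 10.0), 90.0, 90.0, 90.0]
    return u


def _atom_resindex(params: SyntheticPoreParams) -> np.ndarray:
    n_w, n_i = params.n_waters, params.n_ions
    idx = list(range(n_w + n_i))
    res = n_w + n_i
    for _ in range(N_CHAINS):
        # O297, O298, HN301, HN302 each their own residue; CA+CZ share 304
        idx += [res, res + 1, res + 2, res + 3, res + 4, res + 4]
        res += 5
    return np.array(idx)


def _residue_segindex(params: SyntheticPoreParams) -> np.ndarray:
    n_w, n_i = params.n_waters, params.n_ions
    seg = [0] * n_w + [1] * n_i
    for k in range(N_CHAINS):
        seg += [2 + k] * 5
    return np.array(seg)


def write_system(
    params: SyntheticPoreParams,
    frame: Frame,
    topology_path: str,
) -> None:
    """Write the toy system's topology + coordinates as a PDB file."""
    _toy_universe(params, frame).atoms.write(topology_path)


def write_trajectory(
    params: SyntheticPoreParams,
    traj: InMemoryTrajectory,
    path: str,
) -> None:
    """Write frames as XTC or multi-model PDB (chosen by extension)."""
    import MDAnalysis as mda

    u = _toy_universe(params, traj.frames[0])
    with mda.Writer(path, n_atoms=params.n_particles, multiframe=True) as w:
        for frame in traj:
            u.atoms.positions = frame.coords * 10.0
            u.dimensions = [*(frame.box * 10.0), 90.0, 90.0, 90.0]
            u.trajectory.ts.time = frame.time
            w.write(u.atoms)
    if path.lower().endswith(".pdb"):
        _inline_cryst_per_model(path)


def _inline_cryst_per_model(path: str) -> None:
    """Repeat the header CRYST1 record inside every MODEL block.

    The PDB writer emits a single header CRYST1 for a constant box, but
    multi-model readers only associate a box with a frame when a CRYST1
    accompanies each MODEL; without this the re-read frames carry no box.
    """
    with open(path) as fh:
        lines = fh.readlines()
    cryst = next((ln for ln in lines if ln.startswith("CRYST1")), None)
    if cryst is None:
        return
    n_models = sum(1 for ln in lines if ln.startswith("MODEL"))
    if n_models <= 1:
        return
    out = []
    for ln in lines:
        if ln.startswith("CRYST1"):
            continue
        out.append(ln)
        if ln.startswith("MODEL"):
            out.append(cryst)
    with open(path, "w") as fh:
        fh.writelines(out)
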