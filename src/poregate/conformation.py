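"""Gating order parameters.

The conformational state of the channel is tracked through a small set of
scalar metrics: least-squares (Kabsch) RMSD to open/closed reference
structures, the backbone hydrogen-bond lengths at the inner-helix kink
(O...HN distance only — the reported observable is a bond length, not a
geometric H-bond assignment), the side-chain orientation angle of the
cavity-facing phenylalanine against the pore axis, and the diagonal
(opposite-subunit) C-alpha distance across the tetramer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model_core import (
    AtomGroupSpec,
    Frame,
    PoreGeometry,
    ReferenceState,
    minimum_image_distance,
)


@dataclass
class OrderParamSeries:
    times: np.ndarray  # ps
    values: np.ndarray
    metric_name: str
    units: str  # 'nm' or 'degrees'

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.units not in {"nm", "degrees"}:
            raise ValueError("units must be 'nm' or 'degrees'")


@dataclass
class HBondSpec:
    """Backbone O...HN pair, e.g. label '297O-301HN' for the kink bond
    between residue 297's carbonyl O and residue 301's amide H."""

    acceptor: int  # backbone O atom index
    donor_h: int  # backbone HN atom index
    label: str

    def __post_init__(self) -> None:
        if self.acceptor == self.donor_h:
            raise ValueError("acceptor and donor_h must be distinct atoms")


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid-body superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` in the
    least-squares sense.  The rotation is proper (det = +1); reflections
    are excluded by flipping the smallest singular direction.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ValueError("point sets must have the same shape")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points for a unique superposition")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    H = (mobile - mob_c).T @ (reference - ref_c)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mob_c
    fitted = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return R, t, rmsd


def rmsd_after_fit(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_idx: np.ndarray | None = None,
    measure_idx: np.ndarray | None = None,
) -> float:
    """RMSD over ``measure_idx`` after superposing on ``fit_idx``.

    Both default to all points; this separates the alignment region (e.g.
    the rigid scaffold) from the measured region (e.g. the gate helices).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    fit_idx = slice(None) if fit_idx is None else np.asarray(fit_idx, int)
    measure_idx = slice(None) if measure_idx is None else np.asarray(measure_idx, int)
    R, t, _ = kabsch_superpose(mobile[fit_idx], reference[fit_idx])
    fitted = mobile @ R.T + t
    dev = fitted[measure_idx] - reference[measure_idx]
    return float(np.sqrt(np.mean(np.sum(dev**2, axis=1))))


def rmsd_series(
    traj: Iterable[Frame],
    reference: ReferenceState,
    group: AtomGroupSpec,
    fit_group: AtomGroupSpec | None = None,
) -> OrderParamSeries:
    """Per-frame RMSD of ``group`` to a reference state.

    ``reference.coords`` must cover the union group in frame-index order;
    frames are fitted on ``fit_group`` (default: ``group`` itself).
    """
    fit_group = fit_group or group
    union = np.union1d(group.indices, fit_group.indices)
    pos = {idx: k for k, idx in enumerate(union)}
    fit_idx = np.array([pos[i] for i in fit_group.indices])
    measure_idx = np.array([pos[i] for i in group.indices])
    ref = np.asarray(reference.coords, float)
    if ref.shape[0] != len(union):
        raise ValueError(
            f"reference has {ref.shape[0]} coordinates but the union of "
            f"fit and measure groups has {len(union)}"
        )
    times, values = [], []
    for frame in traj:
        times.append(frame.time)
        values.append(
            rmsd_after_fit(frame.coords[union], ref, fit_idx, measure_idx)
        )
    return OrderParamSeries(
        times=np.array(times),
        values=np.array(values),
        metric_name=f"rmsd_to_{reference.label}",
        units="nm",
    )


def average_structure(
    traj: Iterable[Frame],
    group: AtomGroupSpec,
    fit: bool = True,
    passes: int = 2,
) -> np.ndarray:
    """Mean coordinates of ``group`` after iterative superposition.

    Pass 1 fits every frame onto the first frame and averages; each later
    pass re-fits onto the running mean.  ``fit=False`` averages raw
    coordinates (useful for fixed scaffolds).
    """
    frames = [np.asarray(f.coords[group.indices], float) for f in traj]
    if not frames:
        raise ValueError("trajectory has no frames")
    if not fit or len(frames) == 1:
        return np.mean(frames, axis=0)
    reference = frames[0]
    mean = None
    for _ in range(max(1, passes)):
        fitted = []
        for X in frames:
            R, t, _ = kabsch_superpose(X, reference)
            fitted.append(X @ R.T + t)
        mean = np.mean(fitted, axis=0)
        reference = mean
    return mean


def hbond_lengths(
    traj: Iterable[Frame], specs: Sequence[HBondSpec]
) -> list[OrderParamSeries]:
    """Per-frame acceptor-O to donor-H distances (nm, minimum image)."""
    times: list[float] = []
    values: list[list[float]] = [[] for _ in specs]
    for frame in traj:
        times.append(frame.time)
        for k, spec in enumerate(specs):
            d = minimum_image_distance(
                frame.coords[spec.acceptor], frame.coords[spec.donor_h], frame.box
            )
            values[k].append(float(d))
    return [
        OrderParamSeries(
            times=np.array(times),
            values=np.array(v),
            metric_name=spec.label,
            units="nm",
        )
        for spec, v in zip(specs, values)
    ]


def sidechain_angle(
    frame: Frame,
    ca_index: int,
    tip_group: AtomGroupSpec | np.ndarray,
    geometry: PoreGeometry,
) -> float | None:
    """Side-chain orientation angle (degrees) against the pore axis.

    The side chain is represented by the vector from the C-alpha to the
    centroid of the tip atoms (for Phe, the aromatic ring); the angle is
    measured against +axis and lies in [0, 180].  Returns None for a
    zero-length side-chain vector.
    """
    tip_idx = tip_group.indices if isinstance(tip_group, AtomGroupSpec) else np.asarray(tip_group, int)
    if len(tip_idx) == 0:
        raise ValueError("tip group must be non-empty")
    vec = frame.coords[tip_idx].mean(axis=0) - frame.coords[ca_index]
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        return None
    cosang = np.clip(vec @ geometry.axis_direction / norm, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def opposite_ca_distance(
    frame: Frame, ca_index_a: int, ca_index_c: int
) -> float:
    """Minimum-image distance (nm) between diagonal subunits' C-alphas."""
    return float(
        minimum_image_distance(
            frame.coords[ca_index_a], frame.coords[ca_index_c], frame.box
        )
    )
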