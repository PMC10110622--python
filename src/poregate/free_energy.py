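"""Boltzmann inversion of axial densities into free-energy profiles.

At equilibrium the axial number density along the pore satisfies
``rho(z) = rho_ref * exp(-F(z)/kBT)``, so the potential of mean force is
``F(z) = -kBT ln(rho(z)/rho_ref)``.  Profiles are reported in kBT units
and gauged so that F averages to zero over a user-chosen reference slab
(typically bulk-like solvent away from the cavity).  Bins with zero counts
are masked undefined, never clamped: a sampled zero places only a lower
bound on the barrier, and inventing a finite value would fabricate
barrier heights.

Inversion presumes equilibrium sampling; profiles for field-driven ions
are not PMFs and the pipeline computes ion profiles from zero-field runs
by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hydration import DensityProfile


@dataclass
class PMFProfile:
    bin_centers: np.ndarray  # z, nm
    F: np.ndarray  # kBT; nan where undefined
    defined_mask: np.ndarray
    reference_zero: tuple[float, float]  # z range where <F> = 0

    def barrier(self) -> float:
        """Convenience: max defined F (the gauge puts the reference at 0)."""
        return float(np.nanmax(self.F))


def boltzmann_invert(
    profile: DensityProfile,
    reference_slab: tuple[float, float],
    driven: bool = False,
) -> PMFProfile:
    """Invert an axial density profile into F(z) in kBT.

    ``reference_slab`` is the z-range (axis frame) over which F is gauged
    to zero; it must contain defined bins with nonzero density.  Set
    ``driven=True`` to acknowledge that the density came from a biased
    (field-on) run; a warning is emitted because the result is then not an
    equilibrium PMF.
    """
    if driven:
        warnings.warn(
            "Boltzmann inversion of a field-driven density is not an "
            "equilibrium PMF; interpret with care",
            stacklevel=2,
        )
    z = np.asarray(profile.bin_centers, float)
    rho = np.asarray(profile.density, float)
    defined = profile.counts > 0
    lo, hi = reference_slab
    ref_bins = defined & (z >= lo) & (z <= hi)
    if not np.any(ref_bins):
        raise ValueError("reference slab contains no sampled bins")
    with np.errstate(divide="ignore"):
        F = -np.log(np.where(defined, rho, np.nan))
    F -= np.nanmean(F[ref_bins])  # gauge: <F> = 0 over the reference slab
    F[~defined] = np.nan
    return PMFProfile(
        bin_centers=z, F=F, defined_mask=defined, reference_zero=(lo, hi)
    )


def invert_roundtrip(pmf: PMFProfile, rho_ref: float) -> np.ndarray:
    """Map F back to a density: rho = rho_ref * exp(-F).  Exact inverse of
    :func:`boltzmann_invert` up to the gauge constant (used as a
    self-consistency check)."""
    return rho_ref * np.exp(-pmf.F)


def barrier_height(
    pmf: PMFProfile, window: tuple[float, float]
) -> float | None:
    """Barrier height (kBT) within an axial window.

    Defined as the maximum F in the window minus the minimum F on the
    intracellular (low-z) side of that maximum, i.e. the climb an ion or
    water faces entering from the intracellular entrance.  Returns None if
    the window contains no defined bins.
    """
    lo, hi = window
    in_win = pmf.defined_mask & (pmf.bin_centers >= lo) & (pmf.bin_centers <= hi)
    if not np.any(in_win):
        return None
    idx = np.nonzero(in_win)[0]
    F_win = pmf.F[idx]
    peak = int(np.nanargmax(F_win))
    entry_min = float(np.nanmin(F_win[: peak + 1]))
    return float(F_win[peak] - entry_min)
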