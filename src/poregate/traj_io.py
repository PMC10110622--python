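"""Topology/trajectory reading and tabular output.

Readers are backed by MDAnalysis; all coordinates are converted to nm on
read (MDAnalysis reports Angstrom).  Frames are exposed as a lazy iterator
so no analysis ever needs the whole trajectory in memory.

Selection grammar (version 1): each named group is a mapping with a
required ``role`` (see :data:`poregate.model_core.GROUP_ROLES`) plus any of
the filters ``resname``, ``name`` (atom name), ``segid`` (each a string or
list of strings) and ``resid_range`` ([lo, hi], inclusive).  Filters are
ANDed; an empty result is an error naming the failing pattern.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import AtomGroupSpec, Frame

ANGSTROM_TO_NM = 0.1

SELECTION_GRAMMAR_VERSION = 1
_FILTER_KEYS = {"resname", "name", "segid", "resid_range"}


class FormatError(ValueError):
    """A topology or trajectory file could not be parsed."""


class SelectionError(ValueError):
    """A selection pattern matched no atoms."""


@dataclass
class TrajectoryHandle:
    """Lazy view of a trajectory plus resolved named atom groups.

    Iterating the handle yields :class:`Frame` objects in file order; the
    underlying reader seeks per frame, so memory use is one frame.
    """

    source: tuple[str, ...]
    n_frames: int
    dt: float  # ps between stored frames
    groups: dict[str, AtomGroupSpec]
    _universe: object = field(repr=False, default=None)

    def _box_nm(self, ts) -> np.ndarray:
        dims = ts.dimensions
        if dims is None:  # e.g. multi-model PDB with a single CRYST1 record
            dims = self._universe.dimensions
        if dims is None:
            raise FormatError(
                f"no box information in {self.source}; orthorhombic box required"
            )
        return np.asarray(dims[:3], float) * ANGSTROM_TO_NM

    def __iter__(self) -> Iterator[Frame]:
        for ts in self._universe.trajectory:
            yield Frame(
                coords=ts.positions * ANGSTROM_TO_NM,
                box=self._box_nm(ts),
                time=float(ts.time),
            )

    @property
    def n_particles(self) -> int:
        return len(self._universe.atoms)

    def frame(self, i: int) -> Frame:
        """Random access to frame ``i`` (used e.g. to fix geometry at frame 0)."""
        ts = self._universe.trajectory[i]
        return Frame(
            coords=ts.positions * ANGSTROM_TO_NM,
            box=self._box_nm(ts),
            time=float(ts.time),
        )


def _as_list(value) -> list[str]:
    if isinstance(value, str):
        return [value]
    return list(value)


def _resolve_group(universe, name: str, spec: Mapping) -> AtomGroupSpec:
    unknown = set(spec) - _FILTER_KEYS - {"role"}
    if unknown:
        raise SelectionError(f"group {name!r}: unknown selection keys {sorted(unknown)}")
    if "role" not in spec:
        raise SelectionError(f"group {name!r}: missing required 'role'")
    atoms = universe.atoms
    mask = np.ones(len(atoms), dtype=bool)
    if "resname" in spec:
        mask &= np.isin(atoms.resnames, _as_list(spec["resname"]))
    if "name" in spec:
        mask &= np.isin(atoms.names, _as_list(spec["name"]))
    if "segid" in spec:
        mask &= np.isin(atoms.segids, _as_list(spec["segid"]))
    if "resid_range" in spec:
        lo, hi = spec["resid_range"]
        mask &= (atoms.resids >= int(lo)) & (atoms.resids <= int(hi))
    indices = np.nonzero(mask)[0]
    if len(indices) == 0:
        raise SelectionError(
            f"group {name!r}: selection {dict(spec)} matched no atoms"
        )
    return AtomGroupSpec(name=name, indices=indices, role=spec["role"])


def load_system(
    topology_path: str,
    trajectory_path: str | None = None,
    selection_config: Mapping[str, Mapping] | None = None,
) -> TrajectoryHandle:
    """Open a topology (PDB/GRO) with an optional trajectory (XTC/DCD or
    multi-model PDB) and resolve named atom groups.

    Without a trajectory the topology's own coordinates serve as a
    single-frame (or, for multi-model PDB, multi-frame) trajectory.
    """
    import MDAnalysis as mda

    for path in filter(None, (topology_path, trajectory_path)):
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        if ext not in {"pdb", "gro", "xtc", "dcd"}:
            raise FormatError(f"unsupported file format {ext!r}: {path}")
    try:
        if trajectory_path is None:
            universe = mda.Universe(topology_path)
        else:
            universe = mda.Universe(topology_path, trajectory_path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # MDAnalysis raises assorted parse errors
        raise FormatError(f"could not parse {topology_path}: {exc}") from exc

    groups = {
        name: _resolve_group(universe, name, spec)
        for name, spec in (selection_config or {}).items()
    }
    n_frames = len(universe.trajectory)
    dt = float(universe.trajectory.dt) if n_frames > 1 else 1.0
    source = tuple(p for p in (topology_path, trajectory_path) if p)
    return TrajectoryHandle(
        source=source, n_frames=n_frames, dt=dt, groups=groups, _universe=universe
    )


def write_table(
    records: Sequence[Mapping],
    path: str,
    metadata: Mapping | None = None,
    columns: Sequence[str] | None = None,
) -> None:
    """Write records as a TSV with a deterministic column order.

    Floats are printed at 6 significant digits.  Optional metadata is
    emitted as ``# key: value`` comment lines above the header.  For an
    empty record list, ``columns`` supplies the header.
    """
    if records:
        columns = list(records[0].keys())
        for rec in records:
            if list(rec.keys()) != columns:
                raise ValueError("all records must share the same header")
        df = pd.DataFrame(list(records), columns=columns)
    else:
        df = pd.DataFrame(columns=list(columns) if columns else [])
    try:
        with open(path, "w") as fh:
            for key, value in (metadata or {}).items():
                fh.write(f"# {key}: {value}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    except OSError as exc:
        raise OSError(f"failed writing table to {path}: {exc}") from exc


def read_table(path: str) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table` (skips metadata lines)."""
    return pd.read_csv(path, sep="\t", comment="#")
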