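"""Trajectory loading, atom selection, and subsample writing.

The in-memory representation is a :class:`TrajectoryEnsemble`: an ordered
stack of frames of Cartesian coordinates in Angstrom plus a per-atom table
(name, residue name, residue number, chain).  Frames from multiple
trajectory files sharing one topology are concatenated in file order and
addressed by a single global, 0-based frame index everywhere in the package.

All file I/O and the selection grammar are delegated to MDAnalysis; nm-based
formats (GRO, XTC, TRR) are converted to Angstrom on read and back on write
by the MDAnalysis unit machinery, so the ensemble is always in Angstrom.
"""

from __future__ import annotations

import json
import os
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

import MDAnalysis as mda
import numpy as np
import pandas as pd
from MDAnalysis.coordinates.memory import MemoryReader
from MDAnalysis.exceptions import SelectionError as _MDASelectionError

from .errors import BoundsError, ConsistencyError, InputError, SelectionError

__all__ = [
    "TrajectoryEnsemble",
    "AtomSelection",
    "FrameSample",
    "load_trajectory",
    "select_atoms",
    "get_frame_coordinates",
    "write_subsample",
]


@contextmanager
def _quiet_mdanalysis():
    """Silence MDAnalysis's benign box/metadata warnings: the model systems
    here have no unit cell, elements, or B-factors by design."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning,
                                module="MDAnalysis.*")
        warnings.filterwarnings("ignore", category=DeprecationWarning,
                                module="MDAnalysis.*")
        yield


@dataclass
class FrameSample:
    """An ordered record of selected global frame indices.

    Indices are stored ascending (with multiplicity preserved when drawn
    with replacement) so that written subsamples keep temporal order.

    Attributes
    ----------
    frame_indices : numpy.ndarray of int
        0-based global frame indices, ascending.
    strategy : str
        Name of the sampler that produced this sample.
    requested_size : int
        The size the caller asked for; ``len(frame_indices)`` may be
        smaller when a stratum could not fill its quota.
    seed : int
        Seed of the generator stream used for the draw.
    replacement : bool
        Whether indices may repeat.
    shortfall : int
        Total number of frames missing relative to ``requested_size``
        because strata were under-populated (never silently redistributed).
    """

    frame_indices: np.ndarray
    strategy: str
    requested_size: int
    seed: int
    replacement: bool = False
    shortfall: int = 0

    def __post_init__(self) -> None:
        idx = np.asarray(self.frame_indices, dtype=np.intp)
        if idx.ndim != 1:
            raise ValueError("frame_indices must be one-dimensional")
        if np.any(np.diff(idx) < 0):
            idx = np.sort(idx, kind="stable")
        if not self.replacement and len(np.unique(idx)) != len(idx):
            raise ValueError("sample without replacement contains duplicate indices")
        self.frame_indices = idx

    def __len__(self) -> int:
        return len(self.frame_indices)

    @property
    def actual_size(self) -> int:
        return len(self.frame_indices)

    def validate_for(self, n_frames: int) -> None:
        if len(self.frame_indices) and (
            self.frame_indices.min() < 0 or self.frame_indices.max() >= n_frames
        ):
            raise BoundsError(
                f"sample contains frame indices outside [0, {n_frames})"
            )

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "requested_size": int(self.requested_size),
            "actual_size": int(self.actual_size),
            "seed": int(self.seed),
            "replacement": bool(self.replacement),
            "shortfall": int(self.shortfall),
            "frame_indices": [int(i) for i in self.frame_indices],
        }


@dataclass
class AtomSelection:
    """A resolved atom selection: the expression plus matching atom indices.

    ``indices`` are 0-based positions into the ensemble's atom table,
    strictly increasing and non-empty.
    """

    expression: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.ndim != 1 or len(idx) == 0:
            raise SelectionError(
                f"selection {self.expression!r} resolved to no atoms"
            )
        if np.any(np.diff(idx) <= 0):
            raise SelectionError("selection indices must be strictly increasing")
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class TrajectoryEnsemble:
    """Topology metadata plus an ordered stack of coordinate frames (Angstrom).

    Attributes
    ----------
    coordinates : numpy.ndarray, shape (n_frames, n_atoms, 3)
        Cartesian positions in Angstrom.
    atom_table : pandas.DataFrame
        One row per atom with columns ``name``, ``resname``, ``resid``,
        ``chain``.
    source_files : list of str
        Trajectory files in concatenation order (empty for in-memory
        synthetic ensembles).
    topology_file : str or None
        The topology the trajectories were read with, if any.
    """

    coordinates: np.ndarray
    atom_table: pd.DataFrame
    source_files: list[str] = field(default_factory=list)
    topology_file: str | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=np.float64)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] < 1 or coords.shape[1] < 1:
            raise ValueError("ensemble needs at least one frame and one atom")
        if not np.isfinite(coords).all():
            raise ValueError("coordinates contain non-finite values")
        if len(self.atom_table) != coords.shape[1]:
            raise ConsistencyError(
                f"atom table has {len(self.atom_table)} rows but coordinates "
                f"have {coords.shape[1]} atoms"
            )
        self.coordinates = coords

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def topology_universe(self) -> mda.Universe:
        """Build a coordinate-less MDAnalysis Universe carrying the topology.

        Used for selection resolution and as the writing template; cached.
        """
        if getattr(self, "_universe", None) is None:
            self._universe = _universe_from_atom_table(self.atom_table)
        return self._universe


def _universe_from_atom_table(atom_table: pd.DataFrame) -> mda.Universe:
    n_atoms = len(atom_table)
    resids = atom_table["resid"].to_numpy()
    chains = atom_table["chain"].astype(str).to_numpy()
    # consecutive (chain, resid) runs define residues
    boundary = np.ones(n_atoms, dtype=bool)
    boundary[1:] = (resids[1:] != resids[:-1]) | (chains[1:] != chains[:-1])
    resindex = np.cumsum(boundary) - 1
    n_res = int(resindex[-1]) + 1
    first = np.flatnonzero(boundary)
    u = mda.Universe.empty(
        n_atoms, n_residues=n_res, atom_resindex=resindex,
        residue_segindex=np.zeros(n_res, dtype=int), trajectory=False,
    )
    u.add_TopologyAttr("names", atom_table["name"].astype(str).to_numpy())
    u.add_TopologyAttr("resnames", atom_table["resname"].astype(str).to_numpy()[first])
    u.add_TopologyAttr("resids", resids[first])
    u.add_TopologyAttr("chainIDs", chains)
    u.add_TopologyAttr("segids", np.array(["SYSTEM"]))
    u.add_TopologyAttr("elements", np.array([""] * n_atoms))
    return u


def _atom_table_from_universe(u: mda.Universe) -> pd.DataFrame:
    atoms = u.atoms
    n = len(atoms)

    def attr(name, default):
        try:
            return np.asarray(getattr(atoms, name))
        except (AttributeError, mda.exceptions.NoDataError):
            return np.array([default] * n)

    return pd.DataFrame(
        {
            "name": attr("names", "X"),
            "resname": attr("resnames", "UNK"),
            "resid": attr("resids", 1).astype(int),
            "chain": attr("chainIDs", "A"),
        }
    )


def load_trajectory(
    topology_path: str | os.PathLike,
    trajectory_paths: list[str | os.PathLike] | None = None,
) -> TrajectoryEnsemble:
    """Read a topology plus one or more trajectory files into memory.

    Frames are concatenated in the given file order and indexed globally
    from 0.  Coordinates are returned in Angstrom regardless of the source
    format's native unit (MDAnalysis converts nm-based GRO/XTC/TRR).

    Parameters
    ----------
    topology_path
        PDB or GRO file defining the atoms.
    trajectory_paths
        DCD/XTC/TRR (or any MDAnalysis-readable) coordinate files, all with
        the same atom count as the topology.  If omitted, the topology's own
        coordinates form a single-frame ensemble.

    Raises
    ------
    InputError
        If a file is missing or unparseable (the message names the file).
    ConsistencyError
        If a trajectory's atom count differs from the topology's.
    """
    topology_path = os.fspath(topology_path)
    if not os.path.exists(topology_path):
        raise InputError(f"topology file not found: {topology_path}")
    try:
        with _quiet_mdanalysis():
            top = mda.Universe(topology_path)
    except Exception as exc:  # MDAnalysis raises many concrete types here
        raise InputError(f"could not parse topology {topology_path}: {exc}") from exc
    n_atoms = len(top.atoms)
    atom_table = _atom_table_from_universe(top)

    paths = [os.fspath(p) for p in (trajectory_paths or [])]
    if not paths:
        if not hasattr(top, "trajectory"):
            raise InputError(
                f"topology {topology_path} carries no coordinates and no "
                "trajectory files were given"
            )
        coords = np.stack([top.atoms.positions.copy().astype(np.float64)])
        return TrajectoryEnsemble(coords, atom_table, [], topology_path)

    blocks: list[np.ndarray] = []
    for path in paths:
        if not os.path.exists(path):
            raise InputError(f"trajectory file not found: {path}")
        try:
            with _quiet_mdanalysis():
                u = mda.Universe(topology_path, path)
        except ValueError as exc:
            # MDAnalysis signals reader/topology atom-count clashes as ValueError
            raise ConsistencyError(
                f"trajectory {path} is inconsistent with topology "
                f"{topology_path} ({n_atoms} atoms): {exc}"
            ) from exc
        except Exception as exc:
            raise InputError(f"could not read trajectory {path}: {exc}") from exc
        if len(u.atoms) != n_atoms:
            raise ConsistencyError(
                f"atom count mismatch: topology {topology_path} has {n_atoms} "
                f"atoms, trajectory {path} has {len(u.atoms)}"
            )
        with _quiet_mdanalysis():
            frames = np.empty((len(u.trajectory), n_atoms, 3), dtype=np.float64)
            for i, _ts in enumerate(u.trajectory):
                frames[i] = u.atoms.positions
        blocks.append(frames)

    return TrajectoryEnsemble(
        np.concatenate(blocks, axis=0), atom_table, paths, topology_path
    )


def select_atoms(ensemble: TrajectoryEnsemble, expression: str) -> AtomSelection:
    """Resolve a selection string against the ensemble's topology.

    The grammar is MDAnalysis's selection language; the subset exercised
    here is atom-name matches (``name CA``), residue ranges
    (``resid 120-160``), boolean ``and``/``or``, and the ``protein``
    shortcut.

    Raises
    ------
    SelectionError
        On a grammar error, or when the expression matches no atoms (an
        empty selection is never returned silently).
    """
    u = ensemble.topology_universe()
    try:
        group = u.select_atoms(expression)
    except _MDASelectionError as exc:
        raise SelectionError(f"cannot parse selection {expression!r}: {exc}") from exc
    if len(group) == 0:
        raise SelectionError(f"selection {expression!r} matched no atoms")
    return AtomSelection(expression, np.sort(group.ix.astype(np.intp)))


def full_selection(ensemble: TrajectoryEnsemble) -> AtomSelection:
    """The all-atoms selection for an ensemble."""
    return AtomSelection("all", np.arange(ensemble.n_atoms, dtype=np.intp))


def get_frame_coordinates(
    ensemble: TrajectoryEnsemble,
    frame_index: int,
    selection: AtomSelection | None = None,
) -> np.ndarray:
    """Return one frame's coordinates for the selected atoms (k, 3), Angstrom.

    Raises
    ------
    BoundsError
        If ``frame_index`` is outside ``[0, n_frames)``.
    """
    if not 0 <= frame_index < ensemble.n_frames:
        raise BoundsError(
            f"frame index {frame_index} out of range [0, {ensemble.n_frames})"
        )
    frame = ensemble.coordinates[frame_index]
    if selection is None:
        return frame.copy()
    return frame[selection.indices].copy()


def write_subsample(
    ensemble: TrajectoryEnsemble,
    sample: FrameSample,
    out_trajectory_path: str | os.PathLike,
    out_topology_path: str | os.PathLike | None = None,
    provenance_extra: dict | None = None,
) -> None:
    """Write the sampled frames to a trajectory file (plus companion topology).

    Frames are written in ascending original-index order, duplicates
    repeated when the sample was drawn with replacement.  A PDB of the first
    sampled frame is written as companion topology when
    ``out_topology_path`` is given, and a JSON provenance sidecar
    (``<trajectory>.provenance.json``) records inputs, sampler, seed and
    sizes.

    Raises
    ------
    InputError
        If an output path is unwritable.
    """
    sample.validate_for(ensemble.n_frames)
    out_trajectory_path = os.fspath(out_trajectory_path)

    u = ensemble.topology_universe()
    coords = ensemble.coordinates[sample.frame_indices].astype(np.float32)
    try:
        with _quiet_mdanalysis():
            u.load_new(coords, format=MemoryReader, order="fac")
            with mda.Writer(out_trajectory_path, n_atoms=ensemble.n_atoms) as w:
                for _ts in u.trajectory:
                    w.write(u.atoms)
            if out_topology_path is not None:
                u.trajectory[0]
                with mda.Writer(os.fspath(out_topology_path)) as w:
                    w.write(u.atoms)
    except OSError as exc:
        raise InputError(f"cannot write output: {exc}") from exc

    provenance = {
        "topology": ensemble.topology_file,
        "trajectories": list(ensemble.source_files),
        "sample": sample.to_dict(),
        "outputs": {
            "trajectory": out_trajectory_path,
            "topology": os.fspath(out_topology_path) if out_topology_path else None,
        },
    }
    if provenance_extra:
        provenance.update(provenance_extra)
    sidecar = out_trajectory_path + ".provenance.json"
    with open(sidecar, "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
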