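"""Synthetic protein-like trajectories and property series for testing.

Real MD datasets are too large to ship, so every test and example runs on a
generated stand-in: a Cα-only model protein whose trajectory hops between
two conformational states ("closed" and "open"), emulating a protein with a
mobile lid over a binding pocket — the classic open/close motion used to
monitor pocket accessibility.  The open state deforms the lid segment
non-rigidly (a smooth bulge along a fixed direction, largest mid-lid), so
the motion survives least-squares superposition and the RMSD distribution
is genuinely bimodal; a rigid shift of the whole selection would be removed
exactly by the superposition step and register as zero RMSD.

The generator is deterministic for a fixed seed and returns ground-truth
state labels and the ideal (noise-free) state templates, so sampling
strategies can be tested for parameter recovery against known truth.

Defaults model a 214-residue protein with the lid at residues 120-160 and
4000 frames, the scale of a modest production run.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from .errors import InputError
from .trajectory import FrameSample, TrajectoryEnsemble, write_subsample

__all__ = [
    "TwoStateSpec",
    "TwoStateTrajectory",
    "generate_two_state_trajectory",
    "generate_property_series",
    "write_fixture_files",
]


@dataclass
class TwoStateSpec:
    """Parameters of the two-state model trajectory.

    Attributes
    ----------
    n_frames : int
        Number of frames to generate.
    n_residues : int
        Length of the Cα-only chain (one atom per residue).
    open_fraction : float
        Probability that a frame is in the open state, in (0, 1).
    displacement : float
        Peak lid displacement in the open state, Angstrom.  This is the
        amplitude of the mid-lid bulge, not the superposed RMSD (which is
        smaller and is measured, not assumed, in tests).
    noise_sd : float
        Isotropic Gaussian positional noise per atom per frame, Angstrom.
    lid_range : tuple[int, int]
        First and last residue number (1-based, inclusive) of the mobile
        lid segment.
    seed : int
        Generator seed; identical specs produce bit-identical output.
    """

    n_frames: int = 4000
    n_residues: int = 214
    open_fraction: float = 0.5
    displacement: float = 5.0
    noise_sd: float = 0.3
    lid_range: tuple[int, int] = (120, 160)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_residues < 2:
            raise InputError("need n_frames >= 1 and n_residues >= 2")
        if not 0.0 < self.open_fraction < 1.0:
            raise InputError("open_fraction must be in (0, 1)")
        if self.displacement <= 0:
            raise InputError("displacement must be positive")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be nonnegative")
        lo, hi = self.lid_range
        if not 1 <= lo <= hi <= self.n_residues:
            raise InputError(
                f"lid_range {self.lid_range} must lie within [1, {self.n_residues}]"
            )


@dataclass
class TwoStateTrajectory:
    """Generator output: the ensemble plus ground truth for recovery tests."""

    ensemble: TrajectoryEnsemble
    labels: np.ndarray                      # "open"/"closed" per frame
    templates: dict[str, np.ndarray]        # ideal noise-free conformations
    spec: TwoStateSpec


def _backbone(n_residues: int) -> np.ndarray:
    """An idealized Cα trace: a helix with ~3.8 Å Cα-Cα spacing."""
    i = np.arange(n_residues, dtype=np.float64)
    angle = np.deg2rad(100.0) * i
    radius, rise = 2.3, 1.5
    return np.column_stack(
        [radius * np.cos(angle), radius * np.sin(angle), rise * i]
    )


def _lid_bulge(n_residues: int, lid_range: tuple[int, int],
               displacement: float) -> np.ndarray:
    """Per-atom open-state displacement: a sine bulge along +x over the lid.

    Zero at the lid hinges, peak ``displacement`` mid-lid; non-rigid by
    construction so superposition cannot absorb it.
    """
    shift = np.zeros((n_residues, 3))
    lo, hi = lid_range
    lid = np.arange(lo - 1, hi)            # residue numbers are 1-based
    t = (lid - (lo - 1) + 1) / (hi - lo + 2)
    shift[lid, 0] = displacement * np.sin(np.pi * t)
    return shift


def generate_two_state_trajectory(spec: TwoStateSpec) -> TwoStateTrajectory:
    """Generate a two-state Cα trajectory with ground-truth labels.

    Each frame is independently assigned to the open state with probability
    ``spec.open_fraction``; open frames add the lid bulge to the closed
    backbone; isotropic Gaussian noise of ``spec.noise_sd`` is then added to
    every atom.  Deterministic for a fixed spec (including seed).
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    closed = _backbone(spec.n_residues)
    open_ = closed + _lid_bulge(spec.n_residues, spec.lid_range, spec.displacement)

    is_open = rng.random(spec.n_frames) < spec.open_fraction
    coords = np.where(is_open[:, None, None], open_[None], closed[None]).copy()
    if spec.noise_sd > 0:
        coords += rng.normal(0.0, spec.noise_sd, size=coords.shape)

    atom_table = pd.DataFrame(
        {
            "name": ["CA"] * spec.n_residues,
            "resname": ["ALA"] * spec.n_residues,
            "resid": np.arange(1, spec.n_residues + 1),
            "chain": ["A"] * spec.n_residues,
        }
    )
    ensemble = TrajectoryEnsemble(coords, atom_table)
    labels = np.where(is_open, "open", "closed")
    return TwoStateTrajectory(
        ensemble, labels, {"closed": closed, "open": open_}, spec
    )


_FAMILIES = ("uniform", "gaussian", "mixture")


def generate_property_series(
    family: str, params: dict, n_frames: int, seed: int
):
    """Draw a synthetic per-frame property series from a named distribution.

    Supported families and their parameters:

    - ``uniform``: ``a``, ``b`` — bounds;
    - ``gaussian``: ``mu``, ``sigma`` (``sigma=0`` gives a constant series,
      useful to exercise degenerate-range handling downstream);
    - ``mixture``: two-component Gaussian mixture with ``mu1, sigma1,
      mu2, sigma2, pi`` where ``pi`` is the weight of component 1.

    Returns a :class:`~mdsieve.properties.PropertySeries` whose
    ``reference_descriptor`` records the generating family and parameters.
    """
    from .properties import PropertySeries

    rng = np.random.default_rng(seed)
    if family == "uniform":
        values = rng.uniform(params["a"], params["b"], size=n_frames)
    elif family == "gaussian":
        values = rng.normal(params["mu"], params["sigma"], size=n_frames)
    elif family == "mixture":
        pick1 = rng.random(n_frames) < params["pi"]
        comp1 = rng.normal(params["mu1"], params["sigma1"], size=n_frames)
        comp2 = rng.normal(params["mu2"], params["sigma2"], size=n_frames)
        values = np.where(pick1, comp1, comp2)
    else:
        raise InputError(
            f"unknown distribution family {family!r}; choose from {_FAMILIES}"
        )
    descriptor = f"{family}({', '.join(f'{k}={v}' for k, v in params.items())})"
    return PropertySeries(
        values, f"synthetic_{family}", reference_descriptor=descriptor
    )


def write_fixture_files(
    traj: TwoStateTrajectory,
    output_prefix: str | os.PathLike,
    formats: tuple[str, str] = ("pdb", "dcd"),
) -> dict[str, str]:
    """Write a generated trajectory to disk as real topology+trajectory
    files, plus the ground-truth labels CSV and the generating spec JSON.

    ``formats`` is (topology, trajectory), e.g. ``("pdb", "dcd")`` for
    Angstrom-native files or ``("gro", "xtc")`` for nm-native ones, so
    format readers and unit conversion are exercised on real files rather
    than mocks.  Returns the mapping of role to written path.
    """
    prefix = os.fspath(output_prefix)
    top_fmt, trj_fmt = formats
    ens = traj.ensemble
    all_frames = FrameSample(
        np.arange(ens.n_frames), "all", ens.n_frames, traj.spec.seed
    )
    paths = {
        "topology": f"{prefix}.{top_fmt}",
        "trajectory": f"{prefix}.{trj_fmt}",
        "labels": f"{prefix}_labels.csv",
        "spec": f"{prefix}_spec.json",
    }
    write_subsample(ens, all_frames, paths["trajectory"], paths["topology"])
    with open(paths["labels"], "w") as fh:
        fh.write("frame,state\n")
        for i, lab in enumerate(traj.labels):
            fh.write(f"{i},{lab}\n")
    with open(paths["spec"], "w") as fh:
        json.dump(asdict(traj.spec), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
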