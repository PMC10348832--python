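"""Per-frame scalar properties and their discretized distributions.

A *reference property* is one finite scalar per frame — RMSD to a reference
conformation, an inter-group centroid distance, a radius of gyration, or an
externally computed measure imported from a text file (cavity volume,
rescoring energy, ...).  Subsampling quality is judged on the property's
*distribution*, so this module also turns a series into a shared-edge
histogram (:class:`DiscreteDistribution`): bin edges always come from the
full series (or an explicit override), never from a subsample, which keeps
sampled and original histograms directly comparable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation as _Rotation

from .errors import (
    AlignmentError,
    ConsistencyError,
    DegenerateRangeError,
    InputError,
)
from .trajectory import AtomSelection, FrameSample, TrajectoryEnsemble

__all__ = [
    "PropertySeries",
    "DiscreteDistribution",
    "compute_rmsd_series",
    "compute_distance_series",
    "compute_rgyr_series",
    "import_property_series",
    "export_property_series",
    "discretize",
    "export_histogram_csv",
]


@dataclass
class PropertySeries:
    """One scalar per frame for a named property.

    ``units`` is Angstrom for the geometric properties computed here and
    caller-declared for imported series.  ``reference_descriptor`` records
    what an RMSD was measured against (e.g. ``"frame 0"`` or a file path);
    ``source_file`` is set when the series was imported from disk.
    """

    values: np.ndarray
    property_name: str
    units: str = ""
    selection_expression: str = ""
    reference_descriptor: str = ""
    source_file: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 1 or len(vals) == 0:
            raise ValueError("property series must be a non-empty 1-D array")
        if not np.isfinite(vals).all():
            raise ValueError("property series contains non-finite values")
        self.values = vals

    @property
    def n_frames(self) -> int:
        return len(self.values)


@dataclass
class DiscreteDistribution:
    """A histogram on explicit, shared bin edges.

    Bins are half-open ``[lo, hi)`` with the final bin closed on the right.
    ``probabilities`` are ``counts / counts.sum()``; when no value falls in
    the range (possible under an explicit range override) the probabilities
    are all zero, which downstream dissimilarity measures report as
    disjoint support (infinite distance) rather than an exception.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    probabilities: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        counts = np.asarray(self.counts, dtype=np.int64)
        if edges.ndim != 1 or len(edges) < 3:
            raise ValueError("need at least 2 bins (3 edges)")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(counts) != len(edges) - 1 or np.any(counts < 0):
            raise ValueError("counts must be nonnegative, one per bin")
        self.bin_edges = edges
        self.counts = counts
        total = counts.sum()
        if total > 0:
            self.probabilities = counts / float(total)
        else:
            self.probabilities = np.zeros(len(counts), dtype=np.float64)

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _selected(ensemble: TrajectoryEnsemble, selection: AtomSelection) -> np.ndarray:
    return ensemble.coordinates[:, selection.indices, :]


def compute_rmsd_series(
    ensemble: TrajectoryEnsemble,
    selection: AtomSelection,
    reference: np.ndarray | None = None,
) -> PropertySeries:
    """RMSD of each frame's selected atoms to a reference, after optimal
    rigid-body superposition (translation to common centroid plus
    least-squares Kabsch rotation).

    Parameters
    ----------
    reference
        ``(k, 3)`` coordinates matching the selection, in Angstrom.
        Defaults to frame 0 of the ensemble (the reproducible choice when
        no experimental structure is supplied).

    Raises
    ------
    ConsistencyError
        If the reference atom count differs from the selection's.
    ValueError
        If the selection has fewer than 3 atoms (superposition needs a
        non-degenerate point set).
    """
    if len(selection) < 3:
        raise ValueError(
            f"RMSD superposition needs >= 3 atoms, selection has {len(selection)}"
        )
    ref_descriptor = "frame 0"
    if reference is None:
        reference = ensemble.coordinates[0, selection.indices, :]
    else:
        reference = np.asarray(reference, dtype=np.float64)
        ref_descriptor = "user-supplied reference"
    if reference.shape != (len(selection), 3):
        raise ConsistencyError(
            f"reference has shape {reference.shape}, expected ({len(selection)}, 3)"
        )
    coords = _selected(ensemble, selection)
    ref_centered = reference - reference.mean(axis=0)
    values = np.empty(ensemble.n_frames, dtype=np.float64)
    for i in range(ensemble.n_frames):
        mobile = coords[i] - coords[i].mean(axis=0)
        # Kabsch via SVD (Wahba problem on centered point clouds); the
        # residual is evaluated explicitly rather than from the solver's
        # rssd, which loses precision to cancellation near zero RMSD
        rot, _rssd = _Rotation.align_vectors(ref_centered, mobile)
        residual = rot.apply(mobile) - ref_centered
        values[i] = np.sqrt(np.mean(np.sum(residual**2, axis=1)))
    return PropertySeries(
        values, "rmsd", "Å", selection.expression, ref_descriptor
    )


def compute_distance_series(
    ensemble: TrajectoryEnsemble,
    selection_a: AtomSelection,
    selection_b: AtomSelection,
) -> PropertySeries:
    """Per-frame Euclidean distance between the centroids of two selections."""
    ca = _selected(ensemble, selection_a).mean(axis=1)
    cb = _selected(ensemble, selection_b).mean(axis=1)
    values = np.linalg.norm(ca - cb, axis=1)
    return PropertySeries(
        values, "distance", "Å",
        f"({selection_a.expression}) to ({selection_b.expression})",
    )


def compute_rgyr_series(
    ensemble: TrajectoryEnsemble, selection: AtomSelection
) -> PropertySeries:
    """Per-frame unweighted radius of gyration of the selected atoms.

    Mass weighting is deliberately off: the property serves as a sampling
    coordinate, and the fixture topologies carry no reliable masses.
    """
    coords = _selected(ensemble, selection)
    centroids = coords.mean(axis=1, keepdims=True)
    sq = np.sum((coords - centroids) ** 2, axis=(1, 2)) / coords.shape[1]
    return PropertySeries(np.sqrt(sq), "rgyr", "Å", selection.expression)


def import_property_series(
    path: str | os.PathLike,
    n_frames: int,
    one_based: bool = False,
    property_name: str | None = None,
    units: str = "",
) -> PropertySeries:
    """Read a two-column text file (frame index, value) as a property series.

    The file may be whitespace- or comma-delimited, with an optional header
    line ``# property=<name> units=<units>``.  Exactly one value must be
    present for every frame ``0 .. n_frames-1`` (or ``1 .. n_frames`` with
    ``one_based=True`` for files written with 1-based frame numbering).

    Raises
    ------
    AlignmentError
        On missing, duplicate, or out-of-range frame indices (the message
        lists the offending indices; an off-by-one pattern suggests the
        ``one_based`` flag).
    InputError
        On a non-numeric value (the message gives the line number).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"property file not found: {path}")
    name = property_name or os.path.splitext(os.path.basename(path))[0]
    seen: dict[int, float] = {}
    duplicates: list[int] = []
    out_of_range: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            if text.startswith("#"):
                for token in text[1:].split():
                    if token.startswith("property="):
                        name = property_name or token[len("property="):]
                    elif token.startswith("units="):
                        units = units or token[len("units="):]
                continue
            parts = text.replace(",", " ").split()
            if len(parts) != 2:
                raise InputError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            try:
                idx = int(parts[0])
                value = float(parts[1])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-numeric entry: {exc}") from exc
            if one_based:
                idx -= 1
            if not 0 <= idx < n_frames:
                out_of_range.append(idx if not one_based else idx + 1)
            elif idx in seen:
                duplicates.append(idx)
            else:
                seen[idx] = value
    if out_of_range:
        hint = (
            "; file may use 1-based frame numbers (use one_based=True / --one-based)"
            if not one_based and max(out_of_range) == n_frames
            else ""
        )
        raise AlignmentError(
            f"{path}: frame indices out of range [0, {n_frames}): "
            f"{sorted(out_of_range)[:10]}{hint}"
        )
    if duplicates:
        raise AlignmentError(
            f"{path}: duplicate frame indices: {sorted(set(duplicates))[:10]}"
        )
    missing = sorted(set(range(n_frames)) - seen.keys())
    if missing:
        raise AlignmentError(
            f"{path}: no value for frames {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    values = np.array([seen[i] for i in range(n_frames)])
    return PropertySeries(values, name, units, source_file=path)


def export_property_series(
    series: PropertySeries,
    path: str | os.PathLike,
    frame_indices: np.ndarray | None = None,
) -> None:
    """Write a series (optionally restricted to sampled frames) as
    two-column text with a ``# property=... units=...`` header."""
    indices = (
        np.arange(series.n_frames) if frame_indices is None
        else np.asarray(frame_indices, dtype=np.intp)
    )
    with open(os.fspath(path), "w") as fh:
        fh.write(f"# property={series.property_name} units={series.units}\n")
        for i in indices:
            fh.write(f"{int(i)} {series.values[i]:.10g}\n")


def discretize(
    series: PropertySeries,
    n_bins: int = 100,
    range_override: tuple[float, float] | None = None,
    restrict_to: FrameSample | None = None,
) -> DiscreteDistribution:
    """Histogram a property series on equal-width bins.

    Edges span the min-max of the *full* series (or ``range_override``),
    regardless of ``restrict_to``, so a subsample's histogram shares edges
    with the full trajectory's.  When ``restrict_to`` is given, only the
    sampled frames are counted, with multiplicity for bootstrap samples.
    Bins are ``[lo, hi)``, the final bin closed on the right.

    Raises
    ------
    DegenerateRangeError
        If the series has zero variance and no range override is given.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if range_override is not None:
        lo, hi = float(range_override[0]), float(range_override[1])
        if not lo < hi:
            raise ValueError(f"range override needs lo < hi, got ({lo}, {hi})")
    else:
        lo, hi = float(series.values.min()), float(series.values.max())
        if lo == hi:
            raise DegenerateRangeError(
                f"property {series.property_name!r} is constant ({lo}); "
                "pass an explicit range to bin it"
            )
    edges = np.linspace(lo, hi, n_bins + 1)
    if restrict_to is not None:
        restrict_to.validate_for(series.n_frames)
        values = series.values[restrict_to.frame_indices]
    else:
        values = series.values
    counts, _ = np.histogram(values, bins=edges)
    return DiscreteDistribution(edges, counts)


def bin_index_of(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Map values to bin indices under the same edge convention as
    :func:`discretize` (half-open bins, last closed); -1 for out-of-range."""
    values = np.asarray(values, dtype=np.float64)
    idx = np.searchsorted(edges, values, side="right") - 1
    idx[values == edges[-1]] = len(edges) - 2
    idx[(values < edges[0]) | (values > edges[-1])] = -1
    return idx


def export_histogram_csv(dist: DiscreteDistribution, path: str | os.PathLike) -> None:
    """Write a histogram as CSV with columns bin_lo, bin_hi, count, probability."""
    with open(os.fspath(path), "w") as fh:
        fh.write("bin_lo,bin_hi,count,probability\n")
        for i in range(dist.n_bins):
            fh.write(
                f"{dist.bin_edges[i]:.10g},{dist.bin_edges[i + 1]:.10g},"
                f"{int(dist.counts[i])},{dist.probabilities[i]:.10g}\n"
            )
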