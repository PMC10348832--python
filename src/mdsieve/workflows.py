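"""End-to-end subsampling workflows.

Three scenarios compose the lower-level modules:

- **size sweep** (:func:`find_minimal_sample_size`): find the smallest
  random subsample whose reference-property distribution still matches the
  full trajectory's, judged by mean Bhattacharyya distance over replicate
  draws against a user threshold;
- **pocket** (:func:`run_pocket_scenario`): uniform-over-range sampling on
  the lid RMSD so every degree of pocket opening is equally represented —
  conformer selection for ensemble docking;
- **frequency** (:func:`run_frequency_scenario`): weighted sampling with
  per-frame chance proportional to the frequency of the frame's property
  value — favours the most populated conformational states.

plus :func:`export_ml_tensors`, which writes sampled coordinates as a flat
float32 tensor with a train/test split manifest for machine-learning
pipelines.

Every workflow writes a JSON provenance record holding all inputs, seeds
and parameters; :func:`replay` re-executes a workflow from that record so
any result can be reproduced bit-identically.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .dissimilarity import compare_sample
from .errors import InputError, SampleSizeError
from .properties import (
    PropertySeries,
    compute_rmsd_series,
    discretize,
    export_histogram_csv,
    export_property_series,
    import_property_series,
)
from .samplers import sample_random, sample_uniform, sample_weighted, weights_from_frequency
from .trajectory import (
    AtomSelection,
    FrameSample,
    TrajectoryEnsemble,
    get_frame_coordinates,
    load_trajectory,
    select_atoms,
    write_subsample,
)

__all__ = [
    "SizeSweepReport",
    "MLExportManifest",
    "resolve_size",
    "find_minimal_sample_size",
    "run_pocket_scenario",
    "run_frequency_scenario",
    "export_ml_tensors",
    "replay",
]


def resolve_size(size: int | float | str, n_frames: int) -> int:
    """Convert a size given as an absolute count or a percentage string
    (``"2.5%"``) to a frame count, rounding half up.

    Raises
    ------
    SampleSizeError
        If a percentage rounds to 0 frames, or a count is out of range.
    """
    if isinstance(size, str):
        text = size.strip()
        if text.endswith("%"):
            pct = float(text[:-1])
            count = math.floor(n_frames * pct / 100.0 + 0.5)
            if count == 0:
                raise SampleSizeError(
                    f"size {size!r} rounds to 0 frames of {n_frames}"
                )
        else:
            try:
                count = int(text)
            except ValueError:
                raise InputError(
                    f"size must be an integer count or a percentage with "
                    f"trailing '%', got {size!r}"
                ) from None
    else:
        if isinstance(size, float) and not size.is_integer():
            raise InputError(
                f"fractional size {size} is ambiguous; use an integer count "
                "or a percentage string like '2.5%'"
            )
        count = int(size)
    if not 1 <= count <= n_frames:
        raise SampleSizeError(
            f"size {size!r} -> {count} frames is outside [1, {n_frames}]"
        )
    return count


@dataclass
class SizeSweepReport:
    """Per-size dissimilarity statistics and the selected minimal size.

    ``selected_size`` is the smallest grid size whose MEAN distance over
    replicates is at or below ``threshold`` (None when no size qualifies).
    """

    size_grid: list[int]
    requested_grid: list          # as given by the caller (counts or "x%")
    mean_distance: list[float]
    sd_distance: list[float]
    n_replicates: int
    threshold: float
    n_bins: int
    seed: int
    selected_size: int | None = field(init=False)

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.size_grid, self.size_grid[1:])):
            raise ValueError("size grid must be strictly increasing")
        self.selected_size = None
        for size, mean in zip(self.size_grid, self.mean_distance):
            if mean <= self.threshold:
                self.selected_size = size
                break

    def to_dict(self) -> dict:
        return {
            "size_grid": self.size_grid,
            "requested_grid": [str(s) for s in self.requested_grid],
            "mean_distance": self.mean_distance,
            "sd_distance": self.sd_distance,
            "n_replicates": self.n_replicates,
            "threshold": self.threshold,
            "n_bins": self.n_bins,
            "seed": self.seed,
            "selected_size": self.selected_size,
        }

    def write_csv(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            fh.write("size,mean_distance,sd_distance,n_replicates\n")
            for s, m, sd in zip(self.size_grid, self.mean_distance, self.sd_distance):
                fh.write(f"{s},{m:.10g},{sd:.10g},{self.n_replicates}\n")


def find_minimal_sample_size(
    series: PropertySeries,
    size_grid: list[int | float | str],
    threshold: float,
    n_replicates: int = 50,
    n_bins: int = 100,
    seed: int = 0,
) -> SizeSweepReport:
    """Sweep random-sample sizes to find the smallest one preserving the
    property distribution.

    For each candidate size, ``n_replicates`` random samples are drawn and
    the Bhattacharyya distance between the sampled and full property
    histograms (shared edges, ``n_bins`` bins) is averaged; selection is on
    the mean, not a single draw, because a single random draw makes the
    criterion unstable.  Replicate ``r`` of each size uses a generator
    stream derived from ``(seed, size, r)``.

    Raises
    ------
    SampleSizeError
        If a percentage grid entry rounds to 0 frames (the message names
        the entry).
    """
    if not size_grid:
        raise InputError("size grid is empty")
    if not threshold > 0:
        raise InputError(f"threshold must be positive, got {threshold}")
    counts = [resolve_size(s, series.n_frames) for s in size_grid]
    order = np.argsort(counts, kind="stable")
    counts_sorted = [counts[i] for i in order]
    requested_sorted = [size_grid[i] for i in order]
    if len(set(counts_sorted)) != len(counts_sorted):
        raise InputError(f"size grid resolves to duplicate counts: {counts_sorted}")

    means, sds = [], []
    for size in counts_sorted:
        distances = np.empty(n_replicates)
        for r in range(n_replicates):
            sub_seed = int(
                np.random.SeedSequence([seed, size, r]).generate_state(1)[0] >> 1
            )
            sample = sample_random(series.n_frames, size, sub_seed)
            distances[r] = compare_sample(series, sample, n_bins=n_bins).value
        means.append(float(np.mean(distances)))
        sds.append(float(np.std(distances, ddof=1)) if n_replicates > 1 else 0.0)
    return SizeSweepReport(
        counts_sorted, requested_sorted, means, sds,
        n_replicates, float(threshold), n_bins, seed,
    )


def _write_provenance(prefix: str, record: dict) -> str:
    path = f"{prefix}.provenance.json"
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def run_pocket_scenario(
    ensemble: TrajectoryEnsemble,
    lid_selection: AtomSelection,
    reference: np.ndarray | None,
    size: int | str,
    n_strata: int,
    seed: int,
    output_prefix: str | os.PathLike,
    n_bins: int = 100,
) -> FrameSample:
    """Uniform-over-range sampling on the lid RMSD (pocket-opening monitor).

    Computes the RMSD series of the lid selection against ``reference``
    (frame 0 when None), samples an equal number of frames per RMSD
    stratum, and writes the subsampled trajectory (DCD + PDB topology), the
    sampled property file, full and sampled histogram CSVs, and a
    provenance record.
    """
    prefix = os.fspath(output_prefix)
    count = resolve_size(size, ensemble.n_frames)
    series = compute_rmsd_series(ensemble, lid_selection, reference)
    sample = sample_uniform(series, count, n_strata, seed)

    write_subsample(ensemble, sample, f"{prefix}_sample.dcd", f"{prefix}_sample.pdb")
    export_property_series(series, f"{prefix}_property.dat")
    export_property_series(series, f"{prefix}_sample_property.dat",
                           sample.frame_indices)
    full_hist = discretize(series, n_bins=n_bins)
    sub_hist = discretize(
        series, n_bins=n_bins,
        range_override=(full_hist.bin_edges[0], full_hist.bin_edges[-1]),
        restrict_to=sample,
    )
    export_histogram_csv(full_hist, f"{prefix}_hist_full.csv")
    export_histogram_csv(sub_hist, f"{prefix}_hist_sample.csv")
    _write_provenance(prefix, {
        "workflow": "pocket",
        "topology": ensemble.topology_file,
        "trajectories": list(ensemble.source_files),
        "selection": lid_selection.expression,
        "reference": series.reference_descriptor,
        "size": str(size),
        "n_strata": n_strata,
        "n_bins": n_bins,
        "seed": seed,
        "sample": sample.to_dict(),
    })
    return sample


def run_frequency_scenario(
    series: PropertySeries,
    size: int | str,
    n_bins: int,
    seed: int,
    output_prefix: str | os.PathLike,
    ensemble: TrajectoryEnsemble | None = None,
    replacement: bool = False,
) -> FrameSample:
    """Weighted sampling by frequency of the reference property.

    Each frame's selection chance is proportional to the probability mass
    of its property bin, so heavily populated conformational states
    dominate the sample.  Writes the per-frame weights, the sampled
    property file, histogram CSVs, the subsampled trajectory when an
    ensemble is supplied, and a provenance record noting the weight
    construction.
    """
    prefix = os.fspath(output_prefix)
    count = resolve_size(size, series.n_frames)
    weights = weights_from_frequency(series, n_bins=n_bins)
    sample = sample_weighted(weights, count, seed, replacement=replacement)

    with open(f"{prefix}_weights.dat", "w") as fh:
        fh.write("# property=frequency_weight units=probability\n")
        for i, w in enumerate(weights.normalized()):
            fh.write(f"{i} {w:.10g}\n")
    export_property_series(series, f"{prefix}_sample_property.dat",
                           sample.frame_indices)
    full_hist = discretize(series, n_bins=n_bins)
    sub_hist = discretize(
        series, n_bins=n_bins,
        range_override=(full_hist.bin_edges[0], full_hist.bin_edges[-1]),
        restrict_to=sample,
    )
    export_histogram_csv(full_hist, f"{prefix}_hist_full.csv")
    export_histogram_csv(sub_hist, f"{prefix}_hist_sample.csv")
    if ensemble is not None:
        write_subsample(ensemble, sample, f"{prefix}_sample.dcd",
                        f"{prefix}_sample.pdb")
    _write_provenance(prefix, {
        "workflow": "frequency",
        "property_file": series.source_file or None,
        "property_name": series.property_name,
        "topology": ensemble.topology_file if ensemble is not None else None,
        "trajectories": list(ensemble.source_files) if ensemble is not None else [],
        "weight_rule": "per-frame weight = probability mass of the frame's "
                       "property bin, normalized over frames",
        "size": str(size),
        "n_bins": n_bins,
        "seed": seed,
        "replacement": replacement,
        "sample": sample.to_dict(),
    })
    return sample


@dataclass
class MLExportManifest:
    """Description of an exported coordinate tensor and its train/test split."""

    tensor_path: str
    shape: tuple[int, int, int]          # (n_frames, n_atoms_selected, 3)
    dtype: str                           # numpy dtype string, e.g. "<f4"
    order: str                           # index order of the flat binary
    train_indices: list[int]             # positions within the tensor
    test_indices: list[int]
    seed: int
    frame_indices: list[int]             # original global frame indices

    def to_dict(self) -> dict:
        return {
            "tensor_path": self.tensor_path,
            "shape": list(self.shape),
            "dtype": self.dtype,
            "order": self.order,
            "train_indices": self.train_indices,
            "test_indices": self.test_indices,
            "seed": self.seed,
            "frame_indices": self.frame_indices,
        }


def export_ml_tensors(
    ensemble: TrajectoryEnsemble,
    sample: FrameSample,
    selection: AtomSelection,
    train_fraction: float,
    seed: int,
    output_prefix: str | os.PathLike,
) -> MLExportManifest:
    """Write sampled coordinates as an ML-ready flat binary tensor.

    The file holds 32-bit little-endian floats in frame-major (frame, atom,
    xyz) order — ``n_frames * n_atoms * 3 * 4`` bytes — alongside a JSON
    manifest recording shape, encoding, the original frame indices, and a
    seeded uniformly-shuffled train/test split of tensor positions.
    """
    if not 0.0 < train_fraction < 1.0:
        raise InputError(f"train_fraction must be in (0, 1), got {train_fraction}")
    sample.validate_for(ensemble.n_frames)
    prefix = os.fspath(output_prefix)
    tensor = ensemble.coordinates[sample.frame_indices][:, selection.indices, :]
    tensor = tensor.astype("<f4")
    tensor_path = f"{prefix}.bin"
    try:
        tensor.tofile(tensor_path)
    except OSError as exc:
        raise InputError(f"cannot write tensor {tensor_path}: {exc}") from exc

    n = tensor.shape[0]
    n_train = int(math.floor(n * train_fraction + 0.5))
    n_train = min(max(n_train, 0), n)
    perm = np.random.default_rng(seed).permutation(n)
    manifest = MLExportManifest(
        tensor_path=tensor_path,
        shape=tuple(int(s) for s in tensor.shape),
        dtype="<f4",
        order="frame,atom,xyz",
        train_indices=sorted(int(i) for i in perm[:n_train]),
        test_indices=sorted(int(i) for i in perm[n_train:]),
        seed=seed,
        frame_indices=[int(i) for i in sample.frame_indices],
    )
    with open(f"{prefix}.manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_provenance(prefix, {
        "workflow": "ml_export",
        "topology": ensemble.topology_file,
        "trajectories": list(ensemble.source_files),
        "selection": selection.expression,
        "train_fraction": train_fraction,
        "seed": seed,
        "sample": sample.to_dict(),
    })
    return manifest


def replay(provenance_path: str | os.PathLike, output_prefix: str | os.PathLike):
    """Re-run a workflow from its provenance record.

    Reads the JSON written by a previous run, reloads the recorded inputs,
    and re-executes with the recorded parameters and seed, writing to
    ``output_prefix``.  With unchanged input files the outputs are
    bit-identical to the original run's.

    Raises
    ------
    InputError
        If the record's workflow is unknown, or the original inputs were
        in-memory only (no file paths recorded) and cannot be reloaded.
    """
    with open(os.fspath(provenance_path)) as fh:
        record = json.load(fh)
    workflow = record.get("workflow")

    def _load_recorded_ensemble() -> TrajectoryEnsemble:
        if not record.get("topology") or not record.get("trajectories"):
            raise InputError(
                f"{provenance_path}: no input files recorded; the original "
                "run used an in-memory ensemble and cannot be replayed"
            )
        return load_trajectory(record["topology"], record["trajectories"])

    if workflow == "pocket":
        ensemble = _load_recorded_ensemble()
        selection = select_atoms(ensemble, record["selection"])
        reference = None
        if record["reference"] != "frame 0":
            raise InputError(
                "replay of a user-supplied RMSD reference requires the "
                "original reference coordinates, which are not stored"
            )
        return run_pocket_scenario(
            ensemble, selection, reference, record["size"],
            record["n_strata"], record["seed"], output_prefix,
            n_bins=record["n_bins"],
        )
    if workflow == "frequency":
        ensemble = None
        if record.get("topology") and record.get("trajectories"):
            ensemble = _load_recorded_ensemble()
        if record.get("property_file"):
            n_frames = record["sample"]["requested_size"]  # lower bound only
            n_frames = _sniff_property_length(record["property_file"])
            series = import_property_series(record["property_file"], n_frames)
        elif ensemble is not None and record.get("property_name") == "rmsd":
            sel = select_atoms(ensemble, record.get("selection", "name CA"))
            series = compute_rmsd_series(ensemble, sel)
        else:
            raise InputError(
                f"{provenance_path}: property series cannot be reconstructed"
            )
        return run_frequency_scenario(
            series, record["size"], record["n_bins"], record["seed"],
            output_prefix, ensemble=ensemble,
            replacement=record.get("replacement", False),
        )
    if workflow == "ml_export":
        ensemble = _load_recorded_ensemble()
        selection = select_atoms(ensemble, record["selection"])
        sample = FrameSample(
            np.array(record["sample"]["frame_indices"], dtype=np.intp),
            record["sample"]["strategy"],
            record["sample"]["requested_size"],
            record["sample"]["seed"],
            replacement=record["sample"]["replacement"],
            shortfall=record["sample"]["shortfall"],
        )
        return export_ml_tensors(
            ensemble, sample, selection, record["train_fraction"],
            record["seed"], output_prefix,
        )
    raise InputError(f"{provenance_path}: unknown workflow {workflow!r}")


def _sniff_property_length(path: str) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            text = line.strip()
            if text and not text.startswith("#"):
                n += 1
    return n
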